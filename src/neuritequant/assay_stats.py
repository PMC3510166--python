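"""Plate-assay and qPCR reductions plus the statistical battery.

G-LISA absorbance (OD 490 nm) is used directly as RhoA activity and
BrdU absorbance (OD 450–540 nm) as proliferation; percent changes are
arithmetic on condition means and therefore invariant to rescaling all
ODs by a common factor.  qPCR is reduced by the ΔΔCt method with an
amplification efficiency of 2 (fold = 2^(−ΔΔCt) against a
housekeeping gene).  The statistical battery covers one-way ANOVA,
repeated-measures ANOVA (treatment × subject fixed-effects
decomposition) and the paired t test, with Bonferroni-corrected
pairwise post-hoc comparisons at a configurable alpha.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "AssayTable",
    "StatResult",
    "ActivityResult",
    "activity_reduction",
    "proliferation_change",
    "dose_response",
    "qpcr_fold_change",
    "run_stats",
]

_WAVELENGTH = {"glisa": "490 nm", "brdu": "450-540 nm"}


@dataclass
class AssayTable:
    """Long-format absorbance table: (condition, replicate, od)."""

    assay: str  # "glisa" or "brdu"
    data: pd.DataFrame

    def __post_init__(self) -> None:
        if self.assay not in _WAVELENGTH:
            raise ValueError(f"unknown assay {self.assay!r}")
        missing = {"condition", "replicate", "od"} - set(self.data.columns)
        if missing:
            raise ValueError(f"assay table missing columns {sorted(missing)}")
        if (self.data["od"] < 0).any():
            raise ValueError("OD values must be >= 0")

    @property
    def wavelength(self) -> str:
        return _WAVELENGTH[self.assay]

    def condition_values(self, condition: str) -> np.ndarray:
        vals = self.data.loc[self.data["condition"] == condition, "od"]
        if vals.empty:
            raise KeyError(f"condition {condition!r} not in table")
        return vals.to_numpy(dtype=float)


@dataclass
class ActivityResult:
    """Percent change of an OD readout between two conditions."""

    treated: str
    reference: str
    percent_reduction: float  # positive = reduction, negative = increase
    treated_mean: float
    reference_mean: float


def _percent_change(table: AssayTable, treated: str,
                    reference: str) -> ActivityResult:
    t = table.condition_values(treated)
    r = table.condition_values(reference)
    r_mean = float(r.mean())
    if r_mean <= 0:
        raise ValueError("reference mean OD must be > 0")
    t_mean = float(t.mean())
    return ActivityResult(treated=treated, reference=reference,
                          percent_reduction=(1.0 - t_mean / r_mean) * 100.0,
                          treated_mean=t_mean, reference_mean=r_mean)


def activity_reduction(table: AssayTable, treated: str,
                       reference: str = "control") -> ActivityResult:
    """Percent reduction in mean G-LISA OD (RhoA activity) vs. reference."""
    if table.assay != "glisa":
        raise ValueError("activity_reduction expects a glisa table")
    return _percent_change(table, treated, reference)


def proliferation_change(table: AssayTable, treated: str,
                         reference: str = "control") -> ActivityResult:
    """Percent change in mean BrdU OD (proliferation) vs. reference.

    Sign convention: positive values are reductions; an increase shows
    as a negative percent reduction (e.g. swapping a 25%-reduced pair
    gives −33.3%, since 1 − 1/0.75 = −1/3).
    """
    if table.assay != "brdu":
        raise ValueError("proliferation_change expects a brdu table")
    return _percent_change(table, treated, reference)


def dose_response(table: AssayTable,
                  condition_doses: Mapping[str, float],
                  reference: str = "control") -> pd.DataFrame:
    """Percent reduction vs. dose, ordered by increasing dose."""
    rows = []
    for condition, dose in condition_doses.items():
        res = _percent_change(table, condition, reference)
        rows.append({"dose": dose, "condition": condition,
                     "mean_od": res.treated_mean,
                     "percent_reduction": res.percent_reduction})
    return pd.DataFrame(rows).sort_values("dose", ignore_index=True)


def qpcr_fold_change(ct_table: pd.DataFrame, gene: str,
                     reference_gene: str = "gapdh",
                     control_condition: str = "control",
                     treated_condition: str | None = None) -> float:
    """ΔΔCt fold change of ``gene`` in treated vs. control.

    ΔCt = mean Ct(gene) − mean Ct(reference gene) per condition
    (triplicates averaged); fold = 2^(−ΔΔCt).  The round trip with the
    synthetic Ct generator is exact in the noiseless limit.
    """
    genes = set(ct_table["gene"].unique())
    for g in (gene, reference_gene):
        if g not in genes:
            raise ValueError(f"unknown gene label {g!r}")
    conditions = list(ct_table["condition"].unique())
    if treated_condition is None:
        others = [c for c in conditions if c != control_condition]
        if len(others) != 1:
            raise ValueError("treated_condition is ambiguous; pass it")
        treated_condition = others[0]

    def mean_ct(condition: str, g: str) -> float:
        sel = ct_table[(ct_table["condition"] == condition)
                       & (ct_table["gene"] == g)]["ct"]
        if len(sel) < 3:
            raise ValueError(
                f"missing triplicates for {g!r} in {condition!r}")
        return float(sel.mean())

    d_ct_treated = mean_ct(treated_condition, gene) \
        - mean_ct(treated_condition, reference_gene)
    d_ct_control = mean_ct(control_condition, gene) \
        - mean_ct(control_condition, reference_gene)
    dd_ct = d_ct_treated - d_ct_control
    return float(2.0 ** (-dd_ct))


@dataclass
class StatResult:
    """Classical test result with Bonferroni post-hoc flags."""

    test: str
    statistic: float  # F or t
    df: tuple[float, float]
    p_value: float
    alpha: float = 0.05
    posthoc: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if not (np.isnan(self.p_value) or 0.0 <= self.p_value <= 1.0):
            raise ValueError("p-value outside [0, 1]")


def _bonferroni_pairs(groups: Mapping[str, np.ndarray],
                      alpha: float) -> pd.DataFrame:
    names = list(groups)
    pairs = list(itertools.combinations(names, 2))
    n_pairs = len(pairs)
    rows = []
    for a, b in pairs:
        t, p = sps.ttest_ind(groups[a], groups[b])
        p_adj = min(float(p) * n_pairs, 1.0)
        rows.append({"pair": f"{a} vs {b}", "t": float(t),
                     "p_raw": float(p), "p_bonferroni": p_adj,
                     "significant": p_adj < alpha})
    return pd.DataFrame(rows)


def run_stats(groups: Mapping[str, Sequence[float]],
              design: str = "one_way", alpha: float = 0.05) -> StatResult:
    """One-way ANOVA, repeated-measures ANOVA or paired t test.

    ``groups`` maps condition name to its sample; for the repeated-
    measures design the i-th entry of every group is the same subject
    (imaging position), so the design must be balanced — an unbalanced
    group raises an error naming it.
    """
    arrays = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    if len(arrays) < 2:
        raise ValueError("need at least two groups")

    if design == "one_way":
        f, p = sps.f_oneway(*arrays.values())
        k = len(arrays)
        n = sum(a.size for a in arrays.values())
        return StatResult(test="one-way ANOVA", statistic=float(f),
                          df=(k - 1, n - k), p_value=float(p), alpha=alpha,
                          posthoc=_bonferroni_pairs(arrays, alpha))

    if design == "repeated_measures":
        sizes = {k: a.size for k, a in arrays.items()}
        n = next(iter(sizes.values()))
        bad = [k for k, s in sizes.items() if s != n]
        if bad:
            raise ValueError(
                f"unbalanced repeated-measures design: group {bad[0]!r} "
                f"has {sizes[bad[0]]} subjects, expected {n}")
        data = np.column_stack(list(arrays.values()))  # (subjects, k)
        k = data.shape[1]
        grand = data.mean()
        ss_treat = n * np.sum((data.mean(axis=0) - grand) ** 2)
        ss_subj = k * np.sum((data.mean(axis=1) - grand) ** 2)
        ss_tot = np.sum((data - grand) ** 2)
        ss_err = ss_tot - ss_treat - ss_subj
        df_treat = k - 1
        df_err = (k - 1) * (n - 1)
        ms_treat = ss_treat / df_treat
        ms_err = ss_err / df_err if df_err > 0 else np.nan
        f = ms_treat / ms_err if ms_err > 0 else 0.0
        p = float(sps.f.sf(f, df_treat, df_err)) if ms_err > 0 else 1.0
        return StatResult(test="repeated-measures ANOVA", statistic=float(f),
                          df=(df_treat, df_err), p_value=p, alpha=alpha,
                          posthoc=_bonferroni_pairs(arrays, alpha))

    if design == "paired_t":
        if len(arrays) != 2:
            raise ValueError("paired t test needs exactly two groups")
        a, b = arrays.values()
        if a.size != b.size:
            raise ValueError("paired vectors must have equal length")
        t, p = sps.ttest_rel(a, b)
        return StatResult(test="paired t", statistic=float(t),
                          df=(float(a.size - 1), 0.0), p_value=float(p),
                          alpha=alpha)

    raise ValueError(f"unknown design {design!r}")
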