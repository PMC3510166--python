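"""Condition-level quantification: time courses, fold changes, rescue.

Fold changes are computed on means of per-image values (s.e.m. over
images, n = images), the convention used for image-based readouts of
10 images per condition; time courses report per-position curves and
mean ± s.e.m. over positions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .segmentation import (
    MissingDenominatorError,
    PixelClassifier,
    neurite_length_per_cell,
    segment,
)
from .synthetic import Scene

__all__ = [
    "TimeCourse",
    "ConditionReport",
    "RescueReport",
    "timecourse_from_scenes",
    "fold_change",
    "rescue_analysis",
    "plot_timecourse",
    "plot_rescue",
]


@dataclass
class TimeCourse:
    """Neurite length/cell vs. time for one condition.

    ``values`` is (n_positions, n_frames) in µm/cell; frames where no
    nuclei were detected hold NaN (missing, never zero).
    """

    condition: str
    timestamps: np.ndarray  # minutes, strictly increasing
    values: np.ndarray

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if np.any(np.diff(self.timestamps) <= 0):
            raise ValueError("timestamps must be strictly increasing")
        if self.values.shape[1] != self.timestamps.size:
            raise ValueError("values and timestamps length mismatch")

    @property
    def n_positions(self) -> int:
        return self.values.shape[0]

    def mean(self) -> np.ndarray:
        return np.nanmean(self.values, axis=0)

    def sem(self) -> np.ndarray:
        n = np.sum(~np.isnan(self.values), axis=0)
        return np.nanstd(self.values, axis=0, ddof=1) / np.sqrt(
            np.maximum(n, 1))

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for p in range(self.n_positions):
            for t, v in zip(self.timestamps, self.values[p]):
                rows.append({"condition": self.condition, "position": p,
                             "minute": t, "value": v})
        return pd.DataFrame(rows)


def timecourse_from_scenes(positions: Sequence[Sequence[Scene]],
                           classifier: PixelClassifier,
                           timestamps: Sequence[float] | None = None,
                           condition: str | None = None) -> TimeCourse:
    """Segment every frame of every position and measure length/cell.

    ``positions`` is a list of positions, each a list of frames
    (Scenes with both channels).  Timestamps default to the
    ``t_minutes`` metadata of the first position.  Frames with zero
    detected nuclei yield NaN.
    """
    if len(positions) == 0:
        raise ValueError("need at least one position series")
    n_frames = len(positions[0])
    if any(len(p) != n_frames for p in positions):
        raise ValueError("all positions must have the same frame count")
    if timestamps is None:
        timestamps = [s.metadata.get("t_minutes", i)
                      for i, s in enumerate(positions[0])]
    values = np.full((len(positions), n_frames), np.nan)
    for pi, frames in enumerate(positions):
        for fi, scene in enumerate(frames):
            segmap = segment(scene.green, classifier, dapi=scene.dapi,
                             pixel_size=scene.pixel_size)
            try:
                values[pi, fi] = neurite_length_per_cell(segmap)
            except MissingDenominatorError:
                values[pi, fi] = np.nan  # missing, not zero
    cond = condition or (positions[0][0].condition if positions[0] else "")
    return TimeCourse(condition=cond, timestamps=np.asarray(timestamps),
                      values=values)


@dataclass
class ConditionReport:
    """Fold change between a treated and a reference condition."""

    treated: str
    reference: str
    fold_change: float
    percent_change: float  # (1 - fold)*100 for reductions, else increase %
    treated_mean: float
    reference_mean: float
    treated_sem: float
    reference_sem: float
    n_treated: int
    n_reference: int


def _sem(x: np.ndarray) -> float:
    x = np.asarray(x, float)
    return float(np.std(x, ddof=1) / np.sqrt(len(x))) if len(x) > 1 else 0.0


def fold_change(treated, reference, treated_name: str = "treated",
                reference_name: str = "reference") -> ConditionReport:
    """Mean(treated)/mean(reference) with the percent-change convention
    that a reduction (fold < 1) is reported as (1 − fold)·100 %."""
    treated = np.asarray(treated, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if treated.size == 0 or reference.size == 0:
        raise ValueError("both condition samples must be non-empty")
    ref_mean = float(np.mean(reference))
    if ref_mean <= 0:
        raise ValueError("reference mean must be > 0")
    fold = float(np.mean(treated) / ref_mean)
    percent = (1.0 - fold) * 100.0 if fold < 1 else (fold - 1.0) * 100.0
    return ConditionReport(
        treated=treated_name, reference=reference_name,
        fold_change=fold, percent_change=percent,
        treated_mean=float(np.mean(treated)), reference_mean=ref_mean,
        treated_sem=_sem(treated), reference_sem=_sem(reference),
        n_treated=int(treated.size), n_reference=int(reference.size))


@dataclass
class RescueReport:
    """Joint neurite-length / RhoA-activity record of the rescue design
    (RhoA activator for 30 min, then isoquercitrin for 6 h)."""

    length_fold: float                 # rescue arm / activator arm
    activity_percent_difference: float  # (1 - rescue/activator)·100
    length: ConditionReport
    activity: ConditionReport


def rescue_analysis(calpeptin_values, calpeptin_plus_q_values,
                    glisa_pairs: tuple) -> RescueReport:
    """Paired readout of the rescue experiment.

    ``glisa_pairs`` is (activator-arm ODs, rescue-arm ODs).  Reports
    the neurite-length fold (rescue / activator) and the percent
    difference in G-LISA activity in one record.
    """
    cal = np.asarray(calpeptin_values, float)
    res = np.asarray(calpeptin_plus_q_values, float)
    if cal.size == 0 or res.size == 0:
        raise ValueError("both neurite-length arms must be non-empty")
    try:
        cal_od, res_od = glisa_pairs
    except (TypeError, ValueError) as exc:
        raise ValueError("glisa_pairs must be (activator ODs, rescue ODs)") \
            from exc
    cal_od = np.asarray(cal_od, float)
    res_od = np.asarray(res_od, float)
    if cal_od.size == 0 or res_od.size == 0:
        raise ValueError("both activity arms must be non-empty")
    length = fold_change(res, cal, "calpeptin+Q", "calpeptin")
    activity = fold_change(res_od, cal_od, "calpeptin+Q", "calpeptin")
    return RescueReport(
        length_fold=length.fold_change,
        activity_percent_difference=(1.0 - activity.fold_change) * 100.0,
        length=length, activity=activity)


def plot_timecourse(timecourses: Sequence[TimeCourse], ax=None,
                    normalize: bool = False):
    """Mean ± s.e.m. neurite length/cell vs. time per condition."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for tc in timecourses:
        m = tc.mean()
        s = tc.sem()
        if normalize:
            s = s / m[0]
            m = m / m[0]
        ax.errorbar(tc.timestamps / 60.0, m, yerr=s, label=tc.condition,
                    capsize=2)
    ax.set_xlabel("time (h)")
    ax.set_ylabel("neurite length/cell"
                  + (" (normalised)" if normalize else " (µm)"))
    ax.legend()
    return ax


def plot_rescue(report: RescueReport, ax=None):
    """Double-axis bars: neurite length folds and activity, side by side."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax2 = ax.twinx()
    ax.bar([0, 1], [report.length.reference_mean,
                    report.length.treated_mean],
           width=0.35, color="black", label="neurite length/cell")
    ax2.bar([0.4, 1.4], [report.activity.reference_mean,
                         report.activity.treated_mean],
            width=0.35, color="grey", label="RhoA activity (OD)")
    ax.set_xticks([0.2, 1.2])
    ax.set_xticklabels([report.length.reference, report.length.treated])
    ax.set_ylabel("neurite length/cell (µm)")
    ax2.set_ylabel("RhoA activity (OD)")
    return ax
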