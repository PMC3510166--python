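"""Scene, condition and time-lapse configuration.

All geometric quantities are in micrometres unless a field name says
pixels; conversion to the pixel grid happens inside the renderer via
``pixel_size`` (µm/pixel).  The default pixel size of 0.65 µm/px is a
typical 20x-objective class sampling.

``PAPER_EFFECTS`` is the shipped calibration table: one
:class:`ConditionEffects` entry per treatment condition of the study
design (isoquercitrin "Q", ROCK inhibitor Y-27632, Rho inhibitor C3
transferase, RhoA activator calpeptin, and their combinations), with
multipliers encoding the measured effect sizes.  The synthetic-data
generator consumes these multipliers; the analysis pipeline is expected
to recover them.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import yaml

__all__ = [
    "SceneConfig",
    "ConditionEffects",
    "TimelapseConfig",
    "ConfigurationError",
    "PAPER_EFFECTS",
    "CONDITIONS",
    "effects_to_yaml",
    "effects_from_yaml",
]


class ConfigurationError(ValueError):
    """Invalid generator configuration; the message names the field."""


CONDITIONS = (
    "control",
    "Q",
    "Y27632",
    "Q+Y27632",
    "C3",
    "Q+C3",
    "calpeptin",
    "calpeptin+Q",
)


@dataclass(frozen=True)
class SceneConfig:
    """Geometry, optics and noise of one synthetic fluorescence scene.

    Lengths are µm, intensities are arbitrary camera units (the TIFF
    export quantises to 16-bit).  ``poisson_scale`` is the number of
    detected photons per intensity unit; ``None`` (or ``inf``) disables
    shot noise, ``gaussian_sd=0`` disables read noise, together giving
    the noiseless limit in which the rendered scene equals the ideal
    PSF-blurred intensity map.
    """

    width: int = 512
    height: int = 512
    pixel_size: float = 0.65
    n_cells: int = 15
    nucleus_radius_mean: float = 5.0
    nucleus_radius_sd: float = 0.5
    soma_radius_mean: float = 9.0
    neurites_per_cell_mean: float = 1.5
    neurite_length_mean: float = 60.0
    neurite_width: float = 1.3
    spot_density_on_neurite: float = 0.04  # spots per µm of centreline
    spot_density_off_neurite: float = 1e-4  # spots per µm² of field
    spot_amplitude: float = 1500.0
    marker_amplitude: float = 1000.0
    psf_sigma: float = 0.65
    background_level: float = 200.0
    poisson_scale: float | None = 0.25
    gaussian_sd: float = 15.0
    nuc_cyto_ratio: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        positive = (
            "width", "height", "pixel_size", "nucleus_radius_mean",
            "soma_radius_mean", "neurite_length_mean", "neurite_width",
            "spot_amplitude", "marker_amplitude", "psf_sigma",
            "nuc_cyto_ratio",
        )
        for name in positive:
            if not getattr(self, name) > 0:
                raise ConfigurationError(f"{name} must be > 0")
        nonneg = (
            "n_cells", "nucleus_radius_sd", "neurites_per_cell_mean",
            "spot_density_on_neurite", "spot_density_off_neurite",
            "background_level", "gaussian_sd",
        )
        for name in nonneg:
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if self.poisson_scale is not None and not self.poisson_scale > 0:
            raise ConfigurationError("poisson_scale must be > 0 or None")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.height, self.width)

    def replace(self, **changes) -> "SceneConfig":
        return dataclasses.replace(self, **changes)


@dataclass(frozen=True)
class ConditionEffects:
    """Effect sizes of one treatment condition relative to control.

    Multipliers scale the corresponding generator parameter (all 1 for
    control); log2 expression shifts move the qPCR ΔCt (0 for control,
    and always 0 for the gapdh housekeeping gene).
    """

    condition: str
    neurite_length_multiplier: float = 1.0
    spot_on_neurite_multiplier: float = 1.0
    rhoa_activity_multiplier: float = 1.0
    proliferation_multiplier: float = 1.0
    nuc_cyto_multiplier: float = 1.0
    rhoq_log2_expression_shift: float = 0.0
    rhoa_log2_expression_shift: float = 0.0

    def __post_init__(self) -> None:
        for name in (
            "neurite_length_multiplier", "spot_on_neurite_multiplier",
            "rhoa_activity_multiplier", "proliferation_multiplier",
            "nuc_cyto_multiplier",
        ):
            if not getattr(self, name) > 0:
                raise ConfigurationError(f"{name} must be > 0")

    def replace(self, **changes) -> "ConditionEffects":
        return dataclasses.replace(self, **changes)


@dataclass(frozen=True)
class TimelapseConfig:
    """Sampling and kinetics of a time-lapse series.

    ``growth_rate`` is the per-cell neurite elongation rate (µm/hour)
    in elongation mode.  Retraction mode shortens each neurite as a
    single exponential toward a residual fraction of its initial
    length: L(t) = L0·(ρ + (1−ρ)·exp(−(t−onset)/τ)) with time constant
    τ = ``retraction_time_constant`` (minutes) and ρ =
    ``retraction_residual_fraction``.  The defaults (τ = 27 min,
    ρ = 0.1364) put 23% of the initial length at 60 min — a 77%
    decrease — with 87% of the total retraction inside the first
    40 minutes.
    """

    frame_interval: float = 56.0  # minutes
    duration: float = 2880.0  # minutes (48 h)
    growth_rate: float = 1.0  # µm/hour per cell
    retraction_time_constant: float = 27.0  # minutes
    retraction_residual_fraction: float = 0.1364
    onset_delay: float = 0.0  # minutes

    def __post_init__(self) -> None:
        if not self.frame_interval > 0:
            raise ConfigurationError("frame_interval must be > 0")
        if self.duration < self.frame_interval:
            raise ConfigurationError("duration must be >= frame_interval")
        if not self.retraction_time_constant > 0:
            raise ConfigurationError("retraction_time_constant must be > 0")
        if not 0 <= self.retraction_residual_fraction < 1:
            raise ConfigurationError(
                "retraction_residual_fraction must be in [0, 1)")
        if self.onset_delay < 0:
            raise ConfigurationError("onset_delay must be >= 0")

    @property
    def n_frames(self) -> int:
        return int(math.floor(self.duration / self.frame_interval)) + 1

    def timestamps(self) -> list[float]:
        return [k * self.frame_interval for k in range(self.n_frames)]


def _fx(condition: str, **kw) -> ConditionEffects:
    return ConditionEffects(condition=condition, **kw)


#: Calibrated per-condition effect sizes used as generator defaults.
#: Each entry encodes a measured effect of the assay battery:
#:   Q            — 40 µM isoquercitrin: 1.5-fold neurite length/cell at
#:                  48 h, 47% lower GTP-bound RhoA (G-LISA), 25% lower
#:                  BrdU incorporation, 1.7-fold lower nuclear RhoA
#:                  variation, rhoQ (TC10) mRNA up 3.2-fold and rhoA
#:                  mRNA down to 0.8-fold, puncta enriched on neurites.
#:   Y27632       — ROCK inhibitor alone: ~2-fold neurite length (so
#:                  that Q+Y27632 at 3-fold is 1.5x Y27632 alone); acts
#:                  downstream of RhoA, so activity and proliferation
#:                  are unchanged.
#:   Q+Y27632     — synergistic 3-fold neurite length; activity and
#:                  proliferation follow the Q arm.
#:   C3 / Q+C3    — Rho inhibitor: strong outgrowth (5-fold; the
#:                  combination attenuates it to ~3.9-fold), lowest
#:                  proliferation.
#:   calpeptin    — RhoA activator: retracted neurites (0.4-fold in the
#:                  6-h rescue arm) and elevated activity (1.5-fold).
#:   calpeptin+Q  — rescue: 3-fold the calpeptin length (1.2 absolute)
#:                  and 40% lower activity than the calpeptin arm
#:                  (0.9 = 0.6 x 1.5).
PAPER_EFFECTS: dict[str, ConditionEffects] = {
    "control": _fx("control"),
    "Q": _fx(
        "Q",
        neurite_length_multiplier=1.5,
        spot_on_neurite_multiplier=2.0,
        rhoa_activity_multiplier=0.53,
        proliferation_multiplier=0.75,
        nuc_cyto_multiplier=1.0 / 1.7,
        rhoq_log2_expression_shift=math.log2(3.2),
        rhoa_log2_expression_shift=math.log2(0.8),
    ),
    "Y27632": _fx("Y27632", neurite_length_multiplier=2.0),
    "Q+Y27632": _fx(
        "Q+Y27632",
        neurite_length_multiplier=3.0,
        spot_on_neurite_multiplier=2.0,
        rhoa_activity_multiplier=0.53,
        proliferation_multiplier=0.75,
    ),
    "C3": _fx(
        "C3",
        neurite_length_multiplier=5.0,
        rhoa_activity_multiplier=0.4,
        proliferation_multiplier=0.6,
    ),
    "Q+C3": _fx(
        "Q+C3",
        neurite_length_multiplier=3.9,
        spot_on_neurite_multiplier=2.0,
        rhoa_activity_multiplier=0.4,
        proliferation_multiplier=0.75,
    ),
    "calpeptin": _fx(
        "calpeptin",
        neurite_length_multiplier=0.4,
        rhoa_activity_multiplier=1.5,
    ),
    "calpeptin+Q": _fx(
        "calpeptin+Q",
        neurite_length_multiplier=1.2,
        rhoa_activity_multiplier=0.9,
    ),
}


def effects_to_yaml(effects: Mapping[str, ConditionEffects] | Iterable[ConditionEffects],
                    path=None) -> str:
    """Serialise a calibration table to YAML (returns the text)."""
    if isinstance(effects, Mapping):
        effects = effects.values()
    doc = {e.condition: {k: v for k, v in dataclasses.asdict(e).items()
                         if k != "condition"}
           for e in effects}
    text = yaml.safe_dump(doc, sort_keys=False)
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


def effects_from_yaml(source) -> dict[str, ConditionEffects]:
    """Load a calibration table written by :func:`effects_to_yaml`."""
    if hasattr(source, "read"):
        doc = yaml.safe_load(source)
    else:
        try:
            with open(source) as fh:
                doc = yaml.safe_load(fh)
        except (OSError, FileNotFoundError):
            doc = yaml.safe_load(source)
    return {name: ConditionEffects(condition=name, **(kw or {}))
            for name, kw in doc.items()}
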