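"""Synthetic fluorescence scenes, time-lapse series and assay tables.

The generator emulates two-channel micrographs of NG108-15-like cells:
a DAPI nuclear channel and a green marker channel whose content depends
on the marker being imaged — neurofilament (soma + neurite filling
signal), synaptotagmin-1 (puncta on and off neurites over a faint
structural signal) or RhoA (cytoplasmic signal with condition-dependent
punctate nuclear enrichment).  Scenes are rendered as

    shapes -> ideal intensity map -> Gaussian PSF blur
           -> Poisson (shot) noise -> additive Gaussian (read) noise

and every scene carries a :class:`GroundTruth` derived from the
pre-noise geometry: per-pixel masks, nucleus centroids, spot positions
with on/off-neurite flags, and exact per-cell neurite length computed
analytically from the generated centreline polylines.

Treatment conditions act through :class:`~neuritequant.config.ConditionEffects`
multipliers, so the ratio of any ground-truth quantity between two
conditions equals the ratio of the configured multipliers exactly.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
import tifffile
from scipy import ndimage as ndi
from skimage import draw as skdraw
from skimage import morphology

from .config import (
    ConditionEffects,
    ConfigurationError,
    SceneConfig,
    TimelapseConfig,
)

__all__ = [
    "Scene",
    "GroundTruth",
    "SceneGeometry",
    "generate_scene",
    "generate_timelapse",
    "generate_plate_assay",
    "generate_qpcr",
    "sample_geometry",
    "rasterize",
    "apply_noise",
    "save_scene",
    "load_scene",
    "rle_encode",
    "rle_decode",
    "PRIMERS",
    "QPCR_GENES",
]

Marker = Literal["neurofilament", "synaptotagmin", "rhoa"]

# Fixed rendering amplitudes (camera units, pre-background).  The green
# structural amplitude is SceneConfig.marker_amplitude; these are the
# relative levels of the compartments for each marker.
DAPI_AMPLITUDE = 3000.0
_NF_NEURITE = 1.0          # neurite level, x marker_amplitude
_NF_SOMA = 0.5
_SYT_STRUCT = 0.05         # faint structural signal under puncta
_SPOT_MIN_SEP = 8.0        # px, minimum arc separation of on-neurite puncta
_RHOA_CYTO = 0.6           # cytoplasmic level, x marker_amplitude
_SUBNUCLEAR_SPOTS = 5      # punctate nuclear RhoA foci per nucleus
_SUBNUCLEAR_SIGMA = 1.5    # px
_SPOT_SIGMA = 1.0          # px, rendered punctum width (pre-PSF)

#: RT-qPCR primer sequences for the housekeeping gene and the two Rho
#: GTPase transcripts quantified by the pipeline (5'->3').
PRIMERS = {
    "gapdh": {"fwd": "CATGGCCTTCCGTGTTCCTA", "rev": "GCGGCACGTCAGATCCA"},
    "rhoA": {"fwd": "GGGCGTGGATGCGTTCT", "rev": "ACGCGCGCACACTCTCA"},
    "rhoQ": {"fwd": "GCGCGTCCTGTGGGATT", "rev": "GCTCCAAGCGGACATCAGTT"},
}
QPCR_GENES = tuple(PRIMERS)

# Baseline control Ct values per gene (typical abundances).
_CT_BASELINE = {"gapdh": 18.0, "rhoA": 24.0, "rhoQ": 26.0}


# ---------------------------------------------------------------------------
# data containers
# ---------------------------------------------------------------------------

@dataclass
class Scene:
    """A rendered two-channel scene (channel 0 = DAPI, 1 = green)."""

    channels: np.ndarray  # (2, H, W) float64
    pixel_size: float  # µm/pixel
    condition: str = "control"
    marker: str = "neurofilament"
    metadata: dict = field(default_factory=dict)

    @property
    def dapi(self) -> np.ndarray:
        return self.channels[0]

    @property
    def green(self) -> np.ndarray:
        return self.channels[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.channels.shape[1:]


@dataclass
class GroundTruth:
    """Pre-noise geometry of a scene, for training and validation."""

    cell_mask: np.ndarray       # soma disks (bool)
    neurite_mask: np.ndarray    # neurite shafts, excludes soma interior
    nucleus_mask: np.ndarray
    nucleus_centroids: list    # [(row, col), ...]
    spot_positions: list       # [(row, col, on_neurite), ...]
    true_neurite_length_per_cell: float  # µm/cell (nan when no nuclei)
    true_nuc_cyto_ratio: float
    total_neurite_length: float = 0.0    # µm, summed over all cells
    polylines: list = field(default_factory=list)  # [(cell_idx, (m,2) px)]

    @property
    def n_cells(self) -> int:
        return len(self.nucleus_centroids)


@dataclass
class SceneGeometry:
    """Sampled scene geometry in pixel coordinates (row, col)."""

    shape: tuple[int, int]
    soma_centers: np.ndarray      # (n, 2)
    soma_radii: np.ndarray        # px
    nucleus_centers: np.ndarray   # (n, 2)
    nucleus_radii: np.ndarray     # px
    polylines: list               # [(cell_idx, (m, 2) float px), ...]
    spots_on: np.ndarray          # (k, 2) float px
    spots_off: np.ndarray         # (k2, 2) float px
    subnuclear_offsets: list      # per nucleus: (m, 2) offsets in px


# ---------------------------------------------------------------------------
# geometry sampling
# ---------------------------------------------------------------------------

def _polyline_length(points: np.ndarray) -> float:
    """Arc length of a polyline in its own coordinate units."""
    if len(points) < 2:
        return 0.0
    return float(np.sum(np.linalg.norm(np.diff(points, axis=0), axis=1)))


def _walk_polyline(start: np.ndarray, heading: float, length_px: float,
                   shape: tuple[int, int], rng: np.random.Generator,
                   step: float = 1.0, curvature_sd: float = 0.06,
                   margin: float = 6.0) -> np.ndarray:
    """Smoothed random-walk centreline of exact arc length ``length_px``.

    The heading performs a bounded-variance random walk; near the field
    border it is steered back toward the centre so neurites stay inside
    the frame without losing length.
    """
    n_full = int(length_px // step)
    rem = length_px - n_full * step
    pts = [start.astype(float)]
    pos = start.astype(float)
    centre = np.array([shape[0] / 2.0, shape[1] / 2.0])
    steps = [step] * n_full + ([rem] if rem > 1e-9 else [])
    for ds in steps:
        heading += rng.normal(0.0, curvature_sd)
        nxt = pos + ds * np.array([math.sin(heading), math.cos(heading)])
        if (nxt[0] < margin or nxt[0] > shape[0] - 1 - margin
                or nxt[1] < margin or nxt[1] > shape[1] - 1 - margin):
            to_centre = centre - pos
            heading = math.atan2(to_centre[0], to_centre[1]) \
                + rng.normal(0.0, 0.2)
            nxt = pos + ds * np.array([math.sin(heading), math.cos(heading)])
        pos = nxt
        pts.append(pos.copy())
    return np.array(pts)


def _truncate_polyline(points: np.ndarray, target_px: float) -> np.ndarray:
    """Prefix of a polyline with exact arc length ``target_px``."""
    if target_px <= 0 or len(points) < 2:
        return points[:1]
    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    if target_px >= cum[-1]:
        return points
    i = int(np.searchsorted(cum, target_px))
    frac = (target_px - cum[i - 1]) / seg[i - 1]
    last = points[i - 1] + frac * (points[i] - points[i - 1])
    return np.vstack([points[:i], last])


def sample_geometry(config: SceneConfig, effects: ConditionEffects,
                    rng: np.random.Generator) -> SceneGeometry:
    """Sample somata, nuclei, neurite centrelines and spot positions."""
    shape = config.shape
    px = config.pixel_size
    soma_r_px = config.soma_radius_mean / px
    margin = soma_r_px + 8.0
    min_sep = 4.0 * soma_r_px

    centers = []
    attempts = 0
    while len(centers) < config.n_cells and attempts < 20000:
        attempts += 1
        c = rng.uniform([margin, margin],
                        [shape[0] - margin, shape[1] - margin])
        if all(np.linalg.norm(c - o) >= min_sep for o in centers):
            centers.append(c)
    soma_centers = np.array(centers) if centers else np.empty((0, 2))
    n = len(soma_centers)
    soma_radii = np.full(n, soma_r_px) * rng.uniform(0.9, 1.1, n)
    nucleus_radii = np.clip(
        rng.normal(config.nucleus_radius_mean, config.nucleus_radius_sd, n),
        0.4 * config.nucleus_radius_mean, None) / px
    nucleus_centers = soma_centers + rng.normal(0.0, 1.0, (n, 2))

    length_mean = config.neurite_length_mean \
        * effects.neurite_length_multiplier
    # structural randomness (counts, angles, lengths) is drawn before
    # any random walk runs, and the walks use a separate child stream:
    # the number of walk steps depends on the condition's length
    # multiplier, and interleaving the two would desynchronise the
    # draws between conditions sharing a seed — ground-truth ratios
    # must equal the configured multipliers exactly
    plan = []
    for i in range(n):
        k = 1 + rng.poisson(max(config.neurites_per_cell_mean - 1.0, 0.0))
        for _ in range(k):
            ang = rng.uniform(0.0, 2.0 * math.pi)
            z = rng.standard_normal()
            length = max(length_mean * (1.0 + 0.15 * z),
                         0.1 * length_mean)
            plan.append((i, ang, length))
    walk_rng = np.random.default_rng(rng.integers(0, 2**31 - 1))
    polylines = []
    for i, ang, length in plan:
        start = soma_centers[i] + soma_radii[i] * np.array(
            [math.sin(ang), math.cos(ang)])
        pts = _walk_polyline(start, ang, length / px, shape, walk_rng)
        polylines.append((i, pts))

    # on-neurite puncta: placed on the centreline (guarantees the
    # ground-truth invariant that they lie inside the neurite mask)
    dens_on = config.spot_density_on_neurite \
        * effects.spot_on_neurite_multiplier
    spots_on = []
    for _, pts in polylines:
        length_um = _polyline_length(pts) * px
        n_spots = rng.poisson(dens_on * length_um)
        arcs = rng.uniform(2.0, max(length_um / px - 2.0, 2.0), n_spots)
        for s in arcs:
            spots_on.append(_truncate_polyline(pts, s)[-1])
    spots_on = np.array(spots_on) if spots_on else np.empty((0, 2))

    # off-neurite puncta model off-target staining of cell material;
    # a scene without cells is genuinely blank
    area_um2 = shape[0] * shape[1] * px * px
    n_off = rng.poisson(config.spot_density_off_neurite * area_um2) \
        if n > 0 else 0
    spots_off = rng.uniform([4, 4], [shape[0] - 5, shape[1] - 5],
                            (n_off, 2)) if n_off else np.empty((0, 2))

    # subnuclear foci are spread uniformly over the nuclear disk so the
    # punctate pattern does not bias core-vs-rim intensity statistics
    subnuclear = []
    for r in nucleus_radii:
        rad = r * np.sqrt(rng.uniform(0.0, 1.0, _SUBNUCLEAR_SPOTS))
        ang = rng.uniform(0.0, 2.0 * math.pi, _SUBNUCLEAR_SPOTS)
        subnuclear.append(
            np.column_stack([rad * np.sin(ang), rad * np.cos(ang)]))
    return SceneGeometry(shape, soma_centers, soma_radii, nucleus_centers,
                         nucleus_radii, polylines, spots_on, spots_off,
                         subnuclear)


# ---------------------------------------------------------------------------
# rasterisation
# ---------------------------------------------------------------------------

def _snap_to_mask(points: np.ndarray, mask: np.ndarray,
                  max_dist: float = 3.0) -> np.ndarray:
    """Move each point to the nearest True pixel of ``mask`` (drop
    points farther than ``max_dist``)."""
    if len(points) == 0 or not mask.any():
        return np.empty((0, 2))
    dist, (ir, ic) = ndi.distance_transform_edt(~mask, return_indices=True)
    out = []
    for r, c in points:
        ri = int(np.clip(round(r), 0, mask.shape[0] - 1))
        ci = int(np.clip(round(c), 0, mask.shape[1] - 1))
        if mask[ri, ci]:
            out.append((r, c))
        elif dist[ri, ci] <= max_dist:
            out.append((float(ir[ri, ci]), float(ic[ri, ci])))
    return np.array(out) if out else np.empty((0, 2))


def _disk_mask(shape, centers, radii) -> np.ndarray:
    mask = np.zeros(shape, dtype=bool)
    for c, r in zip(centers, radii):
        rr, cc = skdraw.disk((c[0], c[1]), r, shape=shape)
        mask[rr, cc] = True
    return mask


def _polyline_pixels(points: np.ndarray, shape) -> tuple[np.ndarray, np.ndarray]:
    rows, cols = [], []
    pint = np.rint(points).astype(int)
    for a, b in zip(pint[:-1], pint[1:]):
        rr, cc = skdraw.line(a[0], a[1], b[0], b[1])
        rows.append(rr)
        cols.append(cc)
    if not rows:
        return np.empty(0, int), np.empty(0, int)
    rr = np.concatenate(rows)
    cc = np.concatenate(cols)
    ok = (rr >= 0) & (rr < shape[0]) & (cc >= 0) & (cc < shape[1])
    return rr[ok], cc[ok]


def _add_gaussian_spots(img: np.ndarray, positions: np.ndarray,
                        amplitude: float, sigma: float) -> None:
    """Accumulate round Gaussian puncta into ``img`` in place."""
    h, w = img.shape
    half = int(math.ceil(4 * sigma))
    for r0, c0 in positions:
        r0i, c0i = int(round(r0)), int(round(c0))
        rlo, rhi = max(r0i - half, 0), min(r0i + half + 1, h)
        clo, chi = max(c0i - half, 0), min(c0i + half + 1, w)
        if rlo >= rhi or clo >= chi:
            continue
        rr, cc = np.mgrid[rlo:rhi, clo:chi]
        img[rlo:rhi, clo:chi] += amplitude * np.exp(
            -((rr - r0) ** 2 + (cc - c0) ** 2) / (2.0 * sigma ** 2))


def rasterize(geom: SceneGeometry, config: SceneConfig,
              effects: ConditionEffects, marker: Marker,
              ) -> tuple[np.ndarray, GroundTruth]:
    """Render the ideal (pre-PSF, pre-noise) maps and the ground truth."""
    if marker not in ("neurofilament", "synaptotagmin", "rhoa"):
        raise ConfigurationError(f"unknown marker {marker!r}")
    shape = geom.shape
    px = config.pixel_size
    A = config.marker_amplitude

    soma = _disk_mask(shape, geom.soma_centers, geom.soma_radii)
    nucleus = _disk_mask(shape, geom.nucleus_centers, geom.nucleus_radii)
    nucleus &= soma  # nuclei sit inside their soma

    centreline = np.zeros(shape, dtype=bool)
    for _, pts in geom.polylines:
        rr, cc = _polyline_pixels(pts, shape)
        centreline[rr, cc] = True
    w_px = max(int(round(config.neurite_width / px)), 1)
    selem = morphology.disk(max(w_px // 2, 1))
    neurite = morphology.dilation(centreline, selem) & ~soma

    # on-neurite spots sampled near the soma junction can land on
    # pixels claimed by the soma disk; snap them onto the nearest
    # neurite pixel (drop if none nearby) so the ground-truth flag
    # stays truthful without thinning the counts
    spots_on = _snap_to_mask(geom.spots_on, neurite, max_dist=3.0)
    # off-neurite spots within a spot diameter of a neurite are
    # ambiguous even as ground truth; keep only clearly-off positions
    spots_off = geom.spots_off
    if len(spots_off) and neurite.any():
        dist = ndi.distance_transform_edt(~neurite)
        keep = [dist[int(round(r)), int(round(c))] > 6.0
                for r, c in spots_off]
        spots_off = spots_off[np.array(keep, dtype=bool)]

    dapi = np.zeros(shape)
    dapi[nucleus] = DAPI_AMPLITUDE

    green = np.zeros(shape)
    ratio = config.nuc_cyto_ratio * effects.nuc_cyto_multiplier
    if marker == "neurofilament":
        green[soma] = _NF_SOMA * A
        green[neurite] = _NF_NEURITE * A
    elif marker == "synaptotagmin":
        green[soma] = _SYT_STRUCT * A * 0.8
        green[neurite] = _SYT_STRUCT * A
        all_spots = np.vstack([spots_on, spots_off])
        _add_gaussian_spots(green, all_spots, config.spot_amplitude,
                            _SPOT_SIGMA)
    else:  # rhoa
        cyto = (soma & ~nucleus) | neurite
        c_level = _RHOA_CYTO * A
        green[cyto] = c_level
        target = c_level * ratio
        # punctate subnuclear foci scaled so the pre-noise nuclear mean
        # is exactly target (60% flat base + 40% punctate)
        nuc_labels, _ = ndi.label(nucleus)
        for i, (centre, r) in enumerate(zip(geom.nucleus_centers,
                                            geom.nucleus_radii)):
            this = np.zeros(shape)
            pos = centre[None, :] + geom.subnuclear_offsets[i]
            _add_gaussian_spots(this, pos, 1.0, _SUBNUCLEAR_SIGMA)
            lab = nuc_labels[int(round(centre[0])), int(round(centre[1]))] \
                if (0 <= int(round(centre[0])) < shape[0]
                    and 0 <= int(round(centre[1])) < shape[1]) else 0
            if lab == 0:
                continue
            mask = nuc_labels == lab
            mean_p = this[mask].mean()
            if mean_p > 0:
                green[mask] = 0.6 * target + this[mask] * (
                    0.4 * target / mean_p)
            else:
                green[mask] = target

    dapi += config.background_level
    green += config.background_level

    total_um = sum(_polyline_length(pts) for _, pts in geom.polylines) * px
    n_nuc = len(geom.nucleus_centers)
    per_cell = total_um / n_nuc if n_nuc else float("nan")
    spot_positions = (
        [(float(r), float(c), True) for r, c in spots_on]
        + [(float(r), float(c), False) for r, c in spots_off])
    gt = GroundTruth(
        cell_mask=soma,
        neurite_mask=neurite,
        nucleus_mask=nucleus,
        nucleus_centroids=[(float(r), float(c))
                           for r, c in geom.nucleus_centers],
        spot_positions=spot_positions,
        true_neurite_length_per_cell=per_cell,
        true_nuc_cyto_ratio=ratio,
        total_neurite_length=total_um,
        polylines=[(i, pts.copy()) for i, pts in geom.polylines],
    )
    return np.stack([dapi, green]), gt


def apply_noise(ideal: np.ndarray, config: SceneConfig,
                rng: np.random.Generator) -> np.ndarray:
    """PSF blur + Poisson shot noise + Gaussian read noise."""
    sigma_px = config.psf_sigma / config.pixel_size
    blurred = np.stack([ndi.gaussian_filter(ch, sigma_px) for ch in ideal])
    out = blurred
    scale = config.poisson_scale
    if scale is not None and np.isfinite(scale):
        out = rng.poisson(np.clip(out, 0.0, None) * scale) / scale
    if config.gaussian_sd > 0:
        out = out + rng.normal(0.0, config.gaussian_sd, out.shape)
    return out.astype(np.float64)


def generate_scene(config: SceneConfig, effects: ConditionEffects,
                   marker: Marker = "neurofilament",
                   seed: int | None = None,
                   ) -> tuple[Scene, GroundTruth]:
    """Generate one scene plus its ground truth.

    ``seed`` overrides ``config.seed``; identical (config, effects,
    marker, seed) reproduce the scene bit for bit.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    geom = sample_geometry(config, effects, rng)
    ideal, gt = rasterize(geom, config, effects, marker)
    channels = apply_noise(ideal, config, rng)
    scene = Scene(channels=channels, pixel_size=config.pixel_size,
                  condition=effects.condition, marker=marker,
                  metadata={"seed": config.seed if seed is None else seed})
    return scene, gt


# ---------------------------------------------------------------------------
# time lapse
# ---------------------------------------------------------------------------

def generate_timelapse(config: SceneConfig, tconfig: TimelapseConfig,
                       effects: ConditionEffects,
                       mode: Literal["elongation", "retraction"] = "elongation",
                       marker: Marker = "neurofilament",
                       seed: int | None = None,
                       ) -> list[tuple[Scene, GroundTruth]]:
    """Generate a time-lapse series with per-frame ground truth.

    Elongation: per-cell total neurite length grows linearly at
    ``growth_rate`` µm/h, ending at the condition's configured mean.
    Retraction: each neurite shortens exponentially toward a residual
    fraction of its initial length (see :class:`TimelapseConfig`).
    Frame count is floor(duration/frame_interval)+1; true length per
    cell is monotone in time by construction.
    """
    if mode not in ("elongation", "retraction"):
        raise ConfigurationError(f"unknown timelapse mode {mode!r}")
    base_seed = config.seed if seed is None else seed
    rng = np.random.default_rng(base_seed)
    geom = sample_geometry(config, effects, rng)
    times = tconfig.timestamps()
    T = times[-1]
    px = config.pixel_size

    full_lengths = {id(pts): _polyline_length(pts) * px
                    for _, pts in geom.polylines}

    def frame_fraction(t: float, pts) -> float:
        L_full = full_lengths[id(pts)]
        if L_full <= 0:
            return 1.0
        if mode == "elongation":
            # per-cell linear growth ending at the sampled full length;
            # neurites of a cell share the rate pro rata, so the cell
            # total is linear in time with slope growth_rate
            rate_h = tconfig.growth_rate
            cell_idx = next(i for i, p in geom.polylines if p is pts)
            cell_full = sum(_polyline_length(p) * px
                            for i, p in geom.polylines if i == cell_idx)
            if cell_full <= 0:
                return 1.0
            grown = cell_full - rate_h * (T - t) / 60.0
            if grown <= 0:
                raise ConfigurationError(
                    "growth_rate too large for the configured neurite "
                    "length over this duration")
            return grown / cell_full
        # retraction
        t_eff = max(t - tconfig.onset_delay, 0.0)
        rho = tconfig.retraction_residual_fraction
        return rho + (1.0 - rho) * math.exp(
            -t_eff / tconfig.retraction_time_constant)

    frames = []
    child_seeds = np.random.default_rng(base_seed).integers(
        0, 2**31 - 1, size=len(times))
    for k, t in enumerate(times):
        polylines_t = []
        for i, pts in geom.polylines:
            f = frame_fraction(t, pts)
            L_px = full_lengths[id(pts)] / px * f
            polylines_t.append((i, _truncate_polyline(pts, L_px)))
        geom_t = SceneGeometry(
            geom.shape, geom.soma_centers, geom.soma_radii,
            geom.nucleus_centers, geom.nucleus_radii, polylines_t,
            geom.spots_on, geom.spots_off, geom.subnuclear_offsets)
        ideal, gt = rasterize(geom_t, config, effects, marker)
        noise_rng = np.random.default_rng(int(child_seeds[k]))
        channels = apply_noise(ideal, config, noise_rng)
        scene = Scene(channels=channels, pixel_size=px,
                      condition=effects.condition, marker=marker,
                      metadata={"t_minutes": t, "frame": k,
                                "mode": mode, "seed": base_seed})
        frames.append((scene, gt))
    return frames


# ---------------------------------------------------------------------------
# plate assays and qPCR
# ---------------------------------------------------------------------------

def generate_plate_assay(effects: Sequence[ConditionEffects],
                         assay: Literal["glisa", "brdu"],
                         n_replicates: int = 3,
                         noise_sd: float = 0.0,
                         seed: int = 0,
                         control_od: float = 1.0):
    """Absorbance table for a G-LISA (OD 490 nm) or BrdU (OD 450–540 nm).

    Replicate means equal ``control_od`` times the condition's activity
    (glisa) or proliferation (brdu) multiplier in expectation.
    """
    from .assay_stats import AssayTable  # local import avoids a cycle

    if assay not in ("glisa", "brdu"):
        raise ConfigurationError(f"unknown assay {assay!r}")
    if n_replicates < 2:
        raise ConfigurationError("n_replicates must be >= 2")
    if noise_sd < 0:
        raise ConfigurationError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    rows = []
    for eff in effects:
        mult = (eff.rhoa_activity_multiplier if assay == "glisa"
                else eff.proliferation_multiplier)
        for rep in range(n_replicates):
            od = control_od * mult
            if noise_sd > 0:
                od = max(od + rng.normal(0.0, noise_sd), 0.0)
            rows.append({"condition": eff.condition, "replicate": rep,
                         "od": od})
    return AssayTable(assay=assay, data=pd.DataFrame(rows))


def generate_qpcr(effects: ConditionEffects, n_triplicates: int = 3,
                  ct_sd: float = 0.0, seed: int = 0) -> pd.DataFrame:
    """Ct table for genes gapdh/rhoA/rhoQ, control vs. treated.

    Treated Ct for gene g is the control baseline minus the configured
    log2 expression shift (one qPCR cycle per factor of two); the
    housekeeping gapdh shift is always zero.
    """
    if ct_sd < 0:
        raise ConfigurationError("ct_sd must be >= 0")
    if n_triplicates < 1:
        raise ConfigurationError("n_triplicates must be >= 1")
    rng = np.random.default_rng(seed)
    shifts = {"gapdh": 0.0,
              "rhoA": effects.rhoa_log2_expression_shift,
              "rhoQ": effects.rhoq_log2_expression_shift}
    rows = []
    for condition in ("control", effects.condition):
        for gene in QPCR_GENES:
            base = _CT_BASELINE[gene]
            shift = shifts[gene] if condition != "control" else 0.0
            for rep in range(n_triplicates):
                ct = base - shift
                if ct_sd > 0:
                    ct += rng.normal(0.0, ct_sd)
                rows.append({"condition": condition, "gene": gene,
                             "replicate": rep, "ct": ct})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# serialisation
# ---------------------------------------------------------------------------

def rle_encode(mask: np.ndarray) -> list[list[int]]:
    """Row-major run-length encoding of a boolean mask: [start, run]."""
    flat = np.asarray(mask, dtype=bool).ravel()
    if not flat.any():
        return []
    d = np.diff(flat.astype(np.int8))
    starts = np.flatnonzero(d == 1) + 1
    ends = np.flatnonzero(d == -1) + 1
    if flat[0]:
        starts = np.concatenate([[0], starts])
    if flat[-1]:
        ends = np.concatenate([ends, [flat.size]])
    return [[int(s), int(e - s)] for s, e in zip(starts, ends)]


def rle_decode(runs: list, shape: tuple[int, int]) -> np.ndarray:
    flat = np.zeros(shape[0] * shape[1], dtype=bool)
    for start, run in runs:
        flat[start:start + run] = True
    return flat.reshape(shape)


def save_scene(scene: Scene, gt: GroundTruth | None, basepath) -> None:
    """Write ``basepath.tif`` (2-page uint16) + ``basepath.json`` sidecar.

    Channels are clipped to [0, 65535]; the saturated-pixel fraction is
    recorded in the sidecar.  Pixel size goes into the TIFF resolution
    tags (pixels per centimetre).
    """
    basepath = str(basepath)
    data = np.clip(np.rint(scene.channels), 0, 65535).astype(np.uint16)
    saturation = float(np.mean(scene.channels >= 65535))
    px_per_cm = 1e4 / scene.pixel_size
    tifffile.imwrite(basepath + ".tif", data,
                     resolution=(px_per_cm, px_per_cm),
                     resolutionunit="CENTIMETER",
                     metadata={"axes": "CYX"})
    sidecar = {
        "pixel_size_um": scene.pixel_size,
        "condition": scene.condition,
        "marker": scene.marker,
        "channels": ["DAPI", "green"],
        "saturation_fraction": saturation,
        "metadata": scene.metadata,
    }
    if gt is not None:
        sidecar["ground_truth"] = {
            "shape": list(gt.cell_mask.shape),
            "cell_mask_rle": rle_encode(gt.cell_mask),
            "neurite_mask_rle": rle_encode(gt.neurite_mask),
            "nucleus_mask_rle": rle_encode(gt.nucleus_mask),
            "nucleus_centroids": gt.nucleus_centroids,
            "spot_positions": gt.spot_positions,
            "true_neurite_length_per_cell": gt.true_neurite_length_per_cell,
            "true_nuc_cyto_ratio": gt.true_nuc_cyto_ratio,
            "total_neurite_length": gt.total_neurite_length,
        }
    with open(basepath + ".json", "w") as fh:
        json.dump(sidecar, fh)


def load_scene(basepath) -> tuple[Scene, GroundTruth | None]:
    """Load a scene (and ground truth if present) written by save_scene."""
    basepath = str(basepath)
    data = tifffile.imread(basepath + ".tif").astype(np.float64)
    with open(basepath + ".json") as fh:
        sidecar = json.load(fh)
    scene = Scene(channels=data, pixel_size=sidecar["pixel_size_um"],
                  condition=sidecar["condition"], marker=sidecar["marker"],
                  metadata=sidecar.get("metadata", {}))
    gt = None
    if "ground_truth" in sidecar:
        g = sidecar["ground_truth"]
        shape = tuple(g["shape"])
        gt = GroundTruth(
            cell_mask=rle_decode(g["cell_mask_rle"], shape),
            neurite_mask=rle_decode(g["neurite_mask_rle"], shape),
            nucleus_mask=rle_decode(g["nucleus_mask_rle"], shape),
            nucleus_centroids=[tuple(c) for c in g["nucleus_centroids"]],
            spot_positions=[tuple(s) for s in g["spot_positions"]],
            true_neurite_length_per_cell=g["true_neurite_length_per_cell"],
            true_nuc_cyto_ratio=g["true_nuc_cyto_ratio"],
            total_neurite_length=g.get("total_neurite_length", 0.0),
        )
    return scene, gt
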