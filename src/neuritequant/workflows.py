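"""End-to-end recovery workflows over the calibrated generator.

These functions wire the full pipeline together the way the validation
experiments run it: generate scenes under two conditions of the
shipped calibration, push them through detection/segmentation/
quantification, and reduce to the condition-level readout.  Both the
acceptance script and the acceptance test suite call them, so the
measured numbers come from one code path.

Paired design: condition arms share per-scene seeds, so arm contrasts
are not inflated by geometry sampling noise (the analogue of imaging
the same fields of view across wells).
"""

from __future__ import annotations

import numpy as np

from .assay_stats import activity_reduction, proliferation_change, qpcr_fold_change
from .config import PAPER_EFFECTS, SceneConfig, TimelapseConfig
from .localization import compartment_masks, rhoa_localization
from .quantify import fold_change, rescue_analysis, timecourse_from_scenes
from .segmentation import (
    LABEL_BACKGROUND,
    LABEL_CELL,
    LABEL_NEURITE,
    PixelClassifier,
    compute_pixel_features,
    neurite_length_per_cell,
    segment,
    train_pixel_classifier,
)
from .synthetic import (
    generate_plate_assay,
    generate_qpcr,
    generate_scene,
    generate_timelapse,
)

__all__ = [
    "derive_seed",
    "train_default_segmenter",
    "measure_neurite_lengths",
    "length_fold",
    "retraction_percent_decrease",
    "nuclear_sd_condition_ratio",
    "glisa_percent_reduction",
    "brdu_percent_reduction",
    "qpcr_fold",
    "rescue_length_and_activity",
]


def derive_seed(base: int, offset: int) -> int:
    """Deterministic sub-seed below 2**31."""
    return int((base * 1_000_003 + offset * 7919 + 12345) % (2**31 - 1))


def train_default_segmenter(seed: int, n_scenes: int = 4,
                            size: int = 256) -> PixelClassifier:
    """Pixel classifier trained on mixed control/treated scenes."""
    stacks, labs = [], []
    conditions = ["control", "Q"] * ((n_scenes + 1) // 2)
    cfg = SceneConfig(width=size, height=size, n_cells=6)
    for i, cond in enumerate(conditions[:n_scenes]):
        scene, gt = generate_scene(cfg.replace(seed=derive_seed(seed, i)),
                                   PAPER_EFFECTS[cond], "neurofilament")
        labels = np.full(scene.shape, LABEL_BACKGROUND, dtype=np.uint8)
        labels[gt.cell_mask] = LABEL_CELL
        labels[gt.neurite_mask] = LABEL_NEURITE
        stacks.append(compute_pixel_features(scene.green))
        labs.append(labels)
    return train_pixel_classifier(stacks, labs, seed=seed % (2**31 - 1),
                                  max_pixels=120_000)


def measure_neurite_lengths(condition: str, classifier: PixelClassifier,
                            n_scenes: int = 10, seed: int = 1,
                            size: int = 512) -> list[float]:
    """Segment ``n_scenes`` neurofilament scenes; µm/cell per scene."""
    cfg = SceneConfig(width=size, height=size)
    vals = []
    for i in range(n_scenes):
        scene, _ = generate_scene(cfg.replace(seed=derive_seed(seed, i)),
                                  PAPER_EFFECTS[condition], "neurofilament")
        segmap = segment(scene.green, classifier, dapi=scene.dapi,
                         pixel_size=cfg.pixel_size)
        vals.append(neurite_length_per_cell(segmap))
    return vals


def length_fold(treated: str, reference: str, classifier: PixelClassifier,
                n_scenes: int = 10, seed: int = 1, size: int = 512) -> float:
    """Measured neurite length/cell fold change, treated over reference."""
    t = measure_neurite_lengths(treated, classifier, n_scenes, seed, size)
    r = measure_neurite_lengths(reference, classifier, n_scenes, seed, size)
    return fold_change(t, r, treated, reference).fold_change


def retraction_percent_decrease(classifier: PixelClassifier, seed: int = 3,
                                n_positions: int = 3,
                                frame_interval: float = 1.0,
                                duration: float = 60.0,
                                size: int = 256) -> float:
    """Percent decrease of measured neurite length/cell at the end of a
    RhoA-activator retraction series vs. its start."""
    tcfg = TimelapseConfig(frame_interval=frame_interval, duration=duration)
    cfg = SceneConfig(width=size, height=size, n_cells=8)
    positions = []
    for p in range(n_positions):
        frames = generate_timelapse(
            cfg.replace(seed=derive_seed(seed, p)), tcfg,
            PAPER_EFFECTS["Q"], mode="retraction")
        positions.append([s for s, _ in frames])
    tc = timecourse_from_scenes(positions, classifier)
    m = tc.mean()
    return float((1.0 - m[-1] / m[0]) * 100.0)


def nuclear_sd_condition_ratio(n_scenes: int = 10, seed: int = 5,
                               size: int = 512) -> float:
    """Control-over-treated ratio of the image-mean nuclear-SD metric
    on RhoA-marker scenes."""
    cfg = SceneConfig(width=size, height=size)
    means = {}
    for cond in ("control", "Q"):
        vals = []
        for i in range(n_scenes):
            scene, _ = generate_scene(
                cfg.replace(seed=derive_seed(seed, i)),
                PAPER_EFFECTS[cond], "rhoa")
            masks = compartment_masks(scene.dapi, scene.green)
            vals.append(rhoa_localization(scene.green, masks).nuclear_sd_norm)
        means[cond] = float(np.mean(vals))
    return means["control"] / means["Q"]


def glisa_percent_reduction(treated: str = "Q", reference: str = "control",
                            seed: int = 1, n_replicates: int = 3) -> float:
    """Noiseless G-LISA percent reduction under the shipped calibration."""
    table = generate_plate_assay(
        [PAPER_EFFECTS[reference], PAPER_EFFECTS[treated]], "glisa",
        n_replicates=n_replicates, noise_sd=0.0, seed=seed)
    return activity_reduction(table, treated, reference).percent_reduction


def brdu_percent_reduction(treated: str = "Q", reference: str = "control",
                           seed: int = 4, n_replicates: int = 3) -> float:
    table = generate_plate_assay(
        [PAPER_EFFECTS[reference], PAPER_EFFECTS[treated]], "brdu",
        n_replicates=n_replicates, noise_sd=0.0, seed=seed)
    return proliferation_change(table, treated, reference).percent_reduction


def qpcr_fold(gene: str = "rhoQ", seed: int = 6) -> float:
    """Noiseless ΔΔCt fold change of ``gene`` for the treated arm."""
    table = generate_qpcr(PAPER_EFFECTS["Q"], ct_sd=0.0, seed=seed)
    return qpcr_fold_change(table, gene, reference_gene="gapdh",
                            control_condition="control")


def rescue_length_and_activity(classifier: PixelClassifier,
                               n_scenes: int = 10, seed: int = 7,
                               size: int = 512) -> tuple[float, float]:
    """Rescue design: (length fold, activity percent difference)
    between the activator+flavonoid arm and the activator-alone arm."""
    cal = measure_neurite_lengths("calpeptin", classifier, n_scenes, seed,
                                  size)
    res = measure_neurite_lengths("calpeptin+Q", classifier, n_scenes,
                                  seed, size)
    table = generate_plate_assay(
        [PAPER_EFFECTS["calpeptin"], PAPER_EFFECTS["calpeptin+Q"]],
        "glisa", n_replicates=3, noise_sd=0.0, seed=derive_seed(seed, 99))
    cal_od = table.condition_values("calpeptin")
    res_od = table.condition_values("calpeptin+Q")
    report = rescue_analysis(cal, res, (cal_od, res_od))
    return report.length_fold, report.activity_percent_difference
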