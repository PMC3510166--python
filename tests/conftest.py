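"""Shared fixtures: small scene configs and session-scoped classifiers.

Everything is generated programmatically from the synthetic module;
training the pixel and spot classifiers is done once per session
because several test modules exercise the downstream pipeline.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import neuritequant as nq
from neuritequant.segmentation import (
    LABEL_BACKGROUND,
    LABEL_CELL,
    LABEL_NEURITE,
    compute_pixel_features,
    train_pixel_classifier,
)
from neuritequant.spot_context import (
    extract_spot_features,
    label_spots_by_ground_truth,
    train_spot_classifier,
)

settings.register_profile(
    "suite", derandomize=True, max_examples=20,
    suppress_health_check=[HealthCheck.too_slow], deadline=None)
settings.load_profile("suite")


def ground_truth_label_map(gt) -> np.ndarray:
    labels = np.full(gt.cell_mask.shape, LABEL_BACKGROUND, dtype=np.uint8)
    labels[gt.cell_mask] = LABEL_CELL
    labels[gt.neurite_mask] = LABEL_NEURITE
    return labels


@pytest.fixture(scope="session")
def small_config() -> nq.SceneConfig:
    return nq.SceneConfig(width=256, height=256, n_cells=6)


@pytest.fixture(scope="session")
def pixel_classifier(small_config):
    """Random-forest pixel classifier trained on four mixed-condition
    synthetic neurofilament scenes."""
    stacks, labs = [], []
    for i, cond in enumerate(["control", "Q", "control", "Q"]):
        scene, gt = nq.generate_scene(
            small_config.replace(seed=900 + i), nq.PAPER_EFFECTS[cond],
            "neurofilament")
        stacks.append(compute_pixel_features(scene.green))
        labs.append(ground_truth_label_map(gt))
    return train_pixel_classifier(stacks, labs, seed=0, max_pixels=120_000)


@pytest.fixture(scope="session")
def spot_training_data():
    """Detected spots + ground-truth labels from synaptotagmin scenes.

    Detection runs at a permissive threshold (k = 2.0) so the training
    set contains genuine false detections alongside on/off-neurite
    puncta, and half the scenes carry an elevated off-neurite density
    so all three classes are well represented.
    """
    vectors, labels = [], []
    for seed in range(6):
        cfg = nq.SceneConfig(seed=300 + seed)
        if seed % 2:
            cfg = cfg.replace(spot_density_off_neurite=1e-3)
        scene, gt = nq.generate_scene(cfg, nq.PAPER_EFFECTS["Q"],
                                      "synaptotagmin")
        spots = nq.detect_spots(scene.green, k_sigma=2.0)
        labs = label_spots_by_ground_truth(spots, gt)
        for s, lab in zip(spots, labs):
            vectors.append(extract_spot_features(scene.green, s))
            labels.append(lab)
    return vectors, labels


@pytest.fixture(scope="session")
def spot_classifier(spot_training_data):
    vectors, labels = spot_training_data
    n = len(vectors) // 2
    return train_spot_classifier(vectors[:n], labels[:n], seed=0)
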