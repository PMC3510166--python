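"""Generator contracts: geometry, noise model, ground truth, tables."""

import math

import numpy as np
import pytest
from scipy import ndimage as ndi

import neuritequant as nq
from neuritequant.config import ConfigurationError
from neuritequant.synthetic import (
    SceneGeometry,
    apply_noise,
    generate_plate_assay,
    generate_qpcr,
    rasterize,
    rle_decode,
    rle_encode,
    sample_geometry,
)


def test_invalid_config_error_names_field():
    with pytest.raises(ConfigurationError, match="pixel_size"):
        nq.SceneConfig(pixel_size=0)
    with pytest.raises(ConfigurationError, match="spot_density_on_neurite"):
        nq.SceneConfig(spot_density_on_neurite=-1)


def test_empty_scene_is_background_noise_only():
    cfg = nq.SceneConfig(width=128, height=128, n_cells=0, seed=1)
    scene, gt = nq.generate_scene(cfg, nq.PAPER_EFFECTS["control"],
                                  "neurofilament")
    assert gt.n_cells == 0
    assert not gt.cell_mask.any() and not gt.neurite_mask.any()
    assert gt.spot_positions == []
    assert math.isnan(gt.true_neurite_length_per_cell)
    # background + noise only: mean close to the background level
    assert abs(scene.green.mean() - cfg.background_level) < 5


def test_noiseless_limit_equals_ideal_blurred_map():
    cfg = nq.SceneConfig(width=128, height=128, n_cells=3, seed=2,
                         poisson_scale=None, gaussian_sd=0.0)
    rng = np.random.default_rng(cfg.seed)
    geom = sample_geometry(cfg, nq.PAPER_EFFECTS["control"], rng)
    ideal, _ = rasterize(geom, cfg, nq.PAPER_EFFECTS["control"],
                         "neurofilament")
    blurred = np.stack([ndi.gaussian_filter(ch, cfg.psf_sigma / cfg.pixel_size)
                        for ch in ideal])
    scene, _ = nq.generate_scene(cfg, nq.PAPER_EFFECTS["control"],
                                 "neurofilament")
    assert np.max(np.abs(scene.channels - blurred)) < 1e-6 * blurred.max()


def test_straight_neurite_length_matches_analytic_polyline():
    """A designed 100 µm straight centreline must appear in the ground
    truth as exactly 100 µm/cell (1 nucleus), and agree with an
    independent segment-length summation."""
    cfg = nq.SceneConfig(width=256, height=256, n_cells=1, seed=0)
    px = cfg.pixel_size
    n_px = 100.0 / px
    ys = np.full(201, 128.0)
    xs = np.linspace(40.0, 40.0 + n_px, 201)
    poly = np.column_stack([ys, xs])
    geom = SceneGeometry(
        shape=(256, 256),
        soma_centers=np.array([[128.0, 30.0]]),
        soma_radii=np.array([10.0]),
        nucleus_centers=np.array([[128.0, 30.0]]),
        nucleus_radii=np.array([6.0]),
        polylines=[(0, poly)],
        spots_on=np.empty((0, 2)), spots_off=np.empty((0, 2)),
        subnuclear_offsets=[np.zeros((5, 2))],
    )
    _, gt = rasterize(geom, cfg, nq.PAPER_EFFECTS["control"],
                      "neurofilament")
    oracle = sum(np.linalg.norm(poly[i + 1] - poly[i])
                 for i in range(len(poly) - 1)) * px
    assert oracle == pytest.approx(100.0, abs=1e-9)
    assert gt.true_neurite_length_per_cell == pytest.approx(100.0, abs=1e-9)


def test_seed_determinism_across_generators():
    cfg = nq.SceneConfig(width=128, height=128, n_cells=4, seed=7)
    eff = nq.PAPER_EFFECTS["Q"]
    s1, g1 = nq.generate_scene(cfg, eff, "synaptotagmin")
    s2, g2 = nq.generate_scene(cfg, eff, "synaptotagmin")
    assert np.array_equal(s1.channels, s2.channels)
    assert np.array_equal(g1.neurite_mask, g2.neurite_mask)
    t1 = generate_plate_assay([eff], "glisa", n_replicates=3,
                              noise_sd=0.05, seed=3)
    t2 = generate_plate_assay([eff], "glisa", n_replicates=3,
                              noise_sd=0.05, seed=3)
    assert t1.data.equals(t2.data)
    q1 = generate_qpcr(eff, ct_sd=0.2, seed=4)
    q2 = generate_qpcr(eff, ct_sd=0.2, seed=4)
    assert q1.equals(q2)


def test_noise_preserves_mean_of_uniform_map():
    """Poisson + zero-mean Gaussian noise must leave the expected pixel
    value at the ideal level (checked within 3 standard errors)."""
    cfg = nq.SceneConfig(width=64, height=64, psf_sigma=1e-3)
    ideal = np.full((2, 64, 64), 500.0)
    rng = np.random.default_rng(0)
    means = [apply_noise(ideal, cfg, rng)[0].mean() for _ in range(100)]
    # per-pixel var = 500/poisson_scale + gaussian_sd^2
    pixel_var = 500.0 / cfg.poisson_scale + cfg.gaussian_sd ** 2
    se = math.sqrt(pixel_var / (100 * 64 * 64))
    assert abs(np.mean(means) - 500.0) < 3 * se


def test_ground_truth_consistency():
    for seed in range(3):
        cfg = nq.SceneConfig(width=256, height=256, n_cells=5, seed=seed)
        _, gt = nq.generate_scene(cfg, nq.PAPER_EFFECTS["Q"],
                                  "synaptotagmin")
        for r, c, on in gt.spot_positions:
            if on:
                assert gt.neurite_mask[int(round(r)), int(round(c))]
        assert not (gt.neurite_mask & gt.cell_mask).any()
        assert (gt.nucleus_mask & ~gt.cell_mask).sum() == 0


def test_effect_faithfulness_ground_truth_ratios_exact():
    """With a shared seed the ground-truth length and nuclear ratio
    scale exactly by the configured multipliers (pre-noise)."""
    cfg = nq.SceneConfig(width=256, height=256, n_cells=5, seed=11)
    _, g_ctrl = nq.generate_scene(cfg, nq.PAPER_EFFECTS["control"], "rhoa")
    _, g_q = nq.generate_scene(cfg, nq.PAPER_EFFECTS["Q"], "rhoa")
    eff = nq.PAPER_EFFECTS["Q"]
    assert (g_q.true_neurite_length_per_cell
            / g_ctrl.true_neurite_length_per_cell
            ) == pytest.approx(eff.neurite_length_multiplier, rel=1e-9)
    assert (g_q.true_nuc_cyto_ratio / g_ctrl.true_nuc_cyto_ratio
            ) == pytest.approx(eff.nuc_cyto_multiplier, rel=1e-12)


class TestTimelapse:
    cfg = nq.SceneConfig(width=128, height=128, n_cells=3, seed=5)

    def test_zero_growth_is_static(self):
        tcfg = nq.TimelapseConfig(frame_interval=30, duration=90,
                                  growth_rate=0.0)
        frames = nq.generate_timelapse(self.cfg, tcfg,
                                       nq.PAPER_EFFECTS["control"],
                                       mode="elongation")
        lengths = [gt.true_neurite_length_per_cell for _, gt in frames]
        assert len(frames) == 4
        assert all(v == pytest.approx(lengths[0], rel=1e-9)
                   for v in lengths)

    def test_retraction_matches_exponential_decay(self):
        tcfg = nq.TimelapseConfig(frame_interval=60, duration=60)
        frames = nq.generate_timelapse(self.cfg, tcfg,
                                       nq.PAPER_EFFECTS["Q"],
                                       mode="retraction")
        L = [gt.true_neurite_length_per_cell for _, gt in frames]
        rho = tcfg.retraction_residual_fraction
        expected = rho + (1 - rho) * math.exp(
            -60.0 / tcfg.retraction_time_constant)
        assert L[-1] / L[0] == pytest.approx(expected, rel=1e-6)
        assert L[-1] / L[0] == pytest.approx(0.23, abs=0.005)

    def test_elongation_final_is_initial_plus_rate_times_time(self):
        tcfg = nq.TimelapseConfig(frame_interval=1440, duration=2880,
                                  growth_rate=0.5)
        frames = nq.generate_timelapse(self.cfg, tcfg,
                                       nq.PAPER_EFFECTS["control"],
                                       mode="elongation")
        L = [gt.true_neurite_length_per_cell for _, gt in frames]
        assert L[-1] - L[0] == pytest.approx(48.0 * 0.5, rel=1e-6)
        assert all(a <= b + 1e-12 for a, b in zip(L, L[1:]))

    def test_duration_shorter_than_interval_rejected(self):
        with pytest.raises(ConfigurationError):
            nq.TimelapseConfig(frame_interval=60, duration=30)


class TestPlateAssay:
    def test_noiseless_control_replicates_identical(self):
        table = generate_plate_assay([nq.PAPER_EFFECTS["control"]],
                                     "glisa", n_replicates=4, noise_sd=0.0)
        ods = table.condition_values("control")
        assert np.all(ods == ods[0])

    def test_noiseless_multiplier_sets_mean_exactly(self):
        effs = [nq.PAPER_EFFECTS["control"],
                nq.PAPER_EFFECTS["control"].replace(
                    condition="Q", rhoa_activity_multiplier=0.53)]
        table = generate_plate_assay(effs, "glisa", noise_sd=0.0)
        assert table.condition_values("Q").mean() == pytest.approx(0.53)

    def test_negative_noise_rejected(self):
        with pytest.raises(ConfigurationError):
            generate_plate_assay([nq.PAPER_EFFECTS["control"]], "brdu",
                                 noise_sd=-0.1)


class TestQpcr:
    def test_zero_shift_noiseless_equals_control(self):
        eff = nq.PAPER_EFFECTS["control"].replace(condition="X")
        table = generate_qpcr(eff, ct_sd=0.0)
        piv = table.pivot_table(index="gene", columns="condition",
                                values="ct")
        assert np.allclose(piv["control"], piv["X"])

    def test_negative_sd_rejected(self):
        with pytest.raises(ConfigurationError):
            generate_qpcr(nq.PAPER_EFFECTS["Q"], ct_sd=-1)


def test_rle_round_trip_and_scene_io(tmp_path):
    cfg = nq.SceneConfig(width=96, height=96, n_cells=2, seed=9)
    scene, gt = nq.generate_scene(cfg, nq.PAPER_EFFECTS["Q"],
                                  "neurofilament")
    assert np.array_equal(
        rle_decode(rle_encode(gt.neurite_mask), gt.neurite_mask.shape),
        gt.neurite_mask)
    base = tmp_path / "scene"
    nq.save_scene(scene, gt, base)
    loaded, gt2 = nq.load_scene(base)
    assert loaded.pixel_size == scene.pixel_size
    # 16-bit quantisation: within rounding of the in-memory floats
    assert np.max(np.abs(loaded.channels
                         - np.clip(scene.channels, 0, 65535))) <= 0.5
    assert np.array_equal(gt2.neurite_mask, gt.neurite_mask)
    assert gt2.true_neurite_length_per_cell == pytest.approx(
        gt.true_neurite_length_per_cell)
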