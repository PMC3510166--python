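# neuritequant

Quantification of neurite outgrowth, synaptic puncta and RhoA
localization from two-channel fluorescence micrographs, with a
calibrated synthetic-scene generator for validation.

## The problem

NG108-15 neuroblastoma×glioma cells differentiate toward a neuronal
phenotype when RhoA/ROCK signalling is inhibited: neurites elongate,
synaptotagmin-1 puncta appear along them, GTP-bound RhoA drops, and
RhoA redistributes from subnuclear spots to the cytoplasm.  Measuring
these phenotypes from microscopy requires several image-analysis
stages that are usually glued together from interactive tools.  This
package implements the whole chain as a tested Python library for
people running cell-based neurite assays:

* **Spot and nucleus detection** — the undecimated ("à trous")
  B3-spline wavelet transform.  Scale `j` smooths with the separable
  kernel `(1/16, 1/4, 3/8, 1/4, 1/16)` dilated by `2^(j-1)` holes;
  planes `w_j = A_{j-1} − A_j` are hard-thresholded at `k·σ_j`
  (`σ_j = MAD/0.67449`), and spots are connected components of the
  positive multiscale product within an area window.  Detection is
  exact-reconstruction, shift-invariant and insensitive to additive
  offsets.
* **Pixel segmentation** — a 29-filter feature bank (Gaussian,
  gradient, Laplacian, Hessian and structure-tensor eigenvalues at
  σ ∈ {1,2,4,8} px) feeding a seeded random forest that labels
  background / cell / neurite.  Neurite length per cell is the
  skeletonised centreline length (orthogonal step = 1, diagonal = √2,
  × pixel size) divided by the DAPI-detected nucleus count.
* **Spot context (50 features)** — 40 samples of the intensity on the
  radius-9 px circle around each spot, the number of local maxima of
  that circular profile, and mean intensities in 9 centred windows
  (3–19 px); a punctum on a neurite shows exactly two profile maxima
  where the shaft crosses the circle.  A random forest classifies
  spots as on-neurite / off-neurite / false detection.
* **Nuclear vs. cytoplasmic quantification** — Otsu-thresholded DAPI
  objects vs. green-minus-DAPI cytoplasm, per-cell `N/C` mean-intensity
  ratio and the nuclear-SD metric `SD(nuclear) / mean(cytoplasmic)`.
* **Assay statistics** — G-LISA (OD 490 nm) and BrdU (OD 450–540 nm)
  percent changes, `2^(−ΔΔCt)` qPCR fold changes against gapdh, and a
  one-way / repeated-measures ANOVA + paired-t battery with Bonferroni
  post-hoc comparisons.

Because the micrographs behind such studies are rarely deposited, the
package ships a synthetic-data module that renders two-channel scenes
(somata, curvilinear neurites, puncta, condition-dependent nuclear
enrichment; Gaussian PSF → Poisson → Gaussian noise) with exact
ground truth, plus plate-assay and Ct tables.  A calibration table
(`neuritequant.PAPER_EFFECTS`) encodes the study's effect sizes —
1.5× neurite length under 40 µM isoquercitrin ("Q"), 3× with the ROCK
inhibitor Y-27632, 47% RhoA-activity reduction, 25% proliferation
reduction, 77% retraction at 60 min of the RhoA activator calpeptin,
1.7× nuclear-SD contrast, rhoQ (TC10) up 3.2×, and the
calpeptin-rescue design (3× length, 40% activity drop) — so the whole
pipeline can be validated by parameter recovery.

## Worked example

```python
import numpy as np
import neuritequant as nq
from neuritequant import workflows as wf

seg = wf.train_default_segmenter(seed=42)        # pixel classifier
for cond in ("control", "Q"):
    vals = wf.measure_neurite_lengths(cond, seg, n_scenes=3, seed=9,
                                      size=256)
    print(cond, np.round(vals, 1))
print("fold", round(wf.length_fold("Q", "control", seg,
                                   n_scenes=3, seed=9, size=256), 2))

table = nq.generate_plate_assay(
    [nq.PAPER_EFFECTS["control"], nq.PAPER_EFFECTS["Q"]],
    "glisa", n_replicates=3, noise_sd=0.05, seed=2)
res = nq.activity_reduction(table, "Q")
print("G-LISA reduction %", round(res.percent_reduction, 1))
```

prints

```
control [83.6 83.4 77.8]
Q [119.3 112.5 116.5]
fold 1.42
G-LISA reduction % 45.5
```

i.e. three control scenes measure ~80 µm of neurite per cell, the
isoquercitrin arm ~116 µm — a 1.42-fold increase recovered against a
configured 1.5× effect at this small n — and a noisy synthetic G-LISA
plate recovers a 45.5% activity reduction against the calibrated 47%.

A `neuritequant` CLI wraps the stages (`simulate`, `detect`,
`train-segmenter`, `segment`, `ratio`, `stats`, `effects`); see
`neuritequant --help`.

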