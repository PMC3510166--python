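# Methods

## Scope and shape

The package is a validation-oriented re-implementation of an
image-analysis and assay-quantification chain for neurite-outgrowth
studies in NG108-15-like cells.  Each stage is a small module with an
explicit contract (detection, segmentation, spot context,
localization, quantification, assay statistics) and all of them are
exercised end-to-end against a synthetic-scene generator with exact
ground truth.  The generator is first-class code: its defaults define
the study conditions the validation experiments run under.

## Synthetic scenes

A scene is two channels (DAPI, green marker) rendered as
`shapes → ideal map → Gaussian PSF blur → Poisson shot noise →
additive Gaussian read noise`.  Ground truth (masks, nucleus
centroids, spot positions, per-cell neurite length) derives from the
pre-noise geometry; per-cell length is the analytic arc length of the
generated centreline polylines divided by the nucleus count, so it is
exact by construction.

Geometry.  Somata are disks (radius 9 µm ± 10%) placed with a
minimum separation of four radii; nuclei are concentric disks
(5 ± 0.5 µm).  Neurites leave the soma perimeter as smoothed
random-walk polylines (step 1 px, heading SD 0.06 rad/step, steered
back near borders) whose target arc length is drawn per neurite
(mean 60 µm × condition multiplier, CV 15%); neurite count per cell
is 1 + Poisson(0.5).  Widths default to 1.3 µm (2 px at the default
0.65 µm/px — a 20×-objective class sampling; both configurable).

Randomness is split into two streams: structural draws (counts,
angles, lengths) come first from the master generator, the walks from
a child stream.  This matters because the number of walk steps depends
on the condition's length multiplier; interleaving would desynchronise
the draws between two conditions sharing a seed, and the generator
guarantees that ground-truth quantities scale *exactly* by the
configured multipliers under a shared seed (the basis of the
effect-faithfulness tests and of the paired validation design).

Markers.  `neurofilament` fills somata (0.5×) and neurites (1.0× the
marker amplitude, default 1000 over background 200).  `synaptotagmin`
renders σ=1 px Gaussian puncta (amplitude 1500) on neurite
centrelines at 0.04 spots/µm (× condition multiplier) plus uniform
off-neurite puncta at 1e-4 /µm², over a faint (5%) structural signal.
Off-neurite positions within 6 px of a neurite are discarded: a
punctum one spot-diameter from a shaft is ambiguous even as ground
truth.  `rhoa` renders uniform cytoplasm and a nuclear signal that is
60% flat + 40% punctate (5 subnuclear foci, σ 1.5 px, uniform over
the nuclear disk), normalised per nucleus so the pre-noise nuclear
mean is exactly `cytoplasm × nuc_cyto_ratio × multiplier`; both the
N/C ratio and the nuclear SD then scale linearly with the configured
ratio.

Noise defaults: PSF σ 0.65 µm (1 px), Poisson scale 0.25 photons per
intensity unit, Gaussian SD 15.  The noiseless limit
(`poisson_scale=None, gaussian_sd=0`) reproduces the blurred ideal map
exactly and is used for the arithmetic-recovery checks.

Time lapse.  Elongation shortens the sampled final polylines backwards
in time so each cell's total length is linear with slope
`growth_rate` (µm/h); retraction scales each neurite by
`ρ + (1−ρ)·exp(−t/τ)`.  The defaults τ = 27 min and ρ = 0.1364 are a
closed-form calibration: they put the 60-minute length at exactly 23%
of the start (a 77% decrease) with 87% of the total retraction inside
the first 40 minutes.  Frames re-render the truncated geometry with
fresh noise from per-frame child seeds.

Assays.  Plate tables draw `OD = control_od × multiplier + N(0, sd)`
per replicate (G-LISA uses the activity multiplier, BrdU the
proliferation multiplier).  Ct tables shift the treated condition by
`−log2_expression_shift` cycles per gene, with gapdh pinned at zero;
primer sequences for gapdh/rhoA/rhoQ ship as a constant.

What the generator does **not** emulate: photobleaching, drift,
uneven illumination, 3D stacks, brightfield contrast (time-lapse
frames are fluorescence-contrast proxies; the segmentation stages are
contrast-agnostic by contract), touching nuclei, and growth cones.
Passing tests therefore demonstrate correctness of the measurement
chain under a controlled optical model, not performance on any real
instrument's images.

## Spot detection

`atrous_decompose` applies the B3-spline kernel separably with mirror
borders; reconstruction (residual + Σ planes) is a telescoping
identity and is property-tested.  Detection thresholds each plane in
`scale_range` at `k·MAD/0.67449` (k = 3), binarises the pointwise
product of the thresholded planes, and keeps 4-connected components
with area in [2, 200] (nuclei: scales (3,4), area [30, 5000]).

The default puncta range is scales (1,3), not (2,3).  Noise
exceedances in adjacent coarse planes are strongly correlated
(measured corr(w2,w3) ≈ 0.5 under Poisson+Gaussian noise) because the
planes share low-frequency content; a (2,3) product leaves ~6 false
positives per 512² blank image at k = 3, while including the nearly
uncorrelated finest plane drives coincidental exceedances to zero
without losing diffraction-limited puncta (precision 1.0, recall
≈ 0.92 on default scenes, matched at ≤ 3 px).  Declumping of merged
puncta is out of scope; recall losses at high density come almost
entirely from one-to-one matching of merged pairs.

## Segmentation and neurite length

Per-pixel features: intensity plus Gaussian smoothing, gradient
magnitude, Laplacian, Hessian eigenvalues and structure-tensor
eigenvalues at σ ∈ {1,2,4,8} px (mirror borders), a frozen, versioned
29-feature bank.  The classifier contract is 3-class posterior
probabilities; the shipped implementation is a 100-tree random forest
(seeded, min_samples_leaf 2) trained on ground-truth label maps with
stratified pixel subsampling.  Cleanup removes neurite components
< 5 px and fills cell holes < 25 px (declared constants).

Skeleton length counts each adjacent skeleton-pixel pair once:
orthogonal pairs as 1, diagonal pairs as √2, times the pixel size.
This estimator is exact for axis-aligned and 45° lines but carries
the classic staircase anisotropy in between — up to ~7–8%
overestimate near 30° — which the rotation-robustness test documents
(0° vs 45° agree within 5%; 30° within 8%).  Condition contrasts are
ratios of identically distributed geometries, so the bias cancels in
fold changes.  Length per cell divides the total skeleton length by
the DAPI-detected nucleus count; a missing DAPI channel marks the
denominator unavailable and per-cell metrics raise rather than
guessing zero.

## Spot context and classification

The 50-feature split is 40 angular samples (bilinear, radius 9 px,
wrap-around) + 1 maxima count + 9 window means (sides 3–19 px);
border spots are mirror-padded and flagged.  Local maxima are counted
after a circular 3-sample moving average with strict inequality and
plateau collapse.  The spot classifier is a seeded 100-tree random
forest trained on detections labelled by Hungarian matching to
ground-truth positions (≤ 3 px; unmatched ⇒ false detection);
training detections run at a permissive k = 2 so the false-detection
class is populated.

## Localization

Nuclei are Otsu-thresholded DAPI objects (≥ 30 px after 1-px
smoothing); the cytoplasm is the thresholded green mask minus nuclei,
with the green threshold computed on non-nuclear pixels only (the
green histogram is trimodal when nuclei are bright, and a global Otsu
can split at the wrong boundary).  Cytoplasm pixels are assigned to
the nearest nucleus.  Intensity statistics use the full nucleus but
exclude, on the cytoplasm side, a 2-px dilated rim around nuclei and
a 1-px eroded band at the outer mask edge — both guard against PSF
blur and the smoothed threshold bleeding background into the
cytoplasmic mean.  Reported per image (mean over cells): N/C mean
ratio, SD(nuclear)/mean(cytoplasmic) — the headline translocation
metric — and SD(nuclear)/SD(cytoplasmic) as the secondary variant,
since the normalisation convention is ambiguous in this assay family.
At the default PSF the absolute N/C ratio is biased a few percent low
by boundary mixing on thin neurites; condition ratios cancel the
bias, and the noiseless near-delta-PSF check recovers the configured
ratio to ±0.05.

## Quantification and statistics

Fold changes are computed on means of per-image values with s.e.m.
over images (n = images), matching the 10-images-per-condition
convention; reductions are reported as `(1 − fold)·100`%.  Time
courses segment every frame of every position and mark zero-nuclei
frames as missing (never zero).  The rescue analysis couples the
neurite-length fold (activator+flavonoid over activator) with the
G-LISA percent difference in one record, mirroring the double-axis
presentation of such experiments.

qPCR uses ΔΔCt with amplification efficiency fixed at 2.0; the
generator and the reduction are exact inverses in the noiseless
limit, property-tested over arbitrary shifts.  The statistical
battery: one-way ANOVA (scipy), repeated-measures ANOVA as the
treatment × subject fixed-effects decomposition with df
(k−1), (k−1)(n−1), paired t, and Bonferroni-corrected pairwise t
tests at α = 0.05.  Type-I calibration of the one-way test is checked
on 1000 seeded null simulations.

## Validation problem sizes

The acceptance script trains one segmenter (four 256² mixed-condition
scenes, 120k training pixels) and measures: 10 scenes of 512² per
condition for the static fold-change recoveries; 3 positions × 61
frames of 256² (1-min sampling over 60 min) for the retraction
series — the retraction readout is a within-series ratio, so the
smaller field does not change what is being recovered; noiseless
3-replicate tables for the plate/qPCR recoveries.  These sizes were
chosen as the smallest at which the stochastic recoveries sit
comfortably inside their ±15% bands; the whole run takes about two
minutes on one CPU.

## Known limitations

* Absolute neurite lengths are biased a few percent low (skeleton end
  effects, soma junction exclusion) and anisotropically high off-axis;
  only ratios are calibrated.
* Merged puncta are counted once (no declumping), so on-neurite
  counts saturate slightly at high densities; density contrasts
  recover within ±25% at the default density.
* The repeated-measures design assumes balance; unbalanced input is
  rejected, not imputed.
* Classifiers are seeded random forests trained on synthetic scenes;
  applying them to real micrographs requires retraining on labels
  from that modality.
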