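# Methods

This note documents the models and procedures implemented in `cortexlrp`,
the parameter choices that matter, and what the synthetic-data pipeline can
and cannot establish about real recordings.

## Generative model of single-trial cortical activity

The simulator emulates a two-group ERP source-imaging study: patients and
controls perform a task whose retrieval phase evokes activity in a small set
of cortical regions, recorded as current densities at `n_vertices` points
(default 15,002) on two hemispheres, `-200…1500 ms` at 400 samples/s.

One trial at vertex `v` and time `t` is

```
x(v, t) = baseline + g · δ_region(v) · w(t) + b_s(v) + ε(v, t)
```

- `g = 1` for patient trials, 0 for controls; `δ_region` is a per-region
  effect size (current-density units), nonzero only inside configured
  regions.
- `w(t)` is a raised-cosine bump supported on 100–300 ms with peak 1 at
  200 ms. Only the analysis window (150–250 ms) is fixed by the study
  design; the waveform shape is a modeling choice, made smooth so the
  effect is not an artifact of window edges. Its mean over the 41 window
  samples is 0.5 + 1/π ≈ 0.818, so the windowed group difference is
  0.818·δ, not δ — tests use this exact factor.
- `b_s(v)` is the subject random effect with standard deviation
  `subject_sd` (default 0.2), decomposed into a spatially **global** gain
  component and a per-vertex component with share `subject_effect_share`
  (default 0.5). Inter-subject ERP amplitude differences are largely
  coherent across the cortex (anatomy, skull conductivity, overall gain),
  and a purely per-vertex effect would make subject-level regional
  summaries nearly independent of any sub-region mean; the global part is
  removed from classifier inputs by per-image z-scoring, so it stresses
  the clinical-correlation path without leaking into classification.
- `ε(v, t)` is white Gaussian trial noise (`noise_sd`, default 1.0).

Sample sizes default to the emulated study: 13 control subjects totalling
2014 trials (`[155]·12 + [154]`) and 9 patients totalling 1580
(`[176]·5 + [175]·4`); the totals are treated as post-QC counts, so the
synthetic EOG channel has blink probability 0 by default (blinks —
Gaussian bumps of configurable amplitude, default 150 µV — are switched on
in tests of the rejection rule).

Clinical scores for patient subjects are linear read-outs of *realized*
activity: `score = intercept + Σ_i slope_i · activity(region_i) + noise`,
where `activity` is the subject's trial-mean current density over the
region and the 150–250 ms window. Default couplings mirror the emulated
study's significant cells (insular positively with PSQI/ISI/HADS-Anxiety/
IRLS, inferior temporal negatively with PSQI/IRLS, right superior temporal
negatively with ESS); BDI and HADS-Depression stay uncoupled. Because the
scores are computed from the generated data, a zero-noise coupling yields a
Spearman correlation of exactly ±1 — the ground truth the recovery tests
check against.

### Source space

Each hemisphere is a half-sphere chart (`lat ∈ [-π/2, π/2]`,
`lon ∈ [-π/2, π/2]`). Vertices are placed on a deterministic golden-angle
sunflower lattice constructed in the hemisphere's Mollweide disc (radius
√2) with an explicit boundary ring of ~3√n points, then mapped back through
the inverse projection; since the projection is equal-area, the lattice is
near-uniform on the sphere (nearest-neighbour distance CV ≈ 0.2) and
near-uniform in the image plane, which keeps empty raster pixels close to
the geometric minimum. Regions are spherical caps; overlaps resolve by
listing priority. The caps stand in for an anatomical parcellation — real
cortical meshes, folding, and atlas labels are out of scope.

## Preprocessing

Trials with peak |EOG| strictly greater than 100 µV are rejected ("larger
than" ⇒ a peak of exactly 100 µV is retained). Retained trials are averaged
over 150–250 ms with both endpoints inclusive (41 samples at 2.5 ms
spacing; the epoch grid is half-open, `t_k = -200 + 2.5k`, `k = 0…679`, so
t = 0 is on-grid). No baseline correction is applied at the current-density
stage; none is part of the emulated procedure.

## Mollweide projection and rasterization

The auxiliary angle solves `2θ + sin 2θ = π sin(lat)` by Newton–Raphson
from `θ₀ = lat` (50-iteration cap, bisection fallback), poles analytic.
Note that near the poles the defining function is cubically flat, so *any*
solver — including a bisection oracle — carries an irreducible
double-precision plateau of ~1e-5 in θ at the exact pole; comparisons
tighter than that must treat poles in closed form.

Treating a hemisphere as its own half-sphere makes its image a disc of
radius √2 inscribed in the square [-√2, √2]²; this is what reconciles the
projection's 2:1 full-sphere aspect ratio with two *square* per-hemisphere
rasters. The square is divided into `grid²` equal pixels (half-open bins,
far edge closed, rows top-down from +y); a pixel's value is the arithmetic
mean of its vertices, and empty pixels are 0 before z-scoring. The
vertex↔pixel assignment is kept as an invertible `ProjectionMap` so that
relevance can return to the cortex; empty pixels are excluded from
back-projection. Rasterization rule (mean), empty-pixel value, and binning
orientation are explicit choices — alternatives (nearest-vertex,
interpolation) would change pixel values but not the pipeline's contracts.
Standardization is per image over all pixels (inputs are single trials;
per-pixel-across-dataset standardization would leak train/test statistics),
with constant images mapping to zeros.

## Classifier

VGG-style stack for a 60×120 single-channel input: conv3×3 ×2 (c₁), pool2,
conv3×3 ×2 (c₂ = 128), pool2, flatten (128·12·27 = 41,472), dense h₁
(ReLU, 50% dropout), dense h₂ (ReLU, 50% dropout), dense 1 (sigmoid).
Valid padding everywhere — forced by the 12×27 arithmetic. c₁ = 64,
h₁ = 256, h₂ = 64 by default (the reference design fixes only c₂ = 128);
the channel/dense plans are constructor arguments, and the reduced-scale
studies use (4, 8)/(16, 8), which is sufficient for strongly separable
synthetic data and keeps a 22-fold LOOCV run on one CPU in minutes.

Training: binary cross-entropy, Adam (β₁ = 0.9, β₂ = 0.999), batch 64,
max 300 epochs by default; "validation accuracy did not change for more
than 20 epochs" is implemented as early stopping with patience 20 and
restoration of the best-validation weights. The learning rate comes from a
grid search (per fold, on the fold's own split; ties to the smaller rate).
Labels: patient = 1; probability ≥ 0.5 ⇒ patient.

Evaluation uses leave-one-subject-out cross-validation: per fold, the
majority class of the 21 training subjects' trials is subsampled (seeded,
without replacement) to the minority count, then 1/11 of the balanced
trials are held out, stratified by class with largest-remainder
apportionment, for early stopping. ROC/AUC uses the rank (Mann–Whitney)
formulation via scikit-learn; per-subject accuracy comes only from that
subject's held-out trials.

## Layer-wise relevance propagation

Relevance starts at the pre-sigmoid score of the predicted class (so LRP-0
conservation is exact rather than squashed by the sigmoid) and flows
backward. For a linear layer with inputs `a_j`, weights `w_jk`, bias `b_k`
and `z_jk = a_j w_jk`:

- **LRP-0**: `R_j = Σ_k z_jk / (Σ_j z_jk + b_k) · R_k`;
- **LRP-ε**: denominator additionally stabilized by `ε·sign(·)`
  (ε = 0.01);
- **LRP-γ**: weights and bias replaced by `w + γ w⁺` (γ = 0.25).

ε and γ follow common composite-LRP practice and are configurable. Bias
terms sit in the denominator but receive no relevance, so bias-free LRP-0
conserves the total exactly (verified to 1e-6 relative error). Convolutions
propagate through the same im2col linear map as the forward pass and are
test-verified against dense propagation on the explicitly unrolled matrix.
Max-pooling routes relevance winner-take-all to the recorded argmax (ties:
first in row-major order). The composite assignment — LRP-0 on dense, ε on
the second (upper) conv block, γ on the first (lower) block — is the
finest-grained reading of "lower/middle/upper" for this depth.

Heatmaps are computed for held-out trials only, filtered to correct
predictions, and averaged per pixel/vertex; the default aggregate pools all
correct trials, with per-subject means available. Per-trial maps are not
normalized before averaging (a choice; relevance is already anchored to the
logit scale). Back-projection divides a pixel's relevance equally among
the vertices sharing it.

## Critical regions and clinical statistics

The top round(0.03·n) vertices of the pooled aggregate map (ties at the
cutoff broken by vertex id) form the critical set, grouped by source-space
region labels. Per patient, activity is the mean windowed current density
over that group's vertices and the subject's retained trials. Spearman ρ
uses mid-ranks and the two-sided t-approximation
`t = ρ√((n-2)/(1-ρ²))` (|ρ| = 1 ⇒ p = 0), computed via SciPy. Cells are
flagged at p < 0.05 **without multiple-testing correction**, mirroring the
emulated analysis; with 42 cells, ~2 chance flags are expected under the
null — treat the table as descriptive.

## Reproducibility

A single global seed expands into per-stage/per-fold/per-purpose seeds via
`SeedSequence([seed, stage, fold, purpose])` (stage 0 = source space,
1 = simulation, 3 = cross-validation; purposes 0 = balancing, 1 = split,
2 = initialization, 3 = training shuffle/dropout). All derived seeds are
31-bit. Reruns are bit-identical; `run-all` writes a manifest with config
hash and artifact checksums.

## Scale of the bundled studies

The end-to-end recovery study runs at 2,000 vertices, 22 subjects × 40
trials, epoch 0–400 ms, 30×60 images, channel plan (4, 8), a 20-epoch
training cap, and a single insular effect (δ = 3.0, noise 0.5) coupled to
PSQI — sizes chosen so a complete 22-fold study is a minutes-scale,
single-CPU computation while keeping every pipeline contract identical to
full scale.

## What passing tests do and do not show

The generator produces Gaussian, temporally white, spatially unstructured
noise, a shared effect waveform, and cap-shaped regions. Real single-trial
ERP source estimates violate all of this: 1/f and oscillatory noise,
spatial leakage of the inverse solution, correlated artifacts, non-Gaussian
amplitude distributions, and anatomically irregular regions. Passing
recovery tests therefore demonstrates that the pipeline's machinery is
correct and can recover structure it was designed to detect — not that
comparable accuracy, relevance localization, or clinical correlations
would be obtained on real recordings. Headline figures from any real
study (e.g. ~94% LOOCV accuracy, AUC 0.93) are not reproducible here and
are not targets of this package. Known further limitations: no artifact
repair beyond EOG rejection (no filtering or ICA — upstream of this
artifact), no anatomical atlas, no alternative attribution methods, and no
GPU path (the NumPy CNN is deliberately small).
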