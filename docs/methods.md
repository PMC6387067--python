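# Methods

This note documents the models, algorithms and numerical choices behind
`focirad`. The package quantifies radiation-induced DNA double-strand-break
(DSB) repair foci at two scales: diffraction-limited γH2AX/53BP1 foci in 3D
confocal stacks, and the nanoscale arrangement of γH2AX antibody tags in
single-molecule localization microscopy (SMLM). A forward model with known
ground truth drives all testing.

## Repair-focus kinetics model

The expected focus count per nucleus is

    N(D, t) = N0 + e · α · D · F(t) · R(t)
    F(t) = 1 − exp(−t/τ_form)                      formation
    R(t) = f · exp(−t/τ_fast) + (1−f) · exp(−t/τ_slow)   repair

with dose `D` (Gy), time post-irradiation `t` (min), baseline rate `N0`,
induction rate `α` (foci·nucleus⁻¹·Gy⁻¹) and a multiplicative treatment
effect `e` (1.0 = no effect, the null scenario). A focus carries the 53BP1
marker, in addition to γH2AX, with probability
`p_coloc(t) = 1 − exp(−t/τ_coloc)`; only dual-marker foci are scorable as
DSBs, which mirrors early foci being γH2AX-dominated with colocalization
maturing over tens of minutes.

The functional form is a modeling choice: published focus-count time courses
constrain only the qualitative shape (rise to a peak at 30–60 min, then
biphasic decay) and a few anchors (≈12.5 induced foci per Gy on the manual
counting scale; baseline means of 3.47 or 2.03 foci per nucleus depending on
the cell line). Defaults

| parameter | default | unit | role |
|---|---|---|---|
| `alpha_induction` | 12.5 | foci/nucleus/Gy | induction at formation plateau |
| `baseline_rate` | 3.47 (U87-like) / 2.03 (HeLa-like) | foci/nucleus | spontaneous DSBs |
| `tau_form_min` | 15 | min | focus formation |
| `tau_fast_min`, `tau_slow_min`, `fast_fraction` | 100, 1000, 0.6 | min, min, — | biexponential repair |
| `coloc_rise_tau_min` | 20 | min | marker colocalization maturation |
| `size_growth` | (0.25, 0.60, 300) | µm, µm, min | focus radius growth |
| `treatment_effect` | 1.0 | — | nanoparticle effect multiplier |

were fixed once, before any verification runs, so that the total-count curve
peaks at ≈38 min and the colocalized (DSB) curve at ≈55 min — both inside
the 30–60 min window — and the 4 Gy peak lands at ≈36 colocalized foci per
nucleus. Focus radius grows saturating-exponentially from 0.25 µm to
0.60 µm (τ = 300 min), so mean focus area increases monotonically between
1 h and 8 h.

## Confocal stack generator

Nuclei are randomly oriented ellipsoids (axial semi-axis 2.2–3.0 µm, lateral
2.8–3.8 µm) with a low-order azimuthal boundary ripple, placed on a jittered
grid so they never overlap; a `touching` mode places pairs whose surfaces
interpenetrate by ~20 % of a radius to exercise watershed splitting. Stacks
default to 40 slices at 0.3 µm z-step and 0.1 µm lateral pixels.

Per nucleus the true focus count is Poisson with mean `N(D, t)`. Focus
centers are sampled uniformly inside the ellipsoid shrunk to 80 %, subject
to a minimum pairwise separation of 0.7 µm (configurable). The separation
encodes that repair foci are micron-scale chromatin domains that do not
interpenetrate; without it, a uniform draw at the 4 Gy peak density places
~25 % of foci closer than the diffraction limit, where no counting method —
including the real one — can resolve them. Foci are rendered as anisotropic
Gaussian spots (spot σ combines the PSF, default 0.13/0.35 µm lateral/axial,
with the focus radius), the 53BP1 copy displaced by a jitter vector capped
at 0.15 µm. The chromatin channel is the smoothed nucleus body. Photon noise
is Poisson on `photon_scale · (background + signal)` (default peak spot SNR
≈ 20 over the nuclear interior); Gaussian read noise is optional.

What the generator does *not* emulate: nuclear texture and nucleoli,
depth-dependent aberrations, focus substructure, bleaching, spectral
cross-talk, and cell-cycle heterogeneity. Passing tests therefore
demonstrate the pipeline's correctness on well-posed images, not
performance on every real acquisition.

## Counting pipeline

1. **Nucleus segmentation.** Gaussian smoothing (σ = 0.5 µm) of the
   chromatin channel, global Otsu threshold, 3D hole filling, removal of
   components below 30 µm³, anisotropy-aware Euclidean distance transform,
   smoothed, and a watershed seeded at its regional maxima (minimum
   separation 3 µm) to split touching nuclei. The segmenter is
   deliberately classical and pluggable; a learned segmenter can replace
   the thresholding stage without touching the watershed split.
2. **MSER detection.** Inside each nucleus bounding box, every z-slice is
   swept over 48 quantized thresholds; bright connected components are
   tracked across levels into a component tree. The variation of a
   component is its relative area growth over Δ = 2 levels. Each tree leaf
   (a local intensity core) is walked down its threshold chain and the most
   stable node with area in [4, 150] px and variation ≤ 1.0 is emitted; the
   walk stops at an area jump > 3× (a merge with a neighboring structure).
   Within a slice, nested selections are suppressed smallest-first so a
   merged super-region can never shadow the cores it contains. Slice
   regions are linked across z (gap of one slice tolerated) when their
   footprints overlap ≥ 30 % of the smaller one *and* their lateral
   centroids agree within 2.5 px. Linked voxel sets are then split at 3D
   intensity saddles: a watershed seeded at local maxima of the smoothed
   intensity (seeds closer than 0.55 µm are merged — below that separation
   two peaks cannot be distinct foci at this PSF). The defaults are
   high-recall on purpose; precision is the classifier's job.
3. **Classification.** Six features per candidate — mean and peak intensity
   relative to the nucleus median, contrast against a dilated local
   background shell, log volume, log footprint area, MSER variation — feed
   a standardized linear maximum-margin rule (hinge loss). All features are ratios or shape quantities, so counting is
   invariant to rescaling the stack by a positive constant. A user-level
   `bias_shift` moves the decision threshold (+∞ accepts everything). The
   default classifier is trained on generator output with truth-derived
   labels; candidates that sit 0.35–0.7 µm from a true focus are excluded
   from training as ambiguous fragments. Accepted calls closer than 0.5 µm
   to a stronger call (axial distance compressed by 1.3 before comparison,
   reflecting the coarser axial resolution) are suppressed as duplicates.
4. **DSB calling.** Accepted γH2AX and 53BP1 foci are matched one-to-one,
   greedily by centroid distance (threshold 0.5 µm; ties broken by smaller
   distance, then lower focus index), or alternatively by overlap fraction
   (intersection over the smaller volume, threshold 0.25). Each matched
   pair is one DSB; per-DSB focus areas are the max-projection pixel counts
   of the γH2AX member.

Measured on fresh synthetic stacks at 2 Gy / 60 min (the clinically
standard fraction dose), candidate recall is ≈ 0.96–0.99, classified
precision and recall ≈ 0.90–0.97 per channel, and the mean recovered DSB
count is within 10 % of the colocalized truth over 200 nuclei. At the 4 Gy
peak (≈ 36 foci per nucleus) the pipeline undercounts by ≈ 10–15 % because
optically blended neighbors are counted once — the same behavior reported
for automated counting on real data, where strict automated settings gave
≈ 35 foci against ≈ 50 by eye at the 4 Gy peak.

## SMLM generator and statistics

Localization tables emulate dSTORM-style acquisitions: antibody tags in
Gaussian clusters (foci) of σ = 50 nm with a mean of 30 tags per focus, the
expected total tag count linear in dose (`a + b·D`, defaults 400 + 200·D),
optionally supra-linear above 2 Gy via a scenario flag. Each tag blinks a
geometric number of times (mean 1.6) in a short frame burst; every blink is
displaced by its localization precision, drawn uniformly from 10–20 nm.
Background localizations are CSR at 2 µm⁻². Cluster geometry was calibrated
once so the mean nearest-neighbor (NN) distance of localizations falls in
the reported 20–25 nm band (measured ≈ 22 nm). The within-focus tag
multiplicity and blinking statistics are placeholders — no published
measurement constrains them.

Statistics:

* **Ripley's K/L** — `K̂(r) = (A/n²) Σᵢ Σⱼ≠ᵢ w_ij 1[d_ij ≤ r]` with
  translation edge-correction weights `w_ij = A/((W−|dx|)(H−|dy|))` (or
  none, for toroidal synthetic data); `L = √(K/π)`. Monte-Carlo CSR
  envelopes: pointwise min/max of 99 binomial simulations by default
  (2.5/97.5 percentile mode available). Radii beyond a quarter of the
  window side set a warning flag rather than erroring.
* **Next-neighbor density images** — per-localization count of neighbors
  within 1000 nm (the conventional radius), rendered as a max-per-pixel
  grid.
* **Distance frequencies** — nearest-neighbor distances by default
  (all-pairs-within-cutoff available; over a whole nucleus an unrestricted
  all-pairs mean would be µm-scale, so NN is the default consistent with a
  20–25 nm average). The skewed histogram is fitted by maximum-likelihood
  log-normal (or gamma); the reported peak is the fitted mode.
* **Blink merging** — localizations within 50 nm and ≤ 3 frames apart are
  linked; connected components are molecules. The spatial radius is ≈ 2.5×
  the worst-case precision: the distance between two localizations of one
  tag is Rayleigh with σ = √2·precision, so a radius at the precision scale
  itself would split most multi-blink tags. Merge passes repeat until the
  count is stable, making the operation idempotent. Temporal gating keeps
  nearby *distinct* tags separate because their bursts rarely coincide.
* **Dose-efficiency curves** — linear, quadratic and exponential models
  fitted by least squares on per-dose means (weighted by group size), with
  a separate linear fit restricted to ≤ 2 Gy (the low-dose linear regime).
  Model selection uses AICc computed from the residual sum over all
  per-nucleus observations; with only ~5 dose levels an AICc on the means
  alone is undefined for 3-parameter models.

## Kinetics statistics

Box summaries use linear-interpolation quantiles (numpy convention) with
5th/95th percentile whiskers and 1.5·IQR outlier flagging. Two-group
comparisons use the two-sided Mann–Whitney test: exact when the pooled
sample is tie-free and `C(n+m, n) ≤ 1e5`, otherwise the normal approximation
with midrank tie correction and continuity correction; significance at
α = 0.05. Per-time-point p-values are reported without multiplicity
correction by default (a Holm option exists), matching the per-time-point
testing convention of focus-kinetics studies. The whole-experiment
generator emits truth-level count records (Poisson totals thinned
binomially by `p_coloc`, focus areas following the size-growth curve) so
that 200-replicate null experiments run in seconds.

## Numerical and design notes

* All randomness flows through one explicitly passed
  `numpy.random.Generator`; identical seeds give bit-identical stacks,
  localization tables, truth tables and counts.
* Coordinates are 0-based `(z, y, x)` voxel indices; physical confocal
  quantities in µm, SMLM in nm; bounding boxes half-open.
* Intensity re-scaling invariance holds exactly for power-of-two factors;
  arbitrary factors can flip individual borderline threshold pixels within
  floating-point rounding.
* Degenerate inputs: empty chromatin foreground yields an empty label map
  (not an error); a uniform nucleus yields no candidates; single-class
  classifier training, empty groups, and fewer than two localizations are
  errors.
* The interactive correction GUI of the original counting workflow is out
  of scope; `FocusCall.accepted` flags can be edited programmatically to
  the same effect.

## Known limitations

* The per-channel detector resolves foci down to ≈ 0.6–0.7 µm separation;
  denser patterns are under-counted (quantified above). Manual-like counts
  of small/immature foci are not emulated.
* The SMLM model has no drift, no multi-emitter fitting artifacts and no
  dye-specific photophysics; molecule-count recovery under real blinking
  kinetics will be less accurate than the ≈ ±3 % seen here.
* The kinetics functional form is phenomenological; parameter values
  beyond the stated anchors carry no biological claim.
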