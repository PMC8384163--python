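# Methods

This note documents the models, conventions, numerical choices and known
limitations of `pancmri`. Everything stated here is computed by the test
suite or by `scripts/acceptance.py`; problem sizes quoted are the ones
those runs use.

## Coordinate and data model

All geometry lives in one axial millimetre frame: voxel centers at
`origin + index × spacing` (0-based row/column/slice indices), contour
vertices as (x, y) mm on a slice. Alignment between the acquisitions of
one session is translation-only — the series are coplanar axial stacks of
the same session — and rotational/deformable registration is deliberately
out of scope. Invalid voxels carry a single reserved sentinel (IEEE NaN)
that survives NIfTI round-trips and propagates through interpolation: any
source neighbor with nonzero interpolation weight that is invalid
invalidates the output voxel, so an identity regrid is exact even next to
invalid voxels.

Point-in-polygon rasterization uses the even-odd rule with boundary points
counted inside (deterministic on shared edges); a voxel belongs to a
region iff its physical center is inside the slice's polygon. ROI transfer
onto each parametric map rasterizes the contours directly at the map's own
grid rather than resampling a high-resolution mask — one deterministic
rule for "re-gridded to the map resolution".

## Parametric mapping

* **ADC** is the exact two-point closed form; with exactly two b-values it
  is the least-squares monoexponential fit. Voxels with non-positive
  signal or a negative estimate are flagged invalid and counted in the
  map's diagnostics, never clamped — clamping would bias ROI means.
  Only the two b-values of the active variant are used even when four were
  acquired.
* **T1 (VFA/SPGR)**: S0 enters the signal equation linearly, so the
  per-voxel (S0, T1) least-squares problem is solved by profiling S0 out
  exactly and minimizing the residual over T1 alone — a coarse 64-point
  log-spaced bracket over (1, 10000] ms (joined by the DESPOT1 linearized
  start, `S/sin(fα)` regressed on `S/tan(fα)`) followed by golden-section
  refinement to relative tolerance 1e-8. This yields the same minimizer as
  a 2-D bounded nonlinear solver (profiling is exact), is immune to
  per-voxel convergence failures, and vectorizes over the whole volume.
  Boundary-pinned voxels are flagged invalid. Echo-time decay is neglected
  throughout (TE ≪ T2*). The independent check is a dense 2-D brute-force
  grid search, kept in the tests.
* **B1 correction**: the correction-factor map (acquired at 8 mm slices)
  is trilinearly regridded to the 4 mm VFA grid before fitting; smooth
  transmit fields interpolate safely. Fitting with f ≡ 1 is the
  non-standardized variant; on signals generated with f = 1.1 it shifts
  recovered T1 by ≈ f² ≈ 21%, the mechanism by which unharmonized
  processing inflates between-site variance.
* **MTR** is the direct ratio; SI_off ≤ 0 is invalid, and noisy voxels
  outside [0, 1] are kept but counted.

## Digital phantoms

The generator emulates the study conditions, not arbitrary data:

* **Vial phantom**: seven cylindrical vials in a water jar — four T1 vials
  at 500/1000/1250/1500 ms, an ice-water diffusion vial at ADC
  1.1 × 10⁻³ mm²/s, an MT vial (default MTR 0.35) and an oil vial (default
  fat fraction 0.96) — on a 128 × 104 × 24 grid, 3 mm in-plane, 4 mm
  slices, S0 = 1000. Background is water/agar (T1 2900 ms, ADC
  2.0 × 10⁻³ mm²/s).
* **Pancreas shape**: ellipses with linearly tapering axes swept along a
  smooth C-shaped in-plane curve over ≥ 10 contiguous slices, with
  seed-controlled waviness; the real study organ's 3D-printed geometry is
  not available, so this is a synthetic stand-in with matched scale
  (default 89 ml). Contour vertices are scaled exactly so the
  polygon-stack volume equals the request; the mask is their
  rasterization, making the contour/mask pair self-consistent (Dice 1 by
  construction, re-verified > 0.99).
* **Noise** is Rician: `|v + σ(g₁ + i g₂)|` with standard normal g's —
  the magnitude-image distribution, with the correct small-signal bias at
  b = 800. σ is given in absolute signal units. Where a target SNR is
  quoted, σ is referenced to the brightest frame of the simulated series
  (`simulate_acquisition_at_snr`): short-TR SPGR signals are an order of
  magnitude below S0, so an S0-referenced σ would mean per-frame SNR ≈ 2,
  not 50.
* **B1 field**: a random series of low-order cosine-product modes over
  the grid's physical box. Every mode integrates to zero over the box, so
  the analytic mean is 1; coefficients are L1-normalized, so
  |f − 1| ≤ amplitude holds exactly, not statistically. The field depends
  only on the box extent, hence coarse sampling + regridding agrees with
  direct fine-grid evaluation (< 1%). The default amplitude of 10% is a
  choice — the study scanners' transmit deviation is uncharacterized —
  and is exposed as a parameter.
* **Multisite volunteer studies** are simulated at the measure level:
  value(i, j) = μ + aᵢ + eᵢⱼ (+ site bias), aᵢ ~ N(0, subject_sd²),
  eᵢⱼ ~ N(0, site_sd²). Full abdominal image synthesis per site is
  reserved for the phantom workflows; the statistics consume measures, and
  measure-level simulation keeps runtimes at desk scale. One master seed
  feeds `numpy.random.SeedSequence`-derived substreams per operation.

What passing these tests does **not** show about real data: no respiratory
motion (the suspected cause of MTR's in-vivo failure), no EPI distortion
or k-space artifacts, no inter-reader contouring variability, no
field-strength or vendor effects beyond multiplicative gain and B1 scale.

## Morphometry conventions

Surface area is the open-tube construction — summed slice perimeters ×
inter-slice distance, no end caps — because the downstream CV statistics
depend on using exactly this slice-stack formula, not on a better surface
estimate. Inter-slice distance is slice thickness + gap (4.0 mm for the
anatomical series). The surface-to-volume ratio is computed in 1/mm;
source tables that label such values 1/cm at magnitude ≈ 0.1 are
dimensionally consistent with 1/mm, and every statistic built on the ratio
(CVs, ranks) is unit-invariant, so no conversion is applied to fixture
values. The hepatic ROI is an explicit (center, slice) input for a 4 cm²
circle — vessel avoidance is the caller's responsibility, as it was the
radiologist's.

## Reproducibility statistics

* CV uses the n−1 sample SD; this is the convention under which the
  packaged study table reproduces its published summary values.
* Missing cells are dropped pairwise per statistic and every result
  reports its effective n; nothing is imputed.
* Friedman: average-rank ties with the standard tie correction; sites
  that never measured an assay are excluded from that assay's comparison
  before complete-block deletion (otherwise an assay absent at one site
  could never be tested); a fully tied table returns statistic 0, p = 1.
* Pairwise tests are unpaired rank-sum as the default (a paired
  signed-rank variant is available behind `paired=True`): exact
  distribution when both groups have ≤ 10 tie-free values, otherwise the
  tie-corrected normal approximation. Raw p-values are the default;
  `holm=True` applies step-down Holm.
* Variance decomposition is the simple construction: inter-assay SD =
  mean over subjects of the per-subject across-site sample SD;
  inter-individual SD = sample SD of per-subject means. With k sites per
  subject the per-subject sample SD is biased low by the c₄(k) factor
  (≈ 8% at k = 4); the construction is kept as defined, and the
  variance-recovery acceptance bound (15%) accommodates it.

A factual property of the packaged volunteer table worth knowing:
for seven of the eight measures the between-subject SD exceeds the
within-subject between-scanner SD — the ordering that makes a biomarker
trial-worthy — but MTR is the exception (0.048 vs 0.119): one site's MTR
values are strongly suppressed, its three pairwise comparisons against the
other sites reach raw p = 0.016 (Holm-corrected 0.095), and MTR's
within-subject sample size exceeds its two-group total. The tests assert
this table as it is.

## Power analysis

z-based normal-approximation formulas (two-sided α, default 0.05):
per-group n = ⌈2((z₁₋α∕₂ + z_power)·σ_between/δ)²⌉ for two independent
groups (total = 2n), and n = ⌈((z₁₋α∕₂ + z_power)·σ_within/δ)²⌉, floored
at 3, for within-subject change; δ is the stated percentage of the
measure's grand mean. An iterative t-quantile refinement is available
(`use_t=True`) and never returns less than the z result. These formulas
are transparent and monotone in σ, power and δ; they are not calibrated to
reproduce any particular published sample-size table, whose generating
formula is not public — only structure (design × power × difference grid)
and ordering properties are asserted.

## Problem sizes and runtime

The closure checks run on the full 128 × 104 × 24 phantom grid (~3.2 × 10⁵
voxels; ≥ 6 × 10⁴ voxels per truth value in the banded noisy phantom),
chosen to make median-recovery statistics stable; the variance-recovery
study uses 200 subjects × 4 sites. The whole suite runs in well under a
minute on one CPU, the acceptance script in ~20 s.

## Known limitations

Two-point ADC only (no IVIM/multi-exponential fitting); no T2*/TE
correction; fat–water reconstruction is consumed, not performed; no DICOM
reading; no automatic segmentation; translation-only co-registration. The
pancreas shape is a parametric stand-in, not patient anatomy. The Friedman
and rank-sum implementations delegate to scipy's distributions after
block/tie handling; they are cross-checked against from-scratch rank
arithmetic and exact enumeration in the tests.
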