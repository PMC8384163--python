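# pancmri

Standardized pancreas quantitative-MRI processing and multisite
reproducibility analysis.

Quantitative MRI of the pancreas — organ volume and shape, apparent
diffusion coefficient (ADC), longitudinal relaxation time (T1),
magnetization transfer ratio (MTR), and fat fraction — is a promising set
of biomarkers for type 1 and type 2 diabetes, but scanner-to-scanner
differences have kept it out of multisite trials. `pancmri` implements a
harmonized processing chain for such studies: voxel-wise parametric
mapping, contour-based pancreas morphometry, traveling-phantom /
traveling-volunteer reproducibility statistics, and sample-size projection
for trials built on these measures. Digital phantoms with known ground
truth stand in for scanner data, so every stage is verifiable end to end.

It is intended for imaging scientists and trial statisticians who need a
tested, reproducible reference implementation of this processing chain.

## Models

**ADC** from a two-point diffusion experiment at b-values `b_low`, `b_high`
(s/mm²), per voxel:

    ADC = ln( SI(b_low) / SI(b_high) ) / (b_high − b_low)

The standardized protocol uses the (200, 800) pair; (0, 800) is the
non-standardized, perfusion-contaminated variant.

**T1** from variable-flip-angle spoiled gradient echo (SPGR) signals at
prescribed flip angles α with repetition time TR and a transmit (B1)
correction factor *f* = actual/prescribed flip angle:

    S(α) = S0 · sin(f·α) · (1 − E1) / (1 − E1 · cos(f·α)),   E1 = exp(−TR/T1)

fitted per voxel for (S0, T1) by profiled least squares with a linearized
(DESPOT1) initialization; omitting the B1 map (f ≡ 1) reproduces the
non-standardized variant.

**MTR** from gradient-echo magnitudes without/with an MT saturation pulse:

    MTR = (SI_off − SI_on) / SI_off

**Morphometry** from per-slice radiologist-style contours: volume =
Σ slice areas × inter-slice distance; pancreas volume index PVI =
volume / body weight (ml/kg); surface-area-to-volume ratio =
(Σ slice perimeters × inter-slice distance) / volume.

**Reproducibility statistics** on a long-format (subject, site, measure,
value) table: percent difference against calibrated references, per-subject
across-site coefficients of variation (sample SD / mean) and their average,
Friedman's rank test across scanners with post-hoc pairwise rank-sum tests,
and the inter-individual (between-subject) vs inter-assay (within-subject,
between-scanner) SD decomposition, which feeds z-based sample-size formulas
for two-group and within-subject designs.

## Worked example

The packaged five-volunteer × four-site study table ships with the package:

```python
>>> from pancmri import load_volunteer_table, average_cv, variance_components
>>> table = load_volunteer_table()
>>> round(average_cv(table, "t1"), 1)
9.5
>>> round(average_cv(table, "mtr"), 1)
39.3
>>> vc = variance_components(table, "t1")
>>> round(vc.inter_individual_sd, 1), round(vc.inter_assay_sd, 1)
(149.9, 91.0)
```

The average across-site CV of pancreatic T1 is 9.5% — repeated scans of the
same person on different harmonized scanners agree to within about a tenth
of the value — while MTR, acquired free-breathing, varies by 39% and is not
reproducible across sites. Between-subject spread of T1 (150 ms) exceeds
the within-subject between-scanner spread (91 ms), which is what makes the
measure informative in a trial.

The same analyses run from the shell:

```
pancmri repro --out report.json          # full reproducibility report
pancmri power --out power.csv            # sample-size grid
pancmri simulate --phantom vials --out-dir sim --seed 1
pancmri fit adc -i b=200:sim/dwi_b200.nii.gz -i b=800:sim/dwi_b800.nii.gz --out adc.nii.gz
```

## File formats

Volumes are NIfTI-1 (`.nii`/`.nii.gz`; spacing in `pixdim`, label in
`descrip`). Contours are JSON:

```json
{"frame_spacing_mm": 4.0,
 "contours": [{"slice": 0, "vertices_mm": [[x, y], ...]}, ...]}
```

with closed polygons (first vertex not repeated, ≥ 3 vertices, one polygon
per slice) in the same millimetre frame as voxel centers. Measure tables
are CSV with columns `subject, site, measure, value` (empty value =
missing).

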