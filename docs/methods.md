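# Methods

This note documents the models implemented in `dixonvol`, the defaults and
why they were chosen, what the synthetic cohorts do and do not emulate, and
the numerical conventions that affect results.

## MRS quantification

A PRESS-style single-voxel acquisition measures a water amplitude S_w and a
summed lipid amplitude S_f (peaks at 1.3, 0.9 and 1.6 ppm). Both are
attenuated relative to proton density by transverse decay and incomplete
longitudinal recovery; each amplitude is divided by

    exp(−TE/T2) · (1 − exp(−TR/T1))

with species-specific constants before forming PDFF = 100·S_f/(S_f+S_w).
Defaults are liver values at 3 T: TE = 35 ms, TR = 3000 ms, T2 = 30/52 ms
and T1 = 990/402 ms for water/fat. Two conventions are fixed here because
they are underdetermined in practice: the saturation factor is the standard
steady-state form (1 − exp(−TR/T1)), and correction is applied to the raw
amplitudes (the summed lipid amplitude with the single fat T1/T2 pair)
*before* forming the ratio. Both are swappable via
`relaxation_correct`/`AcquisitionConstants`. At TR/T1 ≥ 3 the saturation
term is within 5% of unity, so the choice is second-order.

`integrate_toy_spectrum` is a deliberately minimal peak integrator
(trapezoid above a linear local baseline per window) for spectra this
package synthesises; it is not a substitute pipeline for in-vivo spectra
and clips a few percent of Gaussian tail area by construction.

## Dixon mapping

Magnitude two-point separation under a global water-dominant assumption:
W = (IP + OP)/2, F = (IP − OP)/2, fat-fraction map = 100·F/(F+W), clipped
to [0, 100]. No phase information is modelled, so voxels with true fat
fraction above 50% are mirrored below 50% — the map is a *signal*
fat-fraction, and the round-trip guarantee (exact inversion of the
rendering model) holds only below 50%. Voxels where noise drives OP > IP
are floored at zero fat and tallied; zero-signal voxels are set to 0% and
tallied.

Geometry is axis-aligned world-mm with voxel-centre semantics. The cubic
VOI (default side 20 mm, matching the MRS voxel) selects every voxel whose
centre lies in the closed cube; on a lattice aligned with the cube this
reproduces the nominal voxel count exactly, and shifting the centre by one
spacing shifts the selection by one voxel.

## Volumetrics

LV%_TH = 100 · #{masked voxels with PDFF > TH}/#{masked voxels}. "Above"
is strict: a voxel at exactly TH is not steatotic (an `inclusive` flag is
provided for sensitivity analysis). Default threshold set
{5.56, 7.97, 8.8}%: the conventional normal/fatty-liver PDFF cutoff plus
the two ROC-derived method-specific cutoffs (VOI and whole-liver). Percent
change uses the subject's own baseline as denominator; zero-baseline
subjects keep their absolute change but are excluded (and counted) from
percent-change statistics.

## Statistical layer

* Spearman ρ with mid-ranks and the t-approximation p-value (scipy).
* Bland–Altman: d = a − b, MD ± 1.96·SD (sample SD, n−1). The limits are
  symmetric about MD by construction; `from_md_and_lower` reconstructs the
  upper limit as 2·MD − lower.
* ROC: candidate thresholds are midpoints between adjacent distinct scores
  plus ±∞ sentinels; positive call = score strictly above threshold; AUC by
  trapezoid over the empirical curve, which equals the normalized
  Mann–Whitney U (ties receive half credit). The Youden cutoff maximizes
  J = sensitivity + specificity − 1, ties broken toward the lowest
  threshold for determinism.
* Wilcoxon signed-rank: zeros dropped, mid-rank ties; exact null for
  n ≤ 25 with untied absolute differences, otherwise normal approximation
  with continuity correction. Rank-sum: exact for n_a + n_b ≤ 20 untied,
  otherwise normal approximation with continuity and tie correction. The
  switchover rules are fixed (rather than left to library defaults) for
  cross-platform reproducibility.
* Two-way repeated-measures ANOVA: mixed design, diet between-subject
  (between-subject error term), time within-subject and diet × time
  interaction (subject-by-time residual), via `pingouin.mixed_anova`.
* α = 0.05 throughout; no multiplicity adjustment anywhere, matching the
  analysis design this package implements.

## Synthetic cohorts

The generator produces what the analysis needs and nothing more:

* **Liver mask** — a randomly deformed ellipsoid, largest connected
  component, strictly inside the lattice border. Only connectedness and
  non-triviality matter to any downstream statistic.
* **PDFF field** — smoothed Gaussian random field (Gaussian kernel with
  `correlation_length`, default 15 mm), rescaled to `within_field_sd` and
  recentred. Two severity scales: `mean_pdff` recentres the clipped field
  to a target masked mean (to machine precision away from the 0/100
  edges); `lv_percent` (default) shifts the field so the masked exceedance
  count at the steatosis threshold hits the target LV% exactly, up to
  voxel-count quantisation.
* **Pairing** — the 8-week severity is the baseline plus an independent
  change draw; no free within-subject correlation parameter.
* **Bounded-scale calibration** — both severity scales live on [0, 100],
  and the default arm distributions place appreciable normal mass outside
  the bounds, so naive clamping would bias realized moments by up to
  ~1 %-point. Baseline targets are therefore drawn from a truncated normal
  whose parent parameters are solved so the truncated mean/SD equal the
  configured values, and the change draw's parent parameters are solved
  (400-point quantile quadrature over the baseline × 96-point
  Gauss–Hermite over the change, plus root finding) so the realized change
  after end-point clamping has the configured mean/SD. Cohort-level
  recovery of the configured moments is consequently unbiased, which is
  what the parameter-recovery tests check.
* **Defaults** — arm severities on the LV%_5.56 scale: MUFA baseline
  73.95 ± 21.95 with change −6.66 ± 11.06 %-points; multifactorial
  73.64 ± 19.85 with change −17.61 ± 13.43. A mean-PDFF preset
  (`mean_pdff_effects`: 9.47 ± 8.89 / −1.4 ± 2.7 and 9.18 ± 7.78 /
  −4.0 ± 4.5) is provided. `within_field_sd` defaults to 5.5 %-points —
  chosen once so that a liver with ~74% of its volume above 5.56% has a
  mean PDFF near 9%, making the two scales mutually consistent; voxel-level
  dispersion inside a human liver is not a published quantity and this is a
  modelling choice.
* **Imaging** — noiseless rendering is exactly invertible; additive
  Gaussian noise (default SD 5 signal units on a proton density of 1000,
  i.e. high-SNR 3 T imaging) goes on the water and fat channels before
  composing IP/OP. Noise is Gaussian, not Rician: magnitude-bias modelling
  is out of scope.
* **Method disagreement** — the MRS amplitudes encode the VOI-mean truth
  shifted by −2.07 %-points plus N(0, 2.56) noise, so the MRI-vs-MRS
  Bland–Altman structure (MD ≈ +2.07, limits ≈ [−2.9, 7.1]) emerges from
  the simulation rather than being asserted.

What the phantoms do **not** emulate: k-space/complex-phase acquisition,
field inhomogeneity, fat–water swaps, multi-peak fat spectra, T2* decay,
respiratory motion, segmentation error, or liver-volume change between
timepoints (one mask per subject). Passing tests therefore validate the
analysis chain and its statistical calibration, not the physics of any
scanner.

## Problem sizes

The default study is 21 + 18 subjects on 24×24×16 grids (4×4×5 mm), which
runs in seconds. Parameter-recovery experiments use 500 subjects/arm on
12×12×10 grids (6×6×8 mm) — masks of ~100 voxels, which keeps the LV%
quantisation (~1 %-point) well below the subject-level SDs while allowing
100 seeded replicates of the full imaging chain in a few minutes. Recovery
tolerances are 2 standard errors of the arm mean; the generator-level
calibration check uses 10,000 draws and 3 standard errors.

## Reproducibility

One root seed per cohort; a `SeedSequence` is forked once for the
subject-level target draws and once per subject, so per-subject streams are
stable under changes of cohort size. Re-running with the same config yields
byte-identical CSV tables. Every written study carries a provenance record
(package version, seed, SHA-256 config hash). The CLI accepts `--threads`
for interface stability but executes single-threaded; study-scale runs are
seconds-long and determinism is simpler to guarantee on one stream.

## Known limitations

* Magnitude-only two-point separation cannot represent fat fractions above
  50%; phantoms are kept below that regime for validation.
* The toy spectrum integrator under-reads peak areas by the tail mass
  outside its windows (~2–3% for the default widths).
* The exact Wilcoxon switchover thresholds are conventions; p-values very
  close to the switchover may differ slightly from other software.
* `lv_percent`-scale fields realize LV% targets only to voxel-count
  resolution; on very coarse masks this adds visible quantisation noise to
  per-subject (not arm-level) changes.
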