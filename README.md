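# dixonvol

Whole-liver fat quantification from two-point Dixon MRI, with single-voxel
MRS as the reference method, and a volumetric steatosis statistic for
comparing paired dietary interventions.

## The problem

Hepatic steatosis trials need a non-invasive, whole-liver measure of liver
fat. Single-voxel MR spectroscopy (MRS) is the non-invasive reference — it
measures the proton-density fat fraction

&nbsp;&nbsp;&nbsp;&nbsp;PDFF (%) = 100 · S_f / (S_f + S_w)

from the water peak amplitude S_w and the summed lipid peak amplitudes S_f
(1.3, 0.9, 1.6 ppm), after correcting each amplitude for transverse decay
and longitudinal saturation, S → S / [exp(−TE/T2) · (1 − exp(−TR/T1))] —
but it samples a single 20 mm voxel. Two-point Dixon MRI instead covers the
whole liver: in-phase (IP = W + F) and opposed-phase (OP = |W − F|) images
are inverted voxel-by-voxel into water and fat channels, giving a
signal fat-fraction map 100 · F/(F + W). On that map this package computes,
besides the conventional VOI-mean and whole-liver-mean PDFF, the volumetric
statistic

&nbsp;&nbsp;&nbsp;&nbsp;LV%_TH = 100 · #{liver voxels with PDFF > TH} / #{liver voxels},

the percentage of liver volume above a steatosis threshold TH (default
5.56%, plus ROC/Youden-derived cutoffs), and the paired two-arm statistics
used to compare an 8-week MUFA-rich diet against a multifactorial diet:
Spearman correlation and Bland–Altman limits of agreement between methods,
ROC analysis with MRS-derived steatosis labels, paired Wilcoxon signed-rank
tests within arm, Wilcoxon rank-sum tests on changes between arms, and a
mixed two-way repeated-measures ANOVA (diet between, time within).

Because no patient images are distributed with studies of this kind, the
package ships a first-class synthetic cohort generator
(`dixonvol.synthetic`): seeded paired two-arm cohorts of 3D liver phantoms
with spatially correlated voxel-level PDFF fields, rendered Dixon images,
and MRS signals carrying realistic T1/T2 decay plus a calibrated
between-method bias. Every analysis stage is tested end-to-end against the
generator's stored ground truth.

## Worked example

```python
from dixonvol import PipelineConfig, run_study
from dixonvol.pipeline import render_markdown_report

result = run_study(PipelineConfig(), seed=7)   # 21 + 18 subjects, paired
print(render_markdown_report(result.report, result.provenance))
```

Excerpts of the output:

```
- **mri_pdff_voi**: Spearman rho = 0.89 (p = 3.5e-28); Bland–Altman MD = 2.03 [-2.94, 7.00] %-points
- **mri_pdff_voi**: AUC = 0.95, Youden-optimal cutoff = 7.57% (J = 0.79)

### lv_pct_5.56
- MUFA (n=21): 75.98 ± 21.22 → 66.83 ± 25.48, change -9.15 ± 10.15, signed-rank p = 0.000105
- MULTIFACTORIAL (n=18): 74.84 ± 17.61 → 54.68 ± 16.27, change -20.16 ± 13.57, signed-rank p = 7.63e-05
- between-arm rank-sum on changes: p = 0.0117
```

Reading this: the Dixon VOI-mean tracks MRS-PDFF closely (ρ = 0.89) with a
~2 %-point systematic overestimation (the generator's calibrated method
bias); ROC analysis against the MRS label "PDFF > 5.56%" recovers a
Youden-optimal VOI cutoff near 8%; and the share of liver volume above the
5.56% steatosis threshold falls about twice as much under the
multifactorial diet as under the MUFA diet, a between-arm difference the
rank-sum test flags at p ≈ 0.01 even at n = 21/18.

The same study runs from the shell:

```bash
dixonvol run-all --out study/ --seed 7
dixonvol simulate --out cohort/ --seed 7          # NIfTI volumes + manifest.csv
dixonvol mrs --manifest cohort/manifest.csv --out mrs.csv
dixonvol map --manifest mrs.csv --out maps/       # PDFF maps + VOI/WL means
dixonvol volumetrics --table maps/cohort_mapped.csv --out results.csv
dixonvol stats --table results.csv --out stats/   # report + figures
```

## Layout

| module | contents |
| --- | --- |
| `dixonvol.grid` | `VolumeGrid`/`PDFFMap`/`VOISpec` containers, NIfTI I/O |
| `dixonvol.mrs` | relaxation correction, MRS-PDFF, toy spectrum integrator |
| `dixonvol.fatmap` | two-point separation, fat-fraction map, VOI placement, region means |
| `dixonvol.volumetrics` | LV%_TH, per-subject change / percent-change records |
| `dixonvol.stats` | Spearman, Bland–Altman, ROC/Youden, Wilcoxon tests, mixed ANOVA |
| `dixonvol.synthetic` | liver phantoms, PDFF fields, Dixon/MRS rendering, cohort generator |
| `dixonvol.pipeline` | result table, statistical report, provenance, `run_study` |
| `dixonvol.cli` | `dixonvol` command-line verbs |

See `docs/methods.md` for the modelling assumptions, parameter defaults and
known limitations.
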