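# ctspacing

Slice-spacing quality control for CT DICOM series, written for morphometric
studies that measure distances on reconstructed volumes.

## The problem

A CT series arrives as one DICOM file per slice. The volume's geometry along
the acquisition axis is governed by the **slice spacing** — the distance
between consecutive slice centres — which each file also *claims* in its
metadata. Some exports split one acquisition into V sub-volumes of m slices,
with a constant gap w between slices inside a sub-volume but a different gap
b between sub-volumes. Importers that demand uniform spacing then either
refuse the series or "correct" it by assigning every slice the mean gap

```
s_reg = (last offset − first offset) / (n_slices − 1)
      = (V·(m−1)·w + (V−1)·b) / (V·m − 1)
```

If the metadata claim and s_reg disagree, every measurement made on the
reconstructed volume inherits the error: a distance whose squared length has
fraction f along the slice axis scales by `sqrt((1−f) + f·(s_a/s_t)²)` when
measured under an assigned spacing s_a while the voxels were acquired at
s_t. Frontal-plane skull stacks put cranial length almost entirely along the
slice axis (f ≈ 1), so a 2.8% spacing error becomes a ~5 mm error on a
~175 mm skull — fatal for quantitative genetics of craniofacial variation.

`ctspacing` reconstructs the gap sequence from Image Position (Patient),
detects inconsistent spacing, recovers the sub-volume structure, computes
s_reg, quantifies the induced measurement bias, and runs the
repeated-measures statistics (paired t-tests with Bonferroni adjustment, 99%
prediction intervals for a single future observation, inclusion audits of an
independent digitizer value) that decide *which* spacing faithfully
represents the physical specimen. A synthetic-data module generates phantom
DICOM series and measurement tables with the same structure, so the whole
pipeline is testable without any downloads.

## Worked example

```python
import ctspacing as cs

# the canonical problem series: 51 sub-volumes x 6 slices,
# 0.60 mm within, 0.50 mm between, stated spacing 0.60 mm
geometry, truth = cs.make_series(cs.w584_series_spec())
result = cs.audit(geometry)
print(result.status, round(result.regularized_spacing_mm, 8),
      result.subvolumes.n_runs, round(result.relative_discrepancy, 4))
# INCONSISTENT 0.58360656 51 -0.0273

# the bias that spacing mismatch induces on an axial 173.3 mm distance
print(round(cs.rescale_distance(173.3, 1.0, 178/305, 0.60), 1))
# 178.2   (4.9 mm / 2.83% larger than under the regularized spacing)
```

The audit flags the series as INCONSISTENT, regularizes it to
0.58360656 mm (2.7% below the 0.60 mm metadata claim), and the bias model
shows that keeping the claimed spacing would inflate an axial cranial-length
measurement from 173.3 to 178.2 mm.

From the shell, the same pipeline:

```bash
ctspacing simulate-series --preset w584 --out sim       # phantom series
ctspacing audit sim/dicom --out report                  # exit code 2: flagged
ctspacing correct sim/dicom --out corrected             # NRRD header sidecar
ctspacing simulate-measurements --seed 1 --out table.csv
ctspacing validate table.csv --out validation           # Tables-style reports
ctspacing validate --audit-only --out published         # 17/20 inclusion audit
```

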