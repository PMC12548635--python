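# Methods

## Series geometry and the audit

A single-frame DICOM series is reduced to one scalar per slice: the
projection of Image Position (Patient) onto the slice normal (the cross
product of the two Image Orientation (Patient) direction cosines). Slices
are sorted by that offset — instance number only breaks exact ties — and the
gap sequence is the first difference of the sorted offsets. Sorting is
therefore idempotent and independent of file order. Series whose normals
disagree by more than 1e-3 rad are rejected (gantry-tilt and non-parallel
rescue are out of scope); series with fewer than two usable slices are
rejected as too small.

Gaps are clustered greedily on the sorted values with an absolute tolerance
of **1e-3 mm**: well above float noise and the ~1e-8 mm precision of the
DICOM decimal-string position encoding, well below the 0.1 mm scale at which
real spacing discrepancies live. A series is UNIFORM when one cluster
remains and INCONSISTENT otherwise — a *single* deviant gap flags the
series, because that is when real importers warn and conservative QC should
too. The dominant gap is the highest-count cluster's mean, ties broken
toward the smaller value so reports are deterministic.

Sub-volume structure is recovered from the acquisition-number tag when it
varies (runs are maximal constant-tag blocks); otherwise geometrically, by
splitting wherever a gap leaves the dominant cluster. Geometric recovery is
exact whenever |w − b| exceeds the gap tolerance; below it the two gaps are
indistinguishable by construction.

The **regularized spacing** is total extent over gap count,
`(V(m−1)w + (V−1)b)/(Vm−1)` for a V×m pattern — identically the mean gap,
which is the independent oracle the tests use. It is reported to 8 decimal
places. The metadata verdict compares it to the stated spacing (Spacing
Between Slices preferred over Slice Thickness, since geometry is governed by
spacing) at a default relative tolerance of **0.5%**: scanner rounding is
far below it, while genuine misassignments in this problem domain are ~2.7%.
Correction is metadata-level only — offsets are rewritten as the arithmetic
sequence of the regularized spacing (an idempotent map), and a detached NRRD
header sidecar carries the corrected space directions; pixel data are never
resampled.

The catalogue table behind `expected_group` (W001–W487 at 0.75 mm, clean;
W488–W669 claimed 0.60 mm but actually ~0.58 mm, error-generating;
W670–W985 at 0.60 mm, clean) encodes the studied collection's final
designations. The audit never consults it, so the geometric evidence and the
catalogue expectation remain independent lines of evidence.

## Bias model

Voxel indices acquire physical meaning only through grid spacings, so the
distance between two landmarks at fixed voxel coordinates is
`sqrt((Δrow·p_r)² + (Δcol·p_c)² + (Δslice·s)²)`. Reassigning the slice
spacing from s_old to s_new rescales that distance by
`sqrt((1−f) + f·(s_new/s_old)²)`, where f is the **axial fraction** — the
share of the squared distance along the slice axis. At f = 1 the relative
error is exactly `s_new/s_old − 1`; for the 0.60 vs 178/305 mm pair that is
+2.81%. The slightly different 2.83% that results from forming the ratio of
the two distances *after* rounding them to 0.1 mm (178.2/173.3 − 1) is the
headline convention adopted for report parity: distances are printed to
0.1 mm and relative bias to two decimals in percent, and both arithmetic
paths are exercised in the tests. f defaults to 1 for headline predictions
because the validation measurement runs nearly along the slice axis, but it
is always an explicit parameter.

## Validation statistics

The measurement substrate is a long-format table: specimen × modality ×
replicate → distance in mm, with three specimen groups and the modalities
Original (calipers), CT_0.58 / CT_0.60 / CT_0.75 (CT reconstructions under
candidate spacings) and a single Microscribe digitizer value per specimen.

* **Paired t-tests** between every within-specimen modality pair, replicates
  paired by replicate index. The repeated measurements carry no stated
  pairing, so pairing-by-index is a modelling convention — documented here
  prominently; the test is t = mean(d)/(sd(d)/√n) on differences, df = n−1,
  two-sided p. Zero-variance nonzero-mean differences give a signed infinite
  statistic with p = 0; identical samples raise a degenerate-pairing error
  that is logged per specimen without aborting the run.
* **Multiplicity**: Bonferroni, `min(1, m·p)`, with m defaulting to the
  total number of comparisons in the run (40 in the reference design:
  10 + 15 + 15). Bonferroni at m = 40 reproduces every published p/p.adj
  pair (0.002→0.08, 0.018→0.72, 0.005→0.20); no other standard adjustment
  does at these values, so it is adopted — as an inference, configurable via
  m. Significance labels: ns above 0.05, then */**/***/**** at
  0.05/0.01/0.001/0.0001, most extreme applicable.
* **Prediction intervals**: mean ± t_{(1+c)/2, n−1}·sd·√(1 + 1/n), the
  single-future-observation interval of an intercept-only least-squares fit,
  default confidence 0.99. Zero-sd samples yield a degenerate [mean, mean]
  interval with a warning flag. The implementation is cross-checked against
  statsmodels' OLS `get_prediction` in the tests.
* **Inclusion audit**: closed-interval membership of the Microscribe probe,
  with a signed exceedance (0 when included; distance beyond the violated
  limit otherwise, positive above). Specimens without a probe are excluded
  with a logged warning. Summaries count inclusions per reference modality
  and group and report min/max exceedance per group × modality.

Report rounding follows the published convention: statistics and interval
limits to 2 dp — but rounded values are always printed alongside the
unrounded ones, so a "0.00" is never bare.

The packaged file `ctspacing/data/published_prediction_intervals.csv`
carries the published interval limits, probes and verdicts for the 20
validation specimens. It contains limits only, not replicates, so it
supports audit-only reproduction (every TRUE/FALSE, the 17/20 caliper count,
the 2.86–3.75 mm and 1.97–2.76 mm exceedance bands); re-deriving the
intervals and t-statistics themselves requires the raw replicate file, which
is not redistributable here.

## Synthetic data

`make_series` realizes the V×m/w/b pattern exactly (offsets are the
cumulative gap pattern; positions are written to DICOM at 1e-8 mm), with the
acquisition-number tag incrementing per sub-volume. The canonical problem
preset is V=51, m=6, w=0.60, b=0.50, stated 0.60 — the configuration that
regularizes to 0.58360656 mm; clean presets are single-block series at 0.60
or 0.75 mm. The V×m model assumes every sub-volume has the same slice count,
which is what reproduces that 8-decimal value. The optional phantom is a
bright ellipsoid plus two point fiducials snapped to voxel centres, whose
snapped physical positions are returned as ground truth; phantoms are
geometric only — no CT physics (noise texture, beam hardening, partial
volume), so passing phantom tests demonstrates geometry handling, not image
realism.

`make_measurement_table` draws, per specimen, a true distance D uniform on
**110–155 mm** (spanning the published validation range), then
Original ~ N(D, 0.4 mm), CT ~ N(D·sqrt((1−f)+f·(s_a/s_t)²), 0.3 mm) per
assigned spacing, and one Microscribe value ~ N(D + 0.5 mm, 0.3 mm).
Group true spacings are 0.75 / 0.60 / 178/305 mm; the "0.58" modality is
modelled at 178/305 mm in all groups. The noise sds and the +0.5 mm
digitizer offset are this package's defaults — no variances are published —
chosen to give interval widths of roughly 1–3 mm and the observed tendency
of digitizer values to sit slightly high; all are configurable, and the
Gaussian additive error model is itself an assumption, stated as such.
With these defaults the ~2.8% misassignment bias (≥3 mm at ≥110 mm) is an
order of magnitude above the ~0.16 mm standard error of a 10-replicate
paired difference, which is why parameter-recovery tests expect the
misassigned modality to be flagged for every specimen. One seed governs a
generator call; per-specimen substreams derive from (seed, group, index), so
extending a table never perturbs existing draws.

## Problem sizes and numerical choices

Tests run the canonical 306-slice series, 100-spec randomized oracles for
the regularization identity, a 10,000-simulation empirical-coverage check of
the 99% prediction interval (expected 99% ± 1%), and a 10,000-replicate
law-of-large-numbers check of the table generator — a few seconds in total.
Oracle identities (mean gap, closed form) are asserted at 1e-12/1e-9
relative; geometric round trips at the 1e-8 mm write precision; interval
cross-checks at 1e-9 relative.

## Limitations

Multi-frame DICOM, compressed transfer syntaxes, gantry tilt and
non-parallel slice rescue are out of scope. Whether between-block gaps are
smaller than within-block gaps is not assumed. No nonparametric or
equivalence tests and no repeatability (ICC) decomposition are provided, and
landmark placement is an input, never detected on images (fiducial peaks on
synthetic phantoms aside).
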