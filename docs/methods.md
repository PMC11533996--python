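# Methods

## Scope and model

`solventaudit` audits the solvent component of macromolecular crystal
structures at three levels: (i) per-structure, against the deposited
parameters (occupancies, ADPs, R factors); (ii) per-structure, against the
diffraction data via difference electron-density maps; and (iii) per-cohort,
via multivariate statistics over structure-quality metrics. This note
records the models, defaults and numerical choices, and what the synthetic
tests do and do not demonstrate.

## Structure factors and maps

Structure factors are computed by direct summation over the P1-expanded
atom list,

    F(h) = Σ_j f_j(s) · occ_j · exp(−B_j s²/4) · exp(2πi h·x_j),   s = 1/d(h),

over one Friedel hemisphere to the requested d_min, with F(000) = Σ Z_j·occ_j
carried separately. The default atomic form factor is a single Gaussian per
element, f(s) = Z·exp(−B_ff s²/4) with B_ff = 12 Å² (a ~0.4 Å real-space
blob). This is deliberate: the audit needs realistic peak *shapes* and
positions, not absolute scattering accuracy. Four-term IT92 Gaussian
coefficients are available via `form_factors="it92"` when closer absolute
amplitudes matter.

Maps are plain Fourier syntheses on a periodic unit-cell grid,
ρ(x) = (1/V) Σ_h F(h) exp(−2πi h·x), computed by FFT after Friedel
completion (the map is exactly real). Difference coefficients are
(k|Fo|−|Fc|)·exp(iφc) and (2k|Fo|−|Fc|)·exp(iφc), with k the least-squares
amplitude scale k = Σ|Fo||Fc|/Σ|Fc|². Two simplifications are intentional:

- **No maximum-likelihood m/D weighting.** Maps are unweighted Fo−Fc and
  2Fo−Fc with calculated phases.
- **No bulk-solvent model.** Adequate for the toy crystals audited end to
  end; on refined real entries this is the main cause of R and peak-height
  mismatch at low resolution.

Grid spacing defaults to d_min/3 (at least 3 samples per resolution element
per axis); map σ is the RMS deviation about the mean over the full cell.
Map values at atom sites use trilinear interpolation, not nearest-node
lookup. All distance logic (clash, hydrogen-bond partners, peak merging)
wraps through periodic images; symmetry beyond translations is handled by
prior P1 expansion.

## Peak search and water placement

Peaks are strict local extrema over the 26-neighbour periodic neighbourhood
of each grid node, refined per axis by quadratic (three-point parabola)
interpolation with the offset clamped to ±half a node, and merged greedily
(highest first) within a 2.0 Å radius. A constant map has no extrema.

A positive Fo−Fc peak becomes a candidate water when its height is ≥ 3.5σ,
at least one N or O atom lies within 2.4–3.2 Å under periodic images, and
no atom of any kind is within 2.2 Å. 2Fo−Fc searches use the same rule at
1.4σ. The thresholds that are not standard practice are explicit defaults:
`merge_radius` 2.0 Å and `clash_min` 2.2 Å (just below the 2.4 Å
hydrogen-bond floor, so a candidate cannot double-count an existing atom's
density); both are configurable.

Deposited waters are flagged when the Fo−Fc value at the O site is ≤ −3.0σ
(`negative_density`), when the 2Fo−Fc value is below 1.0σ
(`no_positive_support` — our default, exposed in `SupportThresholds`), when
a non-water atom is within 2.2 Å (`protein_overlap`), when the ADP equals
30.00 ± 0.005 Å² (`default_adp`, the placement-tool default that signals an
unrefined water), or when occupancy is exactly 0 with a refined positive B
(`zero_occupancy_with_refined_adp`).

## Screening rules

- **Working set**: X-ray or neutron method, resolution ≤ 2.5 Å (boundary
  inclusive — "2.5 Å or higher resolution"), longest chain ≥ 30 residues,
  group depositions excluded. Records missing a resolution are excluded
  with the explicit reason `missing_resolution`; every exclusion carries
  its first failing rule. Missingness in metadata is first-class: absent
  cells stay `None`, never 0.
- **Occupancy partition**: zero = {0}; near_zero = (0, 0.1]; normal =
  (0.1, 0.9); near_full = [0.9, 1.0); full = {1.0}; over = (1.0, ∞). Two
  edges were genuinely open: the gap below 0.01 is folded into near_zero
  (occupancies "lower than 0.1" are experimentally equivalent to zero), and
  near_full runs to 1.0 exclusive so that 0.995 is flagged — it is exactly
  as unjustifiable as 0.99. Negative occupancies are data errors and are
  reported separately rather than classified.
- **R consistency**: a depositor→DCC gap above 0.02 is flagged (program-to-
  program differences of ~0.01 are expected, so the threshold sits above
  that); R_work > R_free within one source is flagged as an inverted
  cross-validation relationship.
- **Expected ratio**: the packaged reference for waters-per-residue vs
  resolution is a monotone cubic (PCHIP) interpolant anchored at the cohort
  means 1.78 (≤1.0 Å), 0.61 (2.0 Å) and 0.25 (2.5 Å), with intermediate
  points on a smooth decay between the anchors. Outside the table the
  nearest endpoint is returned. A cohort-fitted `RatioCurve` can be passed
  instead of the packaged table.

## Cohort statistics

All of these are implemented directly (scipy/scikit-learn act only as
cross-checks in the tests), because the audit depends on their exact,
inspectable conventions:

- **Preprocessing order** is median imputation, then 0–1 min–max scaling;
  Euclidean distances on that matrix feed both Ward and LOF. Constant
  columns scale to 0 with a warning; fully missing columns are an error
  naming the column.
- **Ward clustering** uses the Lance–Williams recurrence with heights on
  the conventional scale height² = 2·ΔSSE (matching scipy dendrograms),
  merging the globally closest pair with ties broken by the first pair in
  row-major order. Ward on Euclidean distances is reducible, so heights are
  monotone non-decreasing.
- **LOF** (k = 5 default) follows the original definition with
  tie-inclusive neighbourhoods: the neighbourhood holds *all* points within
  the k-distance. The local reachability density is capped at 10¹⁰
  (coincident duplicates share a zero k-distance; the cap keeps their
  neighbours' scores huge but finite). Scores are translation- and
  scale-invariant.
- **PCA** standardizes columns and eigendecomposes the correlation matrix;
  eigenvalues sum to p. Sign convention: each component's largest-magnitude
  loading is positive. Only complete-case rows are accepted — imputation
  biases PCA, so the caller filters instead.
- **Ratio curves** are least-squares fits in a truncated-power cubic
  regression-spline basis (C² by construction), knots at quantiles of x by
  default, with pointwise 95% confidence bands from σ̂²(XᵀX)⁻¹ under
  homoscedastic Gaussian residuals. Ill-conditioned or underdetermined
  systems are rejected with a suggestion to use fewer knots.
- **Yearly summaries** use linear interpolation between order statistics
  for quartiles (box edges depend on this convention, so it is fixed and
  documented), whiskers at the most extreme point within 1.5·IQR, and
  pooling of years before a configurable floor (default 1995).

## Synthetic data: what it emulates, and what it does not

Toy crystals are P1 boxes (default 18 Å cube) of four-atom pseudo-residues
(N, CA, C, O) placed by rejection sampling at ≥ 2.0 Å separation, with
waters planted 2.5–3.1 Å from a protein N or O and ≥ 2.4 Å from everything
else, B factors uniform in 8–20 Å², and occupancies per the anomaly spec.
Two guarantees are deliberate design, not realism: every water has a polar
partner in hydrogen-bond range (so a failed recovery indicts the search
heuristic, never the fixture), and partners are protein atoms only (so
deleting waters never deletes another water's partner). Observed amplitudes
are |Fc| of the full model with optional multiplicative Gaussian noise —
the simplest model that perturbs R and peak heights smoothly; ~5% of
reflections get a free flag.

The generators do **not** mimic real protein geometry, bonding, secondary
structure, bulk solvent, anisotropy or radiation damage. Passing the
recovery tests therefore shows that the density machinery and placement
rules are internally correct and sharp on well-posed targets; it does not
show that the same thresholds are optimal on real, noisy, solvent-corrected
data, where the missing bulk-solvent model raises R and compresses
low-order difference terms.

Problem sizes used by the test suite and the acceptance script — 20
crystals of ~60 atoms at d_min 1.8 Å for water recovery, 100 seeds of
203 × 8 quality tables for outlier recovery, oracle grids up to 16³ and
matrices up to n = 50 — were chosen so each check runs in seconds while
still exercising every code path; the statistics are flat in these sizes.

## Known limitations

- No refinement of any kind: coordinates, B factors and occupancies are
  never adjusted, so the audit reports the deposition as-is.
- No bulk-solvent or likelihood weighting (above): R values computed for
  real low-resolution entries will exceed refined values.
- Exact water *counts* from interactive model-building tools depend on
  their internal clustering details; this package's counts agree on
  ground-truth synthetics but are not expected to match such tools
  entry-for-entry on real depositions.
- Multi-model NMR files, anisotropic ADP tensors and Laue data handling are
  out of scope; neutron structures are supported only through D/DOD
  recognition.
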