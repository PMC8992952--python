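# Methods

## RBE models and the weighted dose

All four dose variants multiply the physical dose voxel-wise by a model RBE.
The constant comparator uses RBE ≡ 1.1; the McMahon linear fit uses
RBE = 1 + 0.055·LETd with no renormalization (the fit is applied exactly as
published, without rescaling to 1.1 at a reference LET). The McNamara and
Wedenberg models are linear-quadratic (LQ) parameterizations: their
RBE<sub>max</sub>/RBE<sub>min</sub> asymptotes (RBE at vanishing and infinite
dose) are linear in LETd, and the dose-dependent RBE is the closed-form
solution of LQ survival equivalence,

    RBE(d, LETd) = [ sqrt((α/β)² + 4·d·(α/β)·RBEmax + 4·d²·RBEmin²) − α/β ] / (2d).

Assumptions and numerical choices:

* **α/β = 3 Gy** for late-responding heart tissue, a single scalar per run
  (no per-organ map). Configurable per model spec.
* **Fraction dose.** The LQ formalism is defined on the dose per fraction, so
  the default evaluates RBE at d = physical dose / n_fractions (25 fractions
  for the default 50 GyRBE prescription). A `total_dose` mode evaluates on
  the accumulated dose instead; the two are exposed side by side because
  either reading is defensible and the choice shifts LQ-model RBE values by
  a few percent (lower d → closer to RBE_max).
* **Low-dose fallback.** Monte Carlo LET scoring is unreliable below ~10 cGy,
  so voxels with physical dose < 0.10 Gy (configurable) are assigned the
  clinical RBE of 1.1 rather than a model value. Using 1.1 — not 1.0 — makes
  the low-dose region contribute identically to every dose variant, so
  MHD differences between variants reflect only the scored region.
* **RBE_min clamping.** The McNamara RBE_min fit goes negative for
  LETd·√(α/β) ≳ 160 keV/μm·Gy^{1/2}; values are clamped at 0 (keeping the
  closed form real) and the clamp count is logged. Physical proton LETd never
  reaches this regime; the clamp only guards degenerate inputs.

## Grids, masks and file formats

Volumes are scalar fields on a regular lattice, indexed (x, y, z) with
0-based indices; a voxel center sits at origin + index·spacing (the
MetaImage convention). Units ride along as tags (Gy, GyRBE, keV/μm) and are
never converted implicitly — the Gy/GyRBE distinction is the point of the
package. On disk every volume is an uncompressed MetaImage pair; the units
tag is stored in the header's `Comment` field. A case bundle is a directory
(`dose.mhd`, `letd.mhd`, `mask_<name>.mhd`, `plan.txt`). Masks are binary
and consumed as volumes; DICOM-RT structure rasterization is out of scope
and would be a converter in front of `load_case`. Grids within a case must
agree in shape exactly and in spacing/origin to 1e-6 mm; no resampling is
performed.

## Dose metrics

* Vx uses a closed comparison (dose ≥ x), matching common TPS convention;
  volumes are relative (% of structure voxels).
* Dxcc sorts voxel doses descending and returns the dose of the voxel at
  which the accumulated volume (voxel volume = product of spacings) first
  reaches x cc — no partial-voxel interpolation, so on the default 2 mm grid
  the result is granular at 0.008 cc.
* DVH curves are cumulative with absolute dose edges and relative volume;
  by construction the curve at an edge equals Vx at the same threshold.
* LETd histograms restrict to mask voxels above a dose cutoff (1/20/40 Gy
  are the conventional choices) because high LET in near-zero-dose voxels is
  biologically irrelevant; an empty selection is returned as an all-zero
  histogram with an `empty` flag rather than an error.
* Line profiles use trilinear interpolation at fixed steps (default 0.5 mm)
  and require both endpoints inside the voxel-center bounding box.

## Gamma index

Global normalization to the reference maximum, 2%/2 mm criteria, 10%
low-dose cutoff, 3×DTA search radius — all configurable, with a local
(per-voxel) normalization mode behind a flag. Discrete mode searches
evaluated voxel centers; interpolated mode then refines every still-failing
voxel over a trilinear fine lattice at DTA/10 steps. Because a finer search
can only lower the minimum, refining only failing voxels leaves passing
voxels at their discrete value and keeps the pass/fail decision exact while
bounding cost. Gamma is invariant under adding a constant to both grids only
when the normalization dose is pinned explicitly; otherwise the reference
maximum (and with it the dose criterion) shifts.

## ACE risk and cohort statistics

Risk arithmetic is linear in MHD and kept at full precision; one-decimal
half-up rounding is applied only at the reporting layer, which is what makes
rounded risk values reproducible. Cohort excess-risk summaries are medians
of per-patient risks, not the risk of the median MHD; both pathways are
available (`risk_report` vs `ace_risk` of a median) because the two differ
in the second decimal and reports should be explicit about which they print.
The Wilcoxon signed-rank test drops zero differences, requires ≥ 5
informative pairs, and uses exact enumeration of all 2^n sign assignments
(with average ranks under ties) for n ≤ 12, switching to the normal
approximation with tie correction above that.

## The synthetic phantom

No public dose/LETd grids exist for this treatment site, so the pipeline is
exercised on analytic phantoms that reproduce the structure the analysis
actually consumes:

* 60³ voxels at 2 mm (a 12 cm cube) — seconds-scale runtime at clinical
  grid resolution;
* a slab CTV (32 mm deep, 80 mm wide) at uniform physical dose
  prescription/1.1 = 45.45 Gy, with a single effective beam axis along z.
  Clinical plans use two en-face fields, but for the distal-edge physics
  seen by the heart one axis gives the same phenomenology;
* a sigmoid distal falloff 2/(1+e^{ku}) continuous with the plateau,
  k = ln 6 / d80–20, with d80–20 = 6 mm by default;
* LETd ramping 2 → 4 keV/μm across the CTV depth, rising to a peak of
  8 keV/μm at 2 mm beyond the distal face, then decaying very slowly
  (0.02 keV/μm per mm) so the peak location is unique; LET is defined only
  where dose ≥ 0.10 Gy, mirroring the scoring cutoff;
* multiplicative Gaussian dose noise of 0.5% (typical Monte Carlo
  statistical uncertainty), seeded; LETd is noise-free;
* an ellipsoidal heart with semi-axes (30, 26, 18) mm — flattened along the
  beam axis and smaller than anatomy so that it fits the grid while its
  proximal surface can approach within 1 mm of the CTV; a nested ventricle
  ellipsoid (0.55 scale, slightly offset) and a 2.5 mm-radius LAD tube along
  the anterior heart surface, which therefore sits in the high-dose,
  high-LET falloff.

Cohorts sweep the heart–CTV gap: mean heart dose is strictly decreasing in
the gap, and per-case gaps are solved by bisection on the noise-free
analytic field so the realized MHD(RBE=1.1) values span a requested range —
0.39–2.44 GyRBE by default, a representative spread for left-sided
breast/chest-wall cohorts with nodal irradiation. Group labels (chest wall /
intact breast) alternate so both groups cover the range.

What the phantom does **not** emulate: anatomical heterogeneity (lung, ribs),
spot-by-spot beam structure, lateral penumbra shape, inter-patient LET
spectrum variation, and the partial-volume mixing of proximal low-LET and
distal high-LET regions that real hearts see. In the phantom the whole
scored heart lies in the distal high-LET band, so variable-RBE enhancements
of heart metrics are systematically larger than clinical values; passing
cohort tests therefore demonstrates correct mechanics and orderings
(variable-RBE ≥ constant, Wedenberg ≥ McNamara ≥ constant, McMahon ≥
constant per patient; significant MHD shifts), not clinical effect sizes.

## Problem sizes

The default analyses run a 20-case cohort at 60³ voxels; the gamma benchmark
compares a handful of noisy grids against their analytic references in
interpolated mode. These sizes keep a full pipeline run in the tens of
seconds on one CPU while leaving every statistical test adequately powered
(n = 20 pairs for the signed-rank comparisons).

## Known limitations

* No DICOM-RT input; masks must be provided as volumes.
* No resampling: all grids in a case must share one lattice.
* Dxcc granularity is one voxel; supersampled DVHs are not provided.
* The Darby slope's confidence interval (2.9–14.5 %/Gy) is not propagated;
  the slope is a scalar parameter.
* The gamma search radius truncates at 3×DTA, which cannot change pass/fail
  (a passing point needs distance ≤ DTA) but can overstate gamma values > 3.
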