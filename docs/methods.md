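# Methods

This note documents the statistical model behind `thetascreen`, the
choices made where the design was genuinely open, and what the synthetic
screens do and do not establish about real data.

## Pipeline model and assumptions

**Unit of analysis.** Per-object (cell) features are aggregated to
per-image medians and then to per-well medians; the well is the unit
profile. Screens of this design place each compound in one well per cell
line per replicate at a single concentration, so "compound" and "well"
coincide within a replicate; compound-level coordinates are the median of
the compound's well coordinates. The median-of-medians roll-up is robust
to outlier cells and to unequal cell counts per image, and keeps the
image-level rows available for variance estimates.

**Image QC.** Images are removed when their saturated-pixel fraction
exceeds `sat_max` (default 0.2) or their focus score falls below
`focus_min`. No universal focus scale exists across instruments, so by
default `focus_min` is self-calibrated per plate as the 1st percentile of
the negative-control images' focus scores; an explicit threshold can be
given instead. The self-calibrating default intentionally trims the ~1%
blur tail even on clean data — with one field per well this removes a few
percent of wells, which downstream stages tolerate (compounds missing a
replicate are excluded from ranking and reported).

**Feature selection.** Variance filter (< 1e-5) first, then greedy
correlation pruning at |r| > 0.9. "Remove one of the pair" is ambiguous;
we remove the member with the larger mean |r| against all other features
(a fixed redundancy score computed once), breaking ties alphabetically —
deterministic, and it keeps the less redundant feature. Selection is
global (one retained set for the whole screen) because cross-cell-line
comparison requires a common feature basis.

**Normalization.** Per plate and feature: divide by the DMSO median, then
standardize by the DMSO spread. Division is guarded — when
|median| < 1e-9 × (pooled SD + 1) the feature is shifted rather than
divided, since morphology features can legitimately center on zero. The
centering constant is the DMSO *median* of the divided values by default:
this pins the per-plate DMSO feature median at exactly 0 (and, because SD
is translation-invariant, the DMSO SD at exactly 1), making the later
control-centroid-at-origin step an exact no-op per feature and keeping
the null defined entirely by the controls. A `center="mean"` option gives
classical mean/SD z-scores; with well-behaved controls the two differ by
a small per-feature offset. Features with zero DMSO spread on any plate
are dropped with a warning. Missing values are imputed with the plate
DMSO median before the transform, i.e. at the null. Plate-local (not
screen-global) DMSO statistics are used throughout, which is what makes
multiplicative plate effects cancel exactly.

**PCA.** Computed by SVD of the normalized matrix with no re-centering or
re-scaling — standardization already put every feature on the control
scale, and re-centering would reintroduce dependence on the treatment mix.
Variance fractions are singular-value energies; k is the smallest count
reaching `variance_prop` (default 0.9); components beyond the numerical
rank are never retained. Signs are fixed by making each loading vector's
largest-magnitude element positive, so outputs are reproducible across
runs and libraries.

**Activity.** l1 distance of the compound's centered coordinates to the
origin, thresholded at `k_sd` (default 2) × SD (n−1 denominator) of all
compound distances in that cell line. Two properties worth knowing:
the l1 norm is *not* rotation-invariant (a documented, tested property —
the l2 variant would be), and the threshold is scaled by the SD of a
distance distribution that includes the active compounds, so the rule is
calibrated by the screen itself: with few strong actives it is stringent
for nulls, while in a noise-dominated space with many moderate actives it
becomes liberal. The tests therefore always compare its null call rate
against the empirical tail of the same distance distribution rather than
a nominal error rate. Compounds inactive in any screened cell line are
removed before divergence ranking.

**Multivariate Z′.** With hundreds of features and tens of control wells,
covariance-based discriminants are ill-posed (p ≫ n), so control wells
are projected onto the axis joining the negative- and positive-control
per-column medians and the classical Z′ is evaluated on the 1-D
projections. Computed per cell line and pooled (all lines' normalized
controls, one common axis); in feature space by default, with a PC-space
option. A zero-length axis yields a −inf sentinel with a warning.

**TCCS.** θ = atan2(PC2, PC1) in degrees ∈ [0, 360); Δθ is the
wrap-around difference, a pseudometric on directions. θ is flagged
undefined for compounds called inactive in that line (an unreliable
direction is worse than none); undefined records propagate to missing Δθ
and are excluded from ranking with a count. A k-dimensional variant
(arccos of cosine similarity of the full retained coordinate vectors) is
available behind `theta_mode="kd"`; the 2-D angle is the default because
the divergence score is defined in the PC1–PC2 plane. Replicate-level
reporting uses the plain arithmetic mean of per-replicate Δθ values
(already in [0, 180], no circular wrap needed); ranking uses per-replicate
ranks only. Rank-product ties are broken by larger mean Δθ, then
lexicographically — deterministic, and the mean-Δθ tie-break is the one
part of the ordering that is not invariant under monotone transforms of
Δθ (the RP values and per-replicate ranks are).

## Synthetic screens: what they emulate

Per cell line c and feature f, a cell's raw value is

    ( mu_cf + s_cf · [ effect_f + (W_c z)_f + eps_f ] ) · g_pf

- `mu_c`, `s_c`: distinct basal mean and SD scale per line (drawn once per
  line), giving well-separated raw morphologies.
- `W_c z + eps`: low-rank (10-factor) plus unit-diagonal noise in SD
  units, mimicking the strong correlation structure of morphology
  features. The two dominant factors (scales 2.5 and 2.2 vs ≤ 1.2 for the
  rest) lie along a fixed orthonormal plane (e1, e2) of standardized
  feature space shared by all lines, so that plane is the top-2 principal
  plane of the standardized baseline covariance.
- `effect`: magnitude m (baseline-SD units) × unit direction
  cos φ·e1 + sin φ·e2. A compound's φ is shared across lines unless a
  `divergence_spec` entry plants an angular offset for a pair; inactive
  compounds have m = 0. Positive-control wells get a fixed line-specific
  in-plane effect of magnitude 12. Effects are applied on the raw scale
  *before* plate effects, which is exactly what plate-wise normalization
  must undo.
- `g_p`: per-plate, per-feature multiplicative factor exp(N(0,
  `plate_effect_sd`)).

Planted angles live in the standardized (SD-unit) plane because that is
the scale the estimator sees after z-normalization; ground-truth effect
vectors are emitted in those units, and the dot-product oracle on them
reproduces planted angles to 1e-9°. Defaults mirror the full study
design: 8 cell lines × 1280 compounds at one concentration in 384-well
plates (first column DMSO, last column staurosporine → 16 + 16 control
wells), 340 features, one field per well with 8–14 cells per image, 40%
inactive compounds with magnitudes 2–6 SD, plate effect SD 0.1. Cell
counts per image are drawn uniformly so median aggregation is exercised
with unequal n.

**What the simulator does not model:** pixel data and segmentation error;
organelle-specific feature semantics (stains are metadata labels only);
plate-position (edge) effects; dose–response structure; heavy-tailed or
skewed feature noise; batch drift over time. Passing tests establish that
the *estimator chain* is correct and self-consistent under a plausible
generative model — not that any particular biological screen satisfies
that model.

## Numerical choices and degenerate inputs

- Medians everywhere follow the even-count convention (mean of the middle
  pair). SDs use the n−1 denominator.
- Rank products are computed as (∏ ranks)^{1/R}; with ≤ tens of
  thousands of items and a handful of replicates this is exact in double
  precision (e.g. ranks 1, 4, 2 give exactly 2.0).
- PCA rank tolerance: s₀ · max(n, p) · eps, the usual SVD cutoff.
- Degenerate inputs fail loudly with typed errors: empty or key-less
  feature tables, plates with < 2 control wells of either class, < 2
  surviving features, < 3 compounds for the distance SD, no negative
  controls to center on, < 2 retained components for θ.
- Determinism: all simulation randomness flows from a single
  `numpy.random.default_rng(seed)` in fixed iteration order; identical
  config + seed give bit-identical tables, and pipeline manifests contain
  no timestamps or absolute paths, so identical runs give byte-identical
  manifests. The manifest's config hash covers analysis parameters only
  (not file paths).

## Problem sizes used in the checks

The test-suite and acceptance-script simulations are sized for a quick
desk run while keeping every estimator in its working regime: oracle
checks use 10,000 random vector pairs and 1,000 rotations; Z′ calibration
uses 64 wells per control class over 100 seeds; activity recovery uses
1,000 null + 50 planted compounds; end-to-end divergence recovery uses 2
cell lines × 96 compounds × 3 replicates (20 compounds planted at 120°,
and an angle sweep 0–180° in 30° steps); the determinism check runs the
full 8-line × 1280-compound × 384-well design twice.

## Known limitations

- The 2-SD l1 activity rule has no fixed false-positive rate by
  construction (see above); interpret per-line active counts relative to
  the screen's own distance distribution.
- θ compresses a k-dimensional response to a plane; compounds whose
  divergence lies outside PC1–PC2 are invisible to the 2-D score (the
  `kd` variant sees them, at the cost of comparability with the standard
  method).
- Mechanism-of-action triage of the hit list is deliberately manual: the
  package honours an exclusion list but automates no annotation.
- Rank-product significance (permutation p-values) is out of scope; the
  RP is used as an ordering statistic only.
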