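# Methods

## Model and assumptions

The package treats the proximity of tissue to an artery as a proxy for
supply: each ROI voxel is attributed to the artery whose labeled voxels are
closest in Euclidean mm. This is a data-driven stand-in for perfusion
territories, not a perfusion measurement; it assumes that (i) the
delineated vessel segments reach the neighborhood of the ROI, (ii)
closeness correlates with supply probability, and (iii) a hard
winner-takes-all assignment is acceptable (no overlap or watershed
mixtures). Geodesic, vessel-tree-following distances are deliberately out
of scope.

Distances are computed with an exact Euclidean distance transform on voxel
centers, honoring anisotropic spacing, so results are stated in physical mm
and are resolution-independent up to discretization. Supply volume
fractions are voxel-count ratios within the ROI; on a uniform grid this is
identical to a physical-volume ratio.

### Conventions and tie-breaks

- Label ids are fixed: 1 pericallosa, 2 callosomarginalis, 3 precentral,
  4 central, 5 postcentral; background is 0; the ROI is a separate binary
  mask.
- All exact ties (equidistant voxels in parcellation, vote ties in atlas
  fusion, overlapping vessel rasterization) resolve to the smallest label
  id. The choice is arbitrary but fixed, which makes fractions and atlases
  bit-reproducible.
- An artery with no labeled voxel is *absent*: its distance map is flagged
  empty, it is skipped in parcellation, and its supply fraction is exactly
  0. The zero test used for pattern counting is exact (no epsilon), valid
  because fractions derive from integer counts.
- Left–right flipping mirrors the first array axis; volumes entering atlas
  fusion must already share one grid (nonlinear template registration is
  upstream preprocessing, not part of this package).

## Dominance ratios and ratings

Four ratios are computed per hemisphere: combined-ACA over total supply;
pericallosa over total ACA; central over central+precentral (postcentral
excluded from this pairing because of its low, erratic contribution); and
postcentral over total MCA. A zero denominator yields an *undefined*
ratio, encoded as `None` rather than raised, since a hemisphere without an
ACA branch is a legitimate phantom configuration. The postcentral/MCA
ratio is reported but not categorically rated by default.

Ratings use a closed interval: ratios in `[lower, upper]` count as equal
contribution; exactly hitting a threshold therefore rates as equal, which
keeps the equidistant pair (0.33, 0.66) symmetric around 0.5. The sweep
varies the pair jointly — n lower thresholds equally spaced on
[0.05, 0.45], endpoints included, upper = 1 − lower — and scores each
pair's category frequencies against a reference table with
`1 − ½·Σ|f_i − g_i|` (total-variation agreement). The metric choice is
isolated behind `agreement_score`; ties in the best-pair argmax resolve to
the smallest lower threshold. Undefined ratios are excluded from the rated
denominator because no threshold can classify them.

## Statistics

Group tests are selected from the data: Shapiro–Wilk per group (α = 0.05)
for normality and median-centered Levene (α = 0.05) for homoscedasticity;
all-normal and homoscedastic → t-test (paired where requested) or one-way
ANOVA; normal but heteroscedastic → Welch t-test / Welch ANOVA; any
non-normal group → Kruskal–Wallis. The α = 0.05 gates are a conventional
operationalization; they are constants, not tunables.

The regression layer fits `thickness ~ age + sex (+ vascular category)` by
OLS with treatment coding (references: female; 3-vessel pattern; equal
contribution) and reports HC3 robust standard errors with t-distribution
p-values. Full vs. reduced models are compared with the classical partial
F-test on residual sums of squares, `F = ((RSS_r − RSS_f)/Δdf)/(RSS_f/df_f)`
— note the comparison uses the ordinary RSS even though coefficient
inference is HC3-robust, matching common practice of pairing robust
standard errors with an ANOVA-style model comparison. Rank-deficient
designs raise with the aliased terms named instead of silently dropping
columns. Covariate-adjusted thickness is `intercept + residual` of the
reduced model; its sample mean equals the intercept by construction.
Hemispheres are treated as independent observations; within-subject
correlation between left and right hemispheres is not modeled (no
mixed-effects layer), a known simplification.

No multiple-testing correction is applied across the vascular models; the
reported p-values are raw.

## Phantom design

No geometric model of real manual delineations exists, so the phantom
geometry is a free design choice, made once: the cortical sheet is a 120°
section of a cylindrical shell (default radius 0.31 × grid extent,
thickness 2.5 mm) — a curved gyrus-like slab without true folding — and
each artery is a circular arc in its own angular sector, offset 2.8 mm
outside the sheet, rasterized with a one-voxel radius around the continuous
curve. Ground-truth territories use exact point-to-polyline distances at
voxel centers, independent of the voxelized distance-transform path, so
pipeline discretization error is measurable: at 0.45 mm on a 64³ grid the
per-vessel deviation between pipeline and truth fractions stays below 0.05
(measured ≈ 0.03), and a mirror-symmetric two-vessel scene
(`mirrored_phantom_config`, arcs constructed as exact point-wise mirror
images) splits the ROI 0.5/0.5.

What the phantoms do *not* emulate: cortical folding, vessel tortuosity and
radius variation, partial-volume effects, rater variability, and
registration error. Passing phantom tests therefore validates the
computational pipeline, not the anatomical fidelity of territory estimates
on real data.

### Cohort generator

Default cohort conditions: 38 hemispheres with pattern mix
{3-vessel: 10, 4-vessel: 19, 5-vessel: 9} using the dominant compositions
(3-vessel = precentral + central + one ACA branch; 4-vessel adds the second
ACA branch; 5-vessel = all). Covariates: age ~ U(22, 42) years, sex
Bernoulli(½); thickness = 2.70 mm − 0.11 mm·1[male] − 0.0045 mm/yr·age +
N(0, 0.05 mm). The sex effect is roughly twice the residual SD — a large
standardized difference of the size seen in healthy young-adult motor
cortex — and the age slope produces a modest negative correlation over this
age range. Gaussian noise is the standard choice for OLS-recovery
validation. All randomness flows from one integer seed through
`numpy.random.default_rng`; identical seeds give identical cohorts.

## Numerical choices and problem sizes

- Distance-oracle tests run on grids ≤ 16³ where an all-pairs brute force
  is feasible; agreement tolerance 1e-9 mm. At mathematically tied voxels
  the transform and the oracle may round differently, so tie-break labels
  are compared only where the minimizer is unique by > 1e-9 mm.
- The acceptance phantoms use the default 64³ grid at 0.45 mm
  (≈ 14 500 ROI voxels); cohort-level tests use the full 38-hemisphere
  default, and the type-I-error simulation uses 1000 replicates of n = 38,
  sizes chosen to keep the whole suite comfortably fast while leaving
  Monte-Carlo error well inside the asserted bands.
- Fractions sum to 1 up to 1e-12; frequency-table percentages are rounded
  to one decimal for reporting only.

## Known limitations

Euclidean (not geodesic) distances; no perfusion ground truth; no
mixed-effects modeling of paired hemispheres; atlas fusion assumes
upstream registration quality; ROI fusion uses a simple ≥ 50% vote rather
than intensity-weighted joint label fusion, which would require the
underlying MR images.
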