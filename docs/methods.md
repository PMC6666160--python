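# Methods

This note documents the statistical model behind `riceval`, the numerical
conventions it fixes, the choices made where the published account of the
reference study leaves the design open, and what the shipped tests do and
do not demonstrate.

## The evaluation model

A variety's comprehensive quality is modelled as a weighted sum of
standardized representative indexes,

    Y = Σᵢ Xᵢ · Wᵢ ,   0 ≤ Xᵢ ≤ 1,

where the five representatives — palatability, adhesiveness, b\* value,
resilience, iodine color value — are chosen by the screening pipeline so
that each stands for one quasi-independent block of the seventeen-index
panel.  Y is bounded by [0, ΣWᵢ]; higher is better.

### Standardization (ideal-value distance)

The published description of the transform names three steps
(initialization as the absolute distance to the ideal value,
forward-processing, normalization) but never writes the formula.  The
package adopts

    d = |x − x₀|,    X = 1 − d / D,    D = max(|lo − x₀|, |hi − x₀|),

with `[lo, hi]` the reference panel range of the index and x₀ its ideal
value (the range maximum for a positive index, the minimum for a negative
one, an interior optimum — resilience, 0.30 — for a neutral one).  This
reconstruction is validated by regression: applied to the nine
verification samples with the published formula weights it reproduces all
nine printed composite values at two decimal places and the published
quality ranking.  Normalizing within the nine verification samples
instead of against the full panel range does not reproduce the printed
values and was rejected.  Values outside the reference range clamp to
[0, 1] rather than extrapolating negative scores, preserving the stated
0 ≤ Xᵢ ≤ 1 contract for new samples.  X is computed at full precision;
rounding happens only at serialization.

### AHP weighting

Weights come from pairwise judgment matrices on Saaty's 1–9 scale,
validated for exact reciprocity (fractional entries are stored as
rationals, so a[j][i] = 1/a[i][j] holds without decimal drift).  The
priority vector is the normalized principal right eigenvector, computed
by power iteration (tolerance 1e-12 on the weight vector, 10 000
iteration guard; Perron–Frobenius guarantees convergence for valid
positive matrices).  The eigenvector method was chosen over the
geometric-mean (logarithmic least squares) alternative because only the
eigenvector reproduces the published criterion weights: the geometric
mean of the 4×4 criterion matrix gives (0.5638, 0.2634, 0.1178, 0.0550)
while the principal eigenvector gives the published (0.5650, 0.2622,
0.1175, 0.0553).

Consistency: CI = (λ_max − n)/(n − 1) and CR = CI/RI with CR defined as 0
for n ≤ 2.  The random-index table uses RI(4) = 0.89 by default because
the published CR of 0.0438 for the criterion matrix requires it (Saaty's
RI(4) = 0.90 yields 0.0434 and is available as a variant).  Besides
per-matrix CRs the composer reports the hierarchy total-ordering CR,
(CI_crit + Σ wⱼCIⱼ)/(RI_crit + Σ wⱼRIⱼ), which here equals the criterion
CR (0.0438) because the only multi-leaf sub-matrix (adhesiveness vs
resilience, 2×2) is consistent by construction — matching the three
published values 0.0438, 0.0438 and 0.

Two weight vectors ship.  Fresh composition of the hierarchy yields
0.0553 for iodine color value (weights sum to 1); the published model
formula instead uses 0.0533 (weights sum to 0.998).  Both appear in the
source; the scoring default is the formula vector because it is what the
published verification scores were computed with.  Weights are not
renormalized by default; a `renormalize` flag exists for new models.

## The screening pipeline

**Descriptives.** SD uses the sample (n−1) denominator; the variable
coefficient CV = s/x̄ × 100 keeps the sign of the mean (a\* value and
adhesiveness have negative means, hence negative printed CVs) and ranking
uses |CV|, which makes "largest CV" well-defined.  CV is reported as
undefined (NaN) when the mean is exactly zero.  Note the published CV
column is not always consistent with its own printed mean/SD at two
decimals (a\*: 0.18/−2.18 → −8.26 vs printed −8.08); tests therefore
validate CVs against recomputation, not against the printed column.

**Correlation.** Pearson r; two-sided significance from the exact t
transform with df = n − 2, no multiple-testing correction (the published
15/52 significant-pair census is only reproducible uncorrected).  At the
panel size n = 108 the critical |r| values are ≈ 0.1891 (α = 0.05) and
≈ 0.2469 (α = 0.01); every printed flag in the fixture matrix is
consistent with these thresholds, which also pins the panel size
(r = 0.188 unflagged, r = 0.207 flagged).

**Factor analysis.** Principal-component extraction from the correlation
matrix: loadings are eigenvector columns scaled by √λ and a factor's
contribution is λ/p × 100 — identified as the study's method because the
printed contribution rates equal λ/17 exactly (4.918/17 = 28.93 %).
Kaiser retention keeps factors with λ > 1 strictly.  Rotation is varimax
with Kaiser row normalization (the default of the statistical package the
study used; the study text itself never names a rotation).  Column signs
are fixed so each factor's largest-|loading| entry is positive, making
output reproducible across eigensolvers.  Factoring runs directly from a
correlation matrix, so the published matrix can be analysed without raw
data.

**Variable clustering.** Ward minimum-variance agglomeration over the
index columns, each represented by its z-scored sample vector with
Euclidean distance — the standard convention for mixed-unit variables;
for z-scored columns the squared distance is monotone in 1 − r, tying the
dendrogram to the correlation table.  The published "cut at distance 7"
refers to a display-rescaled dendrogram axis and is not reproducible
without raw data; the API cuts by class count (k = 5 default).  Linkage
heights are monotone (a Ward property, asserted in tests) and the
implementation is verified against a brute-force agglomeration oracle
that recomputes the within-cluster variance increase over all pairs at
every step.

**Consensus and selection.** The two partitions usually agree; the
reconciliation rule for disagreements is a design of this package, chosen
to reproduce the study's two manual adjudications from its printed
evidence:

* The factor partition seeds the classes.  It is the variance-based
  grouping the weighting hierarchy is built on, and it is the robust one:
  on synthetic panels with the published correlation structure the factor
  stage recovers the published five groups almost always, while the tree
  cut is sensitive to sampling noise.
* An index that Ward clustering separates from all of its factor
  classmates is re-examined.  Candidate classes are ranked by (1) whether
  the class majority shares the index's measurement category (color /
  physicochemical / texture / sensory), (2) whether the index has any
  significant correlation with the class, (3) the weakest pairwise |r|
  with class members — the index must cohere with the whole class, not
  one strong neighbour.  The index may stay put.
* One representative per class: the member with the largest |CV|, i.e.
  the index that discriminates varieties most strongly relative to its
  scale.

On the packaged fixtures this confirms b\* in the color class (the tree
cut had placed it with the sensory block; its only significant links are
−0.569 and −0.277 with L\* and a\*) and moves light transmittance from
the sensory factor to the physicochemical class (category match, with
significant links −0.295 and −0.313 to iodine color value and
gelatinization degree) — exactly the study's two adjudications.  A
pure-correlation rule cannot do both: light transmittance is
significantly correlated with all five sensory indexes (up to −0.563), so
counting or averaging significant links would keep it in the sensory
class; the category criterion is what the study's own narrative appeals
to.  No general rule is published beyond these two worked cases; this
formalization is one consistent choice and is flagged as such.

## Synthetic panels

The raw 108 × 17 measurement matrix behind the study was never published,
so the generator draws multivariate-normal panels with the published
per-index means and SDs and the published correlation structure; the 3-dp
printed matrix is repaired to the nearest positive-semidefinite
correlation matrix first (alternating projections; the shipped matrix is
in fact already PSD, minimum eigenvalue ≈ 0.017, so repair is a no-op for
it).  A single integer seed controls all draws.  Optional per-index
truncation to the published ranges uses rejection resampling.

The generator reproduces first and second moments only.  Real sensory
scores are bounded, discretized and likely skewed; none of that is
modelled, because every stage of the analysis chain (Pearson r, PCA-based
factoring, Ward on z-scores) is moment-driven.  Consequently, passing
synthetic-recovery tests demonstrates that the pipeline recovers the
structure it assumes from data that has it — not that the assumptions
hold for real panels.

Default problem sizes used by the test suite: screening recovery runs ten
seeds at n = 2000 varieties (the published five representatives are
re-selected in at least 8 of 10 seeds, with the CV ranking taken from the
generating panel statistics, since the CV of a near-zero-mean sensory
score is unstable under resampling); moment- and correlation-recovery
checks use a single n = 10 000 draw (sample correlations within 0.05 of
target, means within 3 standard errors); significance-census plausibility
uses ten panel-sized (n = 108) draws.

## Known inconsistencies in the source tables

These are reported by `riceval reproduce-paper` rather than papered over:

* **Cumulative factor contribution.**  The five-factor cumulative
  contribution is printed as 75.626 %.  Eigendecomposition of the printed
  correlation matrix gives 73.63 %, and the sums of squared loadings of
  the printed rotated loading table give (4.921, 3.022, 1.862, 1.628,
  1.086) → 73.64 % — agreeing with each other to 0.01 pp and with the
  first four printed per-factor "characteristic values" to 3 dp, but not
  with the printed fifth value (1.285, which implies 7.56 %) nor with its
  printed contribution (8.384 %, which implies λ = 1.425).  Rounding of
  the 3-dp correlations can shift the eigenvalue sum by at most ≈ 0.04,
  so the printed 75.626 % cannot derive from the printed matrix; the
  package reports the recomputed value.  Factor retention itself is
  unaffected (the fifth eigenvalue, 1.030, still exceeds 1).
* **The dendrogram partition.**  The published 5-class tree cut is not
  derivable from the printed correlation matrix (it groups iodine color
  value with gelatinization degree at r = 0.067 and b\* with the sensory
  block at |r| ≤ 0.116).  The partition ships as a fixture for the
  selection regression; on synthetic data the package's own Ward stage
  produces a different but internally consistent cut, which the consensus
  stage absorbs.
* **The iodine weight.**  0.0553 (hierarchy section) vs 0.0533 (model
  formula); see above.

## Limitations

* Ideal values and reference ranges are configuration, not estimated from
  data; applying the shipped model to panels measured under different
  protocols requires re-specifying both.
* The consensus rule is a formalization of two worked examples; genuinely
  novel disagreement patterns may still raise a reconciliation error by
  design rather than guess.
* Competition ranking (ties share the minimum rank) and the fixed
  histogram bins [0.1, 0.2) … [0.7, 1] follow the study's reporting
  conventions and are not configurable.
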