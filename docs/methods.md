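# Methods

This note records the statistical conventions behind `perflink`: the models
and procedures, the defaults that matter, what the synthetic-data module
does and does not emulate, and the numerical choices a maintainer would
otherwise have to reverse-engineer.

## Fixed-anchor GRM linking

The core model is the logistic graded response model (GRM).  Calibration is
marginal maximum likelihood via EM on a quadrature grid:

* **Grid.** 61 equally spaced nodes on [−6, 6], weights proportional to the
  standard-normal density and renormalized.  This is ample for 13 items of
  ordinary informativeness; the EAP kernel agrees with adaptive continuous
  integration to well below 1e−6 in θ once the grid is refined, and at 61
  nodes the discretization error is orders of magnitude below sampling
  error.
* **E-step** accumulates expected category counts `r_jkq` from each
  person's posterior mass over nodes (pattern likelihood × prior weight).
  Missing responses simply drop out of the pattern likelihood.
* **M-step** re-maximizes each free item's expected complete-data
  multinomial log-likelihood by BFGS with an analytic gradient on the
  parameterization `(log a, b_1, log(b_2−b_1), …)`.  Working on log
  increments keeps thresholds strictly ordered at every iterate, which
  avoids the oscillation that post-hoc sorting can induce.
* **Convergence**: maximum absolute parameter change < 1e−4 or 500 cycles.
  The marginal log-likelihood trace is recorded and is nondecreasing up to
  1e−8 (EM guarantee); non-convergence returns a flagged partial result.
* **The metric.** Anchor items are never updated and the latent prior stays
  N(0, 1) for every cycle.  Jointly these pin the scale: T = 10·θ + 50
  then reads T-scores off the anchors' reference metric.  Note an exact
  equivariance that makes this interpretable — shifting all anchor
  thresholds *and* the prior location by a constant shifts every estimated
  threshold by exactly that constant (change of variables in the marginal
  likelihood).  With the prior held at N(0, 1), mis-scaled anchors move
  free-item estimates only part of the way (prior shrinkage); anchor
  parameters and the population the prior describes must belong to the
  same metric for the link to be clean.
* **Empty categories** of free items are collapsed to the observed ones
  before estimation, with the recode map reported in the calibration
  result.  Anchors are never collapsed: their parameters are external and
  re-indexing categories would silently change their meaning.
* **Standard errors** (on request) come from per-item blocks of the
  numerically differentiated observed information of the marginal
  log-likelihood at convergence.  Cross-item information is ignored; with
  anchors fixed the blocks are close to the full-information answer, but
  the SEs should be read as approximate.

EAP scoring is posterior mean and SD on the same grid; an all-missing
pattern returns the prior (θ = 0, T = 50, SE ≈ 1).  Aggregate
unbiasedness — the mean EAP over people drawn from the prior equals the
prior mean — is what anchors the "reference population mean T = 50" check.

## Crosswalk

The sum-score → T table is a summed-score EAP: the Lord–Wingersky recursion
gives P(S = s | θ_q), Bayes with the prior weights gives a posterior per
sum score, and each row stores its posterior mean, SD and T.  Rows must be
strictly increasing in θ and the constructor enforces this.  A caveat worth
stating plainly: the GRM does not guarantee monotone likelihood ratio of
the *unweighted* sum score.  With realistic batteries (several items,
well-separated thresholds, slope ratios within ~2) the table is always
monotone in practice, but a two-item bank with strongly unequal slopes can
genuinely produce a non-monotone summed-score EAP — the constructor then
refuses to build the table rather than ship a misleading conversion.
Persons with incomplete battery responses are scored by pattern EAP
instead of table lookup, with the method recorded per person; the reverse
direction (T → sum score) uses the nearest table entry, ties to the lower
score.

## S-X² item fit

For each item, expected category frequencies conditional on the rest score
are computed by integrating the item's category curves against the
posterior of θ given the rest score (Lord–Wingersky on the remaining
items).  Complete cases only.  Adjacent cells with expected count < 1 are
merged toward the nearer tail.  Degrees of freedom are Σ_s (c_s − 1) minus
the number of *estimated* parameters of the item — zero for fixed items,
m for a free m-category item (slope + m−1 thresholds).  Row totals are
fixed by conditioning, hence the per-row −1.  Under the generating model
this calibrates well: the empirical rejection rate at α = 0.001 stays
below 1% across replicated simulations.

## Classical and Mokken diagnostics

Complete cases over the selected item subset throughout (the eligibility
filter makes near-complete data, and listwise deletion is the simplest
defensible default).  Loevinger's H uses the comonotone upper bound for
each pair's covariance given both marginals; perfect Guttman data gives
H = 1 exactly.  The monotonicity check pools rest scores into groups of at
least max(50, n/10) persons, compares P(X ≥ k) across all group pairs, and
counts a violation as *active* only if it is at least 0.03 in size (the
conventional minimum-violation screen; without it, sampling wiggles in
flat regions of the item characteristic curve produce spurious counts) and
significant in a one-sided two-proportion z-test at 0.05, uncorrected.

## Dimensionality

Polychoric correlations are two-step ML (thresholds from inverse-normal
marginals, then a bounded scalar likelihood maximization per pair on
pairwise-complete data), with asymptotic variances from the numerically
differentiated pairwise observed information and a Pearson fallback if a
pair degenerates.  The CFA minimizes the diagonally weighted least-squares
discrepancy (weights = inverse asymptotic variances); fit indices use the
standard discrepancy-based chi-square against an independence baseline.
No mean-variance (robust/WLSMV) adjustment is implemented — the DWLS
chi-square is conservative under a correct model, so CFI/TLI read high and
RMSEA low; treat absolute cutoffs accordingly.  Each factor needs at least
two items; single-item factors are rejected as unidentified.

The bifactor decomposition is Schmid–Leiman.  The first-order correlated
factors follow the user-supplied subdomain partition (fitted by the same
DWLS machinery) rather than an oblique rotation of an unrestricted
extraction: when the data are close to unidimensional — precisely the case
the ECV/ωH check is meant to certify — an oblique rotation degenerates
into single-item noise factors and manufactures specific variance, while
the partition-anchored solution converges cleanly (factor correlations
→ 1, specifics → 0).  The partition is a required input because subdomain
assignments are instrument knowledge, not something the data at hand
identify.  The second-order general factor is a principal-axis extraction
from the factor correlations; then g = Λ·γ and λ_s = Λ·√(1−γ²).  ECV, ωH
and PUC use the standard counting/variance formulas with ωH group sums
taken over partition members.

## DIF screening

Per item, nested proportional-odds models conditioned on the calibrated
EAP score: trait (m1), + group (m2), + trait×group (m3), fitted by
statsmodels' cumulative-logit implementation (the intercept-only
log-likelihood uses the closed multinomial form).  Uniform, non-uniform
and total likelihood-ratio p-values are all reported; the flag uses total
Nagelkerke ΔR² = R²(m3) − R²(m1) against a configurable 3% default, since
an effect-size criterion is far more stable at these sample sizes than
per-test p-values.  Single pass, no purification: the conditioning score
comes from the full calibration once, and a hook accepts user-supplied
scores if purified conditioning is wanted.  Multi-level groups enter as
indicator sets, so ΔR² is joint.

## Agreement

Paired SMD = mean(a−b) / SD(a−b).  The denominator is the SD of the paired
differences, *not* a pooled SD — the two differ materially when scores are
highly correlated, so this convention is stated wherever SMDs are
reported.  The 95% CI is the normal approximation
smd ± 1.96·√(1/n + smd²/2n).  Effect-size labels: negligible/small/medium/
large at 0.2/0.5/0.8.  Bland–Altman limits are mean ± 1.96·SD of the
differences with a least-squares trend of difference on average as the
proportional-bias check.  Ceiling/floor are the fractions of persons at an
instrument's maximum/minimum attainable score — a short anchor form
saturates far earlier than a longer battery, which is the practical
argument for linking in the first place.

## Synthetic data: what it does and does not emulate

The generators produce 5-category graded responses from a latent
physical-function trait with, optionally: a bifactor structure
(general + subdomain/assessment-type specific factors, normal-ogive
thresholding, communality constraint enforced), uniform DIF as a
threshold shift for a focal group, MCAR missingness at a set rate within
an item mask, and covariates built as r·z + √(1−r²)·noise against the
standardized anchor-minus-battery score difference so their population
correlation with that difference is exactly the target.  Codes are 0-based,
so a 9-task battery scores 0–36.  Default bank: slopes uniform on
[0.8, 2.5], sorted threshold draws on [−2.5, 2.5] — the range a
well-constructed 5-category clinical item set occupies.  The end-to-end
demonstration uses slopes on [1.3, 2.5] so that every item clears the
0.50 standardized-loading criterion by design.

Deliberately not emulated: informative (non-MCAR) missingness, realistic
joint clinical covariate distributions, longitudinal structure, and
response styles.  Passing tests on these data certify the *machinery* —
estimator consistency, calibration of the screens, metric preservation —
not the behavior of any particular clinical instrument.

The unidimensional generator uses the logistic GRM; the bifactor generator
uses normal-ogive thresholding (natural for a loading parameterization).
The ~1.7 scale constant between the two conventions is irrelevant here
because bifactor data feed only loading-scale analyses.

## Problem sizes

Defaults used by the test suite and demonstrations: n = 2,000 for
calibration recovery and the DIF/monotonicity screens, n = 5,000 for
generator-closure and bifactor-sensitivity checks, n = 20,000 for the
reference-population mean-T check, and 50 replicates for the S-X² type-I
calibration — sizes at which sampling error is comfortably below each
check's tolerance while the whole suite stays fast.

## Known limitations

* DWLS fit indices without the robust correction (above).
* SMD confidence intervals are asymptotic; no bootstrap in the default
  path.
* DIF thresholds are fixed effect-size cuts, not Monte-Carlo calibrated.
* The S-X² cell-collapse rule (< 1 expected, toward the nearer tail) is
  one of several in circulation; df conventions follow the estimated-
  parameter count as described.
* Only unidimensional linking is provided; projection-style linking for
  imperfectly correlated constructs is out of scope.
* Proportional-odds fits can report quasi-separation on tiny strata; the
  scan warns on group levels under 10 respondents.
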