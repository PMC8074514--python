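# Methods

## The harmonized index

The unit of observation is the household of a cohort member in a given survey
wave. The benchmark index pools all waves into one dataset of 19 indicators —
8 durable assets (radio, record player, sewing machine, refrigerator,
television, bicycle, motorcycle, automobile) and 11 housing characteristics
(land and house ownership, rooms per member, floor/roof/wall quality,
separate kitchen, formal cooking medium, sanitary installation, electricity,
improved water source) — standardizes each column on its *pooled* mean and
SD, and retains the first principal component of the Pearson correlation
matrix. Pooled standardization is essential: per-wave standardization would
remove exactly the cross-wave wealth differences the harmonized index exists
to measure. Higher-order components are not extracted.

Loadings are reported on the component-correlation scale (eigenvector entry
× √λ₁); the unit-norm eigenvector is the scoring vector, so fitted scores
have mean 0 and SD √λ₁ exactly. Scores for new data reuse the stored pooled
means/SDs. The sign of a principal component is arbitrary, so every fitted
model is oriented: the index is flipped, if necessary, so that a reference
item (electricity by default — a large, stable correlate of wealth wherever
it varies) loads non-negatively, with a majority-positive fallback when the
reference is absent or loads zero. Orientation deliberately does not force
all loadings positive: an item whose relevance reverses over the study period
(radio ownership rises and then falls as wealth grows) may legitimately load
negative in the pooled fit, and does so in most draws of the calibrated
simulator — its sign is data-dependent and is not asserted by the tests.

### Missingness and zero-imputation

Two missingness kinds are distinct types in the data model, because they have
opposite analytic consequences:

* **NOT_ASKED** — the item was not on that wave's instrument. This is a
  property of the (item, wave) pair, recoverable from the codebook's
  availability sets. Only these cells are eligible for the deterministic
  zero-imputation rules ("an automobile not asked about in a 1967 village
  census was almost surely not owned"), which are declared as data in the
  codebook (`impute_zero_waves`). A rule targeting a wave in which the item
  was asked is rejected outright — imputation must never overwrite data.
* **NONRESPONSE** — the item was asked and the household has no value. These
  records are excluded listwise from every fit, never imputed. (The source
  protocol does not state how within-wave nonresponse was handled; listwise
  deletion is the default here, and no partial scoring is done.)

Imputation precedes pooling, so imputed zeros participate in the pooled
moments; within a single early wave an imputed item is constant and drops out
of any cross-sectional fit, which is the behaviour the per-wave loading
tables of this literature display as "–" cells.

## Correlation engines

Pearson correlations of the standardized columns feed the benchmark. The
polychoric alternatives treat each categorical item as a discretized latent
normal variable and estimate the latent correlation of each pair by two-step
maximum likelihood: thresholds fixed at normal quantiles of the observed
marginals, then a bounded 1-D search (tolerance 1e-6) over ρ maximizing the
multinomial likelihood, with cell probabilities as bivariate-normal rectangle
probabilities. Rectangle probabilities use Owen's identity
Φ₂(h,k;ρ) = ½Φ(h) + ½Φ(k) − T(h,a_h) − T(k,a_k) − β, evaluated with
scipy's Owen's-T function — exact, and orders of magnitude faster than
numerical integration, which matters for the 171-pair matrices. Estimates
are capped at |ρ| ≤ 0.999. Tables with empty cells receive a +0.5
continuity correction (flagged per pair); empty marginal categories are
merged into their neighbour. Assembled pairwise matrices need not be positive
semi-definite; an indefinite matrix is eigenvalue-smoothed (negative
eigenvalues clipped to 1e-8, diagonal renormalized) and flagged. Crowding is
binarized at > 0.75 rooms per member for all polychoric and MCA variants;
the source protocol states this rule only for MCA, and the extension to the
polychoric variants is this package's choice, made for internal consistency
of "categorical-only" methods (polyserial correlations are out of scope).

## Extraction backends

* **PCA** — leading eigenpair of the correlation matrix (`numpy.linalg.eigh`).
* **EFA (minres, one factor)** — loadings minimize Σ_{i<j}(r_ij − l_i l_j)²
  by L-BFGS with analytic gradient, initialized from the PCA loadings.
  Varimax rotation with a single factor is the identity, so no rotation step
  exists. Heywood solutions are clipped to communality 0.995 and flagged.
  Factor scores use regression weights computed under the fitted model,
  (llᵀ + Ψ)⁻¹l with Ψ = diag(1 − l²). This is the standard regression
  method written against the model-implied matrix rather than the sample
  matrix: on a well-conditioned Pearson matrix the two are interchangeable,
  but a smoothed polychoric matrix has floored eigenvalues whose inversion
  amplifies noise and can destroy the score ranking entirely.
* **MCA** — correspondence analysis of the complete disjunctive coding (two
  indicator columns per binary item): standardized residuals
  S = D_r^{−1/2}(P − rcᵀ)D_c^{−1/2}, SVD, household scores as
  first-dimension row principal coordinates (computed out-of-sample through
  the transition formula), item loadings as column principal coordinates of
  the level-1 categories. Any affine rescaling of MCA scores leaves every
  Spearman comparison unchanged, which is the quantity the protocol reports.

## Diagnostics

Standardized Cronbach's α = k·r̄/(1 + (k−1)·r̄) on the fitted columns;
KMO from anti-image partial correlations of the inverse correlation matrix.
Clumping and truncation are assessed visually (histograms) in the source
literature; the quantitative proxies here are the modal score share and
distinct-value ratio per wave, and the share of a wave's households within
1% of the pooled score range of the pooled minimum/maximum. Outputs label
them as proxies. Quartiles use linear interpolation (R type-7), which
matters when reporting IQRs of discrete early-wave score distributions.
External validity is the Pearson correlation between a household-linked
external measure and the index score at the earliest (parental schooling) or
latest (attained schooling) wave the household is observed; index-vs-index
comparisons are Spearman throughout, mirroring the protocol's usage.

## Sensitivity protocol

Every variant is compared to the benchmark by Spearman rank correlation with
mid-ranks, restricted to households scored by both indices; each report row
records the comparison population. After wave omission the comparison runs
on the households of the remaining waves (the source protocol does not state
the comparison population; this choice is recorded in the report metadata).
Cross-sectional fits drop not-asked and constant items rather than carrying
imputed-constant columns. Urban/rural stratum labels are data carried by the
panel, never inferred.

## The synthetic cohort generator

The generator defines the study conditions under which all end-to-end
properties are asserted. Household h in wave t has latent wealth

    w_ht = μ_t + δ(u_h − p_t) + σ_t(√icc·b_h + √(1−icc)·e_ht)

with a persistent household component b_h (intraclass correlation 0.6 by
default — longitudinal trajectories are meaningful, not re-drawn per wave),
urban flag u_h with wave share p_t and centred urban shift δ = 0.5 in the
final two waves only. Item j is owned iff λ_j·w_ht + u > τ_jt, u ~ N(0,1).
Thresholds are calibrated in closed form,
τ_jt = λ_j μ_t + √(λ_j²σ_t² + 1)·Φ⁻¹(1 − p_jt), so each per-wave marginal
p_jt hits its target exactly in expectation; stratified waves solve the
corresponding two-component mixture equation numerically. Targets are the
published per-wave ownership proportions; marginals printed as 0.00 or 1.00
produce genuinely constant columns. Wave sizes are 547, 755, 617, 820, 1075,
1145 (pooled 4959) with urban shares 302/1075 and 329/1145.

Stipulations the data cannot identify, chosen once and documented rather
than estimated: the latent wave means (−1.5, −1.0, −0.2, 0.6, 1.0, 1.05) and
SDs (0.8–1.0), the item discriminations (0.25–1.5, with radio deliberately
lowest so its pooled relevance is weak), and the intraclass correlation.
Crowding is integer rooms over integer household members (members
1 + Poisson, expected rooms linear in latent wealth): the discreteness of
the ratio is what lets early-wave score distributions exhibit the clumping
the diagnostics are designed to detect, which a continuous crowding draw
would never show. Three-level low/medium/high codes for five housing items
place the "medium" band directly below the high-quality threshold on the
latent response scale (offset 0.8).

External schooling measures couple to standardized latent wealth at the
household's earliest (parental) or latest (attained) observed wave through a
Gaussian copula, then discretize onto a right-skewed grade distribution by a
monotone quantile map. Two attenuations stand between the copula strength
and the measured index–schooling Pearson correlation: the discretization
factor (computed analytically from the grade distribution) and the share of
within-wave latent variance a 19-binary-item index can capture, stipulated
as `index_reliability = 0.8`. The copula strength is divided by both, so
the *measured* correlations land on the calibration targets (0.16 maternal,
0.10 paternal, 0.35 attained).

What the generator does not emulate: attrition and mortality, migration,
intervention effects, item-specific response error, within-village
clustering, or any multi-dimensional wealth structure. Tests passing under
the single-factor design therefore show that the machinery is correct and
that the protocol's robustness bounds hold *when a dominant wealth factor
truly exists* — they do not certify the substantive conclusions on any real
dataset.

## Numerical conventions and problem sizes

Standardization uses ddof = 1; scores rounded to 1e-9 for clumping counts;
eigen-smoothing floor 1e-8; polychoric optimizer tolerance 1e-6 with
|ρ| ≤ 0.999; KMO adds a 1e-8 ridge only on singular input (flagged). The
test suite runs the full protocol at the design size (pooled n = 4959) for
the acceptance properties and on a 1/5-scale cohort for unit tests; the
171-pair leave-out sweep takes a few seconds at full size.

## Known limitations

* Polychoric variants binarize crowding rather than using polyserial
  correlations.
* No survey weights, no model-based imputation, no bootstrap CIs on the
  comparison correlations (point values only, as in the protocol).
* The exact score normalization behind published per-wave summary tables is
  not fully identifiable from printed values; the convention here (pooled
  mean 0, SD √λ₁) reproduces the qualitative pattern — rising means, pooled
  SD well above 1 — but not any particular printed magnitude.
* The CLI accepts flags only; a config-file layer was not needed for the
  bundled workflows.
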