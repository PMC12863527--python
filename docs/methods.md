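# Methods

This note records the models, defaults and numerical choices behind
`adipomet`, and what the synthetic-data checks do and do not establish.

## Matched-cohort generator

The cohort emulates a nested case-control study of middle-aged men with
1:1 incidence-density matching. Each participant carries a latent
standard-normal adiposity factor Z.

**Anthropometrics.** Height ~ N(166.6, 6.0²) cm; BMI = 23.66 + 3.20·(0.9 Z
+ √0.19 ε); WC, HC and adult weight gain are linear in BMI/height/Z with
Gaussian noise. The constants were calibrated once against two published
summary targets of the emulated study: Spearman ρ(WC, WHtR) ≈ 0.94 and
ρ(ABSI, BMI) ≈ −0.03. The second target is largely structural: the
WC-on-BMI slope (2.35 kg·m⁻²·cm⁻¹ at the sample means) sits near the
2/3-power scaling that makes ABSI = WC·BMI^(−2/3)·height^(−1/2)
orthogonal to BMI.

**Metabolites.** log₂ concentrations are multivariate normal with a
single-factor-per-block copula: log₂ m_j = μ_j + α_j Z + √ρ_b F_b +
√(1−ρ_b) ε. `block_rho` accepts a scalar or per-block vector; the default
(one block at 0.85, the rest at 0.45) plants one tightly correlated
bile-acid-like block so that the strongest partial correlation in the
default panel is ≈ 0.8, matching the emulated study's strongest pair.
Default panel: 186 metabolites in 12 blocks; the first 27 are planted
intermediates with α = 0.2 (log₂ units per SD of Z) and b = 0.3 (log-odds
per doubling).

**Outcome.** Case status is assigned *pair-conditionally*: with linear
predictor η = direct·Z + Σ_k b_k·log₂ m_k + γ·HBsAg, member 1 of a pair
is the case with probability σ(η₁ − η₂). This makes the matched-pair
conditional likelihood exactly the generating model, so conditional
logistic regression is unbiased for b by construction — a clean surface
for parameter-recovery checks.

**Confounder.** An HBsAg-like flag has individual prevalence 0.30 and
log-odds effect γ = 4.0 (defaults). With independent within-pair draws
the achievable margins are bounded (case ≈ 45–50%, control ≈ 14–18%
seropositive); the extreme 64%/6% split of the emulated study cannot be
reproduced exactly under this sampling scheme and we deliberately keep
the scheme (model fidelity) over the margins (cosmetics). Chronic
hepatitis and cirrhosis are generated conditionally on HBsAg so the
sensitivity analysis (excluding affected pairs) is exercisable.

**What the generator does not emulate:** measurement error and batch
effects in quantitation, left-censoring at detection limits, incidence-
density sampling over calendar time, correlated missingness, and
covariate-confounder dependence beyond HBsAg. Passing recovery tests
therefore demonstrates estimator correctness under the declared model,
not robustness to those real-data features.

## Summary-statistics generator

Per-SNP effects on a standardized exposure are drawn and rescaled so that
Σ 2p(1−p)γ² = h² (default 0.10 over 100 SNPs). A mediator inherits
θ_XM·γ plus its own variants (h²_mediator = 0.05), which is what makes
multivariable MR identifiable; the outcome receives θ_direct·γ +
θ_MY·(mediator effects) plus optional pleiotropy. Standard errors follow
the standardized-trait form 1/√(2p(1−p)n); estimated betas add
independent noise per trait, making the three samples non-overlapping by
construction. Pleiotropic outcome effects are expressed relative to the
exposure-raising allele (multiplied by sign(γ)); otherwise a nonzero
pleiotropy mean would cancel across mixed-sign SNP effects and
"directional" pleiotropy would be undetectable by any method. Default
sample sizes (500k exposure, 8k mediator, 200k outcome) mirror the scale
of the consortium, metabolite and disease GWAS this design emulates.

## Screening

- Metabolites enter all models as log₂(concentration); effects are per
  doubling.
- Step-1 linear models are fitted to all 186 responses in one pass
  (shared design matrix), with exact t-based inference.
- Step-2 conditional logistic regression maximises Π σ(βᵀd_i) over
  within-pair differences by Newton-Raphson with step halving;
  separation is flagged when the iteration fails to converge or
  |β| > 25, and all-zero difference columns are flagged as
  zero-information. The implementation is cross-checked in the tests
  against an independent numeric likelihood maximisation and against
  statsmodels' ConditionalLogit.
- Restricted cubic splines use the Harrell basis with 4 knots at
  quantiles (0.05, 0.35, 0.65, 0.95) by default (3 or 5 supported);
  nonlinearity is a joint Wald test of the nonlinear basis coefficients
  (exact F in linear models, χ² in the conditional model). One code path
  serves both model families; the Wald form was chosen over the
  likelihood ratio for that uniformity.
- FDR is Benjamini-Hochberg within each exposure across the panel.
  Note the adjusted values are not a fixed point of the procedure in
  general; the tests assert the properties that do hold (q ≥ p, cap at
  1, monotonicity in p-rank).
- "Retained" = FDR < 0.05 OR P_nonlinear < 0.05; the category label
  prefers the linear call when both criteria fire.

## Network and pathways

Partial Spearman = Pearson correlation of rank residuals after least-
squares adjustment, with t-based p-values on n − 2 − c df, computed on
controls only. The PC skeleton uses Fisher-z partial-correlation tests
on rank-transformed data (α = 0.05, conditioning sets up to size 3 —
defaults recorded here because the source workflow names the algorithm
but not the test or level), iterating nodes and subsets in sorted order
for determinism. Walktrap (step length 4, igraph implementation) is cut
at maximum modularity with |partial ρ| edge weights. Pathway enrichment
is the upper-tail hypergeometric test over user-supplied GMT sets
intersected with the measured panel; topology impact sums betweenness
centralities (normalized to unit total over the pathway graph) of the
hit nodes. Graphs where all betweenness is zero (e.g. a single edge)
spread the unit mass uniformly so saturation still scores 1.

## Mediation

Clustering: Ward linkage on 1 − |r| distances of log₂ concentrations,
cut to ≤ 10 clusters; each cluster is represented by its standardized
PC1, with the sign fixed so the largest-|loading| member loads
positively. Decomposition: a-paths by OLS of each cluster score on the
exposure + covariates; b-paths and DE from one outcome model containing
the exposure, all scores and covariates; IE_k = a_k·b_k. Outcome model
families: ordinary logistic (default, PROCESS-style), matched-pair
conditional logistic (used for parameter-recovery checks, since under
pair-conditional sampling the ordinary-logistic coefficients are
population-averaged and attenuated), and linear (under which
product-of-coefficients equals total − direct exactly; asserted to
1e-8). CIs: percentile bootstrap resampling matched pairs (n_boot
default 5000 in the API; smaller counts are used in tests for speed);
non-convergent draws are discarded and counted, with a warning above 5%.
The proportion mediated is TIE/(DE+TIE) on the log-odds scale. On that
scale TIE + DE differs from the mediator-free total effect
(non-collapsibility); the gap is reported as `collapsibility_gap`, never
reconciled.

## Mendelian randomization

- Instrument selection: p < 5e-8 (anthropometrics, disease) or 5e-6
  (metabolites), greedy pruning by p-value with r² < 0.001 within
  10,000 kb; pairwise r² comes from an optional user table, with
  same-position variants treated as perfect proxies when no table is
  given (a documented weakening relative to panel-based clumping).
- Harmonization: swap/strand-flip resolution through the complement
  map; palindromic SNPs kept only when both frequencies lie outside
  [0.42, 0.58] and agree in orientation.
- IVW: multiplicative random effects — fixed-effect SE inflated by
  max(1, √(Q/(k−1))). Egger: weighted with intercept, exposure betas
  oriented positive, t inference on k−2 df, same overdispersion rule.
  Weighted median: inverse-variance-weighted 50th-percentile
  interpolation, parametric-bootstrap SE. Weighted mode: weighted
  Gaussian-kernel density over ratio estimates, bandwidth 0.5× the
  0.9·min(sd, MAD)·n^(−1/5) rule, ties broken to the lower mode and
  flagged.
- MR-PRESSO: leave-one-out residual sum of squares against its
  parametric null distribution (default 1000 simulations); per-SNP
  outlier p-values Bonferroni-thresholded at 0.05/k; corrected estimate
  = IVW on the survivors.
- Steiger: r² recovered from t²/(t²+n−2) per trait; a SNP is kept iff
  it explains more variance in the exposure, with a Fisher-z test
  reported; exact ties are indeterminate and dropped.
- MVMR: weighted no-intercept multiple regression of outcome betas on
  the jointly harmonized exposure-beta matrix; all-zero beta columns are
  unidentified and reported as NaN rather than breaking the nested-model
  limit; near-collinear columns raise an error naming the pair.
- Mediation MR: Difference (total − direct, SEs added in quadrature
  under an independence approximation, noted in output) and Product
  (β_XM·β_MY|X, first-order delta SE); proportion = indirect/total,
  absent when |total| ≈ 0.

Known finite-sample behaviours the tests document rather than hide:
MVMR-IVW attenuates when the mediator GWAS is small (NOME violation), so
recovery checks use a large simulated mediator GWAS; the weighted median
under one-sided invalid weight f sits at the 0.5/(1−f) quantile of the
valid ratio distribution, an O(ratio-noise) bias, so robustness is
asserted as an ordering against IVW rather than exact unbiasedness.

## Pipeline and reproducibility

Stages run in the order simulate → screen → network → pathway → mediate
→ mr. One global seed fans out via `SeedSequence(seed).spawn` in that
fixed order, so any stage can be rerun in isolation. Every run writes
its config (YAML), a SHA-256 config hash, a log of the thresholds
actually used, and `schemas.json` describing every output table. The
canonical on-disk format is UTF-8 TSV with empty fields for missing
values; CSV is accepted on read.

## Problem sizes used in the shipped checks

Type-I calibration: 300 replicates of the 322-pair, 186-metabolite null
screen. FDR control: 400 replicates with 20 planted signals. Mediation
recovery: 200 replicates at 322 pairs with 300–400 bootstrap draws. MR
recovery: 30 simulations of 50-SNP panels; MR-PRESSO detection over 40
panels of 20 SNPs. Structure recovery: 50 chain datasets of n = 2000 for
the PC skeleton and 20 planted 5-block graphs of 27 nodes for walktrap.
These sizes keep the full suite to a few minutes on one core while
leaving Monte-Carlo error well inside the asserted bands.

## Limitations

Exact-string metabolite matching against pathway libraries (identifier
mapping is the user's concern); no CPDAG orientation of the network
skeleton; no imputation of missing covariates; no natural-effect
(counterfactual) mediation estimands beyond the product/difference
approximations; LD pruning without a reference panel is position-based;
the bidirectional-MR null behaviour relies on the outcome having its own
instruments and Steiger filtering removing exposure-first variants.
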