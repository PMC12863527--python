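# adipomet

Adiposity raises liver-cancer risk, but the metabolic route from excess
body fatness to hepatocarcinogenesis is poorly mapped. `adipomet`
implements the full analysis a molecular-epidemiology group would run to
chart that route from a 1:1 matched nested case-control study with
targeted metabolomics, together with a two-sample Mendelian randomization
(MR) suite to triangulate the observational findings. It is aimed at
epidemiologists and biostatisticians who want a tested, scriptable
version of this "meet-in-the-middle" workflow, exercised end-to-end on
synthetic data with known truth.

## The method

**Meet-in-the-middle screen.** For each of seven adiposity indices
(BMI, WC, WHR, WHtR, ABSI, HC, adult weight gain), step 1 fits
covariate-adjusted linear models of log₂ metabolite concentration on the
index, so β is the change per doubling scale; step 2 fits matched-pair
conditional logistic regressions of case status on log₂ metabolite, so
exp(β) is an odds ratio per doubling. Both steps apply Benjamini-Hochberg
FDR across the metabolite panel and a restricted-cubic-spline Wald test
of nonlinearity; an association is retained when FDR < 0.05 or
P_nonlinear < 0.05. Metabolites retained in both steps are the candidate
intermediates.

**Network, pathways, mediation.** Candidate intermediates are organised
by partial Spearman correlation (controls only, to avoid collider bias),
a PC-algorithm skeleton with walktrap modules, and hypergeometric
over-representation plus betweenness-based topology impact against
user-supplied GMT pathway libraries. A parallel multiple mediation model
— hierarchical clusters of mediators, each represented by its first
principal component — decomposes the index→cancer effect into a direct
effect (DE), per-cluster indirect effects IE_k = a_k·b_k, their total
(TIE), and the proportion mediated TIE/(DE+TIE), with percentile
bootstrap CIs resampling matched pairs.

**Two-sample MR.** From GWAS summary statistics: p-value thresholding
and greedy LD pruning (r² < 0.001 in a 10,000-kb window), allele
harmonization with palindrome handling, then Wald ratio, multiplicative
random-effects IVW, MR-Egger, weighted median and weighted mode, with
Cochran's Q, the Egger intercept test, MR-PRESSO outlier correction,
Steiger directionality filtering, bidirectional runs, multivariable MR,
and mediation MR by the Product (β_XM·β_MY|X) and Difference
(total − direct) methods.

Because no participant-level or GWAS data ship with the package, a
first-class synthetic module generates matched cohorts (with planted
adiposity→metabolite→outcome structure, drawn pair-conditionally so the
conditional-logistic analysis model is exactly the generating model) and
non-overlapping-sample summary statistics with controllable horizontal
pleiotropy.

## Worked example

```python
from adipomet import synthetic, anthropometry, screening, mediation

cfg = synthetic.CohortSimConfig(n_pairs=322, n_metabolites=186, seed=7)
sim = synthetic.generate_matched_cohort(cfg)
sim.cohort = sim.cohort.join(anthropometry.derive_indices(sim.cohort))

step1 = screening.fit_exposure_metabolite(
    sim.cohort, sim.metabolites, "bmi",
    ["age", "education", "income", "diet_score", "smoking", "drinking",
     "physical_activity"])
step2 = screening.fit_conditional_logistic(
    sim.cohort, sim.metabolites,
    ["age", "diet_score", "smoking", "drinking", "bmi", "physical_activity",
     "chronic_hepatitis", "cirrhosis", "cholelithiasis", "t2dm"])
inter, incidence = screening.meet_in_middle({"bmi": step1}, step2)

clusters = mediation.cluster_mediators(sim.metabolites[inter], max_clusters=10)
res = mediation.parallel_mediation(
    sim.cohort, "bmi", clusters,
    ["age", "education", "income", "diet_score", "smoking", "drinking",
     "physical_activity", "chronic_hepatitis", "cirrhosis",
     "cholelithiasis", "t2dm"],
    n_boot=1000, seed=7)
```

prints (via the obvious `print` statements):

```
step 1 retained: 26 of 186
step 2 retained: 68 of 186
intermediate metabolites: 16
direct effect      DE  = -0.007
total indirect     TIE = +0.146  (95% CI +0.113, +0.196)
proportion mediated    = 1.050  (95% CI 0.671, 1.796)
```

Read: of the 186 simulated metabolites, 26 are BMI-associated and 68
cancer-associated after FDR; 16 survive the intersection. The mediation
decomposition attributes essentially the whole BMI–cancer log-odds
association to the metabolite clusters (DE ≈ 0, TIE significantly
positive) — the planted structure in the default generator routes the
adiposity effect through the metabolites, so a proportion mediated near 1
is the correct answer here, not an artefact.

The same stages are available from the shell:

```sh
adipomet run-all --outdir demo --seed 7     # simulate → screen → … → mr
adipomet mr run --exposure exp.tsv --outcome out.tsv --p-thresh 5e-8
```

Outputs are tab-separated tables whose columns are documented in the
`schemas.json` written alongside every run.

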