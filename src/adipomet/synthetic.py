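"""Synthetic matched cohorts and GWAS summary statistics.

The cohort generator emulates a 1:1 matched nested case-control study of
middle-aged men: pairwise age matching (±2 years), anthropometrics whose
marginal means/SDs and cross-correlations track the source study's
baseline table (WC and WHtR strongly correlated, ABSI nearly independent
of BMI), a panel of log-normal metabolites with block correlation on the
log2 scale, an HBsAg-like binary confounder, and a planted
adiposity → metabolite → outcome mediation structure.  Case status is
drawn pair-conditionally from the conditional-logistic model itself, so
the matched-pair analysis model is exactly the generating model and
parameter recovery is a clean test surface.

The summary-statistics generator produces exposure / mediator / outcome
SNP tables from non-overlapping simulated samples with controllable
horizontal pleiotropy, so that with no pleiotropy the IVW estimate of the
exposure→outcome effect converges to direct + xm·my.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

METABOLITE_CLASSES = (
    "amino acid", "bile acid", "organic acid", "carnitine", "fatty acid",
    "carbohydrate", "nucleotide", "phospholipid", "sphingolipid", "other",
)


@dataclass
class CohortSimConfig:
    """Conditions for the matched-cohort simulator.

    Effect vectors are per metabolite: ``alpha_vec`` is the adiposity →
    log2-metabolite effect (log2 units per SD of the latent adiposity
    factor), ``b_vec`` the log-odds effect of one doubling of the
    metabolite on the outcome.  Defaults plant 27 intermediate metabolites
    (the first 27 of the panel) with alpha = 0.2 and b = 0.3, mirroring
    the scale of the study the generator emulates.
    """

    n_pairs: int = 322
    n_metabolites: int = 186
    n_blocks: int = 12
    block_rho: float | tuple | list | np.ndarray | None = None
    alpha_vec: np.ndarray | None = None
    b_vec: np.ndarray | None = None
    n_planted: int = 27
    planted_alpha: float = 0.2
    planted_b: float = 0.3
    direct_effect: float = 0.15
    gamma_confounder: float = 4.0
    confounder_prev: float = 0.30
    missing_w20_frac: float = 85 / 644
    bmi_adiposity_loading: float = 0.9
    seed: int = 0

    def __post_init__(self):
        if self.n_pairs < 2:
            raise ValueError("n_pairs must be at least 2")
        if self.alpha_vec is None:
            a = np.zeros(self.n_metabolites)
            a[: self.n_planted] = self.planted_alpha
            self.alpha_vec = a
        else:
            self.alpha_vec = np.asarray(self.alpha_vec, float)
        if self.b_vec is None:
            b = np.zeros(self.n_metabolites)
            b[: self.n_planted] = self.planted_b
            self.b_vec = b
        else:
            self.b_vec = np.asarray(self.b_vec, float)
        for name, v in (("alpha_vec", self.alpha_vec), ("b_vec", self.b_vec)):
            if len(v) != self.n_metabolites:
                raise ValueError(f"{name} must have length n_metabolites")
        if self.block_rho is None:
            rho = np.full(self.n_blocks, 0.45)
            rho[0] = 0.85  # one tight (bile-acid-like) block
            self.block_rho = rho
        else:
            rho = np.atleast_1d(np.asarray(self.block_rho, float))
            if rho.size == 1:
                rho = np.full(self.n_blocks, float(rho.ravel()[0]))
            if rho.size != self.n_blocks:
                raise ValueError("block_rho must be scalar or length n_blocks")
            self.block_rho = rho
        if np.any((self.block_rho < 0) | (self.block_rho >= 1)):
            raise ValueError("block_rho entries must lie in [0, 1)")


@dataclass
class SimulatedCohort:
    cohort: pd.DataFrame
    metabolites: pd.DataFrame
    annotations: pd.DataFrame
    truth: dict = field(default_factory=dict)


def _simulate_anthro(n: int, Z: np.ndarray, rng: np.random.Generator):
    """Anthropometrics given the latent adiposity factor Z (one per person).

    Constants target the baseline table of the emulated study: BMI
    23.7 ± 3.2 kg/m², WC 85 ± 9 cm, HC 94.5, WHR 0.90 ± 0.06, adult weight
    gain 11 ± 9.6 kg, plus the calibration targets Spearman(WC, WHtR) ≈
    0.94 and Spearman(ABSI, BMI) ≈ -0.03.  The WC-on-weight slope sits
    near the 2/3-power scaling that makes ABSI orthogonal to BMI.
    """
    height = rng.normal(166.6, 6.0, n)
    bmi = 23.66 + 3.20 * (0.9 * Z + np.sqrt(1 - 0.81) * rng.standard_normal(n))
    bmi = np.clip(bmi, 15.0, 45.0)
    weight = bmi * (height / 100.0) ** 2
    wc = (
        85.2
        + 2.35 * (bmi - 23.66)
        + 0.80 * (height - 166.6)
        + rng.normal(0.0, 2.8, n)
    )
    hc = (
        94.5
        + 1.55 * (bmi - 23.66)
        + 0.25 * (height - 166.6)
        + rng.normal(0.0, 2.6, n)
    )
    gain = 11.2 + 9.0 * (
        0.55 * Z + np.sqrt(1 - 0.55**2) * rng.standard_normal(n)
    )
    weight_at_20 = weight - gain
    return pd.DataFrame(
        {
            "height_cm": height,
            "weight_kg": weight,
            "weight_at_20_kg": weight_at_20,
            "wc_cm": np.clip(wc, 55, None),
            "hc_cm": np.clip(hc, 65, None),
        }
    )


def generate_matched_cohort(config: CohortSimConfig) -> SimulatedCohort:
    """Simulate the matched cohort and its metabolite matrix.

    Within each pair, member ages agree to ±2 years; case status is
    assigned pair-conditionally: member 1 is the case with probability
    sigma(eta_1 - eta_2) where

        eta = direct_effect·Z + sum_k b_k·log2(metabolite_k)
              + gamma_confounder·HBsAg.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n = 2 * cfg.n_pairs

    # latent adiposity and anthropometrics
    Z = rng.standard_normal(n)
    anthro = _simulate_anthro(n, Z, rng)

    # metabolites: per-block single-factor Gaussian copula on log2 scale
    m = cfg.n_metabolites
    blocks = np.arange(m) % cfg.n_blocks
    mu = rng.normal(3.0, 1.5, m)  # log2 µmol/L baselines
    F = rng.standard_normal((n, cfg.n_blocks))
    eps = rng.standard_normal((n, m))
    rho_j = cfg.block_rho[blocks]
    log2_m = (
        mu[None, :]
        + cfg.alpha_vec[None, :] * Z[:, None]
        + np.sqrt(rho_j)[None, :] * F[:, blocks]
        + np.sqrt(1 - rho_j)[None, :] * eps
    )
    met_names = [f"met_{j:03d}" for j in range(m)]
    metabolites = pd.DataFrame(2.0**log2_m, columns=met_names)
    annotations = pd.DataFrame(
        {
            "name": met_names,
            "class": [METABOLITE_CLASSES[b % len(METABOLITE_CLASSES)]
                      for b in blocks],
            "block": blocks,
        }
    )

    # covariates
    hbsag = rng.binomial(1, cfg.confounder_prev, n)
    chronic_hep = rng.binomial(1, np.where(hbsag == 1, 0.25, 0.02))
    cirrhosis = rng.binomial(1, np.where(hbsag == 1, 0.08, 0.005))
    covars = pd.DataFrame(
        {
            "education": rng.choice([1, 2, 3], n, p=[0.11, 0.72, 0.17]),
            "income": rng.choice([1, 2, 3], n, p=[0.60, 0.31, 0.09]),
            "smoking": rng.binomial(1, 0.68, n),
            "drinking": rng.binomial(1, 0.33, n),
            "physical_activity": np.exp(rng.normal(np.log(58.0), 0.45, n)),
            "diet_score": rng.normal(30.5, 5.0, n),
            "t2dm": rng.binomial(1, 0.09, n),
            "cholelithiasis": rng.binomial(1, 0.10, n),
            "hbsag": hbsag,
            "chronic_hepatitis": chronic_hep,
            "cirrhosis": cirrhosis,
        }
    )

    # age matching within ±2 years; fasting time shared at the pair level
    base_age = rng.uniform(47, 72, cfg.n_pairs)
    age = np.empty(n)
    age[0::2] = base_age + rng.uniform(-1, 1, cfg.n_pairs)
    age[1::2] = np.clip(
        age[0::2] + rng.uniform(-2, 2, cfg.n_pairs), 40, 80
    )
    fasting = np.repeat(
        np.exp(rng.normal(np.log(4.0), 0.5, cfg.n_pairs)), 2
    ) * np.exp(rng.normal(0, 0.05, n))

    # pair-conditional case assignment
    eta = (
        cfg.direct_effect * Z
        + log2_m @ cfg.b_vec
        + cfg.gamma_confounder * hbsag
    )
    d = eta[0::2] - eta[1::2]
    p_first = 1.0 / (1.0 + np.exp(-np.clip(d, -35, 35)))
    first_is_case = rng.random(cfg.n_pairs) < p_first
    is_case = np.empty(n, dtype=int)
    is_case[0::2] = first_is_case.astype(int)
    is_case[1::2] = 1 - first_is_case.astype(int)

    cohort = pd.concat(
        [
            pd.DataFrame(
                {
                    "pair_id": np.repeat(np.arange(cfg.n_pairs), 2),
                    "is_case": is_case,
                    "age": age,
                    "fasting_hours": fasting,
                }
            ),
            anthro,
            covars,
        ],
        axis=1,
    )
    # missing weight at age 20 (self-report unavailable for a fraction)
    n_miss = int(round(cfg.missing_w20_frac * n))
    miss_idx = rng.choice(n, size=n_miss, replace=False)
    cohort.loc[miss_idx, "weight_at_20_kg"] = np.nan

    return SimulatedCohort(
        cohort=cohort,
        metabolites=metabolites,
        annotations=annotations,
        truth={
            "adiposity": Z,
            "alpha_vec": cfg.alpha_vec.copy(),
            "b_vec": cfg.b_vec.copy(),
            "blocks": blocks,
            "log2_mu": mu,
        },
    )


# ---------------------------------------------------------------------------
# GWAS summary statistics
# ---------------------------------------------------------------------------

@dataclass
class SumStatsSimConfig:
    """Conditions for the summary-statistics simulator.

    True per-SNP effects act on a standardized exposure; the mediator and
    outcome inherit them through the causal paths theta_xm and theta_my
    plus the direct path theta_xy_direct.  A ``pleiotropy_frac`` share of
    SNPs gains an independent direct outcome effect drawn from
    N(pleiotropy_mean, pleiotropy_sd²) — mean zero gives balanced,
    mean-nonzero directional, horizontal pleiotropy.  The three samples
    are non-overlapping by construction (independent noise draws).
    """

    n_snps: int = 100
    h2_exposure: float = 0.10
    h2_mediator: float = 0.05
    n_exposure: int = 500_000
    n_mediator: int = 8_000
    n_outcome: int = 200_000
    theta_xm: float = 0.0
    theta_my: float = 0.0
    theta_xy_direct: float = 0.0
    pleiotropy_frac: float = 0.0
    pleiotropy_sd: float = 0.0
    pleiotropy_mean: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if not 0 <= self.pleiotropy_frac <= 1:
            raise ValueError("pleiotropy_frac must lie in [0, 1]")
        if not 0 <= self.h2_exposure < 1:
            raise ValueError("h2_exposure must lie in [0, 1)")
        for s in (self.n_exposure, self.n_mediator, self.n_outcome):
            if s <= 0:
                raise ValueError("sample sizes must be positive")


_BASES = np.array(list("ACGT"))


def generate_sumstats(
    config: SumStatsSimConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate (exposure, mediator, outcome) summary-statistic tables.

    Standard errors follow the standardized-trait approximation
    se = 1/sqrt(2·eaf·(1-eaf)·n); estimated betas are the true effects
    plus independent noise at that scale per trait (non-overlapping
    samples).  SNPs are spread across chromosomes at 20-Mb spacing so the
    default instruments survive window pruning.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    k = cfg.n_snps
    eaf = rng.uniform(0.10, 0.90, k)

    var_unit = 2 * eaf * (1 - eaf)

    def draw_effects(h2):
        raw = rng.standard_normal(k)
        if h2 <= 0:
            return np.zeros(k)
        return raw * np.sqrt(h2 / np.sum(var_unit * raw**2))

    gamma = draw_effects(cfg.h2_exposure)   # SNP -> exposure
    delta = draw_effects(cfg.h2_mediator)   # SNP -> mediator, not via exposure

    # pleiotropic outcome effects are expressed relative to the
    # exposure-raising allele, so a nonzero mean is genuinely directional
    pleio = np.zeros(k)
    n_pleio = int(round(cfg.pleiotropy_frac * k))
    if n_pleio:
        idx = rng.choice(k, n_pleio, replace=False)
        orient = np.sign(gamma[idx])
        orient[orient == 0] = 1.0
        pleio[idx] = orient * rng.normal(cfg.pleiotropy_mean,
                                         cfg.pleiotropy_sd, n_pleio)

    med_true = cfg.theta_xm * gamma + delta
    true = {
        "exposure": gamma,
        "mediator": med_true,
        "outcome": cfg.theta_xy_direct * gamma + cfg.theta_my * med_true
        + pleio,
    }
    sizes = {
        "exposure": cfg.n_exposure,
        "mediator": cfg.n_mediator,
        "outcome": cfg.n_outcome,
    }

    chrom = (np.arange(k) % 22) + 1
    pos = 1_000_000 + (np.arange(k) // 22) * 20_000_000
    a_idx = rng.integers(0, 4, k)
    shift = rng.integers(1, 4, k)
    effect_allele = _BASES[a_idx]
    other_allele = _BASES[(a_idx + shift) % 4]

    from scipy import stats as _st

    tables = []
    for trait in ("exposure", "mediator", "outcome"):
        n = sizes[trait]
        se = 1.0 / np.sqrt(var_unit * n)
        beta = true[trait] + se * rng.standard_normal(k)
        pval = 2 * _st.norm.sf(np.abs(beta / se))
        tables.append(
            pd.DataFrame(
                {
                    "snp": [f"rs{i + 1}" for i in range(k)],
                    "chr": chrom,
                    "pos": pos,
                    "effect_allele": effect_allele,
                    "other_allele": other_allele,
                    "eaf": eaf,
                    "beta": beta,
                    "se": se,
                    "pval": pval,
                    "n": n,
                }
            )
        )
    return tuple(tables)
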