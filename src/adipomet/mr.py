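"""Two-sample Mendelian randomization from GWAS summary statistics.

Instrument selection (p-value threshold + greedy LD pruning), allele
harmonization, the univariable estimators (Wald ratio, multiplicative
random-effects IVW, MR-Egger, weighted median, weighted mode), the
sensitivity suite (Cochran's Q, Egger intercept, MR-PRESSO, Steiger
filtering), multivariable MR, and mediation MR via the Product and
Difference methods.

Summary-statistics tables are pandas DataFrames with columns
``snp, chr, pos, effect_allele, other_allele, eaf, beta, se, pval, n``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

SUMSTATS_COLUMNS = (
    "snp", "chr", "pos", "effect_allele", "other_allele",
    "eaf", "beta", "se", "pval", "n",
)

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


@dataclass
class MrEstimate:
    method: str
    beta: float
    se: float
    ci_low: float
    ci_high: float
    pval: float
    n_snps: int
    intercept: float | None = None
    intercept_se: float | None = None
    intercept_p: float | None = None
    q_stat: float | None = None
    q_p: float | None = None
    notes: str = ""

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in (
            "method", "beta", "se", "ci_low", "ci_high", "pval", "n_snps",
            "intercept", "intercept_p", "q_stat", "q_p")}


@dataclass
class HarmonizedSet:
    """Per-SNP exposure and outcome effects aligned to the same allele."""

    table: pd.DataFrame  # snp, beta_exp, se_exp, eaf_exp, beta_out, se_out, ...
    exclusions: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["snp", "reason"])
    )

    def __len__(self) -> int:
        return len(self.table)

    def arrays(self):
        t = self.table
        return (
            t["beta_exp"].to_numpy(float), t["se_exp"].to_numpy(float),
            t["beta_out"].to_numpy(float), t["se_out"].to_numpy(float),
        )


# ---------------------------------------------------------------------------
# instrument selection & harmonization
# ---------------------------------------------------------------------------

def select_instruments(
    stats_table: pd.DataFrame,
    p_threshold: float = 5e-8,
    ld_r2: float = 0.001,
    window_kb: float = 10_000,
    ld_reference: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Significance filtering plus greedy window-based LD pruning.

    SNPs below ``p_threshold`` are sorted by p ascending and kept greedily:
    a candidate is dropped if a kept SNP on the same chromosome lies within
    the window and their pairwise r² (from ``ld_reference`` with columns
    snp_a/snp_b/r2, or 1.0 for identical positions when no reference is
    given, else 0) reaches ``ld_r2``.  An empty frame — no exception — is
    returned when nothing passes the threshold.
    """
    if not (0 < p_threshold < 1):
        raise ValueError("p_threshold must be in (0, 1)")
    cand = stats_table[stats_table["pval"] < p_threshold].copy()
    if cand.empty:
        return cand
    ld = {}
    if ld_reference is not None:
        for r in ld_reference.itertuples(index=False):
            ld[frozenset((r.snp_a, r.snp_b))] = float(r.r2)
    cand = cand.sort_values(["pval", "snp"], kind="stable")
    kept = []
    window = window_kb * 1000.0
    for row in cand.itertuples(index=False):
        prune = False
        for k in kept:
            if k.chr != row.chr or abs(k.pos - row.pos) > window:
                continue
            r2 = ld.get(frozenset((k.snp, row.snp)))
            if r2 is None:
                r2 = 1.0 if k.pos == row.pos else 0.0
            if r2 >= ld_r2:
                prune = True
                break
        if not prune:
            kept.append(row)
    return pd.DataFrame(kept)[list(cand.columns)]


def _is_palindromic(a1: str, a2: str) -> bool:
    return _COMPLEMENT.get(a1) == a2


def harmonize(
    exposure: pd.DataFrame,
    outcome: pd.DataFrame,
    palindrome_eaf_band: tuple[float, float] = (0.42, 0.58),
) -> HarmonizedSet:
    """Align outcome effects to the exposure effect allele.

    Swapped alleles flip the outcome beta and complement its eaf; strand
    flips (A<->T, C<->G) are resolved through the complement map.
    Palindromic SNPs are kept only when both allele frequencies fall
    outside the ambiguity band and imply the same orientation; everything
    unresolvable is dropped with a logged reason.
    """
    lo, hi = palindrome_eaf_band
    exp = exposure.set_index("snp")
    out = outcome.set_index("snp")
    shared = exp.index.intersection(out.index)
    rows, dropped = [], []
    for snp in shared:
        e, o = exp.loc[snp], out.loc[snp]
        ea, oa = str(e.effect_allele), str(e.other_allele)
        b_out, eaf_out = float(o.beta), float(o.eaf)
        oea, ooa = str(o.effect_allele), str(o.other_allele)
        if _is_palindromic(ea, oa):
            if {oea, ooa} != {ea, oa}:
                dropped.append((snp, "allele_mismatch"))
                continue
            eaf_exp = float(e.eaf)
            if not (eaf_exp < lo or eaf_exp > hi) or not (
                eaf_out < lo or eaf_out > hi
            ):
                dropped.append((snp, "palindromic_ambiguous"))
                continue
            # orient by frequency: minor/major alignment must agree
            if (eaf_exp < 0.5) != (eaf_out < 0.5):
                b_out, eaf_out = -b_out, 1 - eaf_out
                if oea == ea:
                    # frequencies disagreed though alleles matched: ambiguous
                    dropped.append((snp, "palindromic_inconsistent"))
                    continue
            elif oea != ea:
                dropped.append((snp, "palindromic_inconsistent"))
                continue
        else:
            if (oea, ooa) == (ea, oa):
                pass
            elif (oea, ooa) == (oa, ea):
                b_out, eaf_out = -b_out, 1 - eaf_out
            elif (
                _COMPLEMENT.get(oea) == ea and _COMPLEMENT.get(ooa) == oa
            ):
                pass  # strand flip, same orientation
            elif (
                _COMPLEMENT.get(oea) == oa and _COMPLEMENT.get(ooa) == ea
            ):
                b_out, eaf_out = -b_out, 1 - eaf_out
            else:
                dropped.append((snp, "allele_mismatch"))
                continue
        rows.append(
            {
                "snp": snp, "chr": e.chr, "pos": e.pos,
                "effect_allele": ea, "other_allele": oa,
                "beta_exp": float(e.beta), "se_exp": float(e.se),
                "eaf_exp": float(e.eaf), "n_exp": float(e.n),
                "beta_out": b_out, "se_out": float(o.se),
                "eaf_out": eaf_out, "n_out": float(o.n),
            }
        )
    return HarmonizedSet(
        pd.DataFrame(rows),
        pd.DataFrame(dropped, columns=["snp", "reason"]),
    )


# ---------------------------------------------------------------------------
# univariable estimators
# ---------------------------------------------------------------------------

def _normal_ci(beta, se):
    z = 1.959964
    return beta - z * se, beta + z * se


def wald_ratio(hset: HarmonizedSet, second_order: bool = False) -> MrEstimate:
    """Single-SNP causal estimate beta_out / beta_exp."""
    if len(hset) != 1:
        raise ValueError("wald_ratio expects exactly one SNP")
    bx, sx, by, sy = (a[0] for a in hset.arrays())
    if bx == 0:
        raise ZeroDivisionError("zero exposure beta")
    beta = by / bx
    se = sy / abs(bx)
    if second_order:
        se = np.sqrt(sy**2 / bx**2 + by**2 * sx**2 / bx**4)
    lo, hi = _normal_ci(beta, se)
    p = 2 * stats.norm.sf(abs(beta) / se) if se > 0 else 0.0
    return MrEstimate("wald_ratio", beta, se, lo, hi, p, 1)


def ivw(hset: HarmonizedSet) -> MrEstimate:
    """Multiplicative random-effects inverse-variance weighted estimate.

    Equivalent to weighted regression of outcome betas on exposure betas
    through the origin with weights 1/se_out²; the fixed-effect standard
    error is inflated by sqrt(Q/(k-1)) when Cochran's Q exceeds its
    degrees of freedom.
    """
    if len(hset) < 2:
        return wald_ratio(hset)
    bx, sx, by, sy = hset.arrays()
    w = 1.0 / sy**2
    beta = np.sum(w * bx * by) / np.sum(w * bx**2)
    se_fixed = 1.0 / np.sqrt(np.sum(w * bx**2))
    k = len(bx)
    q = float(np.sum(w * (by - beta * bx) ** 2))
    q_p = float(stats.chi2.sf(q, k - 1))
    se = se_fixed * max(1.0, np.sqrt(q / (k - 1)))
    lo, hi = _normal_ci(beta, se)
    p = 2 * stats.norm.sf(abs(beta) / se)
    return MrEstimate("ivw", float(beta), float(se), lo, hi, float(p), k,
                      q_stat=q, q_p=q_p)


def mr_egger(hset: HarmonizedSet) -> MrEstimate:
    """MR-Egger regression; the intercept is the pleiotropy test.

    Exposure betas are orientation-standardized to be positive (with the
    outcome betas flipped in tandem) before the weighted regression with
    intercept.  Standard errors use the multiplicative overdispersion
    factor max(1, sqrt(Q/(k-2))) and p-values a t reference on k-2 df.
    """
    if len(hset) < 3:
        raise ValueError("MR-Egger needs at least 3 SNPs")
    bx, sx, by, sy = hset.arrays()
    flip = np.sign(bx)
    flip[flip == 0] = 1.0
    bx, by = bx * flip, by * flip
    w = 1.0 / sy**2
    X = np.column_stack([np.ones_like(bx), bx])
    WX = X * w[:, None]
    XtWX = X.T @ WX
    coef = np.linalg.solve(XtWX, WX.T @ by)
    resid = by - X @ coef
    k = len(bx)
    q = float(np.sum(w * resid**2))
    phi = max(1.0, q / (k - 2))
    cov = np.linalg.inv(XtWX) * phi
    se = np.sqrt(np.diag(cov))
    tcrit = stats.t.ppf(0.975, k - 2)
    p_slope = 2 * stats.t.sf(abs(coef[1] / se[1]), k - 2)
    p_int = 2 * stats.t.sf(abs(coef[0] / se[0]), k - 2)
    return MrEstimate(
        "mr_egger", float(coef[1]), float(se[1]),
        float(coef[1] - tcrit * se[1]), float(coef[1] + tcrit * se[1]),
        float(p_slope), k,
        intercept=float(coef[0]), intercept_se=float(se[0]),
        intercept_p=float(p_int),
        q_stat=q, q_p=float(stats.chi2.sf(q, k - 2)),
    )


def _weighted_median_point(ratios: np.ndarray, weights: np.ndarray) -> float:
    order = np.argsort(ratios)
    r, w = ratios[order], weights[order]
    w = w / w.sum()
    cum = np.cumsum(w) - 0.5 * w  # midpoint cumulative weights
    if 0.5 <= cum[0]:
        return float(r[0])
    if 0.5 >= cum[-1]:
        return float(r[-1])
    i = int(np.searchsorted(cum, 0.5))
    f = (0.5 - cum[i - 1]) / (cum[i] - cum[i - 1])
    return float(r[i - 1] + f * (r[i] - r[i - 1]))


def weighted_median(hset: HarmonizedSet, n_boot: int = 1000,
                    seed: int | None = None) -> MrEstimate:
    """Inverse-variance weighted median of the per-SNP ratio estimates.

    Consistent when SNPs carrying at least half the weight are valid
    instruments; the standard error comes from a parametric bootstrap.
    """
    if len(hset) < 3:
        raise ValueError("weighted median needs at least 3 SNPs")
    bx, sx, by, sy = hset.arrays()
    ratios = by / bx
    var = sy**2 / bx**2
    w = 1.0 / var
    beta = _weighted_median_point(ratios, w)
    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    for i in range(n_boot):
        bx_s = bx + sx * rng.standard_normal(len(bx))
        by_s = by + sy * rng.standard_normal(len(by))
        r = by_s / bx_s
        boots[i] = _weighted_median_point(r, 1.0 / (sy**2 / bx_s**2))
    se = float(np.std(boots, ddof=1))
    lo, hi = _normal_ci(beta, se)
    p = 2 * stats.norm.sf(abs(beta) / se) if se > 0 else 0.0
    return MrEstimate("weighted_median", beta, se, lo, hi, float(p), len(bx))


def weighted_mode(hset: HarmonizedSet, bandwidth_factor: float = 0.5,
                  n_boot: int = 1000, seed: int | None = None) -> MrEstimate:
    """Mode of the kernel-smoothed weighted ratio-estimate density.

    Bandwidth = ``bandwidth_factor`` x the modified (MAD-based) scale rule.
    Exact ties between density peaks break to the lower mode and are noted.
    """
    if len(hset) < 3:
        raise ValueError("weighted mode needs at least 3 SNPs")
    bx, sx, by, sy = hset.arrays()

    def point(bx_, by_, sy_):
        ratios = by_ / bx_
        w = bx_**2 / sy_**2
        s = 0.9 * min(np.std(ratios, ddof=1),
                      stats.median_abs_deviation(ratios, scale="normal")
                      or np.std(ratios, ddof=1))
        h = max(bandwidth_factor * s * len(ratios) ** (-0.2), 1e-8)
        grid = np.linspace(ratios.min() - 3 * h, ratios.max() + 3 * h, 512)
        dens = np.sum(
            w[:, None] * np.exp(-0.5 * ((grid[None] - ratios[:, None]) / h) ** 2),
            axis=0,
        )
        peak = np.max(dens)
        # lowest grid point attaining the maximum: deterministic tie-break
        tied = np.nonzero(np.isclose(dens, peak, rtol=1e-12))[0]
        return float(grid[tied[0]]), len(tied) > 1

    beta, tie = point(bx, by, sy)
    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    for i in range(n_boot):
        bx_s = bx + sx * rng.standard_normal(len(bx))
        by_s = by + sy * rng.standard_normal(len(by))
        boots[i], _ = point(bx_s, by_s, sy)
    se = float(np.std(boots, ddof=1))
    lo, hi = _normal_ci(beta, se)
    p = 2 * stats.norm.sf(abs(beta) / se) if se > 0 else 0.0
    return MrEstimate("weighted_mode", beta, se, lo, hi, float(p), len(bx),
                      notes="tied_modes" if tie else "")


# ---------------------------------------------------------------------------
# sensitivity suite
# ---------------------------------------------------------------------------

@dataclass
class PressoResult:
    global_p: float
    global_rss: float
    outliers: list[str]
    outlier_p: pd.Series
    corrected: MrEstimate
    uncorrected: MrEstimate


def mr_presso(hset: HarmonizedSet, n_sim: int = 1000, outlier_p: float = 0.05,
              seed: int | None = None) -> PressoResult:
    """MR-PRESSO global pleiotropy test and outlier correction.

    The observed residual sum of squares (each SNP's squared deviation from
    the leave-one-out IVW fit, in outcome-variance units) is compared with
    its parametric distribution under the no-pleiotropy model; per-SNP
    observed-vs-expected comparisons give outlier p-values, Bonferroni
    thresholded, and the corrected estimate is plain IVW on the non-outliers.
    """
    if len(hset) < 4:
        raise ValueError("MR-PRESSO needs at least 4 SNPs")
    rng = np.random.default_rng(seed)
    bx, sx, by, sy = hset.arrays()
    k = len(bx)
    w = 1.0 / sy**2

    def loo_betas(bx_, by_, w_):
        sxy = np.sum(w_ * bx_ * by_)
        sxx = np.sum(w_ * bx_**2)
        return (sxy - w_ * bx_ * by_) / (sxx - w_ * bx_**2)

    beta_loo = loo_betas(bx, by, w)
    obs_res2 = w * (by - beta_loo * bx) ** 2
    obs_rss = float(np.sum(obs_res2))

    sim_rss = np.empty(n_sim)
    sim_res2 = np.empty((n_sim, k))
    for s in range(n_sim):
        bx_s = bx + sx * rng.standard_normal(k)
        by_s = beta_loo * bx + sy * rng.standard_normal(k)
        bl = loo_betas(bx_s, by_s, w)
        r2 = w * (by_s - bl * bx_s) ** 2
        sim_res2[s] = r2
        sim_rss[s] = r2.sum()
    global_p = float((np.sum(sim_rss >= obs_rss) + 1) / (n_sim + 1))

    snp_p = (np.sum(sim_res2 >= obs_res2[None, :], axis=0) + 1) / (n_sim + 1)
    snp_p = pd.Series(snp_p, index=hset.table["snp"].to_numpy())
    thresh = outlier_p / k  # Bonferroni
    outliers = list(snp_p.index[snp_p.to_numpy() < thresh])

    uncorr = ivw(hset)
    keep = ~hset.table["snp"].isin(outliers)
    if keep.sum() < 2:
        raise ValueError("all SNPs flagged as outliers")
    corrected = ivw(HarmonizedSet(hset.table[keep].reset_index(drop=True)))
    corrected.notes = f"outliers_removed={len(outliers)}"
    return PressoResult(global_p, obs_rss, outliers, snp_p, corrected, uncorr)


def steiger_filter(hset: HarmonizedSet) -> tuple[HarmonizedSet, pd.DataFrame]:
    """Steiger directionality filtering.

    Per SNP the variance explained in each trait is recovered from the
    t-statistic, r² = t²/(t² + n - 2); a SNP is retained iff it explains
    more variance in the exposure than in the outcome (z-test on the
    Fisher-transformed correlations reported alongside).  Exact ties are
    indeterminate and dropped.
    """
    t = hset.table
    if t[["n_exp", "n_out"]].isna().any().any():
        raise ValueError("sample sizes required for Steiger filtering")
    tx = (t["beta_exp"] / t["se_exp"]).to_numpy(float)
    ty = (t["beta_out"] / t["se_out"]).to_numpy(float)
    n_exp = t["n_exp"].to_numpy(float)
    n_out = t["n_out"].to_numpy(float)
    r2_exp = tx**2 / (tx**2 + n_exp - 2)
    r2_out = ty**2 / (ty**2 + n_out - 2)
    r_exp, r_out = np.sqrt(r2_exp), np.sqrt(r2_out)
    z = (np.arctanh(r_exp) - np.arctanh(r_out)) / np.sqrt(
        1 / (n_exp - 3) + 1 / (n_out - 3)
    )
    pz = 2 * stats.norm.sf(np.abs(z))
    direction = np.where(
        r2_exp > r2_out, "forward",
        np.where(r2_exp < r2_out, "reverse", "indeterminate"),
    )
    flags = pd.DataFrame(
        {
            "snp": t["snp"].to_numpy(), "r2_exp": r2_exp, "r2_out": r2_out,
            "direction": direction, "steiger_z": z, "steiger_p": pz,
        }
    )
    keep = direction == "forward"
    return (
        HarmonizedSet(t[keep].reset_index(drop=True),
                      hset.exclusions), flags,
    )


# ---------------------------------------------------------------------------
# multivariable & mediation MR
# ---------------------------------------------------------------------------

def mvmr_ivw(
    beta_exposures: pd.DataFrame,
    beta_outcome: np.ndarray,
    se_outcome: np.ndarray,
    cond_threshold: float = 1e8,
) -> pd.DataFrame:
    """Multivariable IVW: weighted multiple regression without intercept.

    ``beta_exposures`` holds one column of instrument-exposure betas per
    exposure (jointly harmonized); outcome betas are regressed on this
    matrix with weights 1/se_out², giving the conditional (direct) effect
    of each exposure.  Collinear exposure columns raise an error naming the
    most correlated pair.
    """
    cols = list(beta_exposures.columns)
    Xfull = beta_exposures.to_numpy(float)
    y = np.asarray(beta_outcome, float)
    sy = np.asarray(se_outcome, float)
    k = Xfull.shape[0]
    if k < Xfull.shape[1] + 1:
        raise ValueError("need more instruments than exposures")
    # an all-zero beta column carries no instrument strength: its
    # conditional effect is unidentified and reported as NaN
    active = [i for i in range(Xfull.shape[1])
              if np.any(Xfull[:, i] != 0)]
    X = Xfull[:, active]
    m = X.shape[1]
    if m == 0:
        raise ValueError("all exposure beta columns are zero")
    w = 1.0 / sy**2
    WX = X * w[:, None]
    XtWX = X.T @ WX
    if m > 1 and np.linalg.cond(XtWX) > cond_threshold:
        C = np.corrcoef(X, rowvar=False)
        np.fill_diagonal(C, 0)
        i, j = np.unravel_index(np.argmax(np.abs(C)), C.shape)
        raise ValueError(
            f"collinear exposure beta columns: {cols[active[i]]!r} and "
            f"{cols[active[j]]!r}"
        )
    coef_a = np.linalg.solve(XtWX, WX.T @ y)
    resid = y - X @ coef_a
    q = float(np.sum(w * resid**2))
    phi = max(1.0, q / (k - m))
    cov = np.linalg.inv(XtWX) * phi
    se_a = np.sqrt(np.diag(cov))
    coef = np.full(len(cols), np.nan)
    se = np.full(len(cols), np.nan)
    coef[active], se[active] = coef_a, se_a
    with np.errstate(invalid="ignore"):
        p = 2 * stats.norm.sf(np.abs(coef / se))
    return pd.DataFrame(
        {
            "exposure": cols,
            "beta": coef, "se": se,
            "ci_low": coef - 1.959964 * se, "ci_high": coef + 1.959964 * se,
            "pval": p, "n_snps": k, "q_stat": q,
        }
    )


@dataclass
class MediationMrResult:
    method: str  # "difference" | "product"
    total: float
    direct: float
    indirect: float
    indirect_se: float
    ci_low: float
    ci_high: float
    proportion_mediated: float | None
    notes: str = ""


def mediation_mr(
    total: MrEstimate,
    direct: MrEstimate,
    xm: MrEstimate,
    my_adj: MrEstimate | pd.Series,
) -> tuple[MediationMrResult, MediationMrResult]:
    """Difference- and Product-method mediation from MR building blocks.

    Difference: indirect = total - direct with se = sqrt(se_tot² + se_dir²)
    (independence of the two estimates is an approximation, noted in the
    output).  Product: indirect = beta_{X→M} · beta_{M→Y|X} with the
    first-order delta-method se.  The mediated proportion is
    indirect / total for each, undefined when the total effect is ≈ 0.
    """
    if isinstance(my_adj, pd.Series):
        b_my, se_my = float(my_adj["beta"]), float(my_adj["se"])
    else:
        b_my, se_my = my_adj.beta, my_adj.se

    ind_d = total.beta - direct.beta
    se_d = float(np.sqrt(total.se**2 + direct.se**2))
    ind_p = xm.beta * b_my
    se_p = float(
        np.sqrt(xm.beta**2 * se_my**2 + b_my**2 * xm.se**2)
    )

    def prop(ind):
        if abs(total.beta) < 1e-12:
            return None
        return ind / total.beta

    out = []
    for method, ind, se, note in (
        ("difference", ind_d, se_d,
         "se assumes independent total and direct estimates"),
        ("product", ind_p, se_p, "first-order delta method"),
    ):
        lo, hi = _normal_ci(ind, se)
        out.append(
            MediationMrResult(
                method, total.beta, direct.beta, float(ind), se,
                float(lo), float(hi), prop(ind), note,
            )
        )
    return out[0], out[1]


# ---------------------------------------------------------------------------
# convenience drivers
# ---------------------------------------------------------------------------

def run_univariable(
    exposure_stats: pd.DataFrame,
    outcome_stats: pd.DataFrame,
    p_threshold: float = 5e-8,
    ld_r2: float = 0.001,
    window_kb: float = 10_000,
    ld_reference: pd.DataFrame | None = None,
    n_boot: int = 1000,
    seed: int | None = None,
) -> dict:
    """Full univariable pipeline: select, harmonize, estimate, sensitivities."""
    iv = select_instruments(exposure_stats, p_threshold, ld_r2, window_kb,
                            ld_reference)
    if iv.empty:
        return {"status": "no_instruments", "estimates": []}
    hset = harmonize(iv, outcome_stats)
    if len(hset) == 0:
        return {"status": "no_harmonized_snps", "estimates": []}
    ests = []
    if len(hset) == 1:
        ests.append(wald_ratio(hset))
    else:
        ests.append(ivw(hset))
        if len(hset) >= 3:
            ests.append(mr_egger(hset))
            ests.append(weighted_median(hset, n_boot=n_boot, seed=seed))
            ests.append(weighted_mode(hset, n_boot=n_boot, seed=seed))
    out = {"status": "ok", "estimates": ests, "harmonized": hset}
    if len(hset) >= 4:
        try:
            out["presso"] = mr_presso(hset, seed=seed)
        except ValueError as exc:  # e.g. every SNP flagged as an outlier
            out["presso_error"] = str(exc)
    filtered, flags = steiger_filter(hset)
    out["steiger_flags"] = flags
    if len(filtered) >= 2:
        out["ivw_steiger"] = ivw(filtered)
    return out


def run_mvmr(
    outcome_stats: pd.DataFrame,
    exposure_stats: dict[str, pd.DataFrame],
    p_thresholds: dict[str, float] | float = 5e-8,
    ld_r2: float = 0.001,
    window_kb: float = 10_000,
) -> pd.DataFrame:
    """Multivariable MR with union instruments, jointly harmonized.

    Instruments are selected per exposure, pooled, and every trait's betas
    are aligned to one shared allele reference before the weighted
    multiple regression.  Returns the conditional effect per exposure.
    """
    names = list(exposure_stats)
    if not isinstance(p_thresholds, dict):
        p_thresholds = {n: float(p_thresholds) for n in names}
    ivs = []
    for n in names:
        sel = select_instruments(exposure_stats[n], p_thresholds[n], ld_r2,
                                 window_kb)
        if not sel.empty:
            ivs.append(sel)
    if not ivs:
        raise ValueError("no instruments for any exposure")
    ref = pd.concat(ivs).drop_duplicates("snp").reset_index(drop=True)

    aligned = {}
    for trait, table in list(exposure_stats.items()) + [("_outcome",
                                                         outcome_stats)]:
        h = harmonize(ref, table)
        aligned[trait] = h.table.set_index("snp")[["beta_out", "se_out"]]
    shared = set(ref["snp"])
    for t in aligned.values():
        shared &= set(t.index)
    shared = sorted(shared)
    if len(shared) < len(names) + 1:
        raise ValueError("too few jointly harmonized instruments")
    X = pd.DataFrame({n: aligned[n].loc[shared, "beta_out"] for n in names})
    y = aligned["_outcome"].loc[shared, "beta_out"].to_numpy()
    sy = aligned["_outcome"].loc[shared, "se_out"].to_numpy()
    return mvmr_ivw(X, y, sy)


def estimates_table(estimates: list[MrEstimate], exposure: str,
                    outcome: str) -> pd.DataFrame:
    rows = []
    for e in estimates:
        d = e.as_dict()
        d.update(exposure=exposure, outcome=outcome)
        rows.append(d)
    return pd.DataFrame(rows)
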