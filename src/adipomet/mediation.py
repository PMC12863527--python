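"""Clustered parallel mediation with bootstrap confidence intervals.

Candidate mediators (intermediate metabolites) are first grouped by
hierarchical clustering — parallel mediation software conventionally caps
the number of mediators around ten — and the first principal component of
each cluster enters the model as that cluster's mediator.  The
decomposition is PROCESS-style product-of-coefficients:

    a_k : cluster-score-on-exposure regression coefficient
    b_k : cluster coefficient in the outcome model containing the
          exposure, all cluster scores and covariates
    IE_k = a_k * b_k,  TIE = sum_k IE_k,  DE = exposure coefficient
    proportion mediated = TIE / (DE + TIE)

Confidence intervals are percentile bootstrap, resampling matched pairs as
units so the design is respected.  On the log-odds scale TIE + DE does not
exactly equal the mediator-free total effect (non-collapsibility); the
discrepancy is reported, never reconciled away.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from adipomet.screening import conditional_logit, pair_differences


@dataclass
class MediatorClusterSet:
    clusters: dict[int, list[str]]
    loadings: dict[int, pd.Series]
    scores: pd.DataFrame  # participants x clusters, unit variance


@dataclass
class MediationDecomposition:
    exposure: str
    de: float
    ie: pd.Series            # per-cluster indirect effects
    tie: float
    proportion_mediated: float
    total_effect: float      # exposure coefficient of the mediator-free model
    collapsibility_gap: float  # (de + tie) - total_effect, reported as-is
    ci: dict = field(default_factory=dict)  # name -> (low, high)
    n_boot: int = 0
    n_discarded: int = 0
    a_paths: pd.Series | None = None
    b_paths: pd.Series | None = None


def _pc1(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """First principal component of standardized columns.

    Sign convention: the member with the largest |loading| gets a positive
    loading, so scores are reproducible across runs.
    """
    Z = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
    _, _, vt = np.linalg.svd(Z, full_matrices=False)
    v = vt[0]
    if v[np.argmax(np.abs(v))] < 0:
        v = -v
    s = Z @ v
    return s / s.std(ddof=1), v


def cluster_mediators(
    metabolites: pd.DataFrame,
    max_clusters: int = 10,
) -> MediatorClusterSet:
    """Hierarchical clustering of the intermediate metabolites.

    Distance 1 - |Pearson r| on log2 concentrations, Ward linkage, tree cut
    to at most ``max_clusters``; per-cluster PC1 scores standardized to
    unit variance.  With fewer metabolites than requested clusters each
    metabolite gets its own singleton cluster.
    """
    names = list(metabolites.columns)
    if len(names) < 2:
        if len(names) == 0:
            raise ValueError("need at least one intermediate metabolite")
        x = metabolites.iloc[:, 0].to_numpy(float)
        x = np.log2(x) if (x > 0).all() else x
        s = (x - x.mean()) / x.std(ddof=1)
        return MediatorClusterSet(
            {1: names},
            {1: pd.Series([1.0], index=names)},
            pd.DataFrame({1: s}, index=metabolites.index),
        )
    X = metabolites.to_numpy(float)
    if (X > 0).all():
        X = np.log2(X)
    corr = np.corrcoef(X, rowvar=False)
    dist = 1.0 - np.abs(corr)
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2, 0.0, None)
    Z = linkage(squareform(dist, checks=False), method="ward")
    k = min(max_clusters, len(names))
    labels = fcluster(Z, t=k, criterion="maxclust")

    clusters, loadings, scores = {}, {}, {}
    for cid in sorted(set(labels)):
        members = [names[i] for i in range(len(names)) if labels[i] == cid]
        clusters[cid] = members
        sub = X[:, [names.index(m) for m in members]]
        if len(members) == 1:
            v = np.array([1.0])
            s = (sub[:, 0] - sub[:, 0].mean()) / sub[:, 0].std(ddof=1)
        else:
            s, v = _pc1(sub)
        loadings[cid] = pd.Series(v, index=members)
        scores[cid] = s
    return MediatorClusterSet(
        clusters, loadings, pd.DataFrame(scores, index=metabolites.index)
    )


def _logit_newton(X: np.ndarray, y: np.ndarray, max_iter: int = 50,
                  tol: float = 1e-9) -> tuple[np.ndarray, bool]:
    """Plain Newton-Raphson logistic fit (intercept must be in X)."""
    beta = np.zeros(X.shape[1])
    ll = -np.inf
    for _ in range(max_iter):
        eta = np.clip(X @ beta, -35, 35)
        mu = 1.0 / (1.0 + np.exp(-eta))
        grad = X.T @ (y - mu)
        W = np.clip(mu * (1 - mu), 1e-10, None)
        H = (X * W[:, None]).T @ X
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            return beta, False
        ll_new = np.sum(y * eta - np.logaddexp(0.0, eta))
        t = 1.0
        cand = beta + step
        for _ in range(25):
            eta_c = np.clip(X @ cand, -35, 35)
            ll_c = np.sum(y * eta_c - np.logaddexp(0.0, eta_c))
            if ll_c >= ll_new - 1e-12 or ll == -np.inf:
                break
            t /= 2
            cand = beta + t * step
        beta = cand
        if np.max(np.abs(grad)) < tol:
            if np.max(np.abs(beta)) > 30:
                return beta, False
            return beta, True
        ll = ll_new
    return beta, False


class _PathData:
    """Precomputed arrays so bootstrap draws avoid any DataFrame work.

    Individual-level rows are ordered by pair (two consecutive rows per
    pair); resampling a pair means taking its two rows, or its single row
    of the difference matrices for the conditional outcome model.
    """

    def __init__(self, df, exposure, score_cols, covariates, outcome_col,
                 outcome_model):
        df = df.sort_values("pair_id", kind="stable").reset_index(drop=True)
        n = len(df)
        self.n_pairs = df["pair_id"].nunique()
        if n != 2 * self.n_pairs:
            raise ValueError("expected exactly two participants per pair")
        self.outcome_model = outcome_model
        self.k = len(score_cols)
        x = df[exposure].to_numpy(float)
        C = (df[covariates].to_numpy(float) if covariates
             else np.empty((n, 0)))
        ones = np.ones(n)
        self.Xa = np.column_stack([ones, x, C])
        self.S = df[score_cols].to_numpy(float)
        self.y = df[outcome_col].to_numpy(float)
        self.Xb = np.column_stack([ones, x, self.S, C])
        self.Xt = np.column_stack([ones, x, C])
        if outcome_model == "conditional":
            vals = df[[exposure] + list(score_cols) + list(covariates)]
            self.D = pair_differences(df, vals).to_numpy(float)
            self.Dt = pair_differences(
                df, df[[exposure] + list(covariates)]).to_numpy(float)

    def fit(self, pair_idx=None):
        """(a, b, DE, total, ok) on the full data or a pair resample."""
        if pair_idx is None:
            rows = slice(None)
            drows = slice(None)
        else:
            rows = np.ravel(np.column_stack([2 * pair_idx, 2 * pair_idx + 1]))
            drows = pair_idx
        a = np.linalg.lstsq(self.Xa[rows], self.S[rows], rcond=None)[0][1]
        if self.outcome_model == "linear":
            bfull = np.linalg.lstsq(self.Xb[rows], self.y[rows],
                                    rcond=None)[0]
            btot = np.linalg.lstsq(self.Xt[rows], self.y[rows], rcond=None)[0]
            ok = True
            de, b, total = bfull[1], bfull[2:2 + self.k], btot[1]
        elif self.outcome_model == "logistic":
            bfull, ok1 = _logit_newton(self.Xb[rows], self.y[rows])
            btot, ok2 = _logit_newton(self.Xt[rows], self.y[rows])
            ok = ok1 and ok2
            de, b, total = bfull[1], bfull[2:2 + self.k], btot[1]
        elif self.outcome_model == "conditional":
            res = conditional_logit(self.D[drows])
            rest = conditional_logit(self.Dt[drows])
            ok = not res.flag and not rest.flag
            de, b, total = res.beta[0], res.beta[1:1 + self.k], rest.beta[0]
        else:
            raise ValueError(
                f"unknown outcome_model {self.outcome_model!r}")
        return a, b, de, total, ok


def parallel_mediation(
    cohort: pd.DataFrame,
    exposure: str,
    clusters: MediatorClusterSet,
    covariates: list[str] | None = None,
    n_boot: int = 5000,
    seed: int | None = None,
    outcome_model: str = "logistic",
    outcome_col: str = "is_case",
) -> MediationDecomposition:
    """Parallel multiple mediation of one adiposity index.

    a-paths by linear regression of each cluster score on the exposure and
    covariates; b-paths and the direct effect from the outcome model with
    all cluster scores entered jointly.  ``outcome_model`` is "logistic"
    (default), "conditional" (matched-pair conditional logistic — exact for
    pair-conditionally generated data) or "linear".  Percentile bootstrap
    over matched pairs gives all CIs; bootstrap draws whose outcome fit
    fails to converge are discarded and counted (a warning is attached to
    the result when more than 5% are lost).
    """
    covariates = list(covariates or [])
    rng = np.random.default_rng(seed)
    score_cols = list(clusters.scores.columns)
    df = cohort.reset_index(drop=True).copy()
    scores = clusters.scores.reset_index(drop=True)
    for c in score_cols:
        df[f"_score_{c}"] = scores[c]
    score_names = [f"_score_{c}" for c in score_cols]

    data = _PathData(df, exposure, score_names, covariates, outcome_col,
                     outcome_model)
    a, b, de, total, ok = data.fit()
    if not ok:
        raise RuntimeError("outcome model failed to converge on the full data")
    ie = a * b
    tie = float(ie.sum())
    pm = tie / (de + tie) if (de + tie) != 0 else np.nan

    boots = {"de": [], "tie": [], "pm": []}
    ie_boot = []
    discarded = 0
    for _ in range(n_boot):
        pair_idx = rng.integers(0, data.n_pairs, data.n_pairs)
        try:
            a_b, b_b, de_b, _tot, okb = data.fit(pair_idx)
        except (np.linalg.LinAlgError, ValueError):
            okb = False
        if not okb:
            discarded += 1
            continue
        ie_b = a_b * b_b
        tie_b = ie_b.sum()
        boots["de"].append(de_b)
        boots["tie"].append(tie_b)
        boots["pm"].append(tie_b / (de_b + tie_b) if (de_b + tie_b) != 0
                           else np.nan)
        ie_boot.append(ie_b)

    ci = {}
    if n_boot > 0 and len(boots["de"]) >= 10:
        for key, vals in boots.items():
            arr = np.asarray(vals, float)
            arr = arr[np.isfinite(arr)]
            ci[key] = tuple(np.percentile(arr, [2.5, 97.5]))
        IE = np.asarray(ie_boot)
        for i, c in enumerate(score_cols):
            ci[f"ie_{c}"] = tuple(np.percentile(IE[:, i], [2.5, 97.5]))

    res = MediationDecomposition(
        exposure=exposure,
        de=float(de),
        ie=pd.Series(ie, index=score_cols, name="ie"),
        tie=tie,
        proportion_mediated=float(pm),
        total_effect=float(total),
        collapsibility_gap=float(de + tie - total),
        ci=ci,
        n_boot=n_boot,
        n_discarded=discarded,
        a_paths=pd.Series(a, index=score_cols, name="a"),
        b_paths=pd.Series(b, index=score_cols, name="b"),
    )
    if n_boot and discarded > 0.05 * n_boot:
        import warnings

        warnings.warn(
            f"{discarded}/{n_boot} bootstrap draws discarded "
            "(non-convergent outcome fits)",
            stacklevel=2,
        )
    return res


def decomposition_table(result: MediationDecomposition,
                        clusters: MediatorClusterSet) -> pd.DataFrame:
    """Tidy per-cluster table plus summary rows (DE, TIE, proportion)."""
    rows = []
    for cid in result.ie.index:
        lo, hi = result.ci.get(f"ie_{cid}", (np.nan, np.nan))
        rows.append(
            {
                "exposure": result.exposure,
                "term": f"cluster_{cid}",
                "members": ";".join(clusters.clusters[cid]),
                "a": result.a_paths[cid],
                "b": result.b_paths[cid],
                "estimate": result.ie[cid],
                "ci_low": lo,
                "ci_high": hi,
            }
        )
    for name, val in [("de", result.de), ("tie", result.tie),
                      ("proportion_mediated", result.proportion_mediated)]:
        lo, hi = result.ci.get(name if name != "proportion_mediated" else "pm",
                               (np.nan, np.nan))
        rows.append(
            {"exposure": result.exposure, "term": name, "members": "",
             "a": np.nan, "b": np.nan, "estimate": val,
             "ci_low": lo, "ci_high": hi}
        )
    return pd.DataFrame(rows)
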