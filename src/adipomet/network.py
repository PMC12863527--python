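"""Metabolite correlation network: partial Spearman, PC skeleton, walktrap.

The correlation analysis is run on controls only (conditioning on case
status — a collider between adiposity and metabolites — would induce
spurious dependence).  The network skeleton comes from the constraint-based
PC algorithm with Fisher-z partial-correlation tests on rank-transformed
data; densely connected modules are then found with the walktrap
random-walk community algorithm.
"""

from __future__ import annotations

from itertools import combinations

import igraph as ig
import numpy as np
import pandas as pd
from scipy import stats


def partial_spearman(
    data: pd.DataFrame,
    adjust_for: pd.DataFrame | None = None,
    min_n: int = 10,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Partial Spearman correlations among all columns of ``data``.

    Each variable is rank-transformed, residualized on the covariates by
    least squares, and the Pearson correlation of the residuals is
    returned together with t-based p-values (df = n - 2 - n_covariates).
    """
    n = len(data)
    if n < min_n:
        raise ValueError(f"need at least {min_n} observations, got {n}")
    X = data.to_numpy(float)
    if np.any(np.ptp(X, axis=0) == 0):
        bad = [c for c, r in zip(data.columns, np.ptp(X, axis=0)) if r == 0]
        raise ValueError(f"constant columns (zero rank variance): {bad}")
    R = np.apply_along_axis(stats.rankdata, 0, X)
    ncov = 0
    if adjust_for is not None and adjust_for.shape[1] > 0:
        Z = np.column_stack(
            [np.ones(n), adjust_for.to_numpy(float)]
        )
        ncov = adjust_for.shape[1]
        R = R - Z @ np.linalg.lstsq(Z, R, rcond=None)[0]
    else:
        R = R - R.mean(axis=0)
    rho = np.corrcoef(R, rowvar=False)
    np.fill_diagonal(rho, 1.0)
    df = n - 2 - ncov
    with np.errstate(divide="ignore", invalid="ignore"):
        t = rho * np.sqrt(df / np.clip(1 - rho**2, 1e-300, None))
    p = 2 * stats.t.sf(np.abs(t), df)
    np.fill_diagonal(p, 0.0)
    cols = data.columns
    return (
        pd.DataFrame(rho, index=cols, columns=cols),
        pd.DataFrame(p, index=cols, columns=cols),
    )


def _fisher_z_test(corr: np.ndarray, i: int, j: int, S: tuple[int, ...],
                   n: int) -> float:
    """p-value of the Fisher-z partial-correlation test of i ⫫ j | S."""
    if not S:
        r = corr[i, j]
    else:
        idx = [i, j] + list(S)
        sub = corr[np.ix_(idx, idx)]
        prec = np.linalg.inv(sub)
        r = -prec[0, 1] / np.sqrt(prec[0, 0] * prec[1, 1])
    r = np.clip(r, -0.999999, 0.999999)
    z = 0.5 * np.log((1 + r) / (1 - r))
    dof = n - len(S) - 3
    if dof <= 0:
        return 1.0
    stat = np.sqrt(dof) * abs(z)
    return 2 * stats.norm.sf(stat)


def pc_skeleton(
    data: pd.DataFrame,
    alpha: float = 0.05,
    max_cond_set: int = 3,
) -> set[tuple[str, str]]:
    """Undirected skeleton of the PC algorithm.

    Starting from the complete graph, the edge (i, j) is removed as soon as
    some conditioning set S of current neighbours with |S| <= max_cond_set
    renders i and j conditionally independent by the Fisher-z test on
    rank-based (Spearman) correlations at level ``alpha``.  Node and subset
    iteration follow a fixed sorted order, so the output is deterministic
    for a given column ordering and invariant to row order.
    """
    n, p = data.shape
    if n <= max_cond_set + 2:
        raise ValueError("too few observations for the conditioning-set cap")
    names = list(data.columns)
    R = np.apply_along_axis(stats.rankdata, 0, data.to_numpy(float))
    corr = np.corrcoef(R, rowvar=False)

    adj = {i: set(range(p)) - {i} for i in range(p)}
    for level in range(max_cond_set + 1):
        removed_any = False
        for i in range(p):
            for j in sorted(adj[i]):
                if j < i:
                    continue
                neighbours = sorted((adj[i] | adj[j]) - {i, j})
                if len(neighbours) < level:
                    continue
                drop = False
                for S in combinations(neighbours, level):
                    try:
                        pval = _fisher_z_test(corr, i, j, S, n)
                    except np.linalg.LinAlgError:
                        continue
                    if pval > alpha:
                        drop = True
                        break
                if drop:
                    adj[i].discard(j)
                    adj[j].discard(i)
                    removed_any = True
        if not removed_any and level > 0:
            break
    return {
        (names[i], names[j]) for i in range(p) for j in adj[i] if i < j
    }


def build_network(
    edges: set[tuple[str, str]],
    rho: pd.DataFrame,
) -> pd.DataFrame:
    """Edge list with |partial rho| weights for the retained skeleton edges."""
    rows = [
        {"node_a": a, "node_b": b, "weight": abs(float(rho.loc[a, b]))}
        for a, b in sorted(edges)
    ]
    return pd.DataFrame(rows, columns=["node_a", "node_b", "weight"])


def walktrap_modules(
    edges: pd.DataFrame,
    nodes: list[str] | None = None,
    steps: int = 4,
) -> tuple[pd.Series, pd.Series]:
    """Walktrap community detection plus degree centrality.

    Agglomerative merging driven by random-walk distances of the given step
    length; the dendrogram is cut at maximum modularity.  Isolated nodes
    (no retained edge) each form their own module.
    """
    if nodes is None:
        nodes = sorted(set(edges["node_a"]) | set(edges["node_b"]))
    if len(nodes) == 0:
        raise ValueError("empty graph")
    g = ig.Graph()
    g.add_vertices(nodes)
    if len(edges):
        g.add_edges(list(zip(edges["node_a"], edges["node_b"])))
        g.es["weight"] = [float(w) for w in edges["weight"]]
        dendro = g.community_walktrap(weights="weight", steps=steps)
        membership = dendro.as_clustering().membership
    else:
        membership = list(range(len(nodes)))
    modules = pd.Series(membership, index=nodes, name="module")
    degree = pd.Series(g.degree(), index=nodes, name="degree")
    return modules, degree
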