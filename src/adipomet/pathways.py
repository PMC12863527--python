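"""Qualitative pathway over-representation and topology impact.

Pathway libraries are plain files supplied by the user — GMT for
membership (the KEGG / SMPDB sets the analysis was designed around) and an
optional edge-list TSV per pathway for topology.  Enrichment is the
upper-tail hypergeometric test; the topology impact of a hit list is the
sum of relative betweenness centralities of the hit nodes within the
pathway graph.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from adipomet.screening import bh_fdr


@dataclass
class PathwayLibrary:
    """Named metabolite sets with optional per-pathway topology graphs."""

    pathways: dict[str, set[str]]
    topology: dict[str, list[tuple[str, str]]] = field(default_factory=dict)

    def __post_init__(self):
        for name, members in self.pathways.items():
            if not members:
                raise ValueError(f"pathway {name!r} has no members")
        for name, edges in self.topology.items():
            members = self.pathways.get(name, set())
            for a, b in edges:
                if a not in members or b not in members:
                    raise ValueError(
                        f"topology edge ({a}, {b}) of {name!r} references "
                        "a non-member"
                    )


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """Read a GMT file (name <tab> description <tab> member...)."""
    pathways = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"malformed GMT line: {line[:80]!r}")
        pathways[parts[0]] = set(parts[2:])
    return pathways


def read_topology(path: str | Path) -> list[tuple[str, str]]:
    """Read an edge-list TSV (two columns, optional header)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    if list(df.iloc[0]) == ["node_a", "node_b"]:
        df = df.iloc[1:]
    return [tuple(r) for r in df.iloc[:, :2].itertuples(index=False)]


def ora_hypergeometric(
    hits: set[str],
    universe: set[str],
    library: PathwayLibrary,
) -> pd.DataFrame:
    """Hypergeometric over-representation of ``hits`` within ``universe``.

    For each pathway, p = P(X >= overlap) with population |universe|,
    successes |pathway ∩ universe|, draws |hits|.  Pathways are first
    intersected with the universe (the measured metabolite panel).  An
    FDR column across pathways is added; the impact column is filled by
    :func:`topology_impact` where topology is available, else left NaN.
    """
    if not universe:
        raise ValueError("empty universe")
    stray = hits - universe
    if stray:
        raise ValueError(f"hits not in universe: {sorted(stray)[:5]}")
    M, N = len(universe), len(hits)
    rows = []
    for name, members in library.pathways.items():
        inset = members & universe
        if not inset:
            continue
        K = len(inset)
        k = len(inset & hits)
        p = float(stats.hypergeom.sf(k - 1, M, K, N))
        impact = np.nan
        if name in library.topology:
            impact = topology_impact(hits, library.topology[name])
        rows.append(
            {"pathway": name, "size": K, "overlap": k,
             "p_enrich": p, "impact": impact}
        )
    res = pd.DataFrame(rows, columns=["pathway", "size", "overlap",
                                      "p_enrich", "impact"])
    if len(res):
        res["q_fdr"] = bh_fdr(res["p_enrich"].to_numpy())
        res = res.sort_values("p_enrich", kind="stable").reset_index(drop=True)
    return res


def relative_betweenness(edges: list[tuple[str, str]]) -> pd.Series:
    """Betweenness centrality normalized to sum to 1 over pathway nodes.

    In a graph where every node is a leaf or the graph is a single edge the
    raw centralities are all zero; the mass is then spread uniformly so the
    impact of hitting every node is still 1.
    """
    g = nx.Graph()
    g.add_edges_from(edges)
    bc = nx.betweenness_centrality(g, normalized=False)
    total = sum(bc.values())
    n = g.number_of_nodes()
    if total == 0:
        return pd.Series({v: 1.0 / n for v in g.nodes})
    return pd.Series({v: bc[v] / total for v in g.nodes})


def topology_impact(hits: set[str], edges: list[tuple[str, str]]) -> float:
    """Sum of relative betweenness centralities over the hit nodes."""
    if not edges:
        raise ValueError("missing topology")
    importance = relative_betweenness(edges)
    return float(importance.reindex(sorted(hits)).fillna(0.0).sum())
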