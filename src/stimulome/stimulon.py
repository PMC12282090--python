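"""Stimulon detection from iModulon activity correlations.

A stimulon is a set of iModulons whose activities co-vary across
samples — a coordinated transcriptional response to a shared stimulus.
Operationally: compute pairwise Spearman correlations of activity
levels over the selected components, keep pairs with |ρ| at or above a
threshold (default 0.7) and p below a cutoff (default 0.05), and take
connected components of the resulting graph as stimulon clusters.
Negative correlations qualify as edges just like positive ones: an
anti-correlated pair is part of the same coordinated trade-off (e.g. a
chemical-stress programme suppressing the general stress response).

Clusters are named after the iModulon with the largest member gene set
(ties broken by degree, then lexicographic id).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from itertools import permutations

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .ica import ActivityMatrix

DEFAULT_RHO_THRESHOLD = 0.7
DEFAULT_P_CUTOFF = 0.05
EXACT_P_MAX_N = 9  # exact permutation null below 10 samples


@lru_cache(maxsize=None)
def _exact_rho_null(n: int) -> np.ndarray:
    """All n! Spearman ρ values against a fixed ranking (no ties)."""
    ident = np.arange(n)
    perms = np.array(list(permutations(range(n))))
    d2 = ((perms - ident) ** 2).sum(axis=1)
    return 1.0 - 6.0 * d2 / (n * (n**2 - 1))


def _spearman_pair(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    n = len(x)
    rho, p_t = stats.spearmanr(x, y)
    if np.isnan(rho):
        return np.nan, np.nan
    has_ties = (len(np.unique(x)) < n) or (len(np.unique(y)) < n)
    if n <= EXACT_P_MAX_N and not has_ties:
        null = _exact_rho_null(n)
        p = float(np.mean(np.abs(null) >= abs(rho) - 1e-12))
        return float(rho), p
    return float(rho), float(p_t)


def activity_spearman(
    A: ActivityMatrix,
    components=None,
    samples=None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise signed Spearman ρ and two-sided p over activity rows.

    p-values use the t-approximation for n ≥ 10 and the exact
    permutation null for smaller n (without ties). A constant activity
    vector has undefined correlation: its pairs are recorded as NaN and
    later excluded from the graph.
    """
    comps = list(components) if components is not None else A.component_names
    cols = list(samples) if samples is not None else A.sample_ids
    if len(cols) < 5:
        raise ValueError("need at least 5 samples for rank correlations")
    missing = set(comps) - set(A.component_names)
    if missing:
        raise ValueError(f"components not in activity matrix: {sorted(missing)}")
    data = A.values.loc[comps, cols].to_numpy()
    k = len(comps)
    rho = np.eye(k)
    pvals = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            r, p = _spearman_pair(data[i], data[j])
            rho[i, j] = rho[j, i] = r
            pvals[i, j] = pvals[j, i] = p
    for i in range(k):
        if np.std(data[i]) == 0:
            rho[i, :] = rho[:, i] = np.nan
            rho[i, i] = np.nan
    return (
        pd.DataFrame(rho, index=comps, columns=comps),
        pd.DataFrame(pvals, index=comps, columns=comps),
    )


@dataclass
class StimulonGraph:
    """Thresholded activity-correlation graph and its clusters.

    ``graph`` is an undirected networkx graph whose edges carry signed
    ``rho`` and ``p``; ``clusters`` are its connected components with at
    least two nodes; ``names`` maps each cluster index to the id of its
    representative iModulon; ``opposition_edges`` lists the qualifying
    negative-correlation edges (the trade-off axes inside stimulons).
    """

    graph: nx.Graph
    clusters: list[frozenset]
    names: dict
    opposition_edges: list[tuple]

    def cluster_of(self, node) -> int | None:
        for i, members in enumerate(self.clusters):
            if node in members:
                return i
        return None

    def edge_table(self) -> pd.DataFrame:
        rows = [
            {"node_i": i, "node_j": j, "rho": d["rho"], "p": d["p"]}
            for i, j, d in sorted(self.graph.edges(data=True))
        ]
        return pd.DataFrame(rows, columns=["node_i", "node_j", "rho", "p"])

    def to_files(self, edges_path, clusters_path) -> None:
        import json

        self.edge_table().to_csv(edges_path, sep="\t", index=False, float_format="%.10g")
        payload = {
            "clusters": [
                {"name": self.names[i], "members": sorted(members)}
                for i, members in enumerate(self.clusters)
            ],
            "opposition_edges": [
                [i, j, round(r, 10), round(p, 10)]
                for i, j, r, p in self.opposition_edges
            ],
        }
        with open(clusters_path, "w") as fh:
            json.dump(payload, fh, sort_keys=True, indent=1)


def build_stimulon_graph(
    corr: pd.DataFrame,
    p: pd.DataFrame,
    member_sizes: dict | pd.Series | None = None,
    rho_threshold: float = DEFAULT_RHO_THRESHOLD,
    p_cutoff: float = DEFAULT_P_CUTOFF,
    method: str = "components",
) -> StimulonGraph:
    """Threshold a correlation matrix into a stimulon graph.

    An edge joins i and j iff |ρ_ij| ≥ rho_threshold and p_ij < p_cutoff
    (NaN correlations never qualify). Clusters are connected components
    with ≥ 2 nodes (``method="components"``, the default) or average-
    linkage hierarchical clusters of the 1 − |ρ| distance cut at
    1 − rho_threshold (``method="hierarchy"``). Each cluster is named
    after its node with the largest member set, ties broken by degree
    then lexicographic id.
    """
    if not corr.index.equals(corr.columns):
        raise ValueError("correlation matrix must be square with matching labels")
    nodes = list(corr.index)
    sizes = {n: 0 for n in nodes}
    if member_sizes is not None:
        sizes.update(dict(member_sizes))
    G = nx.Graph()
    G.add_nodes_from((n, {"member_size": sizes[n]}) for n in nodes)
    for a in range(len(nodes)):
        for b in range(a + 1, len(nodes)):
            r = corr.iloc[a, b]
            pv = p.iloc[a, b]
            if np.isnan(r) or np.isnan(pv):
                continue
            if abs(r) >= rho_threshold and pv < p_cutoff:
                G.add_edge(nodes[a], nodes[b], rho=float(r), p=float(pv))

    if method == "components":
        raw_clusters = [c for c in nx.connected_components(G) if len(c) >= 2]
    elif method == "hierarchy":
        raw_clusters = _hierarchical_clusters(corr, rho_threshold)
    else:
        raise ValueError(f"unknown clustering method {method!r}")
    clusters = sorted((frozenset(c) for c in raw_clusters), key=lambda c: sorted(c))

    names = {}
    for i, members in enumerate(clusters):
        rep = sorted(
            members,
            key=lambda n: (-sizes[n], -G.degree(n), n),
        )[0]
        names[i] = rep
    opposition = [
        (i, j, d["rho"], d["p"])
        for i, j, d in sorted(G.edges(data=True))
        if d["rho"] < 0
    ]
    return StimulonGraph(graph=G, clusters=clusters, names=names, opposition_edges=opposition)


def _hierarchical_clusters(corr: pd.DataFrame, rho_threshold: float) -> list[set]:
    dist = 1.0 - corr.abs().to_numpy()
    np.fill_diagonal(dist, 0.0)
    dist = np.nan_to_num(dist, nan=1.0)
    Z = linkage(squareform(dist, checks=False), method="average")
    labels = fcluster(Z, t=1.0 - rho_threshold, criterion="distance")
    out = {}
    for node, lab in zip(corr.index, labels):
        out.setdefault(lab, set()).add(node)
    return [c for c in out.values() if len(c) >= 2]


def sum_suffixed(A: ActivityMatrix, base_names: list[str]) -> ActivityMatrix:
    """Merge suffixed components (``name-1``, ``name-2`` …) by summing
    their activity rows into one row named ``name*``.

    Mirrors the reporting convention in which, e.g., Crp* is the sum of
    Crp-1 and Crp-2 activities.
    """
    values = A.values.copy()
    for base in base_names:
        matches = [n for n in values.index if str(n).startswith(f"{base}-")]
        if not matches:
            raise ValueError(f"no components match base name {base!r}")
        merged = values.loc[matches].sum(axis=0)
        merged.name = f"{base}*"
        values = values.drop(index=matches)
        values = pd.concat([values, merged.to_frame().T])
    return ActivityMatrix(values)
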