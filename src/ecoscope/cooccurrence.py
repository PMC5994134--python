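"""Spearman co-occurrence networks with random-matrix-theory threshold selection.

The correlation threshold is chosen where the nearest-neighbour spacing
distribution (NNSD) of the unfolded eigenvalues of the thresholded
correlation matrix transitions from the Gaussian orthogonal ensemble law
(Wigner surmise, correlated noise) to the Poisson law (uncorrelated,
signal-only) — spectra dominated by random correlations show level
repulsion, while genuinely modular correlation structure decouples into
independent blocks whose superposed spectra have exponential spacings.
Edges additionally honour the rho > 0.6, P < 0.01 reliability filter.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import interpolate, stats

from .tables_io import AbundanceTable, TaxonomyMap

__all__ = [
    "CorrelationResult",
    "spearman_matrix",
    "RmtScan",
    "rmt_threshold",
    "nnsd_distances",
    "unfold_spectrum",
    "CooccurrenceNetwork",
    "build_network",
    "topology_metrics",
    "detect_modules",
    "lineage_edge_summary",
]


@dataclass(frozen=True)
class CorrelationResult:
    taxa: tuple
    rho: np.ndarray
    p: np.ndarray
    constant_taxa: tuple = ()

    def to_frames(self):
        idx = list(self.taxa)
        return (
            pd.DataFrame(self.rho, index=idx, columns=idx),
            pd.DataFrame(self.p, index=idx, columns=idx),
        )


def spearman_matrix(table: AbundanceTable, min_sequences_per_taxon: int = 5) -> CorrelationResult:
    """All-pairs Spearman correlations over libraries, with mid-rank ties.

    Taxa whose total count is not strictly greater than
    ``min_sequences_per_taxon`` are dropped first.  Correlations use every
    retained library, zeros included — joint absence is part of the
    co-occurrence signal.  p-values come from the two-sided large-sample t
    approximation.  Constant taxa give undefined (NaN) correlations and are
    flagged.
    """
    if len(table.libraries) < 4:
        raise ValueError("need at least 4 libraries for rank correlations")
    totals = table.data.sum(axis=0)
    keep = totals > min_sequences_per_taxon
    data = table.data.loc[:, keep]
    n = len(data)
    ranks = data.rank(axis=0, method="average").to_numpy()
    sd = ranks.std(axis=0)
    constant = tuple(data.columns[sd == 0])
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = np.atleast_2d(np.corrcoef(ranks, rowvar=False))
        rho = np.clip(rho, -1.0, 1.0)
        rho[sd == 0, :] = np.nan
        rho[:, sd == 0] = np.nan
        np.fill_diagonal(rho, 1.0)
        t = rho * np.sqrt(np.maximum(n - 2, 1) / np.maximum(1.0 - rho ** 2, 1e-300))
        p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    np.fill_diagonal(p, 0.0)
    p[np.isnan(rho)] = np.nan
    return CorrelationResult(tuple(data.columns), rho, p, constant)


def unfold_spectrum(eigenvalues: np.ndarray, degree: int = 3, dedup_tol: float = 1e-8):
    """Map eigenvalues to unit mean spacing via a smoothed cumulative density.

    A cubic smoothing spline (degree configurable) of the empirical
    cumulative eigenvalue count is evaluated at each (deduplicated)
    eigenvalue; successive differences of the smoothed counts are the
    unfolded spacings.  Near-degenerate eigenvalues (within ``dedup_tol``)
    collapse to one level first, as is customary before unfolding.
    """
    eigs = np.sort(np.asarray(eigenvalues, dtype=float))
    keep = np.concatenate([[True], np.diff(eigs) > dedup_tol])
    eigs = eigs[keep]
    m = len(eigs)
    if m < max(degree + 2, 5):
        raise ValueError(f"too few distinct eigenvalues ({m}) to unfold")
    counts = np.arange(1, m + 1, dtype=float)
    spline = interpolate.UnivariateSpline(eigs, counts, k=degree)
    unfolded = spline(eigs)
    spacings = np.diff(unfolded)
    spacings = spacings[spacings > 0]
    if spacings.size == 0:
        raise ValueError("unfolding produced no positive spacings")
    return spacings / spacings.mean()


def _chi2_distance(spacings: np.ndarray, cdf, bins: int, s_max: float = 3.0) -> float:
    """Chi-square goodness-of-fit distance of spacings to a law given by its CDF.

    ``bins`` equal-width bins on [0, s_max] plus an overflow bin.
    """
    edges = np.linspace(0.0, s_max, bins + 1)
    observed, _ = np.histogram(spacings, bins=edges)
    observed = np.append(observed, np.sum(spacings >= s_max))
    cum = cdf(edges)
    expected = np.diff(np.append(cum, 1.0)) * len(spacings)
    mask = expected > 1e-12
    return float(np.sum((observed[mask] - expected[mask]) ** 2 / expected[mask]))


def _poisson_cdf(s):
    return 1.0 - np.exp(-np.asarray(s, dtype=float))


def _goe_cdf(s):
    s = np.asarray(s, dtype=float)
    return 1.0 - np.exp(-np.pi * s ** 2 / 4.0)


def nnsd_distances(spacings: np.ndarray, bins: int = 50):
    """(distance to Poisson e^-s, distance to GOE Wigner surmise) of an NNSD."""
    return (
        _chi2_distance(spacings, _poisson_cdf, bins),
        _chi2_distance(spacings, _goe_cdf, bins),
    )


@dataclass(frozen=True)
class RmtScan:
    thresholds: tuple
    poisson_distance: dict
    goe_distance: dict
    skipped: tuple
    selected: float


def rmt_threshold(
    corr: CorrelationResult,
    grid=None,
    bins: int = 50,
    degree: int = 3,
    min_taxa: int = 30,
) -> RmtScan:
    """Scan candidate thresholds for the GOE-to-Poisson NNSD transition.

    At each threshold t the correlation matrix keeps entries with |rho| >= t
    (diagonal intact), isolated rows are dropped, and the NNSD of the
    unfolded spectrum is scored against both laws.  The selected threshold
    is the smallest t at which the Poisson law fits better than the GOE law
    and continues to do so at every larger evaluable t.  Thresholds whose
    spectra are too small (< 2 * bins eigenvalues) are skipped with a
    warning.
    """
    if grid is None:
        grid = np.round(np.arange(0.30, 0.951, 0.01), 2)
    grid = np.sort(np.asarray(grid, dtype=float))
    rho = np.nan_to_num(corr.rho, nan=0.0)
    n0 = _non_isolated_count(rho, grid[0])
    if n0 < min_taxa:
        raise ValueError(
            f"only {n0} non-isolated taxa at threshold {grid[0]}; need >= {min_taxa}"
        )
    pois, goe, skipped = {}, {}, []
    for t in grid:
        A = np.where(np.abs(rho) >= t, rho, 0.0)
        np.fill_diagonal(A, 1.0)
        connected = np.abs(A - np.eye(len(A))).sum(axis=0) > 0
        A = A[np.ix_(connected, connected)]
        if A.shape[0] < 2 * bins:
            skipped.append(float(t))
            continue
        eigs = np.linalg.eigvalsh(A)
        try:
            spacings = unfold_spectrum(eigs, degree=degree)
        except ValueError:
            skipped.append(float(t))
            continue
        d_p, d_g = nnsd_distances(spacings, bins=bins)
        pois[float(t)], goe[float(t)] = d_p, d_g
    if skipped:
        warnings.warn(f"skipped {len(skipped)} thresholds with too-small spectra")
    if not pois:
        raise ValueError("no threshold produced an evaluable spectrum")
    evaluable = sorted(pois)
    selected = None
    for i, t in enumerate(evaluable):
        if all(pois[u] < goe[u] for u in evaluable[i:]):
            selected = t
            break
    if selected is None:
        raise ValueError("no GOE-to-Poisson transition found on the grid")
    return RmtScan(tuple(evaluable), pois, goe, tuple(skipped), selected)


def _non_isolated_count(rho: np.ndarray, t: float) -> int:
    A = np.abs(np.where(np.abs(rho) >= t, rho, 0.0))
    np.fill_diagonal(A, 0.0)
    return int(np.sum(A.sum(axis=0) > 0))


@dataclass
class CooccurrenceNetwork:
    graph: nx.Graph
    rho_min: float
    p_max: float

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def summary(self) -> str:
        return f"{self.n_nodes} nodes and {self.n_edges} edges"


def build_network(
    corr: CorrelationResult,
    rho_min: float = 0.6,
    p_max: float = 0.01,
    rmt_min: float | None = None,
    taxonomy: TaxonomyMap | None = None,
) -> CooccurrenceNetwork:
    """Edges where rho > max(rho_min, rmt_min) and p < p_max; isolated nodes dropped.

    An RMT-selected threshold supersedes ``rho_min`` when it is higher.
    Node ``lineage`` attributes are attached when a taxonomy is given.
    Returns a valid empty network (with a warning) if nothing passes.
    """
    threshold = max(rho_min, rmt_min) if rmt_min is not None else rho_min
    g = nx.Graph()
    n = len(corr.taxa)
    for i in range(n):
        for j in range(i + 1, n):
            r, p = corr.rho[i, j], corr.p[i, j]
            if np.isnan(r) or np.isnan(p):
                continue
            if r > threshold and p < p_max:
                g.add_edge(corr.taxa[i], corr.taxa[j], rho=float(r))
    if taxonomy is not None:
        for node in g.nodes:
            try:
                g.nodes[node]["lineage"] = taxonomy.lineage_of(node)
            except Exception:
                g.nodes[node]["lineage"] = "other"
    if g.number_of_nodes() == 0:
        warnings.warn("co-occurrence filter produced an empty network")
    return CooccurrenceNetwork(graph=g, rho_min=threshold, p_max=p_max)


def topology_metrics(net: CooccurrenceNetwork, node_connectivity: bool = True) -> dict:
    """Per-node and global topology indices on the unweighted graph.

    Closeness is reported twice: ``mean_shortest_path`` (the mean shortest
    path from the node to every other reachable node, a farness — the
    convention used when node size encodes "closeness") and the standard
    reciprocal ``closeness``.  Path statistics are per connected component;
    the global values are node-weighted means over components.
    """
    g = net.graph
    if g.number_of_nodes() == 0:
        raise ValueError("empty network has no topology")
    degree = dict(g.degree())
    betweenness = nx.betweenness_centrality(g, normalized=True)
    closeness = nx.closeness_centrality(g)
    farness = {}
    for node in g.nodes:
        lengths = nx.single_source_shortest_path_length(g, node)
        reachable = len(lengths) - 1
        farness[node] = (sum(lengths.values()) / reachable) if reachable else np.inf

    components = [g.subgraph(c) for c in nx.connected_components(g)]
    apl_parts, diam_parts, weights = [], [], []
    for comp in components:
        if comp.number_of_nodes() > 1:
            apl_parts.append(nx.average_shortest_path_length(comp))
            diam_parts.append(nx.diameter(comp))
            weights.append(comp.number_of_nodes())
    apl = float(np.average(apl_parts, weights=weights)) if apl_parts else 0.0
    degrees = np.array(sorted(degree.values()))
    hist = np.bincount(degrees) if len(degrees) else np.array([])
    global_indices = {
        "n_nodes": g.number_of_nodes(),
        "n_edges": g.number_of_edges(),
        "average_path_length": apl,
        "diameter": int(max(diam_parts)) if diam_parts else 0,
        "clustering_coefficient": float(nx.average_clustering(g)),
        "degree_distribution": {int(k): int(c) for k, c in enumerate(hist) if c},
        "n_components": len(components),
    }
    if node_connectivity:
        global_indices["average_node_connectivity"] = float(nx.average_node_connectivity(g))
    return {
        "degree": degree,
        "betweenness": betweenness,
        "closeness": closeness,
        "mean_shortest_path": farness,
        "global": global_indices,
    }


def detect_modules(net: CooccurrenceNetwork, seed: int = 0):
    """Greedy modularity maximisation; returns (node -> module id, Q).

    The agglomeration is deterministic; the seed argument is kept for
    interface stability and future tie-break randomisation.
    """
    g = net.graph
    if g.number_of_nodes() == 0:
        raise ValueError("empty network has no modules")
    communities = list(nx.algorithms.community.greedy_modularity_communities(g))
    communities.sort(key=lambda c: (-len(c), min(str(x) for x in c)))
    membership = {node: i for i, comm in enumerate(communities) for node in comm}
    q = nx.algorithms.community.modularity(g, communities)
    nx.set_node_attributes(g, membership, "module")
    return membership, float(q)


def lineage_edge_summary(net: CooccurrenceNetwork, taxonomy: TaxonomyMap) -> pd.DataFrame:
    """Node and edge shares per lineage (an edge counts for both endpoint lineages).

    Unmapped nodes fall into "other" with a warning.  Shares are percent of
    all nodes/edges, so edge shares across lineages may exceed 100 in total.
    """
    g = net.graph
    if g.number_of_nodes() == 0:
        return pd.DataFrame(columns=["n_nodes", "node_pct", "n_edges", "edge_pct"])
    lineage = {}
    unmapped = 0
    for node in g.nodes:
        try:
            lineage[node] = taxonomy.lineage_of(node)
        except Exception:
            lineage[node] = "other"
            unmapped += 1
    if unmapped:
        warnings.warn(f"{unmapped} network nodes missing from taxonomy; counted as 'other'")
    total_nodes, total_edges = g.number_of_nodes(), g.number_of_edges()
    rows = {}
    for lin in sorted(set(lineage.values())):
        members = {n for n in g.nodes if lineage[n] == lin}
        n_edges = sum(1 for u, v in g.edges if u in members or v in members)
        rows[lin] = {
            "n_nodes": len(members),
            "node_pct": 100.0 * len(members) / total_nodes,
            "n_edges": n_edges,
            "edge_pct": 100.0 * n_edges / total_edges if total_edges else 0.0,
        }
    return pd.DataFrame(rows).T.astype(
        {"n_nodes": int, "n_edges": int}
    )
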