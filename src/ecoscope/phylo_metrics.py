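"""Phylogeny-aware diversity and structure statistics.

Faith's PD (rooted convention: the minimal spanning subtree includes the
path to the root), phylogenetic species variability (PSV) with two
community-matrix null models, unweighted UniFrac, and the two-tree
monophyly rule used to designate subgroups.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .tables_io import FormatError, Phylogeny

__all__ = [
    "faith_pd",
    "mean_pd_subsampled",
    "psv",
    "psv_null",
    "PsvResult",
    "shared_branch_matrix",
    "unweighted_unifrac",
    "propose_subgroups",
    "SubgroupAssignment",
    "subgroup_coverage",
]


def _tip_index(tree: Phylogeny) -> dict:
    return {leaf.taxon.label: leaf for leaf in tree.leaf_node_iter()}


def _require_tips(tips, present) -> None:
    unknown = [t for t in present if t not in tips]
    if unknown:
        raise FormatError(f"unknown tip(s): {unknown[:5]}")


def faith_pd(tree: Phylogeny, present) -> float:
    """Sum of branch lengths of the minimal rooted subtree spanning ``present``.

    Empty set gives 0; the path from each tip up to the root is included.
    """
    tips = _tip_index(tree)
    present = set(present)
    _require_tips(tips, present)
    if not present:
        return 0.0
    marked = set()
    for label in present:
        node = tips[label]
        while node is not None and node not in marked:
            marked.add(node)
            node = node.parent_node
    # summation in sorted order: identical subsets give bit-identical PD
    # regardless of set iteration order
    return float(
        sum(sorted(n.edge.length or 0.0 for n in marked if n.parent_node is not None))
    )


def mean_pd_subsampled(
    tree: Phylogeny,
    communities: dict,
    subsample_size: int,
    iterations: int = 1000,
    seed: int = 0,
):
    """Mean and SD of PD over random fixed-size subsamples per community.

    ``communities`` maps a biotope name to its taxon pool.  Raises if the
    subsample exceeds any pool.
    """
    rng = np.random.default_rng(seed)
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    out = {}
    for biotope, pool in communities.items():
        pool = sorted(set(pool))
        if subsample_size > len(pool):
            raise ValueError(
                f"subsample_size {subsample_size} exceeds richness {len(pool)} of {biotope!r}"
            )
        draws = np.empty(iterations)
        for i in range(iterations):
            sub = rng.choice(pool, size=subsample_size, replace=False)
            draws[i] = faith_pd(tree, sub)
        out[biotope] = (float(draws.mean()), float(draws.std(ddof=0)))
    return out


def shared_branch_matrix(tree: Phylogeny):
    """(labels, V): V[i, j] = branch length shared by the root paths of tips i and j.

    The diagonal holds root-to-tip distances.  This is the phylogenetic
    covariance matrix of a Brownian neutral trait.
    """
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    idx = {l: i for i, l in enumerate(labels)}
    n = len(labels)
    V = np.zeros((n, n))
    depth = {}
    for node in tree.preorder_node_iter():
        parent_depth = depth.get(node.parent_node, 0.0)
        depth[node] = parent_depth + (node.edge.length or 0.0)
    below = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            below[node] = [idx[node.taxon.label]]
            V[below[node][0], below[node][0]] = depth[node]
            continue
        kids = [below[c] for c in node.child_nodes()]
        for a in range(len(kids)):
            for b in range(a + 1, len(kids)):
                for i in kids[a]:
                    V[i, kids[b]] = depth[node]
                    V[np.array(kids[b]), i] = depth[node]
        below[node] = [i for k in kids for i in k]
    return labels, V


def psv(tree: Phylogeny, present) -> float:
    """Phylogenetic species variability of a tip set, in [0, 1].

    PSV = (n tr C - sum C) / (n (n - 1)) on the tip correlation matrix C
    derived from shared branch lengths; 1 on a star phylogeny, 0 when tips
    share their entire root path.  Invariant to uniform branch scaling.
    """
    present = sorted(set(present))
    if len(present) < 2:
        raise ValueError("PSV needs at least 2 tips")
    labels, V = shared_branch_matrix(tree)
    _require_tips(set(labels), present)
    sub = np.array([labels.index(t) for t in present])
    Vs = V[np.ix_(sub, sub)]
    d = np.sqrt(np.diag(Vs))
    if np.any(d == 0):
        raise ValueError("tip with zero root-to-tip distance; correlation undefined")
    C = Vs / np.outer(d, d)
    n = len(present)
    return float((n * np.trace(C) - C.sum()) / (n * (n - 1)))


@dataclass(frozen=True)
class PsvResult:
    observed: dict          # biotope -> observed PSV
    observed_mean: float
    null_means: dict        # model -> array of null mean PSV
    null_quantiles: dict    # model -> (q2.5, q50, q97.5) of the null means
    p_values: dict          # model -> one-sided p (clustering direction)
    iterations: int


def _mean_psv(V: np.ndarray, occ: np.ndarray) -> float:
    """Mean PSV over rows of a binary site x taxon matrix (rows with >= 2 taxa)."""
    d = np.sqrt(np.diag(V))
    C = V / np.outer(d, d)
    vals = []
    for row in occ:
        sub = np.flatnonzero(row)
        n = len(sub)
        if n < 2:
            continue
        Cs = C[np.ix_(sub, sub)]
        vals.append((n * n - Cs.sum()) / (n * (n - 1)))
    if not vals:
        raise ValueError("no site with >= 2 taxa")
    return float(np.mean(vals))


def null_community_matrix(
    occ: np.ndarray, model: int, rng: np.random.Generator
) -> np.ndarray:
    """One randomised binary site x taxon matrix under null model 1 or 2.

    Model 1 shuffles within columns (each taxon's total occurrence is
    preserved); model 2 redraws each site's taxa equiprobably from the pool
    (each site's richness is preserved).
    """
    n_sites, n_taxa = occ.shape
    if model == 1:
        return np.column_stack([rng.permutation(occ[:, j]) for j in range(n_taxa)])
    perm = np.zeros_like(occ)
    for i in range(n_sites):
        k = int(occ[i].sum())
        if k:
            perm[i, rng.choice(n_taxa, size=k, replace=False)] = 1
    return perm


def psv_null(
    tree: Phylogeny,
    occurrence: pd.DataFrame,
    model: int,
    iterations: int = 1000,
    seed: int = 0,
    two_sided: bool = False,
) -> PsvResult:
    """Compare mean PSV across sites to a community-null distribution.

    Null model 1 shuffles each taxon's occurrences across sites (column
    sums preserved); model 2 redraws each site's taxa equiprobably from the
    taxon pool (row richness preserved).  The default p-value is one-sided
    toward phylogenetic clustering: the fraction of null mean PSV values
    <= the observed mean.
    """
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    if model not in (1, 2):
        raise ValueError("model must be 1 or 2")
    rng = np.random.default_rng(seed)
    labels, V = shared_branch_matrix(tree)
    _require_tips(set(labels), occurrence.columns)
    cols = [labels.index(t) for t in occurrence.columns]
    Vs = V[np.ix_(cols, cols)]
    occ = (occurrence.to_numpy() > 0).astype(int)
    n_sites, n_taxa = occ.shape

    observed = {}
    d = np.sqrt(np.diag(Vs))
    C = Vs / np.outer(d, d)
    for site, row in zip(occurrence.index, occ):
        sub = np.flatnonzero(row)
        if len(sub) >= 2:
            n = len(sub)
            Cs = C[np.ix_(sub, sub)]
            observed[site] = float((n * n - Cs.sum()) / (n * (n - 1)))
    obs_mean = float(np.mean(list(observed.values())))

    null_means = np.empty(iterations)
    for it in range(iterations):
        null_means[it] = _mean_psv(Vs, null_community_matrix(occ, model, rng))

    le = float(np.mean(null_means <= obs_mean + 1e-12))
    ge = float(np.mean(null_means >= obs_mean - 1e-12))
    p = min(1.0, 2 * min(le, ge)) if two_sided else le
    return PsvResult(
        observed=observed,
        observed_mean=obs_mean,
        null_means={model: null_means},
        null_quantiles={model: tuple(np.quantile(null_means, [0.025, 0.5, 0.975]))},
        p_values={model: p},
        iterations=iterations,
    )


def unweighted_unifrac(tree: Phylogeny, community_a, community_b) -> float:
    """Fraction of spanned branch length unique to one community, in [0, 1].

    0 means identical tip membership; 1 means the two communities occupy
    mutually exclusive lineages meeting only at the root.
    """
    a, b = set(community_a), set(community_b)
    if not a or not b:
        raise ValueError("both communities must be non-empty")
    tips = _tip_index(tree)
    _require_tips(tips, a | b)
    in_a, in_b = {}, {}
    unique = shared = 0.0
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            la = node.taxon.label
            in_a[node] = la in a
            in_b[node] = la in b
        else:
            in_a[node] = any(in_a[c] for c in node.child_nodes())
            in_b[node] = any(in_b[c] for c in node.child_nodes())
        if node.parent_node is None:
            continue
        length = node.edge.length or 0.0
        if in_a[node] and in_b[node]:
            shared += length
        elif in_a[node] or in_b[node]:
            unique += length
    total = unique + shared
    if total == 0:
        return 0.0
    return float(unique / total)


@dataclass(frozen=True)
class SubgroupAssignment:
    name: str
    members: frozenset
    monophyletic_in_both: bool
    min_identity: float | None = None


def _clades(tree: Phylogeny) -> set:
    all_tips = frozenset(l.taxon.label for l in tree.leaf_node_iter())
    clades = set()
    below = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            below[node] = frozenset([node.taxon.label])
        else:
            below[node] = frozenset().union(*(below[c] for c in node.child_nodes()))
            if below[node] != all_tips:
                clades.add(below[node])
    return clades


def propose_subgroups(
    tree_a: Phylogeny,
    tree_b: Phylogeny,
    min_size: int = 10,
    identity: pd.DataFrame | None = None,
    strict: bool = True,
) -> list[SubgroupAssignment]:
    """Maximal tip sets that are clades in both trees with > ``min_size`` members.

    The designation rule: a subgroup needs more than ``min_size``
    representative sequences monophyletic under both inference approaches
    (``strict=False`` relaxes to >=).  Nested qualifying clades collapse to
    the outermost, so the returned subgroups partition a subset of the tips;
    remaining tips are "ungrouped".  Output order is by decreasing size then
    lexicographic leading member, independent of traversal order.
    """
    tips_a = frozenset(l.taxon.label for l in tree_a.leaf_node_iter())
    tips_b = frozenset(l.taxon.label for l in tree_b.leaf_node_iter())
    if tips_a != tips_b:
        raise FormatError("trees have different tip sets")
    qualifies = (lambda s: len(s) > min_size) if strict else (lambda s: len(s) >= min_size)
    shared = [c for c in _clades(tree_a) & _clades(tree_b) if qualifies(c)]
    maximal = [c for c in shared if not any(c < other for other in shared)]
    maximal.sort(key=lambda c: (-len(c), min(c)))
    out = []
    for i, members in enumerate(maximal):
        min_id = None
        if identity is not None:
            labels = sorted(members)
            sub = identity.loc[labels, labels].to_numpy(dtype=float)
            iu = np.triu_indices(len(labels), k=1)
            min_id = float(sub[iu].min()) if len(labels) > 1 else 100.0
        out.append(
            SubgroupAssignment(
                name=f"SG-{i + 1:02d}",
                members=members,
                monophyletic_in_both=True,
                min_identity=min_id,
            )
        )
    return out


def subgroup_coverage(total_sequence_count: int, ungrouped_count: int) -> float:
    """Percent of sequences covered by designated subgroups, to 1 decimal.

    100 * (total - ungrouped) / total; e.g. 592 ungrouped of 3584 -> 83.5.
    """
    if total_sequence_count <= 0:
        raise ValueError("total sequence count must be positive")
    if ungrouped_count > total_sequence_count or ungrouped_count < 0:
        raise ValueError("ungrouped count outside [0, total]")
    return round(100.0 * (total_sequence_count - ungrouped_count) / total_sequence_count, 1)
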