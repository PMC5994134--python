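"""Indicator-value analysis and multivariate regression trees.

IndVal combines specificity (A: a lineage's mean abundance concentration in
one group) and fidelity (B: how consistently it occurs in that group's
libraries) into IndVal = 100 A B; significance comes from permuting group
labels.  The multivariate regression tree (MRT) recursively partitions
libraries on categorical environmental variables to minimise the within-node
Euclidean sum of squares of the community abundance rows.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from .tables_io import AbundanceTable, SampleMetadata

__all__ = ["IndValResult", "indval", "MrtNode", "mrt", "mrt_leaves", "mrt_total_ss"]


@dataclass(frozen=True)
class IndValResult:
    specificity: pd.DataFrame   # lineages x groups, A (rows sum to 1)
    fidelity: pd.DataFrame      # lineages x groups, B
    indval: pd.DataFrame        # 100 * A * B
    best_group: pd.Series       # group with the max IndVal per lineage
    statistic: pd.Series        # that max IndVal
    p_value: pd.Series          # permutation p for the max IndVal
    permutations: int
    skipped: tuple = ()         # lineages absent everywhere


def indval(
    table: AbundanceTable, grouping, permutations: int = 999, seed: int = 0
) -> IndValResult:
    """Indicator values of every column (lineage) for a site grouping.

    A_g = (group-g mean abundance) / (sum over groups of group means);
    B_g = fraction of group-g libraries where the lineage is present;
    the reported statistic is the maximum IndVal over groups, with
    p = (1 + #{perm >= obs}) / (1 + permutations) from label permutation.
    Invariant to library order and to rescaling all abundances.
    """
    if isinstance(grouping, dict):
        labels = np.array([grouping[l] for l in table.libraries])
    elif isinstance(grouping, pd.Series):
        labels = grouping.loc[list(table.libraries)].to_numpy()
    else:
        labels = np.asarray(list(grouping))
    groups = np.unique(labels)
    if len(groups) < 2:
        raise ValueError("indval needs at least 2 groups")
    X = table.values
    present = X > 0
    skipped = tuple(t for t, any_ in zip(table.taxa, present.any(axis=0)) if not any_)
    masks = [labels == g for g in groups]

    def stats_for(masks_):
        means = np.stack([X[m].mean(axis=0) for m in masks_])          # groups x taxa
        denom = means.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            A = np.where(denom > 0, means / denom, 0.0)
        B = np.stack([present[m].mean(axis=0) for m in masks_])
        return A, B, 100.0 * A * B

    A, B, iv = stats_for(masks)
    stat = iv.max(axis=0)
    rng = np.random.default_rng(seed)
    count = np.zeros(len(table.taxa))
    for _ in range(permutations):
        perm = rng.permutation(labels)
        pmasks = [perm == g for g in groups]
        _, _, piv = stats_for(pmasks)
        count += piv.max(axis=0) >= stat - 1e-12
    p = (1 + count) / (1 + permutations)

    taxa = list(table.taxa)
    gl = list(groups)
    best = pd.Series([gl[i] for i in iv.argmax(axis=0)], index=taxa, name="best_group")
    return IndValResult(
        specificity=pd.DataFrame(A.T, index=taxa, columns=gl),
        fidelity=pd.DataFrame(B.T, index=taxa, columns=gl),
        indval=pd.DataFrame(iv.T, index=taxa, columns=gl),
        best_group=best,
        statistic=pd.Series(stat, index=taxa, name="indval_max"),
        p_value=pd.Series(p, index=taxa, name="p"),
        permutations=permutations,
        skipped=skipped,
    )


@dataclass
class MrtNode:
    libraries: tuple
    ss: float                         # within-node sum of squares
    depth: int
    split_variable: str | None = None
    split_levels: frozenset | None = None   # levels routed to the left child
    ss_reduction: float = 0.0
    left: "MrtNode | None" = None
    right: "MrtNode | None" = None
    leaf_profile: pd.Series | None = None

    @property
    def is_leaf(self) -> bool:
        return self.left is None


def _node_ss(X: np.ndarray) -> float:
    if len(X) == 0:
        return 0.0
    return float(((X - X.mean(axis=0)) ** 2).sum())


def _candidate_splits(values: np.ndarray):
    """Level-vs-rest splits always; all two-subset splits for <= 5 levels."""
    levels = sorted(set(values))
    if len(levels) < 2:
        return
    seen = set()
    for lv in levels:
        seen.add(frozenset([lv]))
        yield frozenset([lv])
    if len(levels) <= 5:
        for r in range(2, len(levels)):
            for combo in combinations(levels, r):
                left = frozenset(combo)
                right = frozenset(levels) - left
                if left in seen or right in seen:
                    continue
                seen.add(left)
                seen.add(right)
                yield left


def mrt(
    table: AbundanceTable,
    env: SampleMetadata | pd.DataFrame,
    variables=None,
    max_depth: int = 3,
    min_leaf: int = 5,
) -> MrtNode:
    """Multivariate regression tree of community rows on environmental categories.

    Each split routes a subset of one variable's levels left; the chosen
    split maximises the reduction in total within-node SS and must reduce
    it strictly.  Recursion stops at ``max_depth``, when a child would fall
    below ``min_leaf`` libraries, or when no split helps.  A constant
    abundance matrix yields a single leaf.
    """
    envdf = env.data if isinstance(env, SampleMetadata) else env
    if variables is None:
        variables = [c for c in envdf.columns]
    missing = [l for l in table.libraries if l not in envdf.index]
    if missing:
        raise ValueError(f"libraries without environmental data: {missing[:5]}")
    if len(table.libraries) < 2 * min_leaf:
        raise ValueError("too few libraries for the requested min_leaf")
    X = table.values
    lib_index = {l: i for i, l in enumerate(table.libraries)}
    profile = table.data

    def build(libs: tuple, depth: int) -> MrtNode:
        rows = np.array([lib_index[l] for l in libs])
        node = MrtNode(libraries=libs, ss=_node_ss(X[rows]), depth=depth)
        if depth >= max_depth or len(libs) < 2 * min_leaf or node.ss <= 1e-12:
            node.leaf_profile = profile.loc[list(libs)].mean(axis=0)
            return node
        best = None
        for var in variables:
            vals = envdf.loc[list(libs), var].to_numpy()
            for left_levels in _candidate_splits(vals):
                mask = np.isin(vals, list(left_levels))
                n_left = int(mask.sum())
                if n_left < min_leaf or len(libs) - n_left < min_leaf:
                    continue
                ss_children = _node_ss(X[rows[mask]]) + _node_ss(X[rows[~mask]])
                reduction = node.ss - ss_children
                key = (reduction, var, tuple(sorted(left_levels)))
                if reduction > 1e-12 and (best is None or key > best[0]):
                    best = (key, left_levels, mask)
        if best is None:
            node.leaf_profile = profile.loc[list(libs)].mean(axis=0)
            return node
        (reduction, var, _), left_levels, mask = best
        node.split_variable = var
        node.split_levels = left_levels
        node.ss_reduction = float(reduction)
        node.left = build(tuple(np.array(libs)[mask]), depth + 1)
        node.right = build(tuple(np.array(libs)[~mask]), depth + 1)
        return node

    return build(tuple(table.libraries), 0)


def mrt_leaves(root: MrtNode) -> list:
    if root.is_leaf:
        return [root]
    return mrt_leaves(root.left) + mrt_leaves(root.right)


def mrt_total_ss(root: MrtNode) -> tuple:
    """(root SS, summed split reductions, summed leaf SS) bookkeeping triple.

    root SS = reductions + leaf SS holds to numerical tolerance.
    """
    reductions = 0.0

    def walk(node: MrtNode):
        nonlocal reductions
        if node.is_leaf:
            return node.ss
        reductions += node.ss_reduction
        return walk(node.left) + walk(node.right)

    leaf_ss = walk(root)
    return root.ss, reductions, leaf_ss
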