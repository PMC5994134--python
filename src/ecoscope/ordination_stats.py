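"""Distance matrices, ordination, permutational variance partitioning,
environment fitting, and rarefaction.

The "PCA based on Bray-Curtis distances" of the source workflow is realised
here as principal coordinates (classical metric scaling) of the Bray-Curtis
dissimilarity matrix: PCA proper is undefined on a distance matrix, and
metric ordination of the dissimilarity is the only internally consistent
reading.  Negative PCoA eigenvalues are reported, never silently dropped,
and are excluded from variance fractions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import squareform, pdist

from .tables_io import AbundanceTable

__all__ = [
    "DistanceMatrix",
    "bray_curtis",
    "PcoaResult",
    "pcoa",
    "PermanovaResult",
    "permanova",
    "fit_env_factor",
    "rarefaction_curve",
]


@dataclass(frozen=True)
class DistanceMatrix:
    ids: tuple
    values: np.ndarray
    undefined_pairs: tuple = ()

    def __post_init__(self):
        m = self.values
        if m.shape != (len(self.ids), len(self.ids)):
            raise ValueError("distance matrix shape does not match ids")
        if not np.allclose(m, m.T, atol=1e-12):
            raise ValueError("distance matrix not symmetric")
        if np.any(np.abs(np.diag(m)) > 1e-12):
            raise ValueError("distance matrix diagonal not zero")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.ids), columns=list(self.ids))

    def reorder(self, ids) -> "DistanceMatrix":
        pos = [self.ids.index(i) for i in ids]
        return DistanceMatrix(tuple(ids), self.values[np.ix_(pos, pos)], self.undefined_pairs)


def bray_curtis(table: AbundanceTable) -> DistanceMatrix:
    """Bray-Curtis dissimilarity d(i,j) = sum|x_i - x_j| / sum(x_i + x_j).

    Pairs of all-zero libraries are undefined (0/0); they are set to 0 and
    flagged in ``undefined_pairs``.
    """
    X = table.values
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        d = squareform(pdist(X, metric="braycurtis"))
    undefined = []
    zero = np.flatnonzero(X.sum(axis=1) == 0)
    for a in range(len(zero)):
        for b in range(a + 1, len(zero)):
            i, j = zero[a], zero[b]
            undefined.append((table.libraries[i], table.libraries[j]))
            d[i, j] = d[j, i] = 0.0
    d = np.nan_to_num(d, nan=0.0)
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(table.libraries, d, tuple(undefined))


@dataclass(frozen=True)
class PcoaResult:
    ids: tuple
    coordinates: np.ndarray       # n x k, axes ordered by eigenvalue
    eigenvalues: np.ndarray       # all n eigenvalues, descending (negatives kept)
    proportion_explained: np.ndarray  # per retained axis, over positive eigenvalues


def pcoa(d: DistanceMatrix, k: int) -> PcoaResult:
    """Classical scaling of a distance matrix: eigen-decompose -J D^2 J / 2."""
    n = len(d.ids)
    if k >= n:
        raise ValueError(f"k must be < number of objects ({n})")
    D2 = d.values ** 2
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ D2 @ J
    vals, vecs = np.linalg.eigh((B + B.T) / 2)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    coords = np.zeros((n, k))
    for axis in range(k):
        if vals[axis] > 0:
            coords[:, axis] = vecs[:, axis] * np.sqrt(vals[axis])
    pos = vals[vals > 0].sum()
    prop = np.where(vals[:k] > 0, vals[:k] / pos, 0.0) if pos > 0 else np.zeros(k)
    return PcoaResult(d.ids, coords, vals, prop)


@dataclass(frozen=True)
class PermanovaResult:
    r_squared: float
    pseudo_f: float
    p_value: float
    permutations: int


def _permanova_ss(d2: np.ndarray, labels: np.ndarray):
    n = len(labels)
    ss_total = d2[np.triu_indices(n, 1)].sum() / n
    ss_within = 0.0
    for g in np.unique(labels):
        idx = np.flatnonzero(labels == g)
        if len(idx) > 1:
            sub = d2[np.ix_(idx, idx)]
            ss_within += sub[np.triu_indices(len(idx), 1)].sum() / len(idx)
    return ss_total, ss_within


def permanova(
    d: DistanceMatrix, grouping, permutations: int = 1000, seed: int = 0
) -> PermanovaResult:
    """Permutational MANOVA on a distance matrix (pseudo-F over label permutations).

    ``grouping`` maps each id to a group label (dict, Series, or aligned
    sequence).  p = (1 + #{F_perm >= F_obs}) / (1 + permutations).
    """
    if isinstance(grouping, dict):
        labels = np.array([grouping[i] for i in d.ids])
    elif isinstance(grouping, pd.Series):
        labels = grouping.loc[list(d.ids)].to_numpy()
    else:
        labels = np.asarray(list(grouping))
    groups = np.unique(labels)
    if len(groups) < 2:
        raise ValueError("permanova needs at least 2 groups")
    n = len(labels)
    n_groups = len(groups)
    d2 = d.values ** 2
    ss_total, ss_within = _permanova_ss(d2, labels)
    ss_between = ss_total - ss_within

    def f_stat(ss_w):
        if ss_w <= 0:
            return np.inf
        return ((ss_total - ss_w) / (n_groups - 1)) / (ss_w / (n - n_groups))

    f_obs = f_stat(ss_within)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(permutations):
        _, ss_w = _permanova_ss(d2, rng.permutation(labels))
        if f_stat(ss_w) >= f_obs:
            count += 1
    p = (1 + count) / (1 + permutations)
    r2 = float(ss_between / ss_total) if ss_total > 0 else 0.0
    return PermanovaResult(r2, float(f_obs), float(p), permutations)


def fit_env_factor(
    coordinates: np.ndarray,
    variable,
    permutations: int = 999,
    seed: int = 0,
):
    """Strength of association between an environmental variable and ordination axes.

    Numeric variables: R^2 of the least-squares projection of the variable
    onto the axis scores.  Categorical factors: 1 - SS_within / SS_total of
    the axis scores about level centroids.  Constant variables return R^2 = 0
    with a warning.  p is estimated by permuting the variable.
    """
    X = np.asarray(coordinates, dtype=float)
    v = np.asarray(variable)
    if len(v) != X.shape[0]:
        raise ValueError("variable must be defined for every sample")
    numeric = np.issubdtype(v.dtype, np.number)

    if numeric and np.ptp(v.astype(float)) == 0 or (not numeric and len(set(v)) == 1):
        warnings.warn("constant variable; R^2 = 0")
        return 0.0, 1.0

    def r2_of(var):
        if numeric:
            y = var.astype(float) - var.astype(float).mean()
            Xc = X - X.mean(axis=0)
            beta, *_ = np.linalg.lstsq(Xc, y, rcond=None)
            sse = ((y - Xc @ beta) ** 2).sum()
            sst = (y ** 2).sum()
            return 1.0 - sse / sst if sst > 0 else 0.0
        ss_total = ((X - X.mean(axis=0)) ** 2).sum()
        ss_within = 0.0
        for level in np.unique(var):
            rows = X[var == level]
            ss_within += ((rows - rows.mean(axis=0)) ** 2).sum()
        return 1.0 - ss_within / ss_total if ss_total > 0 else 0.0

    r2_obs = r2_of(v)
    rng = np.random.default_rng(seed)
    count = sum(r2_of(rng.permutation(v)) >= r2_obs for _ in range(permutations))
    p = (1 + count) / (1 + permutations)
    return float(r2_obs), float(p)


def rarefaction_curve(
    counts, depths, iterations: int = 100, seed: int = 0
) -> dict:
    """Expected unique-taxon count at each subsampling depth (without replacement).

    ``counts`` is one sample's taxon count vector.  Means over seeded
    hypergeometric subsamples; monotone non-decreasing in depth on average.
    """
    counts = np.asarray(counts, dtype=np.int64)
    counts = counts[counts > 0]
    total = int(counts.sum())
    rng = np.random.default_rng(seed)
    out = {}
    for depth in depths:
        if depth > total:
            raise ValueError(f"depth {depth} exceeds sample total {total}")
        if depth == 0:
            out[depth] = 0.0
            continue
        richness = np.empty(iterations)
        for i in range(iterations):
            sub = rng.multivariate_hypergeometric(counts, depth)
            richness[i] = np.count_nonzero(sub)
        out[depth] = float(richness.mean())
    return out
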