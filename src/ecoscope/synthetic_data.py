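"""Synthetic community, tree, and trait generators with known ground truth.

The community generator emulates the statistical structure of a global
archaeal clone-library compilation: 133 libraries spread over seven biotope
classes, a handful of widespread "core" lineages whose counts are
over-dispersed (negative binomial), and many sparsely occurring "satellite"
lineages with Poisson counts.  OTUs are nested inside lineages, a
configurable multiplicative biotope effect links abundances to the
environment, and correlated OTU pairs can be planted for network-recovery
tests.  All generators are pure functions of (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd
from scipy import stats

from .tables_io import (
    AbundanceTable,
    BIOTOPES,
    FormatError,
    Phylogeny,
    SampleMetadata,
    TaxonomyMap,
)

__all__ = [
    "CommunitySimSpec",
    "TraitSimSpec",
    "CommunityTruth",
    "simulate_community",
    "inject_correlated_pairs",
    "simulate_tree",
    "simulate_traits",
    "BIOTOPE_LIBRARY_COUNTS",
    "BIOTOPE_ENVIRONMENT",
]

# Per-biotope library counts of the compiled 133-library dataset.
BIOTOPE_LIBRARY_COUNTS = {
    "Fwc": 30,
    "Fsed": 32,
    "S": 22,
    "Msed": 19,
    "Mwc": 7,
    "Hsal": 11,
    "Hdv": 12,
}

# Environment descriptors implied by each biotope: oxic water columns are
# the oxic classes; sediments, soil, hypersaline lakes and vents are anoxic.
BIOTOPE_ENVIRONMENT = {
    "Fwc": ("oxic", "non-saline", "ambient", "water column"),
    "Fsed": ("anoxic", "non-saline", "ambient", "sediment"),
    "S": ("anoxic", "non-saline", "ambient", "soil"),
    "Msed": ("anoxic", "saline", "ambient", "sediment"),
    "Mwc": ("oxic", "saline", "ambient", "water column"),
    "Hsal": ("anoxic", "hypersaline", "ambient", "water column"),
    "Hdv": ("anoxic", "saline", "hot", "sediment"),
}


@dataclass(frozen=True)
class CommunitySimSpec:
    """Study conditions for the simulated community compilation.

    Defaults reproduce the compiled dataset's shape: 133 libraries with
    biotope proportions 30/32/22/19/7/11/12, six aggregated core lineages
    (negative binomial, aggregation ``core_k``) occupying ~80% of libraries,
    and forty Poisson satellite lineages occupying ~20%.  ``core_mean`` and
    ``satellite_mean`` are expected counts per occupied library at the
    reference depth; ``anoxic_effect`` multiplies core means in anoxic
    libraries (core lineages are anoxic specialists).
    """

    n_libraries: int = 133
    biotope_counts: dict = field(default_factory=lambda: dict(BIOTOPE_LIBRARY_COUNTS))
    n_core_lineages: int = 6
    n_satellite_lineages: int = 40
    core_occupancy: float = 0.8
    satellite_occupancy: float = 0.2
    core_mean: float = 30.0
    core_k: float = 0.5
    satellite_mean: float = 1.0
    depth_range: tuple = (100, 200)
    otus_per_lineage: int = 8
    anoxic_effect: float = 2.0
    seed: int = 0

    def __post_init__(self):
        for p in (self.core_occupancy, self.satellite_occupancy):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"occupancy probability {p} outside [0, 1]")
        if self.n_libraries < 1 or self.otus_per_lineage < 1:
            raise ValueError("counts must be >= 1")
        if self.depth_range[0] <= 0 or self.depth_range[1] < self.depth_range[0]:
            raise ValueError(f"invalid depth range {self.depth_range}")
        if sum(self.biotope_counts.values()) <= 0:
            raise ValueError("biotope proportions must sum to a positive total")


@dataclass(frozen=True)
class TraitSimSpec:
    """Conditions for evolving a binary habitat trait on a simulated tree.

    States follow the conventional coding 1 = oxic, 2 = anoxic; ``q12`` and
    ``q21`` are the CTMC transition rates between them.  ``root_state`` of
    ``None`` draws the root from the stationary distribution.
    """

    n_tips: int = 100
    birth_rate: float = 1.0
    q12: float = 0.5
    q21: float = 0.5
    root_state: int | None = None
    seed: int = 0

    def __post_init__(self):
        if self.q12 < 0 or self.q21 < 0:
            raise ValueError("rates must be non-negative")
        if self.q12 == 0 and self.q21 == 0 and self.root_state is None:
            raise ValueError("with both rates zero a root_state must be given")
        if self.root_state not in (None, 1, 2):
            raise ValueError("root_state must be 1, 2, or None")


@dataclass(frozen=True)
class CommunityTruth:
    """Ground truth record accompanying a simulated community."""

    lineage_class: dict          # lineage -> "core" | "satellite"
    lineage_of_otu: dict         # otu -> lineage
    depth_factor: dict           # library -> relative sequencing effort
    injected_pairs: tuple = ()   # ((otu_a, otu_b), ...) planted correlations


def _zero_truncated(rng: np.random.Generator, dist) -> np.ndarray:
    """Draw from a frozen discrete distribution conditioned on being >= 1.

    Occupancy means detection: where a lineage is occupied its count is at
    least one sequence, so realised occurrence tracks the occupancy
    probability instead of being eroded by chance zeros.
    """
    p0 = dist.cdf(0)
    u = rng.uniform(p0, 1.0)
    return dist.ppf(np.minimum(u, 1.0 - 1e-12)).astype(np.int64)


def _assign_biotopes(spec: CommunitySimSpec, rng: np.random.Generator) -> list[str]:
    total = sum(spec.biotope_counts.values())
    raw = {b: spec.biotope_counts.get(b, 0) * spec.n_libraries / total for b in BIOTOPES}
    counts = {b: int(np.floor(v)) for b, v in raw.items()}
    # largest-remainder rounding to hit n_libraries exactly
    remainder = spec.n_libraries - sum(counts.values())
    order = sorted(BIOTOPES, key=lambda b: raw[b] - counts[b], reverse=True)
    for b in order[:remainder]:
        counts[b] += 1
    biotopes = [b for b in BIOTOPES for _ in range(counts[b])]
    rng.shuffle(biotopes)
    return biotopes


def simulate_community(spec: CommunitySimSpec):
    """Generate (AbundanceTable, SampleMetadata, TaxonomyMap, CommunityTruth).

    Core lineage counts are negative binomial (variance >> mean where
    occupied), satellites Poisson; lineage counts are split across that
    lineage's OTUs with fixed Dirichlet weights.  Deterministic in
    ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_libraries
    biotopes = _assign_biotopes(spec, rng)
    libraries = [f"lib{i + 1:03d}" for i in range(n)]

    meta = pd.DataFrame(
        [(b, *BIOTOPE_ENVIRONMENT[b]) for b in biotopes],
        index=libraries,
        columns=["biotope", "oxic_status", "salinity", "temperature_class", "lifestyle"],
    )
    metadata = SampleMetadata(data=meta)
    anoxic = (meta["oxic_status"] == "anoxic").to_numpy()

    core = [f"core{i + 1:02d}" for i in range(spec.n_core_lineages)]
    sat = [f"sat{i + 1:02d}" for i in range(spec.n_satellite_lineages)]
    lineages = core + sat

    depth_ref = 0.5 * (spec.depth_range[0] + spec.depth_range[1])
    depths = rng.integers(spec.depth_range[0], spec.depth_range[1] + 1, size=n)
    f = depths / depth_ref
    expected_total = (
        spec.n_core_lineages * spec.core_occupancy * spec.core_mean
        + spec.n_satellite_lineages * spec.satellite_occupancy * spec.satellite_mean
    )
    if expected_total * f.min() < 1.0:
        raise ValueError("library depth too small to place any lineage")

    # Core lineages: independent negative-binomial counts per member OTU
    # (expected shares from stable Dirichlet weights), so each lineage is
    # strongly aggregated (variance >> mean) without single-draw library
    # totals collapsing when one lineage draw is extreme.  Satellites:
    # zero-truncated Poisson lineage counts thinned multinomially to OTUs.
    otu_ids, otu_lineage, columns = [], {}, []
    k = spec.core_k
    for j, lin in enumerate(lineages):
        weights = rng.dirichlet(np.ones(spec.otus_per_lineage))
        block = np.zeros((n, spec.otus_per_lineage), dtype=np.int64)
        if lin in core:
            occ = rng.random(n) < spec.core_occupancy
            # alternate cores are strict anoxic specialists; the rest are
            # facultative, so oxic status shifts community composition
            boost = spec.anoxic_effect if j % 2 == 0 else 1.0
            mean = spec.core_mean * f * np.where(anoxic, boost, 1.0)
            for m in range(spec.otus_per_lineage):
                mu = np.maximum(mean * weights[m], 1e-9)
                block[:, m] = np.where(occ, rng.negative_binomial(k, k / (k + mu)), 0)
            empty = occ & (block.sum(axis=1) == 0)
            if empty.any():  # occupied means detected: place one sequence
                block[empty, int(np.argmax(weights))] = 1
        else:
            occ = rng.random(n) < spec.satellite_occupancy
            total = np.where(
                occ, _zero_truncated(rng, stats.poisson(spec.satellite_mean * f)), 0
            )
            for i in np.flatnonzero(total):
                block[i] = rng.multinomial(total[i], weights)
        for m in range(spec.otus_per_lineage):
            otu = f"{lin}_otu{m + 1}"
            otu_ids.append(otu)
            otu_lineage[otu] = lin
            columns.append(block[:, m])

    table = AbundanceTable(
        data=pd.DataFrame(np.column_stack(columns), index=libraries, columns=otu_ids),
        mode="counts",
    )
    taxonomy = TaxonomyMap(
        data=pd.DataFrame(
            {"lineage": [otu_lineage[o] for o in otu_ids], "subgroup": "ungrouped"},
            index=otu_ids,
        )
    )
    truth = CommunityTruth(
        lineage_class={lin: ("core" if lin in core else "satellite") for lin in lineages},
        lineage_of_otu=otu_lineage,
        depth_factor=dict(zip(libraries, f)),
    )
    return table, metadata, taxonomy, truth


def inject_correlated_pairs(
    table: AbundanceTable, pairs, rho_target: float, seed: int
) -> AbundanceTable:
    """Replant each pair's columns from a Gaussian copula so Spearman rho ~= target.

    The latent bivariate normal uses the classical rank-correlation mapping
    r = 2 sin(pi * rho_s / 6); normal scores are pushed through each taxon's
    empirical Poisson marginal (rate = observed column mean).  Unpaired taxa
    are untouched.  ``rho_target`` = 1 degenerates to identical ranks.
    """
    if not 0.0 < rho_target <= 1.0:
        raise ValueError(f"rho_target {rho_target} outside (0, 1]")
    rng = np.random.default_rng(seed)
    data = table.data.copy()
    for a, b in pairs:
        for t in (a, b):
            if t not in data.columns:
                raise FormatError(f"unknown taxon id {t!r} in pair list")
        r = min(1.0, 2.0 * np.sin(np.pi * rho_target / 6.0))
        z1 = rng.standard_normal(len(data))
        z2 = r * z1 + np.sqrt(max(0.0, 1.0 - r * r)) * rng.standard_normal(len(data))
        for t, z in ((a, z1), (b, z2)):
            lam = max(data[t].mean(), 0.5)
            u = stats.norm.cdf(z)
            data[t] = stats.poisson.ppf(u, lam).astype(np.int64)
    return AbundanceTable(data=data, mode=table.mode)


def simulate_tree(n_tips: int, birth_rate: float = 1.0, seed: int = 0) -> Phylogeny:
    """Pure-birth (Yule) rooted ultrametric tree with exponential waiting times."""
    if n_tips < 2:
        raise ValueError("n_tips must be >= 2")
    if birth_rate <= 0:
        raise ValueError("birth_rate must be positive")
    rng = np.random.default_rng(seed)

    taxa = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=taxa)
    tree.is_rooted = True
    birth_time = {tree.seed_node: 0.0}
    active = [tree.seed_node]
    t = 0.0
    while len(active) < n_tips:
        t += rng.exponential(1.0 / (birth_rate * len(active)))
        node = active.pop(rng.integers(len(active)))
        for _ in range(2):
            child = dendropy.Node()
            node.add_child(child)
            birth_time[child] = t
            active.append(child)
    t += rng.exponential(1.0 / (birth_rate * len(active)))  # final hold before present
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            node.edge.length = None
            continue
        end = t if node.is_leaf() else birth_time[node.child_nodes()[0]]
        node.edge.length = end - birth_time[node]
    for i, leaf in enumerate(tree.leaf_node_iter()):
        leaf.taxon = taxa.new_taxon(label=f"t{i + 1}")
    return tree


def transition_matrix(q12: float, q21: float, t: float) -> np.ndarray:
    """Closed-form 2-state CTMC transition matrix over duration ``t``.

    Row/column order is (state 1, state 2).
    """
    q = q12 + q21
    if q == 0:
        return np.eye(2)
    pi1, pi2 = q21 / q, q12 / q
    e = np.exp(-q * t)
    return np.array(
        [[pi1 + pi2 * e, pi2 * (1.0 - e)], [pi1 * (1.0 - e), pi2 + pi1 * e]]
    )


@dataclass(frozen=True)
class TraitSimulation:
    tip_states: dict   # tip label -> 1 | 2
    node_states: dict  # dendropy node -> 1 | 2 (includes internals and root)


def simulate_traits(tree: Phylogeny, spec: TraitSimSpec) -> TraitSimulation:
    """Evolve the binary trait root-to-tips under the 2-state CTMC."""
    rng = np.random.default_rng(spec.seed)
    q = spec.q12 + spec.q21
    if spec.root_state is not None:
        root_state = spec.root_state
    else:
        pi1 = spec.q21 / q
        root_state = 1 if rng.random() < pi1 else 2
    states = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            states[node] = root_state
            continue
        t = node.edge.length or 0.0
        P = transition_matrix(spec.q12, spec.q21, t)
        prev = states[node.parent_node]
        states[node] = 1 if rng.random() < P[prev - 1, 0] else 2
    tips = {leaf.taxon.label: states[leaf] for leaf in tree.leaf_node_iter()}
    return TraitSimulation(tip_states=tips, node_states=states)
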