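"""Readers, writers, and the shared data model.

Everything downstream operates on four objects: a library x taxon
:class:`AbundanceTable`, per-library :class:`SampleMetadata`, a rooted
:class:`Phylogeny` (a :class:`dendropy.Tree`), and a :class:`TaxonomyMap`
assigning each taxon to a lineage and optional subgroup.  Tables travel as
TSV (comma selectable), trees as newick, networks as GraphML.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "FormatError",
    "AbundanceTable",
    "SampleMetadata",
    "TaxonomyMap",
    "Phylogeny",
    "BIOTOPES",
    "OXIC_STATUSES",
    "SALINITIES",
    "LIFESTYLES",
    "read_abundance_table",
    "write_abundance_table",
    "to_relative",
    "read_metadata",
    "write_metadata",
    "read_taxonomy",
    "write_taxonomy",
    "read_newick",
    "write_newick",
    "read_identity_matrix",
    "export_graphml",
    "import_graphml",
]

BIOTOPES = ("Fwc", "Fsed", "S", "Msed", "Mwc", "Hsal", "Hdv")
OXIC_STATUSES = ("oxic", "anoxic")
SALINITIES = ("non-saline", "saline", "hypersaline")
LIFESTYLES = ("water column", "soil", "sediment")

_REL_TOL = 1e-9


class FormatError(ValueError):
    """Raised when an external file or an in-memory table violates the format contract."""


def _check_ids(ids, what: str) -> tuple[str, ...]:
    ids = tuple(str(i) for i in ids)
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if list(ids).count(i) > 1})
        raise FormatError(f"duplicate {what} identifiers: {dupes[:5]}")
    for i in ids:
        if i == "" or any(c.isspace() for c in i):
            raise FormatError(f"{what} identifier {i!r} is empty or contains whitespace")
    return ids


@dataclass(frozen=True)
class AbundanceTable:
    """Library x taxon non-negative matrix in ``counts`` or ``relative`` mode.

    ``data`` rows are libraries, columns are taxa.  In relative mode every
    non-flagged row sums to 1 (within 1e-9); all-zero rows are permitted and
    listed in ``zero_libraries``.
    """

    data: pd.DataFrame
    mode: str
    zero_libraries: tuple[str, ...] = field(default=())

    def __post_init__(self):
        if self.mode not in ("counts", "relative"):
            raise FormatError(f"mode must be 'counts' or 'relative', got {self.mode!r}")
        _check_ids(self.data.index, "library")
        _check_ids(self.data.columns, "taxon")
        values = self.data.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise FormatError("abundance table contains non-numeric cells")
        if np.any(values < 0):
            r, c = np.argwhere(values < 0)[0]
            raise FormatError(
                f"negative value at library {self.data.index[r]!r}, taxon {self.data.columns[c]!r}"
            )
        row_sums = values.sum(axis=1)
        zeros = tuple(str(i) for i in self.data.index[row_sums == 0])
        object.__setattr__(self, "zero_libraries", zeros)
        if self.mode == "relative":
            bad = (row_sums > 0) & (np.abs(row_sums - 1.0) > _REL_TOL)
            if np.any(bad):
                lib = self.data.index[np.argmax(bad)]
                raise FormatError(
                    f"relative-mode row {lib!r} sums to {row_sums[np.argmax(bad)]:.6g}, not 1"
                )
        elif self.mode == "counts":
            if not np.allclose(values, np.round(values)):
                raise FormatError("counts-mode table contains non-integer cells")

    @property
    def libraries(self) -> tuple[str, ...]:
        return tuple(self.data.index)

    @property
    def taxa(self) -> tuple[str, ...]:
        return tuple(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    def row_totals(self) -> pd.Series:
        return self.data.sum(axis=1)


def to_relative(table: AbundanceTable) -> AbundanceTable:
    """Row-normalise a table to relative abundances.

    All-zero rows stay zero and are flagged in ``zero_libraries``.
    Idempotent on relative-mode tables.
    """
    totals = table.data.sum(axis=1)
    safe = totals.replace(0, 1.0)
    rel = table.data.div(safe, axis=0)
    return AbundanceTable(data=rel, mode="relative")


def read_abundance_table(path, mode: str, sep: str = "\t") -> AbundanceTable:
    """Read a TSV with a taxon-id header row and library ids in the first column."""
    try:
        df = pd.read_csv(path, sep=sep, index_col=0)
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise FormatError(f"cannot parse abundance table {path}: {exc}") from exc
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    for col in df.columns:
        if not np.issubdtype(df[col].dtype, np.number):
            raise FormatError(f"non-numeric column {col!r} in {path}")
    if mode == "counts":
        df = df.astype(np.int64, errors="raise") if np.allclose(
            df.to_numpy(), np.round(df.to_numpy())
        ) else df
    return AbundanceTable(data=df, mode=mode)


def write_abundance_table(table: AbundanceTable, path, sep: str = "\t") -> None:
    table.data.to_csv(path, sep=sep, float_format="%.12g")


@dataclass(frozen=True)
class SampleMetadata:
    """Per-library categorical environment descriptors.

    Columns: ``biotope`` (one of the seven biotope codes), ``oxic_status``,
    ``salinity``, ``temperature_class`` (free categorical), ``lifestyle``.
    """

    data: pd.DataFrame

    REQUIRED = ("biotope", "oxic_status", "salinity", "temperature_class", "lifestyle")

    def __post_init__(self):
        _check_ids(self.data.index, "library")
        missing = [c for c in self.REQUIRED if c not in self.data.columns]
        if missing:
            raise FormatError(f"metadata missing columns: {missing}")
        for col, vocab in (
            ("biotope", BIOTOPES),
            ("oxic_status", OXIC_STATUSES),
            ("salinity", SALINITIES),
            ("lifestyle", LIFESTYLES),
        ):
            bad = set(self.data[col]) - set(vocab)
            if bad:
                raise FormatError(f"metadata column {col!r} has values outside {vocab}: {sorted(bad)}")

    @property
    def libraries(self) -> tuple[str, ...]:
        return tuple(self.data.index)

    def column(self, name: str) -> pd.Series:
        return self.data[name]

    def require_libraries(self, libraries) -> None:
        missing = [l for l in libraries if l not in self.data.index]
        if missing:
            raise FormatError(f"libraries without metadata: {missing[:5]}")


def read_metadata(path, sep: str = "\t") -> SampleMetadata:
    df = pd.read_csv(path, sep=sep, index_col=0, dtype=str)
    df.index = df.index.astype(str)
    return SampleMetadata(data=df)


def write_metadata(meta: SampleMetadata, path, sep: str = "\t") -> None:
    meta.data.to_csv(path, sep=sep)


@dataclass(frozen=True)
class TaxonomyMap:
    """Total map taxon id -> (lineage, subgroup or "ungrouped")."""

    data: pd.DataFrame  # index taxon, columns lineage, subgroup

    def __post_init__(self):
        _check_ids(self.data.index, "taxon")
        for col in ("lineage", "subgroup"):
            if col not in self.data.columns:
                raise FormatError(f"taxonomy map missing column {col!r}")

    @property
    def taxa(self) -> tuple[str, ...]:
        return tuple(self.data.index)

    def lineage_of(self, taxon: str) -> str:
        try:
            return str(self.data.loc[taxon, "lineage"])
        except KeyError as exc:
            raise FormatError(f"taxon {taxon!r} not in taxonomy map") from exc

    def lineages(self) -> tuple[str, ...]:
        return tuple(pd.unique(self.data["lineage"]))

    def members(self, lineage: str) -> tuple[str, ...]:
        return tuple(self.data.index[self.data["lineage"] == lineage])


def read_taxonomy(path, sep: str = "\t") -> TaxonomyMap:
    df = pd.read_csv(path, sep=sep, index_col=0, dtype=str)
    df.index = df.index.astype(str)
    return TaxonomyMap(data=df)


def write_taxonomy(tax: TaxonomyMap, path, sep: str = "\t") -> None:
    tax.data.to_csv(path, sep=sep)


# ---------------------------------------------------------------------------
# Phylogeny

Phylogeny = dendropy.Tree


def validate_tree(tree: dendropy.Tree) -> dendropy.Tree:
    labels = [leaf.taxon.label if leaf.taxon else None for leaf in tree.leaf_node_iter()]
    if any(l is None for l in labels):
        raise FormatError("tree has unlabeled tips")
    _check_ids(labels, "tip")
    for edge in tree.preorder_edge_iter():
        if edge.length is not None and edge.length < 0:
            raise FormatError(f"negative branch length {edge.length} in tree")
    return tree


def read_newick(source) -> Phylogeny:
    """Parse a rooted newick tree; raises :class:`FormatError` on malformed input."""
    try:
        if hasattr(source, "read") or (isinstance(source, str) and source.lstrip().startswith("(")):
            tree = dendropy.Tree.get(
                data=source if isinstance(source, str) else source.read(),
                schema="newick",
                preserve_underscores=True,
            )
        else:
            tree = dendropy.Tree.get(path=str(source), schema="newick", preserve_underscores=True)
    except Exception as exc:
        raise FormatError(f"newick parse error: {exc}") from exc
    tree.is_rooted = True
    return validate_tree(tree)


def write_newick(tree: Phylogeny, path=None) -> str:
    """Serialise a tree to newick text; optionally also write it to ``path``."""
    text = tree.as_string(
        schema="newick",
        suppress_rooting=True,
        unquoted_underscores=True,
        real_value_format_specifier=".12g",
    )
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


def read_identity_matrix(path, sep: str = "\t") -> pd.DataFrame:
    """Square symmetric pairwise sequence-identity matrix (percent)."""
    df = pd.read_csv(path, sep=sep, index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    if list(df.index) != list(df.columns):
        raise FormatError("identity matrix rows and columns disagree")
    m = df.to_numpy(dtype=float)
    if not np.allclose(m, m.T, atol=1e-9):
        raise FormatError("identity matrix is not symmetric")
    return df


# ---------------------------------------------------------------------------
# GraphML


def export_graphml(network, path) -> None:
    """Write a co-occurrence network (or bare nx.Graph) to GraphML.

    Node attributes (lineage, module, closeness, ...) and the edge ``rho``
    attribute survive a round trip.
    """
    graph = network if isinstance(network, nx.Graph) else network.graph
    nx.write_graphml(graph, path, named_key_ids=True)


def import_graphml(path) -> nx.Graph:
    return nx.read_graphml(path)
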