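"""Validated containers and readers/writers for every external format the pipeline touches.

Counts are genes-as-rows TSV/CSV, gene sets are GMT, protein–protein interaction (PPI)
networks are two-column edge lists, ROI metadata is CSV. Gene identity throughout the
package is the uppercased, whitespace-stripped symbol; no alias resolution is attempted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

GROUPS = ("HC", "PD", "MSAP")
QUADRANTS = ("DM", "DL", "VM", "VL")
META_COLUMNS = ["roi_id", "subject_id", "group", "quadrant", "slide_id", "nuclei_count"]


def canonical_gene(symbol: str) -> str:
    """Canonical gene identity: uppercased, stripped symbol."""
    return str(symbol).strip().upper()


def _sep_for(path: str | Path) -> str:
    return "," if str(path).lower().endswith(".csv") else "\t"


# ---------------------------------------------------------------------------
# CountMatrix
# ---------------------------------------------------------------------------

@dataclass
class CountMatrix:
    """Raw nonnegative integer counts, genes × ROIs.

    ``counts`` is a DataFrame indexed by unique gene symbols with ROI ids as
    columns. Invariants (no duplicates, no missing values, integer ≥ 0,
    at least 2 ROIs) are enforced at construction.
    """

    counts: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.counts
        if df.shape[1] < 2:
            raise ValueError("count matrix needs at least 2 ROIs")
        if df.index.duplicated().any():
            dups = df.index[df.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene symbols: {dups}")
        if df.columns.duplicated().any():
            raise ValueError("duplicate ROI ids in count matrix")
        arr = df.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise ValueError("count matrix contains non-numeric entries")
        bad = ~np.isfinite(arr) | (arr < 0) | (np.mod(arr, 1) != 0)
        if bad.any():
            g, r = np.argwhere(bad)[0]
            raise ValueError(
                f"invalid count at gene {df.index[g]!r}, ROI {df.columns[r]!r}: "
                f"{arr[g, r]!r} (must be a nonnegative integer)"
            )
        self.counts = df.astype(np.int64)

    @property
    def genes(self) -> list[str]:
        return list(self.counts.index)

    @property
    def rois(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def subset_rois(self, rois: list[str]) -> "CountMatrix":
        return CountMatrix(self.counts.loc[:, list(rois)].copy())

    def to_file(self, path: str | Path) -> None:
        self.counts.to_csv(path, sep=_sep_for(path), index_label="gene")


def read_count_matrix(path: str | Path) -> CountMatrix:
    """Read a genes × ROIs count table (delimiter sniffed from extension).

    Gene symbols are canonicalized; duplicate symbols are collapsed by
    summation with a warning. Non-integer or negative entries raise with the
    offending cell named.
    """
    try:
        df = pd.read_csv(path, sep=_sep_for(path), index_col=0)
    except pd.errors.EmptyDataError as exc:
        raise ValueError(f"empty count matrix file: {path}") from exc
    if df.empty or df.shape[1] == 0:
        raise ValueError(f"empty count matrix file: {path}")
    df.index = [canonical_gene(g) for g in df.index]
    df.columns = [str(c).strip() for c in df.columns]
    # validate cell-wise before any collapsing so errors name the raw cell
    for roi in df.columns:
        col = pd.to_numeric(df[roi], errors="coerce")
        bad = col.isna() | (col < 0) | (np.mod(col.fillna(0), 1) != 0)
        if bad.any():
            gene = df.index[int(np.argmax(bad.to_numpy()))]
            raise ValueError(
                f"invalid count at gene {gene!r}, ROI {roi!r}: {df.loc[gene, roi]!r}"
            )
        df[roi] = col
    if df.index.duplicated().any():
        dups = sorted(df.index[df.index.duplicated()].unique())
        warnings.warn(f"duplicate gene symbols collapsed by summation: {dups}")
        df = df.groupby(level=0, sort=False).sum()
    return CountMatrix(df)


# ---------------------------------------------------------------------------
# ROI metadata
# ---------------------------------------------------------------------------

def validate_metadata(
    meta: pd.DataFrame,
    counts: CountMatrix | None = None,
    groups: tuple[str, ...] = GROUPS,
    quadrants: tuple[str, ...] = QUADRANTS,
) -> pd.DataFrame:
    """Validate ROI annotations; returns the frame with canonical column order.

    Every ROI of ``counts`` (if given) must have a metadata row; group and
    quadrant labels come from closed vocabularies.
    """
    missing = [c for c in META_COLUMNS if c not in meta.columns]
    if missing:
        raise ValueError(f"metadata missing columns: {missing}")
    meta = meta[META_COLUMNS].copy()
    if meta["roi_id"].duplicated().any():
        raise ValueError("duplicate roi_id in metadata")
    bad_group = set(meta["group"]) - set(groups)
    if bad_group:
        raise ValueError(f"unknown group labels {sorted(bad_group)}; allowed {groups}")
    bad_quad = set(meta["quadrant"]) - set(quadrants)
    if bad_quad:
        raise ValueError(f"unknown quadrant labels {sorted(bad_quad)}; allowed {quadrants}")
    nuc = pd.to_numeric(meta["nuclei_count"], errors="coerce")
    if nuc.isna().any() or (nuc < 0).any() or (np.mod(nuc, 1) != 0).any():
        raise ValueError("nuclei_count must be a nonnegative integer")
    meta["nuclei_count"] = nuc.astype(np.int64)
    if counts is not None:
        absent = set(counts.rois) - set(meta["roi_id"])
        if absent:
            raise ValueError(f"ROIs missing from metadata: {sorted(absent)}")
    return meta


def read_metadata(
    path: str | Path,
    groups: tuple[str, ...] = GROUPS,
    quadrants: tuple[str, ...] = QUADRANTS,
) -> pd.DataFrame:
    meta = pd.read_csv(path)
    return validate_metadata(meta, groups=groups, quadrants=quadrants)


def write_metadata(meta: pd.DataFrame, path: str | Path) -> None:
    meta[META_COLUMNS].to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Gene sets (GMT)
# ---------------------------------------------------------------------------

@dataclass
class GeneSetCollection:
    """Named gene sets: term → (description, member genes).

    Gene lists are non-empty, deduplicated, canonicalized symbols.
    """

    terms: dict[str, tuple[str, list[str]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, (_desc, genes) in self.terms.items():
            if len(genes) == 0:
                raise ValueError(f"gene set {name!r} is empty")
            if len(set(genes)) != len(genes):
                raise ValueError(f"gene set {name!r} contains duplicates")

    def __len__(self) -> int:
        return len(self.terms)

    def genes_of(self, term: str) -> list[str]:
        return self.terms[term][1]

    def to_gmt(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            for name, (desc, genes) in self.terms.items():
                fh.write("\t".join([name, desc, *genes]) + "\n")


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Parse a GMT file (term, description, genes…); genes deduplicated."""
    terms: dict[str, tuple[str, list[str]]] = {}
    with open(path, encoding="utf-8") as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if not lines:
        warnings.warn(f"empty GMT file: {path}")
        return GeneSetCollection({})
    for i, line in enumerate(lines, start=1):
        fields = line.split("\t")
        if len(fields) < 3:
            raise ValueError(f"{path}: line {i} has {len(fields)} fields (need ≥ 3)")
        name, desc = fields[0], fields[1]
        seen: dict[str, None] = {}
        for g in fields[2:]:
            g = canonical_gene(g)
            if g:
                seen.setdefault(g, None)
        terms[name] = (desc, list(seen))
    return GeneSetCollection(terms)


# ---------------------------------------------------------------------------
# PPI network
# ---------------------------------------------------------------------------

@dataclass
class PPINetwork:
    """Undirected simple gene graph (no self-loops, no multi-edges)."""

    graph: nx.Graph

    def __post_init__(self) -> None:
        loops = list(nx.selfloop_edges(self.graph))
        if loops:
            raise ValueError(f"self-loops not allowed: {loops}")

    @property
    def nodes(self) -> list[str]:
        return sorted(self.graph.nodes)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def adjacency(self) -> tuple[np.ndarray, list[str]]:
        """0/1 symmetric adjacency with zero diagonal, nodes sorted."""
        nodes = self.nodes
        A = nx.to_numpy_array(self.graph, nodelist=nodes, dtype=float)
        return A, nodes

    def largest_component(self) -> "PPINetwork":
        if self.n_nodes == 0 or nx.is_connected(self.graph):
            return self
        cc = max(nx.connected_components(self.graph), key=lambda c: (len(c), sorted(c)[0]))
        return PPINetwork(self.graph.subgraph(cc).copy())

    def to_edge_list(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            for u, v in sorted(tuple(sorted(e)) for e in self.graph.edges):
                fh.write(f"{u}\t{v}\n")


def read_edge_list(path: str | Path) -> PPINetwork:
    """Read a ≥2-column edge list; extra columns ignored, self-loops dropped
    with a warning, duplicate edges collapsed. Fewer than 1 valid edge is an
    error."""
    g = nx.Graph()
    n_loops = 0
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            fields = line.split()
            if len(fields) < 2:
                continue
            u, v = canonical_gene(fields[0]), canonical_gene(fields[1])
            if u == v:
                n_loops += 1
                continue
            g.add_edge(u, v)
    if n_loops:
        warnings.warn(f"{path}: dropped {n_loops} self-loop(s)")
    if g.number_of_edges() < 1:
        raise ValueError(f"{path}: no valid edges")
    return PPINetwork(g)
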