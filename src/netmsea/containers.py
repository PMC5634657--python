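"""Shared in-memory containers for the pipeline.

Marker association tables and marker→gene mappings are plain pandas
DataFrames with documented column names; the classes here wrap the two
structures that need non-trivial lookup semantics (pairwise LD and
weighted networks) plus the named-gene-set collection used throughout.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping

import networkx as nx
import numpy as np
import pandas as pd

#: canonical column names of a marker association table
ASSOC_COLUMNS = [
    "marker_id", "p_value", "beta", "effect_allele", "other_allele",
    "maf", "info",
]

#: canonical column names of a marker→gene mapping table
MAPPING_COLUMNS = ["marker_id", "gene_id", "scheme", "tissue"]

MAPPING_SCHEMES = frozenset(
    {"distance", "regulome", "eqtl", "multi_tissue_eqtl",
     "eqtl_plus_regulome", "combined"}
)


class LdTable:
    """Symmetric pairwise r² lookup.

    Unlisted pairs have r² = 0; the diagonal is 1 by definition.
    """

    def __init__(self, pairs: Iterable[tuple[str, str, float]] = ()):
        self._r2: dict[tuple[str, str], float] = {}
        self._adj: dict[str, list[tuple[str, float]]] = {}
        for a, b, r2 in pairs:
            self.add(a, b, float(r2))

    @staticmethod
    def _key(a: str, b: str) -> tuple[str, str]:
        return (a, b) if a <= b else (b, a)

    def add(self, a: str, b: str, r2: float) -> None:
        if a == b:
            return
        if not 0.0 <= r2 <= 1.0:
            raise ValueError(f"r² must lie in [0,1], got {r2} for ({a},{b})")
        key = self._key(a, b)
        if key in self._r2:
            self._r2[key] = max(self._r2[key], r2)
            return
        self._r2[key] = r2
        self._adj.setdefault(a, []).append((b, r2))
        self._adj.setdefault(b, []).append((a, r2))

    def r2(self, a: str, b: str) -> float:
        if a == b:
            return 1.0
        return self._r2.get(self._key(a, b), 0.0)

    def partners(self, marker: str, r2_min: float) -> list[str]:
        """Markers whose r² with `marker` exceeds `r2_min`."""
        return [m for m, r2 in self._adj.get(marker, ()) if r2 > r2_min]

    def __len__(self) -> int:
        return len(self._r2)

    def to_frame(self) -> pd.DataFrame:
        rows = [(a, b, r2) for (a, b), r2 in sorted(self._r2.items())]
        return pd.DataFrame(rows, columns=["marker_1", "marker_2", "r2"])

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "LdTable":
        cols = list(df.columns[:3])
        return cls(df[cols].itertuples(index=False, name=None))


class GeneSetCollection(Mapping):
    """Ordered mapping of set id → frozenset of gene ids."""

    def __init__(self, sets: Mapping[str, Iterable[str]] | None = None):
        self._sets: dict[str, frozenset[str]] = {}
        if sets:
            for name, genes in sets.items():
                self._sets[str(name)] = frozenset(map(str, genes))

    def __getitem__(self, key: str) -> frozenset[str]:
        return self._sets[key]

    def __iter__(self) -> Iterator[str]:
        return iter(self._sets)

    def __len__(self) -> int:
        return len(self._sets)

    def add(self, name: str, genes: Iterable[str]) -> None:
        self._sets[str(name)] = frozenset(map(str, genes))

    @property
    def universe(self) -> frozenset[str]:
        out: set[str] = set()
        for genes in self._sets.values():
            out |= genes
        return frozenset(out)

    def subset(self, names: Iterable[str]) -> "GeneSetCollection":
        return GeneSetCollection({n: self._sets[n] for n in names})

    def to_frame(self) -> pd.DataFrame:
        rows = [(name, g) for name, genes in self._sets.items()
                for g in sorted(genes)]
        return pd.DataFrame(rows, columns=["set_id", "gene_id"])

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "GeneSetCollection":
        out = cls()
        set_col, gene_col = df.columns[:2]
        for name, grp in df.groupby(set_col, sort=False):
            out.add(str(name), grp[gene_col].astype(str))
        return out

    def write_gmt(self, path) -> None:
        with open(path, "w") as fh:
            for name, genes in self._sets.items():
                fh.write("\t".join([name, "na", *sorted(genes)]) + "\n")

    @classmethod
    def read_gmt(cls, path) -> "GeneSetCollection":
        out = cls()
        with open(path) as fh:
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                if len(parts) < 3:
                    continue
                out.add(parts[0], parts[2:])
        return out


@dataclass
class WeightedNetwork:
    """Undirected weighted gene-gene network.

    Edges are stored in canonical (a < b) order with strictly positive
    weights; self-loops are rejected. The weight of an edge produced by
    a tissue-level union is the number of source datasets supporting it
    (a consistency count), but real-valued confidence weights are
    equally valid.
    """

    tissue: str = ""
    source_datasets: int = 1
    _graph: nx.Graph = field(default_factory=nx.Graph, repr=False)

    @classmethod
    def from_edges(cls, edges: Iterable[tuple[str, str, float]],
                   tissue: str = "", source_datasets: int = 1
                   ) -> "WeightedNetwork":
        net = cls(tissue=tissue, source_datasets=source_datasets)
        for a, b, w in edges:
            net.add_edge(str(a), str(b), float(w))
        return net

    def add_edge(self, a: str, b: str, weight: float = 1.0) -> None:
        if a == b:
            raise ValueError(f"self-loop on {a!r} not allowed")
        if weight <= 0:
            raise ValueError(f"edge weight must be positive, got {weight}")
        if a > b:
            a, b = b, a
        self._graph.add_edge(a, b, weight=weight)

    @property
    def graph(self) -> nx.Graph:
        return self._graph

    @property
    def nodes(self) -> list[str]:
        return sorted(self._graph.nodes)

    @property
    def order(self) -> int:
        return self._graph.number_of_nodes()

    def degree(self, node: str) -> int:
        return self._graph.degree(node)

    def neighbors(self, node: str) -> list[str]:
        return sorted(self._graph.neighbors(node))

    def weight(self, a: str, b: str) -> float:
        data = self._graph.get_edge_data(a, b)
        return 0.0 if data is None else data["weight"]

    def __contains__(self, node: str) -> bool:
        return node in self._graph

    def edge_count(self) -> int:
        return self._graph.number_of_edges()

    def to_frame(self) -> pd.DataFrame:
        rows = sorted(
            (min(a, b), max(a, b), d["weight"], self.tissue)
            for a, b, d in self._graph.edges(data=True)
        )
        return pd.DataFrame(rows, columns=["tail", "head", "weight", "tissue"])

    @classmethod
    def from_frame(cls, df: pd.DataFrame, tissue: str | None = None
                   ) -> "WeightedNetwork":
        if tissue is None:
            tissues = df["tissue"].unique() if "tissue" in df else [""]
            tissue = str(tissues[0]) if len(tissues) else ""
        cols = [c for c in ("tail", "head", "weight") if c in df.columns]
        if len(cols) < 3:
            cols = list(df.columns[:3])
        return cls.from_edges(
            df[cols].itertuples(index=False, name=None), tissue=tissue)


def jaccard(a: frozenset, b: frozenset) -> float:
    """Jaccard index |A∩B| / |A∪B|; 1.0 for two empty sets."""
    union = len(a | b)
    if union == 0:
        return 1.0
    return len(a & b) / union


def write_tsv(df: pd.DataFrame, path, float_format: str = "%.6g") -> None:
    df.to_csv(path, sep="\t", index=False, float_format=float_format)


def read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def frame_digest(df: pd.DataFrame) -> str:
    """Stable content digest of a DataFrame (for run manifests)."""
    import hashlib

    buf = io.StringIO()
    df.to_csv(buf, sep="\t", index=False)
    return hashlib.sha256(buf.getvalue().encode()).hexdigest()[:16]
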