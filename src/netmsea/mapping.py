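"""Marker→gene assignment under the pipeline's mapping schemes.

Schemes mirror the usual functional-genomics options: chromosomal
distance to the gene body (50 kb window), distance restricted to
markers with regulatory evidence, tissue-specific cis-eQTLs (single
tissue or pooled multi-tissue), and set unions of the above. All
coordinates are 1-based inclusive.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .containers import MAPPING_COLUMNS

log = logging.getLogger(__name__)

CIS_WINDOW = 1_000_000  # max distance from TSS for a cis-eQTL, bp


def _empty_mapping() -> pd.DataFrame:
    return pd.DataFrame(columns=MAPPING_COLUMNS)


def _finish(df: pd.DataFrame) -> pd.DataFrame:
    if df.empty:
        return _empty_mapping()
    df = df.drop_duplicates(MAPPING_COLUMNS, ignore_index=True)
    return df[MAPPING_COLUMNS]


def map_by_distance(markers: pd.DataFrame, genes: pd.DataFrame,
                    window: int = 50_000, scheme: str = "distance"
                    ) -> pd.DataFrame:
    """Link a marker to every gene whose body ± window contains it.

    `markers` needs columns marker_id, chrom, pos; `genes` needs
    gene_id, chrom, start, end. The window is anchored on the gene
    body [start, end], not the TSS.
    """
    if window < 0:
        raise ValueError("window must be non-negative")
    m_chroms = set(markers["chrom"].astype(str))
    g_chroms = set(genes["chrom"].astype(str))
    if m_chroms and g_chroms and not (m_chroms & g_chroms):
        log.warning("no shared chromosome labels between %d marker and %d "
                    "gene chromosomes", len(m_chroms), len(g_chroms))
    out = []
    for chrom, gsub in genes.groupby(genes["chrom"].astype(str)):
        msub = markers.loc[markers["chrom"].astype(str) == chrom]
        if msub.empty:
            continue
        pos = msub["pos"].to_numpy(dtype=np.int64)
        ids = msub["marker_id"].to_numpy()
        order = np.argsort(pos, kind="stable")
        pos, ids = pos[order], ids[order]
        for g, start, end in gsub[["gene_id", "start", "end"]].itertuples(
                index=False):
            lo = np.searchsorted(pos, int(start) - window, side="left")
            hi = np.searchsorted(pos, int(end) + window, side="right")
            out.extend((ids[i], g) for i in range(lo, hi))
    df = pd.DataFrame(out, columns=["marker_id", "gene_id"])
    df["scheme"] = scheme
    df["tissue"] = ""
    return _finish(df)


def map_by_regulome(markers: pd.DataFrame, genes: pd.DataFrame,
                    evidence: set[str], window: int = 50_000) -> pd.DataFrame:
    """Distance mapping restricted to markers with regulatory evidence."""
    sub = markers.loc[markers["marker_id"].isin(set(evidence))]
    return map_by_distance(sub, genes, window=window, scheme="regulome")


def map_by_eqtl(eqtl_table: pd.DataFrame, tissue_filter: str = "all",
                marker_positions: pd.DataFrame | None = None,
                gene_tss: pd.DataFrame | None = None,
                cis_window: int = CIS_WINDOW) -> pd.DataFrame:
    """eQTL-based mapping, single-tissue or pooled multi-tissue.

    `eqtl_table` has columns marker_id, gene_id, tissue. With
    tissue_filter="all" the tissues are pooled into one deduplicated
    multi-tissue link set. When marker positions and gene TSS tables
    are supplied, links farther than `cis_window` from the TSS are
    rejected (cis validation); otherwise the table is trusted as-is.
    """
    df = eqtl_table[["marker_id", "gene_id", "tissue"]].copy()
    if tissue_filter == "all":
        df = df.drop_duplicates(["marker_id", "gene_id"])
        df["tissue"] = "all"
        df["scheme"] = "multi_tissue_eqtl"
    else:
        available = sorted(eqtl_table["tissue"].astype(str).unique())
        if tissue_filter not in available:
            raise ValueError(
                f"unknown tissue {tissue_filter!r}; available: {available}")
        df = df.loc[df["tissue"] == tissue_filter]
        df["scheme"] = "eqtl"

    if marker_positions is not None and gene_tss is not None:
        pos = marker_positions.set_index("marker_id")[["chrom", "pos"]]
        tss = gene_tss.set_index("gene_id")[["chrom", "tss"]]
        keep = []
        for m, g in df[["marker_id", "gene_id"]].itertuples(index=False):
            ok = True
            if m in pos.index and g in tss.index:
                mrow, grow = pos.loc[m], tss.loc[g]
                ok = (str(mrow["chrom"]) == str(grow["chrom"])
                      and abs(int(mrow["pos"]) - int(grow["tss"]))
                      <= cis_window)
            keep.append(ok)
        n_drop = len(keep) - sum(keep)
        if n_drop:
            log.info("cis validation rejected %d eQTL links beyond %d bp",
                     n_drop, cis_window)
        df = df.loc[keep]
    return _finish(df)


def combine_mappings(parts: list[pd.DataFrame],
                     scheme: str | None = None) -> pd.DataFrame:
    """Set union of mappings; provenance retained once per scheme.

    Commutative and idempotent on the link set. Passing `scheme`
    relabels the union (e.g. "combined" for the all-sources mode).
    """
    parts = [p for p in parts if p is not None and not p.empty]
    if not parts:
        return _empty_mapping()
    df = pd.concat(parts, ignore_index=True)
    if scheme is not None:
        df = df.drop_duplicates(["marker_id", "gene_id"], ignore_index=True)
        df["scheme"] = scheme
    return _finish(df)


def restrict_to_markers(mapping: pd.DataFrame,
                        marker_ids: set[str] | list[str]) -> pd.DataFrame:
    """Drop links whose marker did not survive upstream QC/pruning."""
    keep = mapping["marker_id"].isin(set(marker_ids))
    return mapping.loc[keep].reset_index(drop=True)


def gene_to_markers(mapping: pd.DataFrame) -> dict[str, list[str]]:
    """Invert a mapping to gene → sorted unique marker ids."""
    out: dict[str, list[str]] = {}
    for g, grp in mapping.groupby("gene_id", sort=True):
        out[str(g)] = sorted(grp["marker_id"].unique())
    return out
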