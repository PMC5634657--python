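"""GWAS summary-statistic intake, QC filtering and LD pruning.

Markers are filtered on minor allele frequency and imputation quality,
then reduced to an approximately independent set by a rank-based greedy
walk over the LD table: markers are visited in order of ascending
association p-value and accepted only when not in strong LD (r² above
the threshold) with any already-accepted marker, so each LD component
is represented by its strongest marker. Finally, representatives that
rank in the weaker half of the original p ranking *and* belonged to a
multi-marker LD component are dropped (both conditions must hold: a
weak marker with no LD partner survives).
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd

from .containers import ASSOC_COLUMNS, LdTable

log = logging.getLogger(__name__)

DEFAULT_COLUMN_MAP = {
    "marker_id": "MARKER",
    "p_value": "PVALUE",
    "beta": "BETA",
    "effect_allele": "EFFECT_ALLELE",
    "other_allele": "OTHER_ALLELE",
    "maf": "MAF",
    "info": "INFO",
}


def read_gwas(path, column_map: dict[str, str] | None = None) -> pd.DataFrame:
    """Read a tab-delimited GWAS summary file into a marker table.

    `column_map` maps canonical field names to file column names;
    marker_id and p_value are required, everything else optional.
    Malformed p-values (non-numeric, <= 0 or > 1) are rejected with
    their 1-based data row numbers; duplicate marker ids collapse to
    the minimum-p record.
    """
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)
    raw = pd.read_csv(path, sep="\t", dtype=str)
    for field in ("marker_id", "p_value"):
        if cmap[field] not in raw.columns:
            raise ValueError(
                f"required column {cmap[field]!r} (for {field}) missing "
                f"from {path}; found {list(raw.columns)}")

    out = pd.DataFrame({"marker_id": raw[cmap["marker_id"]].astype(str)})
    p = pd.to_numeric(raw[cmap["p_value"]], errors="coerce")
    bad = p.isna() | (p <= 0) | (p > 1)
    if bad.any():
        rows = [int(i) + 1 for i in np.flatnonzero(bad.to_numpy())]
        raise ValueError(
            f"malformed p-values (must be in (0,1]) on data rows {rows[:20]}"
            + (" ..." if len(rows) > 20 else ""))
    out["p_value"] = p.astype(float)

    for field in ("beta", "maf", "info"):
        col = cmap.get(field)
        out[field] = (pd.to_numeric(raw[col], errors="coerce")
                      if col in raw.columns else np.nan)
    for field in ("effect_allele", "other_allele"):
        col = cmap.get(field)
        out[field] = raw[col].astype(str) if col in raw.columns else pd.NA

    n_dup = out["marker_id"].duplicated().sum()
    if n_dup:
        log.info("collapsing %d duplicate marker rows to minimum-p records",
                 n_dup)
        out = (out.sort_values(["p_value", "marker_id"], kind="mergesort")
               .drop_duplicates("marker_id", keep="first")
               .sort_index(ignore_index=True))
    return out[ASSOC_COLUMNS]


def filter_markers(assocs: pd.DataFrame, maf_min: float = 0.05,
                   info_min: float = 0.3, strict: bool = False
                   ) -> pd.DataFrame:
    """QC filter: keep markers with maf > maf_min and info > info_min.

    A marker missing a QC field passes that criterion (many consortium
    releases omit per-SNP MAF or imputation quality); ``strict=True``
    rejects missing fields instead. Input order is preserved.
    """
    for name, t in (("maf_min", maf_min), ("info_min", info_min)):
        if not 0.0 <= t <= 1.0:
            raise ValueError(f"{name} must lie in [0,1], got {t}")
    maf = assocs["maf"] if "maf" in assocs else pd.Series(np.nan,
                                                          index=assocs.index)
    info = assocs["info"] if "info" in assocs else pd.Series(np.nan,
                                                             index=assocs.index)
    if strict:
        keep = (maf > maf_min) & (info > info_min)
    else:
        keep = ((maf.isna() | (maf > maf_min))
                & (info.isna() | (info > info_min)))
        n_missing = int((maf.isna() | info.isna()).sum())
        if n_missing:
            log.warning("%d markers missing MAF and/or INFO pass QC by the "
                        "lenient missing-field policy", n_missing)
    return assocs.loc[keep].reset_index(drop=True)


def prune_ld(assocs: pd.DataFrame, ld: LdTable, r2_max: float = 0.5,
             drop_bottom_fraction: float = 0.5) -> list[str]:
    """Greedy rank-based LD pruning; returns retained marker ids.

    Markers are ranked by ascending p (ties broken by marker id). The
    walk accepts a marker only if its r² with every already-accepted
    marker is <= r2_max, leaving each LD component represented by its
    minimum-p marker. Accepted markers are then additionally dropped
    when they (a) rank in the bottom ``drop_bottom_fraction`` of the
    original p ranking and (b) had any LD partner above r2_max — i.e.
    weak markers are removed only when LD-linked; isolated weak markers
    survive. ``drop_bottom_fraction=0`` disables the second step.
    """
    if not 0.0 <= r2_max <= 1.0:
        raise ValueError(f"r2_max must lie in [0,1], got {r2_max}")
    if not 0.0 <= drop_bottom_fraction < 1.0:
        raise ValueError("drop_bottom_fraction must lie in [0,1)")

    ranked = sorted(zip(assocs["p_value"], assocs["marker_id"]))
    order = [m for _, m in ranked]
    present = set(order)

    def linked_in_study(m: str) -> list[str]:
        return [a for a in ld.partners(m, r2_max) if a in present]

    accepted: list[str] = []
    accepted_set: set[str] = set()
    for m in order:
        if any(a in accepted_set for a in linked_in_study(m)):
            continue
        accepted.append(m)
        accepted_set.add(m)

    n = len(order)
    if drop_bottom_fraction > 0 and n:
        n_keep_ranks = n - math.floor(n * drop_bottom_fraction)
        top = set(order[:n_keep_ranks])
        retained = [m for m in accepted
                    if m in top or not linked_in_study(m)]
    else:
        retained = accepted
    return retained
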