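"""Meta-analysis of per-study enrichment results (Meta-MSEA).

Per-study Gaussian z-scores for each gene set are combined by
Stouffer's method, meta_z = sum(z_i)/sqrt(m) over the m studies where
the set was tested (missing studies are excluded, never imputed), the
meta p-value is the one-sided upper-tail Gaussian probability, and BH
FDR is taken across all combined sets. Sets at meta-FDR below the
significance threshold (default 5%) are flagged.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .msea import bh_fdr


def stouffer_combine(z_values, weights=None) -> tuple[float, float]:
    """Stouffer's method: meta_z = sum(w·z)/sqrt(sum(w²)), meta_p upper-tail.

    Unweighted by default; non-finite z values are excluded.
    """
    z = np.asarray(z_values, dtype=float)
    if weights is None:
        w = np.ones_like(z)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != z.shape:
            raise ValueError("weights must match z_values in length")
    keep = np.isfinite(z)
    z, w = z[keep], w[keep]
    if z.size == 0:
        raise ValueError("no finite z values to combine")
    meta_z = float((w * z).sum() / np.sqrt((w ** 2).sum()))
    return meta_z, float(stats.norm.sf(meta_z))


def run_meta_msea(per_study_results: dict[str, pd.DataFrame],
                  sig_fdr: float = 0.05) -> pd.DataFrame:
    """Combine MSEA result tables across studies into a meta table.

    Returns one row per set with columns set_id, meta_z, meta_p,
    meta_fdr, n_studies_used, significant, plus z_<study> / p_<study>
    per study (NaN where a set was absent). Study order never affects
    the result.
    """
    if not per_study_results:
        raise ValueError("no study results supplied")
    studies = sorted(per_study_results)
    z_cols = {}
    p_cols = {}
    for s in studies:
        df = per_study_results[s]
        z_cols[s] = df.set_index("set_id")["z_score"]
        p_cols[s] = df.set_index("set_id")["p_value"]
    z_mat = pd.DataFrame(z_cols)
    if z_mat.empty:
        raise ValueError("no sets shared across study results")
    p_mat = pd.DataFrame(p_cols).reindex(z_mat.index)

    meta_rows = []
    for set_id, row in z_mat.iterrows():
        z = row.to_numpy(dtype=float)
        meta_z, meta_p = stouffer_combine(z)
        meta_rows.append((set_id, meta_z, meta_p,
                          int(np.isfinite(z).sum())))
    out = pd.DataFrame(meta_rows,
                       columns=["set_id", "meta_z", "meta_p",
                                "n_studies_used"])
    out["meta_fdr"] = bh_fdr(out["meta_p"])
    out["significant"] = out["meta_fdr"] < sig_fdr
    for s in studies:
        out[f"z_{s}"] = z_mat[s].to_numpy()
        out[f"p_{s}"] = p_mat[s].to_numpy()
    return out.sort_values("meta_p", kind="mergesort",
                           ignore_index=True)


def significant_sets(meta_table: pd.DataFrame) -> list[str]:
    """Set ids flagged significant by the meta analysis."""
    return meta_table.loc[meta_table["significant"], "set_id"].tolist()
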