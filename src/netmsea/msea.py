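"""Marker-set enrichment analysis (MSEA).

A gene set is scored for enrichment of strong GWAS association by a
chi-square-like statistic evaluated at several quantile thresholds of
the study-wide p-value distribution:

    chi = sum_q (O_q - E_q) / sqrt(E_q + kappa)

where at each quantile point q the top (1-q) fraction of all study
markers count as "positive", O_q is the number of the set's markers
among them, E_q = n_set_markers * (1-q) is the expected count under no
enrichment, and kappa (default 1) damps terms with small expected
counts. The statistic depends only on p-value ranks, so any strictly
monotone transform of the p-values leaves it unchanged.

The null is built by permuting gene labels: random gene sets with the
same number of mapped genes are drawn from the mapped-gene universe
while the SNP→gene assignment stays fixed, which preserves gene size,
LD-block structure and SNPs-per-locus confounding. A Gaussian fitted
to the permutation statistics gives one-sided upper-tail p-values with
resolution beyond 1/n_perm, and Benjamini–Hochberg FDR is taken across
all tested sets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import GeneSetCollection
from .mapping import gene_to_markers

log = logging.getLogger(__name__)

#: ten quantile points spanning the top 50% to the top 99.9%, denser in
#: the tail where GWAS signal concentrates
DEFAULT_QUANTILES = (0.50, 0.60, 0.70, 0.80, 0.90,
                     0.95, 0.98, 0.99, 0.995, 0.999)

RESULT_COLUMNS = ["set_id", "statistic", "z_score", "p_value", "fdr",
                  "n_set_genes", "n_set_markers", "null_mean", "null_sd"]


@dataclass(frozen=True)
class EnrichmentConfig:
    """Knobs of the enrichment statistic and its permutation null."""

    quantile_points: tuple[float, ...] = DEFAULT_QUANTILES
    kappa: float = 1.0
    n_perm: int = 10_000
    min_set_genes: int = 10
    seed: int = 0
    sqrt_denominator: bool = True   # (O-E)/sqrt(E+k); False -> (O-E)/(E+k)

    def validate(self) -> None:
        q = self.quantile_points
        if not q or any(not 0 < x < 1 for x in q) or list(q) != sorted(set(q)):
            raise ValueError(
                "quantile_points must be strictly increasing in (0,1)")
        if self.kappa < 0:
            raise ValueError("kappa must be >= 0")
        if self.n_perm < 100:
            raise ValueError("n_perm must be >= 100")


def _thresholds(all_p: np.ndarray, quantiles: tuple[float, ...]
                ) -> tuple[np.ndarray, np.ndarray]:
    """Rank-based thresholds: t_q = p at rank floor(n*(1-q)).

    Returns (thresholds, expected fraction 1-q per point). A quantile
    leaving no positive marker in the pool is out of the data's range.
    """
    n = all_p.size
    srt = np.sort(all_p)
    tail = 1.0 - np.asarray(quantiles)
    # guard the rank computation against fp noise in 1-q (e.g. 1-0.9)
    k = np.floor(n * tail + 1e-9).astype(int)
    if np.any(k < 1):
        bad = [q for q, kk in zip(quantiles, k) if kk < 1]
        raise ValueError(
            f"quantile points {bad} leave no positive marker in a pool of "
            f"{n}; use fewer/looser quantiles or more markers")
    return srt[k - 1], tail


def compute_enrichment_statistic(set_p: np.ndarray, all_p: np.ndarray,
                                 config: EnrichmentConfig | None = None
                                 ) -> float:
    """The quantile-threshold enrichment statistic for one marker set."""
    config = config or EnrichmentConfig()
    config.validate()
    set_p = np.asarray(set_p, dtype=float)
    all_p = np.asarray(all_p, dtype=float)
    if set_p.size == 0:
        raise ValueError("empty marker set")
    thr, tail = _thresholds(all_p, config.quantile_points)
    obs = (set_p[:, None] <= thr[None, :]).sum(axis=0).astype(float)
    exp = set_p.size * tail
    return float(_chi_terms(obs, exp, config).sum())


def _chi_terms(obs: np.ndarray, exp: np.ndarray,
               config: EnrichmentConfig) -> np.ndarray:
    denom = (np.sqrt(exp + config.kappa) if config.sqrt_denominator
             else exp + config.kappa)
    return (obs - exp) / denom


class _StudyIndex:
    """Precomputed positive-marker indicators for fast permutation scoring."""

    def __init__(self, marker_p: pd.Series, config: EnrichmentConfig):
        self.config = config
        self.marker_ids = marker_p.index.to_numpy()
        self.pos_of = {m: i for i, m in enumerate(self.marker_ids)}
        all_p = marker_p.to_numpy(dtype=float)
        thr, self.tail = _thresholds(all_p, config.quantile_points)
        # below[m, q] == marker m counts as positive at quantile q
        self.below = (all_p[:, None] <= thr[None, :]).astype(np.float64)

    def chi_for_marker_idx(self, idx: np.ndarray) -> float:
        obs = self.below[idx].sum(axis=0)
        exp = idx.size * self.tail
        return float(_chi_terms(obs, exp, self.config).sum())


def generate_null(set_gene_count: int,
                  gene_markers: dict[str, list[str]] | dict[str, np.ndarray],
                  index: "_StudyIndex | pd.Series",
                  config: EnrichmentConfig,
                  rng: np.random.Generator | None = None) -> np.ndarray:
    """Permutation null: statistics of random same-size gene sets.

    Gene labels are permuted — ``set_gene_count`` genes drawn without
    replacement from the mapped-gene universe per permutation — while
    each gene keeps its own markers; the permuted set's markers are
    deduplicated before scoring. ``index`` is either a Series of all
    marker p-values indexed by marker id or a prebuilt study index.
    """
    genes = sorted(gene_markers)
    if set_gene_count > len(genes):
        raise ValueError(
            f"set_gene_count {set_gene_count} exceeds mapped-gene universe "
            f"of {len(genes)}")
    if not isinstance(index, _StudyIndex):
        index = _StudyIndex(index, config)
    if rng is None:
        rng = np.random.default_rng(config.seed)
    per_gene_idx = [
        np.array([index.pos_of[m] for m in gene_markers[g]
                  if m in index.pos_of], dtype=np.intp)
        for g in genes
    ]
    out = np.empty(config.n_perm)
    n_genes = len(genes)
    for i in range(config.n_perm):
        pick = rng.choice(n_genes, size=set_gene_count, replace=False)
        idx = np.unique(np.concatenate([per_gene_idx[j] for j in pick]))
        if idx.size == 0:
            out[i] = 0.0
            continue
        out[i] = index.chi_for_marker_idx(idx)
    return out


def estimate_pvalue(observed_stat: float, null_stats: np.ndarray
                    ) -> tuple[float, float]:
    """Gaussian-approximation z and one-sided upper-tail p from a null."""
    null_stats = np.asarray(null_stats, dtype=float)
    if null_stats.size < 2:
        raise ValueError("need at least 2 null statistics")
    mean = float(null_stats.mean())
    sd = float(null_stats.std(ddof=1))
    if sd == 0.0:
        raise ValueError(
            "null distribution has zero variance; increase n_perm or check "
            "for degenerate input")
    z = (observed_stat - mean) / sd
    return z, float(stats.norm.sf(z))


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted values, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0,1]")
    return multipletests(p, method="fdr_bh")[1]


def run_msea(assocs: pd.DataFrame, mapping: pd.DataFrame,
             sets: GeneSetCollection,
             config: EnrichmentConfig | None = None) -> pd.DataFrame:
    """Score every gene set of a study; returns the MSEA result table.

    ``mapping`` must already be restricted to the study's (QC'd,
    LD-pruned) markers. Sets with fewer than ``min_set_genes`` mapped
    genes are skipped with a logged reason. Permutation nulls depend
    only on the mapped-gene count of a set, so they are cached by that
    count across sets.
    """
    config = config or EnrichmentConfig()
    config.validate()
    marker_p = assocs.set_index("marker_id")["p_value"]
    mapping = mapping.loc[mapping["marker_id"].isin(marker_p.index)]
    gm = gene_to_markers(mapping)
    if not gm:
        raise ValueError("no genes with mapped markers in this study")
    index = _StudyIndex(marker_p, config)
    rng = np.random.default_rng(config.seed)
    null_cache: dict[int, np.ndarray] = {}

    rows = []
    for set_id in sets:
        genes = [g for g in sets[set_id] if g in gm]
        if len(genes) < config.min_set_genes:
            log.info("skipping set %s: %d mapped genes < min_set_genes=%d",
                     set_id, len(genes), config.min_set_genes)
            continue
        idx = np.unique(np.concatenate([
            np.array([index.pos_of[m] for m in gm[g]], dtype=np.intp)
            for g in genes]))
        chi = index.chi_for_marker_idx(idx)
        n_genes = len(genes)
        if n_genes not in null_cache:
            null_cache[n_genes] = generate_null(n_genes, gm, index, config,
                                                rng=rng)
        null = null_cache[n_genes]
        z, p = estimate_pvalue(chi, null)
        rows.append((set_id, chi, z, p, np.nan, n_genes, int(idx.size),
                     float(null.mean()), float(null.std(ddof=1))))
    if not rows:
        raise ValueError(
            "no testable set: every set has fewer mapped genes than "
            f"min_set_genes={config.min_set_genes}")
    out = pd.DataFrame(rows, columns=RESULT_COLUMNS)
    out["fdr"] = bh_fdr(out["p_value"])
    return out


def msea_on_gene_stats(gene_stats: dict[str, float] | pd.Series,
                       sets: GeneSetCollection,
                       config: EnrichmentConfig | None = None) -> pd.DataFrame:
    """MSEA over per-gene p-values (e.g. gene-trait correlation p).

    Runs the identical machinery with a degenerate one-marker-per-gene
    mapping, so it reduces exactly to ``run_msea`` when each gene has a
    single marker carrying its p-value.
    """
    if isinstance(gene_stats, dict):
        gene_stats = pd.Series(gene_stats)
    assocs = pd.DataFrame({
        "marker_id": [f"stat:{g}" for g in gene_stats.index],
        "p_value": gene_stats.to_numpy(dtype=float),
    })
    mapping = pd.DataFrame({
        "marker_id": assocs["marker_id"],
        "gene_id": list(gene_stats.index),
        "scheme": "combined",
        "tissue": "",
    })
    return run_msea(assocs, mapping, sets, config)
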