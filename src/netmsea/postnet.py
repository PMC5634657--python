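"""Key-driver prioritization and downstream validation statistics.

After the consensus key drivers (KDs) are known, this module runs the
post-network stages: treating each KD's combined cross-tissue one-edge
neighborhood as a gene set and ranking it by Meta-MSEA against each
disease's GWAS studies; enrichment of KD subnetworks for known disease
genes; inference of the direction of a KD's genetic effect across two
diseases from harmonized signed betas; breadth-first neighbor-level
overlap with differentially expressed genes; and gene-trait
correlation checks for KDs and their subnetworks.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .annotate import fisher_enrichment
from .containers import GeneSetCollection, WeightedNetwork
from .kda import extract_subnetwork
from .meta import run_meta_msea
from .msea import EnrichmentConfig, msea_on_gene_stats, run_msea

log = logging.getLogger(__name__)


@dataclass
class DirectionalityCall:
    """Sign-concordance verdict for one gene between two diseases."""

    gene: str
    n_variants: int
    prop_concordant: float
    z: float
    p: float
    call: str                 # consistent | opposite | uncertain
    mapping_mode: str         # mode that determined the call

    def to_dict(self) -> dict:
        return self.__dict__.copy()


def combined_subnetwork(networks: list[WeightedNetwork], gene: str
                        ) -> tuple[frozenset[str], list[str]]:
    """Union of `gene`'s one-edge neighborhoods across tissue networks.

    Returns (neighbor genes, tissues where the gene is present).
    """
    neighbors: set[str] = set()
    tissues = []
    for net in networks:
        if gene in net:
            neighbors.update(net.neighbors(gene))
            tissues.append(net.tissue)
    neighbors.discard(gene)
    return frozenset(neighbors), tissues


def prioritize_kds(consensus_genes: list[str],
                   networks: list[WeightedNetwork],
                   disease_inputs: dict[str, dict[str, tuple[pd.DataFrame,
                                                             pd.DataFrame]]],
                   config: EnrichmentConfig | None = None,
                   fdr_each: float = 0.10) -> pd.DataFrame:
    """Rank consensus KDs by Meta-MSEA of their subnetworks per disease.

    ``disease_inputs`` maps disease → study → (associations, mapping).
    Each KD's combined cross-tissue neighborhood becomes a gene set;
    per disease, MSEA runs in every study and the z-scores combine via
    Stouffer with BH FDR across KDs. KDs pass when meta-FDR <
    ``fdr_each`` for every disease. KDs whose subnetwork falls below
    the minimum testable size in all studies are skipped with a log.
    """
    config = config or EnrichmentConfig()
    subnet_sets = GeneSetCollection()
    tissues_by_kd = {}
    for gene in consensus_genes:
        nbrs, tissues = combined_subnetwork(networks, gene)
        if not nbrs:
            log.info("KD %s has an empty subnetwork; skipped", gene)
            continue
        subnet_sets.add(gene, nbrs)
        tissues_by_kd[gene] = tissues
    if len(subnet_sets) == 0:
        return pd.DataFrame()

    rows: dict[str, dict] = {
        g: {"gene": g, "tissues": ",".join(tissues_by_kd[g]),
            "subnet_size": len(subnet_sets[g])}
        for g in subnet_sets}
    diseases = sorted(disease_inputs)
    for disease in diseases:
        per_study = {}
        for study, (assocs, mapping) in disease_inputs[disease].items():
            try:
                per_study[study] = run_msea(assocs, mapping, subnet_sets,
                                            config)
            except ValueError as exc:
                log.info("disease %s study %s: %s", disease, study, exc)
        if not per_study:
            raise ValueError(f"no testable study for disease {disease}")
        meta = run_meta_msea(per_study, sig_fdr=fdr_each).set_index("set_id")
        for g in rows:
            if g in meta.index:
                rows[g][f"p_{disease}"] = meta.loc[g, "meta_p"]
                rows[g][f"fdr_{disease}"] = meta.loc[g, "meta_fdr"]
            else:
                rows[g][f"p_{disease}"] = np.nan
                rows[g][f"fdr_{disease}"] = np.nan
    out = pd.DataFrame(list(rows.values()))
    passed = np.ones(len(out), dtype=bool)
    for disease in diseases:
        passed &= (out[f"fdr_{disease}"] < fdr_each).fillna(False)
    out["prioritized"] = passed
    sort_cols = [f"p_{d}" for d in diseases]
    return out.sort_values(sort_cols, kind="mergesort", ignore_index=True)


def known_gene_enrichment(subnet_genes: frozenset[str] | set[str],
                          catalog: frozenset[str] | set[str],
                          universe: set[str] | list[str]
                          ) -> tuple[float, float]:
    """Fold enrichment and Fisher p of a subnetwork for known genes."""
    universe = frozenset(universe)
    if not universe:
        raise ValueError("empty universe")
    sub = frozenset(subnet_genes) & universe
    cat = frozenset(catalog) & universe
    k = len(sub & cat)
    return fisher_enrichment(k, len(sub), len(cat), len(universe))


def _harmonize(gwas_a: pd.DataFrame, gwas_b: pd.DataFrame
               ) -> pd.DataFrame:
    """Align effect alleles of study b to study a; drop irreconcilable rows.

    Both tables need marker_id, beta, effect_allele, other_allele. The
    sign of a study-b beta is flipped when its effect allele equals
    study a's other allele.
    """
    a = gwas_a.set_index("marker_id")
    b = gwas_b.set_index("marker_id")
    shared = a.index.intersection(b.index)
    rows = []
    for m in shared:
        ea_a, oa_a = a.loc[m, "effect_allele"], a.loc[m, "other_allele"]
        ea_b, oa_b = b.loc[m, "effect_allele"], b.loc[m, "other_allele"]
        beta_a, beta_b = a.loc[m, "beta"], b.loc[m, "beta"]
        if pd.isna(beta_a) or pd.isna(beta_b):
            continue
        if ea_b == ea_a and oa_b == oa_a:
            pass
        elif ea_b == oa_a and oa_b == ea_a:
            beta_b = -beta_b
        else:
            continue  # irreconcilable alleles
        rows.append((m, float(beta_a), float(beta_b)))
    return pd.DataFrame(rows, columns=["marker_id", "beta_a", "beta_b"])


def sign_concordance_test(beta_a: np.ndarray, beta_b: np.ndarray
                          ) -> tuple[float, float, float]:
    """(proportion concordant, z, two-sided p) for sign agreement.

    z = (p_hat - 0.5) / sqrt(0.25/n): a binomial z-test against the
    50% agreement expected when effects are unrelated.
    """
    n = len(beta_a)
    if n == 0:
        raise ValueError("no variants")
    concordant = np.sign(beta_a) == np.sign(beta_b)
    p_hat = float(concordant.mean())
    z = (p_hat - 0.5) / math.sqrt(0.25 / n)
    p = 2.0 * float(stats.norm.sf(abs(z)))
    return p_hat, z, min(p, 1.0)


def infer_direction(gene: str, gwas_a: pd.DataFrame, gwas_b: pd.DataFrame,
                    mappings: dict[str, pd.DataFrame],
                    alpha: float = 0.05) -> DirectionalityCall:
    """Classify a gene's effect direction across two diseases.

    ``mappings`` maps mode name (e.g. "eqtl", "eqtl_plus_distance") to
    a marker→gene table; per mode, the gene's variants available in
    both studies are harmonized to shared reference alleles and the
    proportion with agreeing beta signs is z-tested against 0.5. The
    call is "consistent" (or "opposite") when the departure is
    significant at `alpha` in at least one mode with the proportion
    above (below) 0.5; otherwise "uncertain". If significant modes
    disagree, the smaller p wins. Swapping the two studies never
    changes the call class.
    """
    best: tuple[float, float, float, int, str] | None = None
    for mode, mapping in mappings.items():
        variants = mapping.loc[mapping["gene_id"] == gene,
                               "marker_id"].unique()
        sub_a = gwas_a.loc[gwas_a["marker_id"].isin(variants)]
        sub_b = gwas_b.loc[gwas_b["marker_id"].isin(variants)]
        merged = _harmonize(sub_a, sub_b)
        if merged.empty:
            continue
        p_hat, z, p = sign_concordance_test(
            merged["beta_a"].to_numpy(), merged["beta_b"].to_numpy())
        if best is None or p < best[2]:
            best = (p_hat, z, p, len(merged), mode)
    if best is None:
        log.warning("gene %s: no harmonizable variants in any mapping mode",
                    gene)
        return DirectionalityCall(gene, 0, float("nan"), float("nan"),
                                  float("nan"), "uncertain", "none")
    p_hat, z, p, n, mode = best
    if p < alpha and p_hat > 0.5:
        call = "consistent"
    elif p < alpha and p_hat < 0.5:
        call = "opposite"
    else:
        call = "uncertain"
    return DirectionalityCall(gene, n, p_hat, z, p, call, mode)


def bfs_shells(net: WeightedNetwork, source: str, max_level: int
               ) -> dict[int, list[str]]:
    """Exact-distance shells 1..max_level around `source`."""
    if source not in net:
        raise ValueError(f"gene {source!r} not in network")
    dist = nx.single_source_shortest_path_length(net.graph, source,
                                                 cutoff=max_level)
    shells: dict[int, list[str]] = {lvl: [] for lvl in range(1, max_level + 1)}
    for node, d in dist.items():
        if 1 <= d <= max_level:
            shells[d].append(node)
    return {lvl: sorted(nodes) for lvl, nodes in shells.items()}


def neighbor_level_overlap(net: WeightedNetwork, kd: str,
                           deg_genes: frozenset[str] | set[str],
                           universe: set[str] | list[str],
                           max_level: int = 4) -> pd.DataFrame:
    """Per-shell Fisher overlap of a KD's neighbors with DEG genes.

    Shells at exact breadth-first distance 1..max_level from the KD are
    each tested for overlap with `deg_genes` against `universe`;
    Bonferroni correction spans the non-empty levels tested.
    """
    universe = frozenset(universe)
    deg = frozenset(deg_genes) & universe
    shells = bfs_shells(net, kd, max_level)
    tested = [lvl for lvl, nodes in shells.items() if nodes]
    rows = []
    for lvl in range(1, max_level + 1):
        nodes = frozenset(shells[lvl]) & universe
        if not nodes:
            rows.append((lvl, 0, 0, np.nan, np.nan, np.nan))
            continue
        k = len(nodes & deg)
        fold, p = fisher_enrichment(k, len(nodes), len(deg), len(universe))
        bonf = min(p * len(tested), 1.0)
        rows.append((lvl, len(nodes), k, fold, p, bonf))
    return pd.DataFrame(rows, columns=["level", "n_genes", "overlap",
                                       "fold", "p_value", "bonferroni_p"])


def gene_trait_validation(corr_table: pd.DataFrame, kds: list[str],
                          subnets: GeneSetCollection,
                          config: EnrichmentConfig | None = None
                          ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Gene-trait correlation checks for KDs and their subnetworks.

    ``corr_table`` has columns gene_id, trait, r, p_value (one row per
    gene × trait). Per KD: the Pearson r/p per trait with three
    multiplicity tiers (nominal; Bonferroni over KDs; Bonferroni over
    KD × trait pairs). Per subnetwork: gene-level MSEA of the trait
    p-values. KDs absent from the table are reported untested.
    """
    config = config or EnrichmentConfig()
    traits = sorted(corr_table["trait"].unique())
    n_kd = len(kds)
    n_pair = n_kd * len(traits)
    kd_rows = []
    indexed = corr_table.set_index(["gene_id", "trait"])
    for kd in kds:
        for trait in traits:
            try:
                row = indexed.loc[(kd, trait)]
            except KeyError:
                kd_rows.append((kd, trait, np.nan, np.nan, False, False,
                                False, "untested"))
                continue
            r, p = float(row["r"]), float(row["p_value"])
            if not np.isfinite(r):
                kd_rows.append((kd, trait, np.nan, np.nan, False, False,
                                False, "untested"))
                continue
            kd_rows.append((kd, trait, r, p, p < 0.05,
                            p * n_kd < 0.05, p * n_pair < 0.05, "tested"))
    kd_report = pd.DataFrame(
        kd_rows, columns=["gene", "trait", "r", "p_value", "sig_nominal",
                          "sig_kd_corrected", "sig_kd_trait_corrected",
                          "status"])

    subnet_rows = []
    for trait in traits:
        sub = corr_table.loc[corr_table["trait"] == trait]
        gene_p = sub.set_index("gene_id")["p_value"].dropna()
        try:
            res = msea_on_gene_stats(gene_p, subnets, config)
        except ValueError as exc:
            log.info("trait %s: %s", trait, exc)
            continue
        res = res.assign(trait=trait)
        subnet_rows.append(res)
    subnet_report = (pd.concat(subnet_rows, ignore_index=True)
                     if subnet_rows else pd.DataFrame())
    return kd_report, subnet_report
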