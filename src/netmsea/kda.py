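"""Weighted key-driver analysis (wKDA) on gene-gene networks.

Hub genes — nodes whose degree is in the top quartile of the network —
are tested for enrichment of a disease gene set in their one-edge
neighborhood. Edge weights are folded into node strengths (sum of a
neighbor's edge weights within the neighborhood, hub edges included)
and the observed value is the strength-weighted module share of the
neighborhood rescaled to a count:

    O = N_k * strength(neighbors in module) / strength(all neighbors)
    E = N_k * N_p / N            (the hypergeometric mean)
    statistic = (O - E) / sqrt(E + kappa)

With all edge weights equal, O degenerates to the plain count of
module genes among the neighbors. Significance comes from permuting
the gene labels of the network (structure and weights fixed) and
fitting a Gaussian to the permuted statistics; Bonferroni correction
is applied jointly across all (hub, module, tissue) tests.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import GeneSetCollection, WeightedNetwork

log = logging.getLogger(__name__)

KD_COLUMNS = ["hub_gene", "tissue", "module_id", "n_neighbors",
              "n_module_genes", "network_order", "observed", "expected",
              "statistic", "p_value", "bonferroni_p"]


def union_networks(networks: list[WeightedNetwork]) -> WeightedNetwork:
    """Tissue-level union; edge weight = number of datasets containing it."""
    if not networks:
        raise ValueError("no networks to combine")
    tissues = {n.tissue for n in networks}
    if len(tissues) > 1:
        raise ValueError(f"union requires one tissue, got {sorted(tissues)}")
    counts: dict[tuple[str, str], int] = {}
    for net in networks:
        for a, b in net.graph.edges:
            key = (a, b) if a <= b else (b, a)
            counts[key] = counts.get(key, 0) + 1
    out = WeightedNetwork(tissue=networks[0].tissue,
                          source_datasets=len(networks))
    for (a, b), c in counts.items():
        out.add_edge(a, b, float(c))
    return out


def select_hubs(net: WeightedNetwork, top_fraction: float = 0.25
                ) -> list[str]:
    """Nodes whose degree reaches the top `top_fraction` of all degrees.

    The cutoff is the nearest-rank (1 - top_fraction) percentile of the
    node-degree distribution; ties at the cutoff are included.
    """
    if net.order == 0:
        raise ValueError("empty network")
    nodes = net.nodes
    degrees = np.array([net.degree(v) for v in nodes])
    rank = max(int(math.ceil((1.0 - top_fraction) * len(nodes))), 1)
    cutoff = np.sort(degrees)[rank - 1]
    return [v for v, d in zip(nodes, degrees) if d >= cutoff]


@dataclass
class Subnetwork:
    """A hub's neighborhood with per-node strengths (hub excluded)."""

    hub: str
    tissue: str
    nodes: list[str]
    strengths: dict[str, float]

    @property
    def total_strength(self) -> float:
        return sum(self.strengths.values())


def extract_subnetwork(net: WeightedNetwork, hub: str,
                       depth: int = 1) -> Subnetwork:
    """Nodes within `depth` edges of the hub, with neighborhood strengths.

    A node's strength is the sum of the weights of its edges to other
    neighborhood members and to the hub; the hub itself carries no
    strength. Depths beyond 1 are for reporting-level neighbor
    analyses, not for scoring.
    """
    if hub not in net:
        raise ValueError(f"hub {hub!r} not in network")
    g = net.graph
    shell = {hub}
    frontier = {hub}
    for _ in range(depth):
        frontier = {w for v in frontier for w in g.neighbors(v)} - shell
        shell |= frontier
    members = shell
    strengths = {}
    for v in sorted(members - {hub}):
        s = sum(d["weight"] for _, w, d in g.edges(v, data=True)
                if w in members)
        strengths[v] = float(s)
    return Subnetwork(hub=hub, tissue=net.tissue,
                      nodes=sorted(members - {hub}), strengths=strengths)


def wkda_score(subnet: Subnetwork, module_genes: frozenset[str] | set[str],
               network_order: int, kappa: float = 1.0,
               n_module_genes: int | None = None, weighted: bool = True
               ) -> tuple[float, float, float]:
    """(O, E, statistic) for one hub against one module.

    `n_module_genes` is the module size within the network (defaults
    to |module_genes|, callers should pass the in-network count).
    `weighted=False` replaces the strength-weighted share with a plain
    membership count.
    """
    n_k = len(subnet.nodes)
    if not network_order >= n_k >= 1:
        raise ValueError("need network_order >= n_neighbors >= 1")
    n_p = len(module_genes) if n_module_genes is None else n_module_genes
    expected = n_k * n_p / network_order
    if weighted:
        total = subnet.total_strength
        if total <= 0:
            raise ValueError(f"zero total strength around hub {subnet.hub!r}")
        in_module = sum(subnet.strengths[v] for v in subnet.nodes
                        if v in module_genes)
        observed = n_k * in_module / total
    else:
        observed = float(sum(1 for v in subnet.nodes if v in module_genes))
    statistic = (observed - expected) / math.sqrt(expected + kappa)
    return observed, expected, statistic


def run_wkda(modules: GeneSetCollection, networks: list[WeightedNetwork],
             n_perm: int = 10_000, kappa: float = 1.0,
             top_fraction: float = 0.25, seed: int = 0,
             weighted: bool = True) -> pd.DataFrame:
    """Score every (hub, module, tissue) triple; returns the KD table.

    For each network, hub candidates are screened by degree and scored
    against every module; the null relabels the network's gene
    positions uniformly at random (equivalently, permutes the module
    membership indicator over nodes) `n_perm` times with structure and
    weights fixed, and a Gaussian fitted to the null gives the p-value.
    Bonferroni correction spans all tests performed across networks.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for net in networks:
        hubs = select_hubs(net, top_fraction)
        if not hubs:
            log.warning("network %s: no hub passes screening", net.tissue)
            continue
        nodes = net.nodes
        node_pos = {v: i for i, v in enumerate(nodes)}
        n_order = len(nodes)
        subnets = {h: extract_subnetwork(net, h) for h in hubs}
        # per-hub neighbor index/strength arrays for vectorized nulls
        nbr_idx = {h: np.array([node_pos[v] for v in sn.nodes], dtype=np.intp)
                   for h, sn in subnets.items()}
        nbr_s = {h: np.array([sn.strengths[v] for v in sn.nodes])
                 for h, sn in subnets.items()}
        for module_id in modules:
            module = modules[module_id]
            member = np.array([v in module for v in nodes])
            n_p = int(member.sum())
            if n_p == 0:
                log.info("module %s disjoint from network %s",
                         module_id, net.tissue)
            # one label permutation rescoring all hubs, n_perm times
            perms = np.tile(member, (n_perm, 1))
            perms = rng.permuted(perms, axis=1).astype(float)
            for h in hubs:
                sn = subnets[h]
                n_k = len(sn.nodes)
                if n_k == 0:
                    continue
                obs, exp, chi = wkda_score(
                    sn, module, n_order, kappa=kappa,
                    n_module_genes=n_p, weighted=weighted)
                s = nbr_s[h]
                total = s.sum()
                if weighted and total > 0:
                    null_obs = n_k * (perms[:, nbr_idx[h]] @ s) / total
                else:
                    null_obs = perms[:, nbr_idx[h]].sum(axis=1)
                null_chi = (null_obs - exp) / math.sqrt(exp + kappa)
                sd = null_chi.std(ddof=1)
                if sd == 0:
                    p = 1.0 if chi <= null_chi.mean() else 0.0
                else:
                    p = float(stats.norm.sf((chi - null_chi.mean()) / sd))
                rows.append((h, net.tissue, module_id, n_k, n_p, n_order,
                             obs, exp, chi, p))
    if not rows:
        log.warning("wKDA produced no results")
        return pd.DataFrame(columns=KD_COLUMNS)
    out = pd.DataFrame(rows, columns=KD_COLUMNS[:-1])
    n_tests = len(out)
    out["bonferroni_p"] = np.minimum(out["p_value"] * n_tests, 1.0)
    return out.sort_values(["p_value", "hub_gene"], kind="mergesort",
                           ignore_index=True)


def kd_consensus(results_by_network_type: dict[str, pd.DataFrame],
                 alpha: float = 0.05) -> pd.DataFrame:
    """Key drivers significant in every network type.

    A gene qualifies when its Bonferroni-corrected p is below `alpha`
    in at least one tissue in *each* network type (e.g. Bayesian and
    tissue-expression networks); the record keeps the supporting
    tissues and modules per type.
    """
    if len(results_by_network_type) < 2:
        raise ValueError(
            "consensus needs results from at least two network types, got "
            f"{sorted(results_by_network_type)}")
    hits = {}
    for net_type, df in results_by_network_type.items():
        sig = df.loc[df["bonferroni_p"] < alpha]
        hits[net_type] = sig.groupby("hub_gene").agg(
            tissues=("tissue", lambda t: sorted(set(t))),
            modules=("module_id", lambda m: sorted(set(m))),
            best_p=("bonferroni_p", "min"))
    common = set.intersection(*(set(h.index) for h in hits.values()))
    rows = []
    for gene in sorted(common):
        rec = {"hub_gene": gene}
        tissues, mods = set(), set()
        for net_type, h in hits.items():
            rec[f"best_p_{net_type}"] = h.loc[gene, "best_p"]
            tissues.update(h.loc[gene, "tissues"])
            mods.update(h.loc[gene, "modules"])
        rec["tissues"] = ",".join(sorted(tissues))
        rec["modules"] = ",".join(sorted(mods))
        rows.append(rec)
    return pd.DataFrame(rows)
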