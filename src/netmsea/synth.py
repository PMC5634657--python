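"""Synthetic study generator with planted, recoverable truth.

Every downstream stage of the pipeline (QC + LD pruning, marker-set
enrichment, meta-analysis, key-driver analysis, validation statistics)
can be exercised on studies produced here, with a `PlantedTruth` record
naming the enriched module, the planted network hub and the intended
effect-direction class of each gene.

The generative model is deliberately simple and analyzable:

* marker p-values are Uniform(0,1) under the null and Beta(a,1) with
  a < 1 for the planted fraction of markers mapped to the planted
  module (Beta(1,1) recovers the uniform null exactly);
* LD is block-diagonal — constant r² inside consecutive marker blocks,
  zero between blocks — so the LD-pruning oracle is exact;
* the marker→gene map is many-to-many with a Poisson-distributed
  number of markers per gene;
* effect signs between two simulated diseases agree with a stated
  per-marker concordance probability.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import networkx as nx
import numpy as np
import pandas as pd

from .containers import GeneSetCollection, LdTable, WeightedNetwork

log = logging.getLogger(__name__)

#: per-marker sign-agreement probability used when a gene is assigned a
#: planted direction class
DIRECTION_CONCORDANCE = {"consistent": 0.95, "opposite": 0.05, "uncertain": 0.5}


@dataclass(frozen=True)
class SyntheticStudySpec:
    """Parameters of one synthetic GWAS study.

    ``enrichment_shape`` is the ``a`` of a Beta(a, 1) p-value law for
    planted markers; a < 1 produces the small-p excess that marker-set
    enrichment is designed to detect.
    """

    n_markers: int = 2000
    n_genes: int = 400
    ld_block_size: int = 5
    within_block_r2: float = 0.8
    markers_per_gene_mean: float = 5.0
    markers_per_gene_dispersion: float = 1.0
    planted_module: str | None = None
    planted_fraction: float = 0.5
    enrichment_shape: float = 0.2
    beta_sign_concordance: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        if not (self.n_markers >= self.n_genes >= 1):
            raise ValueError("need n_markers >= n_genes >= 1")
        if not 0.0 <= self.planted_fraction <= 1.0:
            raise ValueError("planted_fraction must lie in [0,1]")
        if self.enrichment_shape <= 0:
            raise ValueError("enrichment_shape (Beta a) must be > 0")
        if not 0.0 <= self.within_block_r2 <= 1.0:
            raise ValueError("within_block_r2 must lie in [0,1]")
        if not 0.0 <= self.beta_sign_concordance <= 1.0:
            raise ValueError("beta_sign_concordance must lie in [0,1]")
        if self.ld_block_size < 1:
            raise ValueError("ld_block_size must be >= 1")


@dataclass
class PlantedTruth:
    """Ground truth planted into a synthetic study."""

    enriched_set_ids: list[str] = field(default_factory=list)
    planted_hub_ids: list[str] = field(default_factory=list)
    direction_class_by_gene: dict[str, str] = field(default_factory=dict)


@dataclass
class SyntheticStudy:
    """One simulated study: associations for two diseases over a shared map."""

    associations: pd.DataFrame        # disease A: marker_id, p_value, beta, ...
    associations_b: pd.DataFrame      # disease B, same markers and alleles
    ld: LdTable
    mapping: pd.DataFrame             # marker_id, gene_id, scheme, tissue
    truth: PlantedTruth
    spec: SyntheticStudySpec


def _gene_ids(n: int) -> list[str]:
    return [f"G{i:05d}" for i in range(1, n + 1)]


def _marker_ids(n: int) -> list[str]:
    return [f"rs{i:07d}" for i in range(1, n + 1)]


def _markers_per_gene(spec: SyntheticStudySpec, rng: np.random.Generator,
                      n_genes: int) -> np.ndarray:
    """Draw per-gene marker counts (>= 1).

    A dispersion above the mean switches from Poisson to negative
    binomial so gene "loci" can have heavy-tailed SNP counts.
    """
    mean = max(spec.markers_per_gene_mean, 1.0)
    if spec.markers_per_gene_dispersion > mean:
        # NB parameterised by mean/variance of the (count - 1) part
        mu, var = mean - 1.0, spec.markers_per_gene_dispersion
        p = mu / var
        r = mu * p / (1 - p) if p < 1 else 1.0
        extra = rng.negative_binomial(max(r, 1e-6), min(p, 1 - 1e-9), n_genes)
    else:
        extra = rng.poisson(mean - 1.0, n_genes)
    return extra.astype(int) + 1


def _block_ld(marker_ids: list[str], block_size: int, r2: float) -> LdTable:
    ld = LdTable()
    if r2 <= 0 or block_size < 2:
        return ld
    for start in range(0, len(marker_ids), block_size):
        block = marker_ids[start:start + block_size]
        for i in range(len(block)):
            for j in range(i + 1, len(block)):
                ld.add(block[i], block[j], r2)
    return ld


def simulate_study(spec: SyntheticStudySpec,
                   modules: GeneSetCollection | None = None,
                   direction_class_by_gene: dict[str, str] | None = None,
                   mapping: pd.DataFrame | None = None,
                   ) -> SyntheticStudy:
    """Simulate one two-disease GWAS study.

    ``modules`` supplies the gene-set collection from which
    ``spec.planted_module`` is taken; omitting it with a planted module
    named is a configuration error. Non-planted markers have
    p ~ Uniform(0,1); the planted fraction of the markers mapped to the
    planted module have p ~ Beta(a, 1) *in both diseases* (a shared
    genetic signal). Betas are standard normal in magnitude; the sign
    of the disease-B beta agrees with disease A's with probability
    ``beta_sign_concordance`` (or the per-gene class probability when a
    direction class is planted for the gene).
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)

    genes = _gene_ids(spec.n_genes)
    markers = _marker_ids(spec.n_markers)

    if spec.planted_module is not None:
        if modules is None or spec.planted_module not in modules:
            raise ValueError(
                f"planted module {spec.planted_module!r} absent from the "
                "supplied module collection")
        planted_genes = set(modules[spec.planted_module])
        missing = planted_genes - set(genes)
        if missing:
            raise ValueError(
                f"planted module references genes outside the study universe: "
                f"{sorted(missing)[:5]}")
    else:
        planted_genes = set()

    # many-to-many marker -> gene assignment; markers sampled per gene.
    # A caller-supplied mapping (e.g. shared across cohorts, as SNP
    # annotations are in a real multi-cohort design) is used verbatim.
    if mapping is None:
        counts = _markers_per_gene(spec, rng, spec.n_genes)
        rows = []
        marker_idx = np.arange(spec.n_markers)
        for g, k in zip(genes, counts):
            chosen = rng.choice(marker_idx, size=min(k, spec.n_markers),
                                replace=False)
            rows.extend((markers[i], g) for i in chosen)
        mapping = pd.DataFrame(rows, columns=["marker_id", "gene_id"])
        mapping["scheme"] = "combined"
        mapping["tissue"] = ""
        mapping = mapping.drop_duplicates(["marker_id", "gene_id"],
                                          ignore_index=True)
    else:
        unknown = set(mapping["marker_id"]) - set(markers)
        if unknown:
            raise ValueError(
                f"supplied mapping references unknown markers: "
                f"{sorted(unknown)[:5]}")
        mapping = mapping.copy()

    marker_pos = {m: i for i, m in enumerate(markers)}

    # planted markers: a planted_fraction of the markers mapped to the module
    p = rng.uniform(size=spec.n_markers)
    planted_marker_ids: set[str] = set()
    if planted_genes and spec.planted_fraction > 0:
        module_markers = mapping.loc[
            mapping["gene_id"].isin(planted_genes), "marker_id"].unique()
        n_plant = int(round(spec.planted_fraction * len(module_markers)))
        chosen = rng.choice(module_markers, size=n_plant, replace=False)
        planted_marker_ids = set(chosen)
        idx = [marker_pos[m] for m in chosen]
        p[idx] = rng.beta(spec.enrichment_shape, 1.0, size=len(idx))
    p = np.clip(p, np.nextafter(0.0, 1.0), 1.0)

    # disease B p-values share the planting (a shared signal across diseases)
    p_b = rng.uniform(size=spec.n_markers)
    if planted_marker_ids:
        idx = [marker_pos[m] for m in planted_marker_ids]
        p_b[idx] = rng.beta(spec.enrichment_shape, 1.0, size=len(idx))
    p_b = np.clip(p_b, np.nextafter(0.0, 1.0), 1.0)

    # betas and alleles; sign concordance between the two diseases
    beta_a = rng.normal(size=spec.n_markers)
    concordance = np.full(spec.n_markers, spec.beta_sign_concordance)
    direction_class_by_gene = dict(direction_class_by_gene or {})
    if direction_class_by_gene:
        marker_to_class: dict[str, str] = {}
        for m, g in mapping[["marker_id", "gene_id"]].itertuples(index=False):
            if g in direction_class_by_gene:
                marker_to_class.setdefault(m, direction_class_by_gene[g])
        for m, cls in marker_to_class.items():
            concordance[marker_pos[m]] = DIRECTION_CONCORDANCE[cls]
    agree = rng.uniform(size=spec.n_markers) < concordance
    beta_b = np.abs(rng.normal(size=spec.n_markers))
    beta_b = np.where(agree, np.sign(beta_a), -np.sign(beta_a)) * beta_b

    alleles = rng.choice(list("ACGT"), size=(spec.n_markers, 2))
    same = alleles[:, 0] == alleles[:, 1]
    alleles[same, 1] = np.where(alleles[same, 0] == "A", "G", "A")

    maf = rng.uniform(0.05, 0.5, size=spec.n_markers)
    info = rng.uniform(0.3, 1.0, size=spec.n_markers)

    def assoc_frame(pvals, betas):
        return pd.DataFrame({
            "marker_id": markers,
            "p_value": pvals,
            "beta": betas,
            "effect_allele": alleles[:, 0],
            "other_allele": alleles[:, 1],
            "maf": np.round(maf, 6),
            "info": np.round(info, 6),
        })

    ld = _block_ld(markers, spec.ld_block_size, spec.within_block_r2)

    if not direction_class_by_gene:
        c = spec.beta_sign_concordance
        default_cls = ("consistent" if c >= 0.75
                       else "opposite" if c <= 0.25 else "uncertain")
        direction_class_by_gene = {g: default_cls for g in genes}

    truth = PlantedTruth(
        enriched_set_ids=([spec.planted_module] if spec.planted_module else []),
        planted_hub_ids=[],
        direction_class_by_gene=direction_class_by_gene,
    )
    return SyntheticStudy(
        associations=assoc_frame(p, beta_a),
        associations_b=assoc_frame(p_b, beta_b),
        ld=ld, mapping=mapping, truth=truth, spec=spec,
    )


def simulate_modules(n_modules: int, size_range: tuple[int, int],
                     overlap_jaccard: float, universe: list[str],
                     seed: int = 0) -> GeneSetCollection:
    """Generate overlapping gene-set modules over `universe`.

    Overlap is induced by drawing a fraction f of every module from a
    shared anchor pool of mean-module-size genes; for two modules of
    size s this gives an expected pairwise Jaccard of f²/(2−f²), so
    f = sqrt(2J/(1+J)) targets mean Jaccard J. Accurate (±0.05) for
    J ≤ 0.3; J = 0 yields pairwise-disjoint modules.
    """
    lo, hi = size_range
    if not (1 <= lo <= hi):
        raise ValueError("invalid size_range")
    if hi > len(universe):
        raise ValueError(
            f"max module size {hi} exceeds universe size {len(universe)}")
    if not 0.0 <= overlap_jaccard <= 1.0:
        raise ValueError("overlap_jaccard must lie in [0,1]")
    rng = np.random.default_rng(seed)
    universe = list(universe)
    out = GeneSetCollection()

    if overlap_jaccard == 0.0:
        if n_modules * hi > len(universe):
            raise ValueError(
                f"disjoint modules need n_modules*max_size <= |universe| "
                f"({n_modules}*{hi} > {len(universe)})")
        pool = list(rng.permutation(universe))
        for i in range(n_modules):
            size = int(rng.integers(lo, hi + 1))
            out.add(f"M{i + 1:04d}", pool[:size])
            pool = pool[size:]
        return out

    f = float(np.sqrt(2 * overlap_jaccard / (1 + overlap_jaccard)))
    anchor_size = max(int(round((lo + hi) / 2)), 1)
    anchor = list(rng.choice(universe, size=anchor_size, replace=False))
    rest = [g for g in universe if g not in set(anchor)]
    for i in range(n_modules):
        size = int(rng.integers(lo, hi + 1))
        k = min(int(round(f * size)), anchor_size)
        from_anchor = rng.choice(anchor, size=k, replace=False)
        n_rest = size - k
        if n_rest > len(rest):
            raise ValueError(
                f"universe too small for requested module size {size} at "
                f"overlap {overlap_jaccard}")
        from_rest = rng.choice(rest, size=n_rest, replace=False)
        out.add(f"M{i + 1:04d}", list(from_anchor) + list(from_rest))
    return out


def simulate_network(n_genes: int, attachment: int,
                     planted_hub_module: frozenset[str] | set[str] | None,
                     planted_neighbor_fraction: float,
                     weight_levels: int = 4,
                     universe: list[str] | None = None,
                     tissue: str = "tissue",
                     seed: int = 0) -> tuple[WeightedNetwork, PlantedTruth]:
    """Scale-free weighted network with a planted module-enriched hub.

    A Barabási–Albert graph supplies the heavy-tailed degree
    distribution; its highest-degree node is designated the planted hub
    and gene labels are arranged so that at least
    ``planted_neighbor_fraction`` of the hub's neighbors carry genes
    from ``planted_hub_module``. Edge weights are integer consistency
    counts in 1..weight_levels.
    """
    if not 0.0 <= planted_neighbor_fraction <= 1.0:
        raise ValueError("planted_neighbor_fraction must lie in [0,1]")
    if weight_levels < 1:
        raise ValueError("weight_levels must be >= 1")
    rng = np.random.default_rng(seed)
    g = nx.barabasi_albert_graph(n_genes, attachment,
                                 seed=int(rng.integers(2**31)))
    if universe is None:
        universe = _gene_ids(n_genes)
    if len(universe) < n_genes:
        raise ValueError("universe smaller than n_genes")
    universe = list(universe)[:n_genes]

    module = sorted(planted_hub_module or [])
    module_in_universe = [m for m in module if m in set(universe)]
    # hub = highest-degree top-quartile node whose neighborhood the module
    # can fill at the requested fraction
    degrees = dict(g.degree())
    order_by_deg = sorted(g.nodes, key=lambda v: (-degrees[v], v))
    n_hub_candidates = max(int(np.ceil(0.25 * len(order_by_deg))), 1)
    hub_node = None
    for v in order_by_deg[:n_hub_candidates]:
        if (int(round(planted_neighbor_fraction * degrees[v]))
                <= len(module_in_universe) or not module_in_universe):
            hub_node = v
            break
    if hub_node is None:
        min_deg = degrees[order_by_deg[n_hub_candidates - 1]]
        raise ValueError(
            f"planted module ({len(module_in_universe)} genes in universe) "
            f"too small to fill {planted_neighbor_fraction:.0%} of any "
            f"top-quartile hub neighborhood (smallest candidate degree "
            f"{min_deg})")
    hub_deg = degrees[hub_node]
    k = int(round(planted_neighbor_fraction * hub_deg))
    if k > len(module_in_universe):
        raise ValueError(
            f"planted module ({len(module_in_universe)} genes in universe) too "
            f"small to fill {k} neighbor slots of a degree-{hub_deg} hub")

    # assign gene labels: hub gets a non-module gene where possible, k of
    # its neighbors get module genes, remaining labels are shuffled
    nodes = list(g.nodes)
    neighbors = sorted(g.neighbors(hub_node))
    chosen_nbrs = list(rng.choice(neighbors, size=k, replace=False))
    module_labels = list(rng.choice(module_in_universe, size=k, replace=False))
    non_module = [u for u in universe if u not in set(module)]
    hub_label = non_module[0] if non_module else universe[0]

    assigned = {hub_node: hub_label}
    assigned.update(dict(zip(chosen_nbrs, module_labels)))
    remaining_labels = [u for u in universe
                        if u != hub_label and u not in set(module_labels)]
    remaining_nodes = [v for v in nodes if v not in assigned]
    rng.shuffle(remaining_labels)
    for v, lab in zip(remaining_nodes, remaining_labels):
        assigned[v] = lab

    net = WeightedNetwork(tissue=tissue, source_datasets=weight_levels)
    for a, b in g.edges:
        w = int(rng.integers(1, weight_levels + 1))
        net.add_edge(assigned[a], assigned[b], float(w))

    truth = PlantedTruth(planted_hub_ids=[hub_label])
    return net, truth


def simulate_gene_stats(universe: list[str],
                        signal_set: frozenset[str] | set[str],
                        effect: float, n_strains: int = 100,
                        trait: str = "trait1",
                        seed: int = 0
                        ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Gene-trait correlation and DEG tables with a planted signal set.

    Strain-level data are actually simulated: a latent trait across
    ``n_strains`` strains, expression of signal genes tracking it with
    slope ``effect`` plus unit noise, background genes pure noise; the
    returned table carries the per-gene Pearson r and p. The DEG table
    comes from a two-group contrast with mean shift ``effect`` in
    signal genes (t-test p, BH FDR).

    Returns (correlation table, DEG table, expression matrix).
    """
    from scipy import stats
    from statsmodels.stats.multitest import multipletests

    if not universe:
        raise ValueError("empty gene universe")
    signal = set(signal_set)
    unknown = signal - set(universe)
    if unknown:
        raise ValueError(f"signal genes outside universe: {sorted(unknown)[:5]}")
    rng = np.random.default_rng(seed)
    trait_vals = rng.normal(size=n_strains)
    rows = []
    expr = {}
    for g in universe:
        slope = effect if g in signal else 0.0
        x = slope * trait_vals + rng.normal(size=n_strains)
        r, p = stats.pearsonr(x, trait_vals)
        rows.append((g, trait, r, p))
        expr[g] = x
    corr = pd.DataFrame(rows, columns=["gene_id", "trait", "r", "p_value"])

    half = n_strains // 2
    group = np.zeros(n_strains)
    group[half:] = 1.0
    deg_rows = []
    for g in universe:
        shift = effect if g in signal else 0.0
        y = shift * group + rng.normal(size=n_strains)
        _, p = stats.ttest_ind(y[:half], y[half:])
        deg_rows.append((g, p))
    deg = pd.DataFrame(deg_rows, columns=["gene_id", "p_value"])
    deg["fdr"] = multipletests(deg["p_value"], method="fdr_bh")[1]

    expr_df = pd.DataFrame(expr).T
    expr_df.index.name = "gene_id"
    expr_df.columns = [f"strain{i + 1}" for i in range(n_strains)]
    return corr, deg, expr_df


def simulate_multi_study(base: SyntheticStudySpec, n_studies: int,
                         modules: GeneSetCollection,
                         seed: int = 0) -> list[SyntheticStudy]:
    """Independent cohorts sharing the planted module and gene universe.

    Each cohort re-draws p-values and betas from its own seed; the
    module collection and the marker→gene map (drawn once, by the
    first cohort) are shared, mimicking the multi-cohort design that
    meta-analysis integrates: annotations are common, association
    noise is not.
    """
    rng = np.random.default_rng(seed)
    studies: list[SyntheticStudy] = []
    shared_mapping = None
    for _ in range(n_studies):
        spec_i = replace(base, seed=int(rng.integers(2**31)))
        study = simulate_study(spec_i, modules=modules,
                               mapping=shared_mapping)
        if shared_mapping is None:
            shared_mapping = study.mapping
        studies.append(study)
    return studies
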