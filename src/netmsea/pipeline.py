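"""End-to-end pipeline orchestration.

Runs the stages in order — GWAS QC + LD pruning → marker→gene mapping
restriction → per-study MSEA → Meta-MSEA per disease → annotation →
wKDA per network type → consensus KDs → subnetwork prioritization →
directionality → validation — from a YAML configuration, writing every
stage table as TSV together with a run manifest (parameters, seed,
input digests). Reruns with identical config and inputs are
bit-identical: the master seed fans out to per-stage seeds through a
stable hash of the stage name.

`generate_fixture_study` materializes a small synthetic multi-cohort
demo (with planted module and planted key driver) in the same
tab-delimited formats the pipeline reads, so a full run needs no
external data.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import annotate as annotate_mod
from . import gwas, kda, mapping as snp2gene, meta as meta_mod, postnet
from .containers import (GeneSetCollection, LdTable, WeightedNetwork,
                         frame_digest, write_tsv)
from .msea import EnrichmentConfig, run_msea
from .synth import (SyntheticStudySpec, simulate_modules, simulate_network,
                    simulate_study)

log = logging.getLogger(__name__)

GWAS_COLUMNS = {"marker_id": "MARKER", "p_value": "PVALUE", "beta": "BETA",
                "effect_allele": "EFFECT_ALLELE",
                "other_allele": "OTHER_ALLELE", "maf": "MAF", "info": "INFO"}


def stage_seed(master: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the master seed."""
    digest = hashlib.sha256(f"{master}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "little") % (2**31)


@dataclass
class StudyBlock:
    name: str
    disease: str
    gwas: str
    ld: str | None = None
    mapping: str | None = None


@dataclass
class PipelineConfig:
    """Validated configuration of one pipeline run."""

    seed: int = 0
    outdir: str = "results/run"
    modules: str | None = None
    pathways: str | None = None
    studies: list[StudyBlock] = dc_field(default_factory=list)
    networks: dict[str, list[str]] = dc_field(default_factory=dict)
    known_genes: str | None = None
    maf_min: float = 0.05
    info_min: float = 0.3
    r2_max: float = 0.5
    drop_bottom_fraction: float = 0.5
    quantiles: tuple[float, ...] | None = None
    kappa: float = 1.0
    n_perm: int = 1000
    min_set_genes: int = 10
    meta_sig_fdr: float = 0.05
    kd_fdr_each: float = 0.10
    bonferroni_alpha: float = 0.05
    kd_top_fraction: float = 0.25

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        thresholds = raw.pop("thresholds", {})
        studies = [StudyBlock(**s) for s in raw.pop("studies", [])]
        networks = raw.pop("networks", {})
        cfg = cls(studies=studies, networks=networks,
                  **{**raw, **thresholds})
        cfg.validate(base=Path(path).parent)
        return cfg

    def validate(self, base: Path | None = None) -> None:
        def resolve(p):
            if p is None:
                return None
            q = Path(p)
            if not q.is_absolute() and base is not None:
                q = base / q
            if not q.exists():
                raise FileNotFoundError(f"configured path {p!r} not found")
            return str(q)

        self.modules = resolve(self.modules)
        self.pathways = resolve(self.pathways)
        self.known_genes = resolve(self.known_genes)
        for s in self.studies:
            s.gwas = resolve(s.gwas)
            s.ld = resolve(s.ld)
            s.mapping = resolve(s.mapping)
        self.networks = {t: [resolve(p) for p in paths]
                         for t, paths in self.networks.items()}
        if not self.studies:
            raise ValueError("config declares no studies")
        if self.modules is None:
            raise ValueError("config declares no module file")

    def enrichment_config(self, stage: str) -> EnrichmentConfig:
        kwargs = dict(kappa=self.kappa, n_perm=self.n_perm,
                      min_set_genes=self.min_set_genes,
                      seed=stage_seed(self.seed, stage))
        if self.quantiles:
            kwargs["quantile_points"] = tuple(self.quantiles)
        return EnrichmentConfig(**kwargs)


def _read_modules(path: str) -> GeneSetCollection:
    if path.endswith(".gmt"):
        return GeneSetCollection.read_gmt(path)
    return GeneSetCollection.from_frame(pd.read_csv(path, sep="\t"))


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all configured stages; returns {stage: result table}.

    Stages without configured inputs (e.g. no network block) are
    skipped with a notice. Every result table is written under
    ``config.outdir`` next to ``manifest.json``.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    results: dict[str, object] = {}
    manifest = {"seed": config.seed,
                "parameters": {k: v for k, v in vars(config).items()
                               if isinstance(v, (int, float, str))},
                "inputs": {}, "stages": []}

    modules = _read_modules(config.modules)
    manifest["inputs"]["modules"] = config.modules

    # ---- stage: prep (QC + LD pruning) and per-study MSEA -------------
    per_disease: dict[str, dict[str, pd.DataFrame]] = {}
    disease_inputs: dict[str, dict] = {}
    study_assocs: dict[str, pd.DataFrame] = {}
    full_assocs: dict[str, dict[str, pd.DataFrame]] = {}
    full_mappings: dict[str, dict[str, pd.DataFrame]] = {}
    for block in config.studies:
        assocs = gwas.read_gwas(block.gwas, GWAS_COLUMNS)
        assocs = gwas.filter_markers(assocs, config.maf_min, config.info_min)
        full_assocs.setdefault(block.disease, {})[block.name] = assocs
        if block.ld:
            ld = LdTable.from_frame(pd.read_csv(block.ld, sep="\t"))
            retained = gwas.prune_ld(assocs, ld, config.r2_max,
                                     config.drop_bottom_fraction)
            assocs = assocs.loc[assocs["marker_id"].isin(set(retained))]
            assocs = assocs.reset_index(drop=True)
        write_tsv(assocs, out / f"prep_{block.name}.tsv")
        study_assocs[block.name] = assocs

        if block.mapping is None:
            log.warning("study %s: no mapping file; MSEA skipped", block.name)
            continue
        mp = pd.read_csv(block.mapping, sep="\t")
        mp.columns = [c.lower() for c in mp.columns]
        mp = mp.rename(columns={"marker": "marker_id", "gene": "gene_id"})
        if "scheme" not in mp:
            mp["scheme"] = "combined"
        if "tissue" not in mp:
            mp["tissue"] = ""
        full_mappings.setdefault(block.disease, {})[block.name] = mp
        mp = snp2gene.restrict_to_markers(mp, set(assocs["marker_id"]))
        res = run_msea(assocs, mp, modules,
                       config.enrichment_config(f"msea:{block.name}"))
        write_tsv(res, out / f"msea_{block.name}.tsv")
        per_disease.setdefault(block.disease, {})[block.name] = res
        disease_inputs.setdefault(block.disease, {})[block.name] = (assocs, mp)
    results["msea"] = per_disease
    manifest["stages"].append("prep")
    manifest["stages"].append("msea")

    # ---- stage: Meta-MSEA per disease ---------------------------------
    meta_by_disease = {}
    sig_modules: dict[str, list[str]] = {}
    for disease, tables in per_disease.items():
        meta_table = meta_mod.run_meta_msea(tables, config.meta_sig_fdr)
        write_tsv(meta_table, out / f"meta_{disease}.tsv")
        meta_by_disease[disease] = meta_table
        sig_modules[disease] = meta_mod.significant_sets(meta_table)
    results["meta"] = meta_by_disease
    results["significant_modules"] = sig_modules
    manifest["stages"].append("meta")

    # ---- stage: annotation (optional) ---------------------------------
    if config.pathways:
        pathways = GeneSetCollection.read_gmt(config.pathways)
        tested = sorted({m for mods in sig_modules.values() for m in mods})
        if tested:
            ann = annotate_mod.annotate_gene_sets(
                modules.subset(tested), pathways,
                modules.universe | pathways.universe)
            write_tsv(ann, out / "annotation.tsv")
            results["annotation"] = ann
        manifest["stages"].append("annotate")
    else:
        log.info("no pathway library configured; annotation skipped")

    # ---- stage: wKDA + consensus (optional) ---------------------------
    if config.networks:
        all_networks: list[WeightedNetwork] = []
        kd_by_type: dict[str, dict[str, pd.DataFrame]] = {}
        for net_type, paths in config.networks.items():
            nets = []
            for p in paths:
                df = pd.read_csv(p, sep="\t")
                for tissue, sub in df.groupby("tissue"):
                    nets.append(WeightedNetwork.from_frame(sub,
                                                           tissue=str(tissue)))
            all_networks.extend(nets)
            for disease, mods in sig_modules.items():
                if not mods:
                    log.warning("disease %s: no significant module; wKDA "
                                "skipped for %s", disease, net_type)
                    continue
                kd = kda.run_wkda(
                    modules.subset(mods), nets,
                    n_perm=config.n_perm, kappa=config.kappa,
                    top_fraction=config.kd_top_fraction,
                    seed=stage_seed(config.seed, f"wkda:{net_type}:{disease}"))
                write_tsv(kd, out / f"kda_{net_type}_{disease}.tsv")
                kd_by_type.setdefault(disease, {})[net_type] = kd
        results["kda"] = kd_by_type

        consensus: dict[str, pd.DataFrame] = {}
        for disease, by_type in kd_by_type.items():
            if len(by_type) >= 2:
                consensus[disease] = kda.kd_consensus(
                    by_type, alpha=config.bonferroni_alpha)
                write_tsv(consensus[disease],
                          out / f"consensus_{disease}.tsv")
        results["consensus"] = consensus
        manifest["stages"] += ["wkda", "consensus"]

        # ---- stage: prioritization across diseases --------------------
        shared = None
        for disease, table in consensus.items():
            genes = set(table["hub_gene"]) if len(table) else set()
            shared = genes if shared is None else shared & genes
        shared = sorted(shared or [])
        if shared and len(disease_inputs) >= 1:
            prioritized = postnet.prioritize_kds(
                shared, all_networks, disease_inputs,
                config=config.enrichment_config("prioritize"),
                fdr_each=config.kd_fdr_each)
            write_tsv(prioritized, out / "prioritized_kds.tsv")
            results["prioritized"] = prioritized
            manifest["stages"].append("prioritize")

            # ---- stage: directionality across the two diseases --------
            diseases = sorted(disease_inputs)
            if len(diseases) == 2:
                calls = []
                d_a, d_b = diseases
                study_a = sorted(full_assocs[d_a])[0]
                study_b = sorted(full_assocs[d_b])[0]
                assoc_a = full_assocs[d_a][study_a]
                assoc_b = full_assocs[d_b][study_b]
                map_a = full_mappings.get(d_a, {}).get(
                    study_a, disease_inputs[d_a][study_a][1])
                for gene in shared:
                    call = postnet.infer_direction(
                        gene, assoc_a, assoc_b, {"combined": map_a})
                    calls.append(call.to_dict())
                direction = pd.DataFrame(calls)
                write_tsv(direction, out / "directionality.tsv")
                results["directionality"] = direction
                manifest["stages"].append("direction")

        # ---- stage: known-gene validation (optional) ------------------
        if config.known_genes and shared:
            catalog_df = pd.read_csv(config.known_genes, sep="\t")
            cat_col = catalog_df.columns[-1]
            catalog = frozenset(catalog_df[cat_col].astype(str))
            universe = set()
            for net in all_networks:
                universe.update(net.nodes)
            rows = []
            for gene in shared:
                nbrs, _ = postnet.combined_subnetwork(all_networks, gene)
                fold, p = postnet.known_gene_enrichment(nbrs, catalog,
                                                        universe)
                rows.append((gene, len(nbrs), fold, p))
            known = pd.DataFrame(rows, columns=["gene", "subnet_size",
                                                "fold", "p_value"])
            write_tsv(known, out / "known_gene_enrichment.tsv")
            results["known_gene"] = known
            manifest["stages"].append("validate")
    else:
        log.info("no network block configured; network stages skipped")

    for block in config.studies:
        manifest["inputs"][block.name] = {
            "gwas": block.gwas,
            "digest": frame_digest(study_assocs[block.name]),
        }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return results


# ----------------------------------------------------------------------
# synthetic fixture generation


def generate_fixture_study(outdir, seed: int = 0, n_cohorts: int = 3,
                           n_markers: int = 6000, n_genes: int = 300,
                           n_modules: int = 20,
                           module_size: tuple[int, int] = (20, 30),
                           planted_fraction: float = 0.5,
                           enrichment_shape: float = 0.2,
                           network_size: int = 300,
                           planted_neighbor_fraction: float = 0.8) -> str:
    """Materialize a synthetic multi-cohort demo under `outdir`.

    Writes per-cohort GWAS files for two simulated diseases sharing a
    planted module, the LD table, the marker→gene map, the module
    file, two network types with the same planted hub, a small known-
    gene catalog, and a config.yaml; returns the config path. The
    planted truth is recorded in truth.json.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(stage_seed(seed, "fixture"))

    universe = [f"G{i:05d}" for i in range(1, n_genes + 1)]
    modules = simulate_modules(n_modules, module_size, overlap_jaccard=0.02,
                               universe=universe,
                               seed=stage_seed(seed, "modules"))
    planted_module = next(iter(modules))
    modules.to_frame().rename(
        columns={"set_id": "SET", "gene_id": "GENE"}).to_csv(
        out / "modules.tsv", sep="\t", index=False)

    studies = []
    shared_mapping = None
    for c in range(n_cohorts):
        spec = SyntheticStudySpec(
            n_markers=n_markers, n_genes=n_genes,
            markers_per_gene_mean=8.0,
            planted_module=planted_module,
            planted_fraction=planted_fraction,
            enrichment_shape=enrichment_shape,
            beta_sign_concordance=0.9,
            seed=stage_seed(seed, f"cohort{c}"))
        study = simulate_study(spec, modules=modules,
                               mapping=shared_mapping)
        if shared_mapping is None:
            shared_mapping = study.mapping
        studies.append(study)

    config_studies = []
    for c, study in enumerate(studies):
        for disease, assocs in (("cvd", study.associations),
                                ("t2d", study.associations_b)):
            name = f"cohort{c + 1}_{disease}"
            gfile = out / f"gwas_{name}.tsv"
            assocs.rename(columns={v: k for k, v in
                                   GWAS_COLUMNS.items()}).rename(
                columns=GWAS_COLUMNS).to_csv(gfile, sep="\t", index=False,
                                             float_format="%.8g")
            config_studies.append({
                "name": name, "disease": disease,
                "gwas": gfile.name, "ld": "ld.tsv",
                "mapping": "mapping.tsv"})
    studies[0].ld.to_frame().rename(
        columns={"marker_1": "MARKER1", "marker_2": "MARKER2",
                 "r2": "R2"}).to_csv(out / "ld.tsv", sep="\t", index=False)
    studies[0].mapping.rename(
        columns={"marker_id": "MARKER", "gene_id": "GENE",
                 "scheme": "SCHEME", "tissue": "TISSUE"}).to_csv(
        out / "mapping.tsv", sep="\t", index=False)

    # two network types, same planted hub enriched for the planted module
    hub_gene = None
    for i, net_type in enumerate(("bayesian", "giant")):
        net, truth = simulate_network(
            network_size, attachment=3,
            planted_hub_module=modules[planted_module],
            planted_neighbor_fraction=planted_neighbor_fraction,
            weight_levels=4, universe=universe, tissue="adipose",
            seed=stage_seed(seed, f"net:{net_type}"))
        hub_gene = truth.planted_hub_ids[0] if hub_gene is None else hub_gene
        # keep one shared hub label across types: relabel this type's hub
        if truth.planted_hub_ids[0] != hub_gene:
            df = net.to_frame()
            other = truth.planted_hub_ids[0]
            swap = {other: hub_gene, hub_gene: other}
            df["tail"] = df["tail"].map(lambda g: swap.get(g, g))
            df["head"] = df["head"].map(lambda g: swap.get(g, g))
            net = WeightedNetwork.from_frame(df, tissue="adipose")
        net.to_frame().to_csv(out / f"network_{net_type}.tsv", sep="\t",
                              index=False)

    known = sorted(rng.choice(sorted(modules[planted_module]),
                              size=min(10, len(modules[planted_module])),
                              replace=False))
    pd.DataFrame({"TRAIT": "disease", "GENE": known}).to_csv(
        out / "known_genes.tsv", sep="\t", index=False)

    config = {
        "seed": seed,
        "outdir": str(out / "run"),
        "modules": "modules.tsv",
        "known_genes": "known_genes.tsv",
        "studies": config_studies,
        "networks": {"bayesian": ["network_bayesian.tsv"],
                     "giant": ["network_giant.tsv"]},
        "thresholds": {"n_perm": 500, "min_set_genes": 10},
    }
    cfg_path = out / "config.yaml"
    with open(cfg_path, "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=False)
    with open(out / "truth.json", "w") as fh:
        json.dump({"planted_module": planted_module,
                   "planted_hub": hub_gene}, fh, indent=2)
    return str(cfg_path)
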