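# netmsea

Network-driven integrative genomics for GWAS of complex diseases:
marker-set enrichment analysis (MSEA) of co-expression modules,
cross-cohort meta-analysis (Meta-MSEA), and weighted key-driver
analysis (wKDA) on gene-gene networks — with a synthetic-data
generator that plants recoverable ground truth in every input, so the
whole pipeline can be exercised and validated without any external
download.

## The problem

Individual GWAS hits for diseases such as cardiovascular disease and
type 2 diabetes rarely explain pathogenesis on their own: risk
variants scatter across many loci of small effect, and their target
genes act together in tissue-specific regulatory programs. This
package implements the module-level view: instead of testing one
variant at a time, it asks whether the set of variants mapped to a
*group* of functionally related genes (a co-expression module) is
collectively enriched for strong association, whether that enrichment
replicates across cohorts, and which network hub genes ("key
drivers") organize the affected modules.

It is written for statistical geneticists and systems biologists who
want a tested, reusable, fully scriptable implementation of this
workflow, from summary-statistics QC to key-driver prioritization.

## The statistics

**MSEA.** Markers pass QC (MAF > 0.05, imputation quality > 0.3) and
greedy LD pruning (p-ranked walk, no retained pair with r² > 0.5, and
removal of bottom-half markers that were LD-linked). Markers map to
genes by chromosomal distance (50 kb of the gene body), regulatory
evidence, cis-eQTLs (≤ 1 Mb from the TSS; per-tissue or pooled), or
their union. A gene set *S* with marker p-values inside a study pool
is scored at quantile points q₁ < … < qₙ (default ten points, top 50%
to top 99.9%):

    chi = Σᵢ (Oᵢ − Eᵢ) / sqrt(Eᵢ + κ),   κ = 1

where Oᵢ is the number of *S*'s markers above the i-th quantile
threshold of the pool and Eᵢ = n_S·(1−qᵢ). The null permutes gene
labels (random gene sets of the same size, marker assignments fixed),
a Gaussian fitted to the permuted statistics gives one-sided
p-values, and BH-FDR is taken across modules. Modules with fewer than
10 mapped genes are excluded.

**Meta-MSEA.** Per-study z-scores combine by Stouffer's method,
meta_z = Σz/√m, with BH-FDR across modules; meta-FDR < 5% flags a
module.

**wKDA.** Per tissue, networks from multiple datasets union into one
weighted graph (edge weight = cross-dataset consistency count). Hubs
are nodes in the top quartile of degree. For hub neighborhoods
(one-edge subnetworks) with node strengths s_v (sum of adjacent edge
weights within the neighborhood):

    O = N_k · strength(neighbors ∩ module) / strength(neighbors)
    E = N_k · N_p / N
    chi = (O − E) / sqrt(E + κ)

with N_k the hub degree, N_p the module size in the network, N the
network order. Significance comes from permuting the network's gene
labels; Bonferroni correction spans all (hub, module, tissue) tests.
Consensus key drivers are Bonferroni-significant in *both* network
types; they are prioritized by Meta-MSEA of their subnetworks against
each disease (meta-FDR < 10% for both), and the direction of each
KD's genetic effect across the two diseases is called from the
sign-concordance of allele-harmonized betas (binomial z-test).

## Worked example

The numbered scripts under `analysis/` run the full study on a
synthetic three-cohort, two-disease design with one planted module
and one planted key driver:

```bash
python analysis/01_simulate_cohorts.py     # writes results/data/
python analysis/02_enrichment_meta.py      # per-cohort MSEA + Meta-MSEA
python analysis/03_key_drivers.py          # wKDA on both network types
python analysis/04_prioritize_validate.py  # prioritization + validation
```

Output of a run at seed 1 (abridged):

```
cohort1_cvd: 1158 markers after pruning, 20 modules tested, top M0001 (p=7.75e-19)
cohort2_cvd: 1157 markers after pruning, 20 modules tested, top M0001 (p=5.21e-15)
cohort3_cvd: 1169 markers after pruning, 20 modules tested, top M0001 (p=2.06e-20)
cvd: 3 modules at meta-FDR<5% -> ['M0001', 'M0020', 'M0015']; planted module recovered: True
cvd: consensus key drivers ['G00001']; planted hub recovered: True
prioritized KDs (meta-FDR<10% for both diseases): ['G00001']
direction G00001: consistent (concordance 1.00, n=6)
known-gene enrichment G00001: fold=9.7, p=3.17e-11
```

M0001 is the planted module (Beta(0.2,1) p-values on half its
markers): every cohort ranks it first and the meta-analysis flags it
for both diseases, along with two modules that overlap it. G00001 is
the planted hub (80% of its neighbors are module genes in both
network types): it is the sole consensus KD, survives subnetwork
prioritization for both diseases, its betas are sign-concordant
between the diseases, and its subnetwork is ~10-fold enriched for the
known-gene catalog.

The same run is available as a single command:

```bash
netmsea fixtures demo_dir --seed 1
netmsea pipeline demo_dir/config.yaml
```

The library surface (`import netmsea`) exposes every stage —
`read_gwas`, `filter_markers`, `prune_ld`, the `map_by_*` family,
`run_msea`, `run_meta_msea`, `run_wkda`, `kd_consensus`,
`prioritize_kds`, `infer_direction`, and the `simulate_*` generators.

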