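# Methods

This note documents the statistical model implemented by `netmsea`,
the defaults and why they are set where they are, what the synthetic
data generator emulates, and the numerical choices that affect
results at the margins.

## Marker-level preprocessing

GWAS summary statistics enter as per-marker records (id, association
p, optionally signed beta with effect/other allele, MAF, imputation
quality). QC keeps markers with MAF > `maf_min` (default 0.05) and
info > `info_min` (default 0.3). A marker missing a QC field passes
that criterion by default, because several consortium releases omit
per-SNP MAF or info; `strict=True` inverts the policy. Duplicate
marker rows collapse to the minimum-p record.

LD pruning is a greedy walk down the p-value ranking (ties broken by
marker id for determinism): a marker is accepted only if its r² with
every already-accepted marker is ≤ `r2_max` (default 0.5), so each LD
component is represented by its minimum-p member. A second step
removes accepted markers that *both* rank in the bottom
`drop_bottom_fraction` (default 0.5) of the original ranking *and*
had any r² > `r2_max` partner among the study's markers. The two
conditions are a conjunction: a weak marker with no LD partner
survives. The partner check is restricted to markers present in the
input, which makes pruning idempotent. `drop_bottom_fraction=0`
disables the second step.

## Marker→gene mapping

Four schemes, all over 1-based inclusive coordinates:

* **distance** — marker within `[start − w, end + w]` of the gene
  body, w = 50 kb by default. The window anchors on the gene body,
  not the TSS (both the distance and the regulatory-evidence modes
  use the gene body; only the cis-eQTL definition uses the TSS).
* **regulome** — the distance mapping restricted to markers on a
  caller-supplied regulatory-evidence list. Which evidence classes
  qualify is the caller's concern.
* **eqtl / multi_tissue_eqtl** — a marker–gene–tissue table,
  filtered to one tissue or pooled and deduplicated across tissues.
  When coordinates are supplied, links farther than 1 Mb from the TSS
  are rejected (cis validation); otherwise the table is trusted.
* **combined** — set union with per-scheme provenance; the union is
  commutative and idempotent on the link set.

Mappings are restricted to the post-QC, post-pruning marker set
before enrichment. Markers mapped to several genes within one set are
counted once per set, to avoid double-counting pleiotropic eQTLs.

## The enrichment statistic

For a gene set with marker p-values inside a study pool of n markers,
at quantile points q (default {0.50, 0.60, 0.70, 0.80, 0.90, 0.95,
0.98, 0.99, 0.995, 0.999}):

* the threshold at q is the p-value at rank ⌊n(1−q)⌋ of the pool
  (rank computed as ⌊n(1−q) + 1e−9⌋ to guard against floating-point
  noise in 1−q); a quantile leaving no positive marker raises an
  error rather than silently degenerating — with the default vector
  this requires ≥ 1000 markers in the pool;
* O_q = number of set markers at or below the threshold,
  E_q = n_set · (1−q);
* chi = Σ_q (O_q − E_q)/√(E_q + κ), κ = 1.

The √(E+κ) denominator gives each term the scale of a signed
chi-square-like residual, with κ damping terms with small expected
counts; a plain (O−E)/(E+κ) variant is available via
`EnrichmentConfig(sqrt_denominator=False)` for sensitivity analysis.
The statistic depends only on p-value ranks, hence is invariant under
strictly monotone transforms of the pool.

## Permutation null and p-values

The null permutes *gene labels*: `n_perm` (default 10,000; tests and
the demo use 500–1000) random gene sets of the same mapped-gene count
are drawn from the mapped-gene universe, each assembled into a
deduplicated marker set through the untouched marker→gene map and
scored. Keeping the map fixed makes the null absorb gene size,
LD-block structure and SNPs-per-locus confounding — which also means
the null mean need not be zero for a single study realization (it is
zero in expectation over study draws, and exactly marker-sampling
when each gene carries one unique marker). A Gaussian fitted to the
null (sd with ddof = 1) gives one-sided upper-tail p-values with
resolution beyond 1/n_perm; the fit is accurate because chi sums ten
quantile terms over many markers. Nulls depend only on the gene
count of a set, so they are cached by count across sets — an exact
optimization. BH-FDR (statsmodels step-up) runs across all tested
sets; sets with fewer than `min_set_genes` (default 10) mapped genes
are skipped.

`msea_on_gene_stats` reuses the identical machinery for per-gene
p-values (e.g. gene–trait correlation p) through a degenerate
one-marker-per-gene map, and reduces exactly to `run_msea` in that
case.

## Meta-analysis

Per-study Gaussian z-scores combine by unweighted Stouffer,
meta_z = Σz/√m over the m studies where the set was tested; missing
studies are excluded, never imputed. An optional weight vector exists
for sensitivity work but no weighting is the default. Meta-p is the
one-sided Gaussian tail; BH-FDR across sets; `sig_fdr` (default 5%)
flags significance. Study order never affects results.

## Weighted key-driver analysis

Networks for one tissue union into a single weighted graph whose edge
weight is the number of source datasets containing the edge. Hubs are
nodes with degree at or above the nearest-rank 75th percentile of the
node-degree distribution, ties included — note that in degenerate
profiles (e.g. a star) the cutoff can equal the minimum degree, in
which case every node is screened; screening only limits which nodes
are tested, significance does the ranking.

A hub's one-edge neighborhood is summarized by node strengths: the
sum of a neighbor's edge weights to the hub and to other neighborhood
members. The observed value O rescales the strength-weighted module
share of the neighborhood to a count (so O and E are commensurable);
E = N_k·N_p/N is exactly the hypergeometric mean, with N_p the module
size within the network. With equal edge weights and no
neighborhood-internal edges the strengths coincide and O equals the
plain module count; internal edges shift strengths and the weighted
and unweighted scores then differ by design (an unweighted counting
mode is available). The statistic (O−E)/√(E+κ) mirrors the
enrichment statistic.

The null permutes the network's gene labels (structure and weights
fixed) — implemented as permuting the module-membership indicator
over nodes, with one permutation rescoring every hub — and a
Gaussian fit gives p-values. Bonferroni correction spans all (hub,
module, tissue) tests performed jointly; the consensus step keeps
genes Bonferroni-significant (α = 0.05) in each network type.
A known limitation: on sparse networks with unit weights the
neighborhood count is strongly discrete and the Gaussian tail is
inaccurate; calibration is good once neighborhood shares average over
tens of edges with varied weights (the calibration study uses an
Erdős–Rényi graph at mean degree 30 with integer weights 1–4).

## Prioritization and validation

Each consensus KD's cross-tissue one-edge neighborhood becomes a gene
set; Meta-MSEA runs against every disease's cohorts and a KD is kept
when meta-FDR < `fdr_each` (default 10%) for *each* disease.
Direction of effect: for the KD's mapped variants present in both
diseases' GWAS, betas are harmonized (sign flipped when study b's
effect allele equals study a's other allele; irreconcilable alleles
dropped) and the proportion of agreeing signs is z-tested against
0.5, two-sided (the departure can go either way): z = (p̂−0.5)/
√(0.25/n). The call is consistent/opposite when significant at
α = 0.05 in at least one mapping mode with p̂ above/below 0.5, else
uncertain; if significant modes disagree, the smaller p wins. The
call class is invariant to swapping the two studies. Directionality
uses the full QC'd association tables, not the LD-pruned sets, to
maximize the harmonizable variant count.

Known-gene enrichment and the per-shell DEG overlap use one-sided
Fisher's exact tests (hypergeometric upper tail) with fold =
(overlap/|set|)/(|catalog|/|universe|); the universe is always an
explicit parameter and defaults to the genes present in the relevant
network. BFS shells at exact distance 1..`max_level` partition the
reachable nodes; Bonferroni spans the non-empty levels tested.
Gene–trait validation reports per-KD Pearson r/p at three
multiplicity tiers (nominal, per-KD-count, per-KD×trait-count) and
per-subnetwork gene-level MSEA of the trait p-values. Annotation
against a pathway library is Fisher's exact with per-set Bonferroni
across pathways; significance additionally requires more than five
directly overlapping genes; redundant categories reduce greedily by
ascending p under a pairwise Jaccard < 10% bound, and near-duplicate
sets can merge by single-linkage Jaccard clustering.

## Synthetic data: what it emulates, and what it does not

The generator produces the statistical structure the pipeline
assumes, with planted, recoverable truth:

* marker p-values Uniform(0,1) under the null; planted markers (a
  `planted_fraction` of the planted module's markers, in both
  simulated diseases) follow Beta(a, 1) — a single interpretable
  strength parameter with the uniform null at a = 1; defaults
  a = 0.2, fraction 0.5;
* block-diagonal LD: constant r² (default 0.8) inside consecutive
  blocks of 5 markers, zero between — chosen over realistic decay so
  the pruning oracle is exact;
* a many-to-many marker→gene map with 1 + Poisson(mean−1) markers
  per gene (negative-binomial for over-dispersion); cohorts of a
  multi-study design share the map (annotations are common across
  real cohorts) while re-drawing association noise;
* overlapping modules via a shared anchor pool: drawing a fraction
  f = √(2J/(1+J)) of each module from an anchor of mean module size
  targets mean pairwise Jaccard J (accurate ±0.05 for J ≤ 0.3);
* scale-free (Barabási–Albert) networks whose highest-degree
  suitable hub gets a `planted_neighbor_fraction` (default 0.8) of
  module-gene neighbors; integer edge weights 1..K emulate
  cross-dataset consistency counts;
* strain-level gene–trait data: signal genes track a latent trait
  with slope `effect` plus unit noise; DEG tables from a two-group
  mean-shift contrast with BH-FDR.

Betas are standard normal in magnitude with the disease-B sign
agreeing with disease A's at a configurable per-marker concordance
(planted direction classes use 0.95 / 0.05 / 0.5).

Not emulated: realistic human LD decay, genotype-level data, allele
frequencies correlated with effect sizes, population stratification,
sample overlap between cohorts, and directed or signed network
semantics. Passing tests therefore demonstrate the statistical
machinery's correctness and calibration under the stated generative
model, not robustness to those real-data complications.

## Problem sizes and reproducibility

The packaged demo and validation studies use 6,000 markers × 300
genes × 3 cohorts × 2 diseases with 20 modules and 300-node
networks (500 permutations), which runs end-to-end in a few seconds;
calibration and power studies use 2,000-marker studies, 50–100
modules, 500-node planted networks and 20 replicate seeds. These
sizes give the recovery and calibration checks comfortable margins
while keeping the whole suite quick on a single CPU.

A single master seed fans out to per-stage seeds via
`stage_seed(master, stage_name)` = first 4 bytes of
SHA-256(f"{master}:{stage}") mod 2³¹, so stages can be rerun
independently yet deterministically; identical configs and inputs
reproduce every output byte-for-byte. Each pipeline run writes a
manifest (parameters, seed, input digests) sufficient to reproduce
it.
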