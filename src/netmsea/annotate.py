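"""Functional annotation of gene sets and redundancy reduction.

Significant modules are annotated against a pathway library (GMT) by
one-sided Fisher's exact tests with Bonferroni correction across
pathways per set; an annotation is called significant only when the
corrected p is below 0.05 AND more than five genes overlap directly.
Redundant categories are reduced greedily by ascending p under a
pairwise Jaccard bound, and near-duplicate gene sets can be merged by
single-linkage clustering on Jaccard similarity.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .containers import GeneSetCollection, jaccard

ANNOTATION_COLUMNS = ["set_id", "category_id", "overlap_genes", "fold",
                      "fisher_p", "bonferroni_p", "significant"]

MIN_OVERLAP_GENES = 5          # strict ">" applies
SIG_BONFERRONI_P = 0.05


def fisher_enrichment(n_overlap: int, n_set: int, n_category: int,
                      n_universe: int) -> tuple[float, float]:
    """(fold, one-sided p) for a set/category overlap.

    Fold is the observed overlap fraction of the set over the
    category's background density; p is the hypergeometric upper tail
    (Fisher's exact, one-sided).
    """
    if n_universe <= 0:
        raise ValueError("empty universe")
    if n_set == 0 or n_category == 0:
        return 0.0, 1.0
    fold = (n_overlap / n_set) / (n_category / n_universe)
    p = float(stats.hypergeom.sf(n_overlap - 1, n_universe, n_category,
                                 n_set))
    return fold, min(p, 1.0)


def annotate_gene_sets(sets: GeneSetCollection, pathways: GeneSetCollection,
                       universe: set[str] | frozenset[str]) -> pd.DataFrame:
    """Fisher's exact annotation of every set against every pathway.

    Bonferroni correction is per set across the pathway library; the
    top category of a set is its minimum-p significant record.
    """
    if len(pathways) == 0:
        raise ValueError("empty pathway library")
    universe = frozenset(universe)
    n_universe = len(universe)
    n_pathways = len(pathways)
    rows = []
    for set_id in sets:
        sgenes = sets[set_id] & universe
        for cat_id in pathways:
            cgenes = pathways[cat_id] & universe
            k = len(sgenes & cgenes)
            fold, p = fisher_enrichment(k, len(sgenes), len(cgenes),
                                        n_universe)
            bonf = min(p * n_pathways, 1.0)
            sig = bonf < SIG_BONFERRONI_P and k > MIN_OVERLAP_GENES
            rows.append((set_id, cat_id, k, fold, p, bonf, sig))
    return pd.DataFrame(rows, columns=ANNOTATION_COLUMNS)


def top_categories(annotations: pd.DataFrame) -> pd.DataFrame:
    """Minimum-p significant category per set."""
    sig = annotations.loc[annotations["significant"]]
    if sig.empty:
        return sig
    return (sig.sort_values(["fisher_p", "category_id"], kind="mergesort")
            .groupby("set_id", as_index=False).first())


def reduce_categories(categories: pd.DataFrame,
                      memberships: GeneSetCollection,
                      max_overlap: float = 0.10) -> list[str]:
    """Greedy selection of independent categories.

    `categories` has columns category_id and p (best annotation p);
    walking in ascending p (ties by category id), a category is
    accepted iff its Jaccard overlap with every accepted category is
    strictly below `max_overlap`.
    """
    ordered = categories.sort_values(["p", "category_id"],
                                     kind="mergesort")["category_id"]
    accepted: list[str] = []
    for cat in ordered:
        genes = memberships[cat]
        if all(jaccard(genes, memberships[a]) < max_overlap
               for a in accepted):
            accepted.append(cat)
    return accepted


def set_overlap_matrix(sets: GeneSetCollection) -> pd.DataFrame:
    """Symmetric pairwise Jaccard matrix with unit diagonal."""
    names = list(sets)
    if not names:
        raise ValueError("no sets")
    n = len(names)
    mat = np.ones((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            mat[i, j] = mat[j, i] = jaccard(sets[names[i]], sets[names[j]])
    return pd.DataFrame(mat, index=names, columns=names)


def merge_redundant_sets(sets: GeneSetCollection, merge_jaccard: float
                         ) -> tuple[GeneSetCollection, dict[str, list[str]]]:
    """Single-linkage merge of sets with pairwise Jaccard >= threshold.

    Each cluster becomes the union of its members, named after its
    lexicographically first member; the provenance map records the
    members of each merged set.
    """
    if not 0.0 < merge_jaccard <= 1.0:
        raise ValueError("merge_jaccard must lie in (0,1]")
    names = list(sets)
    parent = {n: n for n in names}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i, a in enumerate(names):
        for b in names[i + 1:]:
            if jaccard(sets[a], sets[b]) >= merge_jaccard:
                ra, rb = find(a), find(b)
                if ra != rb:
                    parent[max(ra, rb)] = min(ra, rb)
    clusters: dict[str, list[str]] = {}
    for n in names:
        clusters.setdefault(find(n), []).append(n)
    merged = GeneSetCollection()
    provenance = {}
    for root, members in clusters.items():
        union = frozenset().union(*(sets[m] for m in members))
        merged.add(root, union)
        provenance[root] = sorted(members)
    return merged, provenance
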