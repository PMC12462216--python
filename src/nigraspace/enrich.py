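"""Over-representation analysis of DEG lists with combined scores,
redundancy-reducing term clustering, and DEG-overlap (Venn) summaries.

Per term the enrichment p-value is the hypergeometric upper tail
P(X >= k | N, K, n); the combined score is c = -ln(p) * z where z is the
standardized deviation of the observed overlap from its hypergeometric
expectation. Similar terms are clustered by average-linkage on Jaccard
distance of their overlap gene sets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .de import bh_adjust
from .io import GeneSetCollection

ENRICH_COLUMNS = [
    "term", "k", "K", "n", "N", "p", "padj", "zscore", "combined_score", "overlap_genes",
]


def _hypergeom_moments(N: int, K: int, n: int) -> tuple[float, float]:
    mean = n * K / N
    var = n * K * (N - K) * (N - n) / (N**2 * (N - 1)) if N > 1 else 0.0
    return mean, var


def combined_score(p: float, zscore: float) -> float:
    """Enrichment ranking score c = -ln(p) * z; p = 0 is clamped."""
    if p <= 0:
        warnings.warn("p = 0 clamped to smallest positive float")
        p = np.finfo(float).tiny
    if p > 1:
        raise ValueError("p must be in (0, 1]")
    return float(-np.log(p) * zscore)


def fisher_enrich(
    query: list[str],
    universe: list[str],
    sets: GeneSetCollection,
) -> pd.DataFrame:
    """Hypergeometric over-representation of ``query`` within ``universe``.

    Gene sets are intersected with the universe first; query genes outside
    the universe are dropped with a warning. Terms with zero overlap are
    reported with p = 1. BH adjustment is across all tested terms.
    """
    uni = list(dict.fromkeys(universe))
    if len(uni) < 2:
        raise ValueError("universe must contain ≥ 2 genes")
    uni_set = set(uni)
    q = list(dict.fromkeys(query))
    if not q:
        raise ValueError("empty query gene list")
    outside = [g for g in q if g not in uni_set]
    if outside:
        warnings.warn(f"{len(outside)} query gene(s) outside universe dropped: {outside[:10]}")
        q = [g for g in q if g in uni_set]
    if not q:
        raise ValueError("no query gene lies in the universe")
    q_set = set(q)
    N, n = len(uni), len(q)

    rows = []
    for term, (_desc, genes) in sets.terms.items():
        members = [g for g in genes if g in uni_set]
        K = len(members)
        overlap = sorted(set(members) & q_set)
        k = len(overlap)
        if K == 0:
            continue
        p = float(stats.hypergeom.sf(k - 1, N, K, n)) if k > 0 else 1.0
        p = min(max(p, np.finfo(float).tiny), 1.0)
        mean, var = _hypergeom_moments(N, K, n)
        z = (k - mean) / np.sqrt(var) if var > 0 else 0.0
        rows.append(
            {
                "term": term,
                "k": k,
                "K": K,
                "n": n,
                "N": N,
                "p": p,
                "zscore": z,
                "combined_score": combined_score(p, z),
                "overlap_genes": overlap,
            }
        )
    if not rows:
        return pd.DataFrame(columns=ENRICH_COLUMNS)
    out = pd.DataFrame(rows)
    out["padj"] = bh_adjust(out["p"].to_numpy())
    out = out.sort_values(["padj", "p", "term"], kind="mergesort").reset_index(drop=True)
    return out[ENRICH_COLUMNS]


@dataclass
class TermClustering:
    """Partition of enriched terms plus per-cluster representative (lowest padj)."""

    assignment: dict[str, int]
    representatives: dict[int, str]
    similarity: pd.DataFrame


def cluster_terms(rows: pd.DataFrame, similarity_threshold: float = 0.5) -> TermClustering:
    """Cluster enriched terms by Jaccard similarity of their overlap genes.

    Average-linkage hierarchical clustering on distance 1 - Jaccard, cut at
    (1 - similarity_threshold). Deterministic for a fixed input order;
    permuting rows relabels clusters but never changes the partition.
    """
    if rows.empty:
        raise ValueError("no enrichment rows to cluster")
    terms = list(rows["term"])
    gene_sets = [set(g) for g in rows["overlap_genes"]]
    m = len(terms)
    sim = np.eye(m)
    for i in range(m):
        for j in range(i + 1, m):
            a, b = gene_sets[i], gene_sets[j]
            union = len(a | b)
            sim[i, j] = sim[j, i] = len(a & b) / union if union else 0.0
    sim_df = pd.DataFrame(sim, index=terms, columns=terms)
    if m == 1:
        labels = np.ones(1, dtype=int)
    else:
        dist = squareform(1.0 - sim, checks=False)
        Z = linkage(dist, method="average")
        labels = fcluster(Z, t=1.0 - similarity_threshold, criterion="distance")
    assignment = dict(zip(terms, (int(c) for c in labels)))
    reps: dict[int, str] = {}
    padj = rows.set_index("term")["padj"]
    for cluster in sorted(set(assignment.values())):
        members = [t for t, c in assignment.items() if c == cluster]
        reps[cluster] = min(members, key=lambda t: (padj[t], t))
    return TermClustering(assignment, reps, sim_df)


def venn_overlap(lists: dict[str, tuple[list[str], list[str]]]) -> dict:
    """Shared/exclusive DEG counts across labeled comparisons, per direction.

    Each label maps to (upregulated, downregulated) gene lists. ``shared`` is
    the intersection across all labels; fractions are reported with two
    denominators: the directional list size and the label's total DEG count.
    Duplicates within a list are removed with a warning.
    """
    if len(lists) < 2:
        raise ValueError("need ≥ 2 labeled DEG lists")
    clean: dict[str, tuple[list[str], list[str]]] = {}
    for label, (up, down) in lists.items():
        for name, lst in (("up", up), ("down", down)):
            if len(set(lst)) != len(lst):
                warnings.warn(f"duplicate genes in {label} {name} list removed")
        clean[label] = (list(dict.fromkeys(up)), list(dict.fromkeys(down)))

    out: dict = {"labels": list(clean)}
    for d, idx in (("up", 0), ("down", 1)):
        sets = {label: set(v[idx]) for label, v in clean.items()}
        shared = set.intersection(*sets.values()) if sets else set()
        entry = {
            "shared": len(shared),
            "shared_genes": sorted(shared),
            "exclusive": {
                label: len(s - set.union(*(o for l, o in sets.items() if l != label)))
                for label, s in sets.items()
            },
            "fraction_of_directional": {
                label: (len(shared) / len(s) if s else 0.0) for label, s in sets.items()
            },
            "fraction_of_total": {
                label: (
                    len(shared) / (len(clean[label][0]) + len(clean[label][1]))
                    if (len(clean[label][0]) + len(clean[label][1]))
                    else 0.0
                )
                for label in clean
            },
        }
        out[d] = entry
    return out
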