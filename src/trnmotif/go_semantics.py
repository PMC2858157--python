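"""GO information content, semantic similarity, cluster validity, enrichment.

Term similarity follows Schlicker's relevance measure, which combines Lin's
normalisation with a (1 - p) weight on the best common ancestor so that
similarity through near-universal terms counts for little.  Gene similarity
is the best-match average (BMA) of the relevance matrix over the genes'
direct term sets, averaged over the ontology branches in which both genes
are annotated.  The mean within-cluster gene similarity of a hardened
partition serves as a cluster-validity score: the partition with the highest
score over a sweep of cluster numbers is retained.

Cluster enrichment is a one-sided hypergeometric test per term with a
resampling-based family-wise adjustment: the adjusted p of a term is the
fraction of random same-size gene sets whose *best* (minimum) term p-value
beats it.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
from scipy.stats import hypergeom

from .clustering import ClusterSet, FuzzyPartition, harden
from .data_io import AnnotationSet, Ontology

log = logging.getLogger(__name__)

__all__ = ["ICTable", "ValidityScore", "information_content", "term_similarity",
           "GeneSimilarity", "gene_similarity", "partition_validity",
           "select_optimal_partition", "enrichment"]


@dataclass
class ICTable:
    """Annotation frequency p(t) and information content -ln p(t) per term."""

    p: dict[str, float]
    ic: dict[str, float]
    n_genes_by_namespace: dict[str, int]


def information_content(ann: AnnotationSet, ont: Ontology) -> ICTable:
    """p(t) = fraction of genes (annotated in t's namespace) whose propagated
    set contains t; ic = -ln p.  Terms never annotated are excluded."""
    if not ann.direct:
        raise ValueError("empty annotation set")
    genes_by_ns: dict[str, set[str]] = {}
    counts: dict[str, int] = {}
    for g, terms in ann.propagated.items():
        seen_ns = set()
        for t in terms:
            if t not in ont.terms:
                continue
            counts[t] = counts.get(t, 0) + 1
            seen_ns.add(ont.namespace(t))
        for ns in seen_ns:
            genes_by_ns.setdefault(ns, set()).add(g)
    n_by_ns = {ns: len(gs) for ns, gs in genes_by_ns.items()}
    p = {t: counts[t] / n_by_ns[ont.namespace(t)] for t in counts}
    ic = {t: float(-np.log(pt)) for t, pt in p.items()}
    return ICTable(p=p, ic=ic, n_genes_by_namespace=n_by_ns)


def term_similarity(t1: str, t2: str, ic: ICTable, ont: Ontology,
                    method: str = "rel") -> float:
    """Similarity of two same-namespace terms over their common ancestors.

    resnik: max ic(a); lin: max 2 ic(a) / (ic(t1)+ic(t2));
    rel: max [2 ic(a) / (ic(t1)+ic(t2))] (1 - p(a)).  Root-only ancestry
    scores 0 for lin/rel; two roots score 0 by convention.
    """
    if ont.namespace(t1) != ont.namespace(t2):
        raise ValueError(f"{t1} and {t2} are in different namespaces")
    common = (ont.ancestors(t1) & ont.ancestors(t2)) & ic.ic.keys()
    if not common:
        return 0.0
    ic1, ic2 = ic.ic.get(t1, 0.0), ic.ic.get(t2, 0.0)
    if method == "resnik":
        return max(ic.ic[a] for a in common)
    if ic1 + ic2 == 0.0:
        return 0.0
    if method == "lin":
        return max(2.0 * ic.ic[a] / (ic1 + ic2) for a in common)
    if method == "rel":
        return max(2.0 * ic.ic[a] / (ic1 + ic2) * (1.0 - ic.p[a]) for a in common)
    raise ValueError(f"unknown method {method!r}")


class GeneSimilarity:
    """Cached best-match-average gene similarity over a fixed annotation set.

    Term-pair and gene-pair scores are memoised, which matters when the same
    gene pairs recur across a partition sweep.
    """

    def __init__(self, ann: AnnotationSet, ic: ICTable, ont: Ontology,
                 method: str = "rel") -> None:
        self.ann, self.ic, self.ont, self.method = ann, ic, ont, method
        self._term_cache: dict[tuple[str, str], float] = {}
        self._gene_cache: dict[tuple[str, str], float | None] = {}
        self._ns_terms: dict[str, dict[str, tuple[str, ...]]] = {}

    def _terms_by_ns(self, gene: str) -> dict[str, tuple[str, ...]]:
        cached = self._ns_terms.get(gene)
        if cached is not None:
            return cached
        out: dict[str, list[str]] = {}
        for t in self.ann.direct.get(gene, ()):  # direct terms only
            if t in self.ic.ic:
                out.setdefault(self.ont.namespace(t), []).append(t)
        result = {ns: tuple(sorted(ts)) for ns, ts in out.items()}
        self._ns_terms[gene] = result
        return result

    def term_sim(self, t1: str, t2: str) -> float:
        key = (t1, t2) if t1 <= t2 else (t2, t1)
        val = self._term_cache.get(key)
        if val is None:
            val = term_similarity(t1, t2, self.ic, self.ont, self.method)
            self._term_cache[key] = val
        return val

    def gene_sim(self, g1: str, g2: str) -> float | None:
        """BMA similarity in [0, 1], or None when no namespace is shared."""
        key = (g1, g2) if g1 <= g2 else (g2, g1)
        if key in self._gene_cache:
            return self._gene_cache[key]
        ns1, ns2 = self._terms_by_ns(g1), self._terms_by_ns(g2)
        shared = sorted(set(ns1) & set(ns2))
        if not shared:
            self._gene_cache[key] = None
            return None
        scores = []
        for ns in shared:
            a, b = ns1[ns], ns2[ns]
            S = np.array([[self.term_sim(t1, t2) for t2 in b] for t1 in a])
            bma = (S.max(axis=1).sum() + S.max(axis=0).sum()) / (len(a) + len(b))
            scores.append(bma)
        val = float(np.mean(scores))
        self._gene_cache[key] = val
        return val


def gene_similarity(g1: str, g2: str, ann: AnnotationSet, ic: ICTable,
                    ont: Ontology, method: str = "rel") -> float | None:
    return GeneSimilarity(ann, ic, ont, method).gene_sim(g1, g2)


@dataclass
class ValidityScore:
    """Mean within-cluster gene-pair similarity of one partition."""

    c: int
    score: float
    n_pairs: int
    n_skipped: int


def partition_validity(cs: ClusterSet, sim: "GeneSimilarity | None" = None,
                       ann: AnnotationSet | None = None,
                       ic: ICTable | None = None, ont: Ontology | None = None,
                       pooling: str = "pairs") -> ValidityScore:
    """Average GO similarity over all within-cluster gene pairs.

    ``pooling='pairs'`` pools every scoreable pair across clusters (default);
    ``pooling='clusters'`` averages per-cluster means instead.  Pairs with no
    shared annotated namespace are skipped, not scored 0, and counted.
    """
    if sim is None:
        if ann is None or ic is None or ont is None:
            raise ValueError("provide either a GeneSimilarity or (ann, ic, ont)")
        sim = GeneSimilarity(ann, ic, ont)
    all_scores: list[float] = []
    cluster_means: list[float] = []
    n_skipped = 0
    for _, members in sorted(cs.members().items()):
        scores = []
        for g1, g2 in itertools.combinations(members, 2):
            s = sim.gene_sim(g1, g2)
            if s is None:
                n_skipped += 1
            else:
                scores.append(s)
        if scores:
            cluster_means.append(float(np.mean(scores)))
            all_scores.extend(scores)
    if not all_scores:
        raise ValueError("no scoreable within-cluster gene pair")
    score = (float(np.mean(all_scores)) if pooling == "pairs"
             else float(np.mean(cluster_means)))
    return ValidityScore(c=cs.n_clusters, score=score,
                         n_pairs=len(all_scores), n_skipped=n_skipped)


_TIE_TOL = 1e-12


def select_from_clustersets(items: list[tuple[int, ClusterSet]],
                            sim: GeneSimilarity, pooling: str = "pairs",
                            ) -> tuple[ClusterSet, ValidityScore, list[ValidityScore]]:
    """Score (c, partition) candidates and keep the highest-validity one.

    Ties (within 1e-12, which also absorbs float summation noise between
    identical pair populations) go to the smallest cluster number.
    """
    if not items:
        raise ValueError("empty sweep")
    best: tuple[ClusterSet, ValidityScore] | None = None
    table: list[ValidityScore] = []
    for c, cs in sorted(items, key=lambda it: it[0]):
        vs = partition_validity(cs, sim=sim, pooling=pooling)
        vs = ValidityScore(c=c, score=vs.score, n_pairs=vs.n_pairs,
                           n_skipped=vs.n_skipped)
        table.append(vs)
        if best is None or vs.score > best[1].score + _TIE_TOL:
            best = (cs, vs)
    assert best is not None
    return best[0], best[1], table


def select_optimal_partition(sweep: list[FuzzyPartition], X,
                             ann: AnnotationSet, ic: ICTable, ont: Ontology,
                             pooling: str = "pairs",
                             ) -> tuple[ClusterSet, ValidityScore, list[ValidityScore]]:
    """Pick the sweep partition with the highest GO validity score.

    The candidate c of each partition (not the post-hardening cluster count)
    labels the score table, which is returned in full for plotting.
    """
    if not sweep:
        raise ValueError("empty sweep")
    sim = GeneSimilarity(ann, ic, ont)
    items = [(p.c, harden(p, X)) for p in sorted(sweep, key=lambda p: p.c)]
    return select_from_clustersets(items, sim, pooling=pooling)


def enrichment(cluster: set[str], universe: set[str], ann: AnnotationSet,
               ont: Ontology, n_resample: int = 1000, seed: int = 0,
               ) -> list[dict]:
    """Hypergeometric GO over-representation with resampling FWER adjustment.

    For every term hit by >= 1 cluster gene (after propagation):
    p = P[X >= k] with X ~ Hypergeom(N, K, n), where N = |universe|,
    K = genes in the universe carrying the term, n = |cluster| and k = hits
    inside the cluster.  p_adj(t) = fraction of ``n_resample`` random
    same-size gene sets whose minimum term p-value is <= p(t).
    """
    if not cluster <= universe:
        raise ValueError("cluster must be a subset of the universe")
    if n_resample < 100:
        raise ValueError("n_resample must be >= 100")
    uni = sorted(universe)
    N, n = len(uni), len(cluster)
    gene_idx = {g: i for i, g in enumerate(uni)}
    term_genes: dict[str, set[str]] = {}
    for g in uni:
        for t in ann.propagated.get(g, ()):  # genes outside ann count as unannotated
            if t in ont.terms:
                term_genes.setdefault(t, set()).add(g)
    terms = sorted(term_genes)
    n_terms = len(terms)
    member = np.zeros((N, n_terms), dtype=np.int32)
    for j, t in enumerate(terms):
        for g in term_genes[t]:
            member[gene_idx[g], j] = 1
    K_vec = member.sum(axis=0)
    # tail probabilities P[X >= k] precomputed for every term and k = 0..n
    ks = np.arange(n + 1)
    p_table = hypergeom.sf(ks[None, :] - 1, N, K_vec[:, None], n)

    cluster_counts = member[[gene_idx[g] for g in sorted(cluster)]].sum(axis=0)
    observed_p = p_table[np.arange(n_terms), cluster_counts]

    rng = np.random.default_rng(seed)
    min_ps = np.empty(n_resample)
    for r in range(n_resample):
        idx = rng.choice(N, size=n, replace=False)
        counts = member[idx].sum(axis=0)
        ps = p_table[np.arange(n_terms), counts]
        hit = counts > 0
        min_ps[r] = ps[hit].min() if hit.any() else 1.0
    min_ps.sort()
    records = []
    for j, t in enumerate(terms):
        k = int(cluster_counts[j])
        if k == 0:
            continue
        p = float(observed_p[j])
        p_adj = float(np.searchsorted(min_ps, p, side="right")) / n_resample
        records.append({"term": t, "name": ont.terms[t]["name"], "k": k,
                        "K": int(K_vec[j]), "n": n, "N": N,
                        "p": p, "p_adj": p_adj})
    records.sort(key=lambda r: (r["p"], r["term"]))
    return records
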