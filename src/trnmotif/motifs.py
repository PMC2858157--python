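"""Three-node motif discovery in a mixed PPI/PDI network.

Every connected node triple is classified into a canonical triad class.  A
triple's state is encoded pairwise: for each of the 3 node pairs there are
eight possible states (no edge; PDI forward / backward / reciprocal; PPI;
PPI combined with each PDI state).  The class signature is the minimum of
this 9-bit code over all 6 relabelings of the triple, so it is invariant to
node order.  A PPI edge and a reciprocal PDI pair are distinct states
(binding is not regulation); an untyped mode that merges them is available.

Significance follows the standard randomization recipe: the observed count
of a class is compared with its counts in degree-preserving randomized
networks (independent edge switching within each edge type, preserving every
node's PPI degree and PDI in-/out-degree).  A class is a motif when it
occurs at least ``min_count`` times and at most a fraction ``alpha`` of the
randomized networks reach the observed count.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np

from .data_io import AnnotationSet, InteractionNetwork, Ontology

log = logging.getLogger(__name__)

__all__ = ["TriadCensus", "MotifRecord", "MotifReport", "TFAssignment",
           "DEFAULT_TF_TERMS", "enumerate_triads", "randomize",
           "motif_significance", "select_tfs", "assign_tfs", "signature_string"]

#: GO terms marking transcription-regulatory function (transcription factor
#: activity, regulation of transcription, transcription factor complex).
DEFAULT_TF_TERMS = frozenset({"GO:0003700", "GO:0061019", "GO:0005667"})

# ---------------------------------------------------------------------------
# canonical triad codes
#
# A triple (a, b, c) in fixed node order is coded with 9 bits, 3 per ordered
# pair in the order (a,b), (a,c), (b,c): bit0 PPI, bit1 PDI forward
# (first -> second), bit2 PDI backward.
# ---------------------------------------------------------------------------

_PAIR_ORDER = ((0, 1), (0, 2), (1, 2))
_PERMS = tuple(itertools.permutations(range(3)))

_STATE_TOKEN = {0: "none", 1: "ppi", 2: "pdi>", 3: "ppi+pdi>", 4: "pdi<",
                5: "ppi+pdi<", 6: "pdi<>", 7: "ppi+pdi<>"}


def _pair_states(code: int) -> dict[tuple[int, int], int]:
    return {pair: (code >> (3 * k)) & 0b111 for k, pair in enumerate(_PAIR_ORDER)}


def _swap_state(s: int) -> int:
    """Exchange the forward and backward PDI bits of a pair state."""
    ppi, fwd, rev = s & 1, (s >> 1) & 1, (s >> 2) & 1
    return ppi | (rev << 1) | (fwd << 2)


def _recode(code: int, perm: tuple[int, int, int]) -> int:
    states = _pair_states(code)
    out = 0
    for k, (a, b) in enumerate(_PAIR_ORDER):
        u, v = perm[a], perm[b]
        s = states[(u, v)] if u < v else _swap_state(states[(v, u)])
        out |= s << (3 * k)
    return out


def _build_canonical_table() -> tuple[np.ndarray, list[tuple[int, ...]]]:
    canon = np.zeros(512, dtype=np.int16)
    argperm: list[tuple[int, ...]] = [(0, 1, 2)] * 512
    for code in range(512):
        best, best_perm = None, None
        for perm in _PERMS:
            rc = _recode(code, perm)
            if best is None or rc < best:
                best, best_perm = rc, perm
        canon[code] = best
        argperm[code] = best_perm
    return canon, argperm


_CANON, _ARGPERM = _build_canonical_table()


def signature_string(canon_code: int) -> str:
    """Readable signature of a canonical code, one token per node pair."""
    states = _pair_states(int(canon_code))
    return "|".join(_STATE_TOKEN[states[p]] for p in _PAIR_ORDER)


#: Canonical signature of the feed-forward loop A->B, A->C, B->C.
FFL_SIGNATURE = signature_string(_CANON[(2 << 0) | (2 << 3) | (2 << 6)])


# ---------------------------------------------------------------------------
# enumeration
# ---------------------------------------------------------------------------

@dataclass
class TriadCensus:
    """Counts (and optionally instances) of every connected triad class."""

    counts: dict[str, int]
    instances: dict[str, list[tuple[str, str, str]]] | None = None
    #: canonical code per signature, kept for role mapping
    codes: dict[str, int] = field(default_factory=dict)
    #: raw (pre-canonical) code per instance, aligned with ``instances``
    raw_codes: dict[str, list[int]] = field(default_factory=dict)

    @property
    def n_triples(self) -> int:
        return sum(self.counts.values())


def _dense(net: InteractionNetwork, nodes: list[str]):
    idx = {n: i for i, n in enumerate(nodes)}
    n = len(nodes)
    P = np.zeros((n, n), dtype=bool)
    D = np.zeros((n, n), dtype=bool)
    for a, b in net.ppi_edges:
        P[idx[a], idx[b]] = P[idx[b], idx[a]] = True
    for a, b in net.pdi_edges:
        D[idx[a], idx[b]] = True
    return P, D


def _connected_triples(A: np.ndarray) -> np.ndarray:
    """Sorted unique connected node triples of an undirected adjacency."""
    ei, ej = np.nonzero(np.triu(A, 1))
    if ei.size == 0:
        return np.empty((0, 3), dtype=np.int64)
    chunks = []
    for i, j in zip(ei.tolist(), ej.tolist()):
        mask = A[i] | A[j]
        mask[i] = mask[j] = False
        ws = np.nonzero(mask)[0]
        if ws.size:
            t = np.empty((ws.size, 3), dtype=np.int64)
            t[:, 0], t[:, 1], t[:, 2] = i, j, ws
            chunks.append(t)
    if not chunks:
        return np.empty((0, 3), dtype=np.int64)
    triples = np.sort(np.concatenate(chunks), axis=1)
    return np.unique(triples, axis=0)


def enumerate_triads(net: InteractionNetwork, typed: bool = True,
                     store_instances: bool = True) -> TriadCensus:
    """Census of all connected three-node subgraphs.

    Each connected triple is counted exactly once; semantics match brute
    force over all node triples.  With ``typed=False`` a PPI edge and a
    reciprocal PDI pair are merged into one state.
    """
    nodes = sorted(net.nodes)
    if len(nodes) < 3:
        return TriadCensus(counts={}, instances={} if store_instances else None)
    P, D = _dense(net, nodes)
    if not typed:
        recip = D & D.T
        P = P | recip
        D = D & ~recip
    A = P | D | D.T
    triples = _connected_triples(A)
    if triples.size == 0:
        return TriadCensus(counts={}, instances={} if store_instances else None)
    a, b, c = triples[:, 0], triples[:, 1], triples[:, 2]
    bit = lambda arr, k: arr.astype(np.int16) << k  # noqa: E731
    code = (bit(P[a, b], 0) | bit(D[a, b], 1) | bit(D[b, a], 2)
            | bit(P[a, c], 3) | bit(D[a, c], 4) | bit(D[c, a], 5)
            | bit(P[b, c], 6) | bit(D[b, c], 7) | bit(D[c, b], 8))
    canon = _CANON[code]
    uniq, counts = np.unique(canon, return_counts=True)
    sigs = {int(u): signature_string(int(u)) for u in uniq}
    census = TriadCensus(
        counts={sigs[int(u)]: int(cnt) for u, cnt in zip(uniq, counts)},
        codes={sigs[int(u)]: int(u) for u in uniq},
    )
    if store_instances:
        node_arr = np.array(nodes)
        census.instances = {}
        for u in uniq:
            sel = canon == u
            sig = sigs[int(u)]
            census.instances[sig] = [tuple(row) for row in node_arr[triples[sel]]]
            census.raw_codes[sig] = [int(x) for x in code[sel]]
    return census


# ---------------------------------------------------------------------------
# randomization null model
# ---------------------------------------------------------------------------

def randomize(net: InteractionNetwork, seed: int | None = None,
              n_swaps_per_edge: int = 100,
              rng: np.random.Generator | None = None) -> InteractionNetwork:
    """Degree-preserving edge switching, independently within each edge type.

    PPI switches preserve every node's PPI degree; PDI switches preserve PDI
    in- and out-degrees.  Proposed switches that would create a self-loop or
    a duplicate edge are rejected.  ``n_swaps_per_edge`` switches are
    attempted per edge of each type.
    """
    if rng is None:
        rng = np.random.default_rng(seed)

    ppi = [tuple(e) for e in sorted(net.ppi_edges)]
    ppi_set = set(ppi)
    if len(ppi) >= 2:
        n_att = n_swaps_per_edge * len(ppi)
        picks = rng.integers(0, len(ppi), size=(n_att, 2))
        flips = rng.integers(0, 2, size=n_att)
        for i1, i2, flip in zip(picks[:, 0].tolist(), picks[:, 1].tolist(),
                                flips.tolist()):
            if i1 == i2:
                continue
            a, b = ppi[i1]
            c, d = ppi[i2]
            if flip:
                c, d = d, c
            if a == d or c == b:
                continue
            e1 = (a, d) if a < d else (d, a)
            e2 = (b, c) if b < c else (c, b)
            if e1 == e2 or e1 in ppi_set or e2 in ppi_set:
                continue
            ppi_set.discard(ppi[i1])
            ppi_set.discard(ppi[i2])
            ppi_set.update((e1, e2))
            ppi[i1], ppi[i2] = e1, e2

    pdi = [tuple(e) for e in sorted(net.pdi_edges)]
    pdi_set = set(pdi)
    if len(pdi) >= 2:
        n_att = n_swaps_per_edge * len(pdi)
        picks = rng.integers(0, len(pdi), size=(n_att, 2))
        for i1, i2 in zip(picks[:, 0].tolist(), picks[:, 1].tolist()):
            if i1 == i2:
                continue
            a, b = pdi[i1]
            c, d = pdi[i2]
            if a == d or c == b:
                continue
            e1, e2 = (a, d), (c, b)
            if e1 == e2 or e1 in pdi_set or e2 in pdi_set:
                continue
            pdi_set.discard(pdi[i1])
            pdi_set.discard(pdi[i2])
            pdi_set.update((e1, e2))
            pdi[i1], pdi[i2] = e1, e2

    return InteractionNetwork(set(net.nodes), ppi_set, pdi_set)


# ---------------------------------------------------------------------------
# significance
# ---------------------------------------------------------------------------

@dataclass
class MotifRecord:
    signature: str
    observed: int
    null_mean: float
    null_sd: float
    p: float
    z: float | None
    significant: bool


@dataclass
class MotifReport:
    """Per-class significance against the randomized ensemble."""

    records: dict[str, MotifRecord]
    n_random: int
    alpha: float
    min_count: int
    seed: int
    instances: dict[str, list[tuple[str, str, str]]]
    raw_codes: dict[str, list[int]]
    codes: dict[str, int]

    def significant_signatures(self) -> list[str]:
        return sorted(s for s, r in self.records.items() if r.significant)


def motif_significance(net: InteractionNetwork, n_random: int = 1000,
                       min_count: int = 5, alpha: float = 0.05, seed: int = 0,
                       n_swaps_per_edge: int = 100,
                       typed: bool = True) -> MotifReport:
    """Motif test: p = fraction of randomized networks with count >= observed.

    The observed network is excluded from the null ensemble.  A class is
    significant when p <= alpha and it occurs at least ``min_count`` times.
    Each null network is re-randomized from the original with a seed derived
    from the master seed, so results are reproducible.
    """
    observed = enumerate_triads(net, typed=typed, store_instances=True)
    sigs = sorted(observed.counts)
    null_counts = np.zeros((n_random, len(sigs)), dtype=np.int64)
    children = np.random.SeedSequence(seed).spawn(n_random)
    for r, child in enumerate(children):
        rnet = randomize(net, rng=np.random.default_rng(child),
                         n_swaps_per_edge=n_swaps_per_edge)
        counts = enumerate_triads(rnet, typed=typed, store_instances=False).counts
        for j, s in enumerate(sigs):
            null_counts[r, j] = counts.get(s, 0)

    records: dict[str, MotifRecord] = {}
    for j, s in enumerate(sigs):
        obs = observed.counts[s]
        nulls = null_counts[:, j]
        mean = float(nulls.mean())
        sd = float(nulls.std(ddof=1)) if n_random > 1 else 0.0
        p = float((nulls >= obs).mean())
        z = (obs - mean) / sd if sd > 0 else None
        records[s] = MotifRecord(signature=s, observed=obs, null_mean=mean,
                                 null_sd=sd, p=p, z=z,
                                 significant=(p <= alpha and obs >= min_count))
    return MotifReport(records=records, n_random=n_random, alpha=alpha,
                       min_count=min_count, seed=seed,
                       instances=observed.instances or {},
                       raw_codes=observed.raw_codes, codes=observed.codes)


# ---------------------------------------------------------------------------
# transcription factors
# ---------------------------------------------------------------------------

def select_tfs(ann: AnnotationSet, ont: Ontology,
               tf_terms: frozenset[str] | set[str] = DEFAULT_TF_TERMS) -> set[str]:
    """Genes annotated (after propagation) to a TF term or any descendant.

    Propagated sets are ancestor-closed, so annotation to a descendant of a
    TF term already places the TF term in the propagated set.
    """
    missing = set(tf_terms) - set(ont.terms)
    if missing:
        log.warning("TF terms absent from ontology: %s", sorted(missing))
    terms = set(tf_terms) & set(ont.terms)
    return {g for g, ts in ann.propagated.items() if ts & terms}


@dataclass
class TFAssignment:
    """TF -> significant motif classes it participates in as a regulator."""

    assigned: dict[str, dict[str, dict]]  # tf -> signature -> {count, roles}
    unassigned: list[str]


def assign_tfs(net: InteractionNetwork, report: MotifReport,
               tfs: set[str]) -> TFAssignment:
    """Assign each TF to every significant class where it acts as regulator.

    A TF counts toward a class instance only when it occupies a node with an
    outgoing PDI edge *within* that instance.  The recorded role is the
    canonical node position the TF maps to under the instance's canonical
    relabeling.
    """
    assigned: dict[str, dict[str, dict]] = {}
    for sig in report.significant_signatures():
        insts = report.instances.get(sig, [])
        raws = report.raw_codes.get(sig, [])
        for inst, raw in zip(insts, raws):
            perm = _ARGPERM[raw]
            for pos, gene in enumerate(inst):
                if gene not in tfs:
                    continue
                if not any((gene, other) in net.pdi_edges
                           for other in inst if other != gene):
                    continue
                canon_pos = perm.index(pos)
                entry = assigned.setdefault(gene, {}).setdefault(
                    sig, {"count": 0, "roles": set()})
                entry["count"] += 1
                entry["roles"].add(canon_pos)
    for tf in assigned:
        for sig in assigned[tf]:
            assigned[tf][sig]["roles"] = sorted(assigned[tf][sig]["roles"])
    unassigned = sorted(tfs - set(assigned))
    if unassigned:
        log.warning("TFs with no significant motif assignment: %s", unassigned)
    return TFAssignment(assigned=assigned, unassigned=unassigned)
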