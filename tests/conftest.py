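import numpy as np
import pytest

from trnmotif.data_io import AnnotationSet, ExpressionMatrix, InteractionNetwork, Ontology


@pytest.fixture()
def toy_dag():
    """Small diamond DAG in one namespace with hand-countable frequencies.

    R <- A <- C <- E and R <- B, with D below both A and B (diamond).
    Ten genes annotated so that p(A)=0.7, p(B)=0.5, p(C)=p(D)=0.3, p(E)=0.2.
    """
    ns = "biological_process"
    terms = {t: {"name": t, "namespace": ns} for t in "RABCDE"}
    parents = {"R": frozenset(), "A": frozenset("R"), "B": frozenset("R"),
               "C": frozenset("A"), "D": frozenset(("A", "B")),
               "E": frozenset("C")}
    ont = Ontology(terms, parents)
    direct = {"g1": {"E"}, "g2": {"E"}, "g3": {"C"}, "g4": {"D"}, "g5": {"D"},
              "g6": {"D"}, "g7": {"B"}, "g8": {"A"}, "g9": {"B"}, "g10": {"R"}}
    ann = AnnotationSet.from_direct(direct, ont)
    return ont, ann


@pytest.fixture()
def ffl_net():
    """One feed-forward loop A->B, A->C, B->C."""
    return InteractionNetwork({"A", "B", "C"}, set(),
                              {("A", "B"), ("A", "C"), ("B", "C")})


@pytest.fixture()
def small_expr():
    rng = np.random.default_rng(7)
    vals = rng.normal(size=(12, 6))
    return ExpressionMatrix([f"g{i}" for i in range(12)],
                            [str(t) for t in range(6)], vals,
                            np.zeros_like(vals, dtype=bool))


def random_mixed_network(rng: np.random.Generator, n_nodes: int,
                         n_ppi: int, n_pdi: int) -> InteractionNetwork:
    nodes = [f"n{i}" for i in range(n_nodes)]
    ppi, pdi = set(), set()
    while len(ppi) < n_ppi:
        a, b = rng.choice(n_nodes, size=2, replace=False)
        ppi.add(tuple(sorted((nodes[a], nodes[b]))))
    while len(pdi) < n_pdi:
        a, b = rng.choice(n_nodes, size=2, replace=False)
        pdi.add((nodes[a], nodes[b]))
    return InteractionNetwork(set(nodes), ppi, pdi)


_TOKEN = {0: "none", 1: "ppi", 2: "pdi>", 3: "ppi+pdi>", 4: "pdi<",
          5: "ppi+pdi<", 6: "pdi<>", 7: "ppi+pdi<>"}


def brute_force_triads(net: InteractionNetwork) -> dict[str, int]:
    """Independent oracle: classify every node triple by explicit lookup.

    Shares only the naming convention (pair order, token map, minimum of the
    9-bit code over relabelings) with the implementation; the enumeration and
    canonicalization logic are re-derived here from scratch.
    """
    import itertools

    def pair_state(u, v):
        s = 0
        if tuple(sorted((u, v))) in net.ppi_edges:
            s |= 1
        if (u, v) in net.pdi_edges:
            s |= 2
        if (v, u) in net.pdi_edges:
            s |= 4
        return s

    counts: dict[str, int] = {}
    for triple in itertools.combinations(sorted(net.nodes), 3):
        a, b, c = triple
        deg = {a: 0, b: 0, c: 0}
        for u, v in ((a, b), (a, c), (b, c)):
            if pair_state(u, v):
                deg[u] += 1
                deg[v] += 1
        if min(deg.values()) == 0:
            continue  # not a connected triple
        best = None
        for order in itertools.permutations(triple):
            code = 0
            for k, (i, j) in enumerate(((0, 1), (0, 2), (1, 2))):
                code |= pair_state(order[i], order[j]) << (3 * k)
            if best is None or code < best:
                best = code
        sig = "|".join(_TOKEN[(best >> (3 * k)) & 0b111] for k in range(3))
        counts[sig] = counts.get(sig, 0) + 1
    return counts
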