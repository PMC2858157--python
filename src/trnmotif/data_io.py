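"""Data model, readers/writers and preprocessing for the motif-inference pipeline.

The pipeline consumes three kinds of input:

* a probe x time-point expression table (tab- or comma-delimited, empty cells
  denote missing values), collapsed to one profile per gene, KNN-imputed and
  min--max standardized to [-1, 1];
* a typed interaction edge list mixing undirected protein--protein
  interactions (PPI) and directed protein--DNA interactions (PDI,
  regulator -> target);
* a Gene Ontology subset in OBO 1.2 format plus two-column gene -> term
  annotations, propagated along ``is_a`` links (true-path rule).

All identifiers are treated as opaque strings; no species mapping or probe
re-annotation is attempted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import obonet

log = logging.getLogger(__name__)

_GENE_HEADER_NAMES = {"gene", "gene_id", "geneid", "symbol", "gene_symbol"}


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------

@dataclass
class ExpressionMatrix:
    """Genes x time points with an explicit missing-value mask.

    ``values[i, t]`` is meaningful only where ``missing_mask[i, t]`` is False.
    """

    gene_ids: list[str]
    time_labels: list[str]
    values: np.ndarray
    missing_mask: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
        n, t = self.values.shape
        if self.missing_mask.shape != (n, t):
            raise ValueError("values and missing_mask shapes differ")
        if len(self.gene_ids) != n:
            raise ValueError("gene_ids length does not match values")
        if len(self.time_labels) != t:
            raise ValueError("time_labels length does not match values")
        if t < 2:
            raise ValueError("an expression matrix needs at least 2 time points")
        if len(set(self.gene_ids)) != n:
            dupes = sorted({g for g in self.gene_ids if self.gene_ids.count(g) > 1})
            raise ValueError(f"duplicate gene ids: {dupes}")
        if not np.all(np.isfinite(self.values[~self.missing_mask])):
            raise ValueError("non-finite value in an observed cell")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_times(self) -> int:
        return self.values.shape[1]

    def row(self, gene: str) -> np.ndarray:
        return self.values[self.gene_ids.index(gene)]

    def copy(self) -> "ExpressionMatrix":
        return ExpressionMatrix(list(self.gene_ids), list(self.time_labels),
                                self.values.copy(), self.missing_mask.copy())


@dataclass
class ProbeTable:
    """One expression profile per probe; several probes may map to one gene."""

    probe_ids: list[str]
    gene_ids: list[str]
    time_labels: list[str]
    values: np.ndarray
    missing_mask: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
        if len(set(self.probe_ids)) != len(self.probe_ids):
            dupes = sorted({p for p in self.probe_ids if self.probe_ids.count(p) > 1})
            raise ValueError(f"duplicate probe ids: {dupes}")
        if len(self.gene_ids) != len(self.probe_ids):
            raise ValueError("gene_ids length does not match probe_ids")


def _resolve_sep(path: str, dialect: str | None) -> str:
    if dialect == "csv":
        return ","
    if dialect == "tsv":
        return "\t"
    return "," if str(path).lower().endswith(".csv") else "\t"


def read_expression(path: str, dialect: str | None = None) -> ProbeTable:
    """Read a delimited probe x time expression table.

    The header row carries the time labels; the first column is the probe id
    and an optional second column (recognised by a gene-like header name) is
    the gene id.  Empty or non-numeric cells are recorded as missing.
    """
    sep = _resolve_sep(path, dialect)
    with open(path) as fh:
        lines = [ln.rstrip("\n").rstrip("\r") for ln in fh if ln.strip() != ""]
    if not lines:
        raise ValueError(f"{path}: empty file")
    header = lines[0].split(sep)
    n_fields = len(header)
    has_gene_col = len(header) > 1 and header[1].strip().lower() in _GENE_HEADER_NAMES
    first_data = 2 if has_gene_col else 1
    time_labels = [h.strip() for h in header[first_data:]]

    probe_ids: list[str] = []
    gene_ids: list[str] = []
    rows: list[list[float]] = []
    mask: list[list[bool]] = []
    for lineno, line in enumerate(lines[1:], start=2):
        fields = line.split(sep)
        if len(fields) != n_fields:
            raise ValueError(
                f"{path}: ragged row at line {lineno} "
                f"({len(fields)} fields, expected {n_fields})")
        probe = fields[0].strip()
        gene = fields[1].strip() if has_gene_col else probe
        vals, miss = [], []
        for cell in fields[first_data:]:
            cell = cell.strip()
            try:
                v = float(cell)
                if not np.isfinite(v):
                    raise ValueError
                vals.append(v)
                miss.append(False)
            except ValueError:
                vals.append(np.nan)
                miss.append(True)
        probe_ids.append(probe)
        gene_ids.append(gene if gene else probe)
        rows.append(vals)
        mask.append(miss)
    values = np.array(rows, dtype=float)
    values[np.array(mask, dtype=bool)] = 0.0
    return ProbeTable(probe_ids, gene_ids, time_labels, values,
                      np.array(mask, dtype=bool))


def write_expression(X: ExpressionMatrix | ProbeTable, path: str,
                     dialect: str | None = None) -> None:
    """Write an expression table; missing cells become empty fields."""
    sep = _resolve_sep(path, dialect)
    if isinstance(X, ExpressionMatrix):
        probe_ids, gene_ids = X.gene_ids, X.gene_ids
    else:
        probe_ids, gene_ids = X.probe_ids, X.gene_ids
    with open(path, "w") as fh:
        fh.write(sep.join(["probe", "gene"] + list(X.time_labels)) + "\n")
        for i, (p, g) in enumerate(zip(probe_ids, gene_ids)):
            cells = ["" if X.missing_mask[i, t] else repr(float(X.values[i, t]))
                     for t in range(X.values.shape[1])]
            fh.write(sep.join([p, g] + cells) + "\n")


def collapse_probes(probes: ProbeTable) -> ExpressionMatrix:
    """Collapse multi-probe genes, keeping the most variable probe per gene.

    Sample variance (denominator n-1) is computed over each probe's observed
    entries; ties are broken by the lexicographically smallest probe id.
    Genes whose probes are all missing are excluded with a warning.
    """
    by_gene: dict[str, list[int]] = {}
    order: list[str] = []
    for i, g in enumerate(probes.gene_ids):
        if g not in by_gene:
            by_gene[g] = []
            order.append(g)
        by_gene[g].append(i)

    keep_gene, keep_idx = [], []
    for g in order:
        best = None  # (-variance, probe_id, row index)
        for i in by_gene[g]:
            obs = probes.values[i][~probes.missing_mask[i]]
            if obs.size == 0:
                continue
            var = float(np.var(obs, ddof=1)) if obs.size >= 2 else -np.inf
            cand = (-var, probes.probe_ids[i], i)
            if best is None or cand < best:
                best = cand
        if best is None:
            log.warning("gene %s has only all-missing probes; excluded", g)
            continue
        keep_gene.append(g)
        keep_idx.append(best[2])
    idx = np.array(keep_idx, dtype=int)
    return ExpressionMatrix(keep_gene, list(probes.time_labels),
                            probes.values[idx].copy(),
                            probes.missing_mask[idx].copy())


def impute_knn(X: ExpressionMatrix, k: int = 10) -> ExpressionMatrix:
    """Fill missing cells from the k nearest gene profiles.

    Distance between two genes is the root-mean-square difference over the
    time points observed in both.  A missing cell (g, t) is replaced by the
    1/distance-weighted average of the k nearest genes observed at t (an
    exact-duplicate neighbour at distance zero is copied verbatim).  When no
    neighbour is observed at t the gene's own observed mean is used and a
    warning is logged.  Observed cells are never modified.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    obs = ~X.missing_mask
    n_obs = obs.sum(axis=1)
    if np.any(n_obs < 2):
        bad = [X.gene_ids[i] for i in np.where(n_obs < 2)[0]]
        raise ValueError(f"genes with fewer than 2 observed entries: {bad}")
    if not X.missing_mask.any():
        return X.copy()

    V = np.where(obs, X.values, 0.0)
    out = X.values.copy()
    for i in np.where(X.missing_mask.any(axis=1))[0]:
        diff = V - V[i]
        mutual = obs & obs[i]
        n_mutual = mutual.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            d = np.sqrt(np.where(mutual, diff ** 2, 0.0).sum(axis=1)
                        / np.maximum(n_mutual, 1))
        d[i] = np.inf
        d[n_mutual == 0] = np.inf
        for t in np.where(X.missing_mask[i])[0]:
            cand = np.where(obs[:, t] & np.isfinite(d))[0]
            if cand.size == 0:
                out[i, t] = X.values[i][obs[i]].mean()
                log.warning("gene %s, time %s: no KNN candidate observed; "
                            "falling back to gene mean", X.gene_ids[i],
                            X.time_labels[t])
                continue
            nearest = cand[np.argsort(d[cand], kind="stable")[:k]]
            dn = d[nearest]
            if np.any(dn == 0):
                out[i, t] = X.values[nearest[dn == 0], t].mean()
            else:
                w = 1.0 / dn
                out[i, t] = float(np.average(X.values[nearest, t], weights=w))
    return ExpressionMatrix(list(X.gene_ids), list(X.time_labels), out,
                            np.zeros_like(X.missing_mask))


def standardize(X: ExpressionMatrix) -> ExpressionMatrix:
    """Min--max standardize every gene profile to [-1, 1].

    x' = 2 (x - min) / (max - min) - 1, per gene; every row attains both -1
    and 1.  Requires a complete matrix; constant rows are a hard error since
    they carry no dynamic signal to fit.
    """
    if X.missing_mask.any():
        raise ValueError("standardize requires a complete matrix; impute first")
    lo = X.values.min(axis=1, keepdims=True)
    hi = X.values.max(axis=1, keepdims=True)
    flat = (hi - lo).ravel() == 0
    if flat.any():
        bad = [X.gene_ids[i] for i in np.where(flat)[0]]
        raise ValueError(f"constant expression rows cannot be standardized: {bad}")
    vals = 2.0 * (X.values - lo) / (hi - lo) - 1.0
    return ExpressionMatrix(list(X.gene_ids), list(X.time_labels), vals,
                            np.zeros_like(X.missing_mask))


# ---------------------------------------------------------------------------
# interaction network
# ---------------------------------------------------------------------------

@dataclass
class InteractionNetwork:
    """Mixed interaction graph.

    PPI edges are undirected (stored as sorted tuples); PDI edges are
    directed regulator -> target pairs.  A node stands for a gene and its
    protein product at once.
    """

    nodes: set[str]
    ppi_edges: set[tuple[str, str]]
    pdi_edges: set[tuple[str, str]]

    def __post_init__(self) -> None:
        for a, b in self.ppi_edges:
            if a == b:
                raise ValueError(f"PPI self-loop on {a}")
            if (a, b) != tuple(sorted((a, b))):
                raise ValueError(f"PPI edge not canonical: {(a, b)}")
        for a, b in self.pdi_edges:
            if a == b:
                raise ValueError(f"PDI self-loop on {a}")
        ends = {n for e in self.ppi_edges for n in e}
        ends |= {n for e in self.pdi_edges for n in e}
        if not ends <= self.nodes:
            raise ValueError(f"edge endpoints outside node set: {sorted(ends - self.nodes)}")

    @property
    def n_edges(self) -> int:
        return len(self.ppi_edges) + len(self.pdi_edges)

    def degree_triple(self, node: str) -> tuple[int, int, int]:
        """(ppi degree, pdi in-degree, pdi out-degree) of a node."""
        ppi = sum(1 for e in self.ppi_edges if node in e)
        pin = sum(1 for _, b in self.pdi_edges if b == node)
        pout = sum(1 for a, _ in self.pdi_edges if a == node)
        return ppi, pin, pout

    def copy(self) -> "InteractionNetwork":
        return InteractionNetwork(set(self.nodes), set(self.ppi_edges),
                                  set(self.pdi_edges))


def read_interactions(path: str) -> InteractionNetwork:
    """Read a 3-column (node_a, node_b, type) edge list; type is PPI or PDI.

    Reciprocal PPI rows collapse to one undirected edge, duplicate rows are
    dropped, and self-loops are dropped with a warning.  PDI rows are read as
    a regulates b.
    """
    nodes: set[str] = set()
    ppi: set[tuple[str, str]] = set()
    pdi: set[tuple[str, str]] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n").rstrip("\r")
            if not line.strip():
                continue
            fields = [f.strip() for f in line.split("\t")]
            if len(fields) == 1:
                fields = [f.strip() for f in line.split(",")]
            if len(fields) != 3:
                raise ValueError(f"{path}: line {lineno}: expected 3 columns")
            a, b, typ = fields
            if lineno == 1 and typ.lower() in {"type", "edge_type"}:
                continue
            typ_u = typ.upper()
            if typ_u not in {"PPI", "PDI"}:
                raise ValueError(f"{path}: line {lineno}: unknown edge type {typ!r}")
            if a == b:
                log.warning("%s: line %d: self-loop on %s dropped", path, lineno, a)
                continue
            nodes.update((a, b))
            if typ_u == "PPI":
                ppi.add(tuple(sorted((a, b))))
            else:
                pdi.add((a, b))
    log.info("%s: %d nodes, %d PPI edges, %d PDI edges", path, len(nodes),
             len(ppi), len(pdi))
    return InteractionNetwork(nodes, ppi, pdi)


def write_interactions(net: InteractionNetwork, path: str) -> None:
    with open(path, "w") as fh:
        for a, b in sorted(net.ppi_edges):
            fh.write(f"{a}\t{b}\tPPI\n")
        for a, b in sorted(net.pdi_edges):
            fh.write(f"{a}\t{b}\tPDI\n")


# ---------------------------------------------------------------------------
# ontology and annotations
# ---------------------------------------------------------------------------

NAMESPACES = ("biological_process", "molecular_function", "cellular_component")


@dataclass
class Ontology:
    """A GO subset: terms with a namespace and acyclic ``is_a`` parent links.

    Only ``is_a`` links are honoured (``part_of`` and other relations are
    ignored).  Each namespace has exactly one root.
    """

    terms: dict[str, dict]                 # id -> {"name", "namespace"}
    parents: dict[str, frozenset[str]]     # id -> is_a parents
    _anc_cache: dict[str, frozenset[str]] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        g = nx.DiGraph()
        g.add_nodes_from(self.terms)
        for t, ps in self.parents.items():
            for p in ps:
                g.add_edge(t, p)
        if not nx.is_directed_acyclic_graph(g):
            cyc = nx.find_cycle(g)
            raise ValueError(f"is_a cycle: {cyc}")
        roots: dict[str, list[str]] = {}
        for t, meta in self.terms.items():
            if not self.parents.get(t):
                roots.setdefault(meta["namespace"], []).append(t)
        for ns, rs in roots.items():
            if len(rs) > 1:
                raise ValueError(f"namespace {ns} has multiple roots: {sorted(rs)}")
        self.roots = {ns: rs[0] for ns, rs in roots.items()}
        for t, meta in self.terms.items():
            root = self.roots.get(meta["namespace"])
            if root is not None and root not in self.ancestors(t):
                raise ValueError(f"term {t} does not reach its namespace root")

    def namespace(self, term: str) -> str:
        return self.terms[term]["namespace"]

    def ancestors(self, term: str) -> frozenset[str]:
        """Ancestor closure of a term, including the term itself."""
        cached = self._anc_cache.get(term)
        if cached is not None:
            return cached
        anc = {term}
        for p in self.parents.get(term, ()):  # noqa: B007
            anc |= self.ancestors(p)
        result = frozenset(anc)
        self._anc_cache[term] = result
        return result

    def descendants(self, terms: set[str]) -> frozenset[str]:
        """All terms whose ancestor closure intersects ``terms`` (incl. themselves)."""
        return frozenset(t for t in self.terms if self.ancestors(t) & terms)


def read_ontology(path: str) -> Ontology:
    """Parse an OBO 1.2 subset into an :class:`Ontology` (is_a links only)."""
    graph = obonet.read_obo(path)
    terms: dict[str, dict] = {}
    parents: dict[str, frozenset[str]] = {}
    for node, data in graph.nodes(data=True):
        if data.get("is_obsolete") in ("true", True):
            continue
        ns = data.get("namespace")
        if ns not in NAMESPACES:
            log.warning("term %s has unknown namespace %r; skipped", node, ns)
            continue
        terms[node] = {"name": data.get("name", node), "namespace": ns}
    for node in terms:
        isa = [p for p in graph.successors(node)
               if p in terms and any(k == "is_a" for k in graph[node][p])]
        parents[node] = frozenset(isa)
    return Ontology(terms, parents)


def write_obo(ont: Ontology, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("format-version: 1.2\nontology: go-subset\n\n")
        for t in sorted(ont.terms):
            meta = ont.terms[t]
            fh.write("[Term]\n")
            fh.write(f"id: {t}\n")
            fh.write(f"name: {meta['name']}\n")
            fh.write(f"namespace: {meta['namespace']}\n")
            for p in sorted(ont.parents.get(t, ())):
                fh.write(f"is_a: {p} ! {ont.terms[p]['name']}\n")
            fh.write("\n")


@dataclass
class AnnotationSet:
    """Direct gene -> term annotations plus their is_a ancestor closure."""

    direct: dict[str, frozenset[str]]
    propagated: dict[str, frozenset[str]]

    @classmethod
    def from_direct(cls, direct: dict[str, set[str]], ont: Ontology) -> "AnnotationSet":
        d = {g: frozenset(ts) for g, ts in direct.items() if ts}
        prop = {}
        for g, ts in d.items():
            closure: set[str] = set()
            for t in ts:
                closure |= ont.ancestors(t)
            prop[g] = frozenset(closure)
        return cls(d, prop)

    @property
    def genes(self) -> set[str]:
        return set(self.direct)


def read_annotations(path: str, ont: Ontology) -> AnnotationSet:
    """Read two-column gene<TAB>term annotations; unknown terms are dropped."""
    direct: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n").rstrip("\r")
            if not line.strip() or line.startswith("#"):
                continue
            fields = [f.strip() for f in line.split("\t")]
            if len(fields) != 2:
                raise ValueError(f"{path}: line {lineno}: expected 2 columns")
            gene, term = fields
            if term not in ont.terms:
                log.warning("%s: line %d: unknown/obsolete term %s dropped",
                            path, lineno, term)
                continue
            direct.setdefault(gene, set()).add(term)
    return AnnotationSet.from_direct(direct, ont)


def write_annotations(ann: AnnotationSet, path: str) -> None:
    with open(path, "w") as fh:
        for g in sorted(ann.direct):
            for t in sorted(ann.direct[g]):
                fh.write(f"{g}\t{t}\n")


def write_gmt(clusters: dict[int, list[str]], path: str,
              description: str = "cluster") -> None:
    """Write clusters as GMT lines: name, description, member genes."""
    with open(path, "w") as fh:
        for ci in sorted(clusters):
            genes = "\t".join(clusters[ci])
            fh.write(f"cluster_{ci}\t{description}\t{genes}\n")


def read_gmt(path: str) -> dict[int, list[str]]:
    out: dict[int, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                continue
            ci = int(fields[0].rsplit("_", 1)[-1])
            out[ci] = fields[2:]
    return out
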