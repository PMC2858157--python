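"""Synthetic scenarios with planted ground truth for every pipeline stage.

The generator emulates the shape of the real inputs without any downloads:

* **Expression** -- periodic, standardizable time courses (default 47 time
  points, the length of the longest real cell-cycle course this kind of
  analysis uses).  Transcription factors are sinusoidal drivers with seeded
  random phase and period; member genes of planted target clusters follow
  the RNN trajectory of their module plus Gaussian noise; the remaining gene
  clusters share a smooth random standardized course plus per-gene noise;
  unclustered filler genes are independent smoothed noise.  A small fraction
  of cells is masked as missing.
* **Network** -- planted copies of a four-motif catalog (single TF driving
  two PPI-linked clusters; two PPI-linked TFs sharing a target; a
  feed-forward loop; a TF plus a cofactor bound to the target) over distinct
  target nodes, plus Erdos--Renyi background edges of both types that avoid
  planted pairs.
* **Annotations** -- a three-level toy DAG per GO namespace; genes of the
  same true cluster share a cluster-specific deep term with probability
  ``annotation_share_p``, everyone carries a few random shallow terms, and
  TF genes carry the transcription-regulation GO terms.

Everything is a deterministic function of the scenario seed.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .clustering import ClusterSet
from .data_io import (AnnotationSet, ExpressionMatrix, InteractionNetwork,
                      Ontology)
from . import data_io
from .module_inference import MotifTopology, RNNParams, TRNM, rnn_simulate
from .motifs import enumerate_triads

__all__ = ["CATALOG", "PlantedModule", "Scenario", "SyntheticData", "generate",
           "make_network", "make_expression", "make_annotations",
           "write_scenario", "small_scenario", "paperlike_scenario",
           "validity_scenario", "ffl_scenario", "topology_signature",
           "evaluate_recovery"]


CATALOG: dict[str, MotifTopology] = {
    # one TF drives two clusters whose products interact
    "tf_two_clusters": MotifTopology(
        tf_roles=("TF",), cluster_roles=("C1", "C2"),
        edges=(("TF", "C1", "pdi"), ("TF", "C2", "pdi"), ("C1", "C2", "ppi"))),
    # two interacting TFs co-regulate one cluster
    "coregulation": MotifTopology(
        tf_roles=("TF", "TF2"), cluster_roles=("C1",),
        edges=(("TF", "TF2", "ppi"), ("TF", "C1", "pdi"), ("TF2", "C1", "pdi"))),
    # feed-forward loop through an intermediate cluster
    "ffl": MotifTopology(
        tf_roles=("TF",), cluster_roles=("C1", "C2"),
        edges=(("TF", "C1", "pdi"), ("C1", "C2", "pdi"), ("TF", "C2", "pdi"))),
    # TF regulates a cluster whose product binds a cofactor
    "cofactor": MotifTopology(
        tf_roles=("TF", "TF2"), cluster_roles=("C1",),
        edges=(("TF", "C1", "pdi"), ("TF2", "C1", "ppi"))),
}


def topology_signature(top: MotifTopology) -> str:
    """Canonical triad signature of a three-role motif topology."""
    roles = list(top.tf_roles) + list(top.cluster_roles)
    if len(roles) != 3:
        raise ValueError("signature defined for three-node topologies only")
    ppi, pdi = set(), set()
    for s, d, kind in top.edges:
        if kind == "ppi":
            ppi.add(tuple(sorted((s, d))))
        else:
            pdi.add((s, d))
    census = enumerate_triads(InteractionNetwork(set(roles), ppi, pdi),
                              store_instances=False)
    (sig,) = census.counts
    return sig


@dataclass
class PlantedModule:
    """One ground-truth regulatory module to plant in the scenario."""

    name: str                      # catalog key
    tf_ids: tuple[str, ...]        # genes for the topology's TF roles, in order
    cluster_ids: tuple[int, ...]   # true-cluster index per cluster role
    n_instances: int = 8
    params: RNNParams | None = None  # drawn from the scenario RNG when None


@dataclass
class Scenario:
    """Generator configuration; all sizes/noise levels live here."""

    seed: int = 0
    T: int = 47
    n_tfs: int = 6
    n_clusters_true: int = 6
    cluster_size: int = 12
    n_noise_genes: int = 8
    instances_per_module: int = 8
    noise_sd: float = 0.15
    background_ppi: int = 40
    background_pdi: int = 20
    missing_rate: float = 0.02
    annotation_share_p: float = 0.8
    n_shallow_terms: int = 2
    #: planted cluster bases are redrawn until at least this far (per-point
    #: RMS) from every other base, so distinct groups are really distinct
    min_base_distance: float = 0.6
    planted: tuple[PlantedModule, ...] | None = None  # None -> default three

    def __post_init__(self) -> None:
        if self.T < 10:
            raise ValueError("T must be >= 10")

    @property
    def tf_ids(self) -> list[str]:
        return [f"TF{i + 1:02d}" for i in range(self.n_tfs)]

    @property
    def cluster_members(self) -> dict[int, list[str]]:
        out = {}
        g = 0
        for c in range(self.n_clusters_true):
            out[c] = [f"G{g + i + 1:03d}" for i in range(self.cluster_size)]
            g += self.cluster_size
        return out

    @property
    def noise_gene_ids(self) -> list[str]:
        return [f"N{i + 1:03d}" for i in range(self.n_noise_genes)]

    def default_planted(self) -> tuple[PlantedModule, ...]:
        if self.n_tfs < 4 or self.n_clusters_true < 5:
            return ()
        tfs = self.tf_ids
        k = self.instances_per_module
        return (
            PlantedModule("tf_two_clusters", (tfs[0],), (0, 1), k),
            PlantedModule("coregulation", (tfs[1], tfs[2]), (2,), k),
            PlantedModule("ffl", (tfs[3],), (3, 4), k),
        )


@dataclass
class SyntheticData:
    scenario: Scenario
    net: InteractionNetwork
    truth: dict
    expr: ExpressionMatrix
    ontology: Ontology
    annotations: AnnotationSet


def _draw_params(top: MotifTopology, rng: np.random.Generator) -> RNNParams:
    # moderate drive: trajectories swing widely without saturating tanh, so
    # the fitting landscape stays smooth and standardization distortion small
    w = {}
    for e in top.param_edges:
        w[e] = float(rng.choice([-1.0, 1.0]) * rng.uniform(1.8, 2.8))
    beta = {r: float(rng.uniform(-0.25, 0.25)) for r in top.cluster_roles}
    tau = {r: float(rng.uniform(1.0, 2.0)) for r in top.cluster_roles}
    return RNNParams(w=w, beta=beta, tau=tau)


def _params_to_dict(p: RNNParams) -> dict:
    return {"w": {f"{s}->{d}({k})": v for (s, d, k), v in sorted(p.w.items())},
            "beta": dict(sorted(p.beta.items())),
            "tau": dict(sorted(p.tau.items())), "dt": p.dt}


def make_network(sc: Scenario, rng: np.random.Generator,
                 ) -> tuple[InteractionNetwork, dict]:
    """Plant motif instances over distinct target nodes, then add background."""
    members = sc.cluster_members
    nodes = set(sc.tf_ids) | {g for gs in members.values() for g in gs} \
        | set(sc.noise_gene_ids)
    planted = sc.planted if sc.planted is not None else sc.default_planted()
    ppi: set[tuple[str, str]] = set()
    pdi: set[tuple[str, str]] = set()
    forbidden: set[tuple[str, str]] = set()  # pairs inside planted instances
    modules_truth = []
    for mod in planted:
        top = CATALOG[mod.name]
        params = mod.params or _draw_params(top, rng)
        if mod.n_instances > sc.cluster_size:
            raise ValueError(f"module {mod.name}: cluster_size "
                             f"{sc.cluster_size} < {mod.n_instances} instances")
        instances = []
        for i in range(mod.n_instances):
            role_gene = {r: g for r, g in zip(top.tf_roles, mod.tf_ids)}
            for r, cid in zip(top.cluster_roles, mod.cluster_ids):
                role_gene[r] = members[cid][i]
            for s, d, kind in top.edges:
                u, v = role_gene[s], role_gene[d]
                if kind == "ppi":
                    ppi.add(tuple(sorted((u, v))))
                else:
                    pdi.add((u, v))
            inst = tuple(sorted(role_gene.values()))
            instances.append(list(inst))
            for a in inst:
                for b in inst:
                    if a < b:
                        forbidden.add((a, b))
        modules_truth.append({
            "name": mod.name,
            "signature": topology_signature(top),
            "tfs": list(mod.tf_ids),
            "clusters": list(mod.cluster_ids),
            "params": _params_to_dict(params),
            "instances": instances,
        })

    node_list = sorted(nodes)
    existing = lambda a, b: (tuple(sorted((a, b))) in ppi or (a, b) in pdi  # noqa: E731
                             or (b, a) in pdi
                             or tuple(sorted((a, b))) in forbidden)
    added = 0
    while added < sc.background_ppi:
        a, b = rng.choice(len(node_list), size=2, replace=False)
        a, b = node_list[a], node_list[b]
        if existing(a, b):
            continue
        ppi.add(tuple(sorted((a, b))))
        added += 1
    added = 0
    while added < sc.background_pdi:
        a, b = rng.choice(len(node_list), size=2, replace=False)
        a, b = node_list[a], node_list[b]
        if existing(a, b):
            continue
        pdi.add((a, b))
        added += 1

    truth = {
        "tf_ids": sc.tf_ids,
        "clusters": {str(c): gs for c, gs in members.items()},
        "modules": modules_truth,
        "planted_params": {m["name"]: m["params"] for m in modules_truth},
    }
    return InteractionNetwork(nodes, ppi, pdi), truth


def make_expression(sc: Scenario, truth: dict,
                    rng: np.random.Generator) -> ExpressionMatrix:
    """Expression courses: sinusoidal TF drivers, RNN module trajectories,
    smooth random cluster bases, smoothed-noise filler genes."""
    t = np.arange(sc.T, dtype=float)
    tf_profiles: dict[str, np.ndarray] = {}
    for g in sc.tf_ids:
        period = sc.T / 2.0 * rng.uniform(0.8, 1.2)
        phase = rng.uniform(0, 2 * np.pi)
        tf_profiles[g] = np.sin(2 * np.pi * t / period + phase)

    members = sc.cluster_members
    module_traj: dict[int, np.ndarray] = {}
    for mod in truth["modules"]:
        top = CATALOG[mod["name"]]
        params = _dict_to_params(mod["params"])
        regulators = {r: tf_profiles[g] for r, g in zip(top.tf_roles, mod["tfs"])}
        traj = rnn_simulate(top, params, regulators)
        for r, cid in zip(top.cluster_roles, mod["clusters"]):
            module_traj[int(cid)] = traj[r]

    gene_ids: list[str] = []
    rows: list[np.ndarray] = []
    for g in sc.tf_ids:
        gene_ids.append(g)
        rows.append(tf_profiles[g])
    bases: dict[int, np.ndarray] = {}
    accepted: list[np.ndarray] = []
    for c in range(sc.n_clusters_true):
        if c in module_traj:
            bases[c] = module_traj[c]
            accepted.append(bases[c])
    for c in range(sc.n_clusters_true):
        if c in module_traj:
            continue
        # smooth random course, standardized to [-1, 1] and redrawn until
        # separated from every base already planted
        best, best_d = None, -1.0
        for _ in range(200):
            b = gaussian_filter1d(rng.normal(0, 1.0, size=sc.T), sigma=3.0)
            b = 2.0 * (b - b.min()) / (b.max() - b.min()) - 1.0
            d = min((float(np.sqrt(np.mean((b - o) ** 2))) for o in accepted),
                    default=np.inf)
            if d > best_d:
                best, best_d = b, d
            if d >= sc.min_base_distance:
                break
        bases[c] = best
        accepted.append(best)
    for c in range(sc.n_clusters_true):
        for g in members[c]:
            gene_ids.append(g)
            rows.append(bases[c] + rng.normal(0, sc.noise_sd, size=sc.T))
    for g in sc.noise_gene_ids:
        gene_ids.append(g)
        rows.append(gaussian_filter1d(rng.normal(0, 1.0, size=sc.T), sigma=2.0))

    values = np.asarray(rows)
    mask = rng.random(values.shape) < sc.missing_rate
    # keep every row imputable and non-constant
    for i in range(mask.shape[0]):
        if (~mask[i]).sum() < 2:
            mask[i] = False
    values = values.copy()
    values[mask] = 0.0
    return ExpressionMatrix(gene_ids, [str(int(x)) for x in t], values, mask)


def _dict_to_params(d: dict) -> RNNParams:
    w = {}
    for key, v in d["w"].items():
        sd, kind = key.rsplit("(", 1)
        s, dst = sd.split("->")
        w[(s, dst, kind.rstrip(")"))] = float(v)
    return RNNParams(w=w, beta={k: float(v) for k, v in d["beta"].items()},
                     tau={k: float(v) for k, v in d["tau"].items()},
                     dt=float(d.get("dt", 1.0)))


#: GO terms flagging transcription-regulatory genes in generated annotations.
TF_TERMS = ("GO:0003700", "GO:0061019", "GO:0005667")


def make_annotations(sc: Scenario, truth: dict, rng: np.random.Generator,
                     ) -> tuple[Ontology, AnnotationSet]:
    """Three-level toy DAG per namespace plus cluster-coherent annotations."""
    if sc.n_clusters_true < 2:
        raise ValueError("need >= 2 true clusters")
    terms: dict[str, dict] = {}
    parents: dict[str, frozenset[str]] = {}

    def add(tid: str, name: str, ns: str, *ps: str) -> None:
        terms[tid] = {"name": name, "namespace": ns}
        parents[tid] = frozenset(ps)

    add("GO:0008150", "biological_process", "biological_process")
    add("GO:0003674", "molecular_function", "molecular_function")
    add("GO:0005575", "cellular_component", "cellular_component")
    generic_mids = []
    for k in range(4):
        add(f"GO:010000{k}", f"bp process {k}", "biological_process", "GO:0008150")
        generic_mids.append(f"GO:010000{k}")
    for k in range(3):
        add(f"GO:020000{k}", f"mf activity {k}", "molecular_function", "GO:0003674")
        generic_mids.append(f"GO:020000{k}")
        add(f"GO:030000{k}", f"cc component {k}", "cellular_component", "GO:0005575")
        generic_mids.append(f"GO:030000{k}")
    add("GO:0003700", "transcription factor activity", "molecular_function",
        "GO:0003674")
    add("GO:0061019", "regulation of transcription", "biological_process",
        "GO:0008150")
    add("GO:0005667", "transcription factor complex", "cellular_component",
        "GO:0005575")
    deep_of_cluster: dict[int, str] = {}
    for c in range(sc.n_clusters_true):
        tid = f"GO:011{c:04d}"
        add(tid, f"cluster process {c}", "biological_process",
            f"GO:010000{c % 4}")
        deep_of_cluster[c] = tid
    ont = Ontology(terms, parents)

    direct: dict[str, set[str]] = {}
    for c, genes in sc.cluster_members.items():
        for g in genes:
            ts = set()
            if rng.random() < sc.annotation_share_p:
                ts.add(deep_of_cluster[c])
            if sc.n_shallow_terms > 0:
                for _ in range(int(rng.integers(1, sc.n_shallow_terms + 1))):
                    ts.add(generic_mids[int(rng.integers(len(generic_mids)))])
            if not ts:
                ts.add(generic_mids[int(rng.integers(len(generic_mids)))])
            direct[g] = ts
    for g in sc.tf_ids:
        ts = {TF_TERMS[int(rng.integers(len(TF_TERMS)))]}
        ts.add(generic_mids[int(rng.integers(len(generic_mids)))])
        direct[g] = ts
    for g in sc.noise_gene_ids:
        direct[g] = {generic_mids[int(rng.integers(len(generic_mids)))]}
    return ont, AnnotationSet.from_direct(direct, ont)


def generate(sc: Scenario) -> SyntheticData:
    """Generate the full scenario deterministically from its seed."""
    rng = np.random.default_rng(np.random.SeedSequence(sc.seed))
    net, truth = make_network(sc, rng)
    expr = make_expression(sc, truth, rng)
    ont, ann = make_annotations(sc, truth, rng)
    return SyntheticData(scenario=sc, net=net, truth=truth, expr=expr,
                         ontology=ont, annotations=ann)


def write_scenario(data: SyntheticData, outdir: str) -> dict[str, str]:
    os.makedirs(outdir, exist_ok=True)
    paths = {
        "expr": os.path.join(outdir, "expr.tsv"),
        "net": os.path.join(outdir, "net.tsv"),
        "obo": os.path.join(outdir, "go.obo"),
        "ann": os.path.join(outdir, "ann.tsv"),
        "truth": os.path.join(outdir, "truth.json"),
    }
    data_io.write_expression(data.expr, paths["expr"])
    data_io.write_interactions(data.net, paths["net"])
    data_io.write_obo(data.ontology, paths["obo"])
    data_io.write_annotations(data.annotations, paths["ann"])
    with open(paths["truth"], "w") as fh:
        json.dump(data.truth, fh, indent=1, sort_keys=True)
    return paths


# ---------------------------------------------------------------------------
# presets
# ---------------------------------------------------------------------------

def small_scenario(seed: int = 0) -> Scenario:
    """End-to-end scenario: 3 planted modules, 86 genes, 47 time points.

    Annotations are homogeneous within true clusters (share 1.0, no shallow
    terms) so the cluster-number selection is identifiable end to end; the
    general :class:`Scenario` defaults keep the noisier annotation model.
    """
    return Scenario(seed=seed, annotation_share_p=1.0, n_shallow_terms=0)


def validity_scenario(seed: int = 0) -> Scenario:
    """Six annotation-coherent expression clusters, no modules; for the c sweep.

    Designed so the planted cluster number is identifiable: the cluster bases
    are separated well beyond the within-group spread (so c=6 recovers them),
    and annotation coherence is homogeneous within groups (every member
    carries the group's deep term and nothing else).  Merging or mixing
    groups then strictly lowers the validity score, while splitting a pure
    group leaves it unchanged -- and ties resolve toward the smallest c.
    """
    return Scenario(seed=seed, T=24, n_tfs=0, n_clusters_true=6,
                    cluster_size=10, n_noise_genes=0, planted=(),
                    noise_sd=0.2, missing_rate=0.0,
                    annotation_share_p=1.0, n_shallow_terms=0,
                    background_ppi=10, background_pdi=5)


def paperlike_scenario(seed: int = 0) -> Scenario:
    """A full-size scenario: 846 genes, 47 points, ~1300 PPIs / ~550 PDIs.

    Echoes the scale of a genome-wide cell-cycle study; intended for
    generating realistic-size inputs, not for quick end-to-end runs.
    """
    return Scenario(seed=seed, T=47, n_tfs=20, n_clusters_true=20,
                    cluster_size=40, n_noise_genes=26,
                    background_ppi=1300, background_pdi=550)


def ffl_scenario(seed: int = 0) -> Scenario:
    """20 feed-forward loops planted in a 100-node sparse mixed background."""
    tfs = [f"TF{i + 1:02d}" for i in range(4)]
    planted = tuple(
        PlantedModule("ffl", (tfs[m],), (2 * m, 2 * m + 1), n_instances=5)
        for m in range(4))
    return Scenario(seed=seed, T=12, n_tfs=4, n_clusters_true=8,
                    cluster_size=5, n_noise_genes=56, planted=planted,
                    background_ppi=60, background_pdi=40, missing_rate=0.0)


# ---------------------------------------------------------------------------
# recovery evaluation
# ---------------------------------------------------------------------------

def map_inferred_clusters(truth: dict, cs: ClusterSet) -> dict[int, int | None]:
    """Majority map from hardened cluster index to true cluster index.

    Each hardened cluster maps to the true cluster contributing most of its
    members (ties to the smaller true index; None when no member belongs to
    any true cluster).  Over-splitting a true cluster maps every fragment
    back to it.
    """
    true_of_gene = {g: int(c) for c, gs in truth["clusters"].items() for g in gs}
    mapping: dict[int, int | None] = {}
    for ci, genes in cs.members().items():
        votes: dict[int, int] = {}
        for g in genes:
            tc = true_of_gene.get(g)
            if tc is not None:
                votes[tc] = votes.get(tc, 0) + 1
        mapping[ci] = (min(sorted(votes), key=lambda c: (-votes[c], c))
                       if votes else None)
    return mapping


def evaluate_recovery(modules: list[TRNM] | list[dict], truth: dict,
                      cs: ClusterSet) -> tuple[int, int]:
    """How many planted modules were recovered exactly (TF, class, clusters).

    A planted module counts as recovered when some inferred module has the
    same motif signature, a focal TF among the module's TFs, and inferred
    target clusters that majority-map onto exactly the planted true clusters
    (as a multiset).  The majority map makes the check robust to a hardened
    partition that splits a true cluster.
    """
    mapping = map_inferred_clusters(truth, cs)
    inferred = []
    for m in modules:
        d = m.to_dict() if isinstance(m, TRNM) else m
        mapped = tuple(sorted((mapping.get(int(ci)) if mapping.get(int(ci))
                               is not None else -1)
                              for ci in d["cluster_map"].values()))
        inferred.append((d["signature"], d["tf_map"].get("TF"), mapped))
    n_rec = 0
    for mod in truth["modules"]:
        want = (mod["signature"], tuple(sorted(int(c) for c in mod["clusters"])))
        ok = any(sig == want[0] and tf in mod["tfs"] and cls == want[1]
                 for sig, tf, cls in inferred)
        n_rec += bool(ok)
    return n_rec, len(truth["modules"])
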