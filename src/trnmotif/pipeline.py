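"""End-to-end orchestration: preprocess -> cluster -> validity -> motifs ->
assign -> infer, with file-based stage outputs, resume, and a run manifest.

Every stage is a pure function of (inputs, config, seed); rerunning with the
same inputs and master seed reproduces the module JSON byte for byte.  On
resume, a stage is skipped when its outputs exist and no upstream stage ran.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
import time
import tomllib
from dataclasses import asdict

import numpy as np

from . import data_io, clustering, go_semantics
from .clustering import ClusterSet
from .module_inference import GAConfig, OptimConfig, PSOConfig, infer_modules
from .motifs import (DEFAULT_TF_TERMS, MotifRecord, MotifReport, TFAssignment,
                     assign_tfs, motif_significance, select_tfs)

log = logging.getLogger(__name__)

__all__ = ["default_config", "write_config_toml", "load_config", "run_pipeline",
           "STAGES"]

STAGES = ("preprocess", "cluster", "validity", "motifs", "assign", "infer")

_DEPS = {
    "preprocess": (),
    "cluster": ("preprocess",),
    "validity": ("cluster",),
    "motifs": (),
    "assign": ("motifs",),
    "infer": ("preprocess", "validity", "motifs", "assign"),
}

_OUTPUTS = {
    "preprocess": ("expr_std.tsv",),
    "cluster": ("sweep.json",),
    "validity": ("validity.tsv", "clusters.gmt", "best_c.json",
                 "enrichment.tsv"),
    "motifs": ("motif_report.json",),
    "assign": ("tf_assignment.json",),
    "infer": ("trnm.json", "summary.tsv"),
}


def default_config(expr: str, net: str, obo: str, ann: str,
                   seed: int = 17) -> dict:
    """Desk-scale defaults for the full pipeline on a synthetic scenario."""
    return {
        "input": {"expr": expr, "net": net, "obo": obo, "ann": ann},
        "seed": seed,
        "preprocess": {"knn_k": 10},
        "cluster": {"c_min": 2, "c_max": 12, "m": "auto", "n_seeds": 3},
        "validity": {"pooling": "pairs"},
        "motifs": {"n_random": 1000, "alpha": 0.05, "min_count": 5,
                   "swaps_per_edge": 100},
        "tfs": {"terms": sorted(DEFAULT_TF_TERMS)},
        "infer": {"pso_swarm": 24, "pso_iterations": 150, "ga_population": 24,
                  "ga_generations": 40, "rmse_stop": 0.05},
    }


def write_config_toml(cfg: dict, path: str) -> None:
    def fmt(v):
        if isinstance(v, bool):
            return "true" if v else "false"
        if isinstance(v, str):
            return json.dumps(v)
        if isinstance(v, (list, tuple)):
            return "[" + ", ".join(fmt(x) for x in v) + "]"
        return repr(v) if isinstance(v, float) else str(v)

    with open(path, "w") as fh:
        # top-level scalars must precede any [table]
        for key, val in cfg.items():
            if not isinstance(val, dict):
                fh.write(f"{key} = {fmt(val)}\n")
        for key, val in cfg.items():
            if isinstance(val, dict):
                fh.write(f"\n[{key}]\n")
                for k, v in val.items():
                    fh.write(f"{k} = {fmt(v)}\n")


def load_config(path: str) -> dict:
    with open(path, "rb") as fh:
        return tomllib.load(fh)


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _dump_json(obj, path: str) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, sort_keys=True)
        fh.write("\n")


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def stage_preprocess(cfg: dict, outdir: str) -> None:
    probes = data_io.read_expression(cfg["input"]["expr"])
    X = data_io.collapse_probes(probes)
    X = data_io.impute_knn(X, k=int(cfg.get("preprocess", {}).get("knn_k", 10)))
    X = data_io.standardize(X)
    data_io.write_expression(X, os.path.join(outdir, "expr_std.tsv"))


def stage_cluster(cfg: dict, outdir: str) -> None:
    probes = data_io.read_expression(os.path.join(outdir, "expr_std.tsv"))
    X = data_io.collapse_probes(probes)
    ccfg = cfg.get("cluster", {})
    m_setting = ccfg.get("m", "auto")
    m = (clustering.estimate_fuzziness(X) if m_setting == "auto"
         else float(m_setting))
    seeds = tuple(range(int(ccfg.get("n_seeds", 3))))
    sweep = clustering.sweep_partitions(
        X, m, c_range=(int(ccfg.get("c_min", 2)), int(ccfg.get("c_max", 12))),
        seeds=seeds)
    payload = {"m": m, "seeds": list(seeds), "partitions": []}
    for part in sweep:
        cs = clustering.harden(part, X)
        payload["partitions"].append({
            "c": part.c, "objective": part.objective, "seed": part.seed,
            "labels": dict(sorted(cs.labels.items())),
        })
    _dump_json(payload, os.path.join(outdir, "sweep.json"))


def _clusterset_from_labels(labels: dict[str, int],
                            X: data_io.ExpressionMatrix) -> ClusterSet:
    profiles: dict[int, np.ndarray] = {}
    row = {g: X.values[i] for i, g in enumerate(X.gene_ids)}
    members: dict[int, list[str]] = {}
    for g, ci in labels.items():
        members.setdefault(int(ci), []).append(g)
    for ci, gs in members.items():
        profiles[ci] = np.mean([row[g] for g in gs], axis=0)
    return ClusterSet(labels={g: int(ci) for g, ci in labels.items()},
                      profiles=profiles)


def stage_validity(cfg: dict, outdir: str) -> None:
    probes = data_io.read_expression(os.path.join(outdir, "expr_std.tsv"))
    X = data_io.collapse_probes(probes)
    with open(os.path.join(outdir, "sweep.json")) as fh:
        sweep = json.load(fh)
    ont = data_io.read_ontology(cfg["input"]["obo"])
    ann = data_io.read_annotations(cfg["input"]["ann"], ont)
    ic = go_semantics.information_content(ann, ont)
    sim = go_semantics.GeneSimilarity(ann, ic, ont)
    items = [(p["c"], _clusterset_from_labels(p["labels"], X))
             for p in sweep["partitions"]]
    pooling = cfg.get("validity", {}).get("pooling", "pairs")
    best_cs, best_vs, table = go_semantics.select_from_clustersets(
        items, sim, pooling=pooling)
    with open(os.path.join(outdir, "validity.tsv"), "w") as fh:
        fh.write("c\tscore\tn_pairs\tn_skipped\n")
        for vs in table:
            fh.write(f"{vs.c}\t{vs.score:.6f}\t{vs.n_pairs}\t{vs.n_skipped}\n")
    data_io.write_gmt(best_cs.members(), os.path.join(outdir, "clusters.gmt"),
                      description=f"m={sweep['m']:.4f}")
    _dump_json({"c": best_vs.c, "score": best_vs.score, "m": sweep["m"]},
               os.path.join(outdir, "best_c.json"))
    # GO over-representation of each cluster of the selected partition
    universe = set(X.gene_ids)
    n_resample = int(cfg.get("validity", {}).get("n_resample", 1000))
    seed = int(cfg.get("seed", 0))
    with open(os.path.join(outdir, "enrichment.tsv"), "w") as fh:
        fh.write("cluster\tterm\tname\tk\tK\tn\tN\tp\tp_adj\n")
        for ci, genes in sorted(best_cs.members().items()):
            recs = go_semantics.enrichment(set(genes), universe, ann, ont,
                                           n_resample=n_resample,
                                           seed=seed + ci)
            for r in recs:
                fh.write(f"{ci}\t{r['term']}\t{r['name']}\t{r['k']}\t"
                         f"{r['K']}\t{r['n']}\t{r['N']}\t{r['p']:.6g}\t"
                         f"{r['p_adj']:.4f}\n")


def stage_motifs(cfg: dict, outdir: str) -> None:
    net = data_io.read_interactions(cfg["input"]["net"])
    mcfg = cfg.get("motifs", {})
    report = motif_significance(
        net, n_random=int(mcfg.get("n_random", 1000)),
        min_count=int(mcfg.get("min_count", 5)),
        alpha=float(mcfg.get("alpha", 0.05)),
        seed=int(cfg.get("seed", 0)),
        n_swaps_per_edge=int(mcfg.get("swaps_per_edge", 100)))
    payload = {
        "n_random": report.n_random, "alpha": report.alpha,
        "min_count": report.min_count, "seed": report.seed,
        "records": {s: asdict(r) for s, r in sorted(report.records.items())},
        "instances": {s: [list(i) for i in v]
                      for s, v in sorted(report.instances.items())},
        "raw_codes": {s: v for s, v in sorted(report.raw_codes.items())},
        "codes": dict(sorted(report.codes.items())),
    }
    _dump_json(payload, os.path.join(outdir, "motif_report.json"))


def _load_report(outdir: str) -> MotifReport:
    with open(os.path.join(outdir, "motif_report.json")) as fh:
        d = json.load(fh)
    records = {s: MotifRecord(**r) for s, r in d["records"].items()}
    instances = {s: [tuple(i) for i in v] for s, v in d["instances"].items()}
    return MotifReport(records=records, n_random=d["n_random"],
                       alpha=d["alpha"], min_count=d["min_count"],
                       seed=d["seed"], instances=instances,
                       raw_codes=d["raw_codes"], codes=d["codes"])


def stage_assign(cfg: dict, outdir: str) -> None:
    ont = data_io.read_ontology(cfg["input"]["obo"])
    ann = data_io.read_annotations(cfg["input"]["ann"], ont)
    net = data_io.read_interactions(cfg["input"]["net"])
    report = _load_report(outdir)
    terms = frozenset(cfg.get("tfs", {}).get("terms", DEFAULT_TF_TERMS))
    tfs = select_tfs(ann, ont, terms)
    assignment = assign_tfs(net, report, tfs)
    _dump_json({"tfs": sorted(tfs),
                "assigned": assignment.assigned,
                "unassigned": assignment.unassigned},
               os.path.join(outdir, "tf_assignment.json"))


def stage_infer(cfg: dict, outdir: str) -> None:
    probes = data_io.read_expression(os.path.join(outdir, "expr_std.tsv"))
    X = data_io.collapse_probes(probes)
    members = data_io.read_gmt(os.path.join(outdir, "clusters.gmt"))
    labels = {g: ci for ci, gs in members.items() for g in gs}
    clusters = _clusterset_from_labels(labels, X)
    net = data_io.read_interactions(cfg["input"]["net"])
    report = _load_report(outdir)
    with open(os.path.join(outdir, "tf_assignment.json")) as fh:
        ad = json.load(fh)
    assignment = TFAssignment(assigned=ad["assigned"],
                              unassigned=ad["unassigned"])
    icfg = cfg.get("infer", {})
    optim = OptimConfig(
        ga=GAConfig(population=int(icfg.get("ga_population", 24)),
                    generations=int(icfg.get("ga_generations", 40))),
        pso=PSOConfig(swarm=int(icfg.get("pso_swarm", 24)),
                      iterations=int(icfg.get("pso_iterations", 150))),
        rmse_stop=float(icfg.get("rmse_stop", 0.05)))
    result = infer_modules(assignment, clusters, X, net, report,
                           cfg=optim, seed=int(cfg.get("seed", 0)),
                           tfs=set(ad["tfs"]))
    payload = {
        "modules": [m.to_dict() for m in result.modules],
        "ranked": {f"{tf}|{sig}": [m.to_dict() for m in lst[:5]]
                   for (tf, sig), lst in sorted(result.ranked.items())},
        "skipped": result.skipped,
    }
    _dump_json(payload, os.path.join(outdir, "trnm.json"))
    with open(os.path.join(outdir, "summary.tsv"), "w") as fh:
        fh.write("tf\tsignature\tclusters\trmse\n")
        for m in result.modules:
            cl = ",".join(str(c) for _, c in sorted(m.cluster_map.items()))
            fh.write(f"{m.tf_map.get('TF')}\t{m.signature}\t{cl}\t{m.rmse:.6f}\n")


_STAGE_FN = {
    "preprocess": stage_preprocess,
    "cluster": stage_cluster,
    "validity": stage_validity,
    "motifs": stage_motifs,
    "assign": stage_assign,
    "infer": stage_infer,
}


# ---------------------------------------------------------------------------
# driver
# ---------------------------------------------------------------------------

def run_pipeline(config: dict | str, outdir: str, resume: bool = True) -> dict:
    """Run all stages in order; returns (and writes) the run manifest.

    A stage is skipped when resuming if all of its outputs exist and none of
    its upstream stages ran in this invocation.  Missing input files abort
    before any computation.
    """
    cfg = load_config(config) if isinstance(config, str) else config
    os.makedirs(outdir, exist_ok=True)
    inputs = cfg.get("input", {})
    missing = [p for p in inputs.values() if not os.path.exists(p)]
    if missing:
        raise FileNotFoundError(f"missing input files: {missing}")

    manifest = {
        "tool": "trnmotif",
        "version": _version(),
        "seed": int(cfg.get("seed", 0)),
        "config": cfg,
        "inputs": {k: {"path": p, "sha256": _sha256(p)}
                   for k, p in sorted(inputs.items())},
        "stages": [],
        "outputs": [],
    }
    ran: dict[str, bool] = {}
    for stage in STAGES:
        outputs = [os.path.join(outdir, f) for f in _OUTPUTS[stage]]
        up_ran = any(ran.get(d, False) for d in _DEPS[stage])
        complete = all(os.path.exists(p) for p in outputs)
        if resume and complete and not up_ran:
            ran[stage] = False
            manifest["stages"].append({"name": stage, "status": "skipped",
                                       "seconds": 0.0, "outputs": outputs})
            continue
        t0 = time.perf_counter()
        log.info("running stage %s", stage)
        _STAGE_FN[stage](cfg, outdir)
        ran[stage] = True
        manifest["stages"].append({
            "name": stage, "status": "ran",
            "seconds": round(time.perf_counter() - t0, 3),
            "outputs": outputs})
        manifest["outputs"].extend(outputs)
    _dump_json(manifest, os.path.join(outdir, "manifest.json"))
    return manifest


def _version() -> str:
    try:
        from importlib.metadata import version
        return version("trnmotif")
    except Exception:
        return "unknown"
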