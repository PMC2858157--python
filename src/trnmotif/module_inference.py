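"""Recurrent-network models of motif-shaped regulation, fitted by GA--PSO.

Each significant motif class is instantiated as a small recurrent neural
network whose nodes are either transcription factors (clamped to their
observed, standardized expression profiles) or target gene clusters (free
dynamic nodes whose trajectories should reproduce the cluster centroids).
The discrete-time leaky update for a cluster node i is

    x_i(t+dt) = (dt/tau_i) tanh( sum_j w_ji x_j(t) + beta_i )
                + (1 - dt/tau_i) x_i(t)

with j ranging over the node's PDI regulators and PPI partners.  PPI edges
carry one shared weight acting symmetrically in both directions.  Because
tau_i >= dt, the state is a convex combination of the previous state and a
tanh output, so trajectories stay in [-1, 1] whenever |x(0)| <= 1 -- matching
the standardization of the expression profiles.

Particle swarm optimization fits the continuous parameters (weights, biases,
time constants) against the cluster centroids (RMSE objective); a genetic
algorithm searches the discrete space of candidate target clusters (and,
when a motif has an unfixed second TF role, candidate partner TFs).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .clustering import ClusterSet
from .data_io import ExpressionMatrix, InteractionNetwork
from .motifs import MotifReport, TFAssignment

log = logging.getLogger(__name__)

__all__ = ["MotifTopology", "RNNParams", "OptimConfig", "GAConfig", "PSOConfig",
           "TRNM", "rnn_simulate", "rmse", "pso_fit", "ga_search",
           "topology_from_instance", "infer_modules"]


# ---------------------------------------------------------------------------
# topology and parameters
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MotifTopology:
    """Role-typed motif shape: clamped TF roles, free cluster roles, typed edges.

    Edges are (src_role, dst_role, kind) with kind 'pdi' (directed) or 'ppi'
    (undirected, endpoint order arbitrary).
    """

    tf_roles: tuple[str, ...]
    cluster_roles: tuple[str, ...]
    edges: tuple[tuple[str, str, str], ...]

    def __post_init__(self) -> None:
        if not self.tf_roles or not self.cluster_roles:
            raise ValueError("a motif topology needs >= 1 TF and >= 1 cluster role")
        roles = set(self.tf_roles) | set(self.cluster_roles)
        if len(roles) != len(self.tf_roles) + len(self.cluster_roles):
            raise ValueError("duplicate role names")
        for s, d, kind in self.edges:
            if kind not in ("pdi", "ppi"):
                raise ValueError(f"unknown edge kind {kind!r}")
            if s not in roles or d not in roles:
                raise ValueError(f"edge endpoint outside roles: {(s, d)}")
        # connectivity over the undirected skeleton
        adj: dict[str, set[str]] = {r: set() for r in roles}
        for s, d, _ in self.edges:
            adj[s].add(d)
            adj[d].add(s)
        seen = {next(iter(roles))}
        stack = list(seen)
        while stack:
            for nb in adj[stack.pop()]:
                if nb not in seen:
                    seen.add(nb)
                    stack.append(nb)
        if seen != roles:
            raise ValueError("motif topology must be connected")

    @property
    def param_edges(self) -> tuple[tuple[str, str, str], ...]:
        """Edges carrying a weight: any edge feeding a cluster node."""
        cl = set(self.cluster_roles)
        out = []
        for s, d, kind in self.edges:
            if kind == "pdi" and d in cl:
                out.append((s, d, kind))
            elif kind == "ppi" and (s in cl or d in cl):
                out.append((s, d, kind))
        return tuple(out)


@dataclass
class RNNParams:
    """Edge weights, per-cluster-node biases and time constants (tau >= dt)."""

    w: dict[tuple[str, str, str], float]
    beta: dict[str, float]
    tau: dict[str, float]
    dt: float = 1.0

    def __post_init__(self) -> None:
        vals = list(self.w.values()) + list(self.beta.values()) + list(self.tau.values())
        if not np.all(np.isfinite(vals)):
            raise ValueError("non-finite RNN parameter")
        for r, t in self.tau.items():
            if t < self.dt:
                raise ValueError(f"tau[{r}]={t} below dt={self.dt}")


@dataclass
class PSOConfig:
    swarm: int = 30
    iterations: int = 1000
    omega: float = 0.729
    c1: float = 1.49445
    c2: float = 1.49445
    w_bounds: tuple[float, float] = (-5.0, 5.0)
    beta_bounds: tuple[float, float] = (-5.0, 5.0)
    tau_bounds: tuple[float, float] = (1.0, 10.0)
    velocity_frac: float = 0.5


@dataclass
class GAConfig:
    population: int = 50
    generations: int = 600
    crossover_p: float = 0.8
    mutation_p: float = 0.1
    elitism: int = 2
    tournament_k: int = 3


@dataclass
class OptimConfig:
    ga: GAConfig = field(default_factory=GAConfig)
    pso: PSOConfig = field(default_factory=PSOConfig)
    rmse_stop: float = 0.05

    def __post_init__(self) -> None:
        if self.ga.generations < 1 or self.pso.iterations < 1:
            raise ValueError("generations and iterations must be >= 1")
        if self.rmse_stop < 0:
            raise ValueError("rmse_stop must be >= 0")

    @classmethod
    def quick(cls) -> "OptimConfig":
        """Reduced budgets for small search spaces (desk-scale problems)."""
        return cls(ga=GAConfig(population=24, generations=40),
                   pso=PSOConfig(swarm=24, iterations=150))


# ---------------------------------------------------------------------------
# simulation core
# ---------------------------------------------------------------------------

class _Compiled:
    """Index structure for batch simulation of one topology."""

    def __init__(self, top: MotifTopology) -> None:
        self.top = top
        self.tf_roles = list(top.tf_roles)
        self.cluster_roles = list(top.cluster_roles)
        tf_idx = {r: i for i, r in enumerate(self.tf_roles)}
        cl_idx = {r: i for i, r in enumerate(self.cluster_roles)}
        self.param_edges = list(top.param_edges)
        n_e = len(self.param_edges)
        n_c = len(self.cluster_roles)
        self.n_params = n_e + 2 * n_c
        self.beta_ofs = n_e
        self.tau_ofs = n_e + n_c
        # inputs[ci] = list of (kind, source index, weight param index)
        self.inputs: list[list[tuple[str, int, int]]] = [[] for _ in range(n_c)]
        for k, (s, d, kind) in enumerate(self.param_edges):
            if kind == "pdi":
                ci = cl_idx[d]
                if s in tf_idx:
                    self.inputs[ci].append(("tf", tf_idx[s], k))
                else:
                    self.inputs[ci].append(("cluster", cl_idx[s], k))
            else:  # ppi: shared weight, acts on both cluster endpoints
                for recv, other in ((s, d), (d, s)):
                    if recv in cl_idx:
                        if other in tf_idx:
                            self.inputs[cl_idx[recv]].append(("tf", tf_idx[other], k))
                        else:
                            self.inputs[cl_idx[recv]].append(
                                ("cluster", cl_idx[other], k))

    def bounds(self, pso: PSOConfig) -> tuple[np.ndarray, np.ndarray]:
        lb = np.empty(self.n_params)
        ub = np.empty(self.n_params)
        n_e, n_c = len(self.param_edges), len(self.cluster_roles)
        lb[:n_e], ub[:n_e] = pso.w_bounds
        lb[n_e:n_e + n_c], ub[n_e:n_e + n_c] = pso.beta_bounds
        lb[n_e + n_c:], ub[n_e + n_c:] = pso.tau_bounds
        return lb, ub

    def simulate(self, theta: np.ndarray, regs: np.ndarray, x0: np.ndarray,
                 dt: float = 1.0) -> np.ndarray:
        """theta (P, D), regs (n_tf, T), x0 (n_cluster,) -> traj (P, n_c, T)."""
        P = theta.shape[0]
        n_c = len(self.cluster_roles)
        T = regs.shape[1]
        traj = np.empty((P, n_c, T))
        traj[:, :, 0] = x0[None, :]
        alpha = dt / theta[:, self.tau_ofs:self.tau_ofs + n_c]  # (P, n_c)
        beta = theta[:, self.beta_ofs:self.beta_ofs + n_c]
        cur = np.broadcast_to(x0[None, :], (P, n_c)).copy()
        for t in range(T - 1):
            inp = beta.copy()
            for ci in range(n_c):
                for kind, j, k in self.inputs[ci]:
                    src = regs[j, t] if kind == "tf" else cur[:, j]
                    inp[:, ci] += theta[:, k] * src
            cur = alpha * np.tanh(inp) + (1.0 - alpha) * cur
            traj[:, :, t + 1] = cur
        return traj

    def pack(self, params: RNNParams) -> np.ndarray:
        theta = np.empty(self.n_params)
        for k, e in enumerate(self.param_edges):
            s, d, kind = e
            if e in params.w:
                theta[k] = params.w[e]
            elif kind == "ppi" and (d, s, kind) in params.w:
                theta[k] = params.w[(d, s, kind)]
            else:
                raise KeyError(f"missing weight for edge {e}")
        for i, r in enumerate(self.cluster_roles):
            theta[self.beta_ofs + i] = params.beta[r]
            theta[self.tau_ofs + i] = params.tau[r]
        return theta

    def unpack(self, theta: np.ndarray, dt: float = 1.0) -> RNNParams:
        w = {e: float(theta[k]) for k, e in enumerate(self.param_edges)}
        beta = {r: float(theta[self.beta_ofs + i])
                for i, r in enumerate(self.cluster_roles)}
        tau = {r: float(theta[self.tau_ofs + i])
               for i, r in enumerate(self.cluster_roles)}
        return RNNParams(w=w, beta=beta, tau=tau, dt=dt)


def rnn_simulate(top: MotifTopology, params: RNNParams,
                 regulators: dict[str, np.ndarray],
                 x0: dict[str, float] | None = None) -> dict[str, np.ndarray]:
    """Simulate the cluster-node trajectories of a motif RNN.

    ``regulators`` maps each TF role to its clamped profile (length T);
    ``x0`` gives initial values per cluster role (default 0).  Returns one
    trajectory of length T per cluster role.
    """
    comp = _Compiled(top)
    missing = [r for r in comp.tf_roles if r not in regulators]
    if missing:
        raise ValueError(f"missing regulator profiles for roles {missing}")
    regs = np.asarray([regulators[r] for r in comp.tf_roles], dtype=float)
    x0v = np.array([0.0 if x0 is None else x0.get(r, 0.0)
                    for r in comp.cluster_roles])
    theta = comp.pack(params)[None, :]
    traj = comp.simulate(theta, regs, x0v, dt=params.dt)[0]
    return {r: traj[i] for i, r in enumerate(comp.cluster_roles)}


def rmse(pred: dict[str, np.ndarray] | np.ndarray,
         obs: dict[str, np.ndarray] | np.ndarray) -> float:
    """Root mean square error over all cluster roles and t >= 2.

    The first time point is the initial condition and is excluded.
    """
    if isinstance(pred, dict):
        keys = sorted(pred)
        if not isinstance(obs, dict) or sorted(obs) != keys:
            raise ValueError("pred and obs must cover the same roles")
        pred = np.asarray([pred[k] for k in keys], dtype=float)
        obs = np.asarray([obs[k] for k in keys], dtype=float)
    pred = np.atleast_2d(np.asarray(pred, dtype=float))
    obs = np.atleast_2d(np.asarray(obs, dtype=float))
    if pred.shape != obs.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {obs.shape}")
    diff = pred[:, 1:] - obs[:, 1:]
    return float(np.sqrt(np.mean(diff ** 2)))


# ---------------------------------------------------------------------------
# particle swarm optimization
# ---------------------------------------------------------------------------

@dataclass
class PSOResult:
    params: RNNParams
    rmse: float
    trace: list[float]


def pso_fit(top: MotifTopology, regulators: dict[str, np.ndarray],
            targets: dict[str, np.ndarray], cfg: OptimConfig | None = None,
            seed: int | np.random.SeedSequence = 0) -> PSOResult:
    """Fit RNN parameters to cluster centroids with a global-best PSO.

    v <- omega v + c1 r1 (pbest - x) + c2 r2 (gbest - x); x <- x + v, with
    velocities clamped to ``velocity_frac`` of the box and positions clamped
    to the bounds.  Stops after ``cfg.pso.iterations`` or when the best RMSE
    reaches ``cfg.rmse_stop``.  Reproducible given the seed.
    """
    cfg = cfg or OptimConfig()
    comp = _Compiled(top)
    regs = np.asarray([regulators[r] for r in comp.tf_roles], dtype=float)
    tgt = np.asarray([targets[r] for r in comp.cluster_roles], dtype=float)
    if regs.shape[1] != tgt.shape[1]:
        raise ValueError("regulator and target profiles differ in length")
    x0 = tgt[:, 0].copy()
    lb, ub = comp.bounds(cfg.pso)
    if np.any(lb >= ub):
        raise ValueError("infeasible parameter bounds")
    vmax = cfg.pso.velocity_frac * (ub - lb)
    rng = np.random.default_rng(seed)
    P, D = cfg.pso.swarm, comp.n_params
    pos = rng.uniform(lb, ub, size=(P, D))
    vel = rng.uniform(-vmax, vmax, size=(P, D))

    def objective(x: np.ndarray) -> np.ndarray:
        traj = comp.simulate(x, regs, x0)
        diff = traj[:, :, 1:] - tgt[None, :, 1:]
        return np.sqrt(np.mean(diff ** 2, axis=(1, 2)))

    fit = objective(pos)
    pbest, pbest_fit = pos.copy(), fit.copy()
    g = int(np.argmin(fit))
    gbest, gbest_fit = pos[g].copy(), float(fit[g])
    trace = [gbest_fit]
    for _ in range(cfg.pso.iterations):
        if gbest_fit <= cfg.rmse_stop:
            break
        r1 = rng.random((P, D))
        r2 = rng.random((P, D))
        vel = (cfg.pso.omega * vel + cfg.pso.c1 * r1 * (pbest - pos)
               + cfg.pso.c2 * r2 * (gbest[None, :] - pos))
        np.clip(vel, -vmax, vmax, out=vel)
        pos = np.clip(pos + vel, lb, ub)
        fit = objective(pos)
        improved = fit < pbest_fit
        pbest[improved] = pos[improved]
        pbest_fit[improved] = fit[improved]
        g = int(np.argmin(pbest_fit))
        if pbest_fit[g] < gbest_fit:
            gbest_fit = float(pbest_fit[g])
            gbest = pbest[g].copy()
        trace.append(gbest_fit)
    return PSOResult(params=comp.unpack(gbest), rmse=gbest_fit, trace=trace)


# ---------------------------------------------------------------------------
# genetic search over candidate clusters
# ---------------------------------------------------------------------------

@dataclass
class TRNM:
    """An inferred regulatory module: motif class with concrete TFs/clusters."""

    signature: str | None
    topology: MotifTopology
    tf_map: dict[str, str]
    cluster_map: dict[str, int]
    params: RNNParams
    rmse: float
    trace: list[float]

    def to_dict(self) -> dict:
        return {
            "signature": self.signature,
            "tf_map": dict(sorted(self.tf_map.items())),
            "cluster_map": dict(sorted(self.cluster_map.items())),
            "edges": [list(e) for e in self.topology.edges],
            "params": {
                "w": {f"{s}->{d}({k})": v for (s, d, k), v in
                      sorted(self.params.w.items())},
                "beta": dict(sorted(self.params.beta.items())),
                "tau": dict(sorted(self.params.tau.items())),
            },
            "rmse": self.rmse,
            "trace": list(self.trace),
        }


@dataclass
class GASearchResult:
    ranked: list[TRNM]
    trace: list[float]


def _derived_seed(master: int, *parts: int) -> np.random.SeedSequence:
    return np.random.SeedSequence(entropy=[int(master) & 0x7FFFFFFF,
                                           *(int(p) & 0x7FFFFFFF for p in parts)])


def ga_search(tf: str, topology: MotifTopology, clusters: ClusterSet,
              tf_profiles: dict[str, np.ndarray], cfg: OptimConfig | None = None,
              seed: int = 0, fixed_tfs: dict[str, str] | None = None,
              tf_pool: list[str] | None = None) -> GASearchResult:
    """Search candidate target clusters (and partner TFs) for one motif.

    The chromosome carries one cluster index per cluster role, plus one
    partner-TF index per TF role that is neither the focal TF nor fixed.
    Fitness is the PSO-fitted RMSE of the instantiated module (cached per
    chromosome, with a per-chromosome derived seed so results do not depend
    on evaluation order).  Tournament selection, uniform crossover, per-locus
    mutation and elitism; stops at ``cfg.ga.generations`` or once the best
    fitness reaches ``cfg.rmse_stop``.  Returns the unique evaluated
    candidates ranked by RMSE plus the per-generation best trace.
    """
    cfg = cfg or OptimConfig()
    fixed_tfs = dict(fixed_tfs or {})
    focal_role = topology.tf_roles[0]
    fixed_tfs[focal_role] = tf
    if tf not in tf_profiles:
        raise ValueError(f"no expression profile for focal TF {tf}")
    free_tf_roles = [r for r in topology.tf_roles if r not in fixed_tfs]
    pool = sorted(p for p in (tf_pool if tf_pool is not None else tf_profiles)
                  if p != tf and p in tf_profiles)
    if free_tf_roles and not pool:
        raise ValueError("motif has an unfixed TF role but the partner pool is empty")
    for role, gene in fixed_tfs.items():
        if gene not in tf_profiles:
            raise ValueError(f"no expression profile for TF {gene} (role {role})")

    cluster_ids = sorted(clusters.profiles)
    q = len(topology.cluster_roles)
    if q > len(cluster_ids):
        raise ValueError(f"motif needs {q} clusters but only "
                         f"{len(cluster_ids)} are available")
    n_cl, n_pool = len(cluster_ids), len(pool)
    n_loci = q + len(free_tf_roles)
    # distinct cluster roles must point at distinct clusters
    space = 1
    for i in range(q):
        space *= (n_cl - i)
    space *= (n_pool ** len(free_tf_roles) or 1)

    cache: dict[tuple[int, ...], tuple[float, RNNParams]] = {}

    def _std_target(x: np.ndarray) -> np.ndarray | None:
        # pso_fit expects targets standardized to [-1, 1]; a centroid of a
        # coherent cluster is barely changed, a flat one is unfittable noise
        lo, hi = float(x.min()), float(x.max())
        if hi - lo <= 1e-12:
            return None
        return 2.0 * (x - lo) / (hi - lo) - 1.0

    def fitness(chrom: tuple[int, ...]) -> float:
        if chrom in cache:
            return cache[chrom][0]
        cl_map = {r: cluster_ids[chrom[i]]
                  for i, r in enumerate(topology.cluster_roles)}
        tf_map = dict(fixed_tfs)
        for j, r in enumerate(free_tf_roles):
            tf_map[r] = pool[chrom[q + j]]
        regulators = {r: tf_profiles[g] for r, g in tf_map.items()}
        targets = {r: _std_target(clusters.profiles[c])
                   for r, c in cl_map.items()}
        if any(t is None for t in targets.values()):
            dummy = RNNParams(w={e: 0.0 for e in topology.param_edges},
                              beta={r: 0.0 for r in topology.cluster_roles},
                              tau={r: 1.0 for r in topology.cluster_roles})
            cache[chrom] = (float("inf"), dummy)
            return float("inf")
        res = pso_fit(topology, regulators, targets, cfg,
                      seed=_derived_seed(seed, *chrom))
        cache[chrom] = (res.rmse, res.params)
        return res.rmse

    def build_trnm(chrom: tuple[int, ...]) -> TRNM:
        fit, params = cache[chrom]
        cl_map = {r: cluster_ids[chrom[i]]
                  for i, r in enumerate(topology.cluster_roles)}
        tf_map = dict(fixed_tfs)
        for j, r in enumerate(free_tf_roles):
            tf_map[r] = pool[chrom[q + j]]
        return TRNM(signature=None, topology=topology, tf_map=tf_map,
                    cluster_map=cl_map, params=params, rmse=fit, trace=[])

    rng = np.random.default_rng(_derived_seed(seed, 0x6A))

    def repair(loci: list[int]) -> tuple[int, ...]:
        """Resample cluster loci until the cluster roles are distinct."""
        seen = set()
        for i in range(q):
            while loci[i] in seen:
                loci[i] = int(rng.integers(n_cl))
            seen.add(loci[i])
        return tuple(loci)

    def random_chrom() -> tuple[int, ...]:
        loci = [int(rng.integers(n_cl)) for _ in range(q)]
        loci += [int(rng.integers(n_pool)) for _ in range(len(free_tf_roles))]
        return repair(loci)

    trace: list[float] = []
    if space <= cfg.ga.population:
        # degenerate search space: evaluate everything once
        import itertools as _it
        all_chroms = [tuple(ch) for ch in _it.product(
            *([range(n_cl)] * q + [range(n_pool)] * len(free_tf_roles)))
            if len(set(ch[:q])) == q]
        for ch in all_chroms:
            fitness(ch)
        trace.append(min(cache[ch][0] for ch in all_chroms))
    else:
        pop = [random_chrom() for _ in range(cfg.ga.population)]
        for _gen in range(cfg.ga.generations):
            fits = [fitness(ch) for ch in pop]
            order = np.argsort(fits, kind="stable")
            best_fit = fits[order[0]]
            trace.append(best_fit if not trace else min(trace[-1], best_fit))
            if trace[-1] <= cfg.rmse_stop:
                break
            elite = [pop[i] for i in order[:cfg.ga.elitism]]
            children = list(elite)
            while len(children) < cfg.ga.population:
                def tournament() -> tuple[int, ...]:
                    cand = rng.integers(len(pop), size=cfg.ga.tournament_k)
                    return pop[min(cand, key=lambda i: fits[i])]
                p1, p2 = tournament(), tournament()
                if rng.random() < cfg.ga.crossover_p:
                    child = tuple(p1[i] if rng.random() < 0.5 else p2[i]
                                  for i in range(n_loci))
                else:
                    child = p1
                child = list(child)
                for i in range(n_loci):
                    if rng.random() < cfg.ga.mutation_p:
                        hi = n_cl if i < q else n_pool
                        child[i] = int(rng.integers(hi))
                children.append(repair(child))
            pop = children

    ranked_chroms = sorted(cache, key=lambda ch: (cache[ch][0], ch))
    ranked = [build_trnm(ch) for ch in ranked_chroms]
    if ranked:
        ranked[0].trace = list(trace)
    return GASearchResult(ranked=ranked, trace=trace)


# ---------------------------------------------------------------------------
# assembling modules from upstream results
# ---------------------------------------------------------------------------

def topology_from_instance(net: InteractionNetwork,
                           instance: tuple[str, str, str], focal: str,
                           tf_genes: set[str], profile_genes: set[str],
                           ) -> tuple[MotifTopology, dict[str, str]]:
    """Turn a concrete motif instance into a role-typed topology.

    The focal gene becomes the clamped role ``TF``; any other instance gene
    that is a TF with an expression profile becomes a clamped partner role
    (``TF2``, ...); remaining genes become free cluster roles (``C1``, ...).
    Returns the topology plus the role -> instance-gene map.
    """
    if focal not in instance:
        raise ValueError("focal gene not in instance")
    role_of: dict[str, str] = {focal: "TF"}
    tf_roles, cluster_roles = ["TF"], []
    n_tf = n_cl = 1
    for gene in sorted(g for g in instance if g != focal):
        if gene in tf_genes and gene in profile_genes:
            n_tf += 1
            role = f"TF{n_tf}"
            tf_roles.append(role)
        else:
            role = f"C{n_cl}"
            cluster_roles.append(role)
            n_cl += 1
        role_of[gene] = role
    edges = []
    genes = sorted(instance)
    for i, u in enumerate(genes):
        for v in genes[i + 1:]:
            if tuple(sorted((u, v))) in net.ppi_edges:
                edges.append((role_of[u], role_of[v], "ppi"))
            if (u, v) in net.pdi_edges:
                edges.append((role_of[u], role_of[v], "pdi"))
            if (v, u) in net.pdi_edges:
                edges.append((role_of[v], role_of[u], "pdi"))
    if not cluster_roles:
        raise ValueError("instance has no candidate target node")
    top = MotifTopology(tf_roles=tuple(tf_roles),
                        cluster_roles=tuple(cluster_roles),
                        edges=tuple(sorted(edges)))
    return top, {r: g for g, r in role_of.items()}


@dataclass
class InferenceResult:
    modules: list[TRNM]
    ranked: dict[tuple[str, str], list[TRNM]]
    skipped: list[str]


def infer_modules(assignment: TFAssignment, clusters: ClusterSet,
                  expr: ExpressionMatrix, net: InteractionNetwork,
                  report: MotifReport, cfg: OptimConfig | None = None,
                  seed: int = 0, tfs: set[str] | None = None) -> InferenceResult:
    """Run the GA--PSO search for every (TF, significant class) pair.

    For each pair a representative instance (the first, in sorted order, in
    which the TF has an outgoing PDI) defines the role-typed topology; a
    second TF role is fixed to the instance's gene when that gene has an
    expression profile, otherwise the GA searches the partner pool.  Emits
    the top-ranked module per pair plus the full ranked lists.  Deterministic
    given the master seed.
    """
    cfg = cfg or OptimConfig()
    tf_genes = tfs if tfs is not None else set(assignment.assigned)
    profiles = {g: expr.values[i] for i, g in enumerate(expr.gene_ids)}
    tf_profiles = {g: profiles[g] for g in tf_genes if g in profiles}

    modules: list[TRNM] = []
    ranked: dict[tuple[str, str], list[TRNM]] = {}
    skipped: list[str] = []
    pairs = sorted((tf, sig) for tf, sigs in assignment.assigned.items()
                   for sig in sigs)
    for k, (tf, sig) in enumerate(pairs):
        if tf not in tf_profiles:
            log.warning("TF %s has no expression profile; skipped", tf)
            skipped.append(tf)
            continue
        rep = None
        for inst in sorted(report.instances.get(sig, [])):
            if tf in inst and any((tf, o) in net.pdi_edges for o in inst if o != tf):
                rep = inst
                break
        if rep is None:
            skipped.append(tf)
            continue
        top, role_genes = topology_from_instance(
            net, rep, tf, tf_genes, set(tf_profiles))
        fixed = {r: g for r, g in role_genes.items()
                 if r.startswith("TF") and r != "TF" and g in tf_profiles}
        res = ga_search(tf, top, clusters, tf_profiles, cfg=cfg,
                        seed=int(np.random.SeedSequence(
                            entropy=[seed & 0x7FFFFFFF, k]).generate_state(1)[0]
                            & 0x7FFFFFFF),
                        fixed_tfs=fixed, tf_pool=sorted(tf_profiles))
        for tr in res.ranked:
            tr.signature = sig
        ranked[(tf, sig)] = res.ranked
        if res.ranked:
            modules.append(res.ranked[0])
    return InferenceResult(modules=modules, ranked=ranked,
                           skipped=sorted(set(skipped)))
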