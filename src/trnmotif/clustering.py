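"""Fuzzy c-means clustering of standardized expression profiles.

Two empirical parameters govern FCM: the fuzziness exponent m (> 1; m -> 1
recovers hard k-means-like behaviour) and the cluster number c.  m is
estimated from the spread of pairwise squared distances between profiles
(Dembele--Kastner style); c is chosen downstream by sweeping a range of
candidate partitions and scoring each with GO semantic similarity
(:mod:`trnmotif.go_semantics`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist, pdist

from .data_io import ExpressionMatrix

__all__ = ["FuzzyPartition", "ClusterSet", "estimate_fuzziness", "fcm",
           "harden", "sweep_partitions"]


def _values(X) -> np.ndarray:
    if isinstance(X, ExpressionMatrix):
        if X.missing_mask.any():
            raise ValueError("clustering requires a complete matrix; impute first")
        return X.values
    return np.asarray(X, dtype=float)


@dataclass
class FuzzyPartition:
    """An FCM solution: memberships U (c x N), centroids and J_m objective."""

    c: int
    m: float
    U: np.ndarray
    centroids: np.ndarray
    objective: float
    seed: int
    n_iter: int
    objective_history: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.c < 2:
            raise ValueError("c must be >= 2")
        col = self.U.sum(axis=0)
        if np.any(np.abs(col - 1.0) > 1e-9):
            raise ValueError("membership columns must sum to 1")
        if np.any(self.U < -1e-12) or np.any(self.U > 1 + 1e-12):
            raise ValueError("memberships must lie in [0, 1]")


@dataclass
class ClusterSet:
    """A crisp partition: gene -> cluster label plus per-cluster mean profiles."""

    labels: dict[str, int]
    profiles: dict[int, np.ndarray]

    @property
    def n_clusters(self) -> int:
        return len(self.profiles)

    def members(self) -> dict[int, list[str]]:
        out: dict[int, list[str]] = {ci: [] for ci in self.profiles}
        for g, ci in self.labels.items():
            out[ci].append(g)
        return {ci: sorted(gs) for ci, gs in out.items()}


# ---------------------------------------------------------------------------
# fuzziness estimation
# ---------------------------------------------------------------------------

_M_GRID = np.round(np.arange(1.05, 3.0 + 1e-9, 0.05), 2)
_CV_THRESHOLD = 0.03


def estimate_fuzziness(X) -> float:
    """Estimate the FCM fuzziness exponent from pairwise profile distances.

    For each candidate m on the grid 1.05:0.05:3.00 the coefficient of
    variation of {d_kl^(1/(m-1))} is computed over all pairwise squared
    Euclidean distances d_kl.  Large exponents (m near 1) amplify the spread;
    as m grows the transformed distances flatten and memberships would turn
    uniform.  The upper edge m_ub of the informative regime is the largest
    grid m whose CV is still >= 0.03, and the returned estimate is
    m = 1 + (m_ub - 1)/2, the midpoint between hard clustering and that edge.
    Deterministic given X.
    """
    V = _values(X)
    if V.shape[0] < 10:
        raise ValueError("need at least 10 profiles to estimate fuzziness")
    d = pdist(V, metric="sqeuclidean")
    mean = d.mean()
    if mean == 0 or d.std(ddof=1) == 0:
        raise ValueError("degenerate distance distribution (all pairwise "
                         "distances equal); fuzziness is undefined")
    d = d / mean  # CV is scale-invariant; normalising avoids overflow
    m_ub = None
    for m in _M_GRID:
        y = d ** (1.0 / (m - 1.0))
        mu = y.mean()
        cv = y.std(ddof=1) / mu if mu > 0 else 0.0
        if cv >= _CV_THRESHOLD:
            m_ub = float(m)
    if m_ub is None:
        m_ub = float(_M_GRID[0])
    return 1.0 + (m_ub - 1.0) / 2.0


# ---------------------------------------------------------------------------
# FCM proper
# ---------------------------------------------------------------------------

def _memberships(D: np.ndarray, m: float) -> np.ndarray:
    """Membership update for squared distances D (c x N)."""
    zero = D <= 1e-300
    with np.errstate(divide="ignore", over="ignore", invalid="ignore"):
        W = D ** (-1.0 / (m - 1.0))
        U = W / W.sum(axis=0, keepdims=True)
    # data point coinciding with >=1 centroid: full membership there
    any_zero = zero.any(axis=0)
    if any_zero.any():
        U[:, any_zero] = zero[:, any_zero] / zero[:, any_zero].sum(axis=0)
    return U


def fcm(X, c: int, m: float, seed: int = 0, tol: float = 1e-5,
        max_iter: int = 300) -> FuzzyPartition:
    """Fuzzy c-means by alternating membership and centroid updates.

    u_ik = 1 / sum_j (d_ik / d_jk)^(2/(m-1)),  v_i = sum_k u_ik^m x_k / sum_k u_ik^m,
    iterated until the largest centroid shift falls below ``tol`` or
    ``max_iter`` is reached.  Centroids are initialised as c distinct data
    rows drawn by a seeded RNG, making runs reproducible.
    """
    V = _values(X)
    n = V.shape[0]
    if not 2 <= c < n:
        raise ValueError(f"need 2 <= c < N (c={c}, N={n})")
    if m <= 1:
        raise ValueError("m must be > 1")
    rng = np.random.default_rng(seed)
    centroids = V[rng.choice(n, size=c, replace=False)].astype(float).copy()

    history: list[float] = []
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        D = cdist(centroids, V, metric="sqeuclidean")
        U = _memberships(D, m)
        Um = U ** m
        new_centroids = (Um @ V) / Um.sum(axis=1, keepdims=True)
        D_new = cdist(new_centroids, V, metric="sqeuclidean")
        history.append(float((Um * D_new).sum()))
        shift = np.abs(new_centroids - centroids).max()
        centroids = new_centroids
        if shift < tol:
            break
    D = cdist(centroids, V, metric="sqeuclidean")
    U = _memberships(D, m)
    objective = float((U ** m * D).sum())
    return FuzzyPartition(c=c, m=m, U=U, centroids=centroids,
                          objective=objective, seed=seed, n_iter=n_iter,
                          objective_history=history)


def harden(P: FuzzyPartition, X) -> ClusterSet:
    """Assign each gene to its argmax-membership cluster (ties: lowest index).

    Empty clusters are removed and indices compacted.  Cluster profiles are
    the means of member profiles (not the FCM centroids).
    """
    V = _values(X)
    gene_ids = X.gene_ids if isinstance(X, ExpressionMatrix) else [
        str(i) for i in range(V.shape[0])]
    hard = np.argmax(P.U, axis=0)  # argmax takes the lowest index on ties
    labels: dict[str, int] = {}
    profiles: dict[int, np.ndarray] = {}
    mapping: dict[int, int] = {}
    for raw in sorted(set(hard.tolist())):
        mapping[raw] = len(mapping)
    for g, raw in zip(gene_ids, hard):
        labels[g] = mapping[int(raw)]
    for raw, ci in mapping.items():
        profiles[ci] = V[hard == raw].mean(axis=0)
    return ClusterSet(labels=labels, profiles=profiles)


def sweep_partitions(X, m: float, c_range: tuple[int, int] = (2, 50),
                     seeds: tuple[int, ...] = (0, 1, 2), tol: float = 1e-5,
                     max_iter: int = 300) -> list[FuzzyPartition]:
    """Best-of-seeds FCM partition (lowest J_m) for each c in the range."""
    c_min, c_max = c_range
    n = _values(X).shape[0]
    if c_min < 2 or c_max > n - 1:
        raise ValueError(f"c_range must lie within [2, N-1]; got {c_range} for N={n}")
    out: list[FuzzyPartition] = []
    for c in range(c_min, c_max + 1):
        runs = [fcm(X, c, m, seed=s, tol=tol, max_iter=max_iter) for s in seeds]
        out.append(min(runs, key=lambda p: p.objective))
    return out
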