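"""Fuzzy c-means clustering of standardized property profiles.

Property indices are clustered in the 20-dimensional space of their z-scored
residue profiles so that near-duplicate indices land in the same cluster.
Fuzzy c-means minimizes

    J = sum_i sum_j u_ij^s d(v_i, x_j)^2

by alternating membership and prototype updates, where u_ij in [0, 1] is the
membership of point x_j in cluster i (columns sum to 1), v_i the cluster
prototype, s > 1 the fuzzifier (s -> 1 approaches hard k-means), and d the
Euclidean distance.  The defaults s = 1.12 and K = 20 follow the fuzzifier
calibration of Dembele & Kastner for this kind of profile data.

Cluster ids are canonicalized by decreasing cluster size (ties by smallest
member index) so that repeated runs report stable labels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .aaindex import PropertyRecord, zscore_profiles


@dataclass
class FuzzyClustering:
    memberships: np.ndarray  # K x n, columns sum to 1
    prototypes: np.ndarray  # K x d
    fuzzifier: float
    objective: float
    hard_labels: np.ndarray  # n, = argmax over clusters
    objective_trace: np.ndarray
    seed: int
    converged: bool

    @property
    def n_clusters(self) -> int:
        return self.prototypes.shape[0]

    def cluster_sizes(self) -> np.ndarray:
        return np.bincount(self.hard_labels, minlength=self.n_clusters)


def _sq_dists(V: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Squared Euclidean distances, K x n."""
    diff = V[:, None, :] - X[None, :, :]
    return np.einsum("kij,kij->ki", diff, diff)


def _memberships_from_dists(D2: np.ndarray, s: float) -> np.ndarray:
    """Standard FCM membership update; coincident points get membership 1.

    Computed from distance ratios against each column's minimum so the
    (-1/(s-1)) power never overflows for small fuzzifiers (s = 1.12 means
    an exponent of about -8.3).
    """
    power = 1.0 / (s - 1.0)
    m = D2.min(axis=0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        inv = (D2 / m) ** (-power)  # in (0, 1], NaN only where m == 0
        U = inv / inv.sum(axis=0, keepdims=True)
    # columns where a point coincides with >= 1 prototype: split among them
    zero_cols = np.nonzero(m[0] == 0)[0]
    for j in zero_cols:
        hits = D2[:, j] == 0
        U[:, j] = 0.0
        U[hits, j] = 1.0 / hits.sum()
    return U


def fcm(
    X: np.ndarray,
    K: int,
    s: float = 1.12,
    tol: float = 1e-6,
    max_iter: int = 500,
    seed: int = 0,
    n_init: int = 5,
) -> FuzzyClustering:
    """Cluster the rows of ``X`` into ``K`` fuzzy clusters.

    The membership matrix is initialized from the seeded generator (columns
    normalized); iteration alternates prototype and membership updates until
    the largest membership change drops below ``tol`` or ``max_iter`` is hit.
    The objective is non-increasing across iterations.  The alternating
    optimization only finds a local minimum of J, so ``n_init`` restarts are
    run (seeds derived deterministically from ``seed``) and the solution
    with the lowest final objective is returned.
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if not 1 <= K <= n:
        raise ValueError(f"K must be in [1, {n}], got {K}")
    if s <= 1:
        raise ValueError("fuzzifier must exceed 1")
    if n_init < 1:
        raise ValueError("n_init must be >= 1")
    best: FuzzyClustering | None = None
    for child in np.random.default_rng(seed).integers(0, 2**31 - 1, size=n_init):
        res = _fcm_once(X, K, s, tol, max_iter, int(child), seed)
        if best is None or res.objective < best.objective:
            best = res
    return best


def _fcm_once(
    X: np.ndarray, K: int, s: float, tol: float, max_iter: int, init_seed: int, seed: int
) -> FuzzyClustering:
    rng = np.random.default_rng(init_seed)
    U = rng.random((K, X.shape[0]))
    U /= U.sum(axis=0, keepdims=True)
    trace: list[float] = []
    converged = False
    for _ in range(max_iter):
        W = U**s
        V = (W @ X) / W.sum(axis=1, keepdims=True)
        D2 = _sq_dists(V, X)
        U_new = _memberships_from_dists(D2, s)
        trace.append(float((U_new**s * D2).sum()))
        delta = np.abs(U_new - U).max()
        U = U_new
        if delta < tol:
            converged = True
            break
    hard = np.argmax(U, axis=0)
    order = _canonical_order(hard, K)
    inv = np.empty(K, dtype=int)
    inv[order] = np.arange(K)
    return FuzzyClustering(
        memberships=U[order],
        prototypes=V[order],
        fuzzifier=s,
        objective=trace[-1],
        hard_labels=inv[hard],
        objective_trace=np.array(trace),
        seed=seed,
        converged=converged,
    )


def _canonical_order(hard: np.ndarray, K: int) -> np.ndarray:
    """Relabel clusters by decreasing size, ties by smallest member index."""
    sizes = np.bincount(hard, minlength=K)
    first = np.full(K, np.iinfo(np.int64).max, dtype=np.int64)
    for j, c in enumerate(hard):
        if j < first[c]:
            first[c] = j
    return np.array(sorted(range(K), key=lambda c: (-sizes[c], first[c])))


def pairwise_distance(p: PropertyRecord, q: PropertyRecord) -> float:
    """Euclidean distance between two property profiles in z-scored space."""
    from .aaindex import PropertyTable

    Z = zscore_profiles(PropertyTable([p, q]))
    return float(np.linalg.norm(Z[0] - Z[1]))


def zscored_distance_matrix(Z: np.ndarray) -> np.ndarray:
    """All-pairs Euclidean distances between z-scored profile rows."""
    from scipy.spatial.distance import squareform, pdist

    return squareform(pdist(Z))


def cluster_table_tsv(accessions: list[str], clustering: FuzzyClustering) -> str:
    """TSV report: accession, cluster id, top membership."""
    lines = ["accession\tcluster\ttop_membership"]
    top = clustering.memberships.max(axis=0)
    for j, acc in enumerate(accessions):
        lines.append(f"{acc}\t{clustering.hard_labels[j]}\t{top[j]:.6f}")
    return "\n".join(lines) + "\n"
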