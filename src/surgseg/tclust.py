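"""Temporal clustering algorithms: ACA, HACA, GMM and spectral clustering.

Aligned cluster analysis (ACA) is kernel k-means over temporal segments: a
time series is cut into M segments with lengths in ``[l_min, l_max]``, each
segment is compared to others through the dynamic time alignment kernel
(DTAK), and coordinate descent alternates cluster reassignment of segments
with a dynamic-programming search for globally optimal boundaries given the
current cluster centroids.  The objective is

    J(G, s) = sum_k sum_m g_{k,m} D^2(Q_m, z_k)

where ``D^2`` is the kernel-space squared distance between segment ``Q_m``
and the centroid ``z_k`` of cluster ``k``, expanded through DTAK values as

    D^2(Q_m, z_k) = tau_mm - (2 / M_k) sum_j g_{kj} tau_mj
                    + (1 / M_k^2) sum_{j1, j2} g_{k j1} g_{k j2} tau_{j1 j2}.

HACA runs ACA twice: first at a fine temporal scale, then again over the
resulting segments using the DTAK matrix between them as the reduced frame
kernel, which cuts cost and lets the second level capture longer structure.
GMM and spectral clustering are per-frame baselines whose label runs are
re-interpreted as segmentations.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.linalg import eigh
from sklearn.cluster import KMeans
from sklearn.mixture import GaussianMixture

from . import _dtak
from .containers import FeatureFrames, FrameKernel, Segmentation
from .errors import EmptyClusterError, ValidationError
from .preprocess import AUTO, frame_kernel


@dataclass
class ACAConfig:
    """Parameters of the ACA/HACA coordinate descent."""

    K: int
    l_min: int = 3
    l_max: int = 30
    max_iter: int = 50
    tol: float = 1e-7
    n_init: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.K < 1:
            raise ValidationError("K must be positive")
        if not 1 <= self.l_min <= self.l_max:
            raise ValidationError("need 1 <= l_min <= l_max")
        if self.max_iter < 1 or self.n_init < 1:
            raise ValidationError("max_iter and n_init must be positive")


@dataclass
class ClusterState:
    """Current assignment of segments to clusters."""

    membership: np.ndarray  # label per segment
    K: int

    def __post_init__(self) -> None:
        self.membership = np.asarray(self.membership, dtype=np.int64)

    @property
    def M_k(self) -> np.ndarray:
        return np.bincount(self.membership, minlength=self.K)


def _as_kernel(F) -> np.ndarray:
    arr = F.F if isinstance(F, FrameKernel) else np.asarray(F, dtype=np.float64)
    if arr.ndim != 2 or arr.shape[0] != arr.shape[1]:
        raise ValidationError("frame kernel must be square")
    return np.ascontiguousarray(arr, dtype=np.float64)


def _check_range(rng, N, name) -> tuple[int, int]:
    a, b = int(rng[0]), int(rng[1])
    if not (0 <= a < b <= N):
        raise ValidationError(f"{name}: range [{a}, {b}) is empty or outside [0, {N})")
    return a, b


def dtak(F, seg_a, seg_b) -> float:
    """Dynamic time alignment kernel between two frame ranges.

    ``seg_a`` and ``seg_b`` are ``(start, end)`` pairs (half-open).  The
    value is symmetric and lies in (0, 1] for kernels with entries in (0, 1].
    """
    arr = _as_kernel(F)
    a0, a1 = _check_range(seg_a, arr.shape[0], "seg_a")
    b0, b1 = _check_range(seg_b, arr.shape[0], "seg_b")
    return float(_dtak.dtak_pair(arr, a0, a1, b0, b1))


def segment_cluster_distance(F, seg, state: ClusterState, segmentation: Segmentation, k: int) -> float:
    """Kernel-space squared distance between a frame range and cluster ``k``'s centroid.

    Reference implementation of the three-term expansion; ``seg`` is a
    ``(start, end)`` pair and the cluster is defined by ``state.membership``
    over the segments of ``segmentation``.
    """
    arr = _as_kernel(F)
    members = np.flatnonzero(state.membership == k)
    if members.size == 0:
        raise EmptyClusterError(f"cluster {k} has no segments")
    b = segmentation.boundaries
    tau_mm = dtak(arr, seg, seg)
    cross = sum(dtak(arr, seg, (b[j], b[j + 1])) for j in members)
    within = sum(
        dtak(arr, (b[j1], b[j1 + 1]), (b[j2], b[j2 + 1]))
        for j1 in members
        for j2 in members
    )
    m_k = members.size
    return tau_mm - 2.0 * cross / m_k + within / (m_k * m_k)


def _objective_from_tau(T: np.ndarray, labels: np.ndarray, K: int) -> float:
    """J = tr(T) - sum_k (1/M_k) * g_k^T T g_k, skipping empty clusters."""
    J = float(np.trace(T))
    for k in range(K):
        members = np.flatnonzero(labels == k)
        if members.size:
            J -= float(T[np.ix_(members, members)].sum()) / members.size
    return J


def aca_objective(F, segmentation: Segmentation) -> float:
    """ACA objective of a labeled segmentation (sum of within-cluster scatter)."""
    arr = _as_kernel(F)
    b = segmentation.boundaries
    T = _dtak.dtak_matrix(arr, b[:-1].astype(np.int64), b[1:].astype(np.int64))
    return _objective_from_tau(T, segmentation.labels, segmentation.K)


def _cluster_distances(T: np.ndarray, labels: np.ndarray, K: int) -> np.ndarray:
    """M x K matrix of D^2(segment m, centroid k); +inf for empty clusters."""
    M = labels.size
    G = np.zeros((M, K))
    G[np.arange(M), labels] = 1.0
    Mk = G.sum(axis=0)
    D2 = np.full((M, K), np.inf)
    nz = Mk > 0
    cross = T @ G[:, nz]
    within = np.einsum("mk,mn,nk->k", G[:, nz], T, G[:, nz])
    D2[:, nz] = np.diag(T)[:, None] - 2.0 * cross / Mk[nz] + within / Mk[nz] ** 2
    return D2


def _assignment_pass(T: np.ndarray, labels: np.ndarray, K: int) -> np.ndarray:
    """Batch reassignment to nearest centroid until stable; re-seeds empty
    clusters with the segment farthest from its own centroid."""
    labels = labels.copy()
    M = labels.size
    for _ in range(100):
        changed = False
        counts = np.bincount(labels, minlength=K)
        for k in range(K):
            if counts[k] == 0 and M >= K:
                D2 = _cluster_distances(T, labels, K)
                own = D2[np.arange(M), labels]
                # only steal from clusters that keep at least one segment
                own[counts[labels] <= 1] = -np.inf
                far = int(np.argmax(own))
                labels[far] = k
                counts = np.bincount(labels, minlength=K)
                changed = True
        D2 = _cluster_distances(T, labels, K)
        new = np.argmin(D2, axis=1)
        if not np.array_equal(new, labels):
            labels = new
            changed = True
        if not changed:
            break
    return labels


def _random_boundaries(N: int, l_min: int, l_max: int, rng: np.random.Generator) -> np.ndarray:
    """Random boundary vector with all segment lengths in [l_min, l_max]."""
    bounds = [0]
    cur = 0
    while N - cur > l_max:
        l = int(rng.integers(l_min, min(l_max, N - cur - l_min) + 1))
        cur += l
        bounds.append(cur)
    bounds.append(N)
    return np.asarray(bounds, dtype=np.int64)


def aca(
    F,
    config: ACAConfig,
    seed: int | None = None,
    *,
    weights: np.ndarray | None = None,
    max_span: int | None = None,
) -> Segmentation:
    """Aligned cluster analysis by coordinate descent.

    Alternates (a) reassignment of segments to the nearest kernel-space
    centroid with empty-cluster re-seeding and (b) a DP over end frames that
    finds the globally optimal boundaries and labels for the current
    centroids.  Both steps are non-increasing in J, so the objective history
    (stored in ``meta['history']``) is monotone.  Returns a segmentation with
    all segment lengths in ``[l_min, l_max]`` and ``energy`` set to the final
    objective.

    ``weights``/``max_span`` support the hierarchical second level, where the
    N positions are themselves segments of the original series: each position
    carries a frame weight and no output segment may span more than
    ``max_span`` frames (single positions are always allowed so a feasible
    segmentation exists).
    """
    arr = _as_kernel(F)
    N = arr.shape[0]
    K, l_min, l_max = config.K, config.l_min, min(config.l_max, N)
    if N < K * l_min:
        raise ValidationError(f"N={N} too short for K={K} clusters of at least {l_min} frames")
    rng = np.random.default_rng(config.seed if seed is None else seed)

    if weights is not None:
        weights = np.asarray(weights, dtype=np.int64)
        if weights.size != N:
            raise ValidationError("weights must have one entry per position")
        cum_w = np.concatenate(([0], np.cumsum(weights)))
        span_cap = np.int64(max_span if max_span is not None else cum_w[-1])
        # start from singleton segments: always feasible under the span cap
        bounds = np.arange(N + 1, dtype=np.int64)
    else:
        cum_w = np.arange(N + 1, dtype=np.int64)
        span_cap = np.int64(N)
        bounds = _random_boundaries(N, l_min, l_max, rng)
    labels = rng.integers(0, K, bounds.size - 1)
    starts, ends = bounds[:-1], bounds[1:]
    T = _dtak.dtak_matrix(arr, starts, ends)
    labels = _assignment_pass(T, labels, K)
    J = _objective_from_tau(T, labels, K)
    history = [J]

    self_tau = _dtak.candidate_self_tau(arr, l_max)
    for _ in range(config.max_iter):
        # costs of every candidate segment against the current centroids
        M = labels.size
        G = np.zeros((M, K))
        G[np.arange(M), labels] = 1.0
        Mk = G.sum(axis=0)
        within = np.einsum("mk,mn,nk->k", G, T, G)
        cross = _dtak.candidate_cross_tau(arr, starts, ends, l_max)
        D = np.full((N, l_max, K), np.inf)
        nz = Mk > 0
        D[:, :, nz] = (
            self_tau[:, :, None]
            - 2.0 * (cross @ G[:, nz]) / Mk[nz]
            + within[nz] / Mk[nz] ** 2
        )
        V, best_l, best_k = _dtak.boundary_dp(D, l_min, l_max, N, K, cum_w, span_cap)
        if not np.isfinite(V[N]):
            raise ValidationError(f"no feasible segmentation of N={N} with lengths in [{l_min}, {l_max}]")
        bounds, labels = _backtrack(best_l, best_k, N)
        starts, ends = bounds[:-1], bounds[1:]
        T = _dtak.dtak_matrix(arr, starts, ends)
        labels = _assignment_pass(T, labels, K)
        J_new = _objective_from_tau(T, labels, K)
        history.append(J_new)
        if J - J_new < config.tol:
            J = min(J, J_new)
            break
        J = J_new

    return Segmentation(
        boundaries=bounds,
        labels=labels,
        K=K,
        N=N,
        energy=J,
        meta={"history": history, "n_iter": len(history) - 1},
    )


def _backtrack(best_l: np.ndarray, best_k: np.ndarray, N: int) -> tuple[np.ndarray, np.ndarray]:
    bounds = [N]
    labels = []
    v = N
    while v > 0:
        l, k = int(best_l[v]), int(best_k[v])
        labels.append(k)
        v -= l
        bounds.append(v)
    return np.asarray(bounds[::-1], dtype=np.int64), np.asarray(labels[::-1], dtype=np.int64)


def haca(
    F,
    config: ACAConfig,
    level1_K: int | None = None,
    l_max_1: int = 20,
    l_max_2: int = 30,
    seed: int | None = None,
) -> Segmentation:
    """Two-level hierarchical ACA.

    Level 1 runs ACA with ``level1_K`` clusters (default ``2 K``, finer
    motifs regrouped at level 2) and maximum segment length ``l_max_1``
    frames.  Level 2 builds the reduced kernel ``F2[a, b] = dtak(F, Q_a,
    Q_b)`` over the level-1 segments and re-runs ACA on it with ``config.K``
    clusters, merging level-1 segments into level-2 segments of up to
    ``l_max_2`` original frames (so ``l_max_1 < l_max_2`` keeps its meaning
    on the frame axis), then expands the level-2 labels back to frames.
    ``energy`` is the frame-level objective of the expanded segmentation,
    comparable across restarts and with plain ACA.
    """
    arr = _as_kernel(F)
    if level1_K is None:
        level1_K = 2 * config.K
    if level1_K < config.K:
        raise ValidationError("level1_K must be at least config.K")
    base_seed = config.seed if seed is None else seed
    cfg1 = replace(config, K=level1_K, l_max=l_max_1)
    seg1 = aca(arr, cfg1, seed=base_seed)

    b1 = seg1.boundaries
    F2 = _dtak.dtak_matrix(arr, b1[:-1], b1[1:])
    M1 = seg1.M
    lengths1 = np.diff(b1)
    cfg2 = replace(config, K=config.K, l_min=1, l_max=min(max(l_max_2 // config.l_min, 1), M1))
    seg2 = aca(F2, cfg2, seed=base_seed + 1, weights=lengths1, max_span=l_max_2)

    out = Segmentation(
        boundaries=b1[seg2.boundaries],
        labels=seg2.labels,
        K=config.K,
        N=seg1.N,
        meta={"level1": seg1, "level2_history": seg2.meta.get("history")},
    )
    out.energy = aca_objective(arr, out)
    return out


def gmm_segment(X: FeatureFrames, K: int, seed: int = 0, n_init: int = 5) -> Segmentation:
    """Frame-wise Gaussian mixture segmentation.

    Fits a K-component diagonal-covariance GMM by EM (seeded k-means
    initialization, ``n_init`` restarts, best log-likelihood kept), labels
    each frame with its maximum-posterior component, and cuts the series
    wherever two consecutive frames change component.  ``energy`` is the
    total negative log-likelihood.
    """
    if K >= X.N:
        raise ValidationError("need more frames than mixture components")
    gm = GaussianMixture(
        n_components=K,
        covariance_type="diag",
        reg_covar=1e-6,
        n_init=n_init,
        random_state=seed,
    )
    pts = X.X.T
    labels = gm.fit_predict(pts)
    nll = -float(gm.score(pts)) * X.N
    return Segmentation.from_frame_labels(labels, K=K, energy=nll, meta={"converged": bool(gm.converged_)})


def spectral_segment(X: FeatureFrames, K: int, sigma: float | str = AUTO, seed: int = 0) -> Segmentation:
    """Spectral clustering of frames, read out as a segmentation.

    Frames are nodes of a fully connected similarity graph with Gaussian
    weights; the K bottom eigenvectors of the normalized symmetric Laplacian
    are row-normalized and clustered with seeded k-means (10 restarts).
    ``energy`` is the k-means inertia in the embedded space.
    """
    if K >= X.N:
        raise ValidationError("need more frames than clusters")
    fk = frame_kernel(X, sigma)
    W = fk.F
    deg = W.sum(axis=1)
    if np.any(deg <= 1e-12):
        raise ValidationError("similarity graph has an isolated frame; increase sigma")
    d_is = 1.0 / np.sqrt(deg)
    L = np.eye(fk.N) - d_is[:, None] * W * d_is[None, :]
    _, vecs = eigh(L, subset_by_index=(0, K - 1))
    norms = np.linalg.norm(vecs, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    U = vecs / norms
    km = KMeans(n_clusters=K, n_init=10, random_state=seed).fit(U)
    return Segmentation.from_frame_labels(
        km.labels_, K=K, energy=float(km.inertia_), meta={"sigma": fk.sigma}
    )


def run_with_restarts(algorithm, inputs: dict, n_init: int = 5, base_seed: int = 0) -> Segmentation:
    """Run ``algorithm(**inputs, seed=...)`` ``n_init`` times, keep minimum energy.

    Seeds are ``base_seed, base_seed + 1, ...`` so a single restart equals a
    plain run with ``base_seed``.  All energies are recorded in
    ``meta['energies']``; ties keep the earliest seed.
    """
    if n_init < 1:
        raise ValidationError("n_init must be at least 1")
    best = None
    energies = []
    for i in range(n_init):
        seg = algorithm(**inputs, seed=base_seed + i)
        if seg.energy is None:
            raise ValidationError("algorithm did not report an energy")
        energies.append(float(seg.energy))
        if best is None or seg.energy < best.energy:
            best = seg
    best.meta = dict(best.meta)
    best.meta["energies"] = energies
    return best
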