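"""Shared fixtures and independent oracles used across the test suite."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from surgseg import GeneratorConfig, Segmentation


def gaussian_kernel(points: np.ndarray, sigma: float) -> np.ndarray:
    """Gaussian kernel over row-vector points (unit diagonal, entries in (0,1])."""
    sq = ((points[:, None, :] - points[None, :, :]) ** 2).sum(-1)
    F = np.exp(-sq / (2 * sigma**2))
    np.fill_diagonal(F, 1.0)
    return F


def random_kernel(rng: np.random.Generator, n: int, dim: int = 2, sigma: float = 1.0) -> np.ndarray:
    return gaussian_kernel(rng.standard_normal((n, dim)), sigma)


def block_kernel(block_sizes, within: float = 1.0, between: float = np.exp(-8.0)) -> np.ndarray:
    """Kernel with perfect diagonal blocks: within-block similarity ``within``,
    between-block ``between``."""
    n = sum(block_sizes)
    F = np.full((n, n), between)
    start = 0
    for b in block_sizes:
        F[start : start + b, start : start + b] = within
        start += b
    np.fill_diagonal(F, 1.0)
    return F


def random_segmentation(rng: np.random.Generator, N: int, K: int, l_min: int = 1,
                        l_max: int | None = None) -> Segmentation:
    """Random valid segmentation with every cluster non-empty when possible."""
    l_max = l_max or max(2, N // K)
    bounds = [0]
    while N - bounds[-1] > l_max:
        bounds.append(bounds[-1] + int(rng.integers(l_min, l_max + 1)))
    bounds.append(N)
    bounds = np.array(bounds)
    M = bounds.size - 1
    labels = rng.integers(0, K, M)
    labels[: min(K, M)] = rng.permutation(K)[: min(K, M)]
    return Segmentation(boundaries=bounds, labels=labels, K=K, N=N)


def dtak_bruteforce(F: np.ndarray, a0: int, a1: int, b0: int, b1: int) -> float:
    """Exhaustive enumeration of monotone alignment paths (lengths <= ~5).

    A path starts at (0, 0) with weight 2 f(0,0) and moves by (1,0), (0,1)
    (weight f) or (1,1) (weight 2 f) to (na-1, nb-1); the DTAK value is the
    best total divided by na + nb.
    """
    na, nb = a1 - a0, b1 - b0

    def best_from(p: int, q: int) -> float:
        if p == na - 1 and q == nb - 1:
            return 0.0
        cands = []
        if p + 1 < na:
            cands.append(F[a0 + p + 1, b0 + q] + best_from(p + 1, q))
        if q + 1 < nb:
            cands.append(F[a0 + p, b0 + q + 1] + best_from(p, q + 1))
        if p + 1 < na and q + 1 < nb:
            cands.append(2 * F[a0 + p + 1, b0 + q + 1] + best_from(p + 1, q + 1))
        return max(cands)

    return (2 * F[a0, b0] + best_from(0, 0)) / (na + nb)


def accuracy_bruteforce(C: np.ndarray) -> float:
    """Best matched-frame fraction over all K! cluster-task permutations."""
    K = C.shape[0]
    best = max(sum(C[p[j], j] for j in range(K)) for p in itertools.permutations(range(K)))
    return best / C.sum()


def trace_objective(T: np.ndarray, labels: np.ndarray, K: int) -> float:
    """Matrix form of the segment-clustering objective,
    tr((I - G^T (G G^T)^{-1} G) T), for instances with no empty cluster."""
    M = labels.size
    G = np.zeros((K, M))
    G[labels, np.arange(M)] = 1.0
    P = G.T @ np.linalg.inv(G @ G.T) @ G
    return float(np.trace((np.eye(M) - P) @ T))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def desk_config() -> GeneratorConfig:
    """Desk-scale generator: full duration statistics shrunk to ~1000 s."""
    return GeneratorConfig(time_scale=0.13, seed=0)
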