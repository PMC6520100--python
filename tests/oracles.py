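"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive (exhaustive enumeration, direct
definitions) and shares no code with the package implementation.
"""

from __future__ import annotations

from itertools import permutations

import numpy as np


def all_pairs_shortest_paths_bruteforce(W: np.ndarray) -> np.ndarray:
    """Exhaustive shortest-path lengths (length = 1/weight) by enumerating
    every simple path; feasible for n <= ~7."""
    n = W.shape[0]
    D = np.full((n, n), np.inf)
    np.fill_diagonal(D, 0.0)
    nodes = range(n)
    for s in nodes:
        for t in nodes:
            if s == t:
                continue
            for k in range(0, n - 1):
                for mid in permutations(set(nodes) - {s, t}, k):
                    path = (s, *mid, t)
                    length = 0.0
                    for a, b in zip(path[:-1], path[1:]):
                        if W[a, b] <= 0:
                            length = np.inf
                            break
                        length += 1.0 / W[a, b]
                    D[s, t] = min(D[s, t], length)
    return D


def global_efficiency_bruteforce(W: np.ndarray) -> float:
    D = all_pairs_shortest_paths_bruteforce(W)
    n = W.shape[0]
    total = 0.0
    for i in range(n):
        for j in range(n):
            if i != j and np.isfinite(D[i, j]) and D[i, j] > 0:
                total += 1.0 / D[i, j]
    return total / (n * (n - 1))


def betweenness_bruteforce(W: np.ndarray, tol: float = 1e-12) -> np.ndarray:
    """Unnormalized betweenness by enumerating all shortest paths per
    unordered pair (ties within tol count fractionally)."""
    n = W.shape[0]
    D = all_pairs_shortest_paths_bruteforce(W)
    bc = np.zeros(n)
    nodes = set(range(n))
    for s in range(n):
        for t in range(s + 1, n):
            if not np.isfinite(D[s, t]):
                continue
            shortest = []
            for k in range(0, n - 1):
                for mid in permutations(nodes - {s, t}, k):
                    path = (s, *mid, t)
                    length = 0.0
                    ok = True
                    for a, b in zip(path[:-1], path[1:]):
                        if W[a, b] <= 0:
                            ok = False
                            break
                        length += 1.0 / W[a, b]
                    if ok and abs(length - D[s, t]) <= tol * max(1.0, D[s, t]):
                        shortest.append(path)
            if not shortest:
                continue
            for path in shortest:
                for v in path[1:-1]:
                    bc[v] += 1.0 / len(shortest)
    return bc


def eigenvector_power_iteration(W: np.ndarray, n_iter: int = 20000) -> np.ndarray:
    """Power iteration on W + cI (same eigenvectors, strictly dominant top
    eigenvalue even for bipartite graphs whose spectrum is symmetric)."""
    M = W + (1.0 + W.sum(axis=1).max()) * np.eye(W.shape[0])
    v = np.ones(W.shape[0])
    v /= np.linalg.norm(v)
    for _ in range(n_iter):
        nv = M @ v
        norm = np.linalg.norm(nv)
        if norm == 0:
            return v
        nv /= norm
        if np.linalg.norm(nv - v) < 1e-14:
            return nv
        v = nv
    return v


def participation_bruteforce(W: np.ndarray, part: np.ndarray) -> np.ndarray:
    n = W.shape[0]
    out = np.zeros(n)
    for i in range(n):
        k = W[i].sum()
        if k == 0:
            continue
        acc = 0.0
        for m in np.unique(part):
            acc += (W[i, part == m].sum() / k) ** 2
        out[i] = 1.0 - acc
    return out


def within_module_z_bruteforce(W: np.ndarray, part: np.ndarray) -> np.ndarray:
    n = W.shape[0]
    out = np.zeros(n)
    for m in np.unique(part):
        idx = np.flatnonzero(part == m)
        kappas = np.array([W[i, idx].sum() for i in idx])
        sd = kappas.std()
        for pos, i in enumerate(idx):
            out[i] = (kappas[pos] - kappas.mean()) / sd if sd > 0 else 0.0
    return out


def distance_shells_bruteforce(
    tumor: np.ndarray, voxel_mm: float, step_mm: float, max_mm: float
) -> list[np.ndarray]:
    """Euclidean distance shells on an isotropic grid via explicit
    min-over-tumor-voxel distances."""
    tumor_idx = np.argwhere(tumor).astype(float)
    shape = tumor.shape
    grid = np.argwhere(np.ones(shape, bool)).astype(float)
    # chunked min distance to any tumor voxel
    dmin = np.full(grid.shape[0], np.inf)
    for start in range(0, grid.shape[0], 8192):
        block = grid[start : start + 8192]
        d2 = ((block[:, None, :] - tumor_idx[None, :, :]) ** 2).sum(axis=2)
        dmin[start : start + 8192] = np.sqrt(d2.min(axis=1)) * voxel_mm
    dmin = dmin.reshape(shape)
    n_bands = int(np.ceil(max_mm / step_mm))
    shells = []
    for k in range(n_bands):
        lo = k * step_mm
        hi = min((k + 1) * step_mm, max_mm)
        shells.append((dmin > lo) & (dmin <= hi))
    return shells


def anova_f_bruteforce(groups: list[np.ndarray]) -> float:
    """One-way ANOVA F by direct computation of the decomposition."""
    allv = np.concatenate(groups)
    grand = allv.mean()
    ssb = sum(len(g) * (np.mean(g) - grand) ** 2 for g in groups)
    ssw = sum(((g - np.mean(g)) ** 2).sum() for g in groups)
    return (ssb / (len(groups) - 1)) / (ssw / (len(allv) - len(groups)))
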