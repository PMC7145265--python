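"""Mini-batch k-means microstate clustering of kinetic-mapped projections.

Standard mini-batch scheme: k-means++ initialization, then per-batch
nearest-center assignment with per-center running-count learning rates
(center <- center + (x - center)/count), and a final full-pass assignment.
Ties in the nearest-center rule break to the lowest center index.  Empty
clusters found at the final pass are reseeded to the point farthest from
its assigned center.  Everything is driven by an explicit seed and is
bit-for-bit reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["Clustering", "fit_minibatch_kmeans", "assign"]


@dataclass
class Clustering:
    """k centers in tIC space plus per-trajectory integer assignments."""

    centers: np.ndarray  # (k, d)
    assignments: list[np.ndarray]
    inertia: float
    seed: int

    @property
    def k(self) -> int:
        return self.centers.shape[0]


def _stack(projections) -> tuple[np.ndarray, list[int]]:
    # float32 inputs are kept as float32 to bound memory on large datasets
    arrays = []
    for p in projections:
        a = np.atleast_2d(np.asarray(p))
        if a.dtype not in (np.float32, np.float64):
            a = a.astype(np.float64)
        arrays.append(a)
    lengths = [a.shape[0] for a in arrays]
    if len(arrays) == 1:  # no copy for a pre-stacked dataset
        return arrays[0], lengths
    return np.vstack(arrays), lengths


def _nearest(x: np.ndarray, centers: np.ndarray,
             chunk: int = 65536) -> tuple[np.ndarray, np.ndarray]:
    """Nearest center index and squared distance, chunked matmul form."""
    centers = centers.astype(x.dtype, copy=False)
    c2 = np.einsum("kd,kd->k", centers, centers)
    idx = np.empty(x.shape[0], dtype=np.int64)
    d2 = np.empty(x.shape[0])
    for i in range(0, x.shape[0], chunk):
        xa = x[i:i + chunk]
        dist = c2[None, :] - 2.0 * (xa @ centers.T)
        j = np.argmin(dist, axis=1)  # argmin -> first (lowest) index on ties
        idx[i:i + chunk] = j
        d2[i:i + chunk] = dist[np.arange(xa.shape[0]), j] + \
            np.einsum("nd,nd->n", xa, xa)
    np.maximum(d2, 0.0, out=d2)
    return idx, d2


def _kmeanspp(x: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """Greedy k-means++: several candidates per step, keep the one that
    lowers the potential most (the standard quality refinement)."""
    x = np.asarray(x, dtype=np.float64)
    n = x.shape[0]
    n_candidates = 2 + int(np.log(k))
    centers = np.empty((k, x.shape[1]))
    centers[0] = x[rng.integers(n)]
    d2 = np.einsum("nd,nd->n", x - centers[0], x - centers[0])
    for j in range(1, k):
        total = d2.sum()
        probs = d2 / total if total > 0 else np.full(n, 1.0 / n)
        cand = rng.choice(n, size=n_candidates, p=probs)
        best_pot, best_i, best_d2 = np.inf, cand[0], None
        for ci in cand:
            nd2 = np.minimum(
                d2, np.einsum("nd,nd->n", x - x[ci], x - x[ci]))
            pot = nd2.sum()
            if pot < best_pot:
                best_pot, best_i, best_d2 = pot, ci, nd2
        centers[j] = x[best_i]
        d2 = best_d2
    return centers


def fit_minibatch_kmeans(projections, k: int = 324, batch_size: int = 1000,
                         n_iter: int = 300, seed: int = 0) -> Clustering:
    """Cluster projected trajectories into ``k`` microstates.

    Parameters
    ----------
    projections
        List of (T_i, d) arrays (or a single array).
    k
        Number of microstates; default 324.
    batch_size, n_iter
        Mini-batch size and number of batch updates.
    seed
        Drives k-means++ and batch sampling; same seed + data gives
        identical centers bit-for-bit.

    Raises
    ------
    ValueError
        If the input is empty or has fewer frames than ``k``.
    """
    single = isinstance(projections, np.ndarray)
    if single:
        projections = [projections]
    if not projections:
        raise ValueError("empty input")
    x, lengths = _stack(projections)
    n = x.shape[0]
    if n == 0:
        raise ValueError("empty input")
    if k > n:
        raise ValueError(f"k={k} exceeds the number of frames ({n})")
    rng = np.random.default_rng(seed)
    # k-means++ on a bounded subsample for tractable seeding at large n
    init_pool = x if n <= 100_000 else x[rng.choice(n, 100_000, replace=False)]
    centers = _kmeanspp(init_pool, k, rng)
    counts = np.zeros(k, dtype=np.int64)
    for _ in range(n_iter):
        batch = x[rng.integers(0, n, size=min(batch_size, n))]
        j, _ = _nearest(batch, centers)
        for c in np.unique(j):
            members = batch[j == c]
            for m in members:  # sequential per-sample update, lr = 1/count
                counts[c] += 1
                centers[c] += (m - centers[c]) / counts[c]
    # final full pass
    idx, d2 = _nearest(x, centers)
    # empty-cluster repair: reseed to the farthest point, then reassign
    empty = np.setdiff1d(np.arange(k), np.unique(idx))
    if empty.size:
        order = np.argsort(d2)[::-1]
        for c, p in zip(empty, order[:empty.size]):
            centers[c] = x[p]
        idx, d2 = _nearest(x, centers)
    inertia = float(d2.sum())
    offsets = np.cumsum([0] + lengths)
    assignments = [idx[offsets[i]:offsets[i + 1]] for i in range(len(lengths))]
    return Clustering(centers=centers, assignments=assignments,
                      inertia=inertia, seed=seed)


def refine_full_batch(clustering: Clustering, projections,
                      n_pass: int = 1) -> Clustering:
    """Full-batch Lloyd refinement passes; inertia is non-increasing."""
    x, lengths = _stack(projections if not isinstance(projections, np.ndarray)
                        else [projections])
    centers = clustering.centers.copy()
    for _ in range(n_pass):
        idx, _ = _nearest(x, centers)
        for c in range(centers.shape[0]):
            members = x[idx == c]
            if members.size:
                centers[c] = members.mean(axis=0)
    idx, d2 = _nearest(x, centers)
    offsets = np.cumsum([0] + lengths)
    assignments = [idx[offsets[i]:offsets[i + 1]] for i in range(len(lengths))]
    return Clustering(centers=centers, assignments=assignments,
                      inertia=float(d2.sum()), seed=clustering.seed)


def assign(clustering: Clustering, projections):
    """Nearest-center discretization (ties break to the lowest index).

    Returns a list of integer trajectories (or a single array if a single
    array was passed).
    """
    single = isinstance(projections, np.ndarray)
    if single:
        projections = [projections]
    out = []
    for p in projections:
        a = np.atleast_2d(np.asarray(p, dtype=np.float64))
        if a.shape[1] != clustering.centers.shape[1]:
            raise ValueError(
                f"dimension mismatch: data has {a.shape[1]}, centers have "
                f"{clustering.centers.shape[1]}")
        idx, _ = _nearest(a, clustering.centers)
        out.append(idx)
    return out[0] if single else out
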