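"""Emergent self-organizing map (ESOM) on fragment composition vectors.

A large toroidal Kohonen map trained online on canonical k-mer frequency
vectors of fixed-size scaffold fragments. The borderless (toroidal) topology
lets genome clusters emerge without edge artifacts; the U-matrix (per-node
mean weight distance to its 8 toroidal neighbors) draws the cluster
boundaries. Co-binning of a query scaffold with a bin is decided by the
fraction of its fragments whose best-matching units (BMUs) fall inside the
bin's dilated BMU territory.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np


@dataclass
class SomConfig:
    rows: int
    cols: int
    toroidal: bool = True
    epochs: int = 20
    lr_initial: float = 0.5
    lr_final: float = 0.05
    radius_initial: float | None = None  # default max(rows, cols) / 2
    radius_final: float = 1.0
    seed: int = 0
    init: str = "pca_plane"  # or "random_uniform"

    def __post_init__(self) -> None:
        if self.rows < 4 or self.cols < 4:
            raise ValueError("grid dimensions must be >= 4")
        if not self.lr_final < self.lr_initial:
            raise ValueError("lr_final must be < lr_initial")
        if self.radius_initial is None:
            self.radius_initial = max(self.rows, self.cols) / 2.0
        if self.radius_final > self.radius_initial:
            raise ValueError("radius_final must be <= radius_initial")
        if self.init not in ("pca_plane", "random_uniform"):
            raise ValueError(f"unknown init {self.init!r}")


@dataclass
class SomGrid:
    config: SomConfig
    weights: np.ndarray  # (rows*cols, dim), row-major node order
    training_quantization_error_by_epoch: list[float]

    @property
    def shape(self) -> tuple[int, int]:
        return self.config.rows, self.config.cols

    def weights_grid(self) -> np.ndarray:
        return self.weights.reshape(self.config.rows, self.config.cols, -1)


@dataclass
class BmuAssignment:
    bmu: dict[str, tuple[int, int]]  # fragment_id -> (row, col)
    quantization_error: dict[str, float]


@dataclass
class EsomVerdict:
    bin_id: str
    scaffold_id: str
    territory: set[tuple[int, int]]
    fraction_in_territory: float
    co_binned: bool
    outlier_fragments: list[str]
    threshold: float = 0.8


def default_grid_shape(n_fragments: int) -> tuple[int, int]:
    """Grid of ~5*sqrt(n) nodes at ~1:1.6 aspect, floors at 4x4."""
    if n_fragments < 10:
        raise ValueError("too few fragments for an ESOM (need >= 10)")
    n_nodes = 5.0 * math.sqrt(n_fragments)
    rows = max(4, round(math.sqrt(n_nodes / 1.6)))
    cols = max(4, round(n_nodes / rows))
    if rows > cols:
        rows, cols = cols, rows
    return rows, cols


def _torus_sq_distances(rows: int, cols: int, toroidal: bool) -> np.ndarray:
    """(nodes, nodes) squared grid distances (wrapped deltas on a torus)."""
    r = np.arange(rows)
    c = np.arange(cols)
    dr = np.abs(r[:, None] - r[None, :])
    dc = np.abs(c[:, None] - c[None, :])
    if toroidal:
        dr = np.minimum(dr, rows - dr)
        dc = np.minimum(dc, cols - dc)
    d2 = (dr[:, None, :, None] ** 2 + dc[None, :, None, :] ** 2).astype(float)
    return d2.reshape(rows * cols, rows * cols)


def _init_weights(X: np.ndarray, config: SomConfig, rng: np.random.Generator) -> np.ndarray:
    n_nodes = config.rows * config.cols
    if config.init == "random_uniform":
        lo, hi = X.min(axis=0), X.max(axis=0)
        return rng.uniform(lo, hi, size=(n_nodes, X.shape[1]))
    # pca_plane: span the grid across the first two principal axes
    mean = X.mean(axis=0)
    Xc = X - mean
    _, s, vt = np.linalg.svd(Xc, full_matrices=False)
    sd = s[:2] / math.sqrt(max(1, X.shape[0] - 1))
    if len(sd) < 2 or sd[1] == 0:  # rank-deficient input
        sd = np.array([sd[0] if len(sd) else 0.0, 0.0])
    a = np.linspace(-2.0, 2.0, config.rows)
    b = np.linspace(-2.0, 2.0, config.cols)
    W = (
        mean[None, None, :]
        + a[:, None, None] * sd[0] * vt[0][None, None, :]
        + (b[None, :, None] * sd[1] * vt[1][None, None, :] if vt.shape[0] > 1 else 0.0)
    )
    return W.reshape(n_nodes, X.shape[1]).astype(float)


def train_som(features: np.ndarray, config: SomConfig) -> SomGrid:
    """Online Kohonen training with Gaussian neighborhood and linear decay.

    Per step: draw the next fragment (seeded shuffle per epoch), find its BMU,
    and pull every node toward it with strength
    ``alpha(t) * exp(-d_torus^2 / (2 sigma(t)^2))``. Deterministic per seed.
    """
    X = np.asarray(features, dtype=float)
    if X.ndim != 2:
        raise ValueError("features must be 2-D (fragments x dims)")
    if not np.isfinite(X).all():
        raise ValueError("NaN or inf in features")
    if X.shape[0] < 10:
        raise ValueError("too few fragments for an ESOM (need >= 10)")
    rng = np.random.default_rng(config.seed)
    W = _init_weights(X, config, rng)
    d2 = _torus_sq_distances(config.rows, config.cols, config.toroidal)

    qe_by_epoch: list[float] = []
    denom = max(1, config.epochs - 1)
    for epoch in range(config.epochs):
        frac = epoch / denom
        alpha = config.lr_initial + frac * (config.lr_final - config.lr_initial)
        sigma = config.radius_initial + frac * (config.radius_final - config.radius_initial)
        h_cache = np.exp(-d2 / (2.0 * sigma * sigma))
        order = rng.permutation(X.shape[0])
        qe_sum = 0.0
        for i in order:
            x = X[i]
            diff = x - W
            sq = np.einsum("ij,ij->i", diff, diff)
            bmu = int(np.argmin(sq))
            qe_sum += math.sqrt(sq[bmu])
            W += (alpha * h_cache[bmu])[:, None] * diff
        qe_by_epoch.append(qe_sum / X.shape[0])
    return SomGrid(config=config, weights=W, training_quantization_error_by_epoch=qe_by_epoch)


def compute_umatrix(grid: SomGrid) -> np.ndarray:
    """Per-node mean Euclidean weight distance to the 8 toroidal neighbors."""
    rows, cols = grid.shape
    W = grid.weights_grid()
    dists = []
    for dr in (-1, 0, 1):
        for dc in (-1, 0, 1):
            if dr == 0 and dc == 0:
                continue
            shifted = np.roll(np.roll(W, dr, axis=0), dc, axis=1)
            dists.append(np.linalg.norm(W - shifted, axis=2))
    return np.mean(dists, axis=0)


def assign_bmu(
    grid: SomGrid, features: np.ndarray, fragment_ids: Sequence[str]
) -> BmuAssignment:
    """Exact argmin BMU per fragment; ties break to the smallest (row, col)."""
    X = np.asarray(features, dtype=float)
    if X.shape[1] != grid.weights.shape[1]:
        raise ValueError(
            f"feature dim {X.shape[1]} != weight dim {grid.weights.shape[1]}"
        )
    # (n, nodes) squared distances; argmin returns the first (row-major =
    # lexicographically smallest (row, col)) minimizer.
    sq = (
        np.einsum("ij,ij->i", X, X)[:, None]
        - 2.0 * X @ grid.weights.T
        + np.einsum("ij,ij->i", grid.weights, grid.weights)[None, :]
    )
    # guard against tiny negative round-off before sqrt
    np.maximum(sq, 0.0, out=sq)
    idx = np.argmin(sq, axis=1)
    cols = grid.config.cols
    bmu = {
        fid: (int(i // cols), int(i % cols)) for fid, i in zip(fragment_ids, idx)
    }
    qe = {
        fid: float(np.linalg.norm(X[j] - grid.weights[idx[j]]))
        for j, fid in enumerate(fragment_ids)
    }
    return BmuAssignment(bmu=bmu, quantization_error=qe)


def dilate_territory(
    nodes: set[tuple[int, int]], rows: int, cols: int, radius: int = 1
) -> set[tuple[int, int]]:
    """Chebyshev dilation of a node set on the torus."""
    out: set[tuple[int, int]] = set()
    for r, c in nodes:
        for dr in range(-radius, radius + 1):
            for dc in range(-radius, radius + 1):
                out.add(((r + dr) % rows, (c + dc) % cols))
    return out


def territory_verdict(
    bin_id: str,
    scaffold_id: str,
    bin_bmus: Mapping[str, tuple[int, int]],
    query_bmus: Mapping[str, tuple[int, int]],
    grid_shape: tuple[int, int],
    dilation_radius: int = 1,
    threshold: float = 0.8,
) -> EsomVerdict:
    """Co-binning verdict: the fraction of query fragments whose BMUs fall in
    the bin's dilated BMU territory must reach ``threshold``."""
    if len(bin_bmus) < 5:
        raise ValueError("territory undefined: bin has < 5 fragments")
    if not query_bmus:
        raise ValueError("empty query fragment set")
    rows, cols = grid_shape
    territory = dilate_territory(set(bin_bmus.values()), rows, cols, dilation_radius)
    inside = {fid for fid, node in query_bmus.items() if node in territory}
    fraction = len(inside) / len(query_bmus)
    return EsomVerdict(
        bin_id=bin_id,
        scaffold_id=scaffold_id,
        territory=territory,
        fraction_in_territory=fraction,
        co_binned=fraction >= threshold,
        outlier_fragments=sorted(set(query_bmus) - inside),
        threshold=threshold,
    )


def tiled_umatrix(grid: SomGrid) -> np.ndarray:
    """2x2 tiled U-matrix view (four copies), the standard borderless render."""
    u = compute_umatrix(grid)
    return np.tile(u, (2, 2))
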