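"""Steady-state RNA velocity estimation and pseudotime-binned summaries.

The steady-state model assumes that for cells at the extremes of a
gene's expression range the unspliced/spliced ratio reflects the
degradation-to-splicing ratio gamma. Velocity is then the residual
v = u - gamma * s on size-normalized (optionally kNN-pooled) layers; a
positive residual means the gene's spliced pool is rising.
"""

from __future__ import annotations

import warnings
from typing import Optional

import numpy as np
import pandas as pd
from sklearn.neighbors import NearestNeighbors

from .containers import EmbeddingState, VelocityField


def size_normalize(layer: np.ndarray, target: Optional[float] = None) -> np.ndarray:
    """Scale each cell (column) to ``target`` total counts (default: the
    median column total of the layer)."""
    layer = np.asarray(layer, dtype=float)
    totals = layer.sum(axis=0)
    if target is None:
        target = np.median(totals[totals > 0]) if (totals > 0).any() else 1.0
    safe = np.where(totals > 0, totals, 1.0)
    return layer / safe * target


def pool_layers(
    spliced: np.ndarray,
    unspliced: np.ndarray,
    coords: Optional[np.ndarray] = None,
    k_pool: int = 30,
    groups: Optional[np.ndarray] = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Smooth both layers by averaging over each cell's k nearest
    neighbors (in ``coords``, a cells x d embedding; when absent, a PCA
    of the size-normalized spliced layer is used).

    With ``groups`` given, neighbors are restricted to cells of the same
    group, so group-specific kinetics are not averaged away where the
    groups share state-space support.
    """
    spliced = np.asarray(spliced, dtype=float)
    unspliced = np.asarray(unspliced, dtype=float)
    n_cells = spliced.shape[1]
    if coords is None:
        # variance-stabilized PCA so no single high-count gene's noise
        # dominates the neighbor graph
        X = np.log1p(spliced.T)
        X = X - X.mean(axis=0)
        _, _, Vt = np.linalg.svd(X, full_matrices=False)
        coords = X @ Vt[: min(10, Vt.shape[0])].T
    s_out = np.empty_like(spliced)
    u_out = np.empty_like(unspliced)
    if groups is None:
        groups = np.zeros(n_cells)
    groups = np.asarray(groups)
    for g in np.unique(groups):
        sel = np.flatnonzero(groups == g)
        k = min(k_pool, len(sel))
        nn = NearestNeighbors(n_neighbors=k).fit(coords[sel])
        _, idx = nn.kneighbors(coords[sel])
        s_out[:, sel] = spliced[:, sel[idx]].mean(axis=2)
        u_out[:, sel] = unspliced[:, sel[idx]].mean(axis=2)
    return s_out, u_out


def fit_gamma(
    spliced: np.ndarray,
    unspliced: np.ndarray,
    extreme_quantile: float = 0.05,
) -> np.ndarray:
    """Per-gene degradation-to-splicing ratio gamma.

    For each gene, cells in the top and bottom ``extreme_quantile`` of
    spliced expression are selected and the least-squares slope through
    the origin of u on s is computed, clipped at 0. All-zero genes get
    gamma = 0 with a warning.
    """
    s = np.atleast_2d(np.asarray(spliced, dtype=float))
    u = np.atleast_2d(np.asarray(unspliced, dtype=float))
    if s.shape != u.shape:
        raise ValueError("spliced and unspliced shapes differ")
    n_genes, n_cells = s.shape
    gamma = np.zeros(n_genes)
    n_ext = max(int(np.ceil(extreme_quantile * n_cells)), 1)
    for g in range(n_genes):
        sg, ug = s[g], u[g]
        if not sg.any() and not ug.any():
            warnings.warn(f"gene index {g}: all-zero; gamma set to 0")
            continue
        order = np.argsort(sg, kind="stable")
        sel = np.concatenate([order[:n_ext], order[-n_ext:]])
        denom = (sg[sel] ** 2).sum()
        gamma[g] = (ug[sel] * sg[sel]).sum() / denom if denom > 0 else 0.0
    return np.clip(gamma, 0.0, None)


def compute_velocity(
    spliced: np.ndarray,
    unspliced: np.ndarray,
    gamma_hat: np.ndarray,
    delta_t: float = 1.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Velocity v = u - gamma*s (cells x genes) and the extrapolated
    future spliced state max(s + v*delta_t, 0)."""
    s = np.atleast_2d(np.asarray(spliced, dtype=float))
    u = np.atleast_2d(np.asarray(unspliced, dtype=float))
    if (s < 0).any() or (u < 0).any():
        raise ValueError("layers must be nonnegative")
    gamma_hat = np.asarray(gamma_hat, dtype=float)
    v = (u - gamma_hat[:, None] * s).T  # cells x genes
    future = np.clip(s.T + v * delta_t, 0.0, None)
    return v, future


def estimate_velocity_field(
    lcm,
    embedding: Optional[EmbeddingState] = None,
    extreme_quantile: float = 0.05,
    k_pool: int = 30,
    delta_t: float = 1.0,
    scale_total: float = 10000.0,
    groups: Optional[np.ndarray] = None,
) -> VelocityField:
    """Full pipeline: size-normalize each layer, kNN-pool, fit gamma,
    compute velocity, and (when an embedding is given) project into it.

    Gamma and velocity live on the linear size-normalized layers. For
    the embedding projection, current and extrapolated future spliced
    expression are both mapped through log1p first — the scale on which
    the embedding was fit — and the coordinate difference per delta_t is
    the embedded velocity.
    """
    # one size factor per cell, from spliced totals, applied to both layers:
    # preserves each cell's unspliced:spliced ratio while removing depth
    totals = np.asarray(lcm.spliced, dtype=float).sum(axis=0)
    factors = np.where(totals > 0, totals, 1.0) / scale_total
    s = np.asarray(lcm.spliced, dtype=float) / factors
    u = np.asarray(lcm.unspliced, dtype=float) / factors
    coords = embedding.coordinates if embedding is not None else None
    s_pool, u_pool = pool_layers(s, u, coords=coords, k_pool=k_pool, groups=groups)
    gamma = fit_gamma(s_pool, u_pool, extreme_quantile)
    v, future = compute_velocity(s_pool, u_pool, gamma, delta_t)
    field = VelocityField(
        gamma_hat=gamma,
        velocity_gene=v,
        gene_ids=list(lcm.gene_ids),
        delta_t=delta_t,
        future_spliced=future,
    )
    if embedding is not None:
        # log-space delta so the projection matches the embedding's scale
        log_field = VelocityField(
            gamma_hat=gamma,
            velocity_gene=(np.log1p(future) - np.log1p(s_pool.T)) / delta_t,
            gene_ids=list(lcm.gene_ids),
            delta_t=delta_t,
        )
        field.velocity_embed = embed_velocity(
            log_field, embedding, np.log1p(s_pool.T)
        )
    return field


def embed_velocity(
    field: VelocityField,
    embedding: EmbeddingState,
    current_expr: np.ndarray,
) -> np.ndarray:
    """Project the velocity extrapolation into the embedding.

    ``current_expr`` is cells x genes in the field's gene order. The
    future expression is passed through the embedding's stored centering
    and loadings (restricted to the shared gene set), and
    velocity_embed = (future coords - current coords) / delta_t.
    """
    shared = [g for g in embedding.gene_ids if g in set(field.gene_ids)]
    if not shared:
        raise ValueError("no genes shared between velocity field and embedding")
    f_pos = {g: i for i, g in enumerate(field.gene_ids)}
    e_pos = {g: i for i, g in enumerate(embedding.gene_ids)}
    fi = [f_pos[g] for g in shared]
    ei = [e_pos[g] for g in shared]
    cur = np.atleast_2d(np.asarray(current_expr, dtype=float))[:, fi]
    fut = cur + field.velocity_gene[:, fi] * field.delta_t
    load = embedding.loadings[ei]
    means = embedding.gene_means[ei]
    return ((fut - means) @ load - (cur - means) @ load) / field.delta_t


def magnitude_by_pseudotime(
    velocity_embed: np.ndarray,
    pseudotime: np.ndarray,
    n_bins: int = 50,
    rolling_window: int = 5,
    min_cells: int = 10,
    edges: Optional[np.ndarray] = None,
) -> pd.DataFrame:
    """Magnitude of the mean velocity vector in equal-width pseudotime bins.

    Bins with fewer than ``min_cells`` cells are reported but masked
    (NaN) in the rolling mean. Pass shared ``edges`` when curves from
    different groups are to be compared bin-by-bin. Returns a table with
    bin_center, magnitude, magnitude_rolling, n_cells, masked.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    v = np.atleast_2d(np.asarray(velocity_embed, dtype=float))
    pt = np.asarray(pseudotime, dtype=float)
    if np.isnan(pt).any():
        raise ValueError("pseudotime must be assigned for all cells")
    if edges is None:
        edges = np.linspace(pt.min(), pt.max(), n_bins + 1)
    else:
        edges = np.asarray(edges, dtype=float)
        n_bins = len(edges) - 1
    which = np.clip(np.digitize(pt, edges) - 1, 0, n_bins - 1)
    mags = np.full(n_bins, np.nan)
    counts = np.zeros(n_bins, dtype=int)
    for b in range(n_bins):
        mask = which == b
        counts[b] = mask.sum()
        if counts[b] > 0:
            mags[b] = np.linalg.norm(v[mask].mean(axis=0))
    masked = counts < min_cells
    usable = pd.Series(np.where(masked, np.nan, mags))
    rolling = usable.rolling(rolling_window, center=True, min_periods=1).mean()
    return pd.DataFrame(
        {
            "bin_center": (edges[:-1] + edges[1:]) / 2.0,
            "magnitude": mags,
            "magnitude_rolling": rolling.to_numpy(),
            "n_cells": counts,
            "masked": masked,
        }
    )
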