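"""Pseudotime mapping, lineage regression, and phase-point simulation.

A kNN regression maps embedding coordinates to pseudotime, so any point
in the state space (including velocity-extrapolated future states and
simulated phase points) can be assigned a position along the activation
trajectory. Delta-pseudotime is the predicted future pseudotime minus
the observed one; cells more than half a standard deviation below zero
are classified as regressing along the lineage. Phase points are
advected through group-specific velocity fields by explicit Euler steps
with a kNN velocity lookup, probing trajectory speed and attractors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dc_field
from typing import Literal, Optional

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d
from sklearn.neighbors import KNeighborsRegressor, NearestNeighbors

from .containers import EmbeddingState, PhaseSimResult, VelocityField


@dataclass
class PseudotimeMap:
    """kNN regression from embedding coordinates to pseudotime."""

    reference_coords: np.ndarray
    reference_pseudotime: np.ndarray
    k: int = 5
    weighting: Literal["uniform", "inverse-distance"] = "uniform"
    _model: KNeighborsRegressor = dc_field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.reference_coords = np.asarray(self.reference_coords, dtype=float)
        self.reference_pseudotime = np.asarray(
            self.reference_pseudotime, dtype=float
        )
        n_ref = len(self.reference_coords)
        if not 1 <= self.k <= n_ref:
            raise ValueError(f"k must lie in [1, {n_ref}]")
        if np.isnan(self.reference_pseudotime).any():
            raise ValueError("pseudotime must be present for all reference cells")
        weights = "uniform" if self.weighting == "uniform" else "distance"
        self._model = KNeighborsRegressor(n_neighbors=self.k, weights=weights)
        self._model.fit(self.reference_coords, self.reference_pseudotime)

    def predict(self, coords: np.ndarray) -> np.ndarray:
        coords = np.atleast_2d(np.asarray(coords, dtype=float))
        return self._model.predict(coords)


def fit_pseudotime_map(
    e: EmbeddingState, k: int = 5, weighting: str = "uniform"
) -> PseudotimeMap:
    if e.pseudotime is None:
        raise ValueError("embedding carries no pseudotime")
    return PseudotimeMap(e.coordinates, e.pseudotime, k=k, weighting=weighting)  # type: ignore[arg-type]


def delta_pseudotime(
    e: EmbeddingState, field: VelocityField, pt_map: PseudotimeMap
) -> np.ndarray:
    """Predicted pseudotime of each cell's velocity-extrapolated future
    state minus its observed pseudotime. Cells with missing observed
    pseudotime get NaN with a warning."""
    if field.velocity_embed is None:
        raise ValueError("field has no embedded velocity")
    if field.velocity_embed.shape[0] != e.n_cells:
        raise ValueError("velocity rows do not match embedding rows")
    observed = (
        e.pseudotime
        if e.pseudotime is not None
        else np.full(e.n_cells, np.nan)
    )
    future = e.coordinates + field.velocity_embed * field.delta_t
    predicted = pt_map.predict(future)
    if np.isnan(observed).any():
        warnings.warn("cells with missing observed pseudotime yield NaN")
    return predicted - observed


def classify_lineage_regression(
    dp: np.ndarray,
    threshold_multiplier: float = 0.5,
    n_bins: int = 20,
    smooth_sigma: float = 1.0,
    pseudotime: Optional[np.ndarray] = None,
) -> dict:
    """Classify regressing cells and summarize their frequency.

    sigma is the sample standard deviation (ddof=1) of delta-pseudotime;
    a cell regresses iff dp < -threshold_multiplier * sigma. When
    ``pseudotime`` is given, a per-bin regressing fraction curve with
    Gaussian smoothing (``smooth_sigma`` bins) and per-bin standard
    errors is included.
    """
    dp = np.asarray(dp, dtype=float)
    valid = ~np.isnan(dp)
    if valid.sum() < 2:
        raise ValueError("need >= 2 cells with delta-pseudotime")
    sigma = float(np.std(dp[valid], ddof=1))
    if sigma == 0:
        warnings.warn("constant delta-pseudotime: sigma=0, no regressing cells")
        mask = np.zeros_like(dp, dtype=bool)
    else:
        mask = dp < -threshold_multiplier * sigma
    out = {
        "mask": mask,
        "sigma": sigma,
        "threshold": -threshold_multiplier * sigma,
        "fraction": float(mask[valid].mean()),
    }
    if pseudotime is not None:
        pt = np.asarray(pseudotime, dtype=float)[valid]
        m = mask[valid]
        edges = np.linspace(pt.min(), pt.max(), n_bins + 1)
        which = np.clip(np.digitize(pt, edges) - 1, 0, n_bins - 1)
        frac = np.full(n_bins, np.nan)
        se = np.full(n_bins, np.nan)
        n = np.zeros(n_bins, dtype=int)
        for b in range(n_bins):
            sel = which == b
            n[b] = sel.sum()
            if n[b]:
                p = m[sel].mean()
                frac[b] = p
                se[b] = np.sqrt(p * (1 - p) / n[b])
        filled = pd.Series(frac).ffill().bfill().to_numpy()
        out["curve"] = pd.DataFrame(
            {
                "bin_center": (edges[:-1] + edges[1:]) / 2.0,
                "fraction": frac,
                "fraction_smooth": gaussian_filter1d(filled, smooth_sigma),
                "se": se,
                "n_cells": n,
            }
        )
    return out


@dataclass
class PhaseSimConfig:
    """Settings for phase-point simulation (defaults follow the study
    design: 1000 points, 5000 explicit-Euler steps, kNN velocity
    lookup)."""

    n_points: int = 1000
    n_steps: int = 5000
    k_field: int = 30
    step_size: float = 0.05
    noise_sd: float = 0.0
    init_region: Literal["primitive_activated", "all"] = "primitive_activated"
    init_quantile: float = 0.25
    normalize_velocity: bool = True
    density_grid_size: int = 100
    seed: int = 0


def select_init_positions(
    coords: np.ndarray,
    cfg: PhaseSimConfig,
    pseudotime: Optional[np.ndarray] = None,
    timepoint: Optional[np.ndarray] = None,
    rng: Optional[np.random.Generator] = None,
) -> np.ndarray:
    """Sample initial phase-point positions from observed cell positions.

    ``primitive_activated`` restricts to activated-timepoint cells whose
    pseudotime falls below that group's ``init_quantile`` quantile — the
    primitive (earliest) region of the activated population.
    """
    rng = rng or np.random.default_rng(cfg.seed)
    mask = np.ones(len(coords), dtype=bool)
    if cfg.init_region == "primitive_activated":
        if timepoint is not None:
            mask &= np.asarray(timepoint) == "activated"
        if pseudotime is not None and mask.any():
            q = np.quantile(np.asarray(pseudotime)[mask], cfg.init_quantile)
            mask &= np.asarray(pseudotime) <= q
    if not mask.any():
        raise ValueError(f"init region {cfg.init_region!r} selected no cells")
    idx = rng.choice(np.flatnonzero(mask), size=cfg.n_points, replace=True)
    return coords[idx].copy()


def simulate_phase_points(
    coords: np.ndarray,
    velocity_embed: np.ndarray,
    cfg: PhaseSimConfig,
    init_positions: Optional[np.ndarray] = None,
    pseudotime: Optional[np.ndarray] = None,
    timepoint: Optional[np.ndarray] = None,
    pt_map: Optional[PseudotimeMap] = None,
) -> PhaseSimResult:
    """Advect phase points through a group-restricted velocity field.

    At each step the velocity at a point is the mean embedded velocity
    of its ``k_field`` nearest cells; the update is
    x <- x + step_size * v + noise. With ``normalize_velocity`` the
    field is pre-scaled to unit median magnitude so step_size is in
    embedding units. Reproducible given the seed.
    """
    coords = np.asarray(coords, dtype=float)
    vel = np.asarray(velocity_embed, dtype=float)
    if len(coords) < cfg.k_field:
        raise ValueError("group has fewer cells than k_field")
    if cfg.normalize_velocity:
        med = np.median(np.linalg.norm(vel, axis=1))
        if med > 0:
            vel = vel / med
    rng = np.random.default_rng(cfg.seed)
    if init_positions is None:
        init_positions = select_init_positions(
            coords, cfg, pseudotime=pseudotime, timepoint=timepoint, rng=rng
        )
    pts = np.asarray(init_positions, dtype=float).copy()
    n_points, d = pts.shape
    nn = NearestNeighbors(n_neighbors=cfg.k_field).fit(coords)
    traj = np.empty((n_points, cfg.n_steps + 1, d))
    traj[:, 0] = pts
    for t in range(1, cfg.n_steps + 1):
        _, idx = nn.kneighbors(pts)
        v = vel[idx].mean(axis=1)
        pts = pts + cfg.step_size * v
        if cfg.noise_sd > 0:
            pts = pts + rng.normal(0.0, cfg.noise_sd, pts.shape)
        traj[:, t] = pts

    flat = traj.reshape(-1, d)
    g = cfg.density_grid_size
    density, xe, ye = np.histogram2d(flat[:, 0], flat[:, 1], bins=g)
    inferred = None
    if pt_map is not None:
        inferred = pt_map.predict(flat).reshape(n_points, cfg.n_steps + 1)
    return PhaseSimResult(
        trajectories=traj,
        terminal_positions=traj[:, -1].copy(),
        density_grid=density,
        density_edges=(xe, ye),
        inferred_pseudotime=inferred,
        config={
            "n_points": cfg.n_points,
            "n_steps": cfg.n_steps,
            "k_field": cfg.k_field,
            "step_size": cfg.step_size,
            "noise_sd": cfg.noise_sd,
            "seed": cfg.seed,
        },
    )


def compare_progression(
    result_a: PhaseSimResult,
    result_b: PhaseSimResult,
    pt_map: PseudotimeMap,
    steps: Optional[np.ndarray] = None,
) -> dict:
    """Mean inferred pseudotime per step for two simulations, their
    per-step difference, and the distance between terminal centroids.

    ``steps`` restricts the pseudotime curves to the given step indices
    (useful for long simulations where only, say, the early window and
    the terminus matter)."""
    if result_a.trajectories.shape[2] != result_b.trajectories.shape[2]:
        raise ValueError("simulations have mismatched embedding dimensions")

    def mean_curve(res: PhaseSimResult) -> np.ndarray:
        if res.inferred_pseudotime is not None and steps is None:
            return res.inferred_pseudotime.mean(axis=0)
        n_pts, n_t, d = res.trajectories.shape
        traj = res.trajectories if steps is None else res.trajectories[:, steps]
        flat = traj.reshape(-1, d)
        return pt_map.predict(flat).reshape(n_pts, traj.shape[1]).mean(axis=0)

    curve_a = mean_curve(result_a)
    curve_b = mean_curve(result_b)
    n = min(len(curve_a), len(curve_b))
    centroid_a = result_a.terminal_positions.mean(axis=0)
    centroid_b = result_b.terminal_positions.mean(axis=0)
    return {
        "mean_pseudotime_a": curve_a,
        "mean_pseudotime_b": curve_b,
        "delta": curve_a[:n] - curve_b[:n],
        "terminal_centroid_distance": float(
            np.linalg.norm(centroid_a - centroid_b)
        ),
    }


def velocity_difference_by_direction(
    velocity_gene: np.ndarray,
    regressing_mask: np.ndarray,
    gene_ids: Optional[list[str]] = None,
) -> pd.DataFrame:
    """Per-gene mean velocity difference, forward minus backward cells,
    ranked descending."""
    v = np.atleast_2d(np.asarray(velocity_gene, dtype=float))
    mask = np.asarray(regressing_mask, dtype=bool)
    if mask.all() or not mask.any():
        raise ValueError("both forward and backward groups must be non-empty")
    diff = v[~mask].mean(axis=0) - v[mask].mean(axis=0)
    genes = gene_ids if gene_ids is not None else [f"g{i}" for i in range(v.shape[1])]
    df = pd.DataFrame({"gene_id": genes, "velocity_difference": diff})
    df = df.sort_values("velocity_difference", ascending=False).reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    return df
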