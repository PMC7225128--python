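"""Synthetic transcriptome and motility data with known kinetic ground truth.

The expression generator draws per-cell latent activation times from a
bimodal (quiescent / activated) mixture, integrates the standard
transcription-splicing-degradation kinetics

    du/dt = alpha(t) - beta * u,      ds/dt = beta * u - gamma * s,

per gene along latent time, and samples UMI counts from a
negative-binomial observation model. Age groups progress along latent
time at group-specific rates (aged slower), and label-retaining-cell
(LRC) status is assigned at physiological fractions (~35% young, ~15%
aged). The track generator produces two-state (immotile/motile)
switching random walks at a fixed 6.5 min frame interval, with a
time-dependent motile on-rate emulating activation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Optional

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .containers import LayeredCountMatrix, TrackSet

Profile = Literal["monotone_up", "monotone_down", "pulse", "flat"]

#: transcription never shuts off completely; basal rate as a fraction of alpha_max
BASAL_FRACTION = 0.1


@dataclass
class KineticGeneSpec:
    """Kinetic parameters for one simulated gene.

    ``profile`` sets the shape of the transcription rate alpha(t) over
    latent time t in [0, 1]; ``alpha_max`` is the peak transcription rate
    (molecules per unit latent time), ``beta`` the splicing rate and
    ``gamma`` the degradation rate (both 1 / unit latent time).
    ``noise_dispersion`` is the negative-binomial dispersion phi
    (variance = m + phi * m^2); 0 means Poisson.
    """

    name: str
    profile: Profile = "flat"
    alpha_max: float = 20.0
    beta: float = 1.0
    gamma: float = 0.5
    noise_dispersion: float = 0.1
    ramp_center: float = 0.35
    ramp_width: float = 0.08
    pulse_center: float = 0.5
    pulse_width: float = 0.15

    def validate(self) -> None:
        if self.alpha_max <= 0 or self.beta <= 0 or self.gamma <= 0:
            raise ValueError(
                f"gene {self.name!r}: alpha_max, beta and gamma must be positive "
                f"(got {self.alpha_max}, {self.beta}, {self.gamma})"
            )
        if self.noise_dispersion < 0:
            raise ValueError(f"gene {self.name!r}: noise_dispersion must be >= 0")
        if self.profile not in ("monotone_up", "monotone_down", "pulse", "flat"):
            raise ValueError(f"gene {self.name!r}: unknown profile {self.profile!r}")

    def alpha(self, t: np.ndarray) -> np.ndarray:
        """Transcription rate over latent time t in [0, 1]."""
        t = np.asarray(t, dtype=float)
        basal = BASAL_FRACTION * self.alpha_max
        span = self.alpha_max - basal
        if self.profile == "flat":
            return np.full_like(t, self.alpha_max)
        # monotone profiles are saturating sigmoids, so the trajectory ends
        # on a transcriptional plateau (an attractor for the velocity field)
        ramp = 1.0 / (1.0 + np.exp(-(t - self.ramp_center) / self.ramp_width))
        if self.profile == "monotone_up":
            return basal + span * ramp
        if self.profile == "monotone_down":
            return basal + span * (1.0 - ramp)
        # pulse: Gaussian bump in alpha over latent time
        return basal + span * np.exp(
            -0.5 * ((t - self.pulse_center) / self.pulse_width) ** 2
        )


@dataclass
class LatentTimeDistribution:
    """Two-component mixture of truncated normals on [0, 1]: a
    quiescent-centered mode and an activated-centered mode."""

    quiescent_loc: float = 0.15
    quiescent_scale: float = 0.05
    activated_loc: float = 0.75
    activated_scale: float = 0.18
    activated_fraction: float = 0.5


@dataclass
class SimPopulationConfig:
    """Population-level settings for expression simulation."""

    n_cells_per_group: int = 500
    age_rate_multiplier: dict = field(
        default_factory=lambda: {"young": 1.0, "aged": 0.5}
    )
    lrc_fraction: dict = field(default_factory=lambda: {"young": 0.35, "aged": 0.15})
    latent_time_distribution: LatentTimeDistribution = field(
        default_factory=LatentTimeDistribution
    )
    count_model: Literal["nb", "none"] = "nb"
    capture_efficiency_sd: float = 0.2  # lognormal sd of per-cell depth factor
    seed: int = 0

    def validate(self) -> None:
        if self.n_cells_per_group < 2:
            raise ValueError("n_cells_per_group must be >= 2")
        for age, f in self.lrc_fraction.items():
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"lrc_fraction[{age!r}] must lie in [0, 1]")
        for age, m in self.age_rate_multiplier.items():
            if m <= 0:
                raise ValueError(f"age_rate_multiplier[{age!r}] must be positive")


def _integrate_gene(
    gene: KineticGeneSpec, t_grid: np.ndarray, rate_scale: float = 1.0
):
    """Integrate the two-ODE kinetics along latent (trajectory) time.

    ``rate_scale`` r models a group progressing along the same latent
    trajectory at r times the reference speed: in trajectory
    coordinates the whole right-hand side is divided by r, which leaves
    steady states (and hence the manifold) untouched but scales the
    kinetic disequilibrium beta*u - gamma*s — the measurable velocity —
    by approximately r. Initial condition is the steady state under
    alpha(0), so flat-profile genes sit exactly at u* = alpha/beta,
    s* = alpha/gamma for all t.
    """
    a0 = float(gene.alpha(np.array([0.0]))[0])
    y0 = [a0 / gene.beta, a0 / gene.gamma]
    if gene.profile == "flat":
        u = np.full_like(t_grid, y0[0])
        s = np.full_like(t_grid, y0[1])
        return u, s

    def rhs(t, y):
        a = float(gene.alpha(np.array([t]))[0])
        return [
            (a - gene.beta * y[0]) / rate_scale,
            (gene.beta * y[0] - gene.gamma * y[1]) / rate_scale,
        ]

    sol = solve_ivp(
        rhs, (t_grid[0], t_grid[-1]), y0, t_eval=t_grid, rtol=1e-8, atol=1e-10
    )
    return sol.y[0], sol.y[1]


def _sample_counts(mean: np.ndarray, dispersion: float, model: str, rng) -> np.ndarray:
    mean = np.maximum(mean, 0.0)
    if model == "none":
        return np.rint(mean).astype(int)
    if dispersion == 0:
        return rng.poisson(mean)
    lam = rng.gamma(shape=1.0 / dispersion, scale=mean * dispersion)
    return rng.poisson(lam)


def simulate_expression(
    genes: list[KineticGeneSpec], pop: SimPopulationConfig
) -> tuple[LayeredCountMatrix, dict]:
    """Simulate a layered spliced/unspliced count matrix.

    Returns the matrix plus a ground-truth dict with a per-cell table
    (base and effective latent time, age, lrc, timepoint) and a per-gene
    table (true alpha_max, beta, gamma, profile).
    """
    if not genes:
        raise ValueError("at least one gene is required")
    for g in genes:
        g.validate()
    pop.validate()
    rng = np.random.default_rng(pop.seed)

    ages = list(pop.age_rate_multiplier)
    ltd = pop.latent_time_distribution
    cell_rows = []
    for age in ages:
        n = pop.n_cells_per_group
        r = pop.age_rate_multiplier[age]
        # slower groups have launched fewer cells into activation by the
        # fixed sampling time (mean latent time ordered by rate), while
        # the trajectory itself — and hence the manifold support — is
        # shared across groups; the rate's velocity-scale effect enters
        # through the kinetic integration below
        launch_scale = (1.0 + r) / 2.0
        is_activated = rng.random(n) < ltd.activated_fraction * launch_scale
        base = np.where(
            is_activated,
            rng.normal(ltd.activated_loc, ltd.activated_scale, n),
            rng.normal(ltd.quiescent_loc, ltd.quiescent_scale, n),
        )
        eff = np.clip(base, 0.0, 1.0)
        # deterministic LRC count: exactly round(frac * n) labels, positions shuffled
        n_lrc = int(round(pop.lrc_fraction.get(age, 0.0) * n))
        lrc = np.zeros(n, dtype=bool)
        lrc[rng.permutation(n)[:n_lrc]] = True
        for i in range(n):
            cell_rows.append(
                {
                    "age": age,
                    "lrc": "LRC" if lrc[i] else "nonLRC",
                    "timepoint": "activated" if is_activated[i] else "quiescent",
                    "latent_time_base": base[i],
                    "latent_time": eff[i],
                }
            )
    cells = pd.DataFrame(cell_rows)
    t_cells = cells["latent_time"].to_numpy()
    n_cells = len(cells)
    # per-cell capture efficiency scales both layers (library-size variation)
    if pop.capture_efficiency_sd > 0 and pop.count_model != "none":
        depth = np.exp(rng.normal(0.0, pop.capture_efficiency_sd, n_cells))
    else:
        depth = np.ones(n_cells)
    cells["capture_efficiency"] = depth

    t_grid = np.linspace(0.0, 1.0, 501)
    age_arr = cells["age"].to_numpy()
    spliced = np.zeros((len(genes), n_cells), dtype=int)
    unspliced = np.zeros((len(genes), n_cells), dtype=int)
    for gi, gene in enumerate(genes):
        u_mean = np.empty(n_cells)
        s_mean = np.empty(n_cells)
        for age in ages:
            sel = age_arr == age
            u_grid, s_grid = _integrate_gene(
                gene, t_grid, rate_scale=pop.age_rate_multiplier[age]
            )
            u_mean[sel] = np.interp(t_cells[sel], t_grid, u_grid)
            s_mean[sel] = np.interp(t_cells[sel], t_grid, s_grid)
        u_mean *= depth
        s_mean *= depth
        unspliced[gi] = _sample_counts(
            u_mean, gene.noise_dispersion, pop.count_model, rng
        )
        spliced[gi] = _sample_counts(s_mean, gene.noise_dispersion, pop.count_model, rng)

    meta = cells[["age", "lrc", "timepoint"]].copy()
    lcm = LayeredCountMatrix(spliced, unspliced, [g.name for g in genes], meta)
    truth = {
        "cells": cells,
        "genes": pd.DataFrame(
            {
                "gene_id": [g.name for g in genes],
                "profile": [g.profile for g in genes],
                "alpha_max": [g.alpha_max for g in genes],
                "beta": [g.beta for g in genes],
                "gamma": [g.gamma for g in genes],
                "gamma_over_beta": [g.gamma / g.beta for g in genes],
            }
        ),
    }
    return lcm, truth


def default_gene_panel(
    n_up: int = 30, n_down: int = 30, n_pulse: int = 20, n_flat: int = 20, seed: int = 0
) -> list[KineticGeneSpec]:
    """A mixed panel of activation-responsive and stable genes with
    moderate rate heterogeneity, for end-to-end pipeline runs.

    Splicing/degradation time constants are short relative to the unit
    latent-time span (beta = 12, gamma in [3, 10]); cells at the
    expression extremes then sit near kinetic steady state, which is the
    regime the steady-state velocity estimator assumes.
    """
    rng = np.random.default_rng(seed)
    genes: list[KineticGeneSpec] = []

    def draw(profile: str, i: int) -> KineticGeneSpec:
        # ramps/pulses complete — and their transcripts relax — well
        # before the activated mode, so the dense activated region is a
        # kinetic fixed point (an attractor of the velocity field);
        # pulse-gene kinetics are fast relative to the pulse width so
        # the spliced pool tracks the transient
        if profile == "pulse":
            gamma = float(rng.uniform(20.0, 28.0))
            beta = 40.0
        else:
            gamma = float(rng.uniform(12.0, 20.0))
            beta = 24.0
        return KineticGeneSpec(
            name=f"{profile}_{i}",
            profile=profile,  # type: ignore[arg-type]
            alpha_max=float(rng.uniform(10.0, 40.0)) * gamma,
            beta=beta,
            gamma=gamma,
            noise_dispersion=0.1,
            ramp_center=0.30,
            ramp_width=0.06,
            pulse_center=float(rng.uniform(0.30, 0.36)),
            pulse_width=float(rng.uniform(0.08, 0.12)),
        )

    for i in range(n_up):
        genes.append(draw("monotone_up", i))
    for i in range(n_down):
        genes.append(draw("monotone_down", i))
    for i in range(n_pulse):
        genes.append(draw("pulse", i))
    for i in range(n_flat):
        genes.append(draw("flat", i))
    return genes


# ---------------------------------------------------------------------------
# Motility tracks
# ---------------------------------------------------------------------------


@dataclass
class MotilityRegime:
    """Two-state switching parameters for one group.

    The immotile->motile probability per frame stays at ``p_on_start``
    until ``ramp_start_hour``, then ramps linearly to ``p_on_end`` at
    the end of the recording, emulating progressive activation;
    ``p_off`` is the motile->immotile probability. Motile step lengths
    are gamma-distributed with the given mean and sd (um/frame); sd 0
    means a fixed step.
    """

    p_on_start: float = 0.02
    p_on_end: float = 0.30
    p_off: float = 0.08
    speed_mean: float = 1.0
    speed_sd: float = 0.3
    ramp_start_hour: float = 10.0

    def validate(self, name: str) -> None:
        for label, p in (
            ("p_on_start", self.p_on_start),
            ("p_on_end", self.p_on_end),
            ("p_off", self.p_off),
        ):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"group {name!r}: {label} must lie in [0, 1]")
        if self.speed_mean < 0 or self.speed_sd < 0:
            raise ValueError(f"group {name!r}: speeds must be >= 0")


def default_track_groups() -> dict[str, MotilityRegime]:
    """Young cells ramp up their motile on-rate strongly with activation;
    aged cells ramp weakly and switch off more readily."""
    return {
        "young": MotilityRegime(p_on_start=0.01, p_on_end=0.40, p_off=0.10),
        "aged": MotilityRegime(p_on_start=0.01, p_on_end=0.08, p_off=0.14),
    }


@dataclass
class TrackSimConfig:
    n_cells_per_group: int = 300
    frame_interval: float = 6.5  # minutes
    duration_hours: float = 35.0
    groups: dict = field(default_factory=default_track_groups)
    initial_state: Literal["immotile", "motile"] = "immotile"
    seed: int = 0

    @property
    def n_frames(self) -> int:
        return int(self.duration_hours * 60.0 / self.frame_interval) + 1

    def validate(self) -> None:
        if self.duration_hours <= 0:
            raise ValueError("duration_hours must be positive")
        if self.n_frames < 2:
            raise ValueError("duration/frame_interval must yield >= 2 frames")
        for name, regime in self.groups.items():
            regime.validate(name)


def simulate_tracks(cfg: TrackSimConfig) -> tuple[TrackSet, np.ndarray]:
    """Simulate two-state switching random-walk tracks.

    Returns a TrackSet (with group labels in ``cell_metadata``) and the
    ground-truth motile-state sequence (n_cells x n_frames bool).
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    n_frames = cfg.n_frames
    groups = list(cfg.groups)
    n_total = cfg.n_cells_per_group * len(groups)

    positions = np.zeros((n_total, n_frames, 2))
    states = np.zeros((n_total, n_frames), dtype=bool)
    labels = []
    hours = np.arange(n_frames) * cfg.frame_interval / 60.0
    n = cfg.n_cells_per_group
    for gi, gname in enumerate(groups):
        regime = cfg.groups[gname]
        rows = slice(gi * n, (gi + 1) * n)
        ramp_span = max(cfg.duration_hours - regime.ramp_start_hour, 1e-9)
        frac = np.clip((hours - regime.ramp_start_hour) / ramp_span, 0.0, 1.0)
        p_on = regime.p_on_start + (regime.p_on_end - regime.p_on_start) * frac
        state = np.full(n, cfg.initial_state == "motile")
        states[rows, 0] = state
        steps = np.zeros((n, n_frames, 2))
        for f in range(1, n_frames):
            u = rng.random(n)
            state = np.where(state, u >= regime.p_off, u < p_on[f])
            states[rows, f] = state
            if regime.speed_sd == 0 or regime.speed_mean == 0:
                step_len = np.full(n, regime.speed_mean)
            else:
                step_len = rng.gamma(
                    (regime.speed_mean / regime.speed_sd) ** 2,
                    regime.speed_sd**2 / regime.speed_mean,
                    n,
                )
            theta = rng.uniform(0.0, 2.0 * np.pi, n)
            steps[:, f, 0] = state * step_len * np.cos(theta)
            steps[:, f, 1] = state * step_len * np.sin(theta)
        positions[rows] = np.cumsum(steps, axis=1)
        labels.extend([gname] * n)

    meta = pd.DataFrame({"group": labels})
    tracks = TrackSet(
        positions,
        cfg.frame_interval,
        window=(10.0, min(35.0, cfg.duration_hours)),
        cell_metadata=meta,
    )
    return tracks, states
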