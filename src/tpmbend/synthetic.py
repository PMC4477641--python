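"""Synthetic data with known ground truth.

Bead motion is emulated by a per-axis Ornstein-Uhlenbeck (OU) process: the
minimal stationary Gaussian process with exponentially decaying position
autocorrelation, i.e. exactly the correlation structure the blur correction
assumes.  Camera blur is reproduced by averaging exact-discretisation OU
substeps across each exposure window (midpoint rule).  Bend-series tables
are generated from the reduced kinked-WLC form plus Gaussian noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
from numba import njit

from .bendfit import BendSeries
from .exceptions import DomainError
from .params import PolymerParams
from .trajectory import Trajectory
from .wlc import cos_coefficient

__all__ = ["OUParams", "gen_trajectory", "gen_bend_series"]


@dataclass(frozen=True)
class OUParams:
    """Ground-truth parameters of the synthetic bead trajectory generator."""

    tau: float = 20.0                      # positional correlation time, ms
    stationary_std: float = 100.0          # per-axis stationary std, nm
    frame_rate: float = 25.0               # Hz
    exposure: float = 40.0                 # ms
    n_substeps: int = 20                   # exposure discretisation
    duration: float = 300.0                # s
    anchor: Tuple[float, float] = (0.0, 0.0)       # nm
    drift_velocity: Tuple[float, float] = (0.0, 0.0)  # nm/s
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tau <= 0:
            raise DomainError("tau must be > 0")
        if self.stationary_std <= 0:
            raise DomainError("stationary_std must be > 0")
        if self.n_substeps < 1:
            raise DomainError("n_substeps must be >= 1")
        if self.duration <= 0:
            raise DomainError("duration must be > 0")
        if self.frame_rate <= 0:
            raise DomainError("frame_rate must be > 0")
        if self.exposure < 0:
            raise DomainError("exposure must be >= 0")
        if self.exposure > 1000.0 / self.frame_rate + 1e-9:
            raise DomainError("exposure cannot exceed the frame interval")

    @property
    def n_frames(self) -> int:
        return int(round(self.duration * self.frame_rate))


@njit(cache=True)
def _ou_frames(n_frames, n_sub, rho_half, rho_sub, rho_tail, sigma, noise):
    """Exact OU transitions; returns per-frame exposure-averaged positions.

    noise has shape (n_frames, n_sub + 1): n_sub transitions to the midpoint
    samples plus one carrying the state to the next exposure start.
    """
    out = np.empty(n_frames)
    x = sigma * noise[0, n_sub]  # start in the stationary state
    s_half = sigma * math.sqrt(max(0.0, 1.0 - rho_half * rho_half))
    s_sub = sigma * math.sqrt(max(0.0, 1.0 - rho_sub * rho_sub))
    s_tail = sigma * math.sqrt(max(0.0, 1.0 - rho_tail * rho_tail))
    for f in range(n_frames):
        acc = 0.0
        # half substep to the first midpoint sample
        x = rho_half * x + s_half * noise[f, 0]
        acc += x
        for s in range(1, n_sub):
            x = rho_sub * x + s_sub * noise[f, s]
            acc += x
        out[f] = acc / n_sub
        # half substep to the exposure end plus the inter-frame gap
        x = rho_tail * x + s_tail * noise[f, n_sub]
    return out


def gen_trajectory(params: OUParams) -> Trajectory:
    """Generate one blurred, optionally drifting, OU bead trajectory.

    Each recorded frame is the midpoint-rule average of ``n_substeps``
    exact-discretisation OU samples across the exposure window; linear
    drift and the anchor offset are added afterwards.  Fully reproducible
    from ``params.seed``.
    """
    rng = np.random.default_rng(params.seed)
    n_frames = params.n_frames
    frame_ms = 1000.0 / params.frame_rate
    exposure = params.exposure if params.exposure > 0 else 1e-9
    dt_sub = exposure / params.n_substeps
    gap = frame_ms - exposure

    rho_half = math.exp(-0.5 * dt_sub / params.tau)
    rho_sub = math.exp(-dt_sub / params.tau)
    rho_tail = math.exp(-(0.5 * dt_sub + gap) / params.tau)

    axes = []
    for _ in range(2):
        noise = rng.standard_normal((n_frames, params.n_substeps + 1))
        axes.append(
            _ou_frames(n_frames, params.n_substeps, rho_half, rho_sub, rho_tail,
                       params.stationary_std, noise)
        )
    times = np.arange(n_frames) / params.frame_rate
    t_center = times + 0.5 * params.exposure / 1000.0
    x = axes[0] + params.anchor[0] + params.drift_velocity[0] * t_center
    y = axes[1] + params.anchor[1] + params.drift_velocity[1] * t_center
    return Trajectory(
        times=times, x=x, y=y,
        particle_id=f"synthetic-{params.seed}",
        frame_rate=params.frame_rate, exposure=params.exposure,
    )


def gen_bend_series(
    D: float,
    theta1: float,
    theta0: float,
    geometry: PolymerParams,
    n_values: Sequence[float] = range(8),
    noise_sd: float = 0.0,
    seed: Optional[int] = None,
) -> Tuple[BendSeries, dict]:
    """Generate a bend-series table from the reduced kinked-WLC form.

    ``R(n) = D * sqrt(1 + c * cos(n*theta1 - theta0)) + N(0, noise_sd)``
    with ``c`` computed from ``geometry``.  Returns the series and a
    ground-truth record.
    """
    if D <= 0:
        raise DomainError("D must be > 0")
    if noise_sd < 0:
        raise DomainError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    n = np.asarray(list(n_values), dtype=float)
    c = cos_coefficient(geometry)
    r = D * np.sqrt(1.0 + c * np.cos(np.radians(n * theta1 - theta0)))
    if noise_sd > 0:
        r = r + rng.normal(0.0, noise_sd, size=len(n))
    sigma = np.full(len(n), noise_sd) if noise_sd > 0 else None
    truth = {
        "amplitude_D_nm": float(D),
        "theta1_deg": float(theta1),
        "theta0_deg": float(theta0),
        "cos_coeff": float(c),
        "noise_sd_nm": float(noise_sd),
        "seed": seed,
    }
    return BendSeries(n_values=n, r_dna=r, geometry=geometry, sigma=sigma), truth
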