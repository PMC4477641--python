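"""Fit bend-series data (end-to-end distance vs number of phased inserts).

The model is the reduced kinked-WLC form

    R(n) = D * sqrt(1 + c * cos(n*theta1 - theta0))

where ``c`` is computed from the chain geometry (never hard-coded), ``D``
is a free amplitude scale, ``theta1`` the per-repeat bend angle and
``theta0`` an optional intrinsic global offset.  The cosine makes the
objective multimodal, so the fit is seeded from a dense grid of angle
starts and the global best is refined by nonlinear least squares.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import least_squares

from .exceptions import DomainError, SolverError
from .params import PolymerParams
from .wlc import cos_coefficient, invert_single_site

__all__ = ["BendSeries", "FitResult", "PerInsertResult", "fit_series", "per_insert_angles"]


@dataclass
class BendSeries:
    """(n, R_DNA) data for a series of constructs with n phased inserts."""

    n_values: np.ndarray
    r_dna: np.ndarray
    geometry: PolymerParams
    sigma: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.n_values = np.asarray(self.n_values, dtype=float)
        self.r_dna = np.asarray(self.r_dna, dtype=float)
        if self.sigma is not None:
            self.sigma = np.asarray(self.sigma, dtype=float)
            if self.sigma.shape != self.r_dna.shape:
                raise DomainError("sigma must match r_dna in length")
            if np.any(self.sigma < 0):
                raise DomainError("sigma must be >= 0")
        if self.n_values.shape != self.r_dna.shape:
            raise DomainError("n_values and r_dna must have equal length")
        if len(np.unique(self.n_values)) != len(self.n_values):
            raise DomainError("n_values must be distinct")
        if np.any(self.n_values < 0):
            raise DomainError("n_values must be >= 0")
        if np.any(self.r_dna <= 0):
            raise DomainError("r_dna must be > 0")


@dataclass
class FitResult:
    """Best-fit parameters of the reduced form and their 1-sigma errors."""

    amplitude_D: float
    theta1: float
    theta0: float = 0.0
    se_D: float = float("nan")
    se_theta1: float = float("nan")
    se_theta0: float = float("nan")
    residual_rms: float = 0.0
    converged: bool = True
    cos_coeff: float = float("nan")
    n_starts: int = 0

    def as_dict(self) -> dict:
        return {
            "amplitude_D_nm": self.amplitude_D,
            "theta1_deg": self.theta1,
            "theta0_deg": self.theta0,
            "se_D_nm": self.se_D,
            "se_theta1_deg": self.se_theta1,
            "se_theta0_deg": self.se_theta0,
            "residual_rms_nm": self.residual_rms,
            "converged": self.converged,
            "cos_coeff": self.cos_coeff,
        }


def _model(n: np.ndarray, c: float, d: float, t1_rad: float, t0_rad: float) -> np.ndarray:
    return d * np.sqrt(1.0 + c * np.cos(n * t1_rad - t0_rad))


def _best_d(n, r, w, c, t1_rad, t0_rad) -> float:
    # For fixed angles, D enters linearly: closed-form weighted LSQ solution.
    m = np.sqrt(1.0 + c * np.cos(n * t1_rad - t0_rad))
    num = np.sum(w * r * m)
    den = np.sum(w * m * m)
    return num / den if den > 0 else np.mean(r)


def fit_series(
    data: BendSeries,
    with_theta0: bool = False,
    weighted: bool = False,
    theta1_grid: Optional[Sequence[float]] = None,
    theta0_grid: Optional[Sequence[float]] = None,
) -> FitResult:
    """Least-squares fit of the reduced kinked-WLC form to a bend series.

    Parameters
    ----------
    data : BendSeries
        The (n, R) series and the chain geometry from which the cosine
        coefficient is computed.
    with_theta0 : bool
        Also fit the intrinsic global offset ``theta0`` (needs >= 4 points).
    weighted : bool
        Weight residuals by 1/sigma (requires ``data.sigma``).
    theta1_grid, theta0_grid : sequence of float, optional
        Multi-start grids in degrees; defaults are 0-60 deg in 1 deg steps
        for theta1 and -90..90 deg in 5 deg steps for theta0.

    Ties between equally good starts are broken by lowest residual, then
    smallest theta1.
    """
    n_min = 4 if with_theta0 else 3
    if len(data.n_values) < n_min:
        raise DomainError(f"need at least {n_min} points for this fit")
    if weighted:
        if data.sigma is None or np.any(data.sigma == 0):
            raise DomainError("weighted fit requires strictly positive sigma")
        w = 1.0 / data.sigma**2
    else:
        w = np.ones_like(data.r_dna)

    c = cos_coefficient(data.geometry)
    n = data.n_values
    r = data.r_dna
    sqw = np.sqrt(w)

    t1_starts = np.radians(theta1_grid if theta1_grid is not None else np.arange(0.0, 60.1, 1.0))
    if with_theta0:
        t0_starts = np.radians(theta0_grid if theta0_grid is not None else np.arange(-90.0, 90.1, 5.0))
    else:
        t0_starts = np.array([0.0])

    # Coarse grid scan with closed-form D, then refine the best starts.
    grid = [(t1, t0) for t1 in t1_starts for t0 in t0_starts]
    scores = []
    for t1, t0 in grid:
        d = _best_d(n, r, w, c, t1, t0)
        res = sqw * (_model(n, c, d, t1, t0) - r)
        scores.append(float(res @ res))
    order = np.argsort(scores)
    top = [grid[i] for i in order[: min(8, len(grid))]]

    def residuals(p):
        d, t1 = p[0], p[1]
        t0 = p[2] if with_theta0 else 0.0
        return sqw * (_model(n, c, d, t1, t0) - r)

    best = None
    for t1, t0 in top:
        x0 = [_best_d(n, r, w, c, t1, t0), t1] + ([t0] if with_theta0 else [])
        try:
            sol = least_squares(residuals, x0=x0, method="lm", max_nfev=5000)
        except Exception:
            continue
        if not sol.success:
            continue
        key = (round(float(sol.cost), 12), abs(float(sol.x[1])))
        if best is None or key < best[0]:
            best = (key, sol)
    if best is None:
        raise SolverError(
            "bend-series fit failed to converge from all starts; "
            f"best grid candidates (theta1, theta0 deg): "
            f"{[(math.degrees(a), math.degrees(b)) for a, b in top[:3]]}"
        )
    sol = best[1]

    d_hat = float(sol.x[0])
    t1_hat = float(sol.x[1])
    t0_hat = float(sol.x[2]) if with_theta0 else 0.0
    # canonicalise: theta1 >= 0 (cos is even in (n*t1 - t0) -> flip both signs)
    if t1_hat < 0:
        t1_hat, t0_hat = -t1_hat, -t0_hat
    t1_hat = math.fmod(t1_hat, 2 * math.pi)
    if t1_hat > math.pi:
        t1_hat = 2 * math.pi - t1_hat
        t0_hat = -t0_hat

    res = sol.fun
    dof = max(len(r) - len(sol.x), 1)
    s2 = float(res @ res) / dof
    try:
        cov = s2 * np.linalg.inv(sol.jac.T @ sol.jac)
        ses = np.sqrt(np.maximum(np.diag(cov), 0.0))
    except np.linalg.LinAlgError:
        ses = np.full(len(sol.x), float("nan"))

    unweighted = _model(n, c, d_hat, t1_hat, t0_hat) - r
    return FitResult(
        amplitude_D=d_hat,
        theta1=math.degrees(t1_hat),
        theta0=math.degrees(t0_hat),
        se_D=float(ses[0]),
        se_theta1=math.degrees(float(ses[1])),
        se_theta0=math.degrees(float(ses[2])) if with_theta0 else 0.0,
        residual_rms=float(np.sqrt(np.mean(unweighted**2))),
        converged=True,
        cos_coeff=c,
        n_starts=len(top),
    )


@dataclass
class PerInsertResult:
    """Per-construct bend angles divided by the repeat number."""

    n_values: np.ndarray
    angles: np.ndarray          # per-insert angle, degrees
    total_angles: np.ndarray    # total recovered angle, degrees
    clamped: np.ndarray
    mean: float = field(init=False)
    sd: float = field(init=False)

    def __post_init__(self) -> None:
        self.mean = float(np.mean(self.angles))
        self.sd = float(np.std(self.angles, ddof=1)) if len(self.angles) > 1 else 0.0


def per_insert_angles(data: BendSeries, reference_n: int = 0) -> PerInsertResult:
    """Single-site inversion applied per construct, normalised per insert.

    For each ``n > reference_n`` the bend angle is recovered from the pair
    (R(n), R(reference_n)) via :func:`tpmbend.wlc.invert_single_site` and
    divided by ``n``; the reference row itself is excluded.
    """
    mask = data.n_values == reference_n
    if not np.any(mask):
        raise DomainError(f"reference n={reference_n} not present in the series")
    r0 = float(data.r_dna[mask][0])

    ns, per, tot, clamped = [], [], [], []
    for n, r in zip(data.n_values, data.r_dna):
        if n <= reference_n:
            continue
        inv = invert_single_site(r, r0, data.geometry)
        ns.append(n)
        tot.append(inv.theta)
        per.append(inv.theta / n)
        clamped.append(inv.clamped)
    if not ns:
        raise DomainError("no rows with n > reference_n")
    return PerInsertResult(
        n_values=np.asarray(ns),
        angles=np.asarray(per),
        total_angles=np.asarray(tot),
        clamped=np.asarray(clamped),
    )
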