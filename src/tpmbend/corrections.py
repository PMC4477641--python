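"""Corrections turning raw tracked amplitudes into DNA end-to-end distances.

Three steps, applied in order where relevant:

1. blur correction — undoes the attenuation of the apparent excursion caused
   by the camera exposure averaging over the bead's correlated motion;
2. minimal particle correction — removes the bead's geometric contribution
   assuming bead and DNA orientations are statistically independent;
3. Segall correction — an alternative bead/wall correction obtained by
   solving a transcendental equation in the excursion number.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, List, Optional

import pandas as pd
from scipy.optimize import brentq
from scipy.special import erf

from .exceptions import BeadDominatesError, DomainError, SolverError

__all__ = [
    "TPMMeasurement",
    "blur_correct",
    "blur_factor",
    "minimal_correction",
    "segall_correction",
    "segall_forward",
    "correct_table",
]

DEFAULT_EXPOSURE_MS = 40.0
DEFAULT_BEAD_RADIUS_NM = 150.0


@dataclass
class TPMMeasurement:
    """One aggregated TPM measurement (one construct / condition).

    Either ``amplitude`` (already blur-corrected) or ``amplitude_raw``
    together with ``tau_parallel`` must be provided.
    """

    sample: str = ""
    amplitude_raw: Optional[float] = None   # R_exp,par,raw (nm)
    amplitude: Optional[float] = None       # R_exp,par, blur-corrected (nm)
    tau_parallel: Optional[float] = None    # positional correlation time (ms)
    exposure: float = DEFAULT_EXPOSURE_MS   # camera exposure (ms)
    bead_radius: float = DEFAULT_BEAD_RADIUS_NM  # nm
    n_trajectories: int = 0
    uncertainty: float = 0.0                # 1-sigma on amplitude (nm)
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("amplitude_raw", "amplitude", "tau_parallel"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise DomainError(f"{name} must be >= 0")
        if self.exposure < 0 or self.bead_radius < 0 or self.uncertainty < 0:
            raise DomainError("exposure, bead_radius and uncertainty must be >= 0")


def blur_factor(tau: float, exposure: float) -> float:
    """Attenuation bracket of exposure-averaged correlated motion.

    Returns ``2(tau/T) - 2(tau/T)^2 (1 - exp(-T/tau))`` with ``T`` the
    exposure; this is the ratio of blurred to true mean-square amplitude,
    in (0, 1], and tends to 1 as ``T/tau -> 0``.
    """
    if tau <= 0:
        raise DomainError("tau must be > 0")
    if exposure <= 0:
        raise DomainError("exposure must be > 0")
    r = tau / exposure
    return 2.0 * r + 2.0 * r * r * math.expm1(-1.0 / r)


def blur_correct(amplitude_raw: float, tau: float, exposure: float) -> float:
    """Undo camera-blur attenuation of a raw amplitude of motion.

    ``amplitude_raw`` (nm) is multiplied by ``bracket**-0.5`` where the
    bracket is :func:`blur_factor`; the result is always >= the input.
    """
    if amplitude_raw < 0:
        raise DomainError("amplitude_raw must be >= 0")
    return amplitude_raw / math.sqrt(blur_factor(tau, exposure))


def minimal_correction(amplitude: float, bead_radius: float) -> float:
    """Minimal bead correction: R_DNA = sqrt(1.5 * amplitude^2 - R_p^2).

    Assumes the bead and the DNA are statistically independent and ignores
    the wall.  Raises :class:`BeadDominatesError` when the bead term
    exhausts the signal.
    """
    if amplitude < 0 or bead_radius < 0:
        raise DomainError("amplitude and bead_radius must be >= 0")
    ms = 1.5 * amplitude * amplitude - bead_radius * bead_radius
    if ms <= 0:
        raise BeadDominatesError(
            f"bead dominates signal: 1.5*{amplitude}^2 <= {bead_radius}^2"
        )
    return math.sqrt(ms)


def _segall_rhs(n_r: float) -> float:
    """RHS of the Segall equation, 1 + 2 N_R / (sqrt(pi) * erf(N_R)).

    Smooth continuation 2 + N_R^2/3 + O(N_R^4) at small N_R.
    """
    if n_r < 1e-6:
        return 2.0 + n_r * n_r / 3.0
    return 1.0 + 2.0 * n_r / (math.sqrt(math.pi) * erf(n_r))


def segall_forward(r_dna: float, bead_radius: float) -> float:
    """Apparent in-plane amplitude implied by the Segall relation.

    Inverse-direction helper (used for testing and simulation checks):
    given ``R_DNA`` returns ``sqrt(<R_par^2>)`` such that
    ``1.5 <R_par^2> / <R_DNA^2> = RHS(N_R)``.
    """
    if r_dna <= 0 or bead_radius < 0:
        raise DomainError("r_dna must be > 0 and bead_radius >= 0")
    r2 = r_dna * r_dna
    n_r = math.sqrt(6.0) * bead_radius / r_dna
    return math.sqrt(r2 * _segall_rhs(n_r) / 1.5)


def segall_correction(amplitude: float, bead_radius: float) -> float:
    """Solve the Segall equation for the DNA end-to-end distance.

    Finds the positive root ``<R_DNA^2>`` of

        1.5 * amplitude^2 / <R_DNA^2> = 1 + 2 N_R / (sqrt(pi) erf(N_R)),
        N_R = sqrt(6) * R_p / sqrt(<R_DNA^2>)

    by bracketed root search to relative tolerance 1e-9 (Brent's method on
    a sign-changing bracket), returning ``sqrt(<R_DNA^2>)``.
    """
    if amplitude <= 0:
        raise DomainError("amplitude must be > 0")
    if bead_radius < 0:
        raise DomainError("bead_radius must be >= 0")

    target_lhs = 1.5 * amplitude * amplitude

    def f(r2: float) -> float:
        n_r = math.sqrt(6.0) * bead_radius / math.sqrt(r2)
        return target_lhs / r2 - _segall_rhs(n_r)

    lo = 1e-9
    hi = target_lhs  # f(hi) = 1 - RHS < 0 always (RHS >= 2)
    flo, fhi = f(lo), f(hi)
    if not (flo > 0 > fhi):
        raise SolverError(
            "no sign change when bracketing the Segall equation: "
            f"f({lo})={flo:.3g}, f({hi})={fhi:.3g} "
            f"(amplitude={amplitude}, bead_radius={bead_radius})"
        )
    r2 = brentq(f, lo, hi, rtol=1e-12, maxiter=200)
    return math.sqrt(r2)


def _corrector(method: str):
    if method == "minimal":
        return minimal_correction
    if method == "segall":
        return segall_correction
    raise DomainError(f"unknown correction method {method!r}; use 'minimal' or 'segall'")


def correct_table(rows: Iterable[TPMMeasurement], method: str = "minimal") -> pd.DataFrame:
    """Apply blur (when raw) and particle corrections to a batch of rows.

    Returns a DataFrame with columns ``sample, n_trajectories, amplitude_nm,
    uncertainty_nm, r_dna_nm, r_dna_sigma_nm, error``.  Per-row failures are
    recorded in ``error`` rather than aborting the batch; an empty input is
    an error.
    """
    rows = list(rows)
    if not rows:
        raise DomainError("correct_table requires at least one row")
    corrector = _corrector(method)

    out: List[dict] = []
    for row in rows:
        rec = {
            "sample": row.sample,
            "n_trajectories": row.n_trajectories,
            "amplitude_nm": float("nan"),
            "uncertainty_nm": row.uncertainty,
            "r_dna_nm": float("nan"),
            "r_dna_sigma_nm": float("nan"),
            "error": "",
        }
        try:
            if row.amplitude is not None:
                amp = float(row.amplitude)
            elif row.amplitude_raw is not None:
                if row.tau_parallel is None:
                    raise DomainError("raw amplitude given without tau_parallel")
                amp = blur_correct(row.amplitude_raw, row.tau_parallel, row.exposure)
            else:
                raise DomainError("row has neither amplitude nor amplitude_raw")
            rec["amplitude_nm"] = amp
            r_dna = corrector(amp, row.bead_radius)
            rec["r_dna_nm"] = r_dna
            # first-order (delta method) propagation of the amplitude uncertainty
            if row.uncertainty > 0:
                h = max(1e-6 * amp, 1e-9)
                deriv = (corrector(amp + h, row.bead_radius) - corrector(amp - h, row.bead_radius)) / (2 * h)
                rec["r_dna_sigma_nm"] = abs(deriv) * row.uncertainty
            else:
                rec["r_dna_sigma_nm"] = 0.0
        except Exception as exc:  # noqa: BLE001 - per-row errors are data, not bugs
            rec["error"] = f"{type(exc).__name__}: {exc}"
        out.append(rec)
    return pd.DataFrame(out)
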