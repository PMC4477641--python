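"""Closed-form worm-like-chain statistics for a tethered DNA with one bend.

The chain is a continuous WLC of contour length ``L`` and persistence length
``L_p`` carrying a fixed angular discontinuity (bend angle ``theta``) at
contour position ``l`` from the anchored end.  Tangent correlations decay as
``exp(-|s - s'| / L_p)`` and pick up a factor ``cos(theta)`` whenever the two
contour points straddle the bend locus.  Integrating twice gives

    <R^2>(theta) = 2 L_p^2 [L/L_p - 2 + e^(-l/L_p) + e^(-(L-l)/L_p)]
                 + cos(theta) * 2 L_p^2 [1 - e^(-(L-l)/L_p) - e^(-l/L_p) + e^(-L/L_p)]

which this module evaluates along with its reduced fitting forms, the
inverse map from a pair of end-to-end distances to the bend angle, and the
generalisation to a piecewise persistence length (a stiff insert).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence, Tuple

from scipy.optimize import brentq

from .exceptions import DomainError, UnattainableError
from .params import MsdResult, PolymerParams

__all__ = [
    "kinked_msd",
    "cos_coefficient",
    "invert_single_site",
    "InversionResult",
    "detection_floor",
    "het_msd",
    "piecewise_msd",
    "solve_insert_lp",
]


def _check_theta(theta: float) -> float:
    theta = float(theta)
    if not math.isfinite(theta) or not (0.0 <= theta <= 180.0):
        raise DomainError(f"theta must be a finite angle in [0, 180] degrees, got {theta!r}")
    return theta


def _brackets(params: PolymerParams) -> Tuple[float, float]:
    """Theta-independent and cos(theta) brackets of the kinked-WLC form, nm^2."""
    L = params.contour_length
    l = params.bend_position
    lp = params.persistence_length
    two_lp2 = 2.0 * lp * lp
    a = two_lp2 * (L / lp - 2.0 + math.exp(-l / lp) + math.exp(-(L - l) / lp))
    b = two_lp2 * (1.0 - math.exp(-(L - l) / lp) - math.exp(-l / lp) + math.exp(-L / lp))
    return a, b


def kinked_msd(params: PolymerParams, theta: float) -> MsdResult:
    """Mean-squared end-to-end distance of a WLC with a single fixed bend.

    Parameters
    ----------
    params : PolymerParams
        Chain geometry (nm internally).
    theta : float
        Bend angle in degrees, in [0, 180]; 0 means an unbent chain.

    Returns
    -------
    MsdResult
        ``mean_square`` in nm^2 and its square ``root`` in nm.  The result
        is strictly decreasing in ``theta``.
    """
    theta = _check_theta(theta)
    a, b = _brackets(params)
    ms = a + math.cos(math.radians(theta)) * b
    return MsdResult(ms)


def cos_coefficient(params: PolymerParams) -> float:
    """Coefficient ``c`` of the reduced form ``R(theta) = D * sqrt(1 + c*cos(theta))``.

    ``c`` is the ratio of the cos(theta) bracket to the theta-independent
    bracket of the kinked-WLC mean-square; ``0 < c <= 1`` for any valid
    geometry (the rigid mid-bend limit gives exactly 1).
    """
    a, b = _brackets(params)
    if a <= 0.0:
        raise DomainError("degenerate geometry: theta-independent bracket is not positive")
    c = b / a
    if not (0.0 < c <= 1.0 + 1e-12):
        raise DomainError(f"cos coefficient {c} outside (0, 1]; degenerate geometry")
    return min(c, 1.0)


@dataclass(frozen=True)
class InversionResult:
    """Bend angle recovered from a pair of end-to-end distances.

    ``clamped`` is True when the raw cosine fell outside [-1, 1] and was
    saturated before taking the arccos (end-to-end distances saturate at
    very high bend angles, so an out-of-range cosine reads as ~180 deg).
    """

    theta: float
    clamped: bool
    raw_cos: float

    def __float__(self) -> float:
        return self.theta


def _inversion_prefactor(params: PolymerParams) -> float:
    L = params.contour_length
    l = params.bend_position
    lp = params.persistence_length
    denom = 1.0 - math.exp(-(L - l) / lp) - math.exp(-l / lp) + math.exp(-L / lp)
    if denom <= 0.0:
        raise DomainError("degenerate geometry: cos bracket is not positive")
    return (math.exp(-L / lp) + L / lp - 1.0) / denom


def invert_single_site(
    r_bent: float, r_straight: float, params: PolymerParams
) -> InversionResult:
    """Recover the bend angle from end-to-end distances with and without the bend.

    Implements the closed-form inversion of the kinked-WLC mean-square:

        cos(theta) = 1 + P * (R_bent^2 - R_straight^2) / R_straight^2,
        P = (e^(-L/Lp) + L/Lp - 1) / (1 - e^(-(L-l)/Lp) - e^(-l/Lp) + e^(-L/Lp))

    The cosine is clamped into [-1, 1] before the arccos and the clamping is
    flagged on the result.
    """
    r_bent = float(r_bent)
    r_straight = float(r_straight)
    if not (math.isfinite(r_bent) and r_bent > 0):
        raise DomainError("r_bent must be a positive finite length")
    if not (math.isfinite(r_straight) and r_straight > 0):
        raise DomainError("r_straight must be a positive finite length")
    pref = _inversion_prefactor(params)
    rel = (r_bent * r_bent - r_straight * r_straight) / (r_straight * r_straight)
    raw_cos = 1.0 + pref * rel
    clamped = not (-1.0 <= raw_cos <= 1.0)
    cos_theta = min(1.0, max(-1.0, raw_cos))
    theta = math.degrees(math.acos(cos_theta))
    return InversionResult(theta=theta, clamped=clamped, raw_cos=raw_cos)


def detection_floor(rel_change: float, params: PolymerParams) -> float:
    """Smallest detectable single-site bend angle, degrees.

    ``rel_change`` is the smallest detectable relative decrease of the
    corrected end-to-end distance (e.g. 0.02 for a 2% resolution); the
    result does not depend on the absolute distance scale.
    """
    rel_change = float(rel_change)
    if not (0.0 <= rel_change < 1.0):
        raise DomainError("rel_change must satisfy 0 <= rel_change < 1")
    r0 = 100.0  # arbitrary scale; the inversion only sees the ratio
    return invert_single_site((1.0 - rel_change) * r0, r0, params).theta


# ---------------------------------------------------------------------------
# Heterogeneous (piecewise persistence length) chain
# ---------------------------------------------------------------------------

def piecewise_msd(segments: Sequence[Tuple[float, float]]) -> MsdResult:
    """Mean-squared end-to-end distance of a WLC with piecewise-constant L_p.

    ``segments`` is an ordered sequence of ``(length, persistence_length)``
    pairs in nm.  With ``G(u) = integral_0^u du'/L_p(u')`` the tangent
    correlation is ``exp(-(G(s') - G(s)))`` and

        <R^2> = 2 * integral_{0<=s<s'<=L} exp(-(G(s') - G(s))) ds ds'

    which factorises per segment pair into the closed form evaluated here.
    """
    segs = [(float(ln), float(lp)) for ln, lp in segments if float(ln) > 0.0]
    if not segs:
        raise DomainError("at least one segment of positive length is required")
    for ln, lp in segs:
        if not (math.isfinite(ln) and math.isfinite(lp)) or ln < 0 or lp <= 0:
            raise DomainError(f"invalid segment (length={ln}, lp={lp})")

    total = 0.0
    # within-segment contribution: uniform WLC of length ln,
    # 2*lp^2*(x - 1 + e^-x) with x = ln/lp; series guard for the stiff limit
    for ln, lp in segs:
        x = ln / lp
        if x < 1e-4:
            g = x * x / 2.0 - x**3 / 6.0 + x**4 / 24.0
        else:
            g = x - 1.0 + math.exp(-x)
        total += 2.0 * lp * lp * g
    # cross terms: I_i * exp(-sum of intervening G) * I_j with
    # I = lp * (1 - exp(-ln/lp)) for both the left and right factors
    factors = [-lp * math.expm1(-ln / lp) for ln, lp in segs]
    g = [ln / lp for ln, lp in segs]
    for i in range(len(segs)):
        mid = 0.0
        for j in range(i + 1, len(segs)):
            total += 2.0 * factors[i] * math.exp(-mid) * factors[j]
            mid += g[j]
    return MsdResult(total)


def het_msd(
    L: float,
    insert_start: float,
    insert_length: float,
    lp_flank: float,
    lp_insert: float,
) -> MsdResult:
    """<R^2> of a chain with a stiffer (or softer) insert of finite length.

    The chain [0, L] has persistence length ``lp_flank`` except on
    [insert_start, insert_start + insert_length] where it is ``lp_insert``.
    Reduces to the uniform WLC when ``lp_insert == lp_flank`` and increases
    monotonically with ``lp_insert``.
    """
    L = float(L)
    insert_start = float(insert_start)
    insert_length = float(insert_length)
    if L <= 0 or insert_start < 0 or insert_length < 0:
        raise DomainError("lengths must be non-negative and L > 0")
    if insert_start + insert_length > L + 1e-12:
        raise DomainError("insert must fit inside the chain")
    if lp_flank <= 0 or lp_insert <= 0:
        raise DomainError("persistence lengths must be > 0")
    segments = [
        (insert_start, lp_flank),
        (insert_length, lp_insert),
        (L - insert_start - insert_length, lp_flank),
    ]
    return piecewise_msd(segments)


def solve_insert_lp(
    delta_r: float,
    L: float,
    insert_start: float,
    insert_length: float,
    lp_flank: float,
) -> float:
    """Insert persistence length explaining an end-to-end distance increase.

    Finds ``lp_insert`` such that the root-mean-square end-to-end distance of
    the heterogeneous chain exceeds the uniform chain's by ``delta_r`` nm.
    The map is monotone, so a bracketed root search is used.

    Raises
    ------
    UnattainableError
        If ``delta_r`` exceeds the rigid-insert limit.
    """
    delta_r = float(delta_r)
    if delta_r < 0:
        raise DomainError("delta_r must be >= 0")
    if insert_length <= 0:
        raise DomainError("insert_length must be > 0 to solve for its rigidity")
    base = het_msd(L, insert_start, insert_length, lp_flank, lp_flank).root
    if delta_r == 0.0:
        return float(lp_flank)
    target = base + delta_r

    lp_rigid = 1e12  # effectively rigid insert
    limit = het_msd(L, insert_start, insert_length, lp_flank, lp_rigid).root
    if target > limit:
        raise UnattainableError(
            f"delta_r={delta_r} nm exceeds the rigid-insert limit "
            f"({limit - base:.3f} nm) for this geometry"
        )

    def f(lp_insert: float) -> float:
        return het_msd(L, insert_start, insert_length, lp_flank, lp_insert).root - target

    return float(brentq(f, lp_flank, lp_rigid, rtol=1e-12, maxiter=200))
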