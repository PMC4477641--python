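"""Equilibrium Monte Carlo of a wall-tethered semiflexible chain with a bead.

The DNA is a freely-rotating discrete chain of rigid bonds of length ``a``
anchored at the origin on a hard wall (z >= 0).  Bending energy, in k_B T
units, is ``kappa * (1 - cos(phi_i))`` at every interior joint; one joint
may instead carry a stiff harmonic well ``0.5 * k_bend * (phi - theta)^2``
imposing a fixed local bend angle theta.  A reporter sphere of radius R_p
rides rigidly on the last bond direction and must clear the wall
(z_bead >= R_p).

Sampling uses symmetric Metropolis moves: crankshaft rotations of interior
sub-chains about the chord joining two vertices, and pivot rotations of the
chain tail about a random axis (a pivot at the last vertex reorients the
final bond and therefore the bead).  Hard constraints are enforced by
rejection, so the move set satisfies detailed balance with respect to the
bending energy alone.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from numba import njit
from scipy.optimize import brentq

from .exceptions import DomainError
from .corrections import minimal_correction

__all__ = [
    "ChainParams",
    "ChainState",
    "SimResult",
    "stiffness_from_persistence",
    "persistence_from_stiffness",
    "discrete_wlc_msd",
    "build_chain",
    "run",
    "angle_sweep",
]

#: Default bond length: 10 bp at 0.34 nm/bp.
DEFAULT_SEGMENT_NM = 3.41

#: Strength of the harmonic well imposing the local bend, k_B T / rad^2.
DEFAULT_BEND_STIFFNESS = 50.0


@dataclass(frozen=True)
class ChainParams:
    """Configuration of the simulated tether."""

    n_segments: int = 58
    segment_length: float = DEFAULT_SEGMENT_NM
    persistence_length: Optional[float] = 51.0  # nm; None with kappa set directly
    kappa: Optional[float] = None               # bending stiffness, k_B T
    bend_vertex: int = 29
    bend_angle: float = 0.0                     # degrees
    bend_stiffness: float = DEFAULT_BEND_STIFFNESS
    bead_radius: float = 150.0
    wall: bool = True
    bead: bool = True
    bead_mount: str = "rigid"   # "rigid": along the last bond; "swivel": free orientation
    bead_wall: bool = True      # reject bead-wall overlap

    def __post_init__(self) -> None:
        if self.n_segments < 2:
            raise DomainError("n_segments must be >= 2")
        if self.segment_length <= 0:
            raise DomainError("segment_length must be > 0")
        if self.bend_angle < 0 or self.bend_angle > 180:
            raise DomainError("bend_angle must be in [0, 180] degrees")
        if self.bend_angle > 0 and not (0 < self.bend_vertex < self.n_segments):
            raise DomainError("bend_vertex must be an interior vertex when bend_angle > 0")
        if self.bead and self.bead_radius <= 0:
            raise DomainError("bead_radius must be > 0 when the bead is enabled")
        if self.bead_mount not in ("rigid", "swivel"):
            raise DomainError("bead_mount must be 'rigid' or 'swivel'")
        if self.kappa is None and (self.persistence_length is None or self.persistence_length <= 0):
            raise DomainError("either kappa or a positive persistence_length is required")

    @property
    def stiffness(self) -> float:
        if self.kappa is not None:
            return float(self.kappa)
        return stiffness_from_persistence(self.segment_length, self.persistence_length)

    @property
    def contour_length(self) -> float:
        return self.n_segments * self.segment_length


@dataclass
class ChainState:
    """Sampler state: vertex coordinates (anchor at origin) and bead centre."""

    vertex_positions: np.ndarray  # (n_segments + 1, 3), nm
    bead_center: np.ndarray       # (3,), nm


@dataclass
class SimResult:
    """Time-averaged in-plane amplitude of the bead centre."""

    r_parallel: float          # sqrt(<x^2 + y^2>), nm
    stderr: float              # batch-means standard error on r_parallel, nm
    n_samples: int
    acceptance_rate: float
    mean_square_3d: float      # <R^2> of the chain end (validation observable)
    stderr_3d: float


def stiffness_from_persistence(segment_length: float, lp: float) -> float:
    """Bond stiffness kappa (k_B T) giving tangent decay exp(-a/L_p) per joint.

    Uses <cos phi> = coth(kappa) - 1/kappa for the Boltzmann weight
    exp(kappa * cos phi) on the sphere.
    """
    if lp <= 0 or segment_length <= 0:
        raise DomainError("lengths must be > 0")
    target = math.exp(-segment_length / lp)

    def f(k: float) -> float:
        return 1.0 / math.tanh(k) - 1.0 / k - target

    return float(brentq(f, 1e-8, 1e6, rtol=1e-12))


def persistence_from_stiffness(segment_length: float, kappa: float) -> float:
    """Inverse of :func:`stiffness_from_persistence`."""
    if kappa <= 0:
        raise DomainError("kappa must be > 0")
    p = 1.0 / math.tanh(kappa) - 1.0 / kappa
    return -segment_length / math.log(p)


def discrete_wlc_msd(n_segments: int, segment_length: float, kappa: float) -> float:
    """Closed-form <R^2> of the free freely-rotating chain (no wall, no bead).

    With p = <cos phi> = coth(kappa) - 1/kappa,

        <R^2> = a^2 [ N (1+p)/(1-p) - 2 p (1 - p^N) / (1-p)^2 ].

    kappa = 0 gives the freely-jointed N a^2.
    """
    a2 = segment_length * segment_length
    if kappa == 0:
        return n_segments * a2
    p = 1.0 / math.tanh(kappa) - 1.0 / kappa
    n = n_segments
    return a2 * (n * (1 + p) / (1 - p) - 2 * p * (1 - p**n) / (1 - p) ** 2)


def build_chain(params: ChainParams, seed: Optional[int] = None) -> ChainState:
    """Deterministic feasible initial state.

    The chain rises along +z; when a bend is imposed, the single bond just
    after the bend vertex is tilted by theta in the xz-plane (all joints
    remain above the wall and the bead clears it for any theta in [0, 180]).
    """
    n = params.n_segments
    a = params.segment_length
    pos = np.zeros((n + 1, 3))
    direction = np.array([0.0, 0.0, 1.0])
    tilt = np.array([math.sin(math.radians(params.bend_angle)), 0.0,
                     math.cos(math.radians(params.bend_angle))])
    for i in range(n):
        d = tilt if (params.bend_angle > 0 and i == params.bend_vertex) else direction
        pos[i + 1] = pos[i] + a * d
    bead = _bead_center(pos, params.bead_radius if params.bead else 0.0, a)
    state = ChainState(vertex_positions=pos, bead_center=bead)
    _check_feasible(state, params)
    return state


def _bead_center(pos: np.ndarray, bead_radius: float, a: float) -> np.ndarray:
    u = (pos[-1] - pos[-2]) / a
    return pos[-1] + bead_radius * u


def _check_feasible(state: ChainState, params: ChainParams) -> None:
    if params.wall:
        if np.any(state.vertex_positions[:, 2] < -1e-9):
            raise DomainError("infeasible initial state: vertex below the wall")
        if params.bead and state.bead_center[2] < params.bead_radius - 1e-9:
            raise DomainError("infeasible initial state: bead overlaps the wall")


@njit(cache=True)
def _rotate_about(pos, origin, axis, ang, lo, hi):
    """Rodrigues rotation of pos[lo:hi] about (origin, unit axis) in place."""
    c = math.cos(ang)
    s = math.sin(ang)
    for k in range(lo, hi):
        px = pos[k, 0] - origin[0]
        py = pos[k, 1] - origin[1]
        pz = pos[k, 2] - origin[2]
        dot = axis[0] * px + axis[1] * py + axis[2] * pz
        cx = axis[1] * pz - axis[2] * py
        cy = axis[2] * px - axis[0] * pz
        cz = axis[0] * py - axis[1] * px
        pos[k, 0] = origin[0] + px * c + cx * s + axis[0] * dot * (1.0 - c)
        pos[k, 1] = origin[1] + py * c + cy * s + axis[1] * dot * (1.0 - c)
        pos[k, 2] = origin[2] + pz * c + cz * s + axis[2] * dot * (1.0 - c)


@njit(cache=True)
def _joint_energy(pos, i, kappa, bend_vertex, theta_rad, bend_k, a2):
    """Bending energy (k_B T) of joint i (1 <= i <= N-1)."""
    b1x = pos[i, 0] - pos[i - 1, 0]
    b1y = pos[i, 1] - pos[i - 1, 1]
    b1z = pos[i, 2] - pos[i - 1, 2]
    b2x = pos[i + 1, 0] - pos[i, 0]
    b2y = pos[i + 1, 1] - pos[i, 1]
    b2z = pos[i + 1, 2] - pos[i, 2]
    c = (b1x * b2x + b1y * b2y + b1z * b2z) / a2
    if c > 1.0:
        c = 1.0
    elif c < -1.0:
        c = -1.0
    if i == bend_vertex:
        phi = math.acos(c)
        d = phi - theta_rad
        return 0.5 * bend_k * d * d
    return kappa * (1.0 - c)


@njit(cache=True)
def _energy_of(pos, joints, n_joints, kappa, bend_vertex, theta_rad, bend_k, a2, n_vert):
    e = 0.0
    for t in range(n_joints):
        j = joints[t]
        if 1 <= j <= n_vert - 2:
            e += _joint_energy(pos, j, kappa, bend_vertex, theta_rad, bend_k, a2)
    return e


@njit(cache=True)
def _mc_kernel(pos, kappa, bend_vertex, theta_rad, bend_k, seg_len, bead_radius,
               use_wall, use_bead, swivel, bead_wall,
               n_sweeps, burn_in, seed, d_crank, d_pivot):
    np.random.seed(seed)
    n_vert = pos.shape[0]
    N = n_vert - 1
    a2 = seg_len * seg_len
    n_keep = n_sweeps - burn_in
    samp_par2 = np.empty(n_keep)
    samp_r2 = np.empty(n_keep)
    accepted = 0
    total = 0
    backup = np.empty((n_vert, 3))
    joints = np.empty(2, dtype=np.int64)
    axis = np.empty(3)
    # swivel-mount bead orientation (unit vector); starts pointing up
    bux, buy, buz = 0.0, 0.0, 1.0
    check_bead = use_bead and use_wall and bead_wall
    n_moves = N + 1 if (use_bead and swivel) else N

    for sweep in range(n_sweeps):
        for move in range(n_moves):
            total += 1
            if use_bead and swivel and move == n_moves - 1:
                # bead orientation resample: uniform on the sphere (symmetric)
                z = 2.0 * np.random.random() - 1.0
                phi_b = 2.0 * math.pi * np.random.random()
                rxy = math.sqrt(max(0.0, 1.0 - z * z))
                nx = rxy * math.cos(phi_b)
                ny = rxy * math.sin(phi_b)
                if (not check_bead) or (pos[N, 2] + bead_radius * z >= bead_radius):
                    bux, buy, buz = nx, ny, z
                    accepted += 1
                continue
            crank = np.random.random() < 0.5 and N >= 2
            if crank:
                i = np.random.randint(0, N - 1)          # 0 .. N-2
                j = i + 2 + np.random.randint(0, N - i - 1)  # i+2 .. N
                ax = pos[j, 0] - pos[i, 0]
                ay = pos[j, 1] - pos[i, 1]
                az = pos[j, 2] - pos[i, 2]
                norm = math.sqrt(ax * ax + ay * ay + az * az)
                if norm < 1e-12:
                    continue
                axis[0] = ax / norm
                axis[1] = ay / norm
                axis[2] = az / norm
                ang = (2.0 * np.random.random() - 1.0) * d_crank
                lo, hi = i + 1, j
                joints[0] = i
                joints[1] = j
                n_joints = 2
                origin = pos[i]
            else:
                i = np.random.randint(0, N)              # 0 .. N-1 pivot vertex
                # uniform axis on the sphere
                z = 2.0 * np.random.random() - 1.0
                phi = 2.0 * math.pi * np.random.random()
                rxy = math.sqrt(max(0.0, 1.0 - z * z))
                axis[0] = rxy * math.cos(phi)
                axis[1] = rxy * math.sin(phi)
                axis[2] = z
                ang = (2.0 * np.random.random() - 1.0) * d_pivot
                lo, hi = i + 1, n_vert
                joints[0] = i
                joints[1] = -1
                n_joints = 1
                origin = pos[i]

            e_old = _energy_of(pos, joints, n_joints, kappa, bend_vertex,
                               theta_rad, bend_k, a2, n_vert)
            for k in range(lo, hi):
                backup[k, 0] = pos[k, 0]
                backup[k, 1] = pos[k, 1]
                backup[k, 2] = pos[k, 2]
            _rotate_about(pos, origin, axis, ang, lo, hi)

            ok = True
            if use_wall:
                for k in range(lo, hi):
                    if pos[k, 2] < 0.0:
                        ok = False
                        break
            if ok and check_bead and hi >= n_vert - 1:
                if swivel:
                    uz = buz
                else:
                    uz = (pos[N, 2] - pos[N - 1, 2]) / seg_len
                bz = pos[N, 2] + bead_radius * uz
                if bz < bead_radius:
                    ok = False
            if ok:
                e_new = _energy_of(pos, joints, n_joints, kappa, bend_vertex,
                                   theta_rad, bend_k, a2, n_vert)
                de = e_new - e_old
                if de <= 0.0 or np.random.random() < math.exp(-de):
                    accepted += 1
                else:
                    ok = False
            if not ok:
                for k in range(lo, hi):
                    pos[k, 0] = backup[k, 0]
                    pos[k, 1] = backup[k, 1]
                    pos[k, 2] = backup[k, 2]

        if sweep >= burn_in:
            if use_bead:
                if swivel:
                    ux, uy = bux, buy
                else:
                    ux = (pos[N, 0] - pos[N - 1, 0]) / seg_len
                    uy = (pos[N, 1] - pos[N - 1, 1]) / seg_len
                bx = pos[N, 0] + bead_radius * ux
                by = pos[N, 1] + bead_radius * uy
            else:
                bx = pos[N, 0]
                by = pos[N, 1]
            samp_par2[sweep - burn_in] = bx * bx + by * by
            samp_r2[sweep - burn_in] = (pos[N, 0] * pos[N, 0]
                                        + pos[N, 1] * pos[N, 1]
                                        + pos[N, 2] * pos[N, 2])
    return samp_par2, samp_r2, accepted, total


def _batch_stats(samples: np.ndarray, n_batches: int = 20):
    n = len(samples)
    n_batches = min(n_batches, n)
    usable = (n // n_batches) * n_batches
    means = samples[:usable].reshape(n_batches, -1).mean(axis=1)
    mean = float(means.mean())
    se = float(means.std(ddof=1) / math.sqrt(n_batches)) if n_batches > 1 else 0.0
    return mean, se


def run(
    params: ChainParams,
    n_sweeps: int = 20000,
    burn_in: Optional[int] = None,
    seed: int = 0,
    d_crank: float = 1.2,
    d_pivot: float = 0.6,
) -> SimResult:
    """Sample the tether and return the time-averaged in-plane amplitude.

    One sweep attempts ``n_segments`` elementary moves; the bead-centre
    in-plane square displacement is recorded once per sweep after burn-in
    (default: 20% of ``n_sweeps``).  Standard errors come from 20 batch
    means, so they account for sweep-to-sweep correlation.
    """
    if burn_in is None:
        burn_in = n_sweeps // 5
    if not (0 <= burn_in < n_sweeps):
        raise DomainError("need n_sweeps > burn_in >= 0")
    state = build_chain(params)
    theta_rad = math.radians(params.bend_angle)
    kappa = params.stiffness if (params.kappa is None or params.kappa > 0) else 0.0
    bend_vertex = params.bend_vertex if params.bend_angle > 0 else -1
    samp_par2, samp_r2, accepted, total = _mc_kernel(
        state.vertex_positions, kappa, bend_vertex, theta_rad,
        params.bend_stiffness, params.segment_length,
        params.bead_radius if params.bead else 0.0,
        params.wall, params.bead,
        params.bead_mount == "swivel", params.bead_wall,
        int(n_sweeps), int(burn_in), int(seed), float(d_crank), float(d_pivot),
    )
    acc = accepted / total if total else 0.0
    if acc < 0.01:
        warnings.warn(
            f"Metropolis acceptance rate {acc:.3%} < 1% "
            f"(n_segments={params.n_segments}, bend_angle={params.bend_angle}); "
            "consider smaller move amplitudes",
            RuntimeWarning,
            stacklevel=2,
        )
    m_par2, se_par2 = _batch_stats(samp_par2)
    m_r2, se_r2 = _batch_stats(samp_r2)
    r_par = math.sqrt(max(m_par2, 0.0))
    se_r = se_par2 / (2.0 * r_par) if r_par > 0 else se_par2
    return SimResult(
        r_parallel=r_par,
        stderr=se_r,
        n_samples=len(samp_par2),
        acceptance_rate=acc,
        mean_square_3d=m_r2,
        stderr_3d=se_r2,
    )


def angle_sweep(
    params: ChainParams,
    theta_list: Sequence[float],
    n_sweeps: int = 20000,
    burn_in: Optional[int] = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Run the simulator over a list of imposed bend angles.

    Returns a DataFrame with columns ``theta_deg, r_parallel_nm, stderr_nm,
    acceptance``; run ``k`` uses ``seed + k`` so the sweep is reproducible
    but decorrelated across angles.
    """
    rows = []
    for k, theta in enumerate(theta_list):
        if not (0.0 <= theta <= 180.0):
            raise DomainError("theta values must be in [0, 180] degrees")
        p = replace(params, bend_angle=float(theta),
                    bend_vertex=params.bend_vertex or params.n_segments // 2)
        res = run(p, n_sweeps=n_sweeps, burn_in=burn_in, seed=seed + k)
        rows.append({
            "theta_deg": float(theta),
            "r_parallel_nm": res.r_parallel,
            "stderr_nm": res.stderr,
            "acceptance": res.acceptance_rate,
        })
    return pd.DataFrame(rows)


def corrected_sweep(sweep: pd.DataFrame, bead_radius: float) -> pd.DataFrame:
    """Minimal-correct a simulated angle sweep (adds r_dna_nm, r_dna_stderr_nm)."""
    out = sweep.copy()
    r_dna = []
    r_se = []
    for r, se in zip(out["r_parallel_nm"], out["stderr_nm"]):
        rd = minimal_correction(r, bead_radius)
        r_dna.append(rd)
        r_se.append(1.5 * r / rd * se)  # delta method through sqrt(1.5 r^2 - Rp^2)
    out["r_dna_nm"] = r_dna
    out["r_dna_stderr_nm"] = r_se
    return out
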