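"""Parameter containers shared across the package.

All lengths are stored internally in nanometres.  Inputs expressed in base
pairs are converted with the helical rise (0.34 nm/bp by default).  Angles
are degrees at every public interface.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import yaml

from .exceptions import DomainError

#: Default helical rise, nm per base pair.
DEFAULT_RISE_NM_PER_BP = 0.34

#: Default DNA persistence length, base pairs (51 nm at 0.34 nm/bp).
DEFAULT_LP_BP = 150.0


def _require_finite(name: str, value: float) -> float:
    value = float(value)
    if not math.isfinite(value):
        raise DomainError(f"{name} must be finite, got {value!r}")
    return value


@dataclass(frozen=True)
class PolymerParams:
    """Geometry of a tethered DNA with a single bend locus.

    Parameters
    ----------
    contour_length : float
        Total contour length in nm.
    bend_position : float
        Distance of the bend locus from the anchored end, nm;
        must lie strictly inside the chain.
    persistence_length : float
        Worm-like-chain persistence length, nm.
    rise_per_bp : float
        Helical rise used for bp -> nm conversions, nm/bp.
    """

    contour_length: float
    bend_position: float
    persistence_length: float
    rise_per_bp: float = DEFAULT_RISE_NM_PER_BP

    def __post_init__(self) -> None:
        for name in ("contour_length", "bend_position", "persistence_length", "rise_per_bp"):
            _require_finite(name, getattr(self, name))
        if self.contour_length <= 0:
            raise DomainError("contour_length must be > 0")
        if not (0 < self.bend_position < self.contour_length):
            raise DomainError(
                "bend_position must lie strictly inside the chain: "
                f"0 < {self.bend_position} < {self.contour_length} required"
            )
        if self.persistence_length <= 0:
            raise DomainError("persistence_length must be > 0")
        if self.rise_per_bp <= 0:
            raise DomainError("rise_per_bp must be > 0")

    @classmethod
    def from_bp(
        cls,
        contour_length_bp: float,
        bend_position_bp: float,
        persistence_length_bp: float = DEFAULT_LP_BP,
        rise_per_bp: float = DEFAULT_RISE_NM_PER_BP,
    ) -> "PolymerParams":
        """Build from lengths expressed in base pairs."""
        return cls(
            contour_length=contour_length_bp * rise_per_bp,
            bend_position=bend_position_bp * rise_per_bp,
            persistence_length=persistence_length_bp * rise_per_bp,
            rise_per_bp=rise_per_bp,
        )

    @classmethod
    def from_config(cls, config: dict) -> "PolymerParams":
        """Build from a flat config mapping.

        Recognised keys: ``contour_length_bp``, ``bend_position_bp``,
        ``persistence_length_bp``, ``rise_nm_per_bp`` (bp variants) or the
        same with ``_nm`` suffixes for direct nm values.
        """
        rise = float(config.get("rise_nm_per_bp", DEFAULT_RISE_NM_PER_BP))
        if "contour_length_bp" in config:
            return cls.from_bp(
                float(config["contour_length_bp"]),
                float(config["bend_position_bp"]),
                float(config.get("persistence_length_bp", DEFAULT_LP_BP)),
                rise_per_bp=rise,
            )
        return cls(
            contour_length=float(config["contour_length_nm"]),
            bend_position=float(config["bend_position_nm"]),
            persistence_length=float(config.get("persistence_length_nm", DEFAULT_LP_BP * rise)),
            rise_per_bp=rise,
        )

    def with_bend_position(self, bend_position_nm: float) -> "PolymerParams":
        return replace(self, bend_position=bend_position_nm)


@dataclass(frozen=True)
class BendModel:
    """Bend-angle parameters of the reduced fitting forms.

    theta is the total local bend; theta1 the per-repeat angle; theta0 an
    intrinsic global offset; n_repeats the number of phased repeats and
    amplitude_D the amplitude scale of the reduced form, nm.
    """

    theta: float = 0.0
    theta1: float = 0.0
    theta0: float = 0.0
    n_repeats: int = 0
    amplitude_D: Optional[float] = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.theta <= 180.0):
            raise DomainError("theta must be in [0, 180] degrees")
        if self.n_repeats < 0:
            raise DomainError("n_repeats must be >= 0")
        if self.amplitude_D is not None and self.amplitude_D <= 0:
            raise DomainError("amplitude_D must be > 0 when set")


@dataclass(frozen=True)
class MsdResult:
    """Mean-squared end-to-end distance and its square root (both >= 0)."""

    mean_square: float
    root: float = field(default=float("nan"))

    def __post_init__(self) -> None:
        if self.mean_square < 0:
            raise DomainError("mean_square must be >= 0")
        if math.isnan(self.root):
            object.__setattr__(self, "root", math.sqrt(self.mean_square))

    def __iter__(self):
        return iter((self.mean_square, self.root))


def load_config(path) -> dict:
    """Load a flat key-value config file (YAML syntax)."""
    with open(path, "r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise DomainError(f"config file {path} must contain a flat mapping")
    return data
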