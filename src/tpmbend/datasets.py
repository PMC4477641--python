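"""Packaged reference data.

The shipped table aggregates published blur-corrected amplitudes of motion
for a series of 575 bp constructs carrying 0-7 phased bent inserts near the
chain centre (plus one out-of-phase control), measured with a 150 nm bead.
"""

from __future__ import annotations

from importlib import resources
from typing import List

import pandas as pd

from .corrections import TPMMeasurement
from .params import PolymerParams

__all__ = [
    "load_bend_series_table",
    "bend_series_measurements",
    "DEFAULT_GEOMETRY",
    "IHF_GEOMETRY",
]

#: Geometry of the packaged construct series: 575 bp chain, bend locus at
#: 318 bp from the anchored end, persistence length 150 bp.
DEFAULT_GEOMETRY = PolymerParams.from_bp(575, 318, 150)

#: Geometry of the published single-site protein-bend example: 1943 bp
#: chain, binding site 301 bp from one end.
IHF_GEOMETRY = PolymerParams.from_bp(1943, 301, 150)


def load_bend_series_table() -> pd.DataFrame:
    """Load the packaged amplitude-of-motion table as a DataFrame."""
    with resources.files("tpmbend.data").joinpath("bend_series_575bp.csv").open("r") as fh:
        return pd.read_csv(fh)


def bend_series_measurements(bead_radius: float = 150.0) -> List[TPMMeasurement]:
    """The packaged table as a list of :class:`TPMMeasurement` rows."""
    df = load_bend_series_table()
    return [
        TPMMeasurement(
            sample=str(r.sample),
            amplitude=float(r.amplitude_nm),
            uncertainty=float(r.uncertainty_nm),
            n_trajectories=int(r.n_trajectories),
            bead_radius=bead_radius,
            extra={"n_repeats": int(r.n_repeats), "phasing": str(r.phasing)},
        )
        for r in df.itertuples()
    ]
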