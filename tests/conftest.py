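import numpy as np
import pytest

from tpmbend.params import PolymerParams


@pytest.fixture(scope="session")
def geometry_318():
    """575 bp chain, bend at 318 bp, Lp = 150 bp (the construct geometry)."""
    return PolymerParams.from_bp(575, 318, 150)


@pytest.fixture(scope="session")
def geometry_mid():
    """575 bp chain, bend exactly at mid-chain."""
    return PolymerParams.from_bp(575, 287.5, 150)


@pytest.fixture(scope="session")
def table_series():
    """The packaged in-phase bend series (n, R_DNA printed to 0.1 nm)."""
    n = np.array([0, 1, 2, 3, 4, 6, 7], dtype=float)
    r = np.array([105.4, 104.1, 105.4, 105.2, 98.5, 95.5, 84.1])
    sigma = np.array([0.2, 0.2, 0.2, 0.2, 0.2, 0.4, 0.4])
    return n, r, sigma


def quad_msd_oracle(L, l, lp, theta_deg, lp_insert=None, insert=None):
    """Adaptive double-quadrature of the tangent-correlation integral.

    Independent oracle: <R^2> = 2 * int_0^L ds int_s^L ds' K(s, s') with
    K = exp(-(G(s') - G(s))) and a cos(theta) factor when the pair straddles
    the bend locus.  ``insert=(start, length)`` switches to a piecewise
    persistence-length chain with ``lp_insert`` inside the insert.
    """
    from scipy.integrate import dblquad

    if insert is None:
        # split the domain at the bend locus so each integrand is smooth
        decay = lambda sp, s: np.exp(-(sp - s) / lp)  # noqa: E731
        below, _ = dblquad(decay, 0, l, lambda s: s, lambda s: l,
                           epsabs=1e-10, epsrel=1e-10)
        above, _ = dblquad(decay, l, L, lambda s: s, lambda s: L,
                           epsabs=1e-10, epsrel=1e-10)
        straddle, _ = dblquad(decay, 0, l, lambda s: l, lambda s: L,
                              epsabs=1e-10, epsrel=1e-10)
        return 2.0 * (below + above + np.cos(np.radians(theta_deg)) * straddle)
    else:
        a, ln = insert
        b = a + ln

        def G(u):
            if u <= a:
                return u / lp
            if u <= b:
                return a / lp + (u - a) / lp_insert
            return a / lp + ln / lp_insert + (u - b) / lp

        def kernel(sp, s):
            return np.exp(-(G(sp) - G(s)))

    val, _ = dblquad(kernel, 0, L, lambda s: s, lambda s: L,
                     epsabs=1e-9, epsrel=1e-9)
    return 2.0 * val
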