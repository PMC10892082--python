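"""Closed-form angle and inverse-radius distributions for fixed-bond walks.

For a two-step random walk in d dimensions with fixed bond length b, the
bond-bending angle theta is distributed as

    p(theta) ∝ sin^(d-2)(theta),        theta in (0, 180) deg,

because the second step lands uniformly on a (d-1)-sphere around the middle
point.  The circle through the three points has radius R = b/(2 cos(theta/2)),
so the change of variables X = 1/R gives the inverse-radius density

    P(X) ∝ (Xb)^(d-2) [1 - (Xb/2)^2]^((d-3)/2),     X in (0, 2/b).

Integrating, the cumulative distribution behaves as X^(d-1) for Xb << 1; in
three dimensions the CDF is exactly (Xb/2)^2 on the whole support.  These
closed forms serve as oracles for the Monte Carlo samplers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import quad
from scipy.special import gamma


@dataclass(frozen=True)
class WalkSpec:
    """A fixed-bond random walk: spatial dimension d >= 2, bond length b (A), steps."""

    d: int
    b: float = 3.81
    n_steps: int = 2

    def __post_init__(self) -> None:
        if self.d < 2:
            raise ValueError("dimension must be >= 2")
        if self.b <= 0:
            raise ValueError("bond length must be positive")
        if self.n_steps < 2:
            raise ValueError("need at least 2 steps (3 points)")

    @property
    def n_points(self) -> int:
        return self.n_steps + 1


def _sin_power_norm(d: int) -> float:
    # integral of sin^(d-2) over (0, pi): sqrt(pi) Gamma((d-1)/2) / Gamma(d/2)
    return float(np.sqrt(np.pi) * gamma((d - 1) / 2.0) / gamma(d / 2.0))


def p_theta(theta, d: int):
    """Normalized bond-angle density of a two-step d-dimensional walk.

    ``theta`` in degrees in (0, 180); the density is per degree, so it
    integrates to 1 over (0, 180).  d = 2 is uniform; d = 3 is sin(theta)
    (in radians) rescaled.
    """
    if d < 2:
        raise ValueError("dimension must be >= 2")
    theta = np.asarray(theta, dtype=np.float64)
    if np.any(theta <= 0) or np.any(theta >= 180):
        raise ValueError("theta must lie in (0, 180) degrees")
    t = np.radians(theta)
    dens_rad = np.sin(t) ** (d - 2) / _sin_power_norm(d)
    dens = dens_rad * np.pi / 180.0  # per degree
    return dens if dens.ndim else float(dens)


def pdf_inverse_radius(X, spec: WalkSpec):
    """Normalized density of X = 1/R for two-step walk triplets, on (0, 2/b)."""
    X = np.asarray(X, dtype=np.float64)
    b, d = spec.b, spec.d
    if np.any(X <= 0) or np.any(X >= 2.0 / b):
        raise ValueError("X must lie strictly inside (0, 2/b)")

    def unnorm(x):
        xb = x * b
        return xb ** (d - 2) * (1.0 - (xb / 2.0) ** 2) ** ((d - 3) / 2.0)

    norm, _ = quad(unnorm, 0.0, 2.0 / b, epsabs=1e-10, epsrel=1e-10)
    dens = unnorm(X) / norm
    return dens if dens.ndim else float(dens)


def cdf_inverse_radius(X, spec: WalkSpec):
    """CDF of X = 1/R for two-step walk triplets, by quadrature of the density."""
    Xarr = np.atleast_1d(np.asarray(X, dtype=np.float64))
    out = np.empty_like(Xarr)
    for k, x in enumerate(Xarr):
        if x <= 0:
            out[k] = 0.0
        elif x >= 2.0 / spec.b:
            out[k] = 1.0
        else:
            val, _ = quad(lambda t: pdf_inverse_radius(t, spec), 1e-12, x, epsabs=1e-10, limit=200)
            out[k] = val
    return out if np.ndim(X) else float(out[0])


def cdf_inverse_radius_closed_form(X, b: float):
    """d = 3 special case: CDF of X = 1/R is exactly (Xb/2)^2 on [0, 2/b]."""
    X = np.asarray(X, dtype=np.float64)
    if np.any(X < 0) or np.any(X > 2.0 / b + 1e-12):
        raise ValueError("X must lie in [0, 2/b]")
    c = (X * b / 2.0) ** 2
    return c if c.ndim else float(c)


def cdf_exponent(d: int) -> int:
    """Leading small-X power of the inverse-radius CDF: d - 1 (2 in 3D)."""
    if d < 2:
        raise ValueError("dimension must be >= 2")
    return d - 1
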