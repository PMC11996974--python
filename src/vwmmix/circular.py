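"""Circular-statistics primitives.

Angles live in radians, wrapped to the half-open interval (-pi, pi].
The von Mises distribution is the response kernel of all mixture models
in this package; ``kappa`` is its concentration, with ``kappa = 0``
giving the circular uniform density 1/(2*pi).
"""

from __future__ import annotations

import numpy as np
from scipy import optimize, special

__all__ = [
    "wrap_angle",
    "deg2rad",
    "rad2deg",
    "vonmises_logpdf",
    "vonmises_pdf",
    "vonmises_sample",
    "k2sd",
    "sd2k",
    "log_bessel_i0",
    "bessel_ratio",
]

TWO_PI = 2.0 * np.pi


def wrap_angle(x):
    """Wrap angles (radians) to the half-open interval (-pi, pi].

    Idempotent: wrapping an already-wrapped angle is a no-op.

    Raises
    ------
    ValueError
        If any input is non-finite.
    """
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("wrap_angle requires finite input")
    wrapped = np.mod(x, TWO_PI)  # [0, 2*pi)
    wrapped = np.where(wrapped > np.pi, wrapped - TWO_PI, wrapped)
    # map the seam -pi (from inputs exactly congruent to pi) onto +pi
    wrapped = np.where(wrapped == -np.pi, np.pi, wrapped)
    if wrapped.ndim == 0:
        return float(wrapped)
    return wrapped


def deg2rad(x):
    """Convert degrees to radians (x * pi / 180)."""
    return np.multiply(x, np.pi / 180.0)


def rad2deg(x):
    """Convert radians to degrees (x / pi * 180); inverse of :func:`deg2rad`."""
    return np.multiply(x, 180.0 / np.pi)


def log_bessel_i0(kappa):
    """log I0(kappa), stable for large kappa via the scaled Bessel i0e."""
    kappa = np.asarray(kappa, dtype=float)
    return np.log(special.i0e(kappa)) + kappa


def bessel_ratio(kappa):
    """A(kappa) = I1(kappa) / I0(kappa), the mean resultant length."""
    kappa = np.asarray(kappa, dtype=float)
    with np.errstate(invalid="ignore"):
        ratio = special.i1e(kappa) / special.i0e(kappa)
    # i1e/i0e -> 0/0 for kappa = inf; the limit of the ratio is 1
    return np.where(np.isfinite(kappa), ratio, 1.0)


def vonmises_logpdf(x, mu, kappa):
    """Log-density of the von Mises distribution on the circle.

    ``log[ exp(kappa * cos(x - mu)) / (2*pi*I0(kappa)) ]``. With
    ``kappa = 0`` this is the circular uniform, ``-log(2*pi)``.

    Raises
    ------
    ValueError
        If any ``kappa`` is negative.
    """
    x = np.asarray(x, dtype=float)
    kappa = np.asarray(kappa, dtype=float)
    if np.any(kappa < 0):
        raise ValueError("kappa must be nonnegative")
    out = kappa * np.cos(x - mu) - np.log(TWO_PI) - log_bessel_i0(kappa)
    if out.ndim == 0:
        return float(out)
    return out


def vonmises_pdf(x, mu, kappa):
    return np.exp(vonmises_logpdf(x, mu, kappa))


def vonmises_sample(mu, kappa, n, seed=None, rng=None):
    """Draw ``n`` von Mises variates, wrapped to (-pi, pi].

    Identical ``(mu, kappa, n, seed)`` produce identical arrays.
    """
    if kappa < 0:
        raise ValueError("kappa must be nonnegative")
    if n < 1:
        raise ValueError("n must be >= 1")
    if rng is None:
        rng = np.random.default_rng(seed)
    draws = rng.vonmises(mu, kappa, size=int(n))
    return wrap_angle(draws)


def k2sd(kappa):
    """Circular standard deviation (radians) of a von Mises with concentration kappa.

    sd = sqrt(-2 * ln(R)) with R = I1(kappa)/I0(kappa); strictly decreasing
    in kappa, with kappa -> inf giving sd -> 0 and kappa -> 0 giving sd -> inf.
    """
    kappa = np.asarray(kappa, dtype=float)
    if np.any(kappa < 0):
        raise ValueError("kappa must be nonnegative")
    with np.errstate(divide="ignore"):
        log_r = np.log(special.i1e(kappa)) - np.log(special.i0e(kappa))
    sd = np.sqrt(-2.0 * log_r)
    if sd.ndim == 0:
        return float(sd)
    return sd


def sd2k(sd):
    """Numerically invert :func:`k2sd`: concentration for a given circular SD."""
    sd_arr = np.atleast_1d(np.asarray(sd, dtype=float))
    if np.any(sd_arr <= 0):
        raise ValueError("sd must be > 0")

    def solve(target):
        f = lambda log_k: k2sd(np.exp(log_k)) - target
        lo, hi = -20.0, 20.0
        # k2sd decreasing => f decreasing in log_k; expand bracket if needed
        while f(lo) < 0 and lo > -100:
            lo -= 20.0
        while f(hi) > 0 and hi < 100:
            hi += 20.0
        return float(np.exp(optimize.brentq(f, lo, hi, xtol=1e-14)))

    out = np.array([solve(t) for t in sd_arr])
    if np.isscalar(sd) or np.ndim(sd) == 0:
        return float(out[0])
    return out
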