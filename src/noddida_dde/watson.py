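"""Watson orientation-distribution mathematics.

The Watson distribution is the antipodally symmetric density on the unit
sphere

    P(u | mu, kappa)  ∝  exp(kappa (u . mu)^2),

with main direction ``mu`` and concentration ``kappa >= 0``.  ``kappa = 0``
is the uniform (isotropic) distribution; ``kappa -> inf`` collapses onto
``+/- mu``.  Everything downstream (signal convolution, cumulant tensors,
degeneracy analysis) is driven by its low-order moments, all of which reduce
to the Dawson function F of sqrt(kappa):

* ``c2 = <(u.mu)^2>``   mean squared cosine, the standard dispersion summary
* ``c4 = <(u.mu)^4>``
* ``p2, p4``            mean Legendre moments <P2>, <P4> (the non-zero
                        spherical-harmonic coefficients of the ODF)
* ``h2(xi), h4(xi)``    moments of the squared/quartic projection onto an
                        arbitrary axis at relative projection ``xi``

The normalization is expressed through ``M(kappa) = int_0^1 exp(kappa t^2) dt
= e^kappa F(sqrt kappa)/sqrt(kappa)`` and is evaluated in the overflow-safe
scaled form ``M e^-kappa``.  Near ``kappa = 0`` the closed forms have a
removable 0/0 singularity; a truncated Taylor series of the moment integrals
is used instead (the two branches agree to ~1e-14 at the switch point).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq
from scipy.special import dawsn

__all__ = [
    "WatsonODF",
    "watson_pdf",
    "c2_of_kappa",
    "c4_of_kappa",
    "kappa_of_c2",
    "p2",
    "p4",
    "h2",
    "h4",
]

# below this kappa the Dawson closed forms lose digits to cancellation;
# the series for the moment integrals is exact to machine precision there
_SERIES_KAPPA = 0.05
_SERIES_TERMS = 14


def _legendre_p2(x):
    return 0.5 * (3.0 * np.asarray(x, float) ** 2 - 1.0)


def _legendre_p4(x):
    x2 = np.asarray(x, float) ** 2
    return 0.125 * (35.0 * x2 * x2 - 30.0 * x2 + 3.0)


def _moment_series(kappa: np.ndarray, order: int) -> np.ndarray:
    """Taylor series of I_2m(kappa) = int_0^1 t^(2m) e^(kappa t^2) dt."""
    out = np.zeros_like(kappa)
    term = np.ones_like(kappa)  # kappa^n / n!
    for n in range(_SERIES_TERMS):
        out = out + term / (2 * n + 2 * order + 1)
        term = term * kappa / (n + 1)
    return out


def _c2_c4(kappa):
    """Vectorized (c2, c4) = (<t^2>, <t^4>) of the Watson distribution."""
    k = np.atleast_1d(np.asarray(kappa, dtype=float))
    if np.any(k < 0):
        raise ValueError("kappa must be non-negative")
    c2 = np.empty_like(k)
    c4 = np.empty_like(k)

    small = k < _SERIES_KAPPA
    if np.any(small):
        ks = k[small]
        i0 = _moment_series(ks, 0)
        c2[small] = _moment_series(ks, 1) / i0
        c4[small] = _moment_series(ks, 2) / i0
    big = ~small
    if np.any(big):
        kb = k[big]
        sk = np.sqrt(kb)
        # e^kappa / M(kappa) = sqrt(kappa)/F(sqrt(kappa))
        ratio = sk / dawsn(sk)
        c2b = (ratio - 1.0) / (2.0 * kb)
        c2[big] = c2b
        c4[big] = (ratio - 3.0 * c2b) / (2.0 * kb)
    return c2, c4


def c2_of_kappa(kappa):
    """Mean squared cosine ``c2 = <(u.mu)^2>`` of the Watson distribution.

    Strictly increasing from 1/3 (kappa = 0, isotropic) towards 1
    (parallel fibers); the closed form is
    ``c2 = 1/(2 sqrt(kappa) F(sqrt kappa)) - 1/(2 kappa)``
    with F the Dawson function.
    """
    c2, _ = _c2_c4(kappa)
    return c2 if np.ndim(kappa) else float(c2[0])


def c4_of_kappa(kappa):
    """Fourth projection moment ``<(u.mu)^4>``."""
    _, c4 = _c2_c4(kappa)
    return c4 if np.ndim(kappa) else float(c4[0])


def kappa_of_c2(c2: float) -> float:
    """Numerical inverse of :func:`c2_of_kappa` on c2 in (1/3, 1)."""
    c2 = float(c2)
    if not (1.0 / 3.0 < c2 < 1.0):
        raise ValueError(f"c2 must lie in (1/3, 1), got {c2}")
    lo, hi = 1e-12, 10.0
    while c2_of_kappa(hi) < c2:
        hi *= 10.0
        if hi > 1e12:  # pragma: no cover - c2 < 1 always brackets earlier
            break
    return brentq(lambda k: c2_of_kappa(k) - c2, lo, hi, xtol=1e-14, rtol=8.9e-16)


def p2(kappa):
    """Second Legendre moment <P2(u.mu)> — the l=2 SH coefficient of the ODF."""
    c2, _ = _c2_c4(kappa)
    out = np.clip(0.5 * (3.0 * c2 - 1.0), 0.0, 1.0)
    return out if np.ndim(kappa) else float(out[0])


def p4(kappa):
    """Fourth Legendre moment <P4(u.mu)> — the l=4 SH coefficient of the ODF."""
    c2, c4 = _c2_c4(kappa)
    out = np.clip(0.125 * (35.0 * c4 - 30.0 * c2 + 3.0), 0.0, 1.0)
    return out if np.ndim(kappa) else float(out[0])


def h2(xi, kappa):
    """Projection moment ``h2(xi, kappa) = 1/3 + 2/3 p2 P2(xi)``.

    Equals ``<(u.n)^2>`` over the Watson ODF for an axis ``n`` with
    ``xi = n.mu``; in particular ``h2(1, kappa) = c2(kappa)`` and
    ``h2(1) + 2 h2(0) = 1``.
    """
    xi_a = np.asarray(xi, dtype=float)
    if np.any(np.abs(xi_a) > 1.0 + 1e-12):
        raise ValueError("xi must lie in [-1, 1]")
    out = 1.0 / 3.0 + (2.0 / 3.0) * p2(kappa) * _legendre_p2(xi_a)
    return out if (np.ndim(xi) or np.ndim(kappa)) else float(out)


def h4(xi, kappa):
    """Projection moment ``h4 = 1/5 + 4/7 p2 P2(xi) + 8/35 p4 P4(xi)``.

    Equals ``<(u.n)^4>`` over the Watson ODF at projection ``xi = n.mu``.
    """
    xi_a = np.asarray(xi, dtype=float)
    if np.any(np.abs(xi_a) > 1.0 + 1e-12):
        raise ValueError("xi must lie in [-1, 1]")
    out = (
        0.2
        + (4.0 / 7.0) * p2(kappa) * _legendre_p2(xi_a)
        + (8.0 / 35.0) * p4(kappa) * _legendre_p4(xi_a)
    )
    return out if (np.ndim(xi) or np.ndim(kappa)) else float(out)


def _unit(v: np.ndarray, tol: float = 1e-12, what: str = "vector") -> np.ndarray:
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v)
    if abs(n - 1.0) > tol:
        raise ValueError(f"{what} must be a unit vector (|v| = {n!r})")
    return v


@dataclass(frozen=True)
class WatsonODF:
    """Watson distribution with main direction ``mu`` and concentration ``kappa``."""

    mu: np.ndarray
    kappa: float

    def __post_init__(self):
        object.__setattr__(self, "mu", _unit(self.mu, what="mu"))
        if self.kappa < 0:
            raise ValueError("kappa must be non-negative")

    @property
    def c2(self) -> float:
        return c2_of_kappa(self.kappa) if self.kappa > 0 else 1.0 / 3.0

    def log_norm_scale(self) -> float:
        """log of M(kappa) e^-kappa = log int_0^1 exp(kappa (t^2 - 1)) dt."""
        k = self.kappa
        if k < _SERIES_KAPPA:
            return math.log(float(_moment_series(np.array([k]), 0)[0])) - k
        sk = math.sqrt(k)
        return math.log(dawsn(sk) / sk)


def watson_pdf(u, odf: WatsonODF):
    """Watson density (per steradian) at unit vector(s) ``u``.

    Evaluated as ``exp(kappa ((u.mu)^2 - 1)) / (4 pi M(kappa) e^-kappa)``
    which never overflows, for any kappa.
    """
    u = np.asarray(u, dtype=float)
    norms = np.linalg.norm(u, axis=-1)
    if np.any(np.abs(norms - 1.0) > 1e-10):
        raise ValueError("u must be unit vector(s)")
    t2 = (u @ odf.mu) ** 2
    log_scale = odf.log_norm_scale()
    out = np.exp(odf.kappa * (t2 - 1.0) - log_scale) / (4.0 * np.pi)
    return out if u.ndim > 1 else float(out)
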