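"""Seawater optical parameterization.

Pure-seawater constants, the power-law (Junge-type) particle size
distribution, the Fournier--Forand scattering phase function of a power-law
particle ensemble, its backscatter fraction, and the molecular
(Brillouin-channel) phase function.

The particulate phase function is controlled by a single parameter, the PSD
slope ``xi``: the relative refractive index of the particle ensemble is tied
to the slope by the empirical relation ``m = 1.01 + 0.1542 (xi - 3)``, and
the Fournier--Forand closed form then gives the angular distribution and the
backscatter fraction ``BF = b_bp / b_p``.  Smaller slopes (relatively more
large particles, turbid coastal water) give more forward-peaked scattering
and a smaller backscatter fraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "PureWaterOptics",
    "PowerLawPSD",
    "FournierForandPhase",
    "MolecularPhase",
    "relative_refractive_index",
    "backscatter_fraction",
    "xi_from_backscatter_fraction",
    "fournier_forand_phase",
    "fournier_forand_cumulative",
    "sample_scattering_angle",
    "XI_MIN",
    "XI_MAX",
]

# Valid PSD-slope domain: the closed form degenerates at xi = 3 (v = 0).
XI_MIN = 3.0
XI_MAX = 5.0


@dataclass(frozen=True)
class PureWaterOptics:
    """Pure-seawater absorption, scattering and backscattering at 532 nm.

    Defaults are the adopted pure-seawater values at 532 nm:
    a_w = 0.042, b_w = 0.0022, b_bw = 0.0011 m^-1.  Temperature and
    salinity dependence is deliberately omitted.
    """

    a_w: float = 0.042
    b_w: float = 0.0022
    b_bw: float = 0.0011
    wavelength: float = 532.0

    def __post_init__(self) -> None:
        if self.a_w < 0 or self.b_w < 0 or self.b_bw < 0:
            raise ValueError("pure-water coefficients must be non-negative")
        if self.b_bw > self.b_w:
            raise ValueError("b_bw cannot exceed b_w")


@dataclass(frozen=True)
class PowerLawPSD:
    """Power-law (Junge) particle size distribution N(D) = N0 (D/D0)^-xi.

    N0 is the number concentration (m^-3 um^-1) at the reference diameter
    D0 (um); xi is the dimensionless slope.
    """

    N0: float
    D0: float
    xi: float

    def __post_init__(self) -> None:
        if self.N0 <= 0 or self.D0 <= 0:
            raise ValueError("N0 and D0 must be positive")
        if not (XI_MIN < self.xi <= XI_MAX):
            raise ValueError(f"xi must lie in ({XI_MIN}, {XI_MAX}]")

    def number_density(self, D):
        """Number concentration at diameter D (um), m^-3 um^-1."""
        D = np.asarray(D, dtype=float)
        if np.any(D <= 0):
            raise ValueError("diameter must be positive")
        return self.N0 * (D / self.D0) ** (-self.xi)


def psd_number_density(psd: PowerLawPSD, D):
    """Functional alias for :meth:`PowerLawPSD.number_density`."""
    return psd.number_density(D)


def relative_refractive_index(xi) -> np.ndarray | float:
    """Relative refractive index of the particle ensemble, m(xi).

    m = 1.01 + 0.1542 (xi - 3), valid for PSD slopes in (3, 5].
    """
    xi = np.asarray(xi, dtype=float)
    if np.any(xi <= XI_MIN) or np.any(xi > XI_MAX):
        raise ValueError(f"xi must lie in ({XI_MIN}, {XI_MAX}]")
    m = 1.01 + 0.1542 * (xi - 3.0)
    return float(m) if m.ndim == 0 else m


def _delta(xi, theta):
    """Fournier-Forand auxiliary delta(theta) = 4 sin^2(theta/2) / (3 (m-1)^2).

    The closed forms have a removable singularity at delta = 1; values are
    nudged off it so table builds never hit the 0/0 point.
    """
    m = 1.01 + 0.1542 * (np.asarray(xi, dtype=float) - 3.0)
    d = 4.0 * np.sin(np.asarray(theta, dtype=float) / 2.0) ** 2 / (3.0 * (m - 1.0) ** 2)
    return np.where(np.abs(d - 1.0) < 1e-9, 1.0 + 2e-9, d)


def fournier_forand_phase(xi, theta):
    """Fournier--Forand phase function p(theta), sr^-1.

    Closed form for homogeneous spheres with a power-law size distribution
    of slope ``xi`` and refractive index ``m(xi)``; normalized so that
    ``int p(theta) dOmega = 1`` over the sphere.  Singular (and undefined)
    at theta = 0.
    """
    xi = np.asarray(xi, dtype=float)
    theta = np.asarray(theta, dtype=float)
    if np.any(xi <= XI_MIN) or np.any(xi > XI_MAX):
        raise ValueError(f"xi must lie in ({XI_MIN}, {XI_MAX}]")
    if np.any(theta <= 0) or np.any(theta > np.pi):
        raise ValueError("theta must lie in (0, pi]")
    v = (3.0 - xi) / 2.0
    d = _delta(xi, theta)
    d180 = _delta(xi, np.pi)
    s2 = np.sin(theta / 2.0) ** 2
    dv = d**v
    term1 = (v * (1.0 - d) - (1.0 - dv) + (d * (1.0 - dv) - v * (1.0 - d)) / s2) / (
        4.0 * np.pi * (1.0 - d) ** 2 * dv
    )
    term2 = (
        (1.0 - d180**v)
        / (16.0 * np.pi * (d180 - 1.0) * d180**v)
        * (3.0 * np.cos(theta) ** 2 - 1.0)
    )
    out = term1 + term2
    return float(out) if out.ndim == 0 else out


def fournier_forand_cumulative(xi, theta):
    """Fraction of scattering into angles <= theta (closed form).

    F(theta) = int_0^theta p(t) 2 pi sin t dt; F(pi) = 1.
    """
    xi = np.asarray(xi, dtype=float)
    theta = np.asarray(theta, dtype=float)
    if np.any(xi <= XI_MIN) or np.any(xi > XI_MAX):
        raise ValueError(f"xi must lie in ({XI_MIN}, {XI_MAX}]")
    if np.any(theta < 0) or np.any(theta > np.pi):
        raise ValueError("theta must lie in [0, pi]")
    v = (3.0 - xi) / 2.0
    d = _delta(xi, theta)
    d180 = _delta(xi, np.pi)
    s2 = np.sin(theta / 2.0) ** 2
    with np.errstate(divide="ignore", invalid="ignore"):
        dv = d**v
        first = ((1.0 - d * dv) - (1.0 - dv) * s2) / ((1.0 - d) * dv)
    # theta -> 0 limit is 0 (d -> 0, d^v -> inf for v < 0)
    first = np.where(d == 0.0, 0.0, first)
    second = (
        (1.0 - d180**v)
        / (8.0 * (d180 - 1.0) * d180**v)
        * np.cos(theta)
        * np.sin(theta) ** 2
    )
    out = first + second
    out = np.clip(out, 0.0, 1.0)
    return float(out) if out.ndim == 0 else out


def backscatter_fraction(xi):
    """Particulate backscatter fraction BF(xi) = b_bp / b_p.

    Evaluated as 1 - F(pi/2) with the Fournier--Forand cumulative
    distribution; uses delta90 = delta(90 deg) and v = (3 - xi)/2.
    Strictly increasing on (3, 5]: steeper slopes (smaller particles)
    backscatter relatively more.
    """
    xi_arr = np.asarray(xi, dtype=float)
    if np.any(xi_arr <= XI_MIN) or np.any(xi_arr > XI_MAX):
        raise ValueError(f"xi must lie in ({XI_MIN}, {XI_MAX}]")
    v = (3.0 - xi_arr) / 2.0
    d90 = _delta(xi_arr, np.pi / 2.0)
    bf = 1.0 - (1.0 - d90 ** (v + 1.0) - 0.5 * (1.0 - d90**v)) / ((1.0 - d90) * d90**v)
    return float(bf) if bf.ndim == 0 else bf


def xi_from_backscatter_fraction(bf: float, lo: float = 3.0005, hi: float = XI_MAX) -> float:
    """Invert BF(xi) on (3, 5] by root bracketing."""
    bf_lo, bf_hi = backscatter_fraction(lo), backscatter_fraction(hi)
    if not (bf_lo <= bf <= bf_hi):
        raise ValueError(
            f"backscatter fraction {bf:.3g} outside invertible range "
            f"[{bf_lo:.3g}, {bf_hi:.3g}]"
        )
    return brentq(lambda x: backscatter_fraction(x) - bf, lo, hi, xtol=1e-12)


# angular grid shared by the sampling tables: uniform in log(theta)
_N_THETA = 2048
_THETA_MIN = 1e-6


def _log_theta_grid(n: int = _N_THETA) -> np.ndarray:
    return np.exp(np.linspace(np.log(_THETA_MIN), np.log(np.pi), n))


@dataclass
class FournierForandPhase:
    """Fournier--Forand phase function bound to one PSD slope.

    Carries the derived quantities (refractive index ``m``, exponent
    ``v = (3 - xi)/2``, ``delta90`` and the backscatter fraction) and a
    tabulated inverse CDF for drawing scattering angles.
    """

    xi: float
    m: float = field(init=False)
    v: float = field(init=False)
    delta90: float = field(init=False)
    bf: float = field(init=False)
    _theta: np.ndarray = field(init=False, repr=False)
    _cdf: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.m = relative_refractive_index(self.xi)
        self.v = (3.0 - self.xi) / 2.0
        self.delta90 = float(_delta(self.xi, np.pi / 2.0))
        self.bf = backscatter_fraction(self.xi)
        self._theta = _log_theta_grid()
        self._cdf = fournier_forand_cumulative(self.xi, self._theta)

    @property
    def backscatter_fraction(self) -> float:
        return self.bf

    def __call__(self, theta):
        return fournier_forand_phase(self.xi, theta)

    def cumulative(self, theta):
        return fournier_forand_cumulative(self.xi, theta)

    def ppf(self, u):
        """Quantile function of the scattering angle (tabulated inverse CDF)."""
        u = np.asarray(u, dtype=float)
        return np.interp(u, self._cdf, self._theta)


@dataclass
class MolecularPhase:
    """Rayleigh-like molecular phase function p(theta) ~ 1 + f cos^2(theta).

    ``f`` is the depolarization-adjusted anisotropy factor (f = 1 is pure
    Rayleigh; default 0.835).  Normalized over the sphere; symmetric about
    90 degrees.
    """

    f: float = 0.835

    def __call__(self, theta):
        theta = np.asarray(theta, dtype=float)
        out = (1.0 + self.f * np.cos(theta) ** 2) / (4.0 * np.pi * (1.0 + self.f / 3.0))
        return float(out) if out.ndim == 0 else out

    @property
    def p180(self) -> float:
        """Phase density at 180 degrees, sr^-1."""
        return float(self(np.pi))

    def cumulative(self, theta):
        """Closed-form CDF of the scattering angle."""
        theta = np.asarray(theta, dtype=float)
        c = np.cos(theta)
        out = ((1.0 - c) + self.f * (1.0 - c**3) / 3.0) / (2.0 * (1.0 + self.f / 3.0))
        return float(out) if out.ndim == 0 else out

    def ppf(self, u):
        u = np.asarray(u, dtype=float)
        grid = np.linspace(0.0, np.pi, _N_THETA)
        return np.interp(u, self.cumulative(grid), grid)


def sample_scattering_angle(phase, n: int, rng) -> np.ndarray:
    """Draw ``n`` scattering angles distributed as p(theta) sin(theta).

    ``phase`` is a :class:`FournierForandPhase` or :class:`MolecularPhase`;
    ``rng`` must be a seeded :class:`numpy.random.Generator` (an explicit
    generator is required so every draw is reproducible).
    """
    if not isinstance(rng, np.random.Generator):
        raise TypeError("rng must be a seeded numpy.random.Generator")
    return phase.ppf(rng.random(n))
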