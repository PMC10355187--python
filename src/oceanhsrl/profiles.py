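"""Depth-gridded inherent optical property (IOP) profiles.

The state vector of the retrieval: absorption ``a``, total scattering
``b`` and PSD slope ``xi`` on a uniform depth grid (bin centers, positive
down, meters).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .optics import XI_MAX, XI_MIN, PureWaterOptics, backscatter_fraction

__all__ = ["IOPProfile"]

# physical retrieval bounds (absorption / scattering ceilings in m^-1)
A_MAX = 2.0
B_MAX = 5.0


@dataclass
class IOPProfile:
    """Vertical profiles of (a, b, xi) on a uniform bin-center depth grid.

    Invariants: a >= a_w, b >= b_w, 3 < xi <= 5, equal-length arrays,
    strictly increasing depths starting at >= 0.
    """

    depths: np.ndarray
    a: np.ndarray
    b: np.ndarray
    xi: np.ndarray
    water: PureWaterOptics = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.water is None:
            self.water = PureWaterOptics()
        self.depths = np.asarray(self.depths, dtype=float)
        self.a = np.asarray(self.a, dtype=float)
        self.b = np.asarray(self.b, dtype=float)
        self.xi = np.asarray(self.xi, dtype=float)
        n = self.depths.size
        if not (self.a.size == self.b.size == self.xi.size == n):
            raise ValueError("depths, a, b, xi must have equal length")
        if n == 0:
            raise ValueError("profile must contain at least one bin")
        if np.any(np.diff(self.depths) <= 0) or self.depths[0] < 0:
            raise ValueError("depths must be strictly increasing and >= 0")
        if np.any(self.a < self.water.a_w - 1e-12):
            raise ValueError("absorption below the pure-water floor a_w")
        if np.any(self.b < self.water.b_w - 1e-12):
            raise ValueError("scattering below the pure-water floor b_w")
        if np.any(self.xi <= XI_MIN) or np.any(self.xi > XI_MAX):
            raise ValueError(f"xi must lie in ({XI_MIN}, {XI_MAX}]")

    def __len__(self) -> int:
        return self.depths.size

    @property
    def dz(self) -> float:
        if len(self) == 1:
            return 2.0 * self.depths[0]
        steps = np.diff(self.depths)
        if not np.allclose(steps, steps[0], rtol=1e-8):
            raise ValueError("profile grid is not uniform")
        return float(steps[0])

    @property
    def c(self) -> np.ndarray:
        """Beam attenuation coefficient c = a + b, m^-1."""
        return self.a + self.b

    @property
    def b_p(self) -> np.ndarray:
        """Particulate scattering coefficient, m^-1."""
        return self.b - self.water.b_w

    @property
    def bbp(self) -> np.ndarray:
        """Particulate backscattering coefficient BF(xi) * b_p, m^-1."""
        return backscatter_fraction(self.xi) * self.b_p

    def copy(self) -> "IOPProfile":
        return IOPProfile(
            self.depths.copy(), self.a.copy(), self.b.copy(), self.xi.copy(), self.water
        )

    @classmethod
    def homogeneous(
        cls,
        a: float,
        b: float,
        xi: float,
        max_depth: float = 30.0,
        dz: float = 1.0,
        water: PureWaterOptics | None = None,
    ) -> "IOPProfile":
        """Constant-with-depth profile on bin centers out to ``max_depth``."""
        n = int(round(max_depth / dz))
        z = (np.arange(n) + 0.5) * dz
        ones = np.ones(n)
        return cls(z, a * ones, b * ones, xi * ones, water or PureWaterOptics())
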