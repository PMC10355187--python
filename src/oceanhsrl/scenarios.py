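"""Synthetic coastal-to-offshore water scenarios (L1 nearshore .. L5 offshore).

Preset IOP magnitudes follow the characteristic values of a
nearshore-to-offshore transect: turbidity (a, b) decreases and the PSD
slope xi increases moving offshore.  The presets are characteristic waters,
homogeneous over 0-30 m by default; the L4 preset has a stratified variant
with a clearer 5 m surface layer emulating a clear-water intrusion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import qmc

from .config import LidarConfig
from .mc import add_noise, simulate_mc
from .profiles import IOPProfile
from .signals import SignalSet

__all__ = ["ScenarioSpec", "PRESETS", "make_profile", "make_ensemble", "make_fixture"]

# surface (a, b, xi) of the named presets, m^-1 / m^-1 / dimensionless
PRESETS = {
    "L1": (0.11, 0.75, 3.15),
    "L2": (0.085, 0.55, 3.35),
    "L3": (0.078, 0.40, 3.35),
    "L4": (0.08, 0.45, 3.30),
    "L5": (0.047, 0.25, 3.42),
}

# parameter box spanned by the coastal-to-offshore transect
A_RANGE = (0.047, 0.11)
B_RANGE = (0.25, 0.75)
XI_RANGE = (3.15, 3.42)


@dataclass
class ScenarioSpec:
    """One synthetic water body.

    ``gradients`` is an optional list of (depth_top_m, a, b, xi) layers:
    piecewise-constant from each depth_top down to the next (surface values
    apply above the first breakpoint).
    """

    name: str = "custom"
    a: float = 0.08
    b: float = 0.45
    xi: float = 3.3
    gradients: list | None = None
    depth_max: float = 30.0
    dz: float = 1.0
    noise: float | None = None  # photon-count scale for add_noise
    seed: int = 0

    @classmethod
    def preset(cls, name: str, stratified: bool = False, **kwargs) -> "ScenarioSpec":
        if name not in PRESETS:
            raise KeyError(f"unknown preset {name!r}; expected one of {list(PRESETS)}")
        a, b, xi = PRESETS[name]
        spec = cls(name=name, a=a, b=b, xi=xi, **kwargs)
        if stratified:
            if name != "L4":
                raise ValueError("the stratified variant is defined for L4")
            # clearer 5 m surface layer over the L4 water (intrusion)
            spec.gradients = [(0.0, 0.078, 0.40, 3.35), (5.0, a, b, xi)]
        return spec


def make_profile(spec: ScenarioSpec) -> IOPProfile:
    """Materialize a spec on its uniform bin-center grid."""
    n = int(round(spec.depth_max / spec.dz))
    z = (np.arange(n) + 0.5) * spec.dz
    a = np.full(n, spec.a)
    b = np.full(n, spec.b)
    xi = np.full(n, spec.xi)
    if spec.gradients:
        for depth_top, la, lb, lxi in sorted(spec.gradients):
            sel = z >= depth_top
            a[sel], b[sel], xi[sel] = la, lb, lxi
    return IOPProfile(z, a, b, xi)


def make_ensemble(
    n: int,
    a_range=A_RANGE,
    b_range=B_RANGE,
    xi_range=XI_RANGE,
    depth_max: float = 30.0,
    dz: float = 1.0,
    seed: int = 0,
) -> list[IOPProfile]:
    """Latin-hypercube ensemble of homogeneous profiles over the box."""
    if n < 1:
        raise ValueError("n must be at least 1")
    for lo, hi in (a_range, b_range, xi_range):
        if not hi > lo:
            raise ValueError("degenerate parameter range")
    sampler = qmc.LatinHypercube(d=3, seed=seed)
    u = sampler.random(n)
    lows = np.array([a_range[0], b_range[0], xi_range[0]])
    highs = np.array([a_range[1], b_range[1], xi_range[1]])
    pts = qmc.scale(u, lows, highs)
    return [
        make_profile(ScenarioSpec(name=f"lhs{i}", a=p[0], b=p[1], xi=p[2],
                                  depth_max=depth_max, dz=dz))
        for i, p in enumerate(pts)
    ]


def make_fixture(
    spec: ScenarioSpec,
    config: LidarConfig | None = None,
    n_photons: int = 1_000_000,
    seed: int = 0,
) -> tuple[IOPProfile, SignalSet]:
    """Profile plus Monte Carlo signals (optionally Poisson-noised)."""
    cfg = config or LidarConfig()
    iop = make_profile(spec)
    sig = simulate_mc(iop, cfg, n_photons=n_photons, seed=seed)
    if spec.noise:
        sig = add_noise(sig, scale=spec.noise, seed=seed + 1)
    sig.meta["scenario"] = spec.name
    return iop, sig
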