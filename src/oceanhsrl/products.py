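"""Derived optical products from wide-FOV channels and retrieved profiles.

Diffuse attenuation K_d from the wide-FOV molecular channel, particulate
backscatter b_bp from the combined/molecular ratio, the lidar ratio R, the
particulate single-scattering albedo omega_0, and the power-law wavelength
conversion of b_bp.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import LidarConfig
from .optics import PureWaterOptics

__all__ = [
    "DerivedProducts",
    "estimate_kd",
    "estimate_bbp",
    "lidar_ratio",
    "single_scattering_albedo",
    "bbp_wavelength_convert",
]


@dataclass
class DerivedProducts:
    """Per-bin derived quantities (NaN marks bins flagged missing)."""

    depths: np.ndarray
    kd: np.ndarray
    bbp: np.ndarray
    lidar_ratio: np.ndarray
    omega0: np.ndarray


def estimate_kd(
    mol_wide: np.ndarray,
    depths: np.ndarray,
    config: LidarConfig | None = None,
    window: int = 5,
) -> np.ndarray:
    """Diffuse attenuation K_d(z) from the wide-FOV molecular channel.

    K_d = -1/2 d/dz ln(range-corrected signal), windowed least-squares
    slope; invariant to the overall signal scale (and hence to the system
    constant).  Bins whose window contains non-positive signal are NaN.
    """
    mol_wide = np.asarray(mol_wide, dtype=float)
    depths = np.asarray(depths, dtype=float)
    h = config.lidar_height if config is not None else 5.0
    rc = mol_wide * (h + depths) ** 2
    n = depths.size
    half = window // 2
    out = np.full(n, np.nan)
    for i in range(n):
        lo, hi = max(0, i - half), min(n, i + half + 1)
        seg = rc[lo:hi]
        if np.any(seg <= 0) or seg.size < 2:
            continue
        out[i] = -0.5 * np.polyfit(depths[lo:hi], np.log(seg), 1)[0]
    return out


def estimate_bbp(
    comb_wide: np.ndarray,
    mol_wide: np.ndarray,
    config: LidarConfig | None = None,
    chi: float = 1.1,
) -> np.ndarray:
    """Particulate backscattering coefficient from the channel ratio.

    The combined/molecular ratio at the wide FOV gives the particulate
    180-degree volume scattering function
    beta_p(pi) = beta_m(pi) * (comb/mol - 1), converted to the integrated
    backscatter with b_bp = 2 pi chi beta_p(pi).  Negative ratios (noise)
    are clipped to zero.
    """
    cfg = config or LidarConfig()
    comb = np.asarray(comb_wide, dtype=float)
    mol = np.asarray(mol_wide, dtype=float)
    beta_p = cfg.beta_m_pi * np.clip(comb / mol - 1.0, 0.0, None)
    return 2.0 * np.pi * chi * beta_p


def lidar_ratio(
    kd: np.ndarray,
    beta_p_180: np.ndarray,
    kd_pure: float | None = None,
    water: PureWaterOptics | None = None,
) -> np.ndarray:
    """Lidar ratio R = (K_d - K_d,pure) / beta_p(180 deg), sr.

    K_d,pure defaults to a_w + b_bw.  Non-positive beta_p gives NaN.
    """
    w = water or PureWaterOptics()
    if kd_pure is None:
        kd_pure = w.a_w + w.b_bw
    kd = np.asarray(kd, dtype=float)
    beta = np.asarray(beta_p_180, dtype=float)
    return np.where(beta > 0, (kd - kd_pure) / np.where(beta > 0, beta, 1.0), np.nan)


def single_scattering_albedo(a, b, water: PureWaterOptics | None = None):
    """Particulate single-scattering albedo.

    omega_0 = b_p / (a_p + b_p) with the pure-seawater contribution
    removed from both absorption and scattering; NaN where the particulate
    beam attenuation vanishes.
    """
    w = water or PureWaterOptics()
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    ap = a - w.a_w
    bp = b - w.b_w
    den = ap + bp
    out = np.where(den > 0, bp / np.where(den > 0, den, 1.0), np.nan)
    return float(out) if out.ndim == 0 else out


def bbp_wavelength_convert(bbp_ref, lambda_ref: float, lambda_out: float):
    """Convert b_bp across wavelengths with b_bp(l) = b_bp(l0) * l0 / l."""
    if lambda_ref <= 0 or lambda_out <= 0:
        raise ValueError("wavelengths must be positive")
    out = np.asarray(bbp_ref, dtype=float) * (lambda_ref / lambda_out)
    return float(out) if out.ndim == 0 else out
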