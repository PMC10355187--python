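"""Lidar instrument configuration.

Geometry and channel layout of the triple-field-of-view HSRL: a coaxial
transmitter/receiver above a flat, refraction-free air--water interface,
three molecular (Brillouin) channels at nested fields of view plus one
combined channel at the widest FOV.
"""

from __future__ import annotations

import hashlib
import json
import tomllib
from dataclasses import dataclass, field, replace

import numpy as np

from .optics import MolecularPhase, PureWaterOptics

__all__ = ["LidarConfig", "CHANNELS"]

# canonical channel order used by every SignalSet
CHANNELS = ("mol_narrow", "mol_mid", "mol_wide", "comb_wide")


@dataclass(frozen=True)
class LidarConfig:
    """Instrument geometry and channel definition.

    Parameters
    ----------
    wavelength : float
        Laser wavelength, nm.
    fovs : tuple of float
        Receiver full-angle fields of view in radians, strictly increasing;
        the three molecular channels sit at these FOVs and the combined
        channel shares the widest one.  Defaults 40/80/200 mrad.
    lidar_height : float
        Platform height above the water surface, m.
    receiver_radius : float
        Effective receiver aperture radius, m.
    bin_size : float
        Range (depth) resolution, m.
    max_depth : float
        Deepest range bin simulated, m.
    system_constant : float
        Overall system constant C0 (arbitrary signal units).
    molecular_f : float
        Anisotropy factor of the molecular phase function
        p(theta) ~ 1 + f cos^2(theta).
    retention_cap : float
        Largest scattering angle treated as "retained in the beam" by the
        analytic multiple-scattering model, rad.
    retention_scale : float
        Shrink factor on the analytic model's geometric retention cutoff,
        compensating the angular random walk of repeated forward
        scattering (calibrated once against the Monte Carlo engine).
    """

    wavelength: float = 532.0
    fovs: tuple[float, float, float] = (0.040, 0.080, 0.200)
    lidar_height: float = 5.0
    receiver_radius: float = 0.1
    bin_size: float = 1.0
    max_depth: float = 30.0
    system_constant: float = 1.0
    molecular_f: float = 0.835
    retention_cap: float = np.pi / 2.0
    retention_scale: float = 1.0
    retention_rw: float = 0.0
    water: PureWaterOptics = field(default_factory=PureWaterOptics)

    def __post_init__(self) -> None:
        if len(self.fovs) != 3 or not all(
            self.fovs[i] < self.fovs[i + 1] for i in range(2)
        ):
            raise ValueError("fovs must be three strictly increasing full angles")
        for name in ("lidar_height", "receiver_radius", "bin_size", "max_depth"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def fov_half(self) -> np.ndarray:
        """Half-angles of the three FOVs, rad."""
        return np.asarray(self.fovs) / 2.0

    @property
    def receiver_area(self) -> float:
        return float(np.pi * self.receiver_radius**2)

    @property
    def n_bins(self) -> int:
        return int(round(self.max_depth / self.bin_size))

    @property
    def depths(self) -> np.ndarray:
        """Bin-center depth grid, m (positive down from the interface)."""
        return (np.arange(self.n_bins) + 0.5) * self.bin_size

    def molecular_phase(self) -> MolecularPhase:
        return MolecularPhase(f=self.molecular_f)

    @property
    def beta_m_pi(self) -> float:
        """Molecular volume scattering function at 180 deg, m^-1 sr^-1."""
        return self.water.b_w * self.molecular_phase().p180

    def hash(self) -> str:
        """Short stable digest of the configuration (for run manifests)."""
        payload = {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in self.__dict__.items()
            if not isinstance(v, PureWaterOptics)
        }
        payload["water"] = [self.water.a_w, self.water.b_w, self.water.b_bw]
        blob = json.dumps(payload, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    def replace(self, **kwargs) -> "LidarConfig":
        return replace(self, **kwargs)

    @classmethod
    def from_toml(cls, path) -> "LidarConfig":
        """Load a configuration from a TOML file; missing keys keep defaults."""
        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        water_raw = raw.pop("water", {})
        kwargs = dict(raw)
        if "fovs" in kwargs:
            kwargs["fovs"] = tuple(kwargs["fovs"])
        if water_raw:
            kwargs["water"] = PureWaterOptics(**water_raw)
        return cls(**kwargs)
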