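"""Range-resolved multi-channel lidar signal container."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import CHANNELS

__all__ = ["SignalSet"]


@dataclass
class SignalSet:
    """Range-resolved signals of the triple-FOV HSRL.

    ``mol`` holds the three molecular channels stacked (3, n_bins) in the
    order narrow / mid / wide; ``comb_wide`` is the combined channel at the
    widest FOV.  ``meta`` records provenance (model tag, seed, photon
    budget, config hash).
    """

    depths: np.ndarray
    mol: np.ndarray
    comb_wide: np.ndarray
    meta: dict = field(default_factory=dict)
    mol_se: np.ndarray | None = None  # per-bin 1-sigma uncertainty, optional
    comb_se: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.depths = np.asarray(self.depths, dtype=float)
        self.mol = np.asarray(self.mol, dtype=float)
        self.comb_wide = np.asarray(self.comb_wide, dtype=float)
        if self.mol.shape != (3, self.depths.size):
            raise ValueError("mol must have shape (3, n_bins)")
        if self.comb_wide.shape != self.depths.shape:
            raise ValueError("comb_wide must match the depth grid")
        if not (np.all(np.isfinite(self.mol)) and np.all(np.isfinite(self.comb_wide))):
            raise ValueError("signals must be finite")
        if self.mol_se is not None:
            self.mol_se = np.asarray(self.mol_se, dtype=float)
            if self.mol_se.shape != self.mol.shape:
                raise ValueError("mol_se must match mol")
        if self.comb_se is not None:
            self.comb_se = np.asarray(self.comb_se, dtype=float)

    @property
    def n_bins(self) -> int:
        return self.depths.size

    @property
    def mol_narrow(self) -> np.ndarray:
        return self.mol[0]

    @property
    def mol_mid(self) -> np.ndarray:
        return self.mol[1]

    @property
    def mol_wide(self) -> np.ndarray:
        return self.mol[2]

    def channel(self, name: str) -> np.ndarray:
        if name not in CHANNELS:
            raise KeyError(f"unknown channel {name!r}; expected one of {CHANNELS}")
        if name == "comb_wide":
            return self.comb_wide
        return self.mol[CHANNELS.index(name)]

    def to_frame(self) -> pd.DataFrame:
        """Flat table with one column per channel, indexed by depth (m)."""
        data = {name: self.channel(name) for name in CHANNELS}
        return pd.DataFrame(data, index=pd.Index(self.depths, name="depth_m"))

    def copy(self) -> "SignalSet":
        return SignalSet(
            self.depths.copy(),
            self.mol.copy(),
            self.comb_wide.copy(),
            dict(self.meta),
            None if self.mol_se is None else self.mol_se.copy(),
            None if self.comb_se is None else self.comb_se.copy(),
        )
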