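"""File I/O: profiles and signals on disk, run manifests.

Profiles travel as CSV with the canonical header
``depth_m, a_m-1, b_m-1, xi``; signal sets as a gridded NetCDF file
(depth x channel, via xarray) or as flat CSV; run manifests as JSON.
"""

from __future__ import annotations

import json
import pathlib

import numpy as np
import pandas as pd
import xarray as xr

from .config import CHANNELS
from .profiles import IOPProfile
from .signals import SignalSet

__all__ = [
    "read_profile",
    "write_profile",
    "read_signals",
    "write_signals",
    "write_manifest",
]

_PROFILE_COLUMNS = ["depth_m", "a_m-1", "b_m-1", "xi"]


def write_profile(path, iop: IOPProfile) -> None:
    """Write an IOP profile as CSV (depth_m, a_m-1, b_m-1, xi)."""
    df = pd.DataFrame(
        {
            "depth_m": iop.depths,
            "a_m-1": iop.a,
            "b_m-1": iop.b,
            "xi": iop.xi,
        }
    )
    df.to_csv(path, index=False, float_format="%.17g")


def read_profile(path) -> IOPProfile:
    """Read an IOP profile CSV; errors name the offending row."""
    df = pd.read_csv(path)
    missing = [c for c in _PROFILE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    for col in _PROFILE_COLUMNS:
        bad = df.index[pd.to_numeric(df[col], errors="coerce").isna()]
        if len(bad):
            raise ValueError(f"{path}: malformed value in row {bad[0] + 2} ({col})")
    z = df["depth_m"].to_numpy(dtype=float)
    if np.any(np.diff(z) <= 0):
        row = int(np.argmax(np.diff(z) <= 0)) + 3
        raise ValueError(f"{path}: non-monotone depth at row {row}")
    return IOPProfile(
        z,
        df["a_m-1"].to_numpy(dtype=float),
        df["b_m-1"].to_numpy(dtype=float),
        df["xi"].to_numpy(dtype=float),
    )


def _to_dataset(sig: SignalSet) -> xr.Dataset:
    data = np.vstack([sig.mol, sig.comb_wide[None, :]])
    ds = xr.Dataset(
        {
            "signal": (("channel", "depth"), data),
        },
        coords={"channel": list(CHANNELS), "depth": sig.depths},
    )
    if sig.mol_se is not None and sig.comb_se is not None:
        se = np.vstack([sig.mol_se, sig.comb_se[None, :]])
        ds["signal_se"] = (("channel", "depth"), se)
    ds["depth"].attrs["units"] = "m"
    ds.attrs.update(
        {k: v for k, v in sig.meta.items() if isinstance(v, (str, int, float))}
    )
    return ds


def _from_dataset(ds: xr.Dataset) -> SignalSet:
    channels = [str(c) for c in ds["channel"].values]
    unknown = set(channels) - set(CHANNELS)
    if unknown:
        raise ValueError(f"unknown channels {sorted(unknown)}")
    if set(channels) != set(CHANNELS):
        raise ValueError(f"expected channels {CHANNELS}, found {channels}")
    sig = ds["signal"].sel(channel=list(CHANNELS)).values
    se = None
    if "signal_se" in ds:
        se = ds["signal_se"].sel(channel=list(CHANNELS)).values
    return SignalSet(
        ds["depth"].values.astype(float),
        sig[:3],
        sig[3],
        dict(ds.attrs),
        None if se is None else se[:3],
        None if se is None else se[3],
    )


def write_signals(path, sig: SignalSet) -> None:
    """Write a SignalSet; ``.nc`` gives gridded NetCDF, ``.csv`` a flat table."""
    path = pathlib.Path(path)
    if path.suffix == ".csv":
        df = sig.to_frame()
        if sig.mol_se is not None:
            for i, name in enumerate(CHANNELS[:3]):
                df[name + "_se"] = sig.mol_se[i]
            df["comb_wide_se"] = sig.comb_se
        df.to_csv(path, float_format="%.12g")
    else:
        _to_dataset(sig).to_netcdf(path, engine="scipy")


def read_signals(path) -> SignalSet:
    """Read a SignalSet written by :func:`write_signals`."""
    path = pathlib.Path(path)
    if path.suffix == ".csv":
        df = pd.read_csv(path, index_col=0)
        unknown = [
            c for c in df.columns if c not in CHANNELS and not c.endswith("_se")
        ]
        if unknown:
            raise ValueError(f"unknown channels {unknown}")
        mol = np.vstack([df[name].to_numpy() for name in CHANNELS[:3]])
        mol_se = comb_se = None
        if "mol_narrow_se" in df.columns:
            mol_se = np.vstack(
                [df[name + "_se"].to_numpy() for name in CHANNELS[:3]]
            )
            comb_se = df["comb_wide_se"].to_numpy()
        return SignalSet(
            df.index.to_numpy(dtype=float),
            mol,
            df["comb_wide"].to_numpy(),
            {},
            mol_se,
            comb_se,
        )
    with xr.open_dataset(path, engine="scipy") as ds:
        return _from_dataset(ds.load())


def write_manifest(path, **entries) -> None:
    """Write a JSON run manifest (config hash, seeds, timings, outputs)."""

    def _clean(v):
        if isinstance(v, (np.integer,)):
            return int(v)
        if isinstance(v, (np.floating,)):
            return float(v)
        if isinstance(v, np.ndarray):
            return v.tolist()
        if isinstance(v, dict):
            return {k: _clean(x) for k, x in v.items()}
        if isinstance(v, (list, tuple)):
            return [_clean(x) for x in v]
        return v

    with open(path, "w") as fh:
        json.dump(_clean(entries), fh, indent=2, sort_keys=True)
        fh.write("\n")
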