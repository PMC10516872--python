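"""CSV (and optional SNIRF) readers/writers for trajectories and recordings.

Trajectory CSV: ``t,ego_x,ego_y,ego_v,obj_x,obj_y,obj_v,obj_heading,obj_mass``
(SI units, header required).  fNIRS CSV: ``t,hbo_1..hbo_N,hbr_1..hbr_N``
(μmol/L); the sample rate is inferred from the timestamps and checked for
uniformity (±1%).  Risk CSV: ``t,Ev,label``.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .fnirs_preprocess import HemoRecording
from .risk_field import RiskSeries

TRAJECTORY_COLUMNS = [
    "t", "ego_x", "ego_y", "ego_v", "obj_x", "obj_y", "obj_v", "obj_heading", "obj_mass",
]

__all__ = [
    "TRAJECTORY_COLUMNS",
    "read_trajectory_csv",
    "write_trajectory_csv",
    "read_fnirs_csv",
    "write_fnirs_csv",
    "write_risk_csv",
    "read_risk_csv",
    "read_snirf",
]


def read_trajectory_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in TRAJECTORY_COLUMNS if c not in df.columns and c != "obj_mass"]
    if missing:
        raise ValueError(f"trajectory CSV {path} missing columns {missing}")
    return df


def write_trajectory_csv(traj: pd.DataFrame, path: str | Path) -> None:
    cols = [c for c in TRAJECTORY_COLUMNS if c in traj.columns]
    traj[cols].to_csv(path, index=False)


def infer_fs(t: np.ndarray, rtol: float = 0.01) -> float:
    """Sample rate from timestamps, validated for uniform spacing (±1%)."""
    dt = np.diff(np.asarray(t, float))
    if dt.size == 0 or np.any(dt <= 0):
        raise ValueError("timestamps must be strictly increasing")
    med = float(np.median(dt))
    if np.any(np.abs(dt - med) > rtol * med):
        raise ValueError("non-uniform sampling: timestep deviates by more than 1%")
    return 1.0 / med


def write_fnirs_csv(rec: HemoRecording, path: str | Path) -> None:
    data = {"t": rec.t}
    for c in range(rec.n_channels):
        data[f"hbo_{c + 1}"] = rec.hbo[c]
    for c in range(rec.n_channels):
        data[f"hbr_{c + 1}"] = rec.hbr[c]
    pd.DataFrame(data).to_csv(path, index=False)


def read_fnirs_csv(path: str | Path, n_channels: int | None = None) -> HemoRecording:
    df = pd.read_csv(path)
    hbo_cols = sorted(
        (c for c in df.columns if c.startswith("hbo_")), key=lambda c: int(c.split("_")[1])
    )
    hbr_cols = sorted(
        (c for c in df.columns if c.startswith("hbr_")), key=lambda c: int(c.split("_")[1])
    )
    if not hbo_cols or len(hbo_cols) != len(hbr_cols):
        raise ValueError(f"fNIRS CSV {path}: mismatched hbo_/hbr_ channel columns")
    if n_channels is not None and len(hbo_cols) != n_channels:
        raise ValueError(
            f"fNIRS CSV {path}: expected {n_channels} channels, found {len(hbo_cols)}"
        )
    t = df["t"].to_numpy(float)
    fs = infer_fs(t)
    return HemoRecording(
        fs=fs,
        t=t,
        hbo=df[hbo_cols].to_numpy(float).T,
        hbr=df[hbr_cols].to_numpy(float).T,
    )


def write_risk_csv(rs: RiskSeries, path: str | Path) -> None:
    rs.to_frame().to_csv(path, index=False)


def read_risk_csv(path: str | Path, threshold: float = 0.05) -> RiskSeries:
    return RiskSeries.from_frame(pd.read_csv(path), threshold)


def read_snirf(path: str | Path) -> HemoRecording:
    """Import a SNIRF (HDF5) file, mapping channels by chromophore label.

    Supports processed HbO/HbR concentration data (dataTypeLabel ``HbO``/
    ``HbR``) in ``/nirs/data1``.
    """
    import h5py

    def _str(x):
        v = x[()]
        return v.decode() if isinstance(v, bytes) else str(v)

    with h5py.File(path, "r") as f:
        data = f["nirs/data1"]
        t = np.asarray(data["time"][()], float).ravel()
        y = np.atleast_2d(np.asarray(data["dataTimeSeries"][()], float))
        hbo_idx, hbr_idx = [], []
        k = 1
        while f"measurementList{k}" in data:
            ml = data[f"measurementList{k}"]
            label = _str(ml["dataTypeLabel"]) if "dataTypeLabel" in ml else ""
            if label.lower() == "hbo":
                hbo_idx.append(k - 1)
            elif label.lower() == "hbr":
                hbr_idx.append(k - 1)
            k += 1
        if not hbo_idx or len(hbo_idx) != len(hbr_idx):
            raise ValueError(f"SNIRF {path}: need matched HbO/HbR chromophore channels")
    return HemoRecording(fs=infer_fs(t), t=t, hbo=y[:, hbo_idx].T, hbr=y[:, hbr_idx].T)
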