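"""Kinetic-energy driving-risk field and episode segmentation.

The risk of a driving scene is summarised by a scalar potential ("kinetic
energy field") around each traffic object.  For an object of mass ``M2``
at separation ``r`` from the ego vehicle, moving at speed ``v2`` at angle
``theta2`` between the separation vector and its velocity, the field felt
by the ego vehicle is

    E = G * R2 * M2 / |r|**k1 * exp(k2 * v2 * cos(theta2))

with dimensionless constants ``G``, ``k1`` and road-friction factor ``R2``.
The field grows as the object gets closer and, through the exponential
term, as the object approaches faster head-on.  Timesteps where the field
magnitude exceeds a threshold (default 0.05) form the *high-risk* episode;
a window of equal duration immediately before the threshold crossing is
the *low-risk* baseline episode.

Only the scalar magnitude is computed: the directional unit vector of the
full vector field cancels in any threshold or mean comparison.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "RiskParams",
    "ObjectState",
    "RiskSeries",
    "EpisodePair",
    "DURATIONS_TABLE1",
    "DURATIONS_METHODS",
    "kinetic_energy_field",
    "risk_series",
    "segment_episodes",
    "mean_risk",
]

#: Per-scenario episode durations in seconds, results-table convention.
DURATIONS_TABLE1 = {"saeb": 20.0, "lci": 15.0, "rci": 10.0, "rpcr": 6.0}
#: Alternative convention with the pedestrian/AEB durations swapped.
DURATIONS_METHODS = {"saeb": 6.0, "lci": 15.0, "rci": 10.0, "rpcr": 20.0}

KMH_TO_MS = 1.0 / 3.6


@dataclass(frozen=True)
class RiskParams:
    """Constants of the kinetic-energy risk field.

    Defaults are the values used in application: G=0.001, k1=1, k2=0.05
    (s/m), M2=1705 kg, R2=1, high-risk threshold 0.05.
    """

    G: float = 0.001
    k1: float = 1.0
    k2: float = 0.05
    R2: float = 1.0
    M2: float = 1705.0
    threshold: float = 0.05

    def __post_init__(self) -> None:
        for name in ("G", "k1", "R2", "M2", "threshold"):
            if not getattr(self, name) > 0:
                raise ValueError(f"RiskParams.{name} must be > 0")

    def with_mass(self, m2: float) -> "RiskParams":
        """Same parameters with a different object mass (e.g. a pedestrian)."""
        return replace(self, M2=float(m2))


@dataclass(frozen=True)
class ObjectState:
    """Instantaneous state of one traffic object relative to the ego vehicle.

    Attributes
    ----------
    r : (2,) array-like
        Planar separation vector ego → object, metres.
    v2 : float
        Object speed, m/s (non-negative).
    theta2 : float
        Angle between ``r`` and the object velocity vector, radians in [0, π].
    """

    r: np.ndarray
    v2: float = 0.0
    theta2: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "r", np.asarray(self.r, dtype=float))
        if self.v2 < 0:
            raise ValueError("object speed v2 must be non-negative")
        if not (0.0 <= self.theta2 <= np.pi + 1e-12):
            raise ValueError("theta2 must lie in [0, pi]")

    @property
    def distance(self) -> float:
        return float(np.linalg.norm(self.r))


def field_magnitude(dist, v2=0.0, theta2=0.0, params: RiskParams | None = None):
    """Vectorised scalar field for separation distance(s) ``dist``."""
    params = params or RiskParams()
    dist = np.asarray(dist, dtype=float)
    if np.any(dist <= 0):
        bad = int(np.argmax(dist <= 0))
        raise ValueError(
            f"zero or negative separation distance at timestep {bad}; "
            "the risk field is undefined at contact"
        )
    v2 = np.asarray(v2, dtype=float)
    theta2 = np.asarray(theta2, dtype=float)
    return (
        params.G * params.R2 * params.M2 / dist**params.k1
        * np.exp(params.k2 * v2 * np.cos(theta2))
    )


def kinetic_energy_field(state: ObjectState, params: RiskParams | None = None) -> float:
    """Scalar risk-field magnitude for one object state."""
    return float(field_magnitude(state.distance, state.v2, state.theta2, params))


@dataclass
class RiskSeries:
    """Risk-field magnitude over time with low/high labels.

    ``label[i]`` is True (high risk) iff ``ev[i] > threshold`` (strict).
    """

    t: np.ndarray
    ev: np.ndarray
    threshold: float = 0.05

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.ev = np.asarray(self.ev, dtype=float)
        if self.t.shape != self.ev.shape:
            raise ValueError("t and Ev must have equal length")
        if self.t.size >= 2 and not np.all(np.diff(self.t) > 0):
            raise ValueError("timestamps must be strictly increasing")
        if np.any(self.ev < 0):
            raise ValueError("risk-field magnitudes must be non-negative")

    @property
    def label(self) -> np.ndarray:
        """Boolean high-risk labels (strict inequality against threshold)."""
        return self.ev > self.threshold

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "t": self.t,
                "Ev": self.ev,
                "label": np.where(self.label, "high", "low"),
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame, threshold: float = 0.05) -> "RiskSeries":
        return cls(df["t"].to_numpy(), df["Ev"].to_numpy(), threshold)


@dataclass
class EpisodePair:
    """Matched low-risk / high-risk spans (half-open, seconds) for one event."""

    scenario_type: str
    low_span: tuple[float, float]
    high_span: tuple[float, float]
    duration: float
    low_truncated: bool = False
    high_truncated: bool = False
    notes: list[str] = field(default_factory=list)


def risk_series(traj: pd.DataFrame, params: RiskParams | None = None) -> RiskSeries:
    """Evaluate the risk field along a trajectory table.

    ``traj`` columns: ``t, ego_x, ego_y, ego_v, obj_x, obj_y, obj_v,
    obj_heading, obj_mass`` (SI units; heading in radians, direction of the
    object's velocity).  A per-row ``obj_mass`` overrides ``params.M2``.
    """
    params = params or RiskParams()
    if len(traj) < 2:
        raise ValueError("trajectory needs at least 2 timesteps")
    t = traj["t"].to_numpy(dtype=float)
    if not np.all(np.diff(t) > 0):
        bad = int(np.argmax(np.diff(t) <= 0)) + 1
        raise ValueError(f"non-monotone timestamps in trajectory at row {bad}")

    rx = traj["obj_x"].to_numpy(float) - traj["ego_x"].to_numpy(float)
    ry = traj["obj_y"].to_numpy(float) - traj["ego_y"].to_numpy(float)
    dist = np.hypot(rx, ry)
    v2 = traj["obj_v"].to_numpy(float)
    heading = traj["obj_heading"].to_numpy(float)
    # angle between r and the object velocity direction; irrelevant when v2=0
    cos_theta = np.where(
        dist > 0,
        (rx * np.cos(heading) + ry * np.sin(heading)) / np.where(dist > 0, dist, 1.0),
        1.0,
    )
    theta2 = np.arccos(np.clip(cos_theta, -1.0, 1.0))

    if "obj_mass" in traj.columns:
        mass = traj["obj_mass"].to_numpy(float)
    else:
        mass = np.full_like(dist, params.M2)
    ev = field_magnitude(dist, v2, theta2, params) * (mass / params.M2)
    return RiskSeries(t, ev, params.threshold)


def high_onset(rs: RiskSeries) -> float:
    """Time of the first sample whose field magnitude exceeds the threshold."""
    idx = np.flatnonzero(rs.label)
    if idx.size == 0:
        raise ValueError("no high-risk episode: field never exceeds threshold")
    return float(rs.t[idx[0]])


def segment_episodes(
    rs: RiskSeries,
    scenario_type: str,
    durations: dict[str, float] | None = None,
    duration_mapping: str = "table1",
) -> EpisodePair:
    """Split a risk series into the low/high-risk episode pair.

    The high-risk span starts at the first threshold crossing and lasts the
    scenario-specific duration ``d``; the low-risk span is the ``d``-second
    window immediately before the crossing, clipped at recording start.
    """
    if durations is None:
        durations = DURATIONS_TABLE1 if duration_mapping == "table1" else DURATIONS_METHODS
    if scenario_type not in durations:
        raise KeyError(f"unknown scenario type {scenario_type!r}")
    d = float(durations[scenario_type])

    onset = high_onset(rs)
    notes: list[str] = []
    t_end = float(rs.t[-1])

    lo_start = onset - d
    low_trunc = lo_start < rs.t[0]
    if low_trunc:
        lo_start = float(rs.t[0])
        warnings.warn("low-risk window clipped to recording start", stacklevel=2)
        notes.append("low window truncated at recording start")
    hi_end = onset + d
    high_trunc = hi_end > t_end + 1e-9
    if high_trunc:
        notes.append("recording shorter than episode duration after onset")
        warnings.warn("high-risk window truncated at recording end", stacklevel=2)

    return EpisodePair(
        scenario_type=scenario_type,
        low_span=(lo_start, onset),
        high_span=(onset, hi_end),
        duration=d,
        low_truncated=low_trunc,
        high_truncated=high_trunc,
        notes=notes,
    )


def span_mask(t: np.ndarray, span: tuple[float, float]) -> np.ndarray:
    """Boolean mask of samples whose timestamp lies in the half-open span."""
    start, end = span
    return (t >= start) & (t < end)


def mean_risk(rs: RiskSeries, span: tuple[float, float]) -> float:
    """Arithmetic mean of the field over samples within a half-open span."""
    m = span_mask(rs.t, span)
    if not m.any():
        raise ValueError(f"span {span} contains no samples")
    return float(rs.ev[m].mean())
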