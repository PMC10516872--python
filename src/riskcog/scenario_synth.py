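"""Synthetic co-simulation of driving scenarios and evoked fNIRS hemodynamics.

Four challenging scenario types are modelled with minimal constant-rate
kinematics, each driving the ego vehicle (70 km/h on a straight road) into
a risk-field threshold crossing:

* ``saeb`` — lead vehicle emergency-brakes at short distance; ego brakes to
  a standstill a few metres behind.
* ``lci`` / ``rci`` — an adjacent-lane vehicle 15 km/h slower cuts in with
  a constant lateral speed; ego closes in and settles to follow.
* ``rpcr`` — a pedestrian steps off the right kerb across the ego lane;
  ego brakes to a stop short of the crossing point.

The hemodynamic forward model produces 8-channel ΔHbO/ΔHbR at 10 Hz: a
boxcar over high-risk spans convolved with a canonical double-gamma HRF
(peak 6 s, undershoot 16 s), scaled per channel (channel 8 strongest by
default), plus quadratic drift, cardiac/respiratory/Mayer-wave sinusoids,
Poisson-rate motion artifacts (spikes and baseline steps) and white noise.
The evoked ΔHbO/ΔHbR signs are set so that ΔCOE = (ΔHbR−ΔHbO)/√2 rises
under high risk by default (``coupling_sign=+1``); the physiologically
more common opposite sign is available with ``coupling_sign=-1``.

Everything is deterministic given spec + seed, and each recording ships
with a ground-truth ledger of all injected components.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .fnirs_preprocess import HemoRecording
from .risk_field import KMH_TO_MS, RiskParams, RiskSeries, risk_series

__all__ = [
    "ScenarioSpec",
    "NoiseProfile",
    "SessionSpec",
    "STUDY_TOTALS",
    "STUDY_REJECTIONS",
    "gen_trajectory",
    "gen_fnirs",
    "gen_segment",
    "gen_session",
    "session_plan",
    "sample_accounting",
    "double_gamma_hrf",
]

EGO_SPEED_DEFAULT = 70.0 * KMH_TO_MS  # 19.444 m/s

#: Study-scale sample bookkeeping across 20 participants.
STUDY_TOTALS = {"saeb": 280, "lci": 560, "rci": 500, "rpcr": 660}
STUDY_REJECTIONS = {"saeb": 13, "lci": 29, "rci": 20, "rpcr": 28}


# ---------------------------------------------------------------------------
# scenario kinematics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ScenarioSpec:
    """Parameters of one scenario instance.

    ``onset`` is the event time (lead braking / cut-in start / pedestrian
    step-off) within the block; ``total_s`` the block length.  Lateral
    positions: adjacent lanes at ±3.5 m, pedestrian kerb at −6 m (right).
    """

    type: str
    ego_speed: float = EGO_SPEED_DEFAULT
    init_distance: float = 150.0       # m, object ahead at onset
    target_speed: float = 55.0 * KMH_TO_MS  # m/s after the event (cut-ins)
    lateral_speed: float = 0.8         # m/s (cut-ins)
    ped_speed: float = 1.4             # m/s (pedestrian)
    end_gap: float = 10.0              # m, settled following/stopping gap
    onset: float = 25.0                # s
    total_s: float = 65.0
    dt: float = 0.1
    obj_mass: float = 1705.0

    def __post_init__(self) -> None:
        if self.type not in ("saeb", "lci", "rci", "rpcr", "other"):
            raise ValueError(f"unknown scenario type {self.type!r}")
        for name in ("ego_speed", "target_speed", "lateral_speed", "ped_speed"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not 0 < self.onset < self.total_s:
            raise ValueError("onset must fall inside the block")
        if self.dt <= 0:
            raise ValueError("timestep must be positive")

    @classmethod
    def default(cls, scenario_type: str) -> "ScenarioSpec":
        presets = {
            "saeb": dict(init_distance=150.0, end_gap=10.0, onset=25.0, total_s=65.0),
            "lci": dict(init_distance=100.0, end_gap=28.0, onset=20.0, total_s=50.0),
            "rci": dict(init_distance=100.0, end_gap=28.0, onset=15.0, total_s=40.0),
            "rpcr": dict(init_distance=251.7, end_gap=10.0, onset=10.0, total_s=25.0),
            "other": dict(init_distance=500.0, onset=5.0, total_s=25.0),
        }
        return cls(type=scenario_type, **presets[scenario_type])

    def jittered(self, rng: np.random.Generator) -> "ScenarioSpec":
        """Mild seeded variation of distances/speeds across instances."""
        return replace(
            self,
            init_distance=self.init_distance * rng.uniform(0.95, 1.1),
            lateral_speed=float(np.clip(self.lateral_speed * rng.uniform(0.8, 1.2), 0.6, 1.0)),
            ped_speed=self.ped_speed * rng.uniform(0.9, 1.1),
            end_gap=self.end_gap * rng.uniform(0.9, 1.1),
        )


def _integrate(spec: ScenarioSpec) -> pd.DataFrame:
    """Euler integration of the per-type kinematic phase model."""
    n = int(round(spec.total_s / spec.dt)) + 1
    t = np.arange(n) * spec.dt
    ego_x = np.zeros(n)
    ego_v = np.full(n, spec.ego_speed)
    ox = np.zeros(n)
    oy = np.zeros(n)
    ovx = np.zeros(n)
    ovy = np.zeros(n)

    v0 = spec.ego_speed
    if spec.type == "saeb":
        a_lead = 5.0
        s_lead = v0**2 / (2 * a_lead)
        brake_dist = spec.init_distance + s_lead - spec.end_gap
        a_ego = v0**2 / (2 * brake_dist)
        ex, ev = 0.0, v0
        lx, lv = spec.init_distance, v0
        for i in range(n):
            ego_x[i], ego_v[i], ox[i], ovx[i] = ex, ev, lx, lv
            oy[i] = 0.0
            if t[i] >= spec.onset:
                lv = max(0.0, lv - a_lead * spec.dt)
                ev = max(0.0, ev - a_ego * spec.dt)
            ex += ev * spec.dt
            lx += lv * spec.dt
    elif spec.type in ("lci", "rci"):
        lane = 3.5 if spec.type == "lci" else -3.5
        a_obj = 2.0
        a_ego = 2.0
        # start ego braking so it reaches the target speed at ~end_gap
        dv = v0 - spec.target_speed
        brake_trigger = spec.end_gap + 0.5 * dv * (dv / a_ego)
        ex, ev = 0.0, v0
        x, y, vx = spec.init_distance, lane, v0
        for i in range(n):
            gap = x - ex
            vy = 0.0
            if t[i] >= spec.onset:
                vx = max(spec.target_speed, vx - a_obj * spec.dt)
                if abs(y) > 1e-9:
                    vy = -np.sign(y) * spec.lateral_speed
                if gap <= brake_trigger:
                    ev = max(spec.target_speed, ev - a_ego * spec.dt)
            ego_x[i], ego_v[i] = ex, ev
            ox[i], oy[i], ovx[i], ovy[i] = x, y, vx, vy
            ex += ev * spec.dt
            x += vx * spec.dt
            y = y + vy * spec.dt
            if np.sign(y) != np.sign(lane):
                y = 0.0
    elif spec.type == "rpcr":
        a_ego = 4.0
        # kerb position such that braking at the event stops end_gap short
        ex, ev = 0.0, v0
        px = spec.onset * v0 + v0**2 / (2 * a_ego) + spec.end_gap
        py = -6.0
        walking = False
        for i in range(n):
            vy = spec.ped_speed if walking else 0.0
            ego_x[i], ego_v[i] = ex, ev
            ox[i], oy[i], ovx[i], ovy[i] = px, py, 0.0, vy
            if t[i] >= spec.onset:
                walking = True
                ev = max(0.0, ev - a_ego * spec.dt)
            ex += ev * spec.dt
            py += (spec.ped_speed if walking else 0.0) * spec.dt
    else:  # "other": uneventful filler, object far ahead at ego speed
        ex = 0.0
        x = spec.init_distance
        for i in range(n):
            ego_x[i] = ex
            ox[i], ovx[i] = x, v0
            ex += v0 * spec.dt
            x += v0 * spec.dt

    speed = np.hypot(ovx, ovy)
    heading = np.where(speed > 1e-9, np.arctan2(ovy, ovx), 0.0)
    # carry the last moving heading through standstill
    for i in range(1, n):
        if speed[i] <= 1e-9:
            heading[i] = heading[i - 1]
    return pd.DataFrame(
        {
            "t": t,
            "ego_x": ego_x,
            "ego_y": 0.0,
            "ego_v": ego_v,
            "obj_x": ox,
            "obj_y": oy,
            "obj_v": speed,
            "obj_heading": heading,
            "obj_mass": spec.obj_mass,
        }
    )


def gen_trajectory(
    spec: ScenarioSpec,
    seed: int | None = None,
    params: RiskParams | None = None,
    validate: bool = True,
) -> pd.DataFrame:
    """Generate one scenario trajectory (optionally jittered by ``seed``).

    Raises a validation error if the induced risk field never crosses the
    threshold (except for event-free ``other`` filler, which must not).
    """
    if seed is not None:
        spec = spec.jittered(np.random.default_rng(seed))
    traj = _integrate(spec)
    if validate:
        params = params or RiskParams()
        rs = risk_series(traj, params)
        crossed = bool(rs.label.any())
        if spec.type == "other":
            if crossed:
                raise ValueError(f"filler scenario crossed the risk threshold: {spec}")
        elif not crossed:
            raise ValueError(
                f"scenario produces no threshold crossing (max Ev="
                f"{rs.ev.max():.4f} <= {params.threshold}); spec: {spec}"
            )
    return traj


# ---------------------------------------------------------------------------
# hemodynamic forward model
# ---------------------------------------------------------------------------

def double_gamma_hrf(fs: float, duration_s: float = 32.0, peak: float = 6.0,
                     undershoot: float = 16.0, ratio: float = 6.0) -> np.ndarray:
    """Canonical double-gamma HRF sampled at ``fs``, normalised to peak 1."""
    from scipy.stats import gamma as gamma_dist

    t = np.arange(0.0, duration_s, 1.0 / fs)
    h = gamma_dist.pdf(t, peak) - gamma_dist.pdf(t, undershoot) / ratio
    return h / h.max()


@dataclass(frozen=True)
class NoiseProfile:
    """Amplitudes (μmol/L) and rates of the structured noise components."""

    drift_amp: float = 0.15          # quadratic drift, scale over the record
    cardiac_amp: float = 0.08
    cardiac_hz: float = 1.1
    resp_amp: float = 0.10
    resp_hz: float = 0.3
    mayer_amp: float = 0.06
    mayer_hz: float = 0.1
    motion_rate_hz: float = 1.0 / 60.0  # Poisson rate of artifacts
    spike_amp: float = 1.0
    step_amp: float = 0.5
    white_sd: float = 0.03

    @classmethod
    def silent(cls) -> "NoiseProfile":
        return cls(0.0, 0.0, 1.1, 0.0, 0.3, 0.0, 0.1, 0.0, 0.0, 0.0, 0.0)


@dataclass(frozen=True)
class SessionSpec:
    """Study-design parameters of a simulated session bundle.

    Defaults mirror the study: 20 participants, 12 segments of 24 scenarios
    each (288 per participant: 14 SAEB + 28 LCI + 25 RCI + 33 RPCR events
    and 188 uneventful fillers), an event-free lead-in worth 1000 m of
    driving, 8 channels at 10 Hz with the strongest evoked response on
    channel 8, and a positive ΔCOE–risk coupling.
    """

    n_participants: int = 20
    n_segments: int = 12
    scenarios_per_segment: int = 24
    scenario_mix: dict = field(
        default_factory=lambda: {"saeb": 14, "lci": 28, "rci": 25, "rpcr": 33, "other": 188}
    )
    lead_in_m: float = 1000.0
    ego_speed: float = EGO_SPEED_DEFAULT
    fs: float = 10.0
    n_channels: int = 8
    activation: tuple = (0.04, 0.04, 0.04, 0.04, 0.04, 0.04, 0.04, 0.12)
    coupling_sign: int = +1
    noise: NoiseProfile = field(default_factory=NoiseProfile)
    seed: int = 0

    def __post_init__(self) -> None:
        total = self.n_segments * self.scenarios_per_segment
        if sum(self.scenario_mix.values()) != total:
            raise ValueError(
                f"scenario mix {self.scenario_mix} does not sum to "
                f"{self.n_segments}x{self.scenarios_per_segment}={total}"
            )
        if len(self.activation) != self.n_channels:
            raise ValueError("one activation amplitude per channel required")
        if self.coupling_sign not in (+1, -1):
            raise ValueError("coupling_sign must be +1 or -1")

    @property
    def lead_in_s(self) -> float:
        return self.lead_in_m / self.ego_speed


def gen_fnirs(
    risk: RiskSeries,
    session: SessionSpec,
    seed: int | None = None,
) -> tuple[HemoRecording, dict]:
    """Simulate ΔHbO/ΔHbR channels evoked by the high-risk spans of ``risk``.

    Returns the recording and a ground-truth ledger with the noiseless
    evoked component, artifact times and all injected amplitudes.
    """
    rng = np.random.default_rng(session.seed if seed is None else seed)
    t = risk.t
    n = t.size
    fs = session.fs
    hrf = double_gamma_hrf(fs)
    boxcar = risk.label.astype(float)
    # normalise so a sustained high-risk block plateaus near amplitude 1
    evoked_shape = np.convolve(boxcar, hrf)[:n] / hrf.sum()

    prof = session.noise
    # evoked COE amplitude A_c is split between HbO (2/3) and HbR (1/3)
    alpha, beta = 2.0 * np.sqrt(2) / 3.0, np.sqrt(2) / 3.0
    sgn = session.coupling_sign

    hbo = np.zeros((session.n_channels, n))
    hbr = np.zeros((session.n_channels, n))
    truth = {
        "activation": list(session.activation),
        "coupling_sign": sgn,
        "evoked_shape": evoked_shape,
        "noise": prof,
        "artifacts": [],
    }
    dur = t[-1] - t[0] if n > 1 else 1.0
    u = (t - t[0]) / dur
    for c in range(session.n_channels):
        a_c = session.activation[c]
        evoked_hbo = -sgn * alpha * a_c * evoked_shape
        evoked_hbr = +sgn * beta * a_c * evoked_shape

        c2, c1 = rng.normal(0, prof.drift_amp, 2)
        drift = c1 * u + c2 * u**2
        phases = rng.uniform(0, 2 * np.pi, 3)
        osc = (
            prof.cardiac_amp * np.sin(2 * np.pi * prof.cardiac_hz * t + phases[0])
            + prof.resp_amp * np.sin(2 * np.pi * prof.resp_hz * t + phases[1])
            + prof.mayer_amp * np.sin(2 * np.pi * prof.mayer_hz * t + phases[2])
        )
        artifacts = np.zeros(n)
        n_art = rng.poisson(prof.motion_rate_hz * dur) if prof.motion_rate_hz > 0 else 0
        for _ in range(n_art):
            i0 = rng.integers(0, n)
            if rng.random() < 0.5 and prof.spike_amp > 0:
                amp = rng.uniform(0.5, 1.5) * prof.spike_amp * rng.choice([-1, 1])
                artifacts[i0 : i0 + 2] += amp
                truth["artifacts"].append({"channel": c + 1, "kind": "spike", "t": float(t[i0]), "amp": float(amp)})
            elif prof.step_amp > 0:
                amp = rng.uniform(0.5, 1.5) * prof.step_amp * rng.choice([-1, 1])
                artifacts[i0:] += amp
                truth["artifacts"].append({"channel": c + 1, "kind": "step", "t": float(t[i0]), "amp": float(amp)})
        white_o = rng.normal(0, prof.white_sd, n)
        white_r = rng.normal(0, prof.white_sd * 0.5, n)

        hbo[c] = evoked_hbo + drift + osc + artifacts + white_o
        hbr[c] = evoked_hbr - 0.3 * drift - 0.3 * osc + white_r
    rec = HemoRecording(fs=fs, t=t.copy(), hbo=hbo, hbr=hbr)
    return rec, truth


# ---------------------------------------------------------------------------
# session assembly
# ---------------------------------------------------------------------------

def session_plan(spec: SessionSpec) -> pd.DataFrame:
    """Seeded random scenario ordering for every participant and segment."""
    rng = np.random.default_rng(spec.seed)
    rows = []
    for p in range(1, spec.n_participants + 1):
        types = [s for s, k in spec.scenario_mix.items() for _ in range(k)]
        order = rng.permutation(len(types))
        types = [types[i] for i in order]
        for i, styp in enumerate(types):
            seg, slot = divmod(i, spec.scenarios_per_segment)
            rows.append(
                {
                    "participant": p,
                    "segment": seg + 1,
                    "slot": slot + 1,
                    "scenario_id": f"p{p:02d}s{seg + 1:02d}n{slot + 1:02d}",
                    "type": styp,
                }
            )
    return pd.DataFrame(rows)


def gen_segment(
    types: list[str],
    spec: SessionSpec,
    seed: int,
    params: RiskParams | None = None,
) -> tuple[pd.DataFrame, RiskSeries, HemoRecording, pd.DataFrame, dict]:
    """One continuous segment: lead-in plus a block per scenario.

    Returns (trajectory, risk series, recording, event table, ground truth).
    Event rows give each block's type, time span and event onset.
    """
    params = params or RiskParams()
    rng = np.random.default_rng(seed)
    dt = 1.0 / spec.fs
    blocks = []
    events = []
    t_off, x_off = 0.0, 0.0

    lead = ScenarioSpec.default("other")
    lead = replace(lead, total_s=max(dt, spec.lead_in_s), onset=min(1.0, spec.lead_in_s / 2),
                   ego_speed=spec.ego_speed, dt=dt)
    seq = [("lead_in", lead)] + [
        (styp, replace(ScenarioSpec.default(styp), ego_speed=spec.ego_speed, dt=dt))
        for styp in types
    ]
    for j, (name, sc) in enumerate(seq):
        sub_seed = int(rng.integers(0, 2**31 - 1))
        traj = gen_trajectory(sc, seed=None if name == "lead_in" else sub_seed, params=params)
        tb = traj.copy()
        tb["t"] = tb["t"] + t_off
        for col in ("ego_x", "obj_x"):
            tb[col] = tb[col] + x_off
        if name != "lead_in":
            events.append(
                {
                    "type": name,
                    "block_start": t_off,
                    "block_end": t_off + sc.total_s,
                    "event_onset": t_off + sc.onset,
                }
            )
        last = j == len(seq) - 1
        # drop the duplicate boundary sample between consecutive blocks
        blocks.append(tb if last else tb.iloc[:-1])
        x_off = float(tb["ego_x"].iloc[-1])
        if not last:
            t_off = float(tb["t"].iloc[-1])

    traj = pd.concat(blocks, ignore_index=True)
    rs = risk_series(traj, params)
    rec, truth = gen_fnirs(rs, spec, seed=int(rng.integers(0, 2**31 - 1)))
    ev_df = pd.DataFrame(events)
    rec.events = [(r["event_onset"], r["type"], f"e{i}") for i, r in ev_df.iterrows()]
    return traj, rs, rec, ev_df, truth


def sample_accounting(
    totals: dict[str, int] | None = None,
    rejections: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Valid-sample bookkeeping: totals minus equipment-failure rejections."""
    totals = STUDY_TOTALS if totals is None else totals
    rejections = STUDY_REJECTIONS if rejections is None else rejections
    rows = []
    for k in totals:
        rej = rejections.get(k, 0)
        if rej < 0 or rej > totals[k]:
            raise ValueError(f"invalid rejection count for {k}")
        rows.append({"type": k, "total": totals[k], "rejected": rej, "valid": totals[k] - rej})
    return pd.DataFrame(rows)


def gen_session(
    spec: SessionSpec,
    out_dir: str | Path,
    participants: list[int] | None = None,
    segments: list[int] | None = None,
    rejection_rates: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Write a session bundle (trajectory + fNIRS CSVs, manifest) to disk.

    ``participants``/``segments`` restrict generation to a subset of the
    plan (the full default plan is 20×12 segments).  Returns the manifest.
    """
    from .io import write_fnirs_csv, write_trajectory_csv

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    plan = session_plan(spec)
    if participants is not None:
        plan = plan[plan["participant"].isin(participants)]
    if segments is not None:
        plan = plan[plan["segment"].isin(segments)]

    rng = np.random.default_rng(spec.seed + 1)
    manifest_rows = []
    for (p, seg), g in plan.groupby(["participant", "segment"], sort=True):
        types = g.sort_values("slot")["type"].tolist()
        event_types = [s for s in types if s != "other"]
        seg_seed = int(np.random.default_rng((spec.seed, p, seg)).integers(0, 2**31 - 1))
        traj, rs, rec, ev_df, _ = gen_segment(event_types, spec, seg_seed)
        stem = f"p{p:02d}_seg{seg:02d}"
        write_trajectory_csv(traj, out / f"{stem}_trajectory.csv")
        write_fnirs_csv(rec, out / f"{stem}_fnirs.csv")
        for i, row in ev_df.iterrows():
            rej = (
                rng.random() < rejection_rates.get(row["type"], 0.0)
                if rejection_rates
                else False
            )
            manifest_rows.append(
                {
                    "participant": p,
                    "segment": seg,
                    "scenario_id": f"p{p:02d}s{seg:02d}e{i + 1:02d}",
                    "type": row["type"],
                    "block_start": row["block_start"],
                    "block_end": row["block_end"],
                    "event_onset": row["event_onset"],
                    "trajectory": f"{stem}_trajectory.csv",
                    "fnirs": f"{stem}_fnirs.csv",
                    "rejected_flag": bool(rej),
                }
            )
    manifest = pd.DataFrame(manifest_rows)
    manifest.to_csv(out / "manifest.csv", index=False)
    return manifest
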