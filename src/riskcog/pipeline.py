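"""End-to-end orchestration: simulate → risk → preprocess → features → stats.

The stages follow the flow of the analysis: the risk field is evaluated
along each trajectory and thresholded into low/high-risk episodes; ΔCOE is
computed from the cleaned hemoglobin channels; each (channel, episode)
segment is reduced to mean-value and K-SVD features; and channel-wise
contrasts plus a Gaussian GLM link the cortical response to the risk
field.  Reports are emitted as a per-scenario risk summary (M_L, M_H,
D_LH, p, episode duration) and a per-channel statistic grid for both
feature methods, together with a run manifest of file hashes and the
effective configuration.
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import feature_extract as fx
from . import risk_stats as rstats
from .config import dump_config, load_config
from .fnirs_preprocess import CoeSeries, preprocess
from .risk_field import (
    DURATIONS_METHODS,
    DURATIONS_TABLE1,
    RiskParams,
    RiskSeries,
    mean_risk,
    risk_series,
    segment_episodes,
    span_mask,
)
from .scenario_synth import KMH_TO_MS, NoiseProfile, SessionSpec, gen_segment, session_plan

__all__ = [
    "validate_inputs",
    "extract_episode_segments",
    "attach_ksvd_features",
    "risk_summary_table",
    "channel_stat_table",
    "glm_risk_coe",
    "run_pipeline",
]


# ---------------------------------------------------------------------------
# input validation
# ---------------------------------------------------------------------------

def validate_inputs(paths: list[str | Path], n_channels: int = 8) -> list[dict]:
    """Schema/monotonicity/uniformity checks; returns a list of issues."""
    from .io import TRAJECTORY_COLUMNS, infer_fs

    issues: list[dict] = []
    for path in paths:
        path = Path(path)
        try:
            df = pd.read_csv(path)
        except Exception as exc:  # noqa: BLE001 - any parse failure is an issue
            issues.append({"file": str(path), "issue": f"unreadable: {exc}"})
            continue
        if "t" not in df.columns:
            issues.append({"file": str(path), "issue": "missing column t"})
            continue
        dt = np.diff(df["t"].to_numpy(float))
        bad = np.flatnonzero(dt <= 0)
        if bad.size:
            issues.append(
                {"file": str(path), "issue": "non-monotone time", "row": int(bad[0]) + 1}
            )
        if {"ego_x", "obj_x"} <= set(df.columns):
            missing = [
                c for c in TRAJECTORY_COLUMNS if c not in df.columns and c != "obj_mass"
            ]
            if missing:
                issues.append(
                    {"file": str(path), "issue": f"missing trajectory columns {missing}"}
                )
        elif any(c.startswith("hbo_") for c in df.columns):
            n_hbo = sum(c.startswith("hbo_") for c in df.columns)
            n_hbr = sum(c.startswith("hbr_") for c in df.columns)
            if n_hbo != n_channels or n_hbr != n_channels:
                issues.append(
                    {
                        "file": str(path),
                        "issue": f"channel count {n_hbo}/{n_hbr} hbo/hbr, expected {n_channels}",
                    }
                )
            if bad.size == 0:
                try:
                    infer_fs(df["t"].to_numpy(float))
                except ValueError as exc:
                    issues.append({"file": str(path), "issue": str(exc)})
        else:
            issues.append({"file": str(path), "issue": "unrecognised schema"})
    return issues


# ---------------------------------------------------------------------------
# episode feature extraction
# ---------------------------------------------------------------------------

def extract_episode_segments(
    coe: CoeSeries,
    rs: RiskSeries,
    events: pd.DataFrame,
    durations: dict[str, float] | None = None,
    duration_mapping: str = "table1",
    segment_points: int = 64,
    participant: int = 1,
) -> pd.DataFrame:
    """Per (event, channel, risk class): episode span, mean feature, segment.

    ``events`` rows need ``type``, ``block_start``, ``block_end``.  Events
    whose block shows no threshold crossing are skipped with a note row.
    """
    rows = []
    for i, ev in events.iterrows():
        m = span_mask(rs.t, (ev["block_start"], ev["block_end"]))
        sub = RiskSeries(rs.t[m], rs.ev[m], rs.threshold)
        try:
            pair = segment_episodes(sub, ev["type"], durations, duration_mapping)
        except ValueError:
            continue
        for risk_class, span in (("low", pair.low_span), ("high", pair.high_span)):
            cmask = span_mask(coe.t, span)
            if cmask.sum() < 2:
                continue
            risk_mean = mean_risk(rs, span)
            for c in range(coe.n_channels):
                seg = coe.data[c, cmask]
                rows.append(
                    {
                        "participant": participant,
                        "scenario_id": ev.get("scenario_id", f"e{i}"),
                        "type": ev["type"],
                        "channel": c + 1,
                        "risk_class": risk_class,
                        "mean": fx.mean_feature(seg),
                        "risk_mean": risk_mean,
                        "segment": fx.resample_segment(seg, segment_points),
                        "truncated": pair.low_truncated or pair.high_truncated,
                    }
                )
    return pd.DataFrame(rows)


def attach_ksvd_features(
    segments: pd.DataFrame,
    K: int = 4,
    T0: int = 1,
    n_iter: int = 15,
    seed: int = 0,
    canonicalize: bool = True,
) -> pd.DataFrame:
    """Learn per-(scenario type, channel) dictionaries and code every segment.

    Dictionaries are learned on the pooled low+high segments of one
    scenario type and channel; the scalar feature is the single-atom OMP
    coefficient.
    """
    import zlib

    out = segments.copy()
    out["ksvd"] = np.nan
    for (styp, ch), g in segments.groupby(["type", "channel"], sort=True):
        X = np.vstack(g["segment"].to_numpy())
        sub_seed = (seed * 1000003 + zlib.crc32(f"{styp}:{int(ch)}".encode())) % (2**31)
        d, _ = fx.ksvd_learn(
            X, K=min(K, X.shape[0]), T0=T0, n_iter=n_iter, seed=sub_seed,
            canonicalize=canonicalize,
        )
        vals = [fx.ksvd_feature(row, d)[0] for row in X]
        out.loc[g.index, "ksvd"] = vals
    return out


def features_long(segments: pd.DataFrame) -> pd.DataFrame:
    """Tidy features table: one row per (episode, channel, method)."""
    value_cols = [c for c in ("mean", "ksvd") if c in segments.columns]
    out = segments.melt(
        id_vars=["participant", "scenario_id", "type", "channel", "risk_class"],
        value_vars=value_cols,
        var_name="method",
        value_name="value",
    ).dropna(subset=["value"])
    out = out.rename(columns={"type": "scenario_type"})
    return out[
        ["participant", "scenario_type", "scenario_id", "channel", "risk_class", "method", "value"]
    ]


# ---------------------------------------------------------------------------
# statistics tables
# ---------------------------------------------------------------------------

def risk_summary_table(
    segments: pd.DataFrame,
    durations: dict[str, float] | None = None,
    duration_mapping: str = "table1",
) -> pd.DataFrame:
    """Per-scenario risk-field summary: M_L, M_H, D_LH, p, episode duration."""
    if durations is None:
        durations = DURATIONS_TABLE1 if duration_mapping == "table1" else DURATIONS_METHODS
    per_ep = segments.drop_duplicates(["scenario_id", "risk_class"])[
        ["scenario_id", "type", "risk_class", "risk_mean"]
    ]
    rows = []
    for styp, g in per_ep.groupby("type", sort=True):
        wide = g.pivot(index="scenario_id", columns="risk_class", values="risk_mean").dropna()
        if wide.empty:
            continue
        res = rstats.risk_mean_test(wide["low"].to_numpy(), wide["high"].to_numpy())
        rows.append(
            {
                "scenario": styp,
                "M_L": res.m_low,
                "M_H": res.m_high,
                "D_LH": res.d_lh,
                "p": res.contrast.p_value,
                "t_episode_s": durations.get(styp, np.nan),
                "n": len(wide),
            }
        )
    return pd.DataFrame(rows)


def channel_stat_table(
    features: pd.DataFrame,
    method: str = "mean",
    mode: str = "paired",
    statistic: str = "t",
    p_adjust: str = "none",
) -> pd.DataFrame:
    """Per-channel contrast grid (rows: scenario type; columns: channels).

    ``statistic`` is ``t`` (episode t-value) or ``z`` (Wilcoxon signed-rank).
    """
    f = features[features["method"] == method]
    rows = []
    for styp, g in f.groupby("scenario_type", sort=True):
        row: dict = {"scenario": styp, "method": method}
        pvals = []
        for ch, gc in g.groupby("channel", sort=True):
            wide = gc.pivot(index="scenario_id", columns="risk_class", values="value").dropna()
            low, high = wide["low"].to_numpy(), wide["high"].to_numpy()
            if statistic == "t":
                res = rstats.episode_tvalue(low, high, mode=mode, channel=int(ch))
            else:
                res = rstats.wilcoxon_z(low, high)
            row[f"ch{int(ch)}"] = res.statistic
            row[f"p{int(ch)}"] = res.p_value
            pvals.append(res.p_value)
        if p_adjust != "none" and pvals:
            adj = rstats.adjust_pvalues(pvals, p_adjust)
            for j, ch in enumerate(sorted(g["channel"].unique())):
                row[f"p{int(ch)}_adj"] = adj[j]
        rows.append(row)
    return pd.DataFrame(rows)


def channel_stat_long(
    features: pd.DataFrame,
    methods: tuple[str, ...] = ("mean", "ksvd"),
    mode: str = "paired",
) -> pd.DataFrame:
    """Tidy stats report: one row per (scenario, channel, method)."""
    rows = []
    for method in methods:
        f = features[features["method"] == method]
        for (styp, ch), g in f.groupby(["scenario_type", "channel"], sort=True):
            wide = g.pivot(index="scenario_id", columns="risk_class", values="value").dropna()
            res = rstats.episode_tvalue(
                wide["low"].to_numpy(), wide["high"].to_numpy(), mode=mode, channel=int(ch)
            )
            rows.append(
                {
                    "scenario": styp,
                    "channel": int(ch),
                    "method": method,
                    "statistic": res.statistic,
                    "p": res.p_value,
                    "n_low": res.n_low,
                    "n_high": res.n_high,
                }
            )
    return pd.DataFrame(rows)


def glm_risk_coe(
    segments: pd.DataFrame,
    channel: int = 8,
    direction: str = "coe_on_risk",
    scenario_type: str | None = None,
) -> rstats.GlmFit:
    """Gaussian GLM linking episode-mean ΔCOE and episode-mean risk field.

    ``direction``: ``coe_on_risk`` (ΔCOE ~ intercept + risk),
    ``risk_on_coe`` (risk ~ intercept + ΔCOE) or ``intercept_only``
    (risk ~ intercept, the form of the printed parameter table).
    """
    g = segments[segments["channel"] == channel]
    if scenario_type is not None:
        g = g[g["type"] == scenario_type]
    coe_vals = g["mean"].to_numpy(float)
    risk_vals = g["risk_mean"].to_numpy(float)
    ones = np.ones_like(risk_vals)
    if direction == "coe_on_risk":
        return rstats.glm_gaussian(
            coe_vals, np.column_stack([ones, risk_vals]),
            names=["(Intercept)", "risk_field"], model="coe ~ risk_field",
        )
    if direction == "risk_on_coe":
        return rstats.glm_gaussian(
            risk_vals, np.column_stack([ones, coe_vals]),
            names=["(Intercept)", "coe"], model="risk_field ~ coe",
        )
    if direction == "intercept_only":
        return rstats.glm_gaussian(
            risk_vals, ones[:, None], names=["(Intercept)"], model="risk_field ~ 1",
        )
    raise ValueError(f"unknown GLM direction {direction!r}")


# ---------------------------------------------------------------------------
# full run
# ---------------------------------------------------------------------------

def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _session_spec_from_config(cfg: dict) -> SessionSpec:
    s = cfg["synth"]
    return SessionSpec(
        n_participants=s["n_participants"],
        n_segments=s["n_segments"],
        scenarios_per_segment=s["scenarios_per_segment"],
        scenario_mix=dict(s["scenario_mix"]),
        lead_in_m=s["lead_in_m"],
        ego_speed=s["ego_speed_kmh"] * KMH_TO_MS,
        fs=s["fs"],
        n_channels=s["n_channels"],
        activation=tuple(s["activation"]),
        coupling_sign=int(s["coupling_sign"]),
        noise=NoiseProfile(),
        seed=cfg["seed"],
    )


def run_pipeline(config: dict | str | Path | None = None, out_dir: str | Path = "out") -> dict:
    """Run simulate → risk → preprocess → features → stats and write reports.

    Returns the run manifest (also written as ``manifest.json``).
    """
    cfg = config if isinstance(config, dict) else load_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_path = out / "run_log.jsonl"
    log_fh = open(log_path, "w")

    def log(stage: str, **info) -> None:
        log_fh.write(json.dumps({"stage": stage, **info}) + "\n")

    manifest: dict = {"stages": [], "config": cfg, "complete": False}
    try:
        params = RiskParams(
            G=cfg["risk"]["G"], k1=cfg["risk"]["k1"], k2=cfg["risk"]["k2"],
            R2=cfg["risk"]["R2"], M2=cfg["risk"]["M2"], threshold=cfg["risk"]["threshold"],
        )
        spec = _session_spec_from_config(cfg)
        plan = session_plan(spec)
        log("simulate", participants=spec.n_participants, segments=spec.n_segments,
            scenarios_per_segment=spec.scenarios_per_segment, seed=cfg["seed"])

        all_segments = []
        for (p, seg), g in plan.groupby(["participant", "segment"], sort=True):
            types = [s for s in g.sort_values("slot")["type"] if s != "other"]
            seg_seed = int(np.random.default_rng((cfg["seed"], p, seg)).integers(0, 2**31 - 1))
            traj, rs, rec, ev_df, _ = gen_segment(types, spec, seg_seed, params)
            coe = preprocess(
                rec,
                detrend_order=cfg["pre"]["detrend_order"],
                tddr_enabled=cfg["pre"]["tddr"]["enabled"],
                tddr_split_hz=cfg["pre"]["tddr"]["split_hz"],
                tddr_biweight_c=cfg["pre"]["tddr"]["biweight_c"],
                tddr_tol=cfg["pre"]["tddr"]["tol"],
                tddr_max_iter=cfg["pre"]["tddr"]["max_iter"],
                band_lo=cfg["pre"]["band"]["lo"],
                band_hi=cfg["pre"]["band"]["hi"],
                band_order=cfg["pre"]["band"]["order"],
                band_family=cfg["pre"]["band"]["family"],
                movavg_window_s=cfg["pre"]["movavg_window_s"],
            )
            segs = extract_episode_segments(
                coe, rs, ev_df,
                durations=cfg["risk"]["durations"],
                duration_mapping=cfg["risk"]["duration_mapping"],
                segment_points=cfg["feat"]["segment_points"],
                participant=p,
            )
            segs["scenario_id"] = [f"p{p:02d}s{seg:02d}_{sid}" for sid in segs["scenario_id"]]
            all_segments.append(segs)
            log("segment", participant=int(p), segment=int(seg), events=len(ev_df),
                episodes=len(segs))
        segments = pd.concat(all_segments, ignore_index=True)
        segments = attach_ksvd_features(
            segments,
            K=cfg["feat"]["ksvd_k"], T0=cfg["feat"]["ksvd_t0"],
            n_iter=cfg["feat"]["ksvd_iters"], seed=cfg["seed"],
            canonicalize=cfg["feat"]["canonicalize"],
        )
        log("features", rows=len(segments))

        feats = features_long(segments)
        feats.to_csv(out / "features.csv", index=False)
        risk_tab = risk_summary_table(
            segments, cfg["risk"]["durations"], cfg["risk"]["duration_mapping"]
        )
        risk_tab.to_csv(out / "risk_summary.csv", index=False)
        grids = []
        for method in ("mean", "ksvd"):
            grids.append(
                channel_stat_table(
                    feats, method=method, mode=cfg["stats"]["t_mode"],
                    p_adjust=cfg["stats"]["p_adjust"],
                )
            )
        pd.concat(grids, ignore_index=True).to_csv(out / "channel_stats.csv", index=False)
        channel_stat_long(feats, mode=cfg["stats"]["t_mode"]).to_csv(
            out / "stats_report.csv", index=False
        )
        fit = glm_risk_coe(segments, direction=cfg["stats"]["glm_direction"])
        fit.summary_frame().to_csv(out / "glm_summary.csv", index=False)
        with open(out / "glm_summary.json", "w") as fh:
            json.dump(
                {
                    "model": fit.model,
                    "params": dict(zip(fit.names, fit.params.tolist())),
                    "se": dict(zip(fit.names, fit.se.tolist())),
                    "scale": fit.scale,
                    "n": fit.n,
                },
                fh,
                indent=2,
            )
        log("stats", glm_model=fit.model, glm_params=fit.params.tolist())

        dump_config(cfg, out / "effective_config.toml")
        outputs = [
            "features.csv", "risk_summary.csv", "channel_stats.csv", "stats_report.csv",
            "glm_summary.csv", "glm_summary.json", "effective_config.toml",
        ]
        manifest["outputs"] = {name: _sha256(out / name) for name in outputs}
        manifest["complete"] = True
        manifest["version"] = _version()
        manifest["timestamp"] = time.strftime("%Y-%m-%dT%H:%M:%S")
    except Exception as exc:
        manifest["error"] = f"{type(exc).__name__}: {exc}"
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, default=str)
        log_fh.close()
        raise
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    log_fh.close()
    return manifest


def _version() -> str:
    from importlib.metadata import version

    try:
        return version("riskcog")
    except Exception:  # noqa: BLE001
        return "unknown"
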