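"""Run configuration: defaults, TOML loading, strict merging, echoing.

A single TOML file configures every stage; unknown keys are rejected so a
typo cannot silently fall back to a default.  The effective (merged)
configuration is written next to the outputs of every run.
"""

from __future__ import annotations

import copy
from pathlib import Path

DEFAULTS: dict = {
    "seed": 0,
    "log_level": "INFO",
    "risk": {
        "G": 0.001,
        "k1": 1.0,
        "k2": 0.05,
        "R2": 1.0,
        "M2": 1705.0,
        "threshold": 0.05,
        "durations": {"saeb": 20.0, "lci": 15.0, "rci": 10.0, "rpcr": 6.0},
        "duration_mapping": "table1",
    },
    "pre": {
        "detrend_order": 2,
        "tddr": {
            "enabled": True,
            "split_hz": 0.5,
            "biweight_c": 4.685,
            "tol": 1e-6,
            "max_iter": 50,
        },
        "band": {"lo": 0.015, "hi": 0.08, "order": 4, "family": "butter"},
        "movavg_window_s": 0.0,
    },
    "feat": {
        "ksvd_k": 4,
        "ksvd_t0": 1,
        "ksvd_iters": 15,
        "segment_points": 64,
        "canonicalize": True,
    },
    "stats": {
        "t_mode": "paired",
        "p_adjust": "none",
        "glm_direction": "coe_on_risk",
    },
    "synth": {
        "n_participants": 1,
        "n_segments": 1,
        "scenarios_per_segment": 12,
        "scenario_mix": {"saeb": 3, "lci": 3, "rci": 3, "rpcr": 3, "other": 0},
        "lead_in_m": 200.0,
        "ego_speed_kmh": 70.0,
        "fs": 10.0,
        "n_channels": 8,
        "activation": [0.04, 0.04, 0.04, 0.04, 0.04, 0.04, 0.04, 0.12],
        "coupling_sign": 1,
    },
}


def _merge(base: dict, override: dict, path: str = "") -> dict:
    out = copy.deepcopy(base)
    for key, val in override.items():
        here = f"{path}.{key}" if path else key
        if key not in base:
            raise KeyError(f"unknown config key: {here}")
        if isinstance(base[key], dict) and key != "scenario_mix":
            if not isinstance(val, dict):
                raise TypeError(f"config key {here} must be a table")
            out[key] = _merge(base[key], val, here)
        else:
            out[key] = val
    return out


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> dict:
    """Defaults merged with a TOML file and/or an override dict."""
    import tomllib

    cfg = copy.deepcopy(DEFAULTS)
    if path is not None:
        with open(path, "rb") as fh:
            cfg = _merge(cfg, tomllib.load(fh))
    if overrides:
        cfg = _merge(cfg, overrides)
    return cfg


def _toml_value(v) -> str:
    if isinstance(v, bool):
        return "true" if v else "false"
    if isinstance(v, str):
        return f'"{v}"'
    if isinstance(v, (list, tuple)):
        return "[" + ", ".join(_toml_value(x) for x in v) + "]"
    return repr(v)


def dump_config(cfg: dict, path: str | Path) -> None:
    """Write the effective configuration as TOML."""

    def _emit(d: dict, prefix: str, lines: list[str]) -> None:
        scalars = {k: v for k, v in d.items() if not isinstance(v, dict)}
        tables = {k: v for k, v in d.items() if isinstance(v, dict)}
        if prefix:
            lines.append(f"[{prefix}]")
        for k, v in scalars.items():
            lines.append(f"{k} = {_toml_value(v)}")
        if scalars or not prefix:
            lines.append("")
        for k, v in tables.items():
            _emit(v, f"{prefix}.{k}" if prefix else k, lines)

    lines: list[str] = []
    _emit(cfg, "", lines)
    Path(path).write_text("\n".join(lines).rstrip() + "\n")
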