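import numpy as np
import pandas as pd
import pytest

from riskcog.scenario_synth import SessionSpec, gen_segment


def small_session_spec(seed: int = 0, activation=(0, 0, 0, 0, 0, 0, 0, 0.12)) -> SessionSpec:
    """One participant, one segment of 12 events (3 per scenario type)."""
    return SessionSpec(
        n_participants=1,
        n_segments=1,
        scenarios_per_segment=12,
        scenario_mix={"saeb": 3, "lci": 3, "rci": 3, "rpcr": 3, "other": 0},
        activation=activation,
        lead_in_m=300.0,
        seed=seed,
    )


@pytest.fixture(scope="session")
def segment_bundle():
    """One simulated segment with trajectory, risk, recording and events."""
    spec = small_session_spec(seed=7)
    traj, rs, rec, events, truth = gen_segment(
        ["saeb", "lci", "rci", "rpcr"] * 3, spec, seed=123
    )
    return {"spec": spec, "traj": traj, "rs": rs, "rec": rec, "events": events, "truth": truth}


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def ramp_series():
    """Risk magnitudes ramping 0 → 0.2 over 100 s at 10 Hz."""
    t = np.arange(0.0, 100.0, 0.1)
    ev = np.linspace(0.0, 0.2, t.size)
    return t, ev
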