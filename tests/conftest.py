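import numpy as np
import pandas as pd
import pytest

import herdmove as hm


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_table():
    """Two agents, 20 s: one walks east at 1 m/s, one stands heading north."""
    rows = []
    for t in range(20):
        rows.append({"time_s": t, "individual_id": "walker", "x_m": float(t),
                     "y_m": 0.0, "heading_rad": 0.0, "day_id": "d0"})
        rows.append({"time_s": t, "individual_id": "stander", "x_m": 5.0,
                     "y_m": 3.0, "heading_rad": np.pi / 2, "day_id": "d0"})
    return hm.TrajectoryTable.from_frame(pd.DataFrame(rows))


@pytest.fixture(scope="session")
def copying_run():
    """One simulated copying departure plus its ground truth."""
    return hm.run_simulation(hm.AgentConfig(mechanism="copying", seed=7))


@pytest.fixture(scope="session")
def all_vote_run():
    return hm.run_simulation(hm.AgentConfig(mechanism="all_vote", seed=7))


@pytest.fixture(scope="session")
def copying_dataset():
    """Small multi-day copying dataset with sensor noise and ground truth."""
    cfg = hm.DatasetConfig(agent=hm.AgentConfig(mechanism="copying"),
                           n_days=2, events_per_day=4, seed=42)
    return hm.simulate_dataset(cfg)


def synthetic_group_series(n_steps=600, t_dep=300, day_id="d0", seed=0,
                           pre_speed=0.03, post_speed=1.0,
                           pre_heading=1.0, post_heading=2.2,
                           speed_noise=0.01, heading_noise=0.02,
                           blip=None):
    """Hand-built group series with one departure step in speed and heading.

    ``blip=(t0, t1, value)`` injects a movement burst into the speed trace.
    """
    g = np.random.default_rng(seed)
    t = np.arange(n_steps)
    speed = np.where(t < t_dep, pre_speed, post_speed) + g.normal(0, speed_noise, n_steps)
    speed = np.clip(speed, 0, None)
    if blip is not None:
        b0, b1, v = blip
        speed[b0:b1] = v
    heading = np.where(t < t_dep, pre_heading, post_heading) + g.normal(0, heading_noise, n_steps)
    cx = np.concatenate([[0.0], np.cumsum(speed[:-1] * np.cos(heading[:-1]))])
    cy = np.concatenate([[0.0], np.cumsum(speed[:-1] * np.sin(heading[:-1]))])
    df = pd.DataFrame({
        "time_s": t,
        "day_id": day_id,
        "centroid_x_m": cx,
        "centroid_y_m": cy,
        "mean_heading_rad": np.mod(heading, 2 * np.pi),
        "mean_speed_mps": speed,
        "polar_order": np.full(n_steps, 0.9),
        "n_members": 10,
    })
    return hm.GroupSeries(df)
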