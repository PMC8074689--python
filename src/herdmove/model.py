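"""Agent-based simulator of collective departures.

Three decision mechanisms are supported:

* ``copying`` — agents are stationary with random headings until their
  movement-initiation time (drawn per agent from a normal distribution),
  then move at ``speed_sigma`` units/s while turning toward the circular
  mean of their neighbours' headings, with per-step turns clamped at
  ``max_turn_rad`` (default 0.75 rad). By default one member (the
  "informed initiator") travels toward a goal direction once moving and the
  rest respond to it through the ordinary averaging rule, so the departure
  direction is decoupled from the group's initial mean heading; set
  ``informed_initiator=False`` for pure leaderless averaging, where the
  consensus direction is emergent.
* ``all_vote`` — before moving, every agent additionally turns (while
  stationary) toward a personal vote direction drawn once from a von Mises
  distribution centred on the event's target direction; vote-initiation
  times precede movement-initiation times in expectation, so the group
  aligns before it accelerates.
* ``sub_vote`` — only a fraction of agents vote; the rest behave exactly as
  copying agents.

Updates are synchronous (turn targets are computed from the previous step's
headings) and fully deterministic under a fixed seed. Speeds take only the
values ``{0, speed_sigma}``.

The module doubles as the pipeline's synthetic-data source:
:func:`run_simulation` produces a single departure with ground truth,
:func:`simulate_dataset` chains events into multi-day recordings with sensor
noise, and :func:`simulate_predictions` generates pooled CorrMax / Sym
prediction distributions by resampling simulated decision events.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .detection import DecisionEvent, departure_direction
from .io import RunConfig, TrajectoryTable, wrap_angle
from .kinematics import circular_mean, group_series, resultant_length
from .metrics import BootstrapSummary, cross_correlate, decision_curve

MECHANISMS = ("copying", "all_vote", "sub_vote")

#: ground-truth departure-direction window relative to departure, matching
#: the detection stage's settled moving-phase window
_DIR_WINDOW = (7, 17)


@dataclass
class AgentConfig:
    """All simulator parameters. Every value is overridable; the defaults
    produce a clear stationary phase, a sigmoid speed onset around
    ``move_init_mean_s``, and (for voting mechanisms) heading consensus that
    precedes movement by ``move_init_mean_s - vote_init_mean_s`` seconds."""

    n_agents: int = 10
    speed_sigma: float = 1.0
    max_turn_rad: float = 0.75
    mechanism: str = "copying"
    vote_fraction: float = 0.5  # only used by sub_vote
    kappa: float = 4.0
    move_init_mean_s: float = 150.0
    move_init_sd_s: float = 3.0
    vote_init_mean_s: float = 130.0
    vote_init_sd_s: float = 3.0
    topology_k: int | None = None  # None -> all neighbours
    rest_turn_sd_rad: float = 0.0  # stationary heading wobble per step
    informed_initiator: bool = True  # one member holds a goal direction
    init_pos_sd: float = 2.0
    #: concentration of initial headings about the rest direction; resting
    #: groups pre-orient loosely, not uniformly (0 = uniform)
    init_heading_kappa: float = 1.0
    #: centre of the initial heading distribution; None -> target direction
    rest_direction_rad: float | None = None
    target_direction_rad: float = 0.0
    n_steps: int = 300
    seed: int | None = None

    def __post_init__(self):
        if self.mechanism not in MECHANISMS:
            raise ValueError(f"mechanism must be one of {MECHANISMS}")
        if self.n_agents < 2:
            raise ValueError("n_agents must be >= 2")
        if not 0.0 < self.vote_fraction <= 1.0:
            raise ValueError("vote_fraction must be in (0, 1]")
        if self.max_turn_rad <= 0:
            raise ValueError("max_turn_rad must be positive")
        if self.kappa < 0:
            raise ValueError("kappa must be >= 0")
        if self.speed_sigma <= 0:
            raise ValueError("speed_sigma must be positive")
        if self.init_pos_sd < 0:
            raise ValueError("init_pos_sd must be >= 0")
        if self.mechanism != "copying" and self.vote_init_mean_s >= self.move_init_mean_s:
            raise ValueError("vote initiation must precede movement initiation "
                             "in expectation under voting mechanisms")

    def replace(self, **kwargs) -> "AgentConfig":
        return dataclasses.replace(self, **kwargs)


@dataclass
class AgentStates:
    """Array-backed state for all agents at one time step."""

    x: np.ndarray
    y: np.ndarray
    heading: np.ndarray
    move_init_time: np.ndarray
    vote_init_time: np.ndarray
    vote_angle: np.ndarray
    is_voter: np.ndarray
    moving: np.ndarray  # has_initiated_move

    def copy(self) -> "AgentStates":
        return AgentStates(**{f.name: getattr(self, f.name).copy()
                              for f in dataclasses.fields(self)})

    def speeds(self, sigma: float) -> np.ndarray:
        return np.where(self.moving, sigma, 0.0)


def init_agents(config: AgentConfig, rng: np.random.Generator) -> AgentStates:
    """Initial cohesive, stationary cluster: positions normal per axis,
    headings uniform, per-agent initiation times drawn once up front."""
    n = config.n_agents
    x = rng.normal(0.0, config.init_pos_sd, n)
    y = rng.normal(0.0, config.init_pos_sd, n)
    if config.init_heading_kappa > 0:
        centre = (config.target_direction_rad if config.rest_direction_rad is None
                  else config.rest_direction_rad)
        heading = wrap_angle(rng.vonmises(centre, config.init_heading_kappa, n))
    else:
        heading = rng.uniform(0.0, 2 * np.pi, n)
    move_t = rng.normal(config.move_init_mean_s, config.move_init_sd_s, n)
    if config.mechanism == "copying":
        vote_t = np.full(n, np.inf)
        vote_angle = np.full(n, np.nan)
        is_voter = np.zeros(n, dtype=bool)
    else:
        vote_t = rng.normal(config.vote_init_mean_s, config.vote_init_sd_s, n)
        vote_angle = wrap_angle(rng.vonmises(config.target_direction_rad, config.kappa, n))
        if config.mechanism == "all_vote":
            is_voter = np.ones(n, dtype=bool)
        else:
            n_vote = max(1, round(config.vote_fraction * n))
            is_voter = np.zeros(n, dtype=bool)
            is_voter[rng.permutation(n)[:n_vote]] = True
        vote_t = np.where(is_voter, vote_t, np.inf)
    return AgentStates(x=x, y=y, heading=heading, move_init_time=move_t,
                       vote_init_time=vote_t, vote_angle=vote_angle,
                       is_voter=is_voter, moving=np.zeros(n, dtype=bool))


def turn_toward(current, target, max_turn: float):
    """Shortest-arc rotation of ``current`` toward ``target``, clamped at
    ``max_turn`` radians. Vectorized; result wrapped to [0, 2pi)."""
    current = np.asarray(current, dtype=float)
    delta = np.mod(np.asarray(target, dtype=float) - current + np.pi, 2 * np.pi) - np.pi
    step = np.clip(delta, -max_turn, max_turn)
    out = wrap_angle(current + step)
    if out.ndim == 0:
        return float(out)
    return out


def _neighbour_mean_headings(states: AgentStates, k: int | None) -> np.ndarray:
    """Circular mean of each agent's k nearest neighbours' headings
    (all others when k is None); self excluded. NaN when degenerate."""
    n = states.x.size
    cos_h, sin_h = np.cos(states.heading), np.sin(states.heading)
    if k is None or k >= n - 1:
        c = cos_h.sum() - cos_h
        s = sin_h.sum() - sin_h
    else:
        dx = states.x[:, None] - states.x[None, :]
        dy = states.y[:, None] - states.y[None, :]
        d2 = dx * dx + dy * dy
        np.fill_diagonal(d2, np.inf)
        nbr = np.argpartition(d2, k - 1, axis=1)[:, :k]
        c = cos_h[nbr].sum(axis=1)
        s = sin_h[nbr].sum(axis=1)
    mean = np.arctan2(s, c)
    mean[np.hypot(c, s) < 1e-12] = np.nan
    return mean


def step(states: AgentStates, config: AgentConfig, t: int,
         rng: np.random.Generator | None = None) -> AgentStates:
    """Advance all agents by one second (synchronous update).

    Agents past their movement-initiation time move at ``speed_sigma`` and
    turn toward their neighbours' circular mean heading; stationary voters
    past their vote-initiation time turn toward their vote angle; everyone
    else holds heading and position. All turns are clamped at
    ``max_turn_rad``.
    """
    new = states.copy()
    new.moving = t >= states.move_init_time
    nbr_mean = _neighbour_mean_headings(states, config.topology_k)

    target = np.full(states.heading.shape, np.nan)
    target[new.moving] = nbr_mean[new.moving]
    voting_now = (~new.moving) & states.is_voter & (t >= states.vote_init_time)
    target[voting_now] = states.vote_angle[voting_now]
    if config.informed_initiator:
        # one informed member (index 0 — a uniformly random agent, since all
        # draws are iid) travels toward its goal once moving; the others
        # respond to it through the ordinary averaging rule
        if new.moving[0]:
            target[0] = config.target_direction_rad

    has_target = np.isfinite(target)
    new.heading[has_target] = turn_toward(states.heading[has_target],
                                          target[has_target], config.max_turn_rad)
    if config.rest_turn_sd_rad > 0:
        # optional milling-about while resting: small random heading drift
        if rng is None:
            raise ValueError("rest_turn_sd_rad > 0 requires an rng")
        wobble = np.clip(rng.normal(0.0, config.rest_turn_sd_rad, new.heading.size),
                         -config.max_turn_rad, config.max_turn_rad)
        resting = ~new.moving & ~has_target
        new.heading[resting] = wrap_angle(states.heading[resting] + wobble[resting])
    turn = np.abs(np.mod(new.heading - states.heading + np.pi, 2 * np.pi) - np.pi)
    assert np.all(turn <= config.max_turn_rad + 1e-9), "turn-rate cap violated"

    new.x = states.x + np.where(new.moving, config.speed_sigma * np.cos(new.heading), 0.0)
    new.y = states.y + np.where(new.moving, config.speed_sigma * np.sin(new.heading), 0.0)
    return new


def _record(rows: list, states: AgentStates, t: int, day_id: str):
    n = states.x.size
    rows.append(pd.DataFrame({
        "time_s": t,
        "individual_id": [f"a{i:02d}" for i in range(n)],
        "x_m": states.x,
        "y_m": states.y,
        "heading_rad": wrap_angle(states.heading),
        "day_id": day_id,
    }))


def _truth(states: AgentStates, t_offset: int = 0) -> dict:
    move_t = states.move_init_time + t_offset
    return {
        "move_init_times_s": move_t.tolist(),
        "vote_init_times_s": [None if not np.isfinite(v) else v + t_offset
                              for v in states.vote_init_time],
        "t_departure_s": int(np.ceil(np.median(move_t))),
        "voters": states.is_voter.tolist(),
    }


def _rest_offset(rng: np.random.Generator) -> float:
    """Angular offset between a group's rest orientation and its next travel
    target: bounded away from 0 (so departures involve a real reorientation)
    and away from pi (so the turn is not pathologically slow)."""
    return float(rng.uniform(0.4, 1.2) * rng.choice([-1.0, 1.0]))


def run_simulation(config: AgentConfig) -> tuple[TrajectoryTable, dict]:
    """Simulate one collective departure at 1 Hz.

    Returns the trajectory table plus ground-truth metadata: per-agent
    initiation times, the true departure time (median movement initiation),
    and the realized departure direction (circular mean heading over the
    final 10 steps).
    """
    rng = np.random.default_rng(config.seed)
    states = init_agents(config, rng)
    truth = _truth(states)
    rows: list[pd.DataFrame] = []
    dep_headings = []
    t_dep = truth["t_departure_s"]
    for t in range(config.n_steps):
        _record(rows, states, t, "d0")
        # true departure direction: settled group heading just after onset
        if t_dep + _DIR_WINDOW[0] <= t < t_dep + _DIR_WINDOW[1]:
            dep_headings.append(states.heading.copy())
        states = step(states, config, t + 1, rng)
    table = TrajectoryTable.from_frame(pd.concat(rows, ignore_index=True))
    truth["direction_true_rad"] = circular_mean(np.concatenate(dep_headings))
    truth["mechanism"] = config.mechanism
    truth["target_direction_rad"] = config.target_direction_rad
    return table, truth


def add_sensor_noise(table: TrajectoryTable, gps_sd_m: float,
                     heading_sd_rad: float, seed=None) -> TrajectoryTable:
    """Inject independent Gaussian position jitter and wrapped-Gaussian
    heading jitter, emulating GPS + magnetometer noise."""
    if gps_sd_m < 0 or heading_sd_rad < 0:
        raise ValueError("noise standard deviations must be >= 0")
    rng = np.random.default_rng(seed)
    df = table.df.copy()
    n = len(df)
    if gps_sd_m > 0:
        df["x_m"] = df["x_m"] + rng.normal(0.0, gps_sd_m, n)
        df["y_m"] = df["y_m"] + rng.normal(0.0, gps_sd_m, n)
    if heading_sd_rad > 0:
        df["heading_rad"] = wrap_angle(df["heading_rad"] + rng.normal(0.0, heading_sd_rad, n))
    return TrajectoryTable.from_frame(df)


@dataclass
class DatasetConfig:
    """Multi-day, multi-event recording layout for end-to-end tests.

    Each event block runs the single-departure dynamics; between blocks the
    agents halt and relax toward fresh random rest headings, so each
    departure has its own direction and its own pre-departure stationary
    phase. Per-event target directions are drawn uniformly.
    """

    agent: AgentConfig = field(default_factory=AgentConfig)
    n_days: int = 7
    events_per_day: int = 5
    gps_sd_m: float = 0.05
    heading_sd_rad: float = 0.05
    rest_turn_sd_rad: float = 0.0  # optional milling-about while resting
    seed: int | None = None


def simulate_dataset(config: DatasetConfig) -> tuple[TrajectoryTable, list[dict]]:
    """Chain independent departure events into noisy multi-day recordings.

    Returns the noisy trajectory table and per-event ground truth (day,
    absolute departure time, realized direction).
    """
    rng = np.random.default_rng(config.seed)
    base = config.agent
    rows: list[pd.DataFrame] = []
    truths: list[dict] = []
    block = base.n_steps
    for d in range(config.n_days):
        day_id = f"d{d}"
        states = None
        for e in range(config.events_per_day):
            target = rng.uniform(0.0, 2 * np.pi)
            wobble = base.rest_turn_sd_rad or config.rest_turn_sd_rad
            cfg = base.replace(target_direction_rad=target,
                               rest_direction_rad=float(
                                   wrap_angle(target + _rest_offset(rng))),
                               rest_turn_sd_rad=wobble,
                               informed_initiator=True,
                               seed=int(rng.integers(2**31)))
            ev_rng = np.random.default_rng(cfg.seed)
            fresh = init_agents(cfg, ev_rng)
            if states is None:
                states = fresh
            else:
                # carry positions over; re-draw headings/initiations for the
                # new event, agents relax to rest headings during the pause
                fresh.x, fresh.y = states.x, states.y
                states = fresh
            offset = (d * config.events_per_day + e) * block  # absolute time
            t_dep_local = _truth(fresh)["t_departure_s"]
            dep_headings = []
            for t in range(block):
                _record(rows, states, offset + t, day_id)
                if t_dep_local + _DIR_WINDOW[0] <= t < t_dep_local + _DIR_WINDOW[1]:
                    dep_headings.append(states.heading.copy())
                states = step(states, cfg, t + 1, ev_rng)
            tru = _truth(fresh, t_offset=offset)
            tru.update({
                "day_id": day_id,
                "event_index": e,
                "mechanism": cfg.mechanism,
                "target_direction_rad": target,
                "direction_true_rad": circular_mean(np.concatenate(dep_headings)),
            })
            truths.append(tru)
            states = states.copy()
            states.moving[:] = False  # halt at block boundary
    table = TrajectoryTable.from_frame(pd.concat(rows, ignore_index=True))
    table = add_sensor_noise(table, config.gps_sd_m, config.heading_sd_rad,
                             seed=None if config.seed is None else config.seed + 1)
    return table, truths


def cohesion_metrics(table: TrajectoryTable, split_distance: float) -> dict:
    """Whether the group split (distance-threshold graph disconnected at the
    final step) and the final consensus (polar order)."""
    df = table.df
    t_last = df["time_s"].max()
    last = df[df["time_s"] == t_last]
    pos = last[["x_m", "y_m"]].to_numpy()
    g = nx.Graph()
    g.add_nodes_from(range(len(pos)))
    d = np.hypot(pos[:, None, 0] - pos[None, :, 0], pos[:, None, 1] - pos[None, :, 1])
    for i in range(len(pos)):
        for j in range(i + 1, len(pos)):
            if d[i, j] <= split_distance:
                g.add_edge(i, j)
    return {
        "split": not nx.is_connected(g),
        "consensus": resultant_length(last["heading_rad"].to_numpy()),
    }


@dataclass
class PredictionStats:
    """Pooled CorrMax / Sym prediction distributions for one mechanism."""

    mechanism: str
    corr_max: BootstrapSummary
    symmetry: BootstrapSummary
    corr_max_mean: float
    symmetry_mean: float
    per_event_corr_max: np.ndarray
    per_event_symmetry: np.ndarray


def _event_stats_from_run(table: TrajectoryTable, truth: dict,
                          run_config: RunConfig):
    """CorrMax and Sym for one simulated departure, using the detection
    stage's departure-direction rule (ground-truth time anchor)."""
    group = group_series(table, run_config)
    t_dep = truth["t_departure_s"]
    t_max = int(group.df["time_s"].max())
    event = DecisionEvent(
        event_id="sim", day_id="d0", t_departure_s=t_dep,
        window=(max(0, t_dep - run_config.window_pre_s),
                min(t_max, t_dep + run_config.window_post_s)),
    )
    direction = departure_direction(event, group, run_config)
    if direction is None:
        direction = truth["direction_true_rad"]
    event.departure_direction_rad = direction
    curve = decision_curve(event, group, "departure", run_config)
    stats = cross_correlate(curve, config=run_config)
    return stats.corr_max_lag_s, stats.symmetry_index


def simulate_predictions(config: AgentConfig, n_decisions: int = 21,
                         n_resample: int = 1000, seed=None,
                         pool_size: int = 50,
                         gps_sd_m: float = 0.05, heading_sd_rad: float = 0.05,
                         run_config: RunConfig | None = None) -> PredictionStats:
    """Mechanism prediction distributions: simulate a pool of departures
    (with the same sensor noise the empirical-style pipeline sees), resample
    ``n_decisions``-event subsets ``n_resample`` times with replacement, and
    summarize the medians of CorrMax and Sym."""
    if pool_size < n_decisions:
        raise ValueError("event pool smaller than n_decisions")
    run_config = run_config or RunConfig()
    rng = np.random.default_rng(seed)
    corr_max = np.empty(pool_size)
    sym = np.empty(pool_size)
    for i in range(pool_size):
        target = rng.uniform(0, 2 * np.pi)
        cfg = config.replace(seed=int(rng.integers(2**31)),
                             target_direction_rad=target,
                             rest_direction_rad=float(
                                 wrap_angle(target + _rest_offset(rng))))
        table, truth = run_simulation(cfg)
        if gps_sd_m or heading_sd_rad:
            table = add_sensor_noise(table, gps_sd_m, heading_sd_rad,
                                     seed=int(rng.integers(2**31)))
        corr_max[i], sym[i] = _event_stats_from_run(table, truth, run_config)

    idx = rng.integers(0, pool_size, size=(n_resample, n_decisions))
    cm_med = np.median(corr_max[idx], axis=1)
    sy_med = np.median(sym[idx], axis=1)

    def summary(meds, values):
        lo, hi = np.percentile(meds, [2.5, 97.5])
        return BootstrapSummary(median=float(np.median(values)),
                                ci_low=float(lo), ci_high=float(hi),
                                n=n_decisions, n_boot=n_resample)

    return PredictionStats(
        mechanism=config.mechanism,
        corr_max=summary(cm_med, corr_max),
        symmetry=summary(sy_med, sym),
        corr_max_mean=float(cm_med.mean()),
        symmetry_mean=float(sy_med.mean()),
        per_event_corr_max=corr_max,
        per_event_symmetry=sym,
    )
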