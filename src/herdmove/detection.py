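"""Collective-departure detection on group series.

Candidate departures are change-points in group mean speed that take the
group from a slow regime into a moving regime. Each candidate is then passed
through three exclusion filters:

* ``no_stationary`` — no clear pre-departure stationary period (a run of at
  least ``stationary_min_s`` seconds with group mean speed below
  ``stationary_speed_mps`` immediately before departure);
* ``first_of_day`` / ``last_of_day`` — the day's boundary decisions, which
  may be externally influenced, are discarded;
* ``no_prewindow_changepoint`` — no heading or heading-variance change-point
  exists in the pre-departure search window, so no departure direction can
  be assigned.

The departure direction is the circular mean of the group mean heading over
the ``moving_phase_s`` seconds following the strongest heading /
heading-directedness change-point near departure; by construction the
decision parameter evaluated against this direction reaches ~1 during the
departure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .changepoint import ChangePointSet, detect_changepoints
from .io import GroupSeries, RunConfig
from .kinematics import circular_mean, circular_variance_sliding


@dataclass
class DecisionEvent:
    """One detected collective departure."""

    event_id: str
    day_id: str
    t_departure_s: int
    window: tuple[int, int]
    t_align_s: int | None = None
    departure_direction_rad: float | None = None
    destination_direction_rad: float | None = None
    stationary_ok: bool = False
    excluded_reason: str | None = None  # None = retained
    strength: float = 0.0

    @property
    def retained(self) -> bool:
        return self.excluded_reason is None

    def to_dict(self) -> dict:
        return {
            "event_id": self.event_id,
            "day_id": self.day_id,
            "t_departure_s": int(self.t_departure_s),
            "window": [int(self.window[0]), int(self.window[1])],
            "t_align_s": None if self.t_align_s is None else int(self.t_align_s),
            "departure_direction_rad": self.departure_direction_rad,
            "destination_direction_rad": self.destination_direction_rad,
            "stationary_ok": bool(self.stationary_ok),
            "excluded_reason": self.excluded_reason,
            "strength": float(self.strength),
        }


def _day_arrays(day: GroupSeries):
    df = day.df
    t = df["time_s"].to_numpy()
    speed = df["mean_speed_mps"].to_numpy().copy()
    if np.any(np.isnan(speed)):
        # trailing/missing instantaneous speeds: forward-fill then zero-fill
        idx = np.where(np.isnan(speed), -1, np.arange(speed.size))
        np.maximum.accumulate(idx, out=idx)
        speed = np.where(idx >= 0, speed[np.maximum(idx, 0)], 0.0)
    heading = df["mean_heading_rad"].to_numpy()
    return t, speed, heading


def heading_changepoints(day: GroupSeries, config: RunConfig) -> list[ChangePointSet]:
    """Change-points on unwrapped group mean heading and on its sliding
    circular 'directedness' (variance), the two departure-direction cues."""
    t, _, heading = _day_arrays(day)
    filled = heading.copy()
    if np.any(np.isnan(filled)):
        ok = ~np.isnan(filled)
        filled = np.interp(np.arange(filled.size), np.flatnonzero(ok), filled[ok])
    unwrapped = np.unwrap(filled)
    sets = [detect_changepoints(unwrapped, target="mean",
                                penalty=config.heading_penalty, times=t,
                                penalty_scale=config.penalty_scale, name="heading")]
    cvar = circular_variance_sliding(filled, config.heading_var_window_s)
    sets.append(detect_changepoints(cvar, target="mean",
                                    penalty=config.heading_penalty, times=t,
                                    penalty_scale=config.penalty_scale,
                                    name="heading_variance"))
    return sets


def _strongest_in_window(cp_sets: list[ChangePointSet], lo: int, hi: int):
    """Strongest change-point with time in [lo, hi]; ties -> earliest time."""
    best = None
    for cps in cp_sets:
        for time, strength in zip(cps.times_s, cps.strengths):
            if lo <= time <= hi:
                if best is None or strength > best[1] + 1e-12 or (
                        abs(strength - best[1]) <= 1e-12 and time < best[0]):
                    best = (int(time), float(strength))
    return best


def departure_direction(event: DecisionEvent, group: GroupSeries,
                        config: RunConfig | None = None,
                        cp_sets: list[ChangePointSet] | None = None) -> float | None:
    """Departure direction: circular mean of group mean heading over the
    ``moving_phase_s`` seconds following the strongest heading /
    heading-variance change-point near the departure. ``None`` when no
    change-point lies in the search window (event must then be excluded)."""
    config = config or RunConfig()
    day = group.day(event.day_id)
    if cp_sets is None:
        cp_sets = heading_changepoints(day, config)
    lo = event.t_departure_s - config.window_pre_s
    hi = event.t_departure_s + config.heading_cp_post_s
    best = _strongest_in_window(cp_sets, lo, hi)
    if best is None:
        return None
    t_align = best[0]
    df = day.df
    # the turn-rate-limited transition takes several seconds; sample the
    # moving-phase heading after it has settled, and never before the
    # departure itself (the alignment change-point can fire early when a
    # single initiator starts turning ahead of the group)
    start = max(t_align, event.t_departure_s) + config.direction_settle_s
    mask = (df["time_s"] >= start) & (df["time_s"] < start + config.moving_phase_s)
    h = df.loc[mask, "mean_heading_rad"].to_numpy()
    h = h[np.isfinite(h)]
    if h.size == 0:
        return None
    event.t_align_s = t_align
    event.strength = best[1]
    return circular_mean(h)


def destination_direction(event: DecisionEvent, group: GroupSeries,
                          config: RunConfig | None = None) -> float | None:
    """Bearing from the centroid at departure to the centroid at the end of
    the post-window (the realized destination). ``None`` when the track ends
    before a sustained travel phase exists."""
    config = config or RunConfig()
    df = group.day(event.day_id).df
    t = df["time_s"].to_numpy()
    t0 = event.t_departure_s
    t1 = min(t0 + config.window_post_s, int(t.max()))
    if t1 - t0 < config.travel_min_s:
        return None
    travel = df[(df["time_s"] >= t0) & (df["time_s"] <= t0 + config.travel_min_s)]
    if travel["mean_speed_mps"].mean() <= config.stationary_speed_mps:
        return None  # no sustained movement
    row0 = df[df["time_s"] == t0]
    row1 = df[df["time_s"] == t1]
    if row0.empty or row1.empty:
        return None
    dx = float(row1["centroid_x_m"].iloc[0] - row0["centroid_x_m"].iloc[0])
    dy = float(row1["centroid_y_m"].iloc[0] - row0["centroid_y_m"].iloc[0])
    if dx == 0 and dy == 0:
        return None
    return float(np.mod(np.arctan2(dy, dx), 2 * np.pi))


def _refine_departure_time(t: np.ndarray, speed: np.ndarray, i: int,
                           config: RunConfig) -> int:
    """Anchor the departure at the half-rise of the speed sigmoid.

    Change-points on a ramp land at its foot; the midpoint of the rise is a
    better-defined, more reproducible departure time.
    """
    hi = min(speed.size, i + config.candidate_post_s + 10)
    plateau = np.mean(speed[min(i + 10, hi - 1):hi])
    thresh = max(config.stationary_speed_mps, plateau / 2.0)
    for j in range(max(0, i - 5), hi):
        if speed[j] >= thresh:
            return int(t[j])
    return int(t[i])


def _has_stationary_period(t: np.ndarray, speed: np.ndarray, t_dep: int,
                           config: RunConfig) -> bool:
    # the window ends one moving-phase before the (half-rise) departure
    # anchor so the onset ramp itself does not spoil the stationary test
    hi = t_dep - config.moving_phase_s
    lo = hi - config.stationary_min_s
    mask = (t >= lo) & (t < hi)
    if mask.sum() < config.stationary_min_s:
        return False
    return bool(np.all(speed[mask] < config.stationary_speed_mps))


def find_decisions(group: GroupSeries, config: RunConfig | None = None) -> list[DecisionEvent]:
    """Detect candidate collective departures and apply the exclusion filters.

    Every candidate is returned; excluded ones carry ``excluded_reason``.
    """
    config = config or RunConfig()
    if len(group) == 0:
        raise ValueError("empty group series")
    events: list[DecisionEvent] = []
    for day_id in sorted(group.df["day_id"].unique()):
        day = group.day(day_id)
        t, speed, _ = _day_arrays(day)
        if t.size < 10:
            continue
        cps = detect_changepoints(speed, target="mean", penalty=config.speed_penalty,
                                  times=t, penalty_scale=config.penalty_scale,
                                  name="speed")
        # candidate = slow regime -> moving regime transitions
        candidates = []
        for cp_time, strength in zip(cps.times_s, cps.strengths):
            i = int(np.searchsorted(t, cp_time))
            pre = speed[max(0, i - config.stationary_min_s):i]
            post = speed[i:i + config.candidate_post_s]
            if pre.size == 0 or post.size == 0:
                continue
            if np.mean(pre) < config.stationary_speed_mps and \
                    np.mean(post) > config.moving_speed_min_mps:
                t_dep = _refine_departure_time(t, speed, i, config)
                candidates.append((t_dep, float(strength)))
        # merge candidates closer than min_event_sep_s, keeping the earliest
        merged = []
        for cand in candidates:
            if merged and cand[0] - merged[-1][0] < config.min_event_sep_s:
                continue
            merged.append(cand)

        cp_sets = heading_changepoints(day, config)
        day_events = []
        for k, (t_dep, strength) in enumerate(merged):
            ev = DecisionEvent(
                event_id=f"{day_id}-e{k}",
                day_id=day_id,
                t_departure_s=t_dep,
                window=(t_dep - config.window_pre_s, t_dep + config.window_post_s),
                strength=strength,
            )
            ev.stationary_ok = _has_stationary_period(t, speed, t_dep, config)
            if not ev.stationary_ok:
                ev.excluded_reason = "no_stationary"
            day_events.append(ev)
        # boundary filter applies to the day's candidate sequence
        if day_events:
            if day_events[0].excluded_reason is None:
                day_events[0].excluded_reason = "first_of_day"
            if len(day_events) > 1 and day_events[-1].excluded_reason is None:
                day_events[-1].excluded_reason = "last_of_day"
        for ev in day_events:
            direction = departure_direction(ev, group, config, cp_sets=cp_sets)
            if direction is None:
                if ev.excluded_reason is None:
                    ev.excluded_reason = "no_prewindow_changepoint"
            else:
                ev.departure_direction_rad = direction
            if ev.excluded_reason is None:
                ev.destination_direction_rad = destination_direction(ev, group, config)
        events.extend(day_events)
    return events


def retained(events: list[DecisionEvent]) -> list[DecisionEvent]:
    return [e for e in events if e.retained]
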