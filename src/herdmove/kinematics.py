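"""Per-individual and group-level motion quantities.

Circular statistics follow the standard unit-vector formulation: the circular
mean is the angle of the summed unit vectors and the mean resultant length is
the norm of their average. Applied to a group's body headings the resultant
length IS the polar order parameter (1 = perfectly aligned, 0 = balanced
opposition).

Body heading for analysis comes from the ``heading_rad`` column (the
magnetometer analogue); GPS-style track heading is derived from displacements
only for speed utilities and validation.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .io import GroupSeries, RunConfig, TrajectoryTable, wrap_angle

#: Resultant lengths below this are treated as degenerate (undefined mean).
_RESULTANT_EPS = 1e-12


def circular_mean(angles_rad) -> float:
    """Circular mean: angle of the summed unit vectors, wrapped to [0, 2pi).

    Returns NaN (flagged undefined) when the resultant length is < 1e-12,
    e.g. for exactly antipodal inputs.
    """
    a = np.asarray(angles_rad, dtype=float)
    if a.size == 0:
        raise ValueError("circular_mean of empty angle set")
    c, s = np.cos(a).sum(), np.sin(a).sum()
    if np.hypot(c, s) / a.size < _RESULTANT_EPS:
        return float("nan")
    return float(wrap_angle(np.arctan2(s, c)))


def resultant_length(angles_rad) -> float:
    """Mean resultant length of unit vectors, in [0, 1].

    This is the polar order parameter when applied to group headings.
    """
    a = np.asarray(angles_rad, dtype=float)
    if a.size == 0:
        raise ValueError("resultant_length of empty angle set")
    r = np.hypot(np.cos(a).mean(), np.sin(a).mean())
    return float(min(r, 1.0))


def circular_variance_sliding(angles_rad, window_s: int) -> np.ndarray:
    """Sliding circular variance (1 - resultant length) over a centred window.

    Edges use the available partial window. Used as the "directedness" series
    for change-point detection.
    """
    a = np.asarray(angles_rad, dtype=float)
    n = a.size
    if window_s < 1:
        raise ValueError("window_s must be >= 1")
    half = window_s // 2
    cs = np.concatenate([[0.0], np.cumsum(np.cos(a))])
    ss = np.concatenate([[0.0], np.cumsum(np.sin(a))])
    idx = np.arange(n)
    lo = np.maximum(idx - half, 0)
    hi = np.minimum(idx + half + 1, n)
    cnt = (hi - lo).astype(float)
    r = np.hypot(cs[hi] - cs[lo], ss[hi] - ss[lo]) / cnt
    return 1.0 - np.minimum(r, 1.0)


def circular_correlation(a_rad, b_rad) -> float:
    """Jammalamadaka–SenGupta circular correlation coefficient."""
    a = np.asarray(a_rad, dtype=float)
    b = np.asarray(b_rad, dtype=float)
    if a.shape != b.shape or a.size < 2:
        raise ValueError("need two equal-length angle arrays of size >= 2")
    sa = np.sin(a - circular_mean(a))
    sb = np.sin(b - circular_mean(b))
    denom = np.sqrt((sa**2).sum() * (sb**2).sum())
    if denom == 0:
        raise ValueError("degenerate circular correlation (zero dispersion)")
    return float((sa * sb).sum() / denom)


def instantaneous_motion(table: TrajectoryTable, dt: float = 1.0) -> pd.DataFrame:
    """Per-individual instantaneous speed and track heading between samples.

    The value at time ``t`` uses the displacement from ``t`` to ``t + dt``;
    the last sample of each contiguous block therefore carries NaN. Track
    heading is NaN (flagged undefined) for zero displacement.

    Returns a frame with columns
    ``individual_id, day_id, time_s, speed_mps, track_heading_rad``.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    out = []
    for (ind, day_id), sub in table.df.groupby(["individual_id", "day_id"], sort=True):
        t = sub["time_s"].to_numpy()
        x = sub["x_m"].to_numpy()
        y = sub["y_m"].to_numpy()
        speed = np.full(t.size, np.nan)
        track = np.full(t.size, np.nan)
        if t.size >= 2:
            dtv = np.diff(t)
            ok = dtv == dt  # only consecutive samples at the declared spacing
            dx = np.diff(x)[ok]
            dy = np.diff(y)[ok]
            idx = np.nonzero(ok)[0]
            speed[idx] = np.hypot(dx, dy) / dt
            moved = np.hypot(dx, dy) > 0
            track[idx[moved]] = wrap_angle(np.arctan2(dy[moved], dx[moved]))
        out.append(pd.DataFrame({
            "individual_id": ind,
            "day_id": day_id,
            "time_s": t,
            "speed_mps": speed,
            "track_heading_rad": track,
        }))
    return pd.concat(out, ignore_index=True)


def group_series(table: TrajectoryTable, config: RunConfig | None = None) -> GroupSeries:
    """Aggregate a trajectory table to per-time-step group quantities.

    A time step is retained only if at least ``min_member_frac`` of the day's
    individuals have data (and at least 2). Group mean speed defaults to the
    mean of individual instantaneous speeds; centroid speed is available via
    ``config.group_speed_source = "centroid"``.
    """
    config = config or RunConfig()
    if len(table.individuals) < 2:
        raise ValueError("group_series requires at least 2 individuals")
    motion = instantaneous_motion(table)
    df = table.df.merge(
        motion[["individual_id", "day_id", "time_s", "speed_mps"]],
        on=["individual_id", "day_id", "time_s"], how="left")

    rows = []
    for day_id, sub in df.groupby("day_id", sort=True):
        n_total = sub["individual_id"].nunique()
        min_members = max(2, int(np.ceil(config.min_member_frac * n_total)))
        for t, step in sub.groupby("time_s", sort=True):
            n = len(step)
            if n < min_members:
                continue
            h = step["heading_rad"].to_numpy()
            sp = step["speed_mps"].to_numpy()
            sp = sp[np.isfinite(sp)]
            rows.append({
                "time_s": int(t),
                "day_id": day_id,
                "centroid_x_m": float(step["x_m"].mean()),
                "centroid_y_m": float(step["y_m"].mean()),
                "mean_heading_rad": circular_mean(h),
                "mean_speed_mps": float(sp.mean()) if sp.size else np.nan,
                "polar_order": resultant_length(h),
                "n_members": n,
            })
    out = pd.DataFrame(rows)
    if out.empty:
        raise ValueError("no time steps satisfy the membership rule")
    if config.group_speed_source == "centroid":
        out = out.sort_values(["day_id", "time_s"]).reset_index(drop=True)
        for day_id, sub in out.groupby("day_id"):
            idx = sub.index.to_numpy()
            t = sub["time_s"].to_numpy()
            cx = sub["centroid_x_m"].to_numpy()
            cy = sub["centroid_y_m"].to_numpy()
            spd = np.full(t.size, np.nan)
            if t.size >= 2:
                ok = np.diff(t) == 1
                ii = np.nonzero(ok)[0]
                spd[ii] = np.hypot(np.diff(cx)[ii], np.diff(cy)[ii])
            out.loc[idx, "mean_speed_mps"] = spd
    return GroupSeries(out.sort_values(["day_id", "time_s"]).reset_index(drop=True))
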