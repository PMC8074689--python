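"""Penalized exact change-point detection (PELT).

Implements optimal penalized segmentation with pruning for two cost models:

* ``"mean"`` — piecewise-constant mean, squared-error segment cost.
* ``"mean_and_variance"`` — piecewise Gaussian, segments may differ in both
  mean and variance; cost is the Gaussian negative log-likelihood up to
  constants, ``n * log(sigma_hat^2)``.

Both costs satisfy ``C(s,t) + C(t,e) <= C(s,e)``, so PELT pruning with
``K = 0`` is exact: the returned segmentation minimizes
``sum_i C(seg_i) + penalty * (#changepoints)`` over all segmentations.

The default penalty is BIC-like and scales with an MAD-based noise-variance
estimate (for the mean cost) or with ``log n`` (for the Gaussian cost), so a
constant series plus tiny noise yields no change-points without tuning.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

_VAR_FLOOR = 1e-10


@dataclass
class ChangePointSet:
    """Detected change-points for one series.

    ``times_s[i]`` is the first sample index (or time stamp, when a ``times``
    axis is supplied) of the new regime; ``strengths[i]`` is the cost
    reduction achieved by that split within the final segmentation.
    """

    series_name: str
    times_s: np.ndarray
    strengths: np.ndarray
    penalty: float = field(default=float("nan"))

    def __post_init__(self):
        self.times_s = np.asarray(self.times_s)
        self.strengths = np.asarray(self.strengths, dtype=float)
        if self.times_s.size > 1 and not np.all(np.diff(self.times_s) > 0):
            raise ValueError("change-point times must be strictly increasing")
        if np.any(self.strengths < -1e-9):
            raise ValueError("change-point strengths must be non-negative")

    def __len__(self) -> int:
        return len(self.times_s)


def _mad_sigma2(y: np.ndarray) -> float:
    # Robust noise variance from first differences; diff of iid noise has
    # variance 2 sigma^2, and MAD is immune to the (sparse) level shifts.
    d = np.diff(y)
    if d.size == 0:
        return _VAR_FLOOR
    mad = np.median(np.abs(d - np.median(d)))
    sigma = 1.4826 * mad / np.sqrt(2.0)
    return max(float(sigma * sigma), _VAR_FLOOR)


def default_penalty(y: np.ndarray, target: str) -> float:
    n = y.size
    if target == "mean":
        return 2.0 * np.log(n) * _mad_sigma2(y)
    return 2.0 * np.log(n)


class _Cost:
    """Segment costs over half-open index ranges [s, e) via prefix sums."""

    def __init__(self, y: np.ndarray, target: str):
        self.target = target
        self.s1 = np.concatenate([[0.0], np.cumsum(y)])
        self.s2 = np.concatenate([[0.0], np.cumsum(y * y)])

    def cost(self, starts: np.ndarray, e: int) -> np.ndarray:
        n = e - starts
        tot = self.s1[e] - self.s1[starts]
        tot2 = self.s2[e] - self.s2[starts]
        sse = np.maximum(tot2 - tot * tot / n, 0.0)
        if self.target == "mean":
            return sse
        var = np.maximum(sse / n, _VAR_FLOOR)
        return n * np.log(var)


def _pelt(y: np.ndarray, target: str, penalty: float, min_size: int) -> list[int]:
    n = y.size
    cost = _Cost(y, target)
    f = np.full(n + 1, np.inf)
    f[0] = -penalty
    prev = np.zeros(n + 1, dtype=int)
    cand = [0]
    for e in range(min_size, n + 1):
        starts = np.array([s for s in cand if e - s >= min_size], dtype=int)
        if starts.size == 0:
            continue
        vals = f[starts] + cost.cost(starts, e) + penalty
        k = int(np.argmin(vals))
        f[e] = vals[k]
        prev[e] = starts[k]
        # prune: s can never be optimal again if already worse without penalty
        keep = starts[vals - penalty <= f[e]]
        cand = sorted(set(keep.tolist()) | {s for s in cand if e - s < min_size})
        cand.append(e)
    # backtrack
    bps = []
    e = n
    while e > 0:
        s = prev[e]
        if s > 0:
            bps.append(s)
        e = s
    return sorted(bps)


def detect_changepoints(series, target: str = "mean", penalty: float | None = None,
                        *, times=None, min_size: int = 2,
                        penalty_scale: float = 1.0, name: str = "") -> ChangePointSet:
    """Detect change-points in a 1-D numeric series.

    Parameters
    ----------
    series:
        Numeric values on a regular grid; length >= 10, all finite.
    target:
        ``"mean"`` or ``"mean_and_variance"``.
    penalty:
        Per-change-point penalty; ``None`` uses a BIC-like default scaled by
        ``penalty_scale`` (the sensitivity-sweep knob).
    times:
        Optional time stamps aligned with ``series``; reported change-point
        times are drawn from this axis instead of raw indices.
    """
    y = np.asarray(series, dtype=float)
    if y.ndim != 1 or y.size < 10:
        raise ValueError("series must be 1-D with length >= 10")
    if not np.all(np.isfinite(y)):
        raise ValueError("series contains non-finite values")
    if target not in ("mean", "mean_and_variance"):
        raise ValueError(f"unknown target {target!r}")
    if penalty is None:
        penalty = default_penalty(y, target) * penalty_scale
    if penalty <= 0:
        raise ValueError("penalty must be positive")
    if target == "mean_and_variance":
        min_size = max(min_size, 3)

    bps = _pelt(y, target, penalty, min_size)

    cost = _Cost(y, target)
    bounds = [0] + bps + [y.size]
    strengths = []
    for i, b in enumerate(bps):
        lo, hi = bounds[i], bounds[i + 2]
        merged = cost.cost(np.array([lo]), hi)[0]
        split = cost.cost(np.array([lo]), b)[0] + cost.cost(np.array([b]), hi)[0]
        strengths.append(max(merged - split, 0.0))

    if times is not None:
        times = np.asarray(times)
        cp_times = times[np.array(bps, dtype=int)] if bps else np.array([], dtype=times.dtype)
    else:
        cp_times = np.array(bps, dtype=int)
    return ChangePointSet(series_name=name, times_s=cp_times,
                          strengths=np.array(strengths), penalty=float(penalty))
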