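"""Decision parameter, cross-correlation statistics, and bootstrap pooling.

The decision parameter ``r`` is the mean resultant length of two unit
vectors — the group mean heading and a reference direction (departure or
destination)::

    r = || ( (cos a1 + cos a2)/2 , (sin a1 + sin a2)/2 ) ||

which reduces in closed form to ``|cos((a1 - a2)/2)|``: 1 for perfect
agreement, 0 for opposite angles.

Cross-correlation convention: ``corr[k]`` correlates the decision parameter
shifted by ``k`` against speed, so a *negative* lag at the correlation
maximum (CorrMax) means decision-parameter changes preceded speed changes —
the voting signature. The symmetry index (Sym) is the right-of-zero area of
the correlation curve minus the left-of-zero area; lag 0 belongs to neither
side, which keeps Sym exactly antisymmetric under time reversal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .detection import DecisionEvent
from .io import GroupSeries, RunConfig


def decision_parameter(group_mean_heading, reference_direction):
    """Mean resultant length of the two direction unit vectors, in [0, 1].

    Vectorized; NaN inputs (undefined group heading) propagate to NaN.
    """
    a1 = np.asarray(group_mean_heading, dtype=float)
    a2 = np.asarray(reference_direction, dtype=float)
    r = 0.5 * np.hypot(np.cos(a1) + np.cos(a2), np.sin(a1) + np.sin(a2))
    r = np.minimum(r, 1.0)
    if r.ndim == 0:
        return float(r)
    return r


@dataclass
class DecisionCurve:
    """Decision parameter, speed and polar order around one departure."""

    event_id: str
    rel_time_s: np.ndarray
    r: np.ndarray
    speed_mps: np.ndarray
    polar_order: np.ndarray
    reference_mode: str  # "departure" | "destination"
    truncated: bool = False

    def __post_init__(self):
        valid = self.r[np.isfinite(self.r)]
        if valid.size and (valid.min() < -1e-9 or valid.max() > 1 + 1e-9):
            raise ValueError("decision parameter outside [0, 1]")


def decision_curve(event: DecisionEvent, group: GroupSeries,
                   mode: str = "departure",
                   config: RunConfig | None = None) -> DecisionCurve:
    """Per-step decision parameter over the event window, aligned with group
    speed and polar order. The curve is truncated (and flagged) when the
    window runs past the day's data."""
    config = config or RunConfig()
    if mode == "departure":
        ref = event.departure_direction_rad
    elif mode == "destination":
        ref = event.destination_direction_rad
    else:
        raise ValueError(f"unknown mode {mode!r}")
    if ref is None:
        raise ValueError(f"event {event.event_id} has no {mode} direction")
    df = group.day(event.day_id).df
    lo, hi = event.window
    win = df[(df["time_s"] >= lo) & (df["time_s"] <= hi)]
    expected = hi - lo + 1
    rel = win["time_s"].to_numpy() - event.t_departure_s
    r = decision_parameter(win["mean_heading_rad"].to_numpy(), ref)
    return DecisionCurve(
        event_id=event.event_id,
        rel_time_s=rel,
        r=np.atleast_1d(r),
        speed_mps=win["mean_speed_mps"].to_numpy(),
        polar_order=win["polar_order"].to_numpy(),
        reference_mode=mode,
        truncated=len(win) < expected,
    )


@dataclass
class CrossCorrStats:
    """Cross-correlation curve and its two summary statistics for one event."""

    event_id: str
    lags_s: np.ndarray
    corr: np.ndarray
    corr_max_lag_s: int
    symmetry_index: float


def cross_correlate(curve: DecisionCurve, max_lag_s: int | None = None,
                    config: RunConfig | None = None) -> CrossCorrStats:
    """Cross-correlate the decision parameter with group speed.

    ``corr[k] = cor(r(t + k), speed(t))`` with the classic sample-ccf
    normalization (full-window means and standard deviations, denominator
    ``n``), so a negative CorrMax lag means ``r`` led speed. Ties at the
    maximum break toward the smallest ``|lag|``, then toward the negative
    lag. NaN ``r`` steps are dropped pairwise.
    """
    config = config or RunConfig()
    L = int(max_lag_s if max_lag_s is not None else config.max_lag_s)
    r = np.asarray(curve.r, dtype=float)
    s = np.asarray(curve.speed_mps, dtype=float)
    n = r.size
    if n < 2 * L + 10:
        raise ValueError(f"curve too short ({n}) for max lag {L}")
    rv, sv = np.isfinite(r), np.isfinite(s)
    if rv.sum() < 2 or sv.sum() < 2:
        raise ValueError("too few finite samples")
    r0 = np.where(rv, r - r[rv].mean(), 0.0)
    s0 = np.where(sv, s - s[sv].mean(), 0.0)
    sd_r = float(np.sqrt((r0[rv] ** 2).mean()))
    sd_s = float(np.sqrt((s0[sv] ** 2).mean()))
    if sd_r == 0.0 or sd_s == 0.0:
        raise ValueError("zero-variance series: cross-correlation undefined")

    lags = np.arange(-L, L + 1)
    corr = np.empty(lags.size)
    if config.ccf_normalization == "overlap":
        for i, k in enumerate(lags):
            a = r[max(k, 0): n + min(k, 0)]
            b = s[max(-k, 0): n - max(k, 0)]
            m = np.isfinite(a) & np.isfinite(b)
            corr[i] = np.corrcoef(a[m], b[m])[0, 1] if m.sum() >= 3 else np.nan
    else:
        denom = n * sd_r * sd_s
        for i, k in enumerate(lags):
            # overlap of r(t+k) with s(t)
            a = r0[max(k, 0): n + min(k, 0)]
            b = s0[max(-k, 0): n - max(k, 0)]
            corr[i] = float(np.dot(a, b)) / denom
    corr = np.clip(corr, -1.0, 1.0)

    finite = np.isfinite(corr)
    m = corr[finite].max()
    at_max = finite & (corr >= m - 1e-12)
    cand = lags[at_max]
    best = cand[np.lexsort((cand, np.abs(cand)))][0]  # min |lag|, then negative
    stats = CrossCorrStats(event_id=curve.event_id, lags_s=lags, corr=corr,
                           corr_max_lag_s=int(best), symmetry_index=np.nan)
    stats.symmetry_index = symmetry_index(stats)
    return stats


def symmetry_index(stats: CrossCorrStats) -> float:
    """Right-of-zero area minus left-of-zero area of the correlation curve
    (unit lag spacing; lag 0 excluded from both sides)."""
    lags = np.asarray(stats.lags_s)
    corr = np.asarray(stats.corr, dtype=float)
    if not np.array_equal(lags, -lags[::-1]):
        raise ValueError("symmetry index requires a symmetric lag range")
    right = np.nansum(corr[lags > 0])
    left = np.nansum(corr[lags < 0])
    return float(right - left)


@dataclass
class BootstrapSummary:
    """Median with percentile bootstrap CI over per-event values."""

    median: float
    ci_low: float
    ci_high: float
    n: int
    n_boot: int

    def contains(self, value: float) -> bool:
        return self.ci_low <= value <= self.ci_high

    def to_dict(self) -> dict:
        return {"median": self.median, "ci": [self.ci_low, self.ci_high],
                "n": self.n, "n_boot": self.n_boot}


def pooled_bootstrap(per_event_values, n_boot: int = 1000, seed=None,
                     rng: np.random.Generator | None = None) -> BootstrapSummary:
    """Percentile bootstrap (2.5%, 97.5%) of the median across events.

    Deterministic under a fixed ``seed`` (or supplied generator).
    """
    values = np.asarray(per_event_values, dtype=float)
    if values.size < 2:
        raise ValueError("pooled_bootstrap requires at least 2 events")
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    if rng is None:
        rng = np.random.default_rng(seed)
    samples = rng.choice(values, size=(n_boot, values.size), replace=True)
    medians = np.median(samples, axis=1)
    lo, hi = np.percentile(medians, [2.5, 97.5])
    return BootstrapSummary(median=float(np.median(values)), ci_low=float(lo),
                            ci_high=float(hi), n=values.size, n_boot=n_boot)


def one_sample_t(values, mu0: float) -> tuple[float, int, float]:
    """One-sample t-test: returns (t, df, two-sided p)."""
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("one_sample_t requires n >= 2")
    if np.std(values, ddof=1) == 0:
        if np.allclose(values, mu0):
            return 0.0, values.size - 1, 1.0
        raise ValueError("zero variance with mean != mu0: t undefined")
    res = sps.ttest_1samp(values, popmean=mu0)
    return float(res.statistic), values.size - 1, float(res.pvalue)
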