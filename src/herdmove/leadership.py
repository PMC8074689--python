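"""Leader/follower scoring from pairwise time-lag heading correlations, and
dominance-network statistics on the resulting leadership matrix.

For each dyad and each second, sliding windows of the two individuals'
(unwrapped) headings are correlated across integer time shifts. If the best
correlation exceeds the threshold (default 0.9), the individual whose
heading changes occur earlier scores +1 (leading) and the other -1
(following); a best shift of zero, or a sub-threshold maximum, scores both 0.
Per-second scores are summed over events into a square leadership matrix,
which is then ranked by normalized David's score and tested for hierarchical
structure (triangle transitivity) and dyadic asymmetry (directional
consistency) with permutation p-values.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np

from .detection import DecisionEvent
from .io import RunConfig, TrajectoryTable


@dataclass
class LeadershipMatrix:
    """Cell (i, j) = summed count of seconds where i led j."""

    ids: list[str]
    scores: np.ndarray
    phase: str  # "departure" | "travelling"

    def __post_init__(self):
        self.scores = np.asarray(self.scores)
        n = len(self.ids)
        if self.scores.shape != (n, n):
            raise ValueError("scores must be square and match ids")
        if np.any(self.scores < 0) or np.any(np.diag(self.scores) != 0):
            raise ValueError("scores must be non-negative with zero diagonal")

    def to_csv(self, path) -> None:
        import pandas as pd
        pd.DataFrame(self.scores, index=self.ids, columns=self.ids).to_csv(path)


@dataclass
class LeadershipStats:
    normDS: dict[str, float]
    t_tri: float
    p_ttri: float
    dc: float
    p_dc: float
    phase: str

    def to_dict(self) -> dict:
        return {"normDS": self.normDS, "t_tri": self.t_tri, "p_ttri": self.p_ttri,
                "dc": self.dc, "p_dc": self.p_dc, "phase": self.phase}


def _rolling_corr_shifted(a: np.ndarray, b: np.ndarray, w: int, shift: int) -> np.ndarray:
    """Pearson correlation of ``a[t-w+1:t+1]`` with ``b[t+shift-w+1:t+shift+1]``
    for every valid window end ``t``; NaN elsewhere (including zero-variance
    windows). Cumulative-sum implementation, O(n) per shift."""
    n = a.size
    lo, hi = max(0, -shift), n - max(0, shift)
    x = a[lo:hi]
    y = b[lo + shift:hi + shift]
    out = np.full(n, np.nan)
    m = x.size
    if m < w:
        return out
    def csum(v):
        return np.concatenate([[0.0], np.cumsum(v)])
    sx, sy = csum(x), csum(y)
    sxx, syy, sxy = csum(x * x), csum(y * y), csum(x * y)
    ends = np.arange(w, m + 1)
    starts = ends - w
    n_w = float(w)
    cov = sxy[ends] - sxy[starts] - (sx[ends] - sx[starts]) * (sy[ends] - sy[starts]) / n_w
    vx = sxx[ends] - sxx[starts] - (sx[ends] - sx[starts]) ** 2 / n_w
    vy = syy[ends] - syy[starts] - (sy[ends] - sy[starts]) ** 2 / n_w
    denom = np.sqrt(np.maximum(vx, 0.0) * np.maximum(vy, 0.0))
    with np.errstate(invalid="ignore", divide="ignore"):
        c = np.where(denom > 1e-12, cov / denom, np.nan)
    out[lo + ends - 1] = np.clip(c, -1.0, 1.0)
    return out


def dyad_lag_score(heading_i, heading_j, window_s: int = 15,
                   max_shift_s: int = 10, threshold: float = 0.9,
                   unwrap: bool = True) -> tuple[np.ndarray, np.ndarray]:
    """Per-second leader/follower scores for individual i against j.

    Returns ``(times, scores)`` where ``times`` are the window-end sample
    indices at which all shifts are evaluable and ``scores`` take values in
    ``{-1, 0, +1}`` for individual i (j's score is the negation).
    """
    hi = np.asarray(heading_i, dtype=float)
    hj = np.asarray(heading_j, dtype=float)
    if hi.shape != hj.shape:
        raise ValueError("heading series must be aligned and equal length")
    n = hi.size
    if n < window_s + 2 * max_shift_s:
        raise ValueError("series shorter than window plus shift range")
    if unwrap:
        hi, hj = np.unwrap(hi), np.unwrap(hj)
    shifts = np.arange(-max_shift_s, max_shift_s + 1)
    times = np.arange(window_s - 1 + max_shift_s, n - max_shift_s)
    corr = np.empty((shifts.size, times.size))
    for k, s in enumerate(shifts):
        corr[k] = _rolling_corr_shifted(hi, hj, window_s, int(s))[times]

    scores = np.zeros(times.size, dtype=int)
    with np.errstate(invalid="ignore"):
        best = np.nanmax(corr, axis=0)
    ok = np.isfinite(best) & (best >= threshold)
    for t in np.flatnonzero(ok):
        cand = shifts[corr[:, t] >= best[t] - 1e-12]
        a = int(np.min(np.abs(cand)))
        if a == 0:
            continue  # best correlation at no shift -> both neutral
        pos, neg = a in cand, -a in cand
        if pos and neg:
            continue  # tie between +s and -s at equal |shift| -> neutral
        # positive shift: j's later samples match i's present, so i leads
        scores[t] = 1 if pos else -1
    return times, scores


def build_matrix(events: list[DecisionEvent], table: TrajectoryTable,
                 phase: str = "departure",
                 config: RunConfig | None = None) -> LeadershipMatrix:
    """Sum per-second dyad scores over all retained events in the given
    phase window (departure: pre-departure span; travelling: post span)."""
    if phase not in ("departure", "travelling"):
        raise ValueError(f"unknown phase {phase!r}")
    config = config or RunConfig()
    ids = table.individuals
    n = len(ids)
    scores = np.zeros((n, n), dtype=int)
    used = [e for e in events if e.retained]
    if not used:
        raise ValueError("no retained events")
    for ev in used:
        day = table.day(ev.day_id).df
        if phase == "departure":
            lo, hi = ev.t_departure_s - config.window_pre_s, ev.t_departure_s
        else:
            lo, hi = ev.t_departure_s, ev.t_departure_s + config.window_post_s
        win = day[(day["time_s"] >= lo) & (day["time_s"] <= hi)]
        series = {}
        grid = np.arange(lo, hi + 1)
        for ind, sub in win.groupby("individual_id"):
            if np.array_equal(sub["time_s"].to_numpy(), grid):
                series[ind] = sub["heading_rad"].to_numpy()
        for a, b in combinations(range(n), 2):
            ia, ib = ids[a], ids[b]
            if ia not in series or ib not in series:
                continue  # no overlapping data for this dyad in this event
            _, sc = dyad_lag_score(series[ia], series[ib],
                                   window_s=config.leadership_window_s,
                                   max_shift_s=config.leadership_max_shift_s,
                                   threshold=config.leadership_threshold)
            scores[a, b] += int(np.sum(sc == 1))
            scores[b, a] += int(np.sum(sc == -1))
    return LeadershipMatrix(ids=ids, scores=scores, phase=phase)


def norm_david_score(matrix: LeadershipMatrix) -> dict[str, float]:
    """Normalized David's score from dyadic win proportions with the
    standard dyadic correction ``Dij = Pij - (Pij - 0.5)/(nij + 1)``;
    normalized as ``(DS + N(N-1)/2) / N``."""
    m = matrix.scores.astype(float)
    n = m.shape[0]
    if n < 2:
        raise ValueError("need at least 2 individuals")
    tot = m + m.T
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(tot > 0, m / np.where(tot > 0, tot, 1), 0.0)
    d = np.where(tot > 0, p - (p - 0.5) / (tot + 1), 0.0)
    np.fill_diagonal(d, 0.0)
    w = d.sum(axis=1)
    l = d.sum(axis=0)
    w2 = d @ w
    l2 = d.T @ l
    ds = w + w2 - l - l2
    nds = (ds + n * (n - 1) / 2.0) / n
    return dict(zip(matrix.ids, nds.tolist()))


def _binarize(matrix: LeadershipMatrix, min_dyad_total: int):
    """Dominant direction per dyad; ties and sparse dyads are undecided."""
    m = matrix.scores
    n = m.shape[0]
    edges = []
    for i, j in combinations(range(n), 2):
        total = m[i, j] + m[j, i]
        if total < min_dyad_total or m[i, j] == m[j, i]:
            continue
        edges.append((i, j) if m[i, j] > m[j, i] else (j, i))
    return edges


def triangle_transitivity(matrix: LeadershipMatrix, n_perm: int = 1000,
                          seed=None, min_dyad_total: int = 10) -> tuple[float, float]:
    """Triangle transitivity ``t_tri = 4 (P_t - 0.75)`` over fully-decided
    triangles, with a permutation p-value from random re-orientation of the
    decided dyads. Returns ``(nan, nan)`` when no complete triangle exists."""
    edges = _binarize(matrix, min_dyad_total)
    n = len(matrix.ids)

    def p_t(edge_list) -> float | None:
        direction = {}
        for i, j in edge_list:
            direction[frozenset((i, j))] = (i, j)
        n_tri = n_trans = 0
        for tri in combinations(range(n), 3):
            pairs = [frozenset(p) for p in combinations(tri, 2)]
            if not all(p in direction for p in pairs):
                continue
            n_tri += 1
            outdeg = {v: 0 for v in tri}
            for p in pairs:
                outdeg[direction[p][0]] += 1
            # a 3-tournament is a cycle iff every node has out-degree 1
            if sorted(outdeg.values()) != [1, 1, 1]:
                n_trans += 1
        if n_tri == 0:
            return None
        return n_trans / n_tri

    obs = p_t(edges)
    if obs is None:
        return float("nan"), float("nan")
    t_tri = 4.0 * (obs - 0.75)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        flips = rng.random(len(edges)) < 0.5
        permuted = [(j, i) if f else (i, j) for (i, j), f in zip(edges, flips)]
        pt = p_t(permuted)
        if pt is not None and 4.0 * (pt - 0.75) >= t_tri - 1e-12:
            count += 1
    p = (1 + count) / (1 + n_perm)
    return float(t_tri), float(p)


def directional_consistency(matrix: LeadershipMatrix, n_perm: int = 1000,
                            seed=None) -> tuple[float, float]:
    """Directional consistency ``dc = sum(H - L) / sum(H + L)`` across dyads
    with interactions, with a permutation p-value from flipping each
    interaction's direction with probability 1/2."""
    m = matrix.scores
    n = m.shape[0]
    wins = np.array([m[i, j] for i, j in combinations(range(n), 2)])
    losses = np.array([m[j, i] for i, j in combinations(range(n), 2)])
    totals = wins + losses
    active = totals > 0
    if not np.any(active):
        return float("nan"), float("nan")
    totals = totals[active]
    grand = totals.sum()
    dc = float(np.abs(wins[active] - losses[active]).sum() / grand)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        w = rng.binomial(totals, 0.5)
        dc_perm = np.abs(2 * w - totals).sum() / grand
        if dc_perm >= dc - 1e-12:
            count += 1
    p = (1 + count) / (1 + n_perm)
    return dc, float(p)


def leadership_stats(matrix: LeadershipMatrix, n_perm: int = 1000,
                     seed=None, min_dyad_total: int = 10) -> LeadershipStats:
    t_tri, p_ttri = triangle_transitivity(matrix, n_perm=n_perm, seed=seed,
                                          min_dyad_total=min_dyad_total)
    dc, p_dc = directional_consistency(matrix, n_perm=n_perm, seed=seed)
    return LeadershipStats(normDS=norm_david_score(matrix), t_tri=t_tri,
                           p_ttri=p_ttri, dc=dc, p_dc=p_dc, phase=matrix.phase)
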