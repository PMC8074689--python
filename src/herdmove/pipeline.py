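"""End-to-end orchestration: group series -> decision detection -> decision
metrics -> leadership -> mechanism verdict.

The verdict is a pure function of the pooled bootstrap CIs, mirroring the
inferential logic applied to the empirical statistics:

* ``copying-consistent`` — both the CorrMax CI and the Sym CI contain 0;
* ``vote-consistent`` — the CorrMax CI lies entirely below 0;
* ``indeterminate`` — anything else.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import leadership as ld
from .detection import DecisionEvent, find_decisions, retained
from .io import GroupSeries, RunConfig, TrajectoryTable
from .kinematics import circular_correlation, group_series
from .metrics import (BootstrapSummary, DecisionCurve, cross_correlate,
                      decision_curve, one_sample_t, pooled_bootstrap)

VERDICTS = ("copying-consistent", "vote-consistent", "indeterminate")


def verdict(corr_max_ci: tuple[float, float], sym_ci: tuple[float, float]) -> str:
    """Mechanism verdict from the two pooled 95% CIs (pure function)."""
    cm_lo, cm_hi = corr_max_ci
    sy_lo, sy_hi = sym_ci
    if cm_hi < 0:
        return "vote-consistent"
    if cm_lo <= 0 <= cm_hi and sy_lo <= 0 <= sy_hi:
        return "copying-consistent"
    return "indeterminate"


def pre_departure_alignment_test(curves: list[DecisionCurve],
                                 at_rel_time_s: int = -100,
                                 chance: float = 2.0 / math.pi) -> dict:
    """Mean decision parameter at a pre-departure offset, with a one-sample
    t-test against the chance level for a uniformly random angle pair
    (``E|cos(delta/2)| = 2/pi``)."""
    values = []
    for c in curves:
        hit = np.flatnonzero(c.rel_time_s == at_rel_time_s)
        if hit.size == 0:
            raise ValueError(
                f"offset {at_rel_time_s} outside window of event {c.event_id}")
        v = c.r[hit[0]]
        if np.isfinite(v):
            values.append(float(v))
    if len(values) < 2:
        raise ValueError("need >= 2 events with a defined r at the offset")
    t, df, p = one_sample_t(values, chance)
    return {"mean_r": float(np.mean(values)), "chance": chance,
            "t": t, "df": df, "p": p, "n": len(values)}


@dataclass
class PipelineReport:
    config: dict
    seed: int
    n_candidate_events: int
    n_retained_events: int
    corr_max: BootstrapSummary | None
    symmetry: BootstrapSummary | None
    pre_departure: dict | None
    departure_destination_corr: float | None
    leadership: dict
    verdict: str
    warnings: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "config": self.config,
            "seed": self.seed,
            "n_candidate_events": self.n_candidate_events,
            "n_retained_events": self.n_retained_events,
            "corr_max_lag": None if self.corr_max is None else self.corr_max.to_dict(),
            "symmetry": None if self.symmetry is None else self.symmetry.to_dict(),
            "pre_departure_alignment": self.pre_departure,
            "departure_destination_circular_corr": self.departure_destination_corr,
            "leadership": self.leadership,
            "verdict": self.verdict,
            "warnings": self.warnings,
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True, **kwargs)

    def summary(self) -> str:
        lines = [
            f"events: {self.n_retained_events} retained of {self.n_candidate_events} candidates",
        ]
        if self.corr_max is not None:
            cm, sy = self.corr_max, self.symmetry
            lines.append(f"CorrMax median {cm.median:+.1f} s, 95% CI "
                         f"[{cm.ci_low:+.1f}, {cm.ci_high:+.1f}]")
            lines.append(f"Sym median {sy.median:+.2f}, 95% CI "
                         f"[{sy.ci_low:+.2f}, {sy.ci_high:+.2f}]")
        if self.pre_departure:
            pd_ = self.pre_departure
            lines.append(f"pre-departure r mean {pd_['mean_r']:.3f} vs chance "
                         f"{pd_['chance']:.3f} (t={pd_['t']:.2f}, df={pd_['df']}, "
                         f"p={pd_['p']:.3g})")
        lines.append(f"verdict: {self.verdict}")
        return "\n".join(lines)


def run_pipeline(table: TrajectoryTable, config: RunConfig | None = None,
                 include_leadership: bool = True,
                 out_dir=None) -> PipelineReport:
    """Run every stage on a validated trajectory table.

    Fully deterministic under ``config.rng_seed``; with zero retained events
    the verdict is ``indeterminate`` with an explicit warning.
    """
    config = config or RunConfig()
    warnings: list[str] = []
    group = group_series(table, config)
    events = find_decisions(group, config)
    kept = retained(events)

    curves: list[DecisionCurve] = []
    corr_max_vals, sym_vals = [], []
    for ev in kept:
        curve = decision_curve(ev, group, "departure", config)
        if curve.truncated:
            warnings.append(f"event {ev.event_id}: window truncated by data edge")
        try:
            stats = cross_correlate(curve, config=config)
        except ValueError as exc:
            warnings.append(f"event {ev.event_id}: {exc}")
            continue
        curves.append(curve)
        corr_max_vals.append(stats.corr_max_lag_s)
        sym_vals.append(stats.symmetry_index)

    corr_max = symmetry = None
    pre_dep = None
    dep_dest = None
    if len(corr_max_vals) >= 2:
        rng = np.random.default_rng(config.rng_seed)
        corr_max = pooled_bootstrap(corr_max_vals, config.bootstrap_n, rng=rng)
        symmetry = pooled_bootstrap(sym_vals, config.bootstrap_n, rng=rng)
        try:
            pre_dep = pre_departure_alignment_test(
                curves, at_rel_time_s=-config.window_pre_s,
                chance=config.chance_alignment)
        except ValueError as exc:
            warnings.append(f"pre-departure alignment test skipped: {exc}")
        pairs = [(e.departure_direction_rad, e.destination_direction_rad)
                 for e in kept if e.destination_direction_rad is not None]
        if len(pairs) >= 3:
            dep = np.array([p[0] for p in pairs])
            dst = np.array([p[1] for p in pairs])
            try:
                dep_dest = circular_correlation(dep, dst)
            except ValueError as exc:
                warnings.append(f"departure/destination correlation skipped: {exc}")
    else:
        warnings.append("fewer than 2 usable events: pooled statistics unavailable")

    leadership_out: dict = {}
    if include_leadership and kept:
        for phase in ("departure", "travelling"):
            try:
                matrix = ld.build_matrix(kept, table, phase, config)
                stats = ld.leadership_stats(matrix, n_perm=config.n_perm,
                                            seed=config.rng_seed,
                                            min_dyad_total=config.min_dyad_steps)
                leadership_out[phase] = stats.to_dict()
            except ValueError as exc:
                warnings.append(f"leadership ({phase}) skipped: {exc}")

    if corr_max is None:
        v = "indeterminate"
    else:
        v = verdict((corr_max.ci_low, corr_max.ci_high),
                    (symmetry.ci_low, symmetry.ci_high))

    report = PipelineReport(
        config=config.to_dict(),
        seed=config.rng_seed,
        n_candidate_events=len(events),
        n_retained_events=len(kept),
        corr_max=corr_max,
        symmetry=symmetry,
        pre_departure=pre_dep,
        departure_destination_corr=dep_dest,
        leadership=leadership_out,
        verdict=v,
        warnings=warnings,
    )
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        (out_dir / "report.json").write_text(report.to_json())
        (out_dir / "summary.txt").write_text(report.summary() + "\n")
        group.to_csv(out_dir / "group_series.csv")
        (out_dir / "events.json").write_text(
            json.dumps([e.to_dict() for e in events], indent=2))
    return report
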