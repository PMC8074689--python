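# herdmove

Tools for asking *how* an animal group agrees on a travel direction when it
departs: do individuals **vote** with their body orientation before moving
off, or do they simply **copy** each other's motion as the group departs?

The package contains two halves that meet in the middle:

* **An agent-based simulator** of collective departures under three decision
  mechanisms (`copying`, `all_vote`, `sub_vote`): agents rest in a cohesive
  cluster, start moving at normally-distributed initiation times at a fixed
  speed, and turn (at most 0.75 rad/s) toward the circular mean of their
  neighbours' headings; under the voting mechanisms they first orient toward
  von Mises-distributed vote directions while still stationary.
* **An empirical pipeline** for 1 Hz trajectory + body-heading data:
  change-point detection of collective departures, a decision parameter
  (alignment of the group mean heading with the departure direction),
  cross-correlation of that parameter with group speed (max-correlation lag
  and a left/right symmetry index, bootstrap CIs over events), and
  leader/follower network statistics (normalized David's score, triangle
  transitivity, directional consistency with permutation tests).

The discriminating logic: if orientations converge **before** the speed
rises (voting), the decision-parameter × speed cross-correlation peaks at a
negative lag and its symmetry index is negative; if alignment and
acceleration are concurrent (copying), both statistics are near zero. The
pipeline reduces a dataset to a verdict — `copying-consistent`,
`vote-consistent`, or `indeterminate` — from the bootstrap CIs.

## Test

```bash
python -m pytest -q tests/
```

The suite includes property tests (hypothesis), independent-oracle checks
(exhaustive change-point search, closed-form circular statistics, textbook
David's score), and an acceptance suite (`tests/test_acceptance.py`) that
exercises the full simulate → detect → measure → verdict loop. The
end-to-end tests run simulations and take a few minutes.

## CLI

```bash
# simulate a 7-day, 5-events-per-day noisy dataset with ground truth
herdmove simulate --mechanism copying --seed 1 --out-dir sim/

# detect collective departures (add --sensitivity for a penalty sweep)
herdmove detect sim/trajectories.csv --out-dir detect/

# decision curves, cross-correlations, pooled bootstrap statistics
herdmove metrics sim/trajectories.csv --out-dir metrics/

# leadership matrix + network statistics for one phase
herdmove leadership sim/trajectories.csv --phase travelling

# full pipeline report (verdict included)
herdmove report sim/trajectories.csv --out-dir report/

# everything at once: simulate then analyse
herdmove all --mechanism all_vote --seed 2 --out-dir run/
```

All commands accept `--config config.yaml` (keys mirror `RunConfig`) and
`--seed`; every analysis is deterministic under a fixed seed.

Trajectory CSVs have columns `time_s,individual_id,x_m,y_m,heading_rad[,day_id]`
with headings in mathematical radians on `[0, 2π)` (degree input is supported
at the I/O boundary via `read_trajectories(..., heading_unit="deg")`; a
lat/lon → local-metres helper is in `herdmove.io`).

## Library tour

```python
import herdmove as hm

table, truth = hm.run_simulation(hm.AgentConfig(mechanism="all_vote", seed=1))
group = hm.group_series(table)
events = hm.retained(hm.find_decisions(group))
curve = hm.decision_curve(events[0], group, "departure")
stats = hm.cross_correlate(curve)
print(stats.corr_max_lag_s, stats.symmetry_index)

report = hm.run_pipeline(table)
print(report.verdict)
```

Module map: `io` (data model, CSV, config) · `kinematics` (speeds, circular
statistics, group series) · `changepoint` (PELT segmentation) · `detection`
(departure events and filters) · `metrics` (decision parameter, ccf,
bootstrap) · `model` (simulator and dataset generator) · `leadership`
(dyadic lag scores and dominance statistics) · `pipeline` (orchestration and
verdict) · `cli`.
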