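# teamsync

Dyadic physiological synchrony analysis for team training sessions.

When a medical team works through a simulated mass-casualty scenario, each
member's cardiac state can be recorded continuously (ECG R-peak streams) along
with their position on the training floor. `teamsync` turns those streams into
a team-level analysis of **physiological synchrony (PS)**: how similar two
members' cardiac dynamics are, second by second, and what influences that
similarity. It is written for simulation-training researchers and
psychophysiologists who have beat-interval and position-tracking data per
participant and want a reproducible pipeline from raw streams to statistics.

## What it computes

1. **Per-second cardiac metrics** from NN (normal-to-normal beat) intervals:
   heart rate as a 30-s moving average, HR(t) = 60000 / mean(NN in (t−30 s, t]),
   and the ultra-short-term HRV indices RMSSD = √(mean ΔNN²) and SDNN
   (sample SD of NN) over trailing 90-s windows.
2. **Dyadic synchrony** for every pair of team members: the dynamic-time-warping
   (DTW) cost of aligning the two members' metric series inside a sampling
   interval of Δ seconds (Δ ∈ {5, 10, 15, 30, 60, 90, 120}), divided by Δ —
   "dtw per second". Local cost |aᵢ − bⱼ|, symmetric unit steps
   {(1,1),(1,0),(0,1)}. Lower dtw/second = more similar patterns = higher
   synchrony.
3. **Dyadic proximity**: mean Euclidean floor-plane distance (m) per sampling
   interval, on exactly the same interval tiling.
4. **Phase comparisons**: per-dyad phase-averaged dtw/second compared between
   baseline, pre-scenario and scenario phases with exact Wilcoxon signed-rank
   tests, Benjamini–Hochberg correction within each metric's family, and
   matched-pairs rank-biserial effect sizes r = (W⁺ − W⁻)/(W⁺ + W⁻).
5. **Influence models**: linear mixed-effects models of interval-level
   dtw/second on proximity, scenario type, scenario order and their
   interaction, with random intercepts for team, dyad and sampling-interval
   index; sequential likelihood-ratio model selection; and a stability sweep
   showing which effects survive as Δ grows.
6. **A synthetic session generator** producing full teams-of-3-or-4 sessions
   (beats, trajectories, annotations, events) with known ground-truth coupling
   and an optional proximity→coupling link, so the entire pipeline is testable
   end to end without any recordings.

## Worked example

Generate four synthetic teams and run the pipeline (HR metric, Δ = 5 and 60 s):

```python
from teamsync import PipelineConfig, run_pipeline

cfg = PipelineConfig(
    seed=7,
    output_dir="demo-out",
    metrics=["HR"],
    intervals=[5, 60],
    synthesis={"n_teams": 4},       # generator defaults: mixed 3-4-member teams
    influence_metrics=["HR"],
    stability_intervals=[60],
)
result = run_pipeline(cfg)
```

`demo-out/phase_stats.json` then contains, among the comparisons:

```
baseline vs scenario: n_pairs=24, p_adj=1.2e-07, r_rb=1.0,
magnitude="large", higher_ps_phase="scenario"
```

Every one of the 24 dyads had lower dtw/second (higher synchrony) during the
scenarios than at baseline — the generator's default coupling rises from 0.1
at baseline to 0.85 in scenarios, and the pipeline recovers that as a large,
significant effect. `demo-out/influence.json` reports the selected mixed
model (tier 2 on this small demo: proximity + scenario type) with a positive
proximity coefficient (+0.090, i.e. greater distance → higher dtw → lower
synchrony) that is not yet significant at this scale (p = 0.21, 4 teams,
4608 intervals); the powered 20-team version of this experiment lives in the
reproduction script below. The tidy tables (`sync.csv`, `proximity.csv`,
`metrics.csv`) have stable column orders:

```
sync.csv:      team_id, member_a, member_b, metric, phase, delta_s,
               interval_index, interval_start_s, dtw_per_second, n_valid
proximity.csv: team_id, member_a, member_b, phase, delta_s,
               interval_index, interval_start_s, mean_distance_m, n_samples
metrics.csv:   participant_id, metric, t_s, value, valid
```

The same run is available from a shell:

```bash
teamsync simulate --seed 7 --n-teams 4 --out data/      # write input files
teamsync run --config config.yaml                       # full pipeline
```

with `metrics`, `sync`, `phases` and `influence` subcommands for stagewise
runs, and `--seed/--intervals/--metrics` overrides.

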