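# Methods

## Signal model and conventions

All streams share one session clock (seconds, t = 0 at recording start) and
phase spans are half-open `[start_s, end_s)`. Beat files carry absolute R-peak
times in milliseconds; NN intervals are always derived as successive peak
differences, never stored, so the two representations cannot disagree. Gaps
between annotated phases (hot washes, breaks) are simply unannotated time:
sampling-interval tilings never cross a phase boundary, while the trailing
metric windows may use whatever recording precedes a phase (sessions include a
lead-in before the baseline for exactly this reason).

### Per-second cardiac metrics

* **HR** — 60000 / mean(NN) over a trailing 30-s window, i.e. beats per minute
  over the window, not the mean of instantaneous rates. The two definitions
  differ under variable rhythm; the reciprocal-of-mean form is the quantity a
  moving-average rate monitor reports.
* **RMSSD, SDNN** — over trailing 90-s windows; SDNN uses the sample (n−1)
  denominator, standard for short segments; RMSSD needs at least 3 NN
  intervals.
* Windows are causal and half-open `(t − w, t]`, and an NN interval belongs to
  the window containing its *terminating* R peak. Centred windows would be an
  equally defensible convention; the causal form was chosen because it is
  unambiguous and usable in streaming settings.
* A sample is valid only if the window does not reach before the first beat
  (warm-up) and the plausible NN intervals in it (≤ 2 s each; longer ones are
  treated as dropout gaps) cover at least `coverage_min` = 0.8 of the window.
  `coverage_min = 0` disables both guards and evaluates the raw formula.
* No beat-artefact correction is applied by default; an optional filter drops
  NN outside 300–2000 ms or jumping more than 20% from the previous interval.

### Synchrony score

Synchrony of a dyad in one sampling interval is the DTW cost of aligning the
two members' per-second metric values inside the interval, divided by the
interval length Δ in seconds. Design choices:

* **Local cost |a − b| (L1)** keeps the score in the metric's units, so
  "dtw per second" for HR is interpretable in bpm.
* **Steps {(1,1),(1,0),(0,1)} with unit weights**, no band constraint —
  sequences are at most 120 points.
* **Normalisation by Δ**, with division by warping-path length available as
  `normalize: path`; the two differ only by the path-length/Δ ratio.
* Phases are tiled by consecutive non-overlapping intervals anchored at the
  phase start, the trailing remainder dropped; interval indices are
  per-phase, so the mixed models' "interval index" grouping factor means
  time-bin identity.
* Seconds invalid for either member are masked pairwise; an interval is scored
  only if joint coverage is ≥ 80% of Δ, otherwise its record carries NaN.
* Series are not z-scored before DTW by default (units retained);
  per-participant standardisation is available for cross-metric comparisons.

Proximity uses the identical tiling: positions are linearly interpolated onto
the 1-Hz grid, the pairwise Euclidean floor-plane distance is averaged within
each interval, and the synchrony and proximity tables join one-to-one on
(dyad, Δ, interval index). Floor-plane (2-D) distance was chosen over 3-D
tracker distance: vertical separation is negligible for people walking a flat
training area.

## Phase comparisons

Per-dyad phase averages of dtw/second are compared with Wilcoxon signed-rank
tests. Zero differences are discarded (Wilcoxon's convention, not Pratt's);
|d| are midranked; for n ≤ 25 the two-sided p is exact, computed by a
subset-sum dynamic program over all 2ⁿ sign assignments (midranks doubled to
integers), and beyond that a normal approximation with continuity and tie
corrections is used. The matched-pairs rank-biserial correlation
r = (W⁺ − W⁻)/(W⁺ + W⁻) is computed on the same ranks, with magnitude labels
at |r| = 0.1 / 0.3 / 0.5 (lower-inclusive boundaries). Benjamini–Hochberg
correction is applied within each metric's family of phase pairs by default
(`bh_family: pooled` corrects across metrics). Because lower dtw/second means
higher synchrony, a comparison (A, B) with positive r — dtw larger in A — is
reported as `higher_ps_phase = B`.

Dyads are treated as the paired unit without a within-team dependence
correction; dyads sharing a member are not independent, and the output
records this caveat. Pooled categories (`baseline`, `pre`, `scenario`)
average a dyad's per-phase means within the category.

## Influence models

The interval-level model table contains one row per dyad × Δ × scenario
interval with response dtw/second and covariates proximity (metres,
untransformed), scenario type (street = reference), scenario order
(first = reference) and their interaction. Fixed effects enter cumulatively
in five tiers (intercept-only through the full interaction model). Random
structure: team is the top-level grouping factor with a random intercept;
dyad identity and interval index enter as variance components within team.
A fully crossed specification (interval index shared across teams) is not
tractable in the variance-components machinery used here, and the within-team
reading — time-bin identity shared across a team's dyads — is the natural
grouping for a protocol where every team runs the same scenario clock.

Tiers are compared by sequential likelihood-ratio tests on maximum-likelihood
fits (χ², 1 df); the selected tier is the highest whose added term is
significant at 0.05, with parsimony on ties. The reported fit of the selected
tier uses REML, with Wald-z confidence intervals and p-values for fixed
effects. Non-convergent fits are retried with the interval component dropped,
then the dyad component; every simplification is recorded in the output.

The stability sweep refits the selected tier per metric for each Δ and
records which fixed effects retain p ≤ 0.05. Two identification caveats that
shape its behaviour (and the package's tests):

* With the interaction term in the model, the scenario main effect is
  identified *between* teams (each team experiences one scenario-order
  arrangement), so its standard error is governed by between-team variance
  and barely shrinks with interval count. Sweeps are therefore run on the
  selected tier capped at the additive model when the interaction was not
  selected.
* Consecutive intervals are serially dependent (the 30-s/90-s metric windows
  overlap across 5-s tiles), so interval-level Wald tests are anti-conservative
  for slowly varying covariates. This is a property of the modelling approach
  itself, visible in the stability sweep as effects "fading" when fewer,
  longer intervals are used.

## Synthetic session generator

The generator emulates a mixed-reality mass-casualty team training: teams of
3–4 members; a 2-min standing baseline, and for each of two scenarios (street,
tunnel; order randomised per team) a 2-min preparation phase followed by a
480-s scenario; 60-s interruptions between blocks and a 120-s lead-in before
the baseline.

**Cardiac model.** Participant i's instantaneous mean RR is
`RR_i(t) = base_i (1 + a·m_i(t))` with
`m_i(t) = κ_i(t)·s(t) + (1 − κ_i(t))·u_i(t)`, where `s` is a team-shared
driver (unit-variance sum of sinusoids at 0.1 Hz — Mayer-wave band — and
0.02 Hz — slow task drift) and `u_i = osc_amp·(same spectrum, random phases) +
bias_i` is the individual process. The personal tonic offset `bias_i`
(SD 3.5 in modulation units) is the key design element: coupling acts on
heart-rate *levels*, pulling members onto the shared driver, because level
alignment is what a 30-s moving-average HR can actually transmit to 5-s DTW
windows — purely oscillatory coupling at these frequencies is almost entirely
averaged away. Beat times accumulate RR plus white noise whose SD is itself
modulated (`rr_noise·(1 + b·m)`), so RMSSD and SDNN also respond to coupling.
Coupling is set per phase (defaults 0.1 baseline / 0.4 pre / 0.85 scenario —
the task-dependence ground truth) and, when the proximity link is on,
attenuated by the member's distance from the team centroid,
`κ_eff = κ·exp(−d/2 m)` — the proximity ground truth. A per-member reaction
latency to the shared driver, applied in the tunnel scenario only
(`tunnel_lag_s`), injects a transient desynchronisation that short DTW windows
detect and long windows warp away; knobs for an order effect
(`kappa_order_delta`) and a scenario×order interaction
(`tunnel_lag_second_only`) exist for model-selection experiments.

**Movement model.** Each member performs a mean-reverting random walk
(attraction 0.8 /s, step SD 1.7 m/s) toward a near-stationary team centroid,
reflected at the 10 × 10 m arena bounds; with attraction 0 the stationary
distribution is uniform over the arena (mean pairwise distance ≈ 5.21 m,
which the tests verify). The fast mixing is deliberate: interval-mean
distances are then serially nearly uncorrelated, which keeps Wald inference
on the proximity coefficient close to nominal when the link is disabled —
slow movement plus the windowing-induced residual autocorrelation produces
classic spurious-regression inflation.

All randomness for a cohort flows from a single seeded generator; beat noise
is pre-drawn with a count independent of coupling parameters, so changing κ
alone changes nothing else. Outputs (CSV/YAML/JSON) are byte-identical across
reruns with the same seed. Ground truth (κ per phase, link parameters, base
RRs, scenario order) is serialised beside each team's files.

**What the generator does and does not emulate.** It reproduces the protocol
structure, realistic RR magnitudes, coupling that all three metrics can see,
and a controllable proximity link. It does not attempt physiological realism
of the cardiac generator itself (no point-process model, baroreflex or
respiration), its arousal-level spread is deliberately wide — synthetic
baseline HRs span roughly 45–190 bpm, so absolute dtw/second values are
larger than typical empirical ones — and movement is a random walk, not
task-driven behaviour. Passing tests therefore demonstrate that the pipeline
recovers known relationships (directions, orderings, significance patterns)
under controlled conditions, not that empirical effect sizes would match.

## Problem sizes used in the shipped studies

The simulation studies bundled with the tests and the reproduction script use
sizes chosen to complete on a single CPU in minutes: coupling monotonicity on
21 dyads (7 teams of 3) per κ level; proximity recovery on 20 replicate
cohorts of 20 mixed-size teams per arm (link on / link off), with the
likelihood-ratio tier selection run once on the first replicate and the
selected tier refitted per replicate; the stability demonstration on 12 teams
with scenario coupling 0.95 and an 8-s tunnel latency. Model selection,
confidence intervals and p-values are computed exactly as in the full
pipeline.

## Known limitations

* Wald-z inference on REML fits, without degrees-of-freedom corrections;
  anti-conservative at small team counts and under serial dependence (above).
* The exact signed-rank enumeration switches to the tie-corrected normal
  approximation above n = 25 pairs.
* Phase comparisons ignore within-team dyad dependence (flagged in output).
* DTW is O(nm) per interval; fine for Δ ≤ 120 s at 1 Hz.
* The annotation reader accepts YAML only.
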