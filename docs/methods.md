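# Methods

## Model

One *attempt* is a continuous-time race of exponential clocks. All `N`
individuals hold initiation clocks at rate `k_i/τ_o`; the earliest
firing designates the sole initiator (other initiation clocks are
discarded — concurrent attempts are out of scope). While `r` individuals
have departed (the count includes the initiator, so `r ≥ 1` wherever the
following and cancelling rates are evaluated), each remaining individual
holds a following clock at rate `1/τ_r`, `τ_r = (1/k_i)(α_f + β_f(N−r)/r)`,
and the initiator holds a cancelling clock at rate
`C_r = k_i·α_c/(1 + (r/γ_c)^{ε_c})`. After every event all pending
clocks are redrawn with the updated `r`; because exponential clocks are
memoryless this "redraw everything" scheme has exactly the law of a
Gillespie direct-method simulation (total rate + categorical winner),
which the test suite uses as an independent oracle. Following decisions
are irreversible; an attempt ends in success (`r = N`) or failure (the
cancel clock fires first). Termination is guaranteed because the cancel
rate is strictly positive for every `r < N`.

The departed-count convention (`r` includes the initiator) is forced by
the rate structure — `τ_r` diverges at `r = 0` — and reproduces the
characteristic crossover of the baseline parameterisation: with `k = 1`
and `N = 10`, the per-follower rate `1/τ_r` first exceeds `C_r` at
`r = 3`, i.e. two followers plus the initiator.

An *evaluation* is `2000 × N` sequential attempts with leadership
tendencies carried over between attempts and reset at the start of the
next evaluation. Only the attempt's initiator updates its tendency
(`L ← L(1−λ) + λr`, truncated to `[0.1, 0.9]`).

## Parameters

| parameter | default | meaning |
|---|---|---|
| `τ_o` | 1290 time units | spontaneous initiation time constant |
| `α_f`, `β_f` | 162.3, 75.4 time units | following time constant offset / group coefficient |
| `α_c` | 0.009 events per time unit | lone-initiator cancel rate |
| `γ_c`, `ε_c` | 2.0, 2.3 (dimensionless) | cancel-decay half-saturation count and steepness |
| sigmoid centre / slope / scale | 0.5 / 10 / 2 | `L → k` logistic; `k(0.5)=1`, `k(L)+k(1−L)=2` |
| `λ` | 0.02 | learning rate; low values emphasise long-term experience |
| LT bounds | `[0.1, 0.9]` | keep `k` strictly positive in both directions |
| rewards | 1 (success), 0 (failure) | symmetric pull, no intrinsic bias |

The rate constants are field estimates from observed group departures;
the sigmoid shape constants are exposed as parameters so that the
slope-sensitivity of differentiation can be explored without code
changes. Time units are arbitrary-but-consistent; only rate ratios
matter for attempt outcomes, so absolute time never enters any reported
statistic.

## Experiment design

Treatments form a (group size × initial LT) grid, by default sizes
10–150 and initial values {0.2 (low), 0.5 (moderate), 0.8 (high)}, 50
replicate evaluations per cell. RNG streams derive from
`SeedSequence(base_seed, spawn_key=(replicate,))` — deliberately
independent of the treatment, so replicate `r` of every cell runs with
identical random streams (matched seeds). A useful exact consequence:
with adaptation off and a *uniform* fixed LT, every rate in an attempt
carries the same factor `k`, which cancels from the clock race, so the
fixed-LT control arms (0.2/0.5/0.8) produce bit-identical attempt
sequences at matched seeds — the fixed-LT neutrality of the control
study holds exactly here, not just statistically.

The "original model" baseline is the fixed-LT arm at `L = 0.5` (`k = 1`
everywhere), which leaves every rate at its baseline value.

## Changepoint analysis

Each agent's LT series (the value in force during each attempt,
piecewise-constant between its initiations) is segmented by exact
least-squares changepoint estimation: dynamic programming over the
O(n²) segment-cost matrix finds, for every break count `m ≤ 5`, the
placement minimising total within-segment squared deviation with every
segment at least 5% of the series; `m` is then chosen by BIC,
`n·log(RSS/n) + (2m+2)·log n`. For feasible sizes the DP is verified
against exhaustive enumeration of all break placements. Segments are
classed high (mean ≥ 0.775), low (mean ≤ 0.225, the symmetric
complement — only the high threshold is externally given) or
intermediate. An evaluation's *differentiation attempt* is the earliest
start of any agent's high segment; *transitions* are low↔high class
changes at breaks at or after that point, with intermediate segments
counting in neither direction.

Numerical choices: dense series longer than 1000 points are averaged
into ≤1000 equal-width bins before segmentation (exact DP is O(n²));
breakpoints map back to attempt indices with ≤0.1%-of-evaluation
resolution loss, negligible against every reported quantity. Constant
series get an RSS floor of `1e-12·n` inside the BIC log to avoid
`log 0`; equal-cost placements resolve to the earliest break
(first-minimum tie-break); a clock-race tie (probability zero in
floating point, but seed-determinism demands a rule) resolves to the
lowest agent id.

## Statistics

Per-evaluation metrics — success percentage, differentiation percentage,
low→high transitions as % of group size, final high-LT share of the
group — are aggregated as mean ± SE over replicates. Cells are compared
with a pooled-variance two-sample Student's t-test (computed from the
textbook formula; a Welch variant is emitted alongside for robustness),
degenerate zero-variance samples following the convention p = 1 for
equal means and p = 0 otherwise. Pairwise p-values are reported raw and
Holm-corrected.

## What the simulations do and do not show

The simulator *is* the study system: there is no external data. Attempt
logs and LT histories are genuine draws from the model, so passing tests
demonstrate internal consistency (engine law, analysis correctness,
reproducibility) and the model's qualitative predictions
(differentiation into extreme roles, success gain over the fixed
baseline, control-arm neutrality). They say nothing about real animal
groups beyond what the observational rate constants carry in. Known
model limitations, deliberate here: global communication (every
individual sees every departure), no spatial movement, all-or-nothing
success, one attempt at a time, a static environment.

One behavioural caveat documented for users: because following and
cancelling scale with the same `k` at uniform LT, a uniform group's
success probability is exactly the baseline's regardless of the shared
LT value. Differentiation from a uniform start therefore proceeds by the
luckiest agent pulling away while the rest decline, and is typically
complete within a few percent of an evaluation — including for small,
initially-high groups, where the eventual leader's LT usually never
leaves the high band, so the measured differentiation cost for that cell
is near zero rather than in the tens of percent. Desk-scale runs
(reduced replicate counts and, for the significance check, shorter
evaluations of `500 × N` attempts — differentiation completes well
inside that budget) keep the default suite within interactive runtimes;
the full grid is cluster-scale and config-driven.
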