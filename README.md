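# leadsim

Emergence of leaders and followers in an initially homogeneous group:
a continuous-time, event-driven simulator of collective-movement
initiation with experience-driven leadership tendencies, plus the
changepoint analysis that detects when stable leader roles appear.

`leadsim` is aimed at researchers in collective animal behaviour and
swarm robotics who want to study how *identical* individuals can
differentiate into stable leaders and followers purely through feedback
from success and failure, without any a-priori differences.

## The model

A group of `N` individuals repeatedly attempts collective movements.
Each attempt is a race of independent exponential clocks governed by
three rules whose rate constants were estimated from direct observation
of primate group departures:

- **Initiation.** Every individual may start a movement at rate
  `k/τ_o`; the first to fire becomes the attempt's sole initiator.
- **Following.** With `r` individuals departed (initiator included),
  each remaining individual joins at rate `1/τ_r` with
  `τ_r = (1/k)(α_f + β_f (N − r)/r)` — mimetic amplification: following
  accelerates as the moving subgroup grows.
- **Cancelling.** The initiator aborts at rate
  `C_r = k α_c / (1 + (r/γ_c)^{ε_c})`, which decays as followers
  accumulate. An attempt ends in success (all `N` departed) or in a
  cancellation (failure).

Each individual carries a leadership tendency `L ∈ [0.1, 0.9]` mapped
onto the rate modifier through a logistic function

    k = 2 / (1 + exp((0.5 − L′) · 10)),

with `L′ = L` for initiating and `L′ = 1 − L` for following and
cancelling: high-`L` individuals initiate more, follow less and give up
less. `L = 0.5` gives `k = 1`, recovering the baseline model exactly,
and `k(L) + k(1 − L) = 2` so low and high tendencies pull with equal
magnitude. After every attempt the initiator reinforces its tendency,

    L ← L(1 − λ) + λr,   r = 1 on success, 0 on failure,   λ = 0.02,

truncated to `[0.1, 0.9]`. Followers never update. Over thousands of
attempts this nonlinear feedback splits an initially identical group
into a few stable high-`L` leaders and many low-`L` followers.

Role differentiation is *measured*, not assumed: each agent's `L`
time series is segmented by exact least-squares multiple-changepoint
estimation (dynamic programming with BIC model selection), and a
segment mean ≥ 0.775 marks an emerged leader.

## Worked example

```python
import numpy as np
from leadsim import EvaluationConfig, run_evaluation, summarize_evaluation, success_percentage

cfg = EvaluationConfig(group_size=10, initial_lt=0.5, attempts_multiplier=2000, seed=42)
result = run_evaluation(cfg, replicate_index=0)
summary = summarize_evaluation(result)

print(f"success: {success_percentage(result):.1f}% of 20000 attempts")
print("final LT values:", np.round(np.sort(result.final_lts), 3))
print("first high-LT emergence at attempt", summary.differentiation_attempt,
      f"({100 * summary.differentiation_fraction:.2f}% of the evaluation)")
```

prints

```
success: 69.1% of 20000 attempts
final LT values: [0.1   0.1   0.1   0.105 0.107 0.109 0.111 0.112 0.118 0.9  ]
first high-LT emergence at attempt 5060 (25.30% of the evaluation)
```

The initially identical group has split into one stable leader locked at
the upper LT bound and nine followers at the lower bound, and success
runs far above the ~32% of the fixed-`k = 1` baseline. In this replicate
the eventual leader first drifted down with the pack before pulling
away, so its high segment begins a quarter of the way in; in other
replicates the winner never dips and the emergence index is 0.

The same experiment from the shell, over a grid of treatments:

```bash
leadsim all --group-sizes 10,20 --initial-lt 0.2,0.5,0.8 \
        --replicates 5 --attempts-multiplier 200 --seed 42 --out-dir out/
```

writes per-cell attempt logs and LT histories (CSV), the per-evaluation
differentiation summary, and treatment-level mean/SE tables with
pairwise t-tests (raw and Holm-corrected p-values).

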