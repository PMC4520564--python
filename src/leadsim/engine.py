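"""Continuous-time event engine for one collective-movement attempt.

An attempt is a race of independent exponential clocks.  Every individual
first draws an initiation time at rate ``k(L_i) / tau_o``; the earliest
wins and departs, and no further initiations are possible.  Then, at each
departed count ``r``, every remaining individual holds a following clock
at rate ``1 / tau_r`` (its own k) while the initiator holds a cancelling
clock at rate ``C_r``.  The earliest clock fires, the state updates, and
all pending clocks are redrawn — valid because exponential clocks are
memoryless, and equivalent in law to a Gillespie direct-method simulation.
The attempt ends in success (all N departed) or failure (cancel fires).

After the attempt, and only in adaptive mode, the initiator's LT is
reinforced up on success and down on failure; followers never update.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import AdaptationParameters, ModelParameters, k_factor, update_lt

__all__ = ["AttemptResult", "draw_event_time", "select_initiator", "simulate_attempt"]


@dataclass
class AttemptResult:
    """Outcome of one initiation attempt.

    ``event_log`` is an ordered list of ``(kind, agent_id, time)`` tuples
    with strictly increasing absolute times, present only when the
    attempt was simulated with ``collect_log=True``.
    """

    initiator_id: int
    success: bool
    final_departed: int
    initiator_lt_before: float
    initiator_lt_after: float
    event_log: list[tuple[str, int, float]] | None = field(default=None, repr=False)


def draw_event_time(rate: float, rng: np.random.Generator) -> float:
    """One exponential waiting time with mean ``1 / rate``.

    A rate of zero means the event can never happen; callers must not
    draw for impossible events, so ``rate <= 0`` raises.
    """
    if not rate > 0:
        raise ValueError(f"rate must be strictly positive, got {rate}")
    return rng.exponential(1.0 / rate)


def select_initiator(
    lts: np.ndarray,
    params: ModelParameters,
    rng: np.random.Generator,
    k_init: np.ndarray | None = None,
) -> tuple[int, float]:
    """Race the initiation clocks; return (winner id, winning time).

    Each individual draws at rate ``k(L_i) / tau_o``; ties (measure zero)
    break to the lowest agent id.  ``k_init`` may be passed to reuse
    precomputed k factors across attempts.
    """
    lts = np.asarray(lts, dtype=float)
    if lts.size < 2:
        raise ValueError(f"group size must be >= 2, got {lts.size}")
    if k_init is None:
        k_init = k_factor(lts, params)
    times = rng.exponential(size=lts.size) * (params.tau_o / k_init)
    winner = int(np.argmin(times))
    return winner, float(times[winner])


def simulate_attempt(
    lts: np.ndarray,
    params: ModelParameters,
    adapt: AdaptationParameters,
    rng: np.random.Generator,
    collect_log: bool = False,
    k_init: np.ndarray | None = None,
    k_follow: np.ndarray | None = None,
) -> AttemptResult:
    """Simulate one attempt; in adaptive mode, update the initiator's LT in place.

    Parameters
    ----------
    lts : ndarray
        Current LT values, one per agent.  Mutated in place at index
        ``initiator_id`` when ``adapt.adaptive`` is set, so that LT
        values persist across a sequence of attempts.
    k_init, k_follow : ndarray, optional
        Precomputed ``k(L_i)`` and ``k(1 - L_i)`` vectors; callers that
        run many attempts maintain these incrementally.  When provided
        they must be consistent with ``lts``.
    collect_log : bool
        Record the full event log (slower); the fast path tracks only
        the outcome.
    """
    lts = np.asarray(lts, dtype=float)
    n = lts.size
    if n < 2:
        raise ValueError(f"group size must be >= 2, got {n}")
    if k_init is None:
        k_init = k_factor(lts, params)
    if k_follow is None:
        k_follow = k_factor(1.0 - lts, params)

    initiator, t0 = select_initiator(lts, params, rng, k_init=k_init)
    lt_before = float(lts[initiator])
    log: list[tuple[str, int, float]] | None = None
    if collect_log:
        log = [("initiate", initiator, t0)]

    # Pending follower clocks: keep candidate k's in ascending agent-id
    # order so argmin's first-occurrence rule breaks ties to lowest id.
    cand_ids = np.delete(np.arange(n), initiator)
    kf = k_follow[cand_ids]
    cancel_base = k_follow[initiator] * params.alpha_c
    t_abs = t0
    r = 1
    success = False
    while True:
        m = n - r  # candidates still undecided
        tau_base = params.alpha_f + params.beta_f * (n - r) / r
        rates = np.empty(m + 1)
        rates[:m] = kf / tau_base
        rates[m] = cancel_base / (1.0 + (r / params.gamma_c) ** params.epsilon_c)
        waits = rng.exponential(size=m + 1) / rates
        j = int(np.argmin(waits))
        t_abs += float(waits[j])
        if j == m:  # the initiator cancelled
            if log is not None:
                log.append(("cancel", initiator, t_abs))
            break
        if log is not None:
            log.append(("follow", int(cand_ids[j]), t_abs))
        kf = np.delete(kf, j)
        cand_ids = np.delete(cand_ids, j)
        r += 1
        if r == n:
            success = True
            break

    lt_after = lt_before
    if adapt.adaptive:
        lt_after = update_lt(lt_before, success, adapt)
        lts[initiator] = lt_after
    return AttemptResult(
        initiator_id=initiator,
        success=success,
        final_departed=r,
        initiator_lt_before=lt_before,
        initiator_lt_after=lt_after,
        event_log=log,
    )
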