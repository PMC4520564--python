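"""Independent reference implementations used only to cross-check the package.

These deliberately share no code with the implementation: the attempt
oracle uses the Gillespie direct method (one total-rate clock plus a
categorical winner draw) instead of redrawing per-individual clocks, and
the segmentation oracle enumerates every admissible break placement.
"""

from __future__ import annotations

import itertools

import numpy as np


def gillespie_success(lts, params, rng) -> bool:
    """One attempt via the direct method; returns the success flag.

    Winner selection: the minimum of independent exponential clocks with
    rates ``r_i`` occurs at rate ``sum r_i`` and belongs to clock i with
    probability ``r_i / sum r_i``.
    """
    lts = np.asarray(lts, dtype=float)
    n = lts.size
    sig = lambda x: params.k_max / (1.0 + np.exp((params.sigmoid_center - x) * params.sigmoid_slope))
    k_init = sig(lts)
    initiator = rng.choice(n, p=k_init / k_init.sum())
    remaining = [i for i in range(n) if i != initiator]
    k_cancel = sig(1.0 - lts[initiator])
    r = 1
    while remaining:
        tau = params.alpha_f + params.beta_f * (n - r) / r
        follow_rates = np.array([sig(1.0 - lts[i]) / tau for i in remaining])
        cancel = k_cancel * params.alpha_c / (1.0 + (r / params.gamma_c) ** params.epsilon_c)
        rates = np.append(follow_rates, cancel)
        pick = rng.choice(rates.size, p=rates / rates.sum())
        if pick == len(remaining):
            return False
        remaining.pop(pick)
        r += 1
    return True


def exhaustive_segment(y: np.ndarray, n_breaks: int, min_len: int):
    """Globally optimal constant-segment fit by brute-force enumeration.

    Returns (breakpoints tuple, RSS).  Breakpoint b is the index of the
    first observation of the following segment.
    """
    y = np.asarray(y, dtype=float)
    n = y.size

    def rss(a, b):
        seg = y[a:b]
        return float(((seg - seg.mean()) ** 2).sum())

    if n_breaks == 0:
        return (), rss(0, n)
    best = None
    for combo in itertools.combinations(range(min_len, n - min_len + 1), n_breaks):
        bounds = (0, *combo, n)
        if any(b - a < min_len for a, b in zip(bounds[:-1], bounds[1:])):
            continue
        total = sum(rss(a, b) for a, b in zip(bounds[:-1], bounds[1:]))
        if best is None or total < best[1]:
            best = (combo, total)
    return best
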