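"""Rate equations and leadership-tendency (LT) dynamics.

The underlying collective decision-making model is a set of three
probabilistic rules, each parameterised by rate constants estimated from
direct observation of primate group departures: an initiation rate, a
mimetic following rate that accelerates with the number of departed
individuals, and a cancellation rate that decays with it.  Each individual
carries a leadership tendency ``L`` in [0.1, 0.9] that modulates all three
rates through a logistic "k factor": high-LT individuals initiate more and
follow/cancel less, low-LT individuals do the opposite, and ``L = 0.5``
(k = 1) leaves the baseline model unchanged.

Conventions
-----------
* ``r`` is the number of *departed* individuals including the initiator,
  so ``r >= 1`` whenever the following/cancelling rates are evaluated.
* All functions accept scalars or numpy arrays for the LT argument.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ModelParameters",
    "AdaptationParameters",
    "AgentState",
    "k_factor",
    "effective_l_prime",
    "initiation_rate",
    "following_time_constant",
    "cancel_rate",
    "update_lt",
]

DECISION_KINDS = ("initiate", "follow", "cancel")


@dataclass(frozen=True)
class ModelParameters:
    """Observed rate constants plus the shape of the LT -> k sigmoid.

    Parameters
    ----------
    tau_o : float
        Time constant of spontaneous initiation; the per-individual
        baseline initiation rate is ``1 / tau_o``.
    alpha_f, beta_f : float
        Offset and group-size coefficient of the following time constant
        ``tau_r = alpha_f + beta_f * (N - r) / r``.
    alpha_c : float
        Baseline cancellation rate of a lone initiator.
    gamma_c, epsilon_c : float
        Half-saturation count and steepness of the cancellation decay
        ``C_r = alpha_c / (1 + (r / gamma_c) ** epsilon_c)``.
    sigmoid_slope, sigmoid_center, k_max : float
        Shape of the logistic mapping from LT to the multiplicative rate
        modifier ``k``; the defaults give ``k(0.5) = 1`` and the
        anti-bias symmetry ``k(L) + k(1 - L) = k_max``.
    """

    tau_o: float = 1290.0
    alpha_f: float = 162.3
    beta_f: float = 75.4
    alpha_c: float = 0.009
    gamma_c: float = 2.0
    epsilon_c: float = 2.3
    sigmoid_slope: float = 10.0
    sigmoid_center: float = 0.5
    k_max: float = 2.0

    def __post_init__(self) -> None:
        for name in ("tau_o", "alpha_f", "beta_f", "alpha_c", "gamma_c"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive, got {getattr(self, name)}")
        if not self.k_max > 0:
            raise ValueError(f"k_max must be strictly positive, got {self.k_max}")


@dataclass(frozen=True)
class AdaptationParameters:
    """Reinforcement-learning parameters for the LT update rule.

    ``lambda_rate`` is the learning rate of the linear update
    ``L <- L * (1 - lambda) + lambda * reward``; the reward is
    ``reward_success`` after a successful initiation and
    ``reward_failure`` after a cancelled one.  Updates are truncated to
    ``[lt_min, lt_max]``; the clip bounds keep the sigmoid's k factor
    away from 0.  With ``adaptive=False`` the update is never applied
    (fixed-LT control mode).
    """

    lambda_rate: float = 0.02
    lt_min: float = 0.1
    lt_max: float = 0.9
    reward_success: float = 1.0
    reward_failure: float = 0.0
    adaptive: bool = True

    def __post_init__(self) -> None:
        if not 0.0 <= self.lambda_rate <= 1.0:
            raise ValueError(f"lambda_rate must be in [0, 1], got {self.lambda_rate}")
        if not 0.0 < self.lt_min < self.lt_max < 1.0:
            raise ValueError(
                f"need 0 < lt_min < lt_max < 1, got lt_min={self.lt_min}, lt_max={self.lt_max}"
            )


@dataclass
class AgentState:
    """One individual: its index within the group and its current LT."""

    agent_id: int
    lt: float


def k_factor(l_prime, params: ModelParameters = ModelParameters()):
    """Logistic conversion of an LT-like value into a rate modifier k.

    ``k = k_max / (1 + exp((center - L') * slope))`` lies in
    ``(0, k_max)`` and increases strictly with ``l_prime``; with the
    default shape ``k(0.5) = 1`` so a moderate LT recovers the baseline
    model exactly.

    Raises
    ------
    ValueError
        If ``l_prime`` is outside the open interval (0, 1) — this
        signals a missing LT clip upstream, not a modelling choice.
    """
    lp = np.asarray(l_prime, dtype=float)
    if np.any(lp <= 0.0) or np.any(lp >= 1.0):
        raise ValueError(f"l_prime must lie strictly inside (0, 1), got {l_prime}")
    k = params.k_max / (1.0 + np.exp((params.sigmoid_center - lp) * params.sigmoid_slope))
    return k if k.ndim else float(k)


def effective_l_prime(lt, decision_kind: str):
    """Map an LT onto the sigmoid input for a given decision.

    High-LT individuals should initiate *more* but follow and cancel
    *less*, so ``L' = L`` for initiating and ``L' = 1 - L`` for
    following and cancelling decisions.
    """
    if decision_kind == "initiate":
        return lt
    if decision_kind in ("follow", "cancel"):
        return 1.0 - np.asarray(lt, dtype=float) if np.ndim(lt) else 1.0 - lt
    raise ValueError(f"unknown decision kind {decision_kind!r}; expected one of {DECISION_KINDS}")


def initiation_rate(lt, params: ModelParameters = ModelParameters()):
    """Per-individual initiation rate ``k(L) / tau_o``."""
    return k_factor(effective_l_prime(lt, "initiate"), params) / params.tau_o


def following_time_constant(lt, n: int, r: int, params: ModelParameters = ModelParameters()):
    """Following time constant ``tau_r`` for one candidate follower.

    ``tau_r = (1 / k(1 - L)) * (alpha_f + beta_f * (N - r) / r)`` where
    ``r >= 1`` counts departed individuals including the initiator.  The
    per-candidate following rate is ``1 / tau_r``; it grows with ``r``
    (mimetic amplification) and shrinks with the candidate's LT.
    """
    if n < 2:
        raise ValueError(f"group size must be >= 2, got {n}")
    if not 1 <= r <= n - 1:
        raise ValueError(f"departed count r must satisfy 1 <= r <= N-1, got r={r}, N={n}")
    k = k_factor(effective_l_prime(lt, "follow"), params)
    return (params.alpha_f + params.beta_f * (n - r) / r) / k


def cancel_rate(lt, r: int, params: ModelParameters = ModelParameters()):
    """Initiator cancellation rate ``C_r = k(1 - L) * alpha_c / (1 + (r / gamma_c)^epsilon_c)``.

    Strictly decreasing in the departed count ``r`` (an initiator with a
    large following rarely gives up) and in the initiator's LT.
    """
    if r < 1:
        raise ValueError(f"departed count r must be >= 1 (it includes the initiator), got {r}")
    k = k_factor(effective_l_prime(lt, "cancel"), params)
    return k * params.alpha_c / (1.0 + (r / params.gamma_c) ** params.epsilon_c)


def update_lt(lt: float, success: bool, adapt: AdaptationParameters = AdaptationParameters()) -> float:
    """Linear reinforcement update of an initiator's LT, truncated to bounds.

    ``L <- clip(L * (1 - lambda) + lambda * reward, lt_min, lt_max)``.
    Success and failure pull with equal magnitude toward the respective
    reward values, so the rule itself does not bias the LT distribution.
    """
    reward = adapt.reward_success if success else adapt.reward_failure
    new = lt * (1.0 - adapt.lambda_rate) + adapt.lambda_rate * reward
    return float(min(max(new, adapt.lt_min), adapt.lt_max))
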