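"""Simulator for the adaptive discounting questionnaire.

The adaptive task re-estimates the respondent's discount rate after every
choice and places the next immediate offer at the currently estimated
indifference point: for the next scheduled delayed reward (R, d), the
immediate amount is the discounted value R / (1 + K_hat d), rounded to a
whole currency unit.  Each trial is therefore maximally informative about
the current estimate.  The session ends once the running log-K estimate is
stable over a short window, or at a trial cap.

The reference procedure's internal offer grid and stopping rule are not
public; this module implements a MAP-updating staircase with a fixed
schedule cycling three delayed-reward magnitudes across five delays,
declared as this package's own convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .hierarchical import PriorHyper, map_fit
from .model import DiscountParams, p_immediate, subjective_value

__all__ = [
    "AdaptiveSession",
    "DEFAULT_SCHEDULE",
    "next_offer",
    "update_estimate",
    "run_session",
    "softmax_agent",
    "deterministic_agent",
    "default_session_prior",
]

# (R, d) pairs: three magnitudes x five delays, interleaved so consecutive
# trials vary both amount and delay.
DEFAULT_SCHEDULE: tuple[tuple[float, int], ...] = tuple(
    (R, d)
    for d, R in product((7, 20, 50, 90, 160), (30.0, 55.0, 80.0))
)

STOP_WINDOW = 3
STOP_TOL = 0.05
MAX_TRIALS = 30


def default_session_prior() -> PriorHyper:
    """Prior over log_k used for the within-session running estimate."""
    return PriorHyper(mean=np.array([-4.0]), cov=np.array([[2.0]]),
                      names=("log_k",))


def next_offer(
    R_delayed: float, delay_days: int, current_log_k: float
) -> tuple[float, float, int]:
    """Construct the next offer at the current indifference point.

    The immediate amount is round(R / (1 + K d)) for the running estimate
    K = exp(current_log_k), clipped to [1, R-1] so the offer keeps valid
    choice geometry.  Up to that integer rounding, the offer's implied
    indifference rate equals the current estimate.
    """
    if not R_delayed > 1:
        raise ValueError(f"schedule R must exceed 1, got {R_delayed}")
    if not np.isfinite(current_log_k):
        raise ValueError("current_log_k must be finite")
    K = float(np.exp(current_log_k))
    r = float(np.round(subjective_value(R_delayed, delay_days, K)))
    r = float(np.clip(r, 1.0, R_delayed - 1.0))
    return r, float(R_delayed), int(delay_days)


def _offer_clipped(r: float, R: float) -> bool:
    """Offer pinned at the geometry boundary: cannot probe indifference."""
    return r <= 1.0 or r >= R - 1.0


def update_estimate(
    history: pd.DataFrame,
    prior: PriorHyper | None = None,
    *,
    pin_log_beta: float = 0.0,
) -> float:
    """MAP log_k given the session history (log_beta pinned).

    Deterministic given the history: a single optimizer start at the prior
    mean, no random restarts.
    """
    if len(history) == 0:
        raise ValueError("update_estimate requires at least one trial")
    prior = prior or default_session_prior()
    res = map_fit(history, prior, n_restarts=0, pin_log_beta=pin_log_beta)
    return float(res.theta[0])


@dataclass
class AdaptiveSession:
    """Trial-by-trial log of one adaptive run."""

    trials: pd.DataFrame
    estimates: list[float] = field(default_factory=list)
    stopped_reason: str = "max_trials"
    final_log_k: float = np.nan


def softmax_agent(log_k: float, log_beta: float) -> Callable:
    """Stochastic respondent choosing via the softmax rule."""
    params = DiscountParams(log_k=log_k, log_beta=log_beta)

    def agent(r, R, d, rng: np.random.Generator) -> str:
        return "immediate" if rng.random() < p_immediate(r, R, d, params) else "delayed"

    return agent


def deterministic_agent(log_k: float) -> Callable:
    """Noiseless respondent: immediate iff it exceeds the discounted value."""
    K = float(np.exp(log_k))

    def agent(r, R, d, rng=None) -> str:
        return "immediate" if r > subjective_value(R, d, K) else "delayed"

    return agent


def run_session(
    agent: Callable,
    prior: PriorHyper | None = None,
    *,
    stop_window: int = STOP_WINDOW,
    stop_tol: float = STOP_TOL,
    max_trials: int = MAX_TRIALS,
    schedule: Sequence[tuple[float, int]] | None = None,
    seed: int = 0,
    participant_id: str = "sim",
    timepoint: str = "MA1",
) -> AdaptiveSession:
    """Run one adaptive session against a choice-generating agent.

    The session stops with reason ``"stable"`` when the range of the last
    ``stop_window + 1`` running log_k estimates falls below ``stop_tol``,
    else with ``"max_trials"`` at the cap.  All randomness (the agent's
    choices) flows from one generator seeded by ``seed``, so a rerun with
    the same seed reproduces the session exactly.
    """
    prior = prior or default_session_prior()
    schedule = tuple(schedule) if schedule is not None else DEFAULT_SCHEDULE
    rng = np.random.default_rng(seed)
    log_k = float(prior.mean[0])
    rows: list[dict] = []
    estimates: list[float] = []
    informative: list[bool] = []
    reason = "max_trials"
    for t in range(max_trials):
        R, d = schedule[t % len(schedule)]
        r, R, d = next_offer(R, d, log_k)
        informative.append(not _offer_clipped(r, R))
        choice = agent(r, R, d, rng)
        rows.append(
            {
                "participant_id": participant_id,
                "timepoint": timepoint,
                "task_tag": "adaptive",
                "trial_index": t + 1,
                "r_immediate": r,
                "R_delayed": R,
                "delay_days": d,
                "choice": choice,
            }
        )
        history = pd.DataFrame(rows)
        log_k = update_estimate(history, prior)
        estimates.append(log_k)
        if len(estimates) > stop_window and all(
            informative[-(stop_window + 1):]
        ):
            window = estimates[-(stop_window + 1):]
            if max(window) - min(window) < stop_tol:
                reason = "stable"
                break
    return AdaptiveSession(
        trials=pd.DataFrame(rows),
        estimates=estimates,
        stopped_reason=reason,
        final_log_k=float(estimates[-1]),
    )
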