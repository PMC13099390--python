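"""Hyperbolic subjective value and the softmax choice likelihood.

The subjective value of a reward R delivered after d days is

    V(R, d) = R / (1 + K d),

with K > 0 the hyperbolic discount rate (1/day).  The probability of taking
the immediate option r over the delayed option (R, d) is a logistic function
of the value difference,

    P(immediate) = sigma(beta * (r - V(R, d))),    sigma(x) = 1/(1+e^(-x)),

where beta > 0 (inverse temperature, 1/currency) scales choice determinism.
Both parameters are carried on the natural-log scale, where the population
distribution of K is approximately Gaussian.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit, log_expit

from .items import ChoiceItem, ItemBank, implied_item_k

__all__ = [
    "DiscountParams",
    "subjective_value",
    "p_immediate",
    "log_likelihood",
    "deterministic_choices",
    "choice_sign",
]

IMMEDIATE = "immediate"
DELAYED = "delayed"


@dataclass(frozen=True)
class DiscountParams:
    """Per-participant parameters on the fitting (natural-log) scale."""

    log_k: float
    log_beta: float = 0.0

    def __post_init__(self) -> None:
        if not (np.isfinite(self.log_k) and np.isfinite(self.log_beta)):
            raise ValueError(
                f"parameters must be finite, got log_k={self.log_k}, "
                f"log_beta={self.log_beta}"
            )

    @property
    def k(self) -> float:
        return float(np.exp(self.log_k))

    @property
    def beta(self) -> float:
        return float(np.exp(self.log_beta))


def subjective_value(R, d, K):
    """Hyperbolically discounted value R / (1 + K d).

    Parameters
    ----------
    R : float or array
        Delayed reward amount, > 0.
    d : float or array
        Delay in days, >= 0.
    K : float or array
        Discount rate, > 0.
    """
    R = np.asarray(R, dtype=float)
    d = np.asarray(d, dtype=float)
    K = np.asarray(K, dtype=float)
    if np.any(R <= 0):
        raise ValueError("R must be > 0")
    if np.any(K <= 0):
        raise ValueError("K must be > 0")
    if np.any(d < 0):
        raise ValueError("d must be >= 0")
    out = R / (1.0 + K * d)
    return float(out) if out.ndim == 0 else out


def _argument(r, R, d, params: DiscountParams):
    v = subjective_value(R, d, params.k)
    return params.beta * (np.asarray(r, dtype=float) - v)


def p_immediate(r, R, d, params: DiscountParams):
    """Softmax probability of choosing the immediate reward.

    Returns sigma(beta * (r - V(R, d))); exactly 0.5 when r equals the
    delayed option's subjective value.  Evaluation is overflow-safe for
    arbitrarily large |arguments| (probabilities saturate without NaN).
    """
    # clip so saturated sigmoids never return exactly 0 or 1
    eps = 1e-16
    out = np.clip(expit(_argument(r, R, d, params)), eps, 1.0 - eps)
    return float(out) if np.ndim(out) == 0 else out


def choice_sign(choice) -> np.ndarray:
    """+1 for immediate choices, -1 for delayed; validates labels."""
    c = np.asarray(choice)
    sign = np.where(c == IMMEDIATE, 1.0, np.where(c == DELAYED, -1.0, np.nan))
    if np.any(np.isnan(sign)):
        bad = sorted(set(np.asarray(c)[np.isnan(sign)].tolist()))
        raise ValueError(f"invalid choice label(s) {bad!r}; "
                         f"expected {IMMEDIATE!r} or {DELAYED!r}")
    return sign


def log_likelihood(trials: pd.DataFrame, params: DiscountParams) -> float:
    """Summed log probability of the observed choices.

    ``trials`` needs columns r_immediate, R_delayed, delay_days, choice.
    Additive over disjoint trial sets and always <= 0.  log probabilities
    are computed through the log-logistic directly, so extreme parameters
    give large negative values rather than -inf from a rounded-to-zero
    probability.
    """
    if len(trials) == 0:
        raise ValueError("log_likelihood requires at least one trial")
    x = _argument(
        trials["r_immediate"].to_numpy(float),
        trials["R_delayed"].to_numpy(float),
        trials["delay_days"].to_numpy(float),
        params,
    )
    sign = choice_sign(trials["choice"].to_numpy())
    return float(np.sum(log_expit(sign * x)))


def deterministic_choices(bank: ItemBank, K: float) -> pd.DataFrame:
    """Choices of a noiseless hyperbolic discounter over an item bank.

    An agent with discount rate K takes the immediate reward on items whose
    implied indifference rate K* lies below K, and the delayed reward where
    K* > K.  Exact ties (K == K*) are flagged.

    Returns
    -------
    DataFrame with columns item_id, implied_k, choice, tie.
    """
    if not K > 0:
        raise ValueError("K must be > 0")
    rows = []
    for item in bank:
        k_star = implied_item_k(item)
        tie = K == k_star
        rows.append(
            {
                "item_id": item.item_id,
                "implied_k": k_star,
                "choice": IMMEDIATE if K > k_star else DELAYED,
                "tie": tie,
            }
        )
    return pd.DataFrame(rows)
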