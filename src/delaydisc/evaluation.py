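"""Participant-level model evaluation and chance-level exclusion.

Three quantities summarize how well the fitted choice model describes a
participant:

* classification accuracy — the fraction of trials where the option the
  model deems more probable matches the observed choice;
* a right-tailed binomial test of that accuracy against chance (p = 0.5):
  p = sum_{i=k}^{n} C(n, i) 0.5^n.  Participants with p > 0.05 are flagged
  for exclusion — their choices are not classified significantly better
  than a coin flip;
* McFadden's pseudo-R2, 1 - L_model / L_chance, where the chance model
  assigns every choice probability 0.5 (the same null the exclusion test
  uses).

Counting conventions: a trial where the model's probability is exactly 0.5
contributes half a success to accuracy but counts as *incorrect* for the
binomial k (the conservative direction).  n is the participant's total
concatenated trial count (MCQ + adaptive), matching how the model is fitted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import binom

from .hierarchical import FitResult
from .model import DiscountParams, choice_sign, p_immediate

__all__ = [
    "EvalRecord",
    "binomial_exclusion_p",
    "mcfadden_r2",
    "evaluate_participant",
    "evaluate_cohort",
    "EXCLUSION_ALPHA",
]

EXCLUSION_ALPHA = 0.05


@dataclass(frozen=True)
class EvalRecord:
    participant_id: str
    n_trials: int
    n_correct: int
    accuracy: float
    binom_p: float
    excluded: bool
    pseudo_r2: float


def binomial_exclusion_p(k: int, n: int) -> float:
    """Right-tail probability of k or more successes out of n at chance.

    Exact Binomial(n, 0.5) upper-tail sum; the participant fails the
    model-accuracy criterion (and is excluded) when this exceeds 0.05.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    if not 0 <= k <= n:
        raise ValueError(f"k must be in [0, {n}], got {k}")
    return float(binom.sf(k - 1, n, 0.5))


def _trial_probs(trials: pd.DataFrame, params: DiscountParams) -> np.ndarray:
    """Model probability assigned to each *observed* choice."""
    p_imm = p_immediate(
        trials["r_immediate"].to_numpy(float),
        trials["R_delayed"].to_numpy(float),
        trials["delay_days"].to_numpy(float),
        params,
    )
    sign = choice_sign(trials["choice"].to_numpy())
    return np.where(sign > 0, p_imm, 1.0 - p_imm)


def mcfadden_r2(trials: pd.DataFrame, params: DiscountParams) -> float:
    """McFadden's pseudo-R2 against the coin-flip null.

    1 - L_model / L_null with L_null = n * log(0.5).  Zero for an
    uninformative model, approaching one as the model concentrates all
    probability on the observed choices.
    """
    if len(trials) == 0:
        raise ValueError("mcfadden_r2 requires at least one trial")
    p_obs = np.clip(_trial_probs(trials, params), 1e-300, 1.0)
    ll_model = float(np.sum(np.log(p_obs)))
    ll_null = len(trials) * np.log(0.5)
    return 1.0 - ll_model / ll_null


def evaluate_participant(
    participant_id: str, trials: pd.DataFrame, params: DiscountParams
) -> EvalRecord:
    """Accuracy, exclusion test and pseudo-R2 for one participant."""
    p_obs = _trial_probs(trials, params)
    n = len(trials)
    strict = int(np.sum(p_obs > 0.5))
    ties = int(np.sum(p_obs == 0.5))
    accuracy = (strict + 0.5 * ties) / n
    p = binomial_exclusion_p(strict, n)
    return EvalRecord(
        participant_id=participant_id,
        n_trials=n,
        n_correct=strict,
        accuracy=accuracy,
        binom_p=p,
        excluded=p > EXCLUSION_ALPHA,
        pseudo_r2=mcfadden_r2(trials, params),
    )


def evaluate_cohort(fit: FitResult, trials: pd.DataFrame) -> pd.DataFrame:
    """Per-participant evaluation table plus cohort means.

    Every participant present in ``trials`` must be covered by ``fit``
    (excluded-at-fit participants are skipped).  Returns a DataFrame in
    the eval.csv schema; cohort summary means are available via
    ``df[["accuracy", "pseudo_r2"]].mean()``.
    """
    records = []
    fitted = set(fit.params.index)
    for pid, df in trials.groupby("participant_id", sort=True):
        pid = str(pid)
        if pid in fit.excluded:
            continue
        if pid not in fitted:
            raise KeyError(
                f"participant {pid!r} has trials but no fitted parameters"
            )
        row = fit.params.loc[pid]
        params = DiscountParams(
            log_k=float(row["log_k_map"]), log_beta=float(row["log_beta_map"])
        )
        if fit.two_timepoint:
            # evaluate each timepoint at its own implied discount rate
            recs = []
            for tp, sub in df.groupby("timepoint", sort=True):
                lk = row["log_k_map"] + (row["delta"] if tp == "MA2" else 0.0)
                recs.append(
                    evaluate_participant(
                        pid, sub,
                        DiscountParams(log_k=float(lk),
                                       log_beta=float(row["log_beta_map"])),
                    )
                )
            n = sum(r.n_trials for r in recs)
            strict = sum(r.n_correct for r in recs)
            acc = sum(r.accuracy * r.n_trials for r in recs) / n
            ll_model = sum(
                (1.0 - r.pseudo_r2) * r.n_trials * np.log(0.5) for r in recs
            )
            rec = EvalRecord(
                participant_id=pid, n_trials=n, n_correct=strict,
                accuracy=acc, binom_p=binomial_exclusion_p(strict, n),
                excluded=binomial_exclusion_p(strict, n) > EXCLUSION_ALPHA,
                pseudo_r2=1.0 - ll_model / (n * np.log(0.5)),
            )
        else:
            rec = evaluate_participant(pid, df, params)
        records.append(rec)
    return pd.DataFrame([r.__dict__ for r in records])
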