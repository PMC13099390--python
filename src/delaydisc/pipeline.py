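"""End-to-end analysis: from choice files to the pre-registered report.

``run_analysis`` consumes the canonical cohort and choices tables, runs the
hierarchical fits and every step of the analysis plan, and returns a
JSON-serializable report; one seed reproduces every number in it.

Cross-validation modes for the relapse classifier:

* ``"paper"`` — discount rates fitted once on all participants, then
  cross-validated (the original analysis; the fitted features leak a
  little information across folds through the shared population prior);
* ``"strict"`` (default) — each participant's features come from a fold
  model whose population prior was estimated without that participant;
  lambda selection then uses the same fold structure on these honest
  features.
"""

from __future__ import annotations

import json
from dataclasses import asdict

import numpy as np
import pandas as pd

from .evaluation import evaluate_cohort
from .hierarchical import FitResult, em_fit, em_fit_two_timepoint, map_fit
from .stats import (
    cox_fit,
    gain_scores,
    gated_two_sample,
    lasso_relapse_cv,
    lme_discontinuation,
    lme_symptom_change,
    spearman_with_bootstrap,
)

__all__ = ["run_analysis", "report_to_json", "strict_cv_features"]

SCALE_COMPARISONS = (
    "hamd_ma1", "erq", "bscs", "swls", "ace", "ctq", "tleq", "mwtb",
)


def strict_cv_features(
    choices: pd.DataFrame,
    participant_ids: list[str],
    labels: np.ndarray,
    *,
    n_folds: int,
    seed: int,
    em_config: dict,
) -> pd.DataFrame:
    """Fold-honest (log_k_ma1, log_k_ma2) features.

    Participants are split into stratified folds; for each fold, the
    hierarchical prior is re-estimated by EM on the training participants
    only, and the held-out participants' parameters are MAP-fitted under
    that training prior without contributing to it.
    """
    from sklearn.model_selection import StratifiedKFold

    ids = np.asarray(participant_ids)
    cv = StratifiedKFold(n_folds, shuffle=True, random_state=seed)
    feats = pd.DataFrame(
        index=pd.Index(ids, name="participant_id"),
        columns=["log_k_ma1", "log_k_ma2", "fold"], dtype=float,
    )
    for f, (train_idx, test_idx) in enumerate(cv.split(ids, labels)):
        train_ids = set(ids[train_idx])
        train_trials = choices[choices["participant_id"].isin(train_ids)]
        fit = em_fit_two_timepoint(train_trials, **em_config)
        prior = fit.prior
        for pid in ids[test_idx]:
            sub = choices[choices["participant_id"] == pid]
            res = map_fit(sub, prior, n_restarts=0, two_timepoint=True)
            idx = {n: i for i, n in enumerate(prior.names)}
            lk1 = float(res.theta[idx["log_k_ma1"]])
            feats.loc[pid, "log_k_ma1"] = lk1
            feats.loc[pid, "log_k_ma2"] = lk1 + float(res.theta[idx["delta"]])
            feats.loc[pid, "fold"] = f
    return feats


def _comparison_dict(res) -> dict:
    d = asdict(res)
    return d


def run_analysis(
    cohort: pd.DataFrame,
    choices: pd.DataFrame,
    *,
    seed: int = 0,
    n_boot: int = 10_000,
    n_folds: int = 10,
    cv_mode: str = "strict",
    em_config: dict | None = None,
) -> dict:
    """Run the full pre-registered analysis and return the report dict."""
    if cv_mode not in ("paper", "strict"):
        raise ValueError("cv_mode must be 'paper' or 'strict'")
    em_config = dict(em_config or {})
    em_config.setdefault("seed", seed)
    report: dict = {"seed": seed, "cv_mode": cv_mode}

    # ---- hierarchical fit at baseline (concatenated MCQ + adaptive) -----
    ma1 = choices[choices["timepoint"] == "MA1"]
    fit_ma1 = em_fit(ma1, **em_config)
    eval_df = evaluate_cohort(fit_ma1, ma1)
    included = eval_df.loc[~eval_df["excluded"], "participant_id"]
    report["model_fit"] = {
        "n_fitted": int(len(eval_df)),
        "n_excluded": int(eval_df["excluded"].sum()),
        "mean_accuracy": float(eval_df["accuracy"].mean()),
        "mean_pseudo_r2": float(eval_df["pseudo_r2"].mean()),
        "em_iterations": fit_ma1.n_iter,
        "em_converged": bool(fit_ma1.converged),
    }
    logk = fit_ma1.params.loc[
        fit_ma1.params.index.isin(included), "log_k_map"
    ]
    meta = cohort.set_index("participant_id")

    # ---- step 1: patients vs controls at baseline (one-tailed) ----------
    pat = logk[meta.loc[logk.index, "group"] == "patient"].to_numpy()
    ctl = logk[meta.loc[logk.index, "group"] == "control"].to_numpy()
    cmp1 = gated_two_sample(pat, ctl, tails="one", direction="greater",
                            n_boot=n_boot, seed=seed)
    report["step1_group_comparison"] = _comparison_dict(cmp1)

    # ---- two-timepoint joint fit (patients with both assessments) -------
    patients = meta[meta["group"] == "patient"].index
    pat_choices = choices[choices["participant_id"].isin(patients)]
    fit_2tp = em_fit_two_timepoint(pat_choices, **em_config)
    gains = gain_scores(fit_2tp, cohort)

    # ---- step 2: discontinuation effect on log K ------------------------
    long_rows = []
    for pid, row in fit_2tp.params.iterrows():
        arm = meta.loc[pid, "arm"]
        long_rows.append({"participant_id": pid, "timepoint": "MA1",
                          "log_k": row["log_k_map"], "arm": arm})
        long_rows.append({"participant_id": pid, "timepoint": "MA2",
                          "log_k": row["log_k_map"] + row["delta"],
                          "arm": arm})
    lme2 = lme_discontinuation(pd.DataFrame(long_rows))
    report["step2_lme_discontinuation"] = {
        "fixed_effects": lme2.fixed_effects.to_dict("records"),
        "fallback_random_intercept": lme2.fallback_random_intercept,
        "converged": lme2.converged,
    }

    # ---- step 3: correlations with rating scales (Bonferroni over 8) ----
    scales_present = [s for s in SCALE_COMPARISONS if s in cohort.columns]
    corr_out = {}
    for s in scales_present:
        vals = meta.loc[logk.index, s].to_numpy(dtype=float)
        res = spearman_with_bootstrap(
            logk.to_numpy(), vals, n_boot=n_boot,
            n_comparisons=len(scales_present), seed=seed,
            pair=("log_k_ma1", s),
        )
        corr_out[s] = asdict(res)
    report["step3_scale_correlations"] = corr_out

    # ---- steps 4-5: prediction of relapse --------------------------------
    rel_mask = meta["relapsed"].notna() & ~meta["dropped_out"].astype(bool)
    rel_ids = [p for p in meta.index[rel_mask] if p in fit_2tp.params.index
               and p in logk.index]
    labels = meta.loc[rel_ids, "relapsed"].astype(bool).to_numpy()
    report["relapse_n"] = {"n": len(rel_ids), "n_relapsed": int(labels.sum())}

    lk1_rel = logk.loc[rel_ids].to_numpy()
    cmp_rel = gated_two_sample(
        lk1_rel[labels], lk1_rel[~labels], tails="one", direction="greater",
        n_boot=n_boot, seed=seed,
    )
    cmp_rel_2t = gated_two_sample(
        lk1_rel[labels], lk1_rel[~labels], tails="two",
        n_boot=n_boot, seed=seed,
    )
    report["relapse_baseline_comparison"] = _comparison_dict(cmp_rel)
    report["relapse_baseline_comparison_two_tailed"] = _comparison_dict(cmp_rel_2t)

    g = gains.set_index("participant_id")
    disc = g[(g["arm"] == "MA1-D-MA2") & g["relapsed"].notna()
             & ~g["dropped_out"].astype(bool)]
    if disc["relapsed"].astype(bool).nunique() == 2:
        dl = disc["delta"].to_numpy()
        dr = disc["relapsed"].astype(bool).to_numpy()
        if dr.sum() >= 3 and (~dr).sum() >= 3:
            cmp_gain = gated_two_sample(dl[dr], dl[~dr], tails="one",
                                        direction="greater", n_boot=n_boot,
                                        seed=seed)
            report["relapse_gain_score_comparison"] = _comparison_dict(cmp_gain)
    arm_gains = gains[~gains["dropped_out"].astype(bool)]
    ga = arm_gains[arm_gains["arm"] == "MA1-D-MA2"]["delta"].to_numpy()
    gb = arm_gains[arm_gains["arm"] == "MA1-MA2-D"]["delta"].to_numpy()
    if len(ga) >= 3 and len(gb) >= 3:
        report["gain_score_arm_comparison"] = _comparison_dict(
            gated_two_sample(ga, gb, tails="one", direction="greater",
                             n_boot=n_boot, seed=seed)
        )

    times = meta.loc[rel_ids, "days_to_event"].to_numpy(dtype=float)
    lk2_rel = (
        fit_2tp.params.loc[rel_ids, "log_k_map"]
        + fit_2tp.params.loc[rel_ids, "delta"]
    ).to_numpy()
    cox1 = cox_fit(times, labels, pd.DataFrame({"log_k_ma1": lk1_rel}))
    cox2 = cox_fit(
        times, labels,
        pd.DataFrame({"log_k_ma1": lk1_rel, "log_k_ma2": lk2_rel}),
    )
    report["step4_cox_ma1"] = {
        "coef": cox1.coefficients.to_dict(),
        "se": cox1.standard_errors.to_dict(),
        "p": cox1.p_values.to_dict(),
        "n_events": cox1.n_events,
    }
    report["step5_cox_ma1_ma2"] = {
        "coef": cox2.coefficients.to_dict(),
        "se": cox2.standard_errors.to_dict(),
        "p": cox2.p_values.to_dict(),
        "n_events": cox2.n_events,
    }

    if cv_mode == "strict":
        feats = strict_cv_features(
            pat_choices[pat_choices["participant_id"].isin(rel_ids)],
            rel_ids, labels, n_folds=n_folds, seed=seed, em_config=em_config,
        )
        f1 = feats.loc[rel_ids, ["log_k_ma1"]].to_numpy(dtype=float)
        f2 = feats.loc[rel_ids, ["log_k_ma1", "log_k_ma2"]].to_numpy(dtype=float)
    else:
        f1 = lk1_rel[:, None]
        f2 = np.column_stack([lk1_rel, lk2_rel])
    lasso1 = lasso_relapse_cv(f1, labels, n_folds=n_folds, seed=seed,
                              feature_names=("log_k_ma1",))
    lasso2 = lasso_relapse_cv(f2, labels, n_folds=n_folds, seed=seed,
                              feature_names=("log_k_ma1", "log_k_ma2"))
    for key, res in (("step4_lasso_ma1", lasso1), ("step5_lasso_ma1_ma2", lasso2)):
        report[key] = {
            "reg_strength": res.reg_strength,
            "coefficients": res.coefficients.tolist(),
            "intercept": res.intercept,
            "balanced_accuracy": res.balanced_accuracy,
            "feature_names": list(res.feature_names),
        }

    # ---- step 6: symptom change vs baseline discounting ------------------
    sym_rows = []
    for pid, row in fit_2tp.params.iterrows():
        m = meta.loc[pid]
        if pd.isna(m["hamd_ma2"]):
            continue
        for tp, h in (("MA1", m["hamd_ma1"]), ("MA2", m["hamd_ma2"])):
            sym_rows.append(
                {"participant_id": pid, "timepoint": tp, "hamd": float(h),
                 "log_k_ma1": row["log_k_map"], "arm": m["arm"]}
            )
    lme6 = lme_symptom_change(pd.DataFrame(sym_rows))
    report["step6_lme_symptom_change"] = {
        "fixed_effects": lme6.fixed_effects.to_dict("records"),
        "fallback_random_intercept": lme6.fallback_random_intercept,
        "converged": lme6.converged,
    }
    return report


def report_to_json(report: dict) -> str:
    """Canonical JSON serialization (sorted keys, full float precision)."""
    return json.dumps(report, sort_keys=True, indent=1, default=_jsonable)


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (pd.Series,)):
        return obj.to_dict()
    if obj is pd.NA:
        return None
    raise TypeError(f"not JSON-serializable: {type(obj)}")
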