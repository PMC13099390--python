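"""Pre-registered downstream statistics for the discounting cohort.

Implements the analysis plan around the fitted discount rates:

1. group comparison of baseline log K (patients vs controls), through a
   normality/equal-variance-gated t test with Cohen's d and bootstrap CI;
2. linear mixed-effects model for the effect of medication discontinuation
   on log K (group x timepoint interaction, participant random slope);
3. Spearman correlations of baseline log K with eight rating scales,
   10,000-iteration bootstrap CIs, Bonferroni correction;
4./5. relapse prediction: one-tailed comparisons, Cox proportional-hazards
   on days to relapse, and L1-regularized logistic regression with
   stratified tenfold cross-validation reporting balanced accuracy;
6. linear mixed-effects model for symptom change vs baseline log K.

Plus the post-hoc power of the two-sample t test via the noncentral t
distribution, and extraction of jointly-fitted gain scores (delta log K).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from scipy import stats as sps
from statsmodels.duration.hazard_regression import PHReg
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.linear_model import LogisticRegression, LogisticRegressionCV
from sklearn.metrics import balanced_accuracy_score
from sklearn.model_selection import KFold, StratifiedKFold
from sklearn.preprocessing import StandardScaler

from .hierarchical import FitResult

__all__ = [
    "ComparisonResult",
    "CorrelationResult",
    "SurvivalFit",
    "LassoCVResult",
    "LmeResult",
    "gated_two_sample",
    "spearman_with_bootstrap",
    "cox_fit",
    "LassoRelapseCV",
    "lasso_relapse_cv",
    "lme_discontinuation",
    "lme_symptom_change",
    "posthoc_power_t",
    "gain_scores",
]

GATE_ALPHA = 0.05
DEFAULT_N_BOOT = 10_000


# ---------------------------------------------------------------------------
# result containers

@dataclass
class ComparisonResult:
    test_used: str                  # student_t | wilcoxon_signed_rank | rank_sum
    statistic: float
    df: float | None
    p: float
    tails: str
    cohens_d: float
    d_ci: tuple[float, float]
    summary: dict = field(default_factory=dict)


@dataclass
class CorrelationResult:
    pair: tuple[str, str]
    spearman_rho: float
    p: float
    p_bonferroni: float
    rho_ci: tuple[float, float]
    n: int


@dataclass
class SurvivalFit:
    coefficients: pd.Series
    standard_errors: pd.Series
    p_values: pd.Series
    n_events: int
    ties_method: str = "breslow"
    collinear: bool = False


@dataclass
class LassoCVResult:
    reg_strength: float             # selected lambda (1/C)
    coefficients: np.ndarray
    intercept: float
    fold_assignments: np.ndarray
    balanced_accuracy: float
    feature_names: tuple[str, ...] = ()


@dataclass
class LmeResult:
    fixed_effects: pd.DataFrame     # term, estimate, stat, df, p
    random_variances: dict
    formula: str
    random_structure: str
    converged: bool
    fallback_random_intercept: bool = False


# ---------------------------------------------------------------------------
# gated group comparison

def _pooled_sd(x: np.ndarray, y: np.ndarray) -> float:
    nx, ny = len(x), len(y)
    return float(np.sqrt(
        ((nx - 1) * np.var(x, ddof=1) + (ny - 1) * np.var(y, ddof=1))
        / (nx + ny - 2)
    ))


def cohens_d(x, y) -> float:
    """Pooled-SD standardized mean difference (x minus y)."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    sp = _pooled_sd(x, y)
    if sp == 0.0:
        return 0.0
    return float((x.mean() - y.mean()) / sp)


def _ks_normal(v: np.ndarray) -> float:
    """KS test of standardized values against the standard normal."""
    s = np.std(v, ddof=1)
    if s == 0:
        return 0.0  # degenerate: force the nonparametric path
    return float(sps.kstest((v - v.mean()) / s, "norm").pvalue)


def _boot_d_ci(x, y, paired, n_boot, rng) -> tuple[float, float]:
    if n_boot <= 0:
        return (float("nan"), float("nan"))
    nx, ny = len(x), len(y)
    ds = np.empty(n_boot)
    for b in range(n_boot):
        if paired:
            idx = rng.integers(0, nx, nx)
            ds[b] = cohens_d(x[idx], y[idx])
        else:
            ds[b] = cohens_d(x[rng.integers(0, nx, nx)],
                             y[rng.integers(0, ny, ny)])
    return (float(np.percentile(ds, 2.5)), float(np.percentile(ds, 97.5)))


def gated_two_sample(
    x,
    y,
    *,
    tails: str = "two",
    direction: str = "greater",
    paired: bool = False,
    n_boot: int = DEFAULT_N_BOOT,
    seed: int = 0,
) -> ComparisonResult:
    """Two-sample comparison with normality / equal-variance gating.

    A Kolmogorov-Smirnov test on standardized values (both samples, or the
    paired differences) and a Bartlett equal-variance test (independent
    samples only) are run at the 0.05 level; Student's t is used when the
    gates pass, otherwise the Wilcoxon signed-rank (paired) or rank-sum
    (independent) test.  One-tailed tests require an explicit ``direction``
    ("greater" means x tends above y); the direction is part of the
    hypothesis and never inferred from the data.

    Cohen's d (pooled SD) with a percentile bootstrap 95% CI is always
    reported, alongside means/SDs and medians/IQRs per sample.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3 or len(y) < 3:
        raise ValueError("each sample needs n >= 3")
    if paired and len(x) != len(y):
        raise ValueError("paired samples must have equal length")
    if tails not in ("one", "two"):
        raise ValueError("tails must be 'one' or 'two'")
    if direction not in ("greater", "less"):
        raise ValueError("direction must be 'greater' or 'less'")
    alternative = "two-sided" if tails == "two" else direction

    degenerate = np.std(x, ddof=1) == 0 or np.std(y, ddof=1) == 0
    if paired and np.std(x - y, ddof=1) == 0:
        degenerate = True
    if degenerate:
        warnings.warn("zero-variance input: using the nonparametric path")
        normal_ok = var_ok = False
    elif paired:
        normal_ok = _ks_normal(x - y) > GATE_ALPHA
        var_ok = True
    else:
        normal_ok = (_ks_normal(x) > GATE_ALPHA) and (_ks_normal(y) > GATE_ALPHA)
        var_ok = float(sps.bartlett(x, y).pvalue) > GATE_ALPHA

    if normal_ok and var_ok:
        if paired:
            res = sps.ttest_rel(x, y, alternative=alternative)
            df = float(len(x) - 1)
        else:
            res = sps.ttest_ind(x, y, equal_var=True, alternative=alternative)
            df = float(len(x) + len(y) - 2)
        test_used, statistic, p = "student_t", float(res.statistic), float(res.pvalue)
    elif paired:
        diffs = x - y
        if np.all(diffs == 0):
            test_used, statistic, p, df = "wilcoxon_signed_rank", 0.0, 1.0, None
        else:
            res = sps.wilcoxon(x, y, alternative=alternative,
                               zero_method="wilcox")
            test_used, statistic, p, df = (
                "wilcoxon_signed_rank", float(res.statistic), float(res.pvalue),
                None,
            )
    else:
        res = sps.ranksums(x, y, alternative=alternative)
        test_used, statistic, p, df = (
            "rank_sum", float(res.statistic), float(res.pvalue), None,
        )

    rng = np.random.default_rng(seed)
    d = cohens_d(x, y)
    lo, hi = _boot_d_ci(x, y, paired, n_boot, rng)
    summary = {
        "x": {"mean": float(x.mean()), "sd": float(np.std(x, ddof=1)),
              "median": float(np.median(x)),
              "iqr": float(np.percentile(x, 75) - np.percentile(x, 25)),
              "n": int(len(x))},
        "y": {"mean": float(y.mean()), "sd": float(np.std(y, ddof=1)),
              "median": float(np.median(y)),
              "iqr": float(np.percentile(y, 75) - np.percentile(y, 25)),
              "n": int(len(y))},
    }
    return ComparisonResult(
        test_used=test_used, statistic=statistic, df=df, p=p, tails=tails,
        cohens_d=d, d_ci=(lo, hi), summary=summary,
    )


# ---------------------------------------------------------------------------
# correlations

def spearman_with_bootstrap(
    x,
    y,
    *,
    n_boot: int = DEFAULT_N_BOOT,
    n_comparisons: int = 1,
    seed: int = 0,
    pair: tuple[str, str] = ("x", "y"),
) -> CorrelationResult:
    """Spearman rank correlation with percentile bootstrap CI.

    Mid-ranks handle ties; the 95% CI resamples participant pairs
    ``n_boot`` times; the Bonferroni-corrected p is min(1, m * p) for m
    pre-specified comparisons.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    n = len(x)
    if n < 5:
        raise ValueError("need at least 5 complete pairs")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("correlation undefined for a constant input vector")
    rho, p = sps.spearmanr(x, y)
    rng = np.random.default_rng(seed)
    if n_boot > 0:
        rhos = np.empty(n_boot)
        for b in range(n_boot):
            idx = rng.integers(0, n, n)
            xb, yb = x[idx], y[idx]
            if np.all(xb == xb[0]) or np.all(yb == yb[0]):
                rhos[b] = np.nan
                continue
            rhos[b] = sps.spearmanr(xb, yb).statistic
        ci = (float(np.nanpercentile(rhos, 2.5)),
              float(np.nanpercentile(rhos, 97.5)))
    else:
        ci = (float("nan"), float("nan"))
    return CorrelationResult(
        pair=pair,
        spearman_rho=float(rho),
        p=float(p),
        p_bonferroni=float(min(1.0, n_comparisons * p)),
        rho_ci=ci,
        n=n,
    )


# ---------------------------------------------------------------------------
# survival

def cox_fit(times, events, covariates: pd.DataFrame) -> SurvivalFit:
    """Cox proportional hazards on days to relapse (Breslow ties).

    ``covariates`` is a DataFrame of numeric predictors (e.g. log K at
    MA1, or at MA1 and MA2 jointly).  Censored participants carry their
    censoring time with event = False.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    if np.any(times <= 0):
        raise ValueError("times must be > 0")
    if events.sum() < 1:
        raise ValueError("at least one event is required")
    X = pd.DataFrame(covariates).reset_index(drop=True)
    arr = X.to_numpy(float)
    collinear = np.linalg.matrix_rank(arr) < X.shape[1]
    keep = list(range(X.shape[1]))
    if collinear:
        warnings.warn("collinear covariates in Cox fit")
        # drop aliased columns (as R's coxph does), reporting them as NaN
        from scipy.linalg import qr

        _, R, piv = qr(arr, pivoting=True)
        rank = int(np.sum(np.abs(np.diag(R)) > 1e-10 * abs(R[0, 0])))
        keep = sorted(piv[:rank])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = PHReg(np.asarray(times), arr[:, keep],
                      status=events.astype(int), ties="breslow")
        res = model.fit()
    names = pd.Index(X.columns)
    coefs = pd.Series(np.nan, index=names)
    bse = pd.Series(np.nan, index=names)
    pvals = pd.Series(np.nan, index=names)
    coefs.iloc[keep] = res.params
    bse.iloc[keep] = res.bse
    pvals.iloc[keep] = res.pvalues
    return SurvivalFit(
        coefficients=coefs,
        standard_errors=bse,
        p_values=pvals,
        n_events=int(events.sum()),
        ties_method="breslow",
        collinear=bool(collinear),
    )


# ---------------------------------------------------------------------------
# lasso relapse prediction

class LassoRelapseCV(BaseEstimator, ClassifierMixin):
    """L1-regularized logistic relapse classifier with CV-selected strength.

    Features are standardized internally; the regularization parameter is
    chosen over a log-spaced grid by (stratified) k-fold cross-validated
    deviance, and the model is refitted on the full training data at the
    chosen strength.  ``selection="min_deviance"`` (default) takes the
    deviance-minimizing strength; ``"1se"`` takes the strongest
    regularization within one standard error of the minimum.  Balanced
    accuracy (mean of per-class recalls) is the reported score: any
    constant classifier — in particular the all-zero coefficient solution
    — scores exactly 0.5.
    """

    def __init__(self, *, n_folds: int = 10, stratified: bool = True,
                 seed: int = 0, n_grid: int = 25,
                 selection: str = "min_deviance"):
        self.n_folds = n_folds
        self.stratified = stratified
        self.seed = seed
        self.n_grid = n_grid
        self.selection = selection

    def fit(self, X, y):
        if self.selection not in ("min_deviance", "1se"):
            raise ValueError("selection must be 'min_deviance' or '1se'")
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        y = np.asarray(y).astype(int)
        classes = np.unique(y)
        if len(classes) < 2:
            raise ValueError("labels must contain both classes")
        self.scaler_ = StandardScaler().fit(X)
        Xs = self.scaler_.transform(X)
        if self.stratified:
            cv = StratifiedKFold(self.n_folds, shuffle=True,
                                 random_state=self.seed)
        else:
            cv = KFold(self.n_folds, shuffle=True, random_state=self.seed)
        folds = np.empty(len(y), dtype=int)
        for f, (_, test_idx) in enumerate(cv.split(Xs, y)):
            folds[test_idx] = f
        Cs = np.logspace(-4, 2, self.n_grid)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", FutureWarning)
            clf = LogisticRegressionCV(
                Cs=Cs, cv=cv, penalty="l1", solver="liblinear",
                scoring="neg_log_loss", refit=True, max_iter=1000,
            ).fit(Xs, y)
        if self.selection == "1se":
            scores = clf.scores_[classes[1]]       # (n_folds, n_Cs)
            mean = scores.mean(axis=0)
            se = scores.std(axis=0, ddof=1) / np.sqrt(scores.shape[0])
            best = int(np.argmax(mean))
            # Cs ascend, so the first index within one SE of the optimum is
            # the strongest acceptable regularization
            idx = int(np.nonzero(mean >= mean[best] - se[best])[0][0])
            refit = LogisticRegression(
                penalty="l1", solver="liblinear", C=float(Cs[idx]),
                max_iter=1000,
            ).fit(Xs, y)
            self.C_ = float(Cs[idx])
            self.coef_ = refit.coef_[0].copy()
            self.intercept_ = float(refit.intercept_[0])
            self._clf = refit
        else:
            self.C_ = float(clf.C_[0])
            self.coef_ = clf.coef_[0].copy()
            self.intercept_ = float(clf.intercept_[0])
            self._clf = clf
        self.reg_strength_ = 1.0 / self.C_
        self.fold_assignments_ = folds
        self.classes_ = classes
        self.balanced_accuracy_ = float(
            balanced_accuracy_score(y, self.predict(X))
        )
        return self

    def predict(self, X):
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        return self._clf.predict(self.scaler_.transform(X))

    def predict_proba(self, X):
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        return self._clf.predict_proba(self.scaler_.transform(X))


def lasso_relapse_cv(
    features,
    labels,
    *,
    n_folds: int = 10,
    stratified: bool = True,
    seed: int = 0,
    selection: str = "min_deviance",
    feature_names: tuple[str, ...] = (),
) -> LassoCVResult:
    """Functional wrapper over :class:`LassoRelapseCV`."""
    est = LassoRelapseCV(n_folds=n_folds, stratified=stratified,
                         seed=seed, selection=selection).fit(features, labels)
    return LassoCVResult(
        reg_strength=est.reg_strength_,
        coefficients=est.coef_,
        intercept=est.intercept_,
        fold_assignments=est.fold_assignments_,
        balanced_accuracy=est.balanced_accuracy_,
        feature_names=tuple(feature_names),
    )


# ---------------------------------------------------------------------------
# linear mixed-effects models

def _fit_lme(formula: str, data: pd.DataFrame, re_formula: str) -> LmeResult:
    """MixedLM fit with a documented random-intercept fallback.

    With only two timepoints per participant a random slope is weakly
    identified; if the slope model fails to converge (or goes singular)
    the model is refitted with a random intercept and flagged.
    """
    def attempt(re_f):
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model = smf.mixedlm(formula, data,
                                    groups=data["participant_id"],
                                    re_formula=re_f)
                fit = model.fit(reml=True, maxiter=200)
        except (np.linalg.LinAlgError, ValueError):
            return None, False
        singular = bool(np.any(np.diag(np.atleast_2d(fit.cov_re)) < 1e-10))
        return fit, bool(fit.converged) and not singular
    fit, ok = attempt(re_formula)
    fallback = False
    if not ok:
        fit2, ok2 = attempt("1")
        if fit2 is not None:
            fit, ok = fit2, ok2
            fallback = True
        elif fit is None:
            raise RuntimeError("mixed model failed under both random-effect "
                               "structures")
    n_fixed = len(fit.fe_params)
    df_resid = float(fit.nobs - n_fixed)
    terms = fit.fe_params.index
    fixed = pd.DataFrame(
        {
            "term": terms,
            "estimate": fit.fe_params.values,
            "stat": fit.tvalues[terms].values,
            "df": df_resid,
            "p": fit.pvalues[terms].values,
        }
    )
    return LmeResult(
        fixed_effects=fixed,
        random_variances={
            "re_cov": np.atleast_2d(fit.cov_re).tolist(),
            "residual": float(fit.scale),
        },
        formula=formula,
        random_structure="random_intercept" if fallback else re_formula,
        converged=bool(fit.converged),
        fallback_random_intercept=fallback,
    )


def lme_discontinuation(data: pd.DataFrame) -> LmeResult:
    """Effect of discontinuation on log K.

    ``data``: long format with participant_id, log_k, timepoint (MA1/MA2)
    and arm (MA1-D-MA2 / MA1-MA2-D).  Fits
    log_k ~ group + timepoint + group x timepoint with a participant
    random slope on timepoint; the interaction term carries the
    discontinuation hypothesis.
    """
    d = data.copy()
    if set(d["timepoint"]) != {"MA1", "MA2"}:
        raise ValueError("both timepoints are required")
    d["time"] = (d["timepoint"] == "MA2").astype(float)
    d["grp"] = (d["arm"] == "MA1-D-MA2").astype(float)
    return _fit_lme("log_k ~ grp * time", d, re_formula="0 + time")


def lme_symptom_change(data: pd.DataFrame) -> LmeResult:
    """Symptom change vs baseline discounting.

    ``data``: long format with participant_id, hamd, timepoint, arm and
    the participant's baseline log_k_ma1.  Fits
    hamd ~ log_k_ma1 * timepoint + arm * timepoint with a participant
    random slope; the log_k x timepoint interaction expresses how symptom
    change depends on baseline discounting.
    """
    d = data.copy()
    if set(d["timepoint"]) != {"MA1", "MA2"}:
        raise ValueError("both timepoints are required")
    d["time"] = (d["timepoint"] == "MA2").astype(float)
    d["grp"] = (d["arm"] == "MA1-D-MA2").astype(float)
    return _fit_lme("hamd ~ log_k_ma1 * time + grp * time", d,
                    re_formula="0 + time")


# ---------------------------------------------------------------------------
# power

def posthoc_power_t(
    d: float, n1: int, n2: int, alpha: float = 0.05, tails: str = "two"
) -> float:
    """Power of the two-sample t test via the noncentral t distribution.

    Noncentrality is d * sqrt(n1 n2 / (n1 + n2)) with df = n1 + n2 - 2.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("group sizes must be >= 2")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    dof = n1 + n2 - 2
    ncp = d * np.sqrt(n1 * n2 / (n1 + n2))
    if tails == "two":
        crit = sps.t.ppf(1 - alpha / 2, dof)
        return float(sps.nct.sf(crit, dof, ncp) + sps.nct.cdf(-crit, dof, ncp))
    if tails == "one":
        crit = sps.t.ppf(1 - alpha, dof)
        return float(sps.nct.sf(crit, dof, ncp))
    raise ValueError("tails must be 'one' or 'two'")


# ---------------------------------------------------------------------------
# gain scores

def gain_scores(fit: FitResult, cohort: pd.DataFrame) -> pd.DataFrame:
    """Per-participant jointly fitted change in log K, with arm labels.

    Extracts delta (log K at MA2 minus MA1, estimated concurrently with
    baseline) from a two-timepoint fit and attaches arm and relapse
    status for the downstream comparisons.  Participants without a fitted
    delta are dropped with a notice.
    """
    if not fit.two_timepoint or "delta" not in fit.params.columns:
        raise ValueError("gain_scores requires a two-timepoint fit")
    deltas = fit.params["delta"].rename("delta").reset_index()
    meta = cohort[["participant_id", "arm", "relapsed", "dropped_out"]]
    out = deltas.merge(meta, on="participant_id", how="left")
    missing = out["delta"].isna()
    if missing.any():
        warnings.warn(
            f"{int(missing.sum())} participant(s) without a fitted delta "
            "excluded from gain-score analyses"
        )
    return out[~missing].reset_index(drop=True)
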