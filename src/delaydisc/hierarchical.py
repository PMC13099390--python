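"""Hierarchical empirical-Bayes estimation of discounting parameters.

Each participant's choices are modelled with the hyperbolic softmax
likelihood (:mod:`delaydisc.model`); participant parameters share a
population Gaussian prior whose hyperparameters are learned from the data
by Expectation-Maximization:

* E-step — per-participant MAP estimate under the current prior, with a
  Laplace (inverse-Hessian) approximation to the posterior covariance;
* M-step — prior mean set to the average MAP, prior covariance to the
  average of (outer product of centred MAPs + Laplace covariance).

The prior shrinks poorly constrained participants (for example, someone
answering "immediate" on every item) toward the population mean instead of
letting their estimates diverge.

Two parameterizations are supported:

* single-timepoint: theta = (log_k[, log_beta]);
* two-timepoint: theta = (log_k_ma1, delta[, log_beta]), where the MA2
  discount rate is exp(log_k_ma1 + delta).  Estimating the within-person
  change ``delta`` jointly with the baseline avoids the error accumulation
  of subtracting two independently fitted noisy estimates; the fitted
  delta is the gain score used downstream.

The EM loop is exposed as the scikit-learn style estimator
:class:`HierarchicalDiscountModel`; :func:`em_fit`,
:func:`em_fit_two_timepoint` and :func:`map_fit` are thin functional
wrappers.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit, log_expit
from sklearn.base import BaseEstimator

from .model import DiscountParams, choice_sign

__all__ = [
    "PriorHyper",
    "MapResult",
    "FitResult",
    "map_fit",
    "em_fit",
    "em_fit_two_timepoint",
    "HierarchicalDiscountModel",
    "write_fits",
    "load_fits",
]

logger = logging.getLogger(__name__)

DEFAULT_INIT_MEAN = {"log_k": -4.0, "log_k_ma1": -4.0, "log_beta": 0.0,
                     "delta": 0.0}
DEFAULT_INIT_VAR = 2.0


@dataclass(frozen=True)
class PriorHyper:
    """Gaussian population prior over the fitted parameter vector."""

    mean: np.ndarray
    cov: np.ndarray
    names: tuple[str, ...]

    def __post_init__(self) -> None:
        mean = np.atleast_1d(np.asarray(self.mean, dtype=float))
        cov = np.atleast_2d(np.asarray(self.cov, dtype=float))
        object.__setattr__(self, "mean", mean)
        object.__setattr__(self, "cov", cov)
        p = mean.shape[0]
        if cov.shape != (p, p) or len(self.names) != p:
            raise ValueError("prior mean, covariance and names disagree in size")
        if not np.allclose(cov, cov.T):
            raise ValueError("prior covariance must be symmetric")
        if np.any(np.linalg.eigvalsh(cov) <= 0):
            raise ValueError("prior covariance must be positive definite")

    @property
    def precision(self) -> np.ndarray:
        return np.linalg.inv(self.cov)

    def logpdf(self, theta: np.ndarray) -> float:
        d = np.asarray(theta, dtype=float) - self.mean
        p = self.mean.shape[0]
        sign, logdet = np.linalg.slogdet(self.cov)
        return float(
            -0.5 * (d @ self.precision @ d) - 0.5 * logdet
            - 0.5 * p * np.log(2.0 * np.pi)
        )


def default_prior(names: tuple[str, ...]) -> PriorHyper:
    """EM initialization prior: mean (-4, 0[, 0]), covariance 2*I.

    exp(-4) ~ 0.018/day sits mid-range of the MCQ item indifference rates.
    """
    mean = np.array([DEFAULT_INIT_MEAN[n] for n in names])
    return PriorHyper(mean=mean, cov=DEFAULT_INIT_VAR * np.eye(len(names)),
                      names=tuple(names))


# ---------------------------------------------------------------------------
# likelihood plumbing

@dataclass(frozen=True)
class _TrialArrays:
    """Column-extracted trial data for one participant."""

    r: np.ndarray
    R: np.ndarray
    d: np.ndarray
    sign: np.ndarray          # +1 immediate, -1 delayed
    ma2: np.ndarray           # boolean; all-False for single-timepoint fits

    @classmethod
    def from_frame(cls, trials: pd.DataFrame, two_timepoint: bool):
        if len(trials) == 0:
            raise ValueError("at least one trial is required")
        ma2 = (
            (trials["timepoint"].to_numpy() == "MA2")
            if two_timepoint
            else np.zeros(len(trials), dtype=bool)
        )
        return cls(
            r=trials["r_immediate"].to_numpy(float),
            R=trials["R_delayed"].to_numpy(float),
            d=trials["delay_days"].to_numpy(float),
            sign=choice_sign(trials["choice"].to_numpy()),
            ma2=ma2,
        )


def _layout(names: tuple[str, ...], pin_log_beta: float | None):
    """Map parameter names to vector indices."""
    idx = {n: i for i, n in enumerate(names)}
    return (
        idx.get("log_k", idx.get("log_k_ma1")),
        idx.get("delta"),
        idx.get("log_beta"),
        0.0 if pin_log_beta is None else float(pin_log_beta),
    )


def _nll_grad(theta: np.ndarray, data: _TrialArrays, names, pin_log_beta):
    """Negative choice log-likelihood and its gradient in theta."""
    i_lk, i_delta, i_lb, lb_pin = _layout(names, pin_log_beta)
    lk_eff = theta[i_lk] + (theta[i_delta] * data.ma2 if i_delta is not None
                            else 0.0)
    lb = theta[i_lb] if i_lb is not None else lb_pin
    K = np.exp(np.clip(lk_eff, -60.0, 60.0))
    beta = np.exp(np.clip(lb, -60.0, 60.0))
    V = data.R / (1.0 + K * data.d)
    w = K * data.d / (1.0 + K * data.d)
    x = np.clip(beta * (data.r - V), -700.0, 700.0)
    ll = float(np.sum(log_expit(data.sign * x)))
    y = (data.sign + 1.0) / 2.0
    resid = y - expit(x)
    g_lk = resid * beta * V * w
    grad = np.zeros_like(theta)
    grad[i_lk] = np.sum(g_lk)
    if i_delta is not None:
        grad[i_delta] = np.sum(g_lk[data.ma2])
    if i_lb is not None:
        grad[i_lb] = np.sum(resid * x)
    return -ll, -grad


def _penalized(theta, data, prior: PriorHyper, pin_log_beta):
    nll, grad = _nll_grad(theta, data, prior.names, pin_log_beta)
    d = theta - prior.mean
    prec = prior.precision
    return nll + 0.5 * float(d @ prec @ d), grad + prec @ d


def _num_hessian(fun_grad, theta, h=1e-5):
    """Central-difference Hessian from an analytic gradient."""
    p = theta.shape[0]
    H = np.zeros((p, p))
    for j in range(p):
        tp, tm = theta.copy(), theta.copy()
        tp[j] += h
        tm[j] -= h
        _, gp = fun_grad(tp)
        _, gm = fun_grad(tm)
        H[:, j] = (gp - gm) / (2.0 * h)
    return 0.5 * (H + H.T)


def _floor_spd(mat: np.ndarray, floor: float) -> np.ndarray:
    """Eigenvalue-clip a symmetric matrix to be at least `floor`-definite."""
    vals, vecs = np.linalg.eigh(0.5 * (mat + mat.T))
    return (vecs * np.maximum(vals, floor)) @ vecs.T


@dataclass
class MapResult:
    """Per-participant MAP fit with its Laplace posterior approximation."""

    theta: np.ndarray
    names: tuple[str, ...]
    laplace_cov: np.ndarray
    loglik: float              # data log-likelihood at the MAP
    objective: float           # penalized negative objective value
    converged: bool

    @property
    def params(self) -> DiscountParams:
        idx = {n: i for i, n in enumerate(self.names)}
        lk = self.theta[idx.get("log_k", idx.get("log_k_ma1"))]
        lb = self.theta[idx["log_beta"]] if "log_beta" in idx else 0.0
        return DiscountParams(log_k=float(lk), log_beta=float(lb))


def map_fit(
    trials: pd.DataFrame,
    prior: PriorHyper,
    init: np.ndarray | DiscountParams | None = None,
    *,
    n_restarts: int = 5,
    rng: np.random.Generator | None = None,
    pin_log_beta: float | None = None,
    two_timepoint: bool = False,
    grad_tol: float = 1e-4,
) -> MapResult:
    """Maximum-a-posteriori fit of one participant's choices.

    Maximizes log-likelihood + log Gaussian prior density with L-BFGS from
    the supplied ``init`` (default: prior mean) plus ``n_restarts`` draws
    from the prior; the best penalized objective wins, ties going to the
    first found.  The Laplace covariance is the inverse Hessian of the
    negative penalized objective at the solution.

    Non-convergence after all restarts is flagged on the result (carrying
    the best iterate found), never silent.
    """
    data = _TrialArrays.from_frame(trials, two_timepoint)
    pin = pin_log_beta if pin_log_beta is not None else (
        0.0 if "log_beta" not in prior.names else None)
    if isinstance(init, DiscountParams):
        init = np.array(
            [{"log_k": init.log_k, "log_k_ma1": init.log_k,
              "log_beta": init.log_beta, "delta": 0.0}[n]
             for n in prior.names]
        )
    starts = [prior.mean if init is None else np.asarray(init, dtype=float)]
    if n_restarts > 0:
        if rng is None:
            rng = np.random.default_rng(0)
        starts += list(
            rng.multivariate_normal(prior.mean, prior.cov, size=n_restarts)
        )
    best = None
    for x0 in starts:
        res = minimize(
            _penalized, x0, args=(data, prior, pin), jac=True,
            method="L-BFGS-B", options={"maxiter": 200},
        )
        if best is None or res.fun < best.fun - 1e-12:
            best = res
    theta = np.asarray(best.x, dtype=float)
    _, grad = _penalized(theta, data, prior, pin)
    converged = bool(best.success) and float(np.max(np.abs(grad))) < max(
        grad_tol, 1e-6 * (1 + abs(best.fun)))
    H = _num_hessian(lambda t: _penalized(t, data, prior, pin), theta)
    laplace_cov = np.linalg.inv(_floor_spd(H, 1e-8))
    nll, _ = _nll_grad(theta, data, prior.names, pin)
    return MapResult(
        theta=theta,
        names=prior.names,
        laplace_cov=laplace_cov,
        loglik=-nll,
        objective=float(best.fun),
        converged=converged,
    )


# ---------------------------------------------------------------------------
# EM estimator

class HierarchicalDiscountModel(BaseEstimator):
    """Empirical-Bayes hierarchical fitter for discounting parameters.

    Parameters
    ----------
    two_timepoint : bool
        Fit (log_k_ma1, delta[, log_beta]) jointly from MA1+MA2 trials
        instead of a single (log_k[, log_beta]) per participant.
    pin_log_beta : bool
        Fix log_beta = 0 (unscaled sigmoid) instead of fitting it.
    covariance_mode : {"full", "diagonal"}
        Structure of the population prior covariance.
    max_em_iter, em_tol
        EM stops when the max-absolute hyperparameter change drops below
        ``em_tol`` or after ``max_em_iter`` iterations.
    n_restarts : int
        Random optimizer restarts per participant per E-step, drawn from
        the current prior.
    cov_floor : float
        Eigenvalue floor for the prior covariance (guards collapse when
        participants are near-identical).
    seed : int
        Seeds every stochastic restart; same data + seed + config gives a
        bit-identical fit.

    Attributes
    ----------
    prior_mean_, prior_cov_, param_names_ : learned population prior.
    params_ : DataFrame indexed by participant_id with MAP estimates,
        Laplace variances and per-participant log-likelihoods.
    n_iter_, converged_, objective_path_ : EM diagnostics.
    excluded_ : participants dropped before fitting (e.g. missing a
        timepoint in two-timepoint mode).
    """

    def __init__(
        self,
        *,
        two_timepoint: bool = False,
        pin_log_beta: bool = False,
        covariance_mode: str = "full",
        max_em_iter: int = 100,
        em_tol: float = 1e-3,
        n_restarts: int = 5,
        cov_floor: float = 1e-4,
        seed: int = 0,
    ):
        self.two_timepoint = two_timepoint
        self.pin_log_beta = pin_log_beta
        self.covariance_mode = covariance_mode
        self.max_em_iter = max_em_iter
        self.em_tol = em_tol
        self.n_restarts = n_restarts
        self.cov_floor = cov_floor
        self.seed = seed

    # -- internals ---------------------------------------------------------

    def _param_names(self) -> tuple[str, ...]:
        if self.two_timepoint:
            names = ["log_k_ma1", "delta"]
        else:
            names = ["log_k"]
        if not self.pin_log_beta:
            names.append("log_beta")
        return tuple(names)

    def _split(self, X: pd.DataFrame):
        """Per-participant trial tables, with two-timepoint screening."""
        if not isinstance(X, pd.DataFrame):
            raise TypeError("X must be a trials DataFrame")
        needed = {"participant_id", "r_immediate", "R_delayed", "delay_days",
                  "choice"}
        missing = needed - set(X.columns)
        if missing:
            raise ValueError(f"trials frame missing column(s) {sorted(missing)}")
        groups, excluded = {}, []
        for pid, df in X.groupby("participant_id", sort=True):
            if self.two_timepoint:
                tps = set(df["timepoint"])
                if not {"MA1", "MA2"} <= tps:
                    excluded.append(str(pid))
                    continue
            groups[str(pid)] = df
        if self.two_timepoint and excluded:
            logger.info(
                "two-timepoint fit: excluding %d participant(s) missing a "
                "timepoint: %s", len(excluded), excluded,
            )
        if len(groups) < 2:
            raise ValueError(
                "hyperparameter estimation needs at least 2 participants "
                f"(got {len(groups)})"
            )
        return groups, excluded

    def fit(self, X: pd.DataFrame, y=None):
        """Run EM over all participants' concatenated trials in ``X``."""
        groups, excluded = self._split(X)
        names = self._param_names()
        prior = default_prior(names)
        pin = 0.0 if self.pin_log_beta else None
        pids = list(groups.keys())
        root = np.random.SeedSequence(self.seed)
        objective_path: list[float] = []
        converged = False
        n_iter = 0
        warm: dict[str, np.ndarray] = {}
        maps: dict[str, MapResult] = {}
        for it in range(self.max_em_iter):
            n_iter = it + 1
            # one child stream per participant per iteration, order-independent
            streams = root.spawn(len(pids))
            total_obj = 0.0
            for pid, ss in zip(pids, streams):
                res = map_fit(
                    groups[pid], prior, init=warm.get(pid),
                    n_restarts=self.n_restarts,
                    rng=np.random.default_rng(ss),
                    pin_log_beta=pin,
                    two_timepoint=self.two_timepoint,
                )
                maps[pid] = res
                warm[pid] = res.theta
                # penalized log-objective incl. prior normalizer (ascent check)
                total_obj += res.loglik + prior.logpdf(res.theta)
            objective_path.append(total_obj)
            thetas = np.array([maps[p].theta for p in pids])
            new_mean = thetas.mean(axis=0)
            centred = thetas - new_mean
            new_cov = (
                centred.T @ centred / len(pids)
                + np.mean([maps[p].laplace_cov for p in pids], axis=0)
            )
            if self.covariance_mode == "diagonal":
                new_cov = np.diag(np.diag(new_cov))
            floored = _floor_spd(new_cov, self.cov_floor)
            if not np.allclose(floored, new_cov, atol=1e-12):
                logger.warning("prior covariance floored at %g", self.cov_floor)
            new_cov = floored
            change = max(
                float(np.max(np.abs(new_mean - prior.mean))),
                float(np.max(np.abs(new_cov - prior.cov))),
            )
            prior = PriorHyper(mean=new_mean, cov=new_cov, names=names)
            if change < self.em_tol:
                converged = True
                break
        if not converged:
            warnings.warn(
                f"EM did not converge in {self.max_em_iter} iterations",
                RuntimeWarning,
            )
        self.param_names_ = names
        self.prior_mean_ = prior.mean
        self.prior_cov_ = prior.cov
        self.prior_ = prior
        self.n_iter_ = n_iter
        self.converged_ = converged
        self.objective_path_ = np.asarray(objective_path)
        self.excluded_ = tuple(excluded)
        self.params_ = self._params_frame(pids, maps, names)
        return self

    def _params_frame(self, pids, maps, names) -> pd.DataFrame:
        idx = {n: i for i, n in enumerate(names)}
        i_lk = idx.get("log_k", idx.get("log_k_ma1"))
        rows = []
        for pid in pids:
            m = maps[pid]
            row = {
                "log_k_map": float(m.theta[i_lk]),
                "log_beta_map": (
                    float(m.theta[idx["log_beta"]]) if "log_beta" in idx else 0.0
                ),
                "laplace_var_log_k": float(m.laplace_cov[i_lk, i_lk]),
                "loglik": m.loglik,
                "map_converged": m.converged,
            }
            if "delta" in idx:
                row["delta"] = float(m.theta[idx["delta"]])
            rows.append(row)
        return pd.DataFrame(rows, index=pd.Index(pids, name="participant_id"))

    # -- prediction --------------------------------------------------------

    def _participant_params(self, pid: str, timepoint: str) -> DiscountParams:
        row = self.params_.loc[pid]
        lk = row["log_k_map"]
        if self.two_timepoint and timepoint == "MA2":
            lk = lk + row["delta"]
        return DiscountParams(log_k=float(lk), log_beta=float(row["log_beta_map"]))

    def predict_proba(self, X: pd.DataFrame) -> np.ndarray:
        """Per-trial probability of the *immediate* option under the fit."""
        if not hasattr(self, "params_"):
            raise RuntimeError("fit the model before predicting")
        out = np.empty(len(X))
        for i, (_, row) in enumerate(X.iterrows()):
            pid = str(row["participant_id"])
            if pid not in self.params_.index:
                raise KeyError(f"participant {pid!r} was not fitted")
            p = self._participant_params(pid, row.get("timepoint", "MA1"))
            from .model import p_immediate

            out[i] = p_immediate(
                row["r_immediate"], row["R_delayed"], row["delay_days"], p
            )
        return out

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        p = self.predict_proba(X)
        return np.where(p > 0.5, "immediate", "delayed")


# ---------------------------------------------------------------------------
# functional surface

@dataclass
class FitResult:
    """Outcome of an EM hierarchical fit."""

    params: pd.DataFrame
    prior: PriorHyper
    n_iter: int
    converged: bool
    objective_path: np.ndarray = field(default_factory=lambda: np.array([]))
    excluded: tuple[str, ...] = ()
    two_timepoint: bool = False

    def to_frame(self) -> pd.DataFrame:
        """Flat table in the canonical fits.csv schema."""
        df = self.params.reset_index()
        df.insert(1, "timepoint", "MA1" if self.two_timepoint else "all")
        if "delta" not in df.columns:
            df["delta"] = np.nan
        df["excluded_flag"] = False
        extra = pd.DataFrame(
            {
                "participant_id": list(self.excluded),
                "timepoint": "MA1" if self.two_timepoint else "all",
                "excluded_flag": True,
            }
        )
        if len(extra):
            df = pd.concat([df, extra], ignore_index=True)
        cols = [
            "participant_id", "timepoint", "log_k_map", "log_beta_map",
            "delta", "laplace_var_log_k", "loglik", "excluded_flag",
        ]
        return df.reindex(columns=cols)

    @classmethod
    def from_estimator(cls, est: HierarchicalDiscountModel) -> "FitResult":
        return cls(
            params=est.params_,
            prior=est.prior_,
            n_iter=est.n_iter_,
            converged=est.converged_,
            objective_path=est.objective_path_,
            excluded=est.excluded_,
            two_timepoint=est.two_timepoint,
        )


def em_fit(trials: pd.DataFrame, **config) -> FitResult:
    """EM fit of (log_k[, log_beta]) on each participant's concatenated trials."""
    est = HierarchicalDiscountModel(two_timepoint=False, **config).fit(trials)
    return FitResult.from_estimator(est)


def em_fit_two_timepoint(trials: pd.DataFrame, **config) -> FitResult:
    """EM fit of (log_k_ma1, delta[, log_beta]) from MA1+MA2 trials."""
    est = HierarchicalDiscountModel(two_timepoint=True, **config).fit(trials)
    return FitResult.from_estimator(est)


def write_fits(fit: FitResult, path) -> None:
    fit.to_frame().to_csv(path, index=False)


def load_fits(path) -> pd.DataFrame:
    return pd.read_csv(path, dtype={"participant_id": str})
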