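"""Synthetic patient-level survival data and Weibull recovery.

The published model inputs are Weibull parameters obtained upstream by
digitizing trial Kaplan-Meier curves and fitting parametric survival
models. This module emulates that stage end-to-end so the survival
machinery can be validated without external data: individual event times
are simulated from known Weibull parameters via the inverse CDF, censored
administratively (optionally with uniform dropout), summarized by the
product-limit estimator, and re-fit by maximum likelihood under right
censoring on the same S(t) = exp(-scale * t**shape) parameterization used
throughout the package.

Conversion helpers translate to/from the time-scaled (lambda, rho)
Weibull form used by lifelines, S(t) = exp(-(t/lambda)**rho).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from scipy import optimize

from .parameters import WeibullParams

__all__ = [
    "SimulatedCohort",
    "WeibullFit",
    "simulate_cohort",
    "fit_weibull",
    "km_estimate",
    "to_time_scale_form",
    "from_time_scale_form",
]


@dataclass(frozen=True)
class SimulatedCohort:
    """Right-censored event times (in cycles) for a simulated trial arm."""

    time: np.ndarray
    event: np.ndarray  # True = event observed, False = censored
    true_params: WeibullParams
    censor_time: float
    seed: int

    def __len__(self) -> int:
        return len(self.time)

    @property
    def n_events(self) -> int:
        return int(self.event.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "id": np.arange(1, len(self.time) + 1),
            "time": self.time,
            "event": self.event.astype(int),
        })

    def save(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass(frozen=True)
class WeibullFit:
    """Maximum-likelihood Weibull estimates with Wald standard errors.

    Standard errors are on the log-parameter scale (the optimization
    scale), so 95 % intervals are exp(log_estimate +/- 1.96 * se).
    """

    params: WeibullParams
    se_log_scale: float
    se_log_shape: float
    loglik: float
    converged: bool
    n_events: int

    def ci(self, which: str, level: float = 0.95) -> tuple[float, float]:
        from scipy.stats import norm
        z = norm.ppf(0.5 + level / 2.0)
        est = getattr(self.params, which)
        se = self.se_log_scale if which == "scale" else self.se_log_shape
        return est * np.exp(-z * se), est * np.exp(z * se)


def simulate_cohort(p: WeibullParams, n: int, censor_time: float, seed: int,
                    dropout_rate: float = 0.0) -> SimulatedCohort:
    """Draw ``n`` Weibull event times and apply right censoring.

    Event times come from the inverse CDF, t = (-ln U / scale)^(1/shape).
    Censoring is administrative at ``censor_time``; with ``dropout_rate``
    > 0 an independent uniform dropout time on (0, censor_time] is drawn
    for that fraction of patients, mimicking loss to follow-up.
    """
    if n < 1:
        raise ValueError("need at least one patient")
    if censor_time <= 0:
        raise ValueError("censoring time must be positive")
    rng = np.random.default_rng(seed)
    u = rng.uniform(size=n)
    t_event = np.power(-np.log(u) / p.scale, 1.0 / p.shape)
    t_censor = np.full(n, float(censor_time))
    if dropout_rate > 0:
        drops = rng.uniform(size=n) < dropout_rate
        t_censor[drops] = rng.uniform(0.0, censor_time, size=int(drops.sum()))
    time = np.minimum(t_event, t_censor)
    event = t_event <= t_censor
    return SimulatedCohort(time=time, event=event, true_params=p,
                           censor_time=float(censor_time), seed=seed)


def _neg_loglik(log_params: np.ndarray, time: np.ndarray, event: np.ndarray) -> float:
    lam, gam = np.exp(log_params)
    lt = np.log(time)
    cum_haz = lam * np.power(time, gam)
    ll = np.sum(event * (np.log(lam) + np.log(gam) + (gam - 1.0) * lt)) - np.sum(cum_haz)
    return -ll


def fit_weibull(cohort: SimulatedCohort | pd.DataFrame,
                fix_shape: float | None = None) -> WeibullFit:
    """Maximum-likelihood Weibull fit under right censoring.

    Optimizes the log-likelihood in log-parameter space (guaranteeing
    positivity); Wald standard errors come from the numerical inverse
    Hessian. ``fix_shape`` profiles the scale with the shape pinned, in
    which case the scale MLE has the closed form events / sum(t^shape).
    """
    if isinstance(cohort, pd.DataFrame):
        time = cohort["time"].to_numpy(dtype=float)
        event = cohort["event"].to_numpy().astype(bool)
    else:
        time, event = cohort.time, cohort.event
    n_events = int(event.sum())
    if n_events < 2 and fix_shape is None:
        raise ValueError("need at least two observed events to fit both parameters")
    if n_events < 1:
        raise ValueError("cannot fit a survival model with no observed events")
    if np.any(time <= 0):
        raise ValueError("survival times must be positive")

    if fix_shape is not None:
        gam = float(fix_shape)
        lam = n_events / float(np.sum(np.power(time, gam)))
        ll = -_neg_loglik(np.log([lam, gam]), time, event)
        se_log_scale = 1.0 / np.sqrt(n_events)  # Fisher information of a rate
        return WeibullFit(WeibullParams(scale=lam, shape=gam),
                          se_log_scale=se_log_scale, se_log_shape=0.0,
                          loglik=ll, converged=True, n_events=n_events)

    # crude exponential start: rate = events / total time, shape 1
    lam0 = n_events / float(time.sum())
    res = optimize.minimize(_neg_loglik, x0=np.log([lam0, 1.0]),
                            args=(time, event), method="BFGS")
    if not res.success and not np.isfinite(res.fun):
        raise RuntimeError(f"Weibull fit did not converge: {res.message}\n{res}")
    lam, gam = np.exp(res.x)
    # numerical Hessian on the log scale for Wald errors
    hess = _numerical_hessian(lambda x: _neg_loglik(x, time, event), res.x)
    try:
        cov = np.linalg.inv(hess)
        se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    except np.linalg.LinAlgError:
        se = np.sqrt(np.maximum(np.diag(res.hess_inv), 0.0))
    return WeibullFit(WeibullParams(scale=float(lam), shape=float(gam)),
                      se_log_scale=float(se[0]), se_log_shape=float(se[1]),
                      loglik=float(-res.fun), converged=bool(res.success),
                      n_events=n_events)


def _numerical_hessian(f, x: np.ndarray, eps: float = 1e-5) -> np.ndarray:
    n = len(x)
    h = np.zeros((n, n))
    for i in range(n):
        for j in range(i, n):
            ei = np.zeros(n); ei[i] = eps
            ej = np.zeros(n); ej[j] = eps
            h[i, j] = h[j, i] = (
                f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej)
            ) / (4.0 * eps * eps)
    return h


def km_estimate(cohort: SimulatedCohort | pd.DataFrame) -> pd.DataFrame:
    """Product-limit (Kaplan-Meier) survival estimate.

    Returns a step table with columns ``time`` and ``survival``; S(0) = 1
    and steps occur only at observed event times.
    """
    if isinstance(cohort, pd.DataFrame):
        time = cohort["time"].to_numpy(dtype=float)
        event = cohort["event"].to_numpy().astype(bool)
    else:
        time, event = cohort.time, cohort.event
    if len(time) < 1:
        raise ValueError("need at least one subject")
    kmf = KaplanMeierFitter()
    kmf.fit(time, event_observed=event)
    sf = kmf.survival_function_
    return pd.DataFrame({"time": sf.index.to_numpy(dtype=float),
                         "survival": sf.iloc[:, 0].to_numpy(dtype=float)})


def to_time_scale_form(p: WeibullParams) -> tuple[float, float]:
    """(lambda_time, rho) of S(t) = exp(-(t/lambda_time)**rho), the
    parameterization used by lifelines' WeibullFitter."""
    rho = p.shape
    lam_time = p.scale ** (-1.0 / rho)
    return lam_time, rho


def from_time_scale_form(lam_time: float, rho: float) -> WeibullParams:
    """Inverse of :func:`to_time_scale_form`."""
    return WeibullParams(scale=lam_time ** (-rho), shape=rho)
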