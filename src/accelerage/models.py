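"""Survival models for residual-life based biological age prediction.

Three model classes, all fitted to left-truncated right-censored cohort
data with chronological age as the primary timescale:

- :class:`GompertzAFT`: fully parametric accelerated failure time model
  with a Gompertz baseline, fitted by maximum likelihood with delayed
  entry. The acceleration factor exp(beta @ x) is interpretable as an
  individual aging rate; the conditional law is again Gompertz.
- :class:`CoxAge`: semiparametric Cox proportional hazards model on the
  age axis with delayed-entry risk sets and a Breslow baseline cumulative
  hazard. Converts to residual life through the estimated baseline.
- :class:`GrimAgeModel`: comparator built the way mortality-trained
  epigenetic clocks are: a Cox model on time-on-study with chronological
  age among the covariates, followed by an affine rescaling of the linear
  predictor to the training set's age mean and SD.

Each ``fit()`` returns a Results object carrying estimates, standard
errors, diagnostics and a ``summary()`` table.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .data import SurvivalData
from .distributions import GompertzParams
from .lifetable import MEAN_TAIL_TOL, InsufficientTailSupportError

__all__ = [
    "GompertzAFT",
    "GompertzAFTResults",
    "CoxAge",
    "CoxAgeResults",
    "GrimAgeModel",
    "GrimAgeResults",
    "FitFailureError",
]

LOG2 = float(np.log(2.0))


class FitFailureError(RuntimeError):
    """Optimization failed (non-convergence or singular Hessian).

    Carries optimizer diagnostics; failed fits are never silently imputed.
    """


def _summary_frame(names, est, se) -> pd.DataFrame:
    from scipy.stats import norm

    z = est / se
    return pd.DataFrame(
        {
            "coef": est,
            "se": se,
            "z": z,
            "p": 2 * norm.sf(np.abs(z)),
            "ci_low": est - 1.96 * se,
            "ci_high": est + 1.96 * se,
        },
        index=names,
    )


# =====================================================================
# Gompertz AFT
# =====================================================================


class GompertzAFT:
    """Gompertz accelerated failure time model with delayed entry.

    The baseline hazard is ``h0(t) = a exp(b t)``; covariates rescale age by
    ``theta = exp(beta @ x)`` so the conditional law is Gompertz(a*theta,
    b*theta). The log-likelihood conditions on survival to the entry age::

        sum_i  d_i * log h(t_i|x_i) - [H(t_i|x_i) - H(c_i|x_i)]

    Parameters are optimized on the scale ``(log a, log b, beta)`` for
    positivity and conditioning.
    """

    def __init__(self, data: SurvivalData):
        if data.n_events < 2:
            raise ValueError("need at least 2 events to fit")
        if np.linalg.matrix_rank(data.markers) < data.n_markers:
            raise ValueError("marker matrix is rank deficient")
        self.data = data

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "GompertzAFT":
        return cls(SurvivalData.from_dataframe(df))

    # -- likelihood -----------------------------------------------------

    def loglike(self, params) -> float:
        """Delayed-entry log-likelihood at ``params = (log a, log b, beta)``."""
        return self._loglike_grad(np.asarray(params, dtype=float))[0]

    def score(self, params) -> np.ndarray:
        return self._loglike_grad(np.asarray(params, dtype=float))[1]

    def _loglike_grad(self, p):
        d = self.data
        la, lb = p[0], p[1]
        beta = p[2:]
        a, b = np.exp(la), np.exp(lb)
        lp = d.markers @ beta if beta.size else np.zeros(len(d))
        theta = np.exp(lp)
        bt_t = np.minimum(b * theta * d.exit_age, 600.0)
        bt_c = np.minimum(b * theta * d.entry_age, 600.0)
        e_t, e_c = np.exp(bt_t), np.exp(bt_c)
        r = a / b
        delta = d.status
        ll = np.sum(delta * (la + lp + bt_t)) - r * np.sum(e_t - e_c)
        g = np.empty_like(p)
        g[0] = delta.sum() - r * np.sum(e_t - e_c)
        w = bt_t * e_t - bt_c * e_c
        g[1] = np.sum(delta * bt_t) + r * np.sum(e_t - e_c) - r * np.sum(w)
        if beta.size:
            per = delta * (1.0 + bt_t) - r * w
            g[2:] = d.markers.T @ per
        return ll, g

    def hessian(self, params, rel_step: float = 1e-6) -> np.ndarray:
        """Observed Hessian by central differences of the analytic score."""
        p = np.asarray(params, dtype=float)
        k = p.size
        H = np.empty((k, k))
        for j in range(k):
            h = rel_step * (1.0 + abs(p[j]))
            pp, pm = p.copy(), p.copy()
            pp[j] += h
            pm[j] -= h
            H[:, j] = (self.score(pp) - self.score(pm)) / (2 * h)
        return (H + H.T) / 2.0

    # -- fitting ---------------------------------------------------------

    def fit(self, start_params=None, maxiter: int = 500) -> "GompertzAFTResults":
        """Maximize the likelihood; raises :class:`FitFailureError` on failure.

        Starting values: a marginal Gompertz fit ignoring covariates
        (itself started near typical human-mortality values a = exp(-9),
        b = 0.085), with beta = 0. This model is numerically delicate; the
        optimum is polished by Newton steps until the score norm is tiny.
        """
        k = self.data.n_markers
        if start_params is None:
            start = np.zeros(2 + k)
            start[:2] = self._marginal_start(maxiter)
        else:
            start = np.asarray(start_params, dtype=float)
        p, ll, niter = self._maximize(start, maxiter)
        grad = self.score(p)
        H = self.hessian(p)
        gnorm = float(np.linalg.norm(grad))
        converged = gnorm < 1e-5
        try:
            vcov = np.linalg.inv(-H)
        except np.linalg.LinAlgError as exc:
            raise FitFailureError(
                f"singular Hessian at the optimum (|score| = {gnorm:.2e})"
            ) from exc
        if not converged or np.any(np.diag(vcov) <= 0):
            raise FitFailureError(
                f"optimization did not converge: |score| = {gnorm:.2e} after "
                f"{niter} iterations; Hessian diagonal "
                f"{np.diag(-H).round(3).tolist()}"
            )
        return GompertzAFTResults(model=self, params_internal=p, vcov_internal=vcov,
                                  llf=ll, converged=True, niter=niter)

    def _marginal_start(self, maxiter):
        # marginal Gompertz likelihood: same data, beta frozen at 0
        def nll(q):
            ll, g = self._loglike_grad(np.concatenate([q, np.zeros(self.data.n_markers)]))
            return -ll, -g[:2]

        res = minimize(nll, np.array([-9.0, np.log(0.085)]), jac=True,
                       method="L-BFGS-B", options={"maxiter": maxiter})
        return res.x

    def _maximize(self, start, maxiter):
        def nll(q):
            ll, g = self._loglike_grad(q)
            return -ll, -g

        res = minimize(nll, start, jac=True, method="L-BFGS-B",
                       options={"maxiter": maxiter, "ftol": 1e-13, "gtol": 1e-9})
        p = res.x
        ll = -res.fun
        # Newton polish: relative log-likelihood change < 1e-9 or score ~ 0
        for it in range(50):
            ll, g = self._loglike_grad(p)
            if np.linalg.norm(g) < 1e-7:
                break
            H = self.hessian(p)
            try:
                step = np.linalg.solve(H, -g)
            except np.linalg.LinAlgError as exc:
                raise FitFailureError("singular Hessian during Newton polish") from exc
            if not np.all(np.isfinite(step)):
                raise FitFailureError("non-finite Newton step")
            # backtrack if the step does not improve the likelihood
            lam = 1.0
            for _ in range(30):
                ll_new = self.loglike(p + lam * step)
                if ll_new >= ll - 1e-12:
                    break
                lam /= 2.0
            p = p + lam * step
            if abs(ll_new - ll) < 1e-9 * (1 + abs(ll)) and np.linalg.norm(self.score(p)) < 1e-5:
                ll = ll_new
                break
            ll = ll_new
        return p, self.loglike(p), res.nit + it + 1


@dataclass
class GompertzAFTResults:
    """Fitted Gompertz AFT model: estimates, covariance and predictions."""

    model: GompertzAFT
    params_internal: np.ndarray  # (log a, log b, beta)
    vcov_internal: np.ndarray
    llf: float
    converged: bool
    niter: int

    @property
    def a_hat(self) -> float:
        return float(np.exp(self.params_internal[0]))

    @property
    def b_hat(self) -> float:
        return float(np.exp(self.params_internal[1]))

    @property
    def beta_hat(self) -> np.ndarray:
        return self.params_internal[2:]

    @property
    def baseline(self) -> GompertzParams:
        return GompertzParams(a=self.a_hat, b=self.b_hat)

    @property
    def bse(self) -> np.ndarray:
        """Standard errors on the internal scale (log a, log b, beta)."""
        return np.sqrt(np.diag(self.vcov_internal))

    @property
    def param_names(self) -> list[str]:
        return ["log_a", "log_b", *self.model.data.marker_names]

    def summary(self) -> pd.DataFrame:
        return _summary_frame(self.param_names, self.params_internal, self.bse)

    def linear_predictor(self, X) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.beta_hat.shape[0]:
            raise ValueError("marker dimension mismatch")
        return X @ self.beta_hat

    def predict_residual_life(self, entry_age, X, kind: str = "median",
                              missing: str = "raise") -> np.ndarray:
        """Conditional residual life at the entry age given markers.

        The conditional law is Gompertz(a*theta, b*theta); the median solves
        ``H(c + m | x) - H(c | x) = log 2`` in closed form, and the mean is
        integrated by the trapezoidal rule on the conditional survival.
        (``missing`` is accepted for interface symmetry; the parametric law
        is defined at every age, so nothing can be unsupported.)
        """
        c = np.atleast_1d(np.asarray(entry_age, dtype=float))
        theta = np.exp(self.linear_predictor(X))
        a, b = self.a_hat, self.b_hat
        if kind == "median":
            # exp(b theta t_med) = exp(b theta c) + (b/a) log 2, computed as
            # t_med = c + log1p((b/a) log2 exp(-b theta c)) / (b theta)
            # which never overflows even for extreme acceleration factors
            bt_c = b * theta * c
            return np.log1p((b / a) * LOG2 * np.exp(-bt_c)) / (b * theta)
        if kind == "mean":
            # mrl(c|x) = int_0^inf exp(-(H(c+u) - H(c))) du on a fine grid
            u = np.linspace(0.0, 140.0, 2801)
            bt = b * theta[:, None] * (c[:, None] + u[None, :])
            bt_c = b * theta * c
            logs = -(a / b) * (np.exp(np.minimum(bt, 600.0)) - np.exp(bt_c)[:, None])
            s = np.exp(logs)
            return np.trapezoid(s, u, axis=1)
        raise ValueError(f"kind must be 'mean' or 'median', got {kind!r}")

    def predict_bioage(self, table, data: SurvivalData | None = None, kind: str = "median"):
        from .bioage import predict_bioage

        return predict_bioage(self, table, data if data is not None else self.model.data, kind)

    def to_dict(self) -> dict:
        return {
            "model": "gompertz_aft",
            "a_hat": self.a_hat,
            "b_hat": self.b_hat,
            "beta_hat": self.beta_hat.tolist(),
            "marker_names": list(self.model.data.marker_names),
            "loglik": float(self.llf),
            "vcov_internal": self.vcov_internal.tolist(),
            "converged": bool(self.converged),
        }


# =====================================================================
# Cox PH on the age axis
# =====================================================================


class CoxAge:
    """Semiparametric Cox PH model using chronological age as the timescale.

    Subject i is in the risk set at event age t iff entry_age_i < t <=
    exit_age_i (delayed entry). Coefficients come from the partial
    likelihood (fitted by lifelines); the baseline cumulative hazard uses
    the Breslow estimator throughout — simulated event times are
    continuous, so ties are measure-zero.
    """

    def __init__(self, data: SurvivalData):
        if data.n_events < 2:
            raise ValueError("need at least 2 events to fit")
        self.data = data

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "CoxAge":
        return cls(SurvivalData.from_dataframe(df))

    def partial_loglike(self, beta) -> float:
        """Breslow partial log-likelihood with delayed-entry risk sets."""
        beta = np.asarray(beta, dtype=float)
        d = self.data
        lp = d.markers @ beta
        ll = 0.0
        for i in np.flatnonzero(d.status == 1):
            t = d.exit_age[i]
            at_risk = (d.entry_age < t) & (t <= d.exit_age)
            ll += lp[i] - np.log(np.sum(np.exp(lp[at_risk])))
        return float(ll)

    def fit(self) -> "CoxAgeResults":
        from lifelines import CoxPHFitter
        from lifelines.exceptions import ConvergenceError

        d = self.data
        df = pd.DataFrame(d.markers, columns=d.marker_names)
        df["exit_age"] = d.exit_age
        df["entry_age"] = d.entry_age
        df["status"] = d.status
        cph = CoxPHFitter()
        try:
            cph.fit(df, duration_col="exit_age", event_col="status", entry_col="entry_age")
        except ConvergenceError as exc:
            raise FitFailureError(f"Cox partial-likelihood fit failed: {exc}") from exc
        beta = cph.params_.to_numpy()
        bse = cph.standard_errors_.to_numpy()
        vcov = cph.variance_matrix_.to_numpy()
        event_ages, cumhaz = self._breslow(beta)
        return CoxAgeResults(
            model=self,
            beta_hat=beta,
            bse=bse,
            vcov=vcov,
            llf=float(cph.log_likelihood_),
            breslow_ages=event_ages,
            breslow_cumhaz=cumhaz,
            support=(float(d.entry_age.min()), float(d.exit_age.max())),
        )

    def _breslow(self, beta):
        """Breslow baseline cumulative hazard on the age axis (uncentered lp)."""
        d = self.data
        lp = d.markers @ beta
        elp = np.exp(lp)
        order = np.argsort(d.exit_age, kind="stable")
        event_mask = d.status[order] == 1
        event_ages = d.exit_age[order][event_mask]
        # risk-set sums by sorting entries and exits once
        jumps = np.empty(event_ages.size)
        exit_sorted = d.exit_age[order]
        elp_sorted = elp[order]
        # cumulative sum of exp(lp) for subjects with exit >= t: suffix sums
        suffix = np.concatenate([np.cumsum(elp_sorted[::-1])[::-1], [0.0]])
        entry_sorted_idx = np.argsort(d.entry_age, kind="stable")
        entry_sorted = d.entry_age[entry_sorted_idx]
        elp_entry_cum = np.concatenate([[0.0], np.cumsum(elp[entry_sorted_idx])])
        for k, t in enumerate(event_ages):
            # subjects with exit_age >= t
            j = np.searchsorted(exit_sorted, t, side="left")
            total_exit = suffix[j]
            # minus those who enter at or after t (entry >= t means entry < t fails)
            m = np.searchsorted(entry_sorted, t, side="left")
            not_yet_entered = elp_entry_cum[-1] - elp_entry_cum[m]
            denom = total_exit - not_yet_entered
            jumps[k] = 1.0 / denom
        return event_ages, np.cumsum(jumps)


@dataclass
class CoxAgeResults:
    """Fitted age-timescale Cox model with Breslow baseline."""

    model: CoxAge
    beta_hat: np.ndarray
    bse: np.ndarray
    vcov: np.ndarray
    llf: float
    breslow_ages: np.ndarray
    breslow_cumhaz: np.ndarray
    support: tuple[float, float]

    @property
    def converged(self) -> bool:
        return True

    def summary(self) -> pd.DataFrame:
        return _summary_frame(list(self.model.data.marker_names), self.beta_hat, self.bse)

    def cumhaz_at(self, t) -> np.ndarray:
        """Breslow step function evaluated at age(s) t (zero below first event)."""
        idx = np.searchsorted(self.breslow_ages, np.asarray(t, dtype=float), side="right")
        padded = np.concatenate([[0.0], self.breslow_cumhaz])
        return padded[idx]

    def linear_predictor(self, X) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.beta_hat.shape[0]:
            raise ValueError("marker dimension mismatch")
        return X @ self.beta_hat

    def predict_residual_life(self, entry_age, X, kind: str = "median",
                              missing: str = "raise") -> np.ndarray:
        """Residual life from the estimated step-function survival.

        ``S(t|x) = exp(-H0(t) exp(beta @ x))``. When the Breslow support
        ends before the conditional survival reaches the needed level —
        the documented failure mode of semiparametric predictors when the
        data do not cover the tail of lifespan — raises
        :class:`InsufficientTailSupportError`, or returns NaN for the
        affected subjects with ``missing="nan"``.
        """
        c = np.atleast_1d(np.asarray(entry_age, dtype=float))
        lp = self.linear_predictor(X)
        elp = np.exp(lp)
        H_c = self.cumhaz_at(c)
        if kind == "median":
            target = H_c + LOG2 / elp
            idx = np.searchsorted(self.breslow_cumhaz, target, side="left")
            unsupported = idx >= self.breslow_ages.size
            if np.any(unsupported):
                if missing == "raise":
                    raise InsufficientTailSupportError(
                        "baseline cumulative hazard support ends before conditional "
                        "survival reaches half its value; the data do not cover the "
                        "tail of lifespan"
                    )
                idx = np.where(unsupported, 0, idx)
            out = self.breslow_ages[idx] - c
            return np.where(unsupported, np.nan, out)
        if kind == "mean":
            ages = self.breslow_ages
            out = np.empty(c.shape)
            for i in range(c.size):
                s_cond_end = np.exp(-(self.breslow_cumhaz[-1] - H_c[i]) * elp[i])
                if s_cond_end > MEAN_TAIL_TOL:
                    if missing == "raise":
                        raise InsufficientTailSupportError(
                            "conditional survival mass beyond the Breslow support is "
                            "non-negligible; mean residual life is undefined"
                        )
                    out[i] = np.nan
                    continue
                after = ages > c[i]
                grid = np.concatenate([[c[i]], ages[after]])
                Hg = np.concatenate([[H_c[i]], self.breslow_cumhaz[after]])
                s = np.exp(-(Hg - H_c[i]) * elp[i])
                # survival is a right-continuous step function: rectangles
                out[i] = np.sum(s[:-1] * np.diff(grid))
            return out
        raise ValueError(f"kind must be 'mean' or 'median', got {kind!r}")

    def predict_bioage(self, table, data: SurvivalData | None = None, kind: str = "median"):
        from .bioage import predict_bioage

        return predict_bioage(self, table, data if data is not None else self.model.data, kind)

    def to_dict(self) -> dict:
        return {
            "model": "cox_age",
            "beta_hat": self.beta_hat.tolist(),
            "marker_names": list(self.model.data.marker_names),
            "loglik": float(self.llf),
            "breslow_ages": self.breslow_ages.tolist(),
            "breslow_cumhaz": self.breslow_cumhaz.tolist(),
            "support": list(self.support),
        }


# =====================================================================
# GrimAge-type comparator
# =====================================================================


class GrimAgeModel:
    """Mortality-trained clock in the style of GrimAge.

    Stage 1: Cox PH model on *time-on-study* (time zero at entry) with
    covariates [entry age, markers]. Stage 2: the full linear predictor
    (including the age term) is rescaled to the training set's
    chronological-age mean and SD, giving predictions in units of years.
    No life table or residual-life step is involved.
    """

    def __init__(self, data: SurvivalData):
        if data.n_events < 2:
            raise ValueError("need at least 2 events to fit")
        self.data = data

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "GrimAgeModel":
        return cls(SurvivalData.from_dataframe(df))

    def fit(self) -> "GrimAgeResults":
        from lifelines import CoxPHFitter
        from lifelines.exceptions import ConvergenceError

        d = self.data
        df = pd.DataFrame(d.markers, columns=d.marker_names)
        df.insert(0, "age", d.entry_age)
        df["duration"] = d.time_on_study
        df["status"] = d.status
        cph = CoxPHFitter()
        try:
            cph.fit(df, duration_col="duration", event_col="status")
        except ConvergenceError as exc:
            raise FitFailureError(f"time-on-study Cox fit failed: {exc}") from exc
        beta = cph.params_.to_numpy()
        design = np.column_stack([d.entry_age, d.markers])
        lp = design @ beta
        lp_sd = float(np.std(lp, ddof=1))
        if lp_sd <= 0:
            raise ValueError("degenerate linear predictor (zero variance)")
        return GrimAgeResults(
            model=self,
            beta_hat=beta,
            bse=cph.standard_errors_.to_numpy(),
            llf=float(cph.log_likelihood_),
            lp_mean=float(np.mean(lp)),
            lp_sd=lp_sd,
            age_mean=float(np.mean(d.entry_age)),
            age_sd=float(np.std(d.entry_age, ddof=1)),
        )


@dataclass
class GrimAgeResults:
    """Fitted GrimAge-type clock: Cox coefficients plus rescaling moments."""

    model: GrimAgeModel
    beta_hat: np.ndarray
    bse: np.ndarray
    llf: float
    lp_mean: float
    lp_sd: float
    age_mean: float
    age_sd: float

    @property
    def converged(self) -> bool:
        return True

    def summary(self) -> pd.DataFrame:
        names = ["age", *self.model.data.marker_names]
        return _summary_frame(names, self.beta_hat, self.bse)

    def linear_predictor(self, entry_age, X) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        design = np.column_stack([np.atleast_1d(entry_age), X])
        if design.shape[1] != self.beta_hat.shape[0]:
            raise ValueError("marker dimension mismatch")
        return design @ self.beta_hat

    def predict_bioage_values(self, entry_age, X) -> np.ndarray:
        """B_hat = age_mean + age_sd * (lp - lp_mean) / lp_sd."""
        lp = self.linear_predictor(entry_age, X)
        return self.age_mean + self.age_sd * (lp - self.lp_mean) / self.lp_sd

    def predict_bioage(self, data: SurvivalData | None = None):
        from .bioage import predict_grimage

        return predict_grimage(self, data if data is not None else self.model.data)

    def to_dict(self) -> dict:
        return {
            "model": "grimage_type",
            "beta_hat": self.beta_hat.tolist(),
            "marker_names": ["age", *self.model.data.marker_names],
            "loglik": float(self.llf),
            "lp_mean": self.lp_mean,
            "lp_sd": self.lp_sd,
            "age_mean": self.age_mean,
            "age_sd": self.age_sd,
        }
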