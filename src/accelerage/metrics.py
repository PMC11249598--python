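"""Evaluation measures for biological age predictors.

- RMSE against known true biological age (simulation only).
- Uno's inverse-probability-of-censoring-weighted (IPCW) concordance,
  which does not depend on the study-specific censoring distribution.
- Life-table calibration: predicted X-year mortality probabilities from
  the reference table versus Kaplan-Meier observed event rates in
  equally sized predicted-risk groups.
- The traditional check: hazard ratio of the standardized age
  acceleration delta in a Cox model adjusted for chronological age (and
  stratum).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import SurvivalData

__all__ = [
    "rmse",
    "uno_concordance",
    "ConcordanceResult",
    "calibration",
    "CalibrationTable",
    "delta_association",
]


def rmse(bioage_hat, bioage_true) -> float:
    """Root-mean-square error sqrt(mean((b_hat - b)^2)), in years.

    Flagged (missing) predictions must be excluded by the caller; their
    presence here is an error rather than a silent drop.
    """
    a = np.asarray(bioage_hat, dtype=float)
    b = np.asarray(bioage_true, dtype=float)
    if a.shape != b.shape:
        raise ValueError("vectors must have equal length")
    if np.isnan(a).any() or np.isnan(b).any():
        raise ValueError("missing values present; exclude flagged predictions upstream")
    return float(np.sqrt(np.mean((a - b) ** 2)))


@dataclass(frozen=True)
class ConcordanceResult:
    c_index: float
    se: float
    tau: float
    n_pairs: float  # IPCW-weighted comparable mass

    def __post_init__(self):
        if not 0.0 <= self.c_index <= 1.0:
            raise ValueError("concordance outside [0, 1]")


def _censoring_km(time, status):
    """Kaplan-Meier of the censoring distribution on time-on-study.

    Events and censorings swap roles; entry is time zero on this scale, so
    no delayed entry is involved. Returns a step-function evaluator for
    the left limit G(t-).
    """
    from lifelines import KaplanMeierFitter

    kmf = KaplanMeierFitter()
    kmf.fit(time, event_observed=1 - np.asarray(status))
    grid = kmf.survival_function_.index.to_numpy(dtype=float)
    vals = kmf.survival_function_.iloc[:, 0].to_numpy(dtype=float)

    padded = np.concatenate([[1.0], vals])

    def g_left(t):
        # value of the right-continuous step function just before t
        idx = np.searchsorted(grid, np.asarray(t, dtype=float), side="left")
        return padded[idx]

    return g_left


def uno_concordance(
    data: SurvivalData, risk_scores, tau: float | None = None, chunk: int = 512
) -> ConcordanceResult:
    """Uno's IPCW concordance on time-on-study.

    Scores must be oriented so that larger means higher risk (e.g.
    predicted biological age, or minus predicted residual life). A pair
    (i, j) is comparable when T_i < T_j, T_i < tau and subject i had the
    event; it is weighted 1/G(T_i-)^2 with G the Kaplan-Meier estimate of
    the censoring distribution. Ties in score count one half. The default
    tau is the largest event time with G(tau-) >= 0.1, which caps the
    weight explosion near the end of follow-up. The standard error is a
    leave-one-subject-out jackknife (with the censoring weights held
    fixed).
    """
    scores = np.asarray(risk_scores, dtype=float)
    if scores.shape[0] != len(data):
        raise ValueError("scores must have one entry per subject")
    time = data.time_on_study
    status = data.status
    g = _censoring_km(time, status)
    event_times = time[status == 1]
    if event_times.size == 0:
        raise ValueError("no events; concordance undefined")
    if tau is None:
        ok = g(event_times) >= 0.1
        if not ok.any():
            raise ValueError("censoring survival drops below 0.1 before the first event")
        tau = float(event_times[ok].max()) + 1e-12
    gt = g(time)
    usable = (status == 1) & (time < tau)
    if np.any(gt[usable] <= 0):
        raise ValueError(
            "censoring survival reaches 0 before tau; choose a smaller tau"
        )
    n = len(data)
    w = np.zeros(n)
    w[usable] = 1.0 / gt[usable] ** 2
    row_num = np.zeros(n)
    row_den = np.zeros(n)
    col_num = np.zeros(n)
    col_den = np.zeros(n)
    idx_i = np.flatnonzero(usable)
    for start in range(0, idx_i.size, chunk):
        ii = idx_i[start : start + chunk]
        comp = time[ii][:, None] < time[None, :]  # T_i < T_j
        conc = (scores[ii][:, None] > scores[None, :]) * 1.0
        conc += 0.5 * (scores[ii][:, None] == scores[None, :])
        wi = w[ii][:, None]
        num_ij = wi * comp * conc
        den_ij = wi * comp
        row_num[ii] += num_ij.sum(axis=1)
        row_den[ii] += den_ij.sum(axis=1)
        col_num += num_ij.sum(axis=0)
        col_den += den_ij.sum(axis=0)
    num, den = row_num.sum(), row_den.sum()
    if den == 0:
        raise ValueError("no comparable pairs before tau")
    c = num / den
    # jackknife over subjects: remove row and column contributions of k
    num_k = num - row_num - col_num
    den_k = den - row_den - col_den
    with np.errstate(invalid="ignore", divide="ignore"):
        c_k = np.where(den_k > 0, num_k / den_k, c)
    se = float(np.sqrt((n - 1) / n * np.sum((c_k - c_k.mean()) ** 2)))
    return ConcordanceResult(c_index=float(c), se=se, tau=float(tau), n_pairs=float(den))


@dataclass
class CalibrationTable:
    """Mean predicted mortality probability vs KM observed rate per group."""

    table: pd.DataFrame  # columns: group, n, mean_predicted, observed, observed_se
    horizon: float
    n_groups: int

    def __str__(self) -> str:
        return (
            f"Calibration at {self.horizon}-year horizon "
            f"({self.n_groups} groups)\n{self.table.to_string(index=False)}"
        )


def predicted_mortality(table, bioage_hat, horizon: float, stratum=None) -> np.ndarray:
    """Life-table X-year mortality probability at each predicted bioage.

    q_i = 1 - S_pop(b_i + horizon) / S_pop(b_i).
    """
    b = np.asarray(bioage_hat, dtype=float)
    if isinstance(table, dict):
        if stratum is None:
            raise ValueError("stratified tables require a stratum per subject")
        out = np.empty(b.shape)
        for label in np.unique(stratum):
            m = stratum == label
            out[m] = predicted_mortality(table[label], b[m], horizon)
        return out
    s_now = table.survival_at(b)
    s_then = table.survival_at(np.minimum(b + horizon, table.t_max))
    return 1.0 - s_then / s_now


def calibration(
    preds, table, data: SurvivalData, horizon: float = 5.0, n_groups: int = 5
) -> CalibrationTable:
    """Life-table calibration of biological age predictions.

    Subjects are placed in ``n_groups`` equally sized groups (sizes differ
    by at most one) by their predicted ``horizon``-year mortality
    probability from the reference table; the observed rate per group is
    the Kaplan-Meier complement at the horizon on time-on-study, which is
    unbiased under censoring within the horizon where a raw fraction is
    not.
    """
    from lifelines import KaplanMeierFitter

    bio = preds.bioage_hat if hasattr(preds, "bioage_hat") else np.asarray(preds, dtype=float)
    keep = np.isfinite(bio)
    if not keep.all():
        warnings.warn(f"excluding {int((~keep).sum())} flagged prediction(s)", stacklevel=2)
    bio = bio[keep]
    sub = data.subset(keep)
    q = predicted_mortality(table, bio, horizon, stratum=sub.stratum)
    order = np.argsort(q, kind="stable")
    rows = []
    for gidx, members in enumerate(np.array_split(order, n_groups)):
        if members.size == 0:
            continue
        tg = sub.time_on_study[members]
        sg = sub.status[members]
        if horizon == 0:
            observed, ose = 0.0, 0.0
        elif np.all((sg == 0) & (tg < horizon)):
            warnings.warn(f"group {gidx + 1}: all subjects censored before the horizon",
                          stacklevel=2)
            observed, ose = np.nan, np.nan
        else:
            kmf = KaplanMeierFitter()
            kmf.fit(tg, event_observed=sg)
            observed = 1.0 - float(kmf.survival_function_at_times(horizon).iloc[0])
            try:
                ci = kmf.confidence_interval_survival_function_
                lo = np.interp(horizon, ci.index.to_numpy(), ci.iloc[:, 0].to_numpy())
                hi = np.interp(horizon, ci.index.to_numpy(), ci.iloc[:, 1].to_numpy())
                ose = float((hi - lo) / (2 * 1.96))
            except Exception:
                ose = np.nan
        rows.append(
            {
                "group": gidx + 1,
                "n": int(members.size),
                "mean_predicted": float(q[members].mean()),
                "observed": observed,
                "observed_se": ose,
            }
        )
    return CalibrationTable(table=pd.DataFrame(rows), horizon=horizon, n_groups=n_groups)


def delta_association(data: SurvivalData, delta, adjust_stratum: bool = True) -> dict:
    """Hazard ratio per SD of age acceleration, adjusted for age (and stratum).

    Fits a Cox PH model on time-on-study with covariates [delta / SD(delta),
    entry age, stratum dummies] and reports exp(coef) for the delta term
    with a 95% Wald interval. Rescaling delta by any positive constant
    leaves the result unchanged.
    """
    delta = np.asarray(delta, dtype=float)
    keep = np.isfinite(delta)
    sub = data.subset(keep)
    delta = delta[keep]
    sd = np.std(delta, ddof=1)
    if sd <= 0:
        raise ValueError("delta has zero variance")
    df = pd.DataFrame({"delta_std": delta / sd, "entry_age": sub.entry_age})
    if adjust_stratum and sub.stratum is not None:
        dummies = pd.get_dummies(pd.Series(sub.stratum), drop_first=True, dtype=float)
        for cname in dummies.columns:
            df[f"stratum_{cname}"] = dummies[cname].to_numpy()
    adj = df.drop(columns="delta_std").to_numpy()
    X = np.column_stack([np.ones(len(df)), adj])
    resid = df["delta_std"].to_numpy() - X @ np.linalg.lstsq(X, df["delta_std"].to_numpy(), rcond=None)[0]
    if np.var(resid) < 1e-10:
        raise ValueError("delta is collinear with the adjusters")
    df["duration"] = sub.time_on_study
    df["status"] = sub.status
    from lifelines import CoxPHFitter

    cph = CoxPHFitter()
    cph.fit(df, duration_col="duration", event_col="status")
    coef = float(cph.params_["delta_std"])
    se = float(cph.standard_errors_["delta_std"])
    return {
        "hr": float(np.exp(coef)),
        "ci_low": float(np.exp(coef - 1.96 * se)),
        "ci_high": float(np.exp(coef + 1.96 * se)),
        "p": float(cph.summary.loc["delta_std", "p"]),
        "coef": coef,
        "se": se,
    }
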