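"""Reference life tables and residual-life computations.

A :class:`LifeTable` tabulates population survival ``S_pop(t)`` on a regular
age grid. It is the reference object of the second step of residual-life
based biological age prediction: an individual's model-predicted residual
life is looked up in the table to find the chronological age in the
reference population with the same (mean or median) residual life.

Tables can be built from a parametric mortality law (baseline or
marginalized over a normally distributed linear predictor), estimated from
cohort data by Kaplan-Meier with delayed entry, or read from national
statistics style files (survival, lx or qx columns).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import cumulative_trapezoid

from .distributions import BaselineParams, CovariateEffect

__all__ = [
    "LifeTable",
    "build_from_parametric",
    "build_from_data",
    "read_lifetable",
    "write_lifetable",
]

DEFAULT_GRID = (0.0, 120.0, 0.05)

# relative survival mass allowed beyond the grid end when computing mean
# residual life
MEAN_TAIL_TOL = 1e-6


class InsufficientTailSupportError(ValueError):
    """Survival does not drop far enough before the end of support."""


class NotInvertibleError(ValueError):
    """Residual life is constant over the table; no unique age matches."""


def _make_grid(grid_spec=None) -> np.ndarray:
    lo, hi, step = grid_spec if grid_spec is not None else DEFAULT_GRID
    if step <= 0:
        raise ValueError("grid step must be positive")
    n = int(round((hi - lo) / step))
    return lo + step * np.arange(n + 1)


@dataclass
class LifeTable:
    """Population survival on a regular age grid.

    Parameters
    ----------
    ages : ndarray
        Strictly increasing age grid with constant step, in years.
    survival : ndarray
        Population survival probability at each grid age; ``survival[0]``
        is normalized to 1.
    stratum : str, optional
        Label when the table describes one stratum (e.g. a sex).
    provenance : str
        One of ``parametric``, ``empirical``, ``file``.
    """

    ages: np.ndarray
    survival: np.ndarray
    stratum: str | None = None
    provenance: str = "parametric"
    _rl_cache: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        ages = np.asarray(self.ages, dtype=float)
        surv = np.asarray(self.survival, dtype=float)
        if ages.ndim != 1 or ages.shape != surv.shape or ages.size < 2:
            raise ValueError("ages and survival must be matching 1-d arrays")
        steps = np.diff(ages)
        if np.any(steps <= 0) or not np.allclose(steps, steps[0], rtol=1e-6):
            raise ValueError("ages must be strictly increasing with constant step")
        if np.any(np.diff(surv) > 1e-9):
            raise ValueError("survival must be nonincreasing")
        if surv[0] <= 0:
            raise ValueError("survival at the first age must be positive")
        surv = np.minimum.accumulate(surv / surv[0])  # normalize, clip tiny wiggles
        self.ages = ages
        self.survival = surv

    @property
    def step(self) -> float:
        return float(self.ages[1] - self.ages[0])

    @property
    def t_max(self) -> float:
        return float(self.ages[-1])

    def survival_at(self, t):
        """Linearly interpolated survival at age(s) ``t`` within the grid."""
        t = np.asarray(t, dtype=float)
        if np.any(t < self.ages[0]) or np.any(t > self.t_max):
            raise ValueError("age outside the tabulated grid")
        return np.interp(t, self.ages, self.survival)

    # -- residual life ----------------------------------------------------

    def residual_life_curve(self, kind: str = "median") -> np.ndarray:
        """Residual life at every grid age (NaN where undefined)."""
        if kind not in self._rl_cache:
            self._rl_cache[kind] = _residual_life_grid(self.ages, self.survival, kind)
        return self._rl_cache[kind]

    def residual_life(self, t, kind: str = "median"):
        """Mean or median residual life at age ``t``, in years.

        mean:   mrl(t) = int_t^tmax S(u) du / S(t)  (trapezoidal rule)
        median: medrl(t) = t_med - t with S(t_med) = S(t)/2.
        """
        scalar = np.isscalar(t)
        t = np.atleast_1d(np.asarray(t, dtype=float))
        st = self.survival_at(t)
        if np.any(st <= 0):
            raise InsufficientTailSupportError("survival is zero at a queried age")
        if kind == "mean":
            if np.any(self.survival[-1] > MEAN_TAIL_TOL * st):
                raise InsufficientTailSupportError(
                    "survival mass beyond the end of the table is non-negligible; "
                    "extend the grid or use the median"
                )
            total = cumulative_trapezoid(self.survival, self.ages, initial=0.0)
            cum_at_t = np.interp(t, self.ages, total)
            out = (total[-1] - cum_at_t) / st
        elif kind == "median":
            target = st / 2.0
            out = _interp_survival_crossing(self.ages, self.survival, target) - t
            if np.any(np.isnan(out)):
                raise InsufficientTailSupportError(
                    "survival never reaches half its value at a queried age "
                    "before the end of the table"
                )
        else:
            raise ValueError(f"kind must be 'mean' or 'median', got {kind!r}")
        return float(out[0]) if scalar else out

    def invert_residual_life(self, value, kind: str = "median", out_of_range: str = "raise"):
        """Age whose residual life equals ``value`` (biological age).

        Returns the first downward crossing of the tabulated residual-life
        curve, refined by linear interpolation between grid ages. Values
        outside the curve's range raise (or become NaN with
        ``out_of_range="nan"``); a flat curve (exponential law) raises
        :class:`NotInvertibleError`.
        """
        scalar = np.isscalar(value)
        value = np.atleast_1d(np.asarray(value, dtype=float))
        if out_of_range == "raise" and np.any(value <= 0):
            raise ValueError("residual life must be positive")
        curve = self.residual_life_curve(kind)
        valid = ~np.isnan(curve)
        ages = self.ages[valid]
        curve = curve[valid]
        if curve.size < 2:
            raise InsufficientTailSupportError("residual life undefined on the grid")
        if np.nanmax(curve) - np.nanmin(curve) < 1e-9:
            raise NotInvertibleError(
                "residual life is constant over the table (memoryless law); "
                "no unique age corresponds to a residual-life value"
            )
        # first downward crossing: use the running minimum so that any local
        # wiggle at the ragged tail cannot produce a second, later solution
        rmin = np.minimum.accumulate(curve)
        bad = (value > curve[0]) | (value < rmin[-1]) | ~np.isfinite(value) | (value <= 0)
        if np.any(bad):
            if out_of_range == "raise":
                raise ValueError(
                    f"residual-life value(s) {value[bad]} outside the invertible range "
                    f"[{rmin[-1]:.3f}, {curve[0]:.3f}] years"
                )
            if out_of_range == "clip":
                clippable = np.isfinite(value)
                value = np.clip(value, rmin[-1], curve[0], where=clippable, out=value.copy())
                bad = bad & ~clippable
            else:
                value = np.where(bad, rmin[-1], value)  # placeholder; masked below
        idx = np.searchsorted(-rmin, -value, side="left")
        idx = np.clip(idx, 1, rmin.size - 1)
        lo, hi = curve[idx - 1], curve[idx]
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = np.where(lo > hi, (lo - value) / (lo - hi), 0.0)
        frac = np.clip(frac, 0.0, 1.0)
        out = ages[idx - 1] + frac * (ages[idx] - ages[idx - 1])
        exact = value >= curve[0]
        out = np.where(exact, ages[0], out)
        out = np.where(bad, np.nan, out)
        return float(out[0]) if scalar else out


def _interp_survival_crossing(ages, survival, target):
    """Earliest age where survival drops to ``target`` (linear interpolation).

    ``target`` may be an array; NaN where the curve never reaches it.
    """
    target = np.atleast_1d(np.asarray(target, dtype=float))
    idx = np.searchsorted(-survival, -target, side="left")
    out = np.full(target.shape, np.nan)
    ok = idx < survival.size
    idx_ok = np.clip(idx[ok], 1, survival.size - 1)
    lo = survival[idx_ok - 1]
    hi = survival[idx_ok]
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(lo > hi, (lo - target[ok]) / (lo - hi), 1.0)
    frac = np.clip(frac, 0.0, 1.0)
    out[ok] = ages[idx_ok - 1] + frac * (ages[idx_ok] - ages[idx_ok - 1])
    # exact hit at or before the first grid point
    at_start = ok & (target >= survival[0])
    out[at_start] = ages[0]
    return out


def _residual_life_grid(ages, survival, kind):
    if kind == "mean":
        total = cumulative_trapezoid(survival, ages, initial=0.0)
        with np.errstate(invalid="ignore", divide="ignore"):
            out = (total[-1] - total) / survival
        # undefined where the tail beyond the grid still matters
        bad = survival[-1] > MEAN_TAIL_TOL * survival
        out[bad | (survival <= 0)] = np.nan
        return out
    if kind == "median":
        target = survival / 2.0
        t_med = _interp_survival_crossing(ages, survival, target)
        return t_med - ages
    raise ValueError(f"kind must be 'mean' or 'median', got {kind!r}")


# -- construction ---------------------------------------------------------


def build_from_parametric(
    params: BaselineParams,
    effect: CovariateEffect | None = None,
    marker_sd_linear_predictor: float = 0.0,
    mode: str = "baseline",
    grid=None,
    stratum: str | None = None,
    n_quad: int = 80,
) -> LifeTable:
    """Life table from a parametric mortality law.

    ``mode="baseline"`` tabulates the baseline survival ``S0(t)``.
    ``mode="marginal"`` tabulates ``E_Z[S(t | lp = Z)]`` for a normal linear
    predictor ``Z ~ N(0, sigma_lp^2)``, integrated by Gauss-Hermite
    quadrature; independent normal markers enter only through ``beta @ X``,
    which is itself univariate normal.
    """
    ages = _make_grid(grid)
    if mode == "baseline":
        surv = params.survival(ages)
    elif mode == "marginal":
        if effect is None:
            raise ValueError("mode='marginal' requires a covariate effect")
        sigma = float(marker_sd_linear_predictor)
        if sigma < 0:
            raise ValueError("linear-predictor SD must be nonnegative")
        if sigma == 0:
            surv = params.survival(ages)
        else:
            nodes, weights = np.polynomial.hermite.hermgauss(n_quad)
            lp = np.sqrt(2.0) * sigma * nodes  # N(0, sigma^2) change of variables
            w = weights / np.sqrt(np.pi)
            theta = np.exp(lp)
            h0 = params.cumulative_hazard
            if effect.assumption == "PH":
                logs = -np.outer(h0(ages), theta)
            else:
                # S(theta * t) on an ages x nodes grid
                logs = -h0(np.outer(ages, theta))
            surv = np.exp(logs) @ w
    else:
        raise ValueError(f"mode must be 'baseline' or 'marginal', got {mode!r}")
    return LifeTable(ages=ages, survival=surv, stratum=stratum, provenance="parametric")


def build_from_data(data, grid=None, stratum: str | None = None) -> LifeTable:
    """Kaplan-Meier life table from a left-truncated cohort.

    Subjects enter the risk set at their entry age (delayed entry); the
    estimated curve is interpolated onto the regular grid, with survival
    fixed at 1 below the earliest entry age.
    """
    from lifelines import KaplanMeierFitter

    if len(data) == 0:
        raise ValueError("dataset is empty")
    if data.status.sum() == 0:
        raise ValueError("no events in the dataset; survival cannot be estimated")
    kmf = KaplanMeierFitter()
    kmf.fit(data.exit_age, event_observed=data.status, entry=data.entry_age)
    ages = _make_grid(grid)
    km_ages = kmf.survival_function_.index.to_numpy(dtype=float)
    km_surv = kmf.survival_function_.iloc[:, 0].to_numpy(dtype=float)
    # step function: survival at t is the value at the last event age <= t
    idx = np.searchsorted(km_ages, ages, side="right") - 1
    surv = np.where(idx >= 0, km_surv[np.maximum(idx, 0)], 1.0)
    surv[ages < data.entry_age.min()] = 1.0
    if km_surv[-1] > 0.5 * km_surv[0]:
        warnings.warn(
            "estimated survival never reaches half its initial value within the "
            "observed age range; median residual life will be undefined at most ages",
            stacklevel=2,
        )
    return LifeTable(ages=ages, survival=surv, stratum=stratum, provenance="empirical")


def extend_tail_gompertz(table: LifeTable, fit_years: float = 15.0) -> LifeTable:
    """Extend an empirical table's ragged tail with a fitted Gompertz law.

    A Gompertz cumulative hazard is fitted (log-linear least squares) on the
    last ``fit_years`` of informative support and used to extrapolate to the
    end of the grid. Off by default everywhere: silent extrapolation can hide
    that the data do not cover the tail.
    """
    surv = table.survival.copy()
    ages = table.ages
    decreasing = np.diff(surv) < -1e-12
    if not decreasing.any():
        raise ValueError("table has no informative support to fit a tail")
    last = ages[1:][decreasing][-1]
    window = (ages <= last) & (ages >= last - fit_years) & (surv > 0)
    h = -np.log(surv[window])
    t = ages[window]
    keep = h > 0
    if keep.sum() < 3:
        raise ValueError("too few informative grid points to fit a Gompertz tail")
    # log H0(t) ~ log(a/b) + b t for bt >> 0
    coef = np.polyfit(t[keep], np.log(h[keep]), 1)
    b, log_ab = coef[0], coef[1]
    if b <= 0:
        raise ValueError("fitted tail hazard is not increasing; refusing to extrapolate")
    beyond = ages > last
    surv[beyond] = np.exp(-np.exp(log_ab + b * ages[beyond]))
    surv = np.minimum.accumulate(surv)
    return LifeTable(ages=ages, survival=surv, stratum=table.stratum, provenance=table.provenance)


# -- file I/O -------------------------------------------------------------


def read_lifetable(path, dialect: str = "survival", stratum_col: str | None = None, grid=None):
    """Read a life table from delimited text.

    ``dialect`` selects the survival column convention:

    - ``survival``: a column named ``survival`` with S(t) directly;
    - ``lx``: national-statistics style number-alive column, normalized by lx[0];
    - ``qx``: per-interval death probability, accumulated as S = prod(1 - qx).

    Files with a stratum column yield a dict mapping stratum label to table.
    """
    df = pd.read_csv(path)
    if "age" not in df.columns:
        raise ValueError(f"{path}: missing required 'age' column")
    if dialect not in ("survival", "lx", "qx"):
        raise ValueError(f"unknown dialect {dialect!r}")
    if dialect not in df.columns:
        raise ValueError(f"{path}: missing required {dialect!r} column")
    if stratum_col is not None:
        out = {}
        for label, sub in df.groupby(stratum_col, sort=True):
            out[label] = _table_from_frame(sub, dialect, str(path), grid, stratum=str(label))
        return out
    return _table_from_frame(df, dialect, str(path), grid)


def _table_from_frame(df, dialect, path, grid, stratum=None):
    ages = df["age"].to_numpy(dtype=float)
    if np.any(np.diff(ages) <= 0):
        bad = int(np.argmax(np.diff(ages) <= 0)) + 2
        raise ValueError(f"{path}: ages not strictly increasing at data line {bad}")
    col = df[dialect].to_numpy(dtype=float)
    if dialect == "survival":
        surv = col
    elif dialect == "lx":
        if col[0] <= 0:
            raise ValueError(f"{path}: lx at the first age must be positive")
        surv = col / col[0]
    else:  # qx: survival to age k is the product of (1 - qx) below k
        if np.any((col < 0) | (col > 1)):
            raise ValueError(f"{path}: qx values must lie in [0, 1]")
        surv = np.concatenate([[1.0], np.cumprod(1.0 - col[:-1])])
    inc = np.diff(surv) > 1e-9
    if np.any(inc):
        bad = int(np.argmax(inc)) + 2
        raise ValueError(f"{path}: survival increases at data line {bad}")
    grid_ages = _make_grid(grid if grid is not None else (ages[0], ages[-1], _infer_step(ages)))
    surv_i = np.interp(grid_ages, ages, surv)
    return LifeTable(ages=grid_ages, survival=surv_i, stratum=stratum, provenance="file")


def _infer_step(ages):
    steps = np.diff(ages)
    return float(steps[0]) if np.allclose(steps, steps[0]) else float(np.min(steps))


def write_lifetable(table, path) -> None:
    """Write a table (or dict of stratified tables) in the survival dialect."""
    if isinstance(table, dict):
        frames = [
            pd.DataFrame({"age": t.ages, "survival": t.survival, "stratum": label})
            for label, t in sorted(table.items())
        ]
        pd.concat(frames, ignore_index=True).to_csv(path, index=False, float_format="%.12g")
        return
    pd.DataFrame({"age": table.ages, "survival": table.survival}).to_csv(
        path, index=False, float_format="%.12g"
    )
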