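"""Prospective-cohort simulator with known true biological age.

Emulates the design of the cohorts used to train mortality-based
biological age clocks: markers are drawn at birth and held constant over
life, subjects enter the study at a uniform random chronological age,
ages-at-death follow a Gompertz or Weibull law under a PH or AFT covariate
mechanism, subjects who died before their entry age are discarded (left
truncation — people who have already died cannot be enrolled), and
follow-up is administratively censored after a fixed number of years.

Because the generating law is known, every retained subject also carries
their *true* biological age: the age in the (marginal) true population
life table whose residual life matches the subject's analytic conditional
residual life at entry.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .data import SurvivalData
from .distributions import (
    BaselineParams,
    CovariateEffect,
    GompertzParams,
    WeibullParams,
)
from .lifetable import LifeTable, build_from_parametric

__all__ = ["SimConfig", "SimulatedCohort", "draw_event_time", "draw_cohort", "true_bioage"]

MECHANISMS = ("gompertz_ph", "gompertz_aft", "weibull_ph", "weibull_aft")

_DEFAULT_BETA = {
    "gompertz_ph": (0.3, 0.3),
    "gompertz_aft": (0.05, 0.05),
    "weibull_ph": (0.35, 0.35),
    # the Weibull law is simultaneously PH and AFT: beta_AFT = beta_PH / nu
    "weibull_aft": (0.35 / 8.0, 0.35 / 8.0),
}


@dataclass(frozen=True)
class SimConfig:
    """Data-generating configuration.

    Defaults reproduce the study conditions used throughout the test
    suite: Gompertz baseline a = exp(-9), b = 0.085 (adult human
    mortality), Weibull rate lam = 34**-10 with shape nu = 8 (median
    lifespan near 78 y), standard-normal markers, uniform entry ages
    20-80, 20-year administrative censoring.
    """

    mechanism: str = "gompertz_aft"
    n_obs: int = 5000
    a: float = float(np.exp(-9.0))
    b: float = 0.085
    lam: float = 34.0**-10
    nu: float = 8.0
    beta: tuple = None  # per-mechanism default applied in __post_init__
    sigma1: float = 1.0
    sigma2: float = 1.0
    c_min: float = 20.0
    c_max: float = 80.0
    followup_years: float = 20.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mechanism not in MECHANISMS:
            raise ValueError(f"mechanism must be one of {MECHANISMS}, got {self.mechanism!r}")
        if self.n_obs <= 0:
            raise ValueError("n_obs must be positive")
        if not self.c_min < self.c_max:
            raise ValueError("need c_min < c_max")
        if self.followup_years <= 0:
            raise ValueError("followup_years must be positive")
        if self.beta is None:
            object.__setattr__(self, "beta", _DEFAULT_BETA[self.mechanism])
        object.__setattr__(self, "beta", tuple(float(x) for x in self.beta))

    @property
    def baseline(self) -> BaselineParams:
        if self.mechanism.startswith("gompertz"):
            return GompertzParams(a=self.a, b=self.b)
        return WeibullParams(lam=self.lam, nu=self.nu)

    @property
    def assumption(self) -> str:
        return "PH" if self.mechanism.endswith("_ph") else "AFT"

    @property
    def effect(self) -> CovariateEffect:
        return CovariateEffect(beta=np.asarray(self.beta), assumption=self.assumption)

    @property
    def lp_sd(self) -> float:
        """SD of the linear predictor beta @ X over the marker law at birth."""
        b1, b2 = self.beta
        return float(np.sqrt((b1 * self.sigma1) ** 2 + (b2 * self.sigma2) ** 2))

    def with_seed(self, seed: int) -> "SimConfig":
        return replace(self, seed=int(seed))


@dataclass
class SimulatedCohort:
    """Observed cohort plus the latent truth the simulator knows."""

    data: SurvivalData
    death_age: np.ndarray  # uncensored age-at-death T of retained subjects
    linear_predictor: np.ndarray
    attrition: int  # draws discarded because T < C
    config: SimConfig
    true_b: np.ndarray | None = field(default=None)

    def __len__(self) -> int:
        return len(self.data)

    @property
    def censoring_fraction(self) -> float:
        return 1.0 - self.data.status.mean()


def draw_event_time(config: SimConfig, x, u):
    """Age-at-death by inverse-cumulative-hazard sampling.

    PH:  t = H0^{-1}(-log U / exp(beta @ x))
    AFT: t = H0^{-1}(-log U) / exp(beta @ x)

    Deterministic given (x, u); ``u`` must lie strictly in (0, 1).
    """
    u = np.asarray(u, dtype=float)
    if np.any((u <= 0) | (u >= 1)):
        raise ValueError("uniform draws must lie strictly in (0, 1)")
    theta = config.effect.theta(x)
    base = config.baseline
    if config.assumption == "PH":
        return base.inverse_cumulative_hazard(-np.log(u) / theta)
    return base.inverse_cumulative_hazard(-np.log(u)) / theta


def draw_cohort(config: SimConfig, max_draw_factor: int = 1000) -> SimulatedCohort:
    """Draw a cohort of ``n_obs`` retained (post-truncation) subjects.

    Draws (X, C, U) triples in batches, discards draws with T < C, and
    keeps exactly the first ``n_obs`` retained subjects of the stream, so
    the result is fully reproducible from the seed. Administrative
    censoring after ``followup_years`` sets status 0 and exit = C +
    followup. Aborts if the retention probability is vanishingly small.
    """
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    n = config.n_obs
    kept: list = []
    attrition = 0
    total_drawn = 0
    n_kept = 0
    while n_kept < n:
        m = max(2 * (n - n_kept), 1000)
        total_drawn += m
        if total_drawn > max_draw_factor * n:
            raise RuntimeError(
                "retention probability appears vanishingly small under this "
                "configuration; aborting after the draw budget"
            )
        x = np.column_stack(
            [rng.normal(0.0, config.sigma1, m), rng.normal(0.0, config.sigma2, m)]
        )
        c = rng.uniform(config.c_min, config.c_max, m)
        u = rng.uniform(0.0, 1.0, m)
        # u = 0 or 1 occurs with probability 0 but guard the open interval
        u = np.clip(u, np.nextafter(0.0, 1.0), np.nextafter(1.0, 0.0))
        t = draw_event_time(config, x, u)
        keep = t > c
        n_batch = int(keep.sum())
        if n_kept + n_batch >= n:
            # trim to the draw that yields the n-th retained subject so the
            # attrition count refers to exactly the first n retained
            kth = np.flatnonzero(keep)[n - n_kept - 1]
            keep = keep[: kth + 1]
            x, c, t = x[: kth + 1], c[: kth + 1], t[: kth + 1]
        attrition += int((~keep).sum())
        kept.append((x[keep], c[keep], t[keep]))
        n_kept += int(keep.sum())
    x = np.concatenate([k[0] for k in kept])
    c = np.concatenate([k[1] for k in kept])
    t = np.concatenate([k[2] for k in kept])
    status = (t <= c + config.followup_years).astype(int)
    exit_age = np.where(status == 1, t, c + config.followup_years)
    data = SurvivalData(entry_age=c, exit_age=exit_age, status=status, markers=x)
    return SimulatedCohort(
        data=data,
        death_age=t,
        linear_predictor=config.effect.linear_predictor(x),
        attrition=attrition,
        config=config,
    )


def population_table(config: SimConfig, mode: str = "marginal", grid=(0.0, 140.0, 0.05)) -> LifeTable:
    """True-parameter population life table for the configured mechanism.

    ``marginal`` (default) integrates the conditional survival over the
    marker distribution at birth; ``baseline`` tabulates S0 directly. The
    grid runs to 140 y so that the residual life of even strongly
    accelerated late entrants stays inside the invertible range.
    """
    return build_from_parametric(
        config.baseline,
        effect=config.effect,
        marker_sd_linear_predictor=config.lp_sd,
        mode=mode,
        grid=grid,
    )


def true_residual_life(config: SimConfig, entry_age, x, kind: str = "median"):
    """Analytic conditional residual life under the true mechanism."""
    c = np.atleast_1d(np.asarray(entry_age, dtype=float))
    theta = np.atleast_1d(config.effect.theta(x))
    base = config.baseline
    if kind == "median":
        ln2 = np.log(2.0)
        if config.assumption == "PH":
            # theta * H0(t_med) = theta * H0(c) + log 2
            t_med = base.inverse_cumulative_hazard(base.cumulative_hazard(c) + ln2 / theta)
        else:
            # H0(theta t_med) = H0(theta c) + log 2
            t_med = base.inverse_cumulative_hazard(
                base.cumulative_hazard(theta * c) + ln2
            ) / theta
        return t_med - c
    if kind == "mean":
        u = np.linspace(0.0, 140.0, 2801)
        tt = c[:, None] + u[None, :]
        if config.assumption == "PH":
            logs = -theta[:, None] * (base.cumulative_hazard(tt) - base.cumulative_hazard(c)[:, None])
        else:
            logs = -(
                base.cumulative_hazard(theta[:, None] * tt)
                - base.cumulative_hazard(theta * c)[:, None]
            )
        return np.trapezoid(np.exp(logs), u, axis=1)
    raise ValueError(f"kind must be 'mean' or 'median', got {kind!r}")


def true_bioage(
    cohort: SimulatedCohort,
    table: LifeTable | None = None,
    kind: str = "median",
    mode: str = "marginal",
    out_of_range: str = "clip",
) -> np.ndarray:
    """True biological age of every retained subject.

    Computes the analytic conditional residual life at entry under the
    true mechanism and inverts it in the true-population life table
    (marginal over the markers by default). A handful of extreme subjects
    per million can have residual life outside the table's range (e.g. a
    strongly decelerated ager whose remaining life exceeds a newborn's);
    their truth saturates at the table bounds by default
    (``out_of_range="clip"``) so every retained subject has a finite B.
    The result is stored on the cohort and returned.
    """
    config = cohort.config
    if table is None:
        table = population_table(config, mode=mode)
    rl = true_residual_life(config, cohort.data.entry_age, cohort.data.markers, kind=kind)
    b = table.invert_residual_life(rl, kind=kind, out_of_range=out_of_range)
    cohort.true_b = np.atleast_1d(b)
    return cohort.true_b
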