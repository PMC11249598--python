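"""Simulation-study orchestration: mechanisms x sample sizes x predictors.

For every replicate a training cohort and an independent test cohort are
drawn under the chosen mechanism; each predictor is fitted on the
training data and evaluated by the RMSE of its biological age
predictions against the simulator's known truth on the test cohort.
Residual-life based predictors translate through the true-mechanism
marginal life table, which isolates model-fit error from life-table
estimation error; the GrimAge-type comparator needs no table. Failed
fits are excluded from the cell average and counted, never imputed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .bioage import predict_bioage, predict_grimage
from .lifetable import InsufficientTailSupportError
from .metrics import rmse
from .models import CoxAge, FitFailureError, GompertzAFT, GrimAgeModel
from .simulate import SimConfig, draw_cohort, population_table, true_bioage

__all__ = ["ExperimentGrid", "ExperimentResult", "run_experiment"]

PREDICTORS = ("accelerage_gompertz", "ph_semipar", "grimage_type")


@dataclass(frozen=True)
class ExperimentGrid:
    """Grid of simulation-study cells.

    The replicate seed scheme is a documented counter: the stream for
    (mechanism m, replicate r) uses SeedSequence((root_seed, m_index, r,
    role)) with role 0 for training and 1 for test data, so every cell is
    independently reproducible and test cohorts are shared across sample
    sizes within a replicate.
    """

    mechanisms: tuple = ("gompertz_aft",)
    n_obs_list: tuple = (5000,)
    predictors: tuple = PREDICTORS
    n_sim: int = 20
    n_test: int = 5000
    root_seed: int = 0
    kind: str = "median"

    def __post_init__(self):
        object.__setattr__(self, "mechanisms", tuple(self.mechanisms))
        object.__setattr__(self, "n_obs_list", tuple(int(n) for n in self.n_obs_list))
        object.__setattr__(self, "predictors", tuple(self.predictors))
        for p in self.predictors:
            if p not in PREDICTORS:
                raise ValueError(f"unknown predictor {p!r}")
        if self.n_sim <= 0 or self.n_test <= 0 or not self.n_obs_list:
            raise ValueError("all counts must be positive")


@dataclass
class ExperimentResult:
    """Per-cell mean RMSE with replicate SD and failed-fit counts."""

    table: pd.DataFrame
    grid: ExperimentGrid
    per_replicate: pd.DataFrame = field(default=None, repr=False)

    def cell(self, mechanism: str, n_obs: int, predictor: str) -> pd.Series:
        t = self.table
        m = (
            (t.mechanism == mechanism) & (t.n_obs == n_obs) & (t.predictor == predictor)
        )
        if not m.any():
            raise KeyError((mechanism, n_obs, predictor))
        return t[m].iloc[0]

    def write(self, path) -> None:
        self.table.to_csv(path, index=False, float_format="%.8g")

    def plot(self, path=None):
        """RMSE versus training size, one panel per mechanism."""
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        mechs = self.table.mechanism.unique()
        fig, axes = plt.subplots(1, len(mechs), figsize=(4.5 * len(mechs), 3.6), squeeze=False)
        for ax, mech in zip(axes[0], mechs):
            sub = self.table[self.table.mechanism == mech]
            for pred, grp in sub.groupby("predictor"):
                grp = grp.sort_values("n_obs")
                ax.errorbar(grp.n_obs, grp.mean_rmse,
                            yerr=grp.sd_rmse / np.sqrt(grp.n_completed), marker="o", label=pred)
            ax.set_xlabel("training size $n_{obs}$")
            ax.set_ylabel("mean RMSE (years)")
            ax.set_title(mech)
            ax.legend(fontsize=8)
        fig.tight_layout()
        if path is not None:
            fig.savefig(path, dpi=150)
            plt.close(fig)
        return fig


def _fit_predictor(name: str, data):
    if name == "accelerage_gompertz":
        return GompertzAFT(data).fit()
    if name == "ph_semipar":
        return CoxAge(data).fit()
    if name == "grimage_type":
        return GrimAgeModel(data).fit()
    raise ValueError(name)


def _predict(name: str, fit, table, test_data, kind: str):
    if name == "grimage_type":
        return predict_grimage(fit, test_data)
    return predict_bioage(fit, table, test_data, kind=kind, missing="nan")


def run_experiment(grid: ExperimentGrid, progress: bool = False) -> ExperimentResult:
    """Run all cells of the grid; fully deterministic given the root seed."""
    rows = []
    per_rep = []
    for m_idx, mech in enumerate(grid.mechanisms):
        base_config = SimConfig(mechanism=mech, n_obs=grid.n_test)
        table = population_table(base_config, mode="marginal")
        for rep in range(grid.n_sim):
            test_cfg = SimConfig(
                mechanism=mech, n_obs=grid.n_test,
                seed=(grid.root_seed, m_idx, rep, 1),
            )
            test = draw_cohort(test_cfg)
            truth = true_bioage(test, table=table, kind=grid.kind)
            for n_obs in grid.n_obs_list:
                train_cfg = SimConfig(
                    mechanism=mech, n_obs=int(n_obs),
                    seed=(grid.root_seed, m_idx, rep, 0, int(n_obs)),
                )
                train = draw_cohort(train_cfg)
                for pred in grid.predictors:
                    try:
                        fit = _fit_predictor(pred, train.data)
                        preds = _predict(pred, fit, table, test.data, grid.kind)
                    except (FitFailureError, InsufficientTailSupportError) as exc:
                        per_rep.append(
                            {"mechanism": mech, "n_obs": n_obs, "predictor": pred,
                             "replicate": rep, "rmse": np.nan, "n_flagged": np.nan,
                             "failed": True, "error": str(exc)[:120]}
                        )
                        continue
                    ok = ~preds.flagged
                    value = rmse(preds.bioage_hat[ok], truth[ok])
                    per_rep.append(
                        {"mechanism": mech, "n_obs": n_obs, "predictor": pred,
                         "replicate": rep, "rmse": value,
                         "n_flagged": int(preds.n_flagged), "failed": False, "error": ""}
                    )
            if progress:
                print(f"[{mech}] replicate {rep + 1}/{grid.n_sim} done", flush=True)
    per_rep = pd.DataFrame(per_rep)
    rows = []
    for (mech, n_obs, pred), sub in per_rep.groupby(
        ["mechanism", "n_obs", "predictor"], sort=False
    ):
        done = sub[~sub.failed]
        rows.append(
            {
                "mechanism": mech,
                "n_obs": int(n_obs),
                "predictor": pred,
                "mean_rmse": float(done.rmse.mean()) if len(done) else np.nan,
                "sd_rmse": float(done.rmse.std(ddof=1)) if len(done) > 1 else np.nan,
                "n_completed": int(len(done)),
                "n_failed": int(sub.failed.sum()),
                "mean_flagged": float(done.n_flagged.mean()) if len(done) else np.nan,
            }
        )
    return ExperimentResult(table=pd.DataFrame(rows), grid=grid, per_replicate=per_rep)
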