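"""Two-step biological age prediction and the age-acceleration residual.

Step 1 takes a fitted survival model and produces each subject's
conditional residual life at their current (entry) age. Step 2 looks that
value up in a reference life table: the biological age ``b_hat`` is the
chronological age in the reference population with the same residual
life. The age acceleration ``delta`` is the residual of an ordinary
least-squares regression of ``b_hat`` on chronological age — the
age-independent part of the prediction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import SurvivalData
from .lifetable import LifeTable

__all__ = ["BioAgePredictions", "predict_bioage", "predict_grimage", "age_acceleration"]


@dataclass
class BioAgePredictions:
    """Per-subject biological age predictions with provenance metadata.

    Out-of-range life-table inversions are flagged (NaN bioage) and
    counted, never clipped to the table bounds: clipping would silently
    distort calibration.
    """

    entry_age: np.ndarray
    residual_life_hat: np.ndarray | None
    bioage_hat: np.ndarray
    delta: np.ndarray
    flagged: np.ndarray  # True where inversion was out of range
    predictor: str
    kind: str | None = None
    table_id: str | None = None
    metadata: dict = field(default_factory=dict)

    @property
    def n_flagged(self) -> int:
        return int(self.flagged.sum())

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame({"entry_age": self.entry_age})
        if self.residual_life_hat is not None:
            df["residual_life_hat"] = self.residual_life_hat
        df["bioage_hat"] = self.bioage_hat
        df["delta"] = self.delta
        df["flag"] = self.flagged.astype(int)
        return df

    def write(self, path) -> None:
        df = self.to_dataframe()
        df.insert(0, "id", np.arange(len(df)))
        df.to_csv(path, index=False, float_format="%.12g")


def _table_for(table, label):
    if isinstance(table, dict):
        if label is None:
            raise ValueError("stratified life tables require a stratum per subject")
        try:
            return table[label]
        except KeyError as exc:
            raise ValueError(f"no life table for stratum {label!r}") from exc
    return table


def predict_bioage(
    fit, table, data: SurvivalData, kind: str = "median", missing: str = "raise"
) -> BioAgePredictions:
    """Biological age for every subject via residual life and a life table.

    ``fit`` must expose ``predict_residual_life(entry_age, X, kind)`` (the
    Gompertz AFT and age-timescale Cox results both do). ``table`` may be a
    single :class:`LifeTable` or a dict of stratified tables keyed by the
    subjects' stratum labels. With ``missing="nan"``, subjects whose
    residual life is unsupported by the fit are flagged instead of raising.
    """
    rl = np.asarray(
        fit.predict_residual_life(data.entry_age, data.markers, kind=kind, missing=missing),
        dtype=float,
    )
    bio = np.empty(len(data))
    if isinstance(table, dict):
        if data.stratum is None:
            raise ValueError("stratified life tables require a stratum per subject")
        bio[:] = np.nan
        for label in np.unique(data.stratum):
            mask = data.stratum == label
            bio[mask] = _table_for(table, label).invert_residual_life(
                rl[mask], kind=kind, out_of_range="nan"
            )
        table_id = "stratified:" + ",".join(str(k) for k in sorted(table))
    else:
        bio = np.atleast_1d(table.invert_residual_life(rl, kind=kind, out_of_range="nan"))
        table_id = f"{table.provenance}:{table.stratum or 'all'}"
    flagged = ~np.isfinite(bio)
    delta = np.full(len(data), np.nan)
    ok = ~flagged
    if ok.sum() >= 3 and np.ptp(data.entry_age[ok]) > 0:
        delta[ok] = age_acceleration(bio[ok], data.entry_age[ok])
    return BioAgePredictions(
        entry_age=data.entry_age.copy(),
        residual_life_hat=rl,
        bioage_hat=bio,
        delta=delta,
        flagged=flagged,
        predictor=type(fit).__name__,
        kind=kind,
        table_id=table_id,
        metadata={"n_flagged": int(flagged.sum())},
    )


def predict_grimage(fit, data: SurvivalData) -> BioAgePredictions:
    """Biological age from a GrimAge-type fit (no life table involved).

    The prediction is the affine rescaling of the Cox linear predictor to
    the training set's chronological-age mean and SD; there is no defined
    translation to a residual-life value, so that field is left empty.
    """
    bio = fit.predict_bioage_values(data.entry_age, data.markers)
    flagged = ~np.isfinite(bio)
    delta = np.full(len(data), np.nan)
    ok = ~flagged
    if ok.sum() >= 3 and np.ptp(data.entry_age[ok]) > 0:
        delta[ok] = age_acceleration(bio[ok], data.entry_age[ok])
    return BioAgePredictions(
        entry_age=data.entry_age.copy(),
        residual_life_hat=None,
        bioage_hat=bio,
        delta=delta,
        flagged=flagged,
        predictor="GrimAgeResults",
        kind=None,
        table_id=None,
        metadata={"n_flagged": int(flagged.sum())},
    )


def age_acceleration(bioage_hat, entry_age) -> np.ndarray:
    """Age acceleration: OLS residuals of predicted bioage on chronological age.

    Any affine dependence of the prediction on chronological age is
    absorbed by the regression (intercept included), so delta is invariant
    to affine recalibration of the predictor in C.
    """
    b = np.asarray(bioage_hat, dtype=float)
    c = np.asarray(entry_age, dtype=float)
    if b.shape != c.shape:
        raise ValueError("bioage and entry-age vectors must have equal length")
    if b.size < 3:
        raise ValueError("need at least 3 subjects")
    if np.ptp(c) == 0:
        raise ValueError("chronological age is constant; regression undefined")
    X = np.column_stack([np.ones_like(c), c])
    coef, *_ = np.linalg.lstsq(X, b, rcond=None)
    return b - X @ coef
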