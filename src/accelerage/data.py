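"""Cohort data container for left-truncated, right-censored survival data.

All ages are in years. Each subject carries an entry age (chronological age
at study inclusion, the left-truncation time), an exit age (age at death or
censoring), an event indicator, a marker vector and an optional stratum
label (typically sex).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["SurvivalData", "read_cohort", "write_cohort"]


@dataclass
class SurvivalData:
    entry_age: np.ndarray
    exit_age: np.ndarray
    status: np.ndarray
    markers: np.ndarray  # n x p
    stratum: np.ndarray | None = None
    marker_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.entry_age = np.asarray(self.entry_age, dtype=float)
        self.exit_age = np.asarray(self.exit_age, dtype=float)
        self.status = np.asarray(self.status)
        self.markers = np.atleast_2d(np.asarray(self.markers, dtype=float))
        if self.markers.shape[0] != self.entry_age.shape[0] and self.markers.shape[1] == self.entry_age.shape[0]:
            self.markers = self.markers.T
        n = self.entry_age.shape[0]
        for name, arr in (("exit_age", self.exit_age), ("status", self.status)):
            if arr.shape[0] != n:
                raise ValueError(f"{name} has length {arr.shape[0]}, expected {n}")
        if self.markers.shape[0] != n:
            raise ValueError(f"markers have {self.markers.shape[0]} rows, expected {n}")
        bad = np.flatnonzero(self.exit_age <= self.entry_age)
        if bad.size:
            raise ValueError(f"exit_age <= entry_age at row(s) {bad[:10].tolist()}")
        if not np.isin(self.status, [0, 1]).all():
            bad = np.flatnonzero(~np.isin(self.status, [0, 1]))
            raise ValueError(f"status must be 0 or 1; bad row(s) {bad[:10].tolist()}")
        self.status = self.status.astype(int)
        if np.isnan(self.markers).any():
            bad = np.flatnonzero(np.isnan(self.markers).any(axis=1))
            raise ValueError(f"missing marker values at row(s) {bad[:10].tolist()}")
        if self.stratum is not None:
            self.stratum = np.asarray(self.stratum)
            if self.stratum.shape[0] != n:
                raise ValueError("stratum has wrong length")
        if not self.marker_names:
            self.marker_names = [f"x{i + 1}" for i in range(self.markers.shape[1])]

    def __len__(self) -> int:
        return self.entry_age.shape[0]

    @property
    def n_markers(self) -> int:
        return self.markers.shape[1]

    @property
    def n_events(self) -> int:
        return int(self.status.sum())

    @property
    def time_on_study(self) -> np.ndarray:
        """Follow-up duration, exit_age - entry_age (derived, never stored)."""
        return self.exit_age - self.entry_age

    def subset(self, mask) -> "SurvivalData":
        return SurvivalData(
            entry_age=self.entry_age[mask],
            exit_age=self.exit_age[mask],
            status=self.status[mask],
            markers=self.markers[mask],
            stratum=None if self.stratum is None else self.stratum[mask],
            marker_names=list(self.marker_names),
        )

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {"entry_age": self.entry_age, "exit_age": self.exit_age, "status": self.status}
        )
        for j, name in enumerate(self.marker_names):
            df[name] = self.markers[:, j]
        if self.stratum is not None:
            df["stratum"] = self.stratum
        return df

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "SurvivalData":
        required = ["entry_age", "exit_age", "status"]
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise ValueError(f"missing required column(s) {missing}")
        marker_cols = [
            c for c in df.columns if c not in required and c not in ("stratum", "id")
        ]
        if not marker_cols:
            raise ValueError("no marker columns found")
        return cls(
            entry_age=df["entry_age"].to_numpy(dtype=float),
            exit_age=df["exit_age"].to_numpy(dtype=float),
            status=df["status"].to_numpy(),
            markers=df[marker_cols].to_numpy(dtype=float),
            stratum=df["stratum"].to_numpy() if "stratum" in df.columns else None,
            marker_names=marker_cols,
        )


def read_cohort(path) -> SurvivalData:
    """Read a cohort CSV (columns entry_age, exit_age, status, x1..xp[, stratum])."""
    df = pd.read_csv(path)
    try:
        return SurvivalData.from_dataframe(df)
    except ValueError as exc:
        raise ValueError(f"{path}: {exc}") from exc


def write_cohort(data: SurvivalData, path) -> None:
    # %.17g keeps the writer -> reader round trip bit-exact for doubles
    data.to_dataframe().to_csv(path, index=False, float_format="%.17g")
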