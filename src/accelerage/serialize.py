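"""Save and load fitted predictors as structured text (YAML)."""

from __future__ import annotations

from types import SimpleNamespace

import numpy as np
import yaml

from .models import CoxAgeResults, GompertzAFTResults, GrimAgeResults

__all__ = ["save_model", "load_model"]


def save_model(results, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(results.to_dict(), fh, sort_keys=False)


def _stub_model(marker_names):
    # enough structure for summaries and predictions without the data
    return SimpleNamespace(data=SimpleNamespace(marker_names=list(marker_names)))


def load_model(path):
    """Reconstruct a Results object from a file written by save_model."""
    with open(path) as fh:
        d = yaml.safe_load(fh)
    kind = d.get("model")
    if kind == "gompertz_aft":
        params = np.concatenate(
            [[np.log(d["a_hat"]), np.log(d["b_hat"])], np.asarray(d["beta_hat"], dtype=float)]
        )
        return GompertzAFTResults(
            model=_stub_model(d["marker_names"]),
            params_internal=params,
            vcov_internal=np.asarray(d["vcov_internal"], dtype=float),
            llf=float(d["loglik"]),
            converged=bool(d["converged"]),
            niter=-1,
        )
    if kind == "cox_age":
        beta = np.asarray(d["beta_hat"], dtype=float)
        return CoxAgeResults(
            model=_stub_model(d["marker_names"]),
            beta_hat=beta,
            bse=np.full_like(beta, np.nan),
            vcov=np.full((beta.size, beta.size), np.nan),
            llf=float(d["loglik"]),
            breslow_ages=np.asarray(d["breslow_ages"], dtype=float),
            breslow_cumhaz=np.asarray(d["breslow_cumhaz"], dtype=float),
            support=tuple(d["support"]),
        )
    if kind == "grimage_type":
        beta = np.asarray(d["beta_hat"], dtype=float)
        return GrimAgeResults(
            model=_stub_model(d["marker_names"][1:]),
            beta_hat=beta,
            bse=np.full_like(beta, np.nan),
            llf=float(d["loglik"]),
            lp_mean=float(d["lp_mean"]),
            lp_sd=float(d["lp_sd"]),
            age_mean=float(d["age_mean"]),
            age_sd=float(d["age_sd"]),
        )
    raise ValueError(f"{path}: unknown model kind {kind!r}")
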