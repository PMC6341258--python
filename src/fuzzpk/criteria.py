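"""Statistical evaluation criteria of a fitted PopPK model.

Three criteria feed the fuzzy evaluation system:

* ``AIC = N*log(OFV) + 2*NP``
* ``SC  = N*log(OFV) + NP*log(NP)`` — note the penalty is NP*log NP, as
  published; the standard Schwarz penalty NP*log N is available behind an
  explicit option and never silently substituted.
* ``MSE = sum(residual^2) / (n - p)`` — the REML-flavoured error-variance
  estimator; ``p = 0`` gives the plain divide-by-n variance.

The objective function value (OFV) entering AIC/SC is a configuration
choice: ``"mse"`` (SSE/N, default), ``"sse"`` or ``"minus_two_loglik"``.
Logarithms are natural by default; the base is configurable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

#: OFV definitions accepted by :func:`FitSummary.ofv_value` and friends.
OFV_KINDS = ("mse", "sse", "minus_two_loglik")

#: Columns a criteria table must provide (extra columns are tolerated).
CRITERIA_COLUMNS = ("model_id", "aic", "cs", "mse")


def _log(x: float, base: float | None = None) -> float:
    return math.log(x) if base is None else math.log(x, base)


def aic(n_obs: int, ofv: float, n_params: int, base: float | None = None) -> float:
    """Akaike information criterion, N*log(OFV) + 2*NP."""
    if ofv <= 0:
        raise ValueError(f"AIC requires OFV > 0, got {ofv}")
    return n_obs * _log(ofv, base) + 2.0 * n_params


def sc(n_obs: int, ofv: float, n_params: int, base: float | None = None,
       penalty: str = "np_log_np") -> float:
    """Schwarz criterion, N*log(OFV) + NP*log(NP) as published.

    ``penalty="np_log_n"`` selects the textbook Schwarz/BIC penalty
    NP*log(N) instead.
    """
    if ofv <= 0:
        raise ValueError(f"SC requires OFV > 0, got {ofv}")
    if n_params < 1:
        raise ValueError(f"SC requires NP >= 1, got {n_params}")
    if penalty == "np_log_np":
        pen = n_params * _log(n_params, base)
    elif penalty == "np_log_n":
        pen = n_params * _log(n_obs, base)
    else:
        raise ValueError(f"unknown SC penalty {penalty!r}")
    return n_obs * _log(ofv, base) + pen


def mse_reml(residuals, n_params: int = 0) -> float:
    """Error-variance estimate sum(r^2)/(n - p); ``p=0`` is the plain variance."""
    r = np.asarray(residuals, dtype=float)
    n = r.size
    if n <= n_params:
        raise ValueError(
            f"error variance needs more residuals ({n}) than parameters ({n_params})")
    return float(np.sum(r * r) / (n - n_params))


@dataclass
class FitSummary:
    """Per-model fit statistics from which the three criteria are computed.

    ``ofv`` may be supplied directly (e.g. -2 log-likelihood from an
    estimation run); when absent it is derived from the residuals per the
    configured OFV kind.
    """

    n_obs: int
    n_params: int
    residuals: np.ndarray
    ofv: float | None = None

    def __post_init__(self) -> None:
        self.residuals = np.asarray(self.residuals, dtype=float)
        if self.n_obs <= 0 or self.n_params <= 0:
            raise ValueError("n_obs and n_params must be positive")
        if self.residuals.size != self.n_obs:
            raise ValueError(
                f"residual count {self.residuals.size} does not match n_obs {self.n_obs}")

    def sse(self) -> float:
        return float(np.sum(self.residuals ** 2))

    def ofv_value(self, kind: str = "mse") -> float:
        """OFV under the configured definition."""
        if kind not in OFV_KINDS:
            raise ValueError(f"unknown OFV kind {kind!r}")
        if kind == "minus_two_loglik":
            if self.ofv is None:
                raise ValueError("minus_two_loglik OFV requested but none was supplied")
            return self.ofv
        return self.sse() if kind == "sse" else self.sse() / self.n_obs

    def criteria(self, ofv_kind: str = "mse", base: float | None = None,
                 sc_penalty: str = "np_log_np") -> dict[str, float]:
        """The (aic, cs, mse) triple for this fit, plus the OFV used."""
        ofv = self.ofv_value(ofv_kind)
        return {
            "aic": aic(self.n_obs, ofv, self.n_params, base),
            "cs": sc(self.n_obs, ofv, self.n_params, base, sc_penalty),
            "mse": mse_reml(self.residuals, self.n_params),
            "ofv": ofv,
        }


def read_criteria_table(path) -> pd.DataFrame:
    """Read a per-model criteria CSV (columns model_id, aic, cs, mse, ...).

    Extra columns (n_params, covariates, ...) are carried through untouched.
    """
    df = pd.read_csv(path)
    df.columns = [c.strip().lower() for c in df.columns]
    missing = [c for c in CRITERIA_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"criteria table {path} is missing column(s) {missing}; "
                         f"found {list(df.columns)}")
    for c in ("aic", "cs", "mse"):
        df[c] = pd.to_numeric(df[c])
    return df
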