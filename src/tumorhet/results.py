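"""Results container for two-stage polytomous fits."""

from __future__ import annotations

import json

import numpy as np
import pandas as pd
from scipy import stats


def or_ci(log_or: float, se: float, level: float = 0.95):
    """Exponentiated Wald interval: (OR, lo, hi)."""
    if se <= 0:
        raise ValueError("se must be positive")
    z = stats.norm.ppf(0.5 + level / 2.0)
    return (float(np.exp(log_or)),
            float(np.exp(log_or - z * se)),
            float(np.exp(log_or + z * se)))


class TwoStageResults:
    """Estimates, covariance and diagnostics of a two-stage fit.

    Attributes
    ----------
    params : ParameterSet (alpha, theta, xi)
    cov_params : full parameter covariance from the observed information
    cov_theta : second-stage block of the covariance
    loglik : observed-data log-likelihood at the optimum
    converged, n_iter, method : convergence metadata
    """

    def __init__(self, model, params_vec, cov_params, loglik, n_iter,
                 converged, method, loglik_trace=None):
        self.model = model
        self.params_vec = params_vec
        self.params = model.unpack(params_vec)
        self.cov_params = cov_params
        self.loglik = loglik
        self.n_iter = n_iter
        self.converged = converged
        self.method = method
        self.loglik_trace = loglik_trace or []

    # -- second-stage quantities -----------------------------------------
    @property
    def theta(self) -> np.ndarray:
        return self.params.theta

    @property
    def cov_theta(self) -> np.ndarray:
        s = slice(self.model.Ma, self.model.Ma + self.model.p)
        return self.cov_params[s, s]

    @property
    def bse_theta(self) -> np.ndarray:
        return np.sqrt(np.maximum(np.diag(self.cov_theta), 0.0))

    @property
    def theta_labels(self):
        return self.model.design.labels

    def beta(self) -> np.ndarray:
        """Per-cell genotype log-ORs over all cells of the design.

        Cells supported only by dropped (case-free) design columns get the
        remaining columns' contribution, which is zero for indicator-type
        designs.
        """
        return self.model.design.matrix @ self.theta

    # -- tables ------------------------------------------------------------
    def theta_table(self) -> pd.DataFrame:
        se = self.bse_theta
        z = np.where(se > 0, self.theta / np.where(se > 0, se, 1.0), np.nan)
        p = 2.0 * stats.norm.sf(np.abs(z))
        return pd.DataFrame(
            {"estimate": self.theta, "se": se, "z": z, "p": p},
            index=list(self.theta_labels))

    def or_table(self, level: float = 0.95) -> pd.DataFrame:
        """Odds ratios with Wald CIs for each second-stage parameter."""
        rows = []
        for lab, est, se in zip(self.theta_labels, self.theta, self.bse_theta):
            if se > 0:
                o, lo, hi = or_ci(est, se, level)
                p = 2.0 * stats.norm.sf(abs(est / se))
            else:
                o, lo, hi, p = np.exp(est), np.nan, np.nan, np.nan
            rows.append({"category": lab, "log_or": est, "se": se,
                         "OR": o, "ci_lo": lo, "ci_hi": hi, "p": p})
        return pd.DataFrame(rows).set_index("category")

    def summary(self) -> str:
        head = (
            f"Two-stage polytomous regression ({self.method}), "
            f"design={self.model.design.kind}\n"
            f"n={self.model.status.shape[0]}  cells={self.model.Ma} active"
            f"/{self.model.A_full.shape[0]}  covariates={self.model.k}\n"
            f"loglik={self.loglik:.4f}  iter={self.n_iter}  "
            f"converged={self.converged}\n")
        tab = self.theta_table()
        return head + tab.to_string(float_format=lambda v: f"{v: .4f}") + "\n"

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "design": self.model.design.kind,
            "theta_labels": list(self.theta_labels),
            "theta": self.theta.tolist(),
            "cov_theta": self.cov_theta.tolist(),
            "alpha": self.params.alpha.tolist(),
            "xi": self.params.xi.tolist(),
            "active_cells": self.params.active_cells.tolist(),
            "loglik": self.loglik,
            "n_iter": self.n_iter,
            "converged": bool(self.converged),
            "method": self.method,
        }

    def to_json(self, path=None) -> str:
        s = json.dumps(self.to_dict(), indent=1)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(s)
        return s
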