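"""Case-control odds ratios for intrinsic-like subtypes and for grade.

Model 3 constrains the per-cell genotype log-OR to be constant within each
of the five intrinsic-like subtypes (a 24-cell two-stage model with a
subtype-indicator second stage), so cases with partially observed markers
are handled by the same EM/observed-likelihood machinery as the
heterogeneity models.  Model 4 does the same with grade indicators (three
free genotype parameters).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .markers import second_stage_design
from .model import CohortData, build_model
from .results import TwoStageResults, or_ci


def _indicator_fit(data: CohortData, variant, kind: str, method: str,
                   level: float, **fit_kw):
    design = second_stage_design(data.schema, kind)
    full_labels = design.labels
    # categories whose cells carry no consistent case mass are dropped by
    # the model and reported as undefined
    model = build_model(data, variant, design=design)
    res = model.fit(method=method, **fit_kw)
    active_cols = np.array([lab in res.theta_labels for lab in full_labels])
    return res, full_labels, active_cols


def subtype_or_table(res: TwoStageResults, full_labels, active_cols,
                     level: float = 0.95) -> pd.DataFrame:
    """Tidy per-category OR table; undefined categories appear as NaN."""
    tab = res.or_table(level=level)
    rows = []
    j = 0
    for lab, ok in zip(full_labels, active_cols):
        if ok:
            rows.append(tab.iloc[j].rename(lab))
            j += 1
        else:
            rows.append(pd.Series(
                {c: np.nan for c in tab.columns}, name=lab))
    out = pd.DataFrame(rows)
    out.index.name = "category"
    out.attrs["undefined"] = [lab for lab, ok in zip(full_labels, active_cols) if not ok]
    return out


def fit_model3(data: CohortData, variant, method: str = "newton",
               level: float = 0.95, return_results: bool = False, **fit_kw):
    """ORs (95% CI) for the five intrinsic-like subtypes vs controls."""
    res, labels, active = _indicator_fit(data, variant, "subtype_indicators",
                                         method, level, **fit_kw)
    tab = subtype_or_table(res, labels, active, level)
    return (tab, res) if return_results else tab


def fit_model4(data: CohortData, variant, method: str = "newton",
               level: float = 0.95, return_results: bool = False, **fit_kw):
    """ORs (95% CI) for tumor grade 1/2/3 vs controls."""
    res, labels, active = _indicator_fit(data, variant, "grade_indicators",
                                         method, level, **fit_kw)
    tab = subtype_or_table(res, labels, active, level)
    return (tab, res) if return_results else tab


__all__ = ["fit_model3", "fit_model4", "subtype_or_table", "or_ci"]
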