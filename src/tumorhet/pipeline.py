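"""Variant-screen orchestration: model 1 -> FDR gate -> models 2/3 -> model 4.

The screen mirrors the published analytic strategy: for every variant a
mixed-effects global heterogeneity test (model 1) is run per genotyping
stratum and meta-combined; Benjamini-Hochberg FDR across all screened
variants gates the follow-up.  FDR-significant variants get fixed-effects
marker-specific tests (model 2) and intrinsic-like-subtype ORs (model 3);
variants significant only for grade in model 2 additionally get per-grade
ORs (model 4).  Per-stratum estimates are combined by fixed-effect
inverse-variance meta-analysis.  Variants that fail to converge in any
stratum are reported with NA results and a status flag instead of aborting
the screen.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform

from .heterogeneity import (
    bh_fdr,
    meta_fixed,
    meta_global_mixed,
    stratum_score_pieces,
)
from .model import CohortData, build_model
from .subtype_effects import fit_model3, fit_model4

logger = logging.getLogger("tumorhet")

MARKERS = ("ER", "PR", "HER2", "grade")


@dataclass
class ScreenConfig:
    fdr_alpha: float = 0.05
    marker_p_threshold: float = 0.05
    global_method: str = "mixture_chisq"   # or "monte_carlo" or "wald_fixed"
    per_stratum: bool = True
    fit_method: str = "newton"
    seed: int = 0

    def __post_init__(self):
        for v in (self.fdr_alpha, self.marker_p_threshold):
            if not (0.0 < v < 1.0):
                raise ValueError("thresholds must lie in (0, 1)")


@dataclass
class ScreenResult:
    """All tables produced by one screen run."""
    table: pd.DataFrame                   # the ScreenTable
    z_markers: pd.DataFrame               # model-2 z matrix (hits only)
    z_subtypes: pd.DataFrame              # model-3 z matrix (hits only)
    subtype_ors: pd.DataFrame             # tidy model-3/4 OR table
    config: ScreenConfig

    def write(self, outdir):
        import pathlib
        out = pathlib.Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.table.to_csv(out / "screen_table.tsv", sep="\t", index=False)
        self.z_markers.to_csv(out / "z_markers.tsv", sep="\t")
        self.z_subtypes.to_csv(out / "z_subtypes.tsv", sep="\t")
        self.subtype_ors.to_csv(out / "subtype_ors.tsv", sep="\t", index=False)
        return out


def _stratum_cohorts(data: CohortData, per_stratum: bool):
    if per_stratum and len(pd.unique(data.stratum)) > 1:
        return list(data.split_by_stratum().values())
    return [data]


def _meta_theta(fits):
    ths = [(f.theta, f.cov_theta) for f in fits]
    if len(ths) == 1:
        return ths[0]
    return meta_fixed(ths)


def run_screen(data: CohortData, config: ScreenConfig | None = None) -> ScreenResult:
    config = config or ScreenConfig()
    cohorts = _stratum_cohorts(data, config.per_stratum)
    strata_names = [str(pd.unique(c.stratum)[0]) if config.per_stratum else "pooled"
                    for c in cohorts]
    eas = getattr(data, "effect_alleles", {})

    rows = []
    for vid in data.variant_ids:
        row = {"variant_id": vid, "effect_allele": eas.get(vid, "A"),
               "status": "ok"}
        try:
            if config.global_method == "wald_fixed":
                fits = [build_model(c, vid).fit(method=config.fit_method)
                        for c in cohorts]
                th, cov = _meta_theta(fits)
                idx = np.arange(1, 5)
                stat = float(th[idx] @ np.linalg.solve(cov[np.ix_(idx, idx)], th[idx]))
                row["p_global"] = float(stats.chi2.sf(stat, 4))
            else:
                pieces = []
                for c in cohorts:
                    pieces.extend(stratum_score_pieces(c, vid))
                res = meta_global_mixed(pieces, method=config.global_method,
                                        seed=config.seed)
                row["p_global"] = res.p_value
        except Exception as e:  # keep screening; report the failure
            logger.warning("variant %s: global test failed: %s", vid, e)
            row["status"] = f"global_failed: {type(e).__name__}"
            row["p_global"] = np.nan
        rows.append(row)

    table = pd.DataFrame(rows)
    ok = table["p_global"].notna()
    qvals = np.full(len(table), np.nan)
    if ok.any():
        qvals[ok.to_numpy()] = bh_fdr(table.loc[ok, "p_global"].to_numpy())
    table["q_global"] = qvals
    table["fdr_sig"] = (table["q_global"] < config.fdr_alpha).fillna(False)

    # --- models 2 and 3 for FDR-significant variants --------------------
    z_rows, z_sub_rows, or_rows = {}, {}, []
    marker_p = {}
    for vid in table.loc[table["fdr_sig"], "variant_id"]:
        try:
            fits = [build_model(c, vid).fit(method=config.fit_method)
                    for c in cohorts]
            th, cov = _meta_theta(fits)
            se = np.sqrt(np.diag(cov))
            z = th / se
            p = 2 * stats.norm.sf(np.abs(z))
            idx = table["variant_id"] == vid
            for j, mk in enumerate(MARKERS, start=1):
                table.loc[idx, f"z_{mk}"] = z[j]
                table.loc[idx, f"p_{mk}"] = p[j]
            for sname, f in zip(strata_names, fits):
                for j, lab in enumerate(("baseline",) + MARKERS):
                    table.loc[idx, f"theta_{lab}_{sname}"] = f.theta[j]
            for j, lab in enumerate(("baseline",) + MARKERS):
                table.loc[idx, f"theta_{lab}_meta"] = th[j]
            z_rows[vid] = dict(zip(MARKERS, z[1:]))
            marker_p[vid] = dict(zip(MARKERS, p[1:]))

            m3 = [fit_model3(c, vid, method=config.fit_method,
                             return_results=True) for c in cohorts]
            th3, cov3 = _meta_theta([r for _, r in m3])
            labels3 = list(m3[0][0].index)
            se3 = np.sqrt(np.diag(cov3))
            z_sub_rows[vid] = dict(zip(labels3, th3 / se3))
            for lab, t_, s_ in zip(labels3, th3, se3):
                or_rows.append({
                    "variant_id": vid, "model": "model3", "category": lab,
                    "log_or": t_, "se": s_, "OR": np.exp(t_),
                    "ci_lo": np.exp(t_ - 1.959963984540054 * s_),
                    "ci_hi": np.exp(t_ + 1.959963984540054 * s_),
                    "p": 2 * stats.norm.sf(abs(t_ / s_))})
        except Exception as e:
            logger.warning("variant %s: follow-up models failed: %s", vid, e)
            table.loc[table["variant_id"] == vid, "status"] = (
                f"followup_failed: {type(e).__name__}")

    # --- model 4: variants associated at p<threshold only with grade ----
    for vid, pmap in marker_p.items():
        sig = {mk for mk, pv in pmap.items() if pv < config.marker_p_threshold}
        if sig == {"grade"}:
            try:
                m4 = [fit_model4(c, vid, method=config.fit_method,
                                 return_results=True) for c in cohorts]
                th4, cov4 = _meta_theta([r for _, r in m4])
                labels4 = list(m4[0][0].index)
                se4 = np.sqrt(np.diag(cov4))
                for lab, t_, s_ in zip(labels4, th4, se4):
                    or_rows.append({
                        "variant_id": vid, "model": "model4", "category": lab,
                        "log_or": t_, "se": s_, "OR": np.exp(t_),
                        "ci_lo": np.exp(t_ - 1.959963984540054 * s_),
                        "ci_hi": np.exp(t_ + 1.959963984540054 * s_),
                        "p": 2 * stats.norm.sf(abs(t_ / s_))})
            except Exception as e:
                logger.warning("variant %s: model 4 failed: %s", vid, e)

    lead = ["variant_id", "effect_allele", "p_global", "q_global", "fdr_sig"]
    marker_cols = [c for mk in MARKERS for c in (f"z_{mk}", f"p_{mk}")]
    theta_cols = [c for c in table.columns if c.startswith("theta_")]
    for c in marker_cols:
        if c not in table.columns:
            table[c] = np.nan
    table = table[lead + marker_cols + theta_cols + ["status"]]

    z_markers = pd.DataFrame.from_dict(z_rows, orient="index")
    z_markers.index.name = "variant_id"
    z_subtypes = pd.DataFrame.from_dict(z_sub_rows, orient="index")
    z_subtypes.index.name = "variant_id"
    subtype_ors = pd.DataFrame(
        or_rows, columns=["variant_id", "model", "category", "log_or", "se",
                          "OR", "ci_lo", "ci_hi", "p"])
    return ScreenResult(table=table, z_markers=z_markers,
                        z_subtypes=z_subtypes, subtype_ors=subtype_ors,
                        config=config or ScreenConfig())


# ---------------------------------------------------------------------------
# |z| clustering for the heatmap reports
# ---------------------------------------------------------------------------

def cluster_zmatrix(z: pd.DataFrame, linkage: str = "complete"):
    """Hierarchical clustering of |z| rows and columns (Euclidean distance).

    Returns (row_order, col_order, row_linkage, col_linkage) with
    deterministic leaf ordering.  Signs of z do not affect the clustering.
    """
    if z.shape[0] < 2:
        raise ValueError("need at least 2 rows to cluster")
    vals = np.abs(np.asarray(z, dtype=float))
    if np.isnan(vals).any():
        raise ValueError("z matrix contains NaN")
    row_link = hierarchy.linkage(pdist(vals), method=linkage)
    row_order = hierarchy.leaves_list(row_link)
    if z.shape[1] >= 2:
        col_link = hierarchy.linkage(pdist(vals.T), method=linkage)
        col_order = hierarchy.leaves_list(col_link)
    else:
        col_link, col_order = None, np.arange(z.shape[1])
    return row_order, col_order, row_link, col_link


def zmatrix_distances(z: pd.DataFrame) -> np.ndarray:
    """Pairwise Euclidean distances between |z| rows (square form)."""
    return squareform(pdist(np.abs(np.asarray(z, dtype=float))))
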