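"""Heterogeneity tests, FDR screening and fixed-effect meta-analysis.

Three testing layers sit on top of the two-stage model:

* marker-specific case-case Wald tests from the fixed-effects main-effects
  model (each marker's parameter adjusted for the others by joint fitting);
* a global heterogeneity test of H0: all four case-case parameters are
  zero, either as a 4-df Wald test from the fixed-effects fit or as a
  mixed-effects score test in which the ER parameter is fixed and the
  PR/HER2/grade parameters share a random distribution N(mu, sigma^2) —
  the null sits on the sigma^2 = 0 boundary, so the statistic is a
  quadratic form in the efficient scores whose null law is a positively
  weighted mixture of 1-df chi-squares (evaluated by Imhof integration,
  with a Monte Carlo option);
* Benjamini-Hochberg FDR across the variant screen and inverse-variance
  fixed-effect meta-analysis across genotyping-array strata.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .model import CohortData, TwoStagePolytomousModel, build_model
from .results import TwoStageResults

RANDOM_MARKERS = ("PR", "HER2", "grade")


@dataclass
class GlobalTestResult:
    statistic: float
    p_value: float
    components: tuple
    method: str
    df: float | None = None
    weights: np.ndarray | None = None
    score: np.ndarray | None = None
    score_cov: np.ndarray | None = None


# ---------------------------------------------------------------------------
# Marker-specific (model 2) tests
# ---------------------------------------------------------------------------

def marker_tests(fit: TwoStageResults) -> pd.DataFrame:
    """Wald z and two-sided normal p per case-case parameter.

    Requires a converged main-effects fit; the baseline (overall
    association) row is excluded.
    """
    if fit.model.design.kind != "main_effects":
        raise ValueError("marker tests require the main_effects design")
    if not fit.converged:
        raise ValueError("fit did not converge; marker tests unavailable")
    tab = fit.theta_table().drop(index="baseline")
    return tab


def global_test_fixed(fit: TwoStageResults) -> GlobalTestResult:
    """4-df Wald test that every case-case parameter is zero."""
    if fit.model.design.kind != "main_effects":
        raise ValueError("global test requires the main_effects design")
    idx = [i for i, lab in enumerate(fit.theta_labels) if lab != "baseline"]
    th = fit.theta[idx]
    V = fit.cov_theta[np.ix_(idx, idx)]
    try:
        stat = float(th @ np.linalg.solve(V, th))
    except np.linalg.LinAlgError as e:
        raise np.linalg.LinAlgError(f"singular case-case covariance: {e}")
    df = len(idx)
    p = float(stats.chi2.sf(stat, df))
    return GlobalTestResult(statistic=stat, p_value=p,
                            components=(stat, 0.0), method="wald_fixed_df4",
                            df=df)


# ---------------------------------------------------------------------------
# Mixture-of-chi-square machinery (sigma^2 = 0 boundary)
# ---------------------------------------------------------------------------

def mixture_chisq_sf(q: float, weights: np.ndarray) -> float:
    """P(sum_j w_j Z_j^2 > q) for iid standard normal Z, by Imhof's method."""
    w = np.asarray(weights, dtype=float)
    w = w[np.abs(w) > 1e-12 * max(np.abs(w).max(), 1.0)]
    if w.size == 0:
        return 1.0
    if q <= 0:
        return 1.0

    if w.size == 1:  # single weight: exactly a scaled 1-df chi-square
        return float(stats.chi2.sf(q / w[0], 1))
    # Imhof integrand: sin(theta(u)) / (u * rho(u)); finite at u=0.
    # The envelope 1/(u*rho) decays like u^{-(r/2+1)}, and past the first
    # oscillations the truncation error is ~ envelope(U)/freq, so truncate
    # where that product is negligible and use a grid fine enough to
    # resolve the oscillation frequency 0.5*(q + sum|w|).
    freq = 0.5 * (q + np.abs(w).sum())

    def envelope(u):
        return 1.0 / (u * np.exp(0.25 * np.log1p((w * u) ** 2).sum()))

    hi = 1.0
    while hi < 1e7 and envelope(hi) / max(freq, 1.0) > 1e-12:
        hi *= 1.6
    n_nodes = int(min(3_000_000, max(8_000, hi * freq * 2.6)))
    u = np.linspace(1e-9, hi, n_nodes)
    theta = 0.5 * np.arctan(np.outer(u, w)).sum(axis=1) - 0.5 * q * u
    log_rho = 0.25 * np.log1p(np.outer(u, w) ** 2).sum(axis=1)
    vals = np.sin(theta) / (u * np.exp(log_rho))
    val = np.trapezoid(vals, u)
    p = 0.5 + val / np.pi
    return float(min(max(p, 0.0), 1.0))


def mixture_chisq_sf_mc(q: float, cov: np.ndarray, weights_matrix: np.ndarray,
                        n_draws: int = 100_000, seed: int = 0) -> float:
    """Monte Carlo tail probability of Z' M Z with Z ~ N(0, cov)."""
    rng = np.random.default_rng(seed)
    L = np.linalg.cholesky(cov + 1e-12 * np.eye(cov.shape[0]))
    Z = rng.standard_normal((n_draws, cov.shape[0])) @ L.T
    vals = np.einsum("ij,jk,ik->i", Z, weights_matrix, Z)
    return float((vals >= q).mean())


# ---------------------------------------------------------------------------
# Mixed-effects (model 1) global score test
# ---------------------------------------------------------------------------

def _null_score_pieces(data: CohortData, variant, **fit_kw):
    """Efficient score and its covariance for the case-case parameters.

    Fits the null model (baseline genotype effect, saturated intercepts,
    covariates; all case-case parameters zero), then evaluates the score
    and observed information of the *full* main-effects model there.  The
    efficient information is the case-case block Schur complement over the
    estimated nuisance parameters.
    """
    full = build_model(data, variant, design_kind="main_effects")
    # null: restrict theta to the baseline column
    from .markers import SecondStageDesign
    null_design = SecondStageDesign(
        kind="main_effects_null", matrix=full.A_full[:, :1], labels=("baseline",))
    null_model = TwoStagePolytomousModel(
        status=data.status, dosage=full.g, mask=data.pattern_mask(),
        design=null_design, covariates=data.covariates)
    null_fit = null_model.fit(method="newton", **fit_kw)
    if not null_fit.converged:
        raise RuntimeError("null model did not converge for the score test")
    # embed null parameters in the full parameterization
    vec = np.concatenate([
        null_fit.params.alpha,
        [null_fit.params.theta[0]], np.zeros(full.p - 1),
        null_fit.params.xi])
    U_full = full.score(vec)
    info = -full.hessian(vec)
    cc = np.arange(full.Ma + 1, full.Ma + full.p)          # case-case rows
    nuis = np.concatenate([np.arange(full.Ma + 1),          # alpha + baseline
                           np.arange(full.Ma + full.p, full.nparams)])
    U = U_full[cc]
    I_cc = info[np.ix_(cc, cc)]
    I_cn = info[np.ix_(cc, nuis)]
    I_nn = info[np.ix_(nuis, nuis)]
    V = I_cc - I_cn @ np.linalg.solve(I_nn, I_cn.T)
    labels = [lab for lab in full.design.labels if lab != "baseline"]
    return U, 0.5 * (V + V.T), labels


def _mixed_weight_matrix(V: np.ndarray, labels) -> np.ndarray:
    """Quadratic-form matrix of the mixed-effects global statistic.

    T = U' M U combines an efficient-score Wald form for the fixed
    directions (the ER parameter and the shared random-effect mean) with a
    variance-component score (inverse-variance-standardized sum of squared
    random-marker scores) for the sigma^2 = 0 boundary.
    """
    k = len(labels)
    e_er = np.zeros(k)
    e_er[labels.index("ER")] = 1.0
    c_mu = np.array([1.0 if lab in RANDOM_MARKERS else 0.0 for lab in labels])
    L = np.vstack([e_er, c_mu])
    Vf = L @ V @ L.T
    M_fixed = L.T @ np.linalg.solve(Vf, L)
    B = np.diag([1.0 / V[i, i] if lab in RANDOM_MARKERS else 0.0
                 for i, lab in enumerate(labels)])
    return M_fixed + B, M_fixed, B


def _mixed_from_scores(U, V, labels, method="mixture_chisq",
                       n_draws=100_000, seed=0) -> GlobalTestResult:
    M, M_fixed, B = _mixed_weight_matrix(V, list(labels))
    stat = float(U @ M @ U)
    fixed_part = float(U @ M_fixed @ U)
    random_part = float(U @ B @ U)
    # null law: eigenvalues of V^{1/2} M V^{1/2}
    evals, evecs = np.linalg.eigh(V)
    evals = np.clip(evals, 0.0, None)
    Vh = (evecs * np.sqrt(evals)) @ evecs.T
    lam = np.linalg.eigvalsh(Vh @ M @ Vh)
    lam = np.clip(lam, 0.0, None)
    if method == "mixture_chisq":
        p = mixture_chisq_sf(stat, lam)
    elif method == "monte_carlo":
        p = mixture_chisq_sf_mc(stat, V, M, n_draws=n_draws, seed=seed)
    else:
        raise ValueError(f"unknown method {method!r}")
    return GlobalTestResult(statistic=stat, p_value=p,
                            components=(fixed_part, random_part),
                            method=method, weights=lam, score=U, score_cov=V)


def global_test_mixed(data: CohortData, variant, method: str = "mixture_chisq",
                      n_draws: int = 100_000, seed: int = 0,
                      **fit_kw) -> GlobalTestResult:
    """Mixed-effects global heterogeneity score test (model 1).

    H0: theta_ER = 0, mu = 0, sigma^2 = 0 — the genotype effect is
    identical across all tumor cells.  The baseline genotype effect,
    intercepts and covariate coefficients are estimated under the null.
    """
    U, V, labels = _null_score_pieces(data, variant, **fit_kw)
    return _mixed_from_scores(U, V, labels, method=method,
                              n_draws=n_draws, seed=seed)


def meta_global_mixed(score_pieces, method: str = "mixture_chisq",
                      n_draws: int = 100_000, seed: int = 0) -> GlobalTestResult:
    """Combine per-stratum (score, covariance, labels) and test globally.

    Scores and informations are additive across independent strata; the
    combined quantities feed the same mixture machinery as a single
    stratum.
    """
    pieces = list(score_pieces)
    if not pieces:
        raise ValueError("no strata supplied")
    labels0 = list(pieces[0][2])
    for _, _, lab in pieces[1:]:
        if list(lab) != labels0:
            raise ValueError("strata have mismatched parameterizations")
    U = np.sum([p[0] for p in pieces], axis=0)
    V = np.sum([p[1] for p in pieces], axis=0)
    return _mixed_from_scores(U, V, labels0, method=method,
                              n_draws=n_draws, seed=seed)


def stratum_score_pieces(data: CohortData, variant, **fit_kw):
    """Per-stratum efficient scores for the mixed global test."""
    return [_null_score_pieces(sub, variant, **fit_kw)
            for sub in data.split_by_stratum().values()]


# ---------------------------------------------------------------------------
# FDR and meta-analysis
# ---------------------------------------------------------------------------

def bh_fdr(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def meta_fixed(estimates):
    """Multivariate inverse-variance fixed-effect meta-analysis.

    Parameters
    ----------
    estimates : list of (theta, cov) pairs, conformable across strata.

    Returns
    -------
    (theta_meta, cov_meta)
    """
    estimates = [(np.atleast_1d(np.asarray(t, dtype=float)),
                  np.atleast_2d(np.asarray(c, dtype=float)))
                 for t, c in estimates]
    if not estimates:
        raise ValueError("no estimates supplied")
    dim = estimates[0][0].shape[0]
    prec_sum = np.zeros((dim, dim))
    wsum = np.zeros(dim)
    for th, cov in estimates:
        if th.shape[0] != dim or cov.shape != (dim, dim):
            raise ValueError("non-conformable estimates")
        prec = np.linalg.inv(cov)
        prec_sum += prec
        wsum += prec @ th
    cov_meta = np.linalg.inv(prec_sum)
    theta_meta = cov_meta @ wsum
    return theta_meta, 0.5 * (cov_meta + cov_meta.T)
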