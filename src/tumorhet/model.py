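"""Two-stage polytomous logistic regression with missing tumor markers.

The first stage is a multinomial logistic model contrasting each of the M
tumor cells (cross-classified disease subtypes) against controls:

    log P(cell m | g, x) / P(control | g, x) = alpha_m + beta_m * g + xi' x

where ``g`` is the genotype dosage and ``x`` are adjustment covariates
(ancestry principal components) with cell-invariant coefficients.  The
second stage constrains the per-cell genotype log-odds-ratios to a linear
decomposition

    beta = A @ theta

with a small design matrix A (M x p): a baseline effect plus one case-case
parameter per tumor marker (main effects), indicators of the intrinsic-like
subtypes, indicators of grade, or the saturated identity.

Cases with partially observed markers contribute the sum of cell
probabilities over every cell consistent with their observed pattern,
assuming markers are missing at random (MAR).  The resulting observed-data
log-likelihood is maximized either directly by Newton iterations with the
exact analytic gradient and Hessian, or by an EM algorithm treating the
unobserved cell membership as missing data.  Standard errors come from the
observed information of the observed-data log-likelihood, which is correct
under MAR missingness.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .markers import (
    MarkerSchema,
    ObservedPattern,
    SecondStageDesign,
    SUBTYPE_LABELS,
    consistent_cells,
    consistent_intrinsic,
    default_schema,
    enumerate_cells,
    second_stage_design,
)


class ConvergenceError(RuntimeError):
    """Raised when the optimizer fails or the likelihood is unbounded."""


@dataclass
class CohortData:
    """A case-control cohort for one analysis stratum (or pooled).

    Attributes
    ----------
    status : (n,) int array, 0 control / 1 case
    patterns : list of ObservedPattern, one per subject (ignored for
        controls, which carry no tumor markers)
    covariates : (n, k) float array, e.g. ancestry PCs; may have k = 0
    stratum : (n,) array of stratum labels
    dosages : (V, n) float array of per-variant genotype dosages in [0, 2]
    variant_ids : length-V list
    """

    status: np.ndarray
    patterns: list
    covariates: np.ndarray
    stratum: np.ndarray
    dosages: np.ndarray
    variant_ids: list
    schema: MarkerSchema = field(default_factory=default_schema)

    def __post_init__(self):
        self.status = np.asarray(self.status, dtype=int)
        self.covariates = np.atleast_2d(np.asarray(self.covariates, dtype=float))
        if self.covariates.shape[0] != self.status.shape[0]:
            self.covariates = self.covariates.T
        self.dosages = np.atleast_2d(np.asarray(self.dosages, dtype=float))
        if self.dosages.size and (self.dosages.min() < 0 or self.dosages.max() > 2):
            raise ValueError("dosages must lie in [0, 2]")

    @property
    def n(self) -> int:
        return self.status.shape[0]

    def dosage(self, variant) -> np.ndarray:
        return self.dosages[self.variant_ids.index(variant)]

    def pattern_mask(self) -> np.ndarray:
        """(n, M) boolean: cells consistent with each subject's pattern.

        Control rows are all False (controls have no tumor).
        """
        M = self.schema.n_cells
        mask = np.zeros((self.n, M), dtype=bool)
        cache: dict[tuple, np.ndarray] = {}
        for i in np.flatnonzero(self.status == 1):
            key = self.patterns[i].values
            row = cache.get(key)
            if row is None:
                row = np.zeros(M, dtype=bool)
                row[sorted(consistent_cells(self.patterns[i], self.schema))] = True
                cache[key] = row
            mask[i] = row
        return mask

    def split_by_stratum(self) -> dict:
        out = {}
        for s in pd.unique(self.stratum):
            idx = np.flatnonzero(self.stratum == s)
            out[s] = CohortData(
                status=self.status[idx],
                patterns=[self.patterns[i] for i in idx],
                covariates=self.covariates[idx],
                stratum=self.stratum[idx],
                dosages=self.dosages[:, idx],
                variant_ids=list(self.variant_ids),
                schema=self.schema,
            )
        return out


@dataclass
class ParameterSet:
    """Unpacked parameters of a two-stage fit.

    ``alpha`` has one intercept per *active* cell (cells with no consistent
    case mass are excluded: their maximum-likelihood intercept is -inf).
    ``beta = A @ theta`` gives the per-cell genotype log-OR for all cells.
    """

    alpha: np.ndarray
    theta: np.ndarray
    xi: np.ndarray
    active_cells: np.ndarray

    def beta(self, design: SecondStageDesign) -> np.ndarray:
        return design.matrix @ self.theta


def _logsumexp_rows(a: np.ndarray, mask: np.ndarray | None = None) -> np.ndarray:
    if mask is not None:
        a = np.where(mask, a, -np.inf)
    m = np.max(a, axis=1)
    m = np.where(np.isfinite(m), m, 0.0)
    with np.errstate(divide="ignore"):
        return m + np.log(np.exp(a - m[:, None]).sum(axis=1))


class TwoStagePolytomousModel:
    """Case-control polytomous model over tumor cells with a second stage.

    Parameters
    ----------
    status : (n,) 0/1
    dosage : (n,) genotype dosages
    mask : (n, M) boolean consistent-cell indicators for cases
    design : SecondStageDesign with an M-row matrix
    covariates : (n, k), optional
    """

    def __init__(self, status, dosage, mask, design: SecondStageDesign,
                 covariates=None, cell_labels=None):
        self.status = np.asarray(status, dtype=int)
        n = self.status.shape[0]
        if n == 0:
            raise ValueError("empty data")
        self.g = np.asarray(dosage, dtype=float)
        mask = np.asarray(mask, dtype=bool)
        self.is_case = self.status == 1
        if self.is_case.any():
            bad = np.flatnonzero(self.is_case & ~mask.any(axis=1))
            if bad.size:
                raise ValueError(f"case(s) {bad[:5].tolist()} have no consistent cell")
        # Cells never consistent with any case have MLE intercept -inf:
        # restrict the category space to cells with potential case mass.
        self.active = mask[self.is_case].any(axis=0)
        if not self.active.any():
            raise ValueError("no case mass on any cell (need >=1 case)")
        self.mask = mask[:, self.active]
        self.mask[~self.is_case] = False
        self.A_full = design.matrix
        A_act = design.matrix[self.active]
        # design columns supported only by inactive cells are undefined:
        # drop them (their labels disappear from the fit)
        col_keep = (A_act != 0).any(axis=0)
        if not col_keep.all():
            from .markers import SecondStageDesign as _SSD
            A_act = A_act[:, col_keep]
            design = _SSD(kind=design.kind,
                          matrix=design.matrix[:, col_keep],
                          labels=tuple(np.asarray(design.labels)[col_keep]))
        self.col_keep = col_keep
        self.A = A_act
        self.design = design
        self.X = (np.zeros((n, 0)) if covariates is None
                  else np.atleast_2d(np.asarray(covariates, dtype=float)))
        if self.X.shape[0] != n:
            self.X = self.X.T
        self.Ma = int(self.active.sum())
        self.p = self.A.shape[1]
        self.k = self.X.shape[1]
        self.nparams = self.Ma + self.p + self.k
        self.cell_labels = cell_labels
        if np.linalg.matrix_rank(self.A) < self.p:
            raise ValueError("second-stage design is rank deficient on active cells")

    # -- parameter packing ------------------------------------------------
    def unpack(self, vec: np.ndarray) -> ParameterSet:
        return ParameterSet(
            alpha=vec[: self.Ma],
            theta=vec[self.Ma: self.Ma + self.p],
            xi=vec[self.Ma + self.p:],
            active_cells=self.active.copy(),
        )

    def pack(self, alpha, theta, xi=None) -> np.ndarray:
        xi = np.zeros(self.k) if xi is None else xi
        return np.concatenate([alpha, theta, xi])

    # -- likelihood pieces ------------------------------------------------
    def linpred(self, vec: np.ndarray) -> np.ndarray:
        """(n, Ma) cell log-odds vs control: alpha + (A theta) g + xi'x."""
        alpha = vec[: self.Ma]
        beta = self.A @ vec[self.Ma: self.Ma + self.p]
        eta = alpha[None, :] + beta[None, :] * self.g[:, None]
        if self.k:
            eta = eta + (self.X @ vec[self.Ma + self.p:])[:, None]
        return eta

    def _probs(self, eta):
        """Category probabilities P (n, Ma) and log-normalizer logD (n,)."""
        m = np.maximum(eta.max(axis=1), 0.0)
        logD = m + np.log(np.exp(-m) + np.exp(eta - m[:, None]).sum(axis=1))
        P = np.exp(eta - logD[:, None])
        return P, logD

    def loglike(self, vec: np.ndarray) -> float:
        eta = self.linpred(vec)
        P, logD = self._probs(eta)
        logS = _logsumexp_rows(eta, self.mask)
        ll = np.where(self.is_case, logS, 0.0) - logD
        return float(ll.sum())

    def _weights(self, eta):
        """Posterior cell weights W (n, Ma); zero rows for controls."""
        logS = _logsumexp_rows(eta, self.mask)
        logS = np.where(np.isfinite(logS), logS, 0.0)
        W = np.where(self.mask, np.exp(eta - logS[:, None]), 0.0)
        W[~self.is_case] = 0.0
        return W

    def score(self, vec: np.ndarray, W: np.ndarray | None = None) -> np.ndarray:
        """Gradient of the observed-data log-likelihood.

        If ``W`` is supplied it is held fixed: that is the gradient of the
        EM Q-function, which coincides with the observed score when W is
        the posterior at ``vec``.
        """
        eta = self.linpred(vec)
        P, _ = self._probs(eta)
        if W is None:
            W = self._weights(eta)
        R = W - P
        g_alpha = R.sum(axis=0)
        g_theta = self.A.T @ (R.T @ self.g)
        g_xi = self.X.T @ R.sum(axis=1) if self.k else np.zeros(0)
        return np.concatenate([g_alpha, g_theta, g_xi])

    def hessian(self, vec: np.ndarray, observed: bool = True) -> np.ndarray:
        """Analytic Hessian of the observed log-likelihood (n x n blocks).

        With ``observed=False`` the posterior-weight curvature term is
        dropped, giving the Hessian of the EM Q-function (complete-data
        information): that is the matrix used in M-step Newton updates.
        """
        eta = self.linpred(vec)
        P, _ = self._probs(eta)
        W = self._weights(eta) if observed else np.zeros_like(P)
        g = self.g
        S = P.sum(axis=1)

        def curv(weight):
            # sum_i weight_i * [diag(W_i)-W_i W_i' - diag(P_i)+P_i P_i']
            d = (weight[:, None] * (W - P)).sum(axis=0)
            return (np.diag(d) - (W * weight[:, None]).T @ W
                    + (P * weight[:, None]).T @ P)

        ones = np.ones_like(g)
        B0 = curv(ones)
        B1 = curv(g)
        B2 = curv(g * g)
        H = np.zeros((self.nparams, self.nparams))
        ia = slice(0, self.Ma)
        it = slice(self.Ma, self.Ma + self.p)
        ix = slice(self.Ma + self.p, self.nparams)
        H[ia, ia] = B0
        H[ia, it] = B1 @ self.A
        H[it, ia] = H[ia, it].T
        H[it, it] = self.A.T @ B2 @ self.A
        if self.k:
            # For every subject the row-sum of the per-subject curvature is
            # -P_i (1 - S_i) in the W-present case as well (posterior rows
            # sum to one so their curvature block annihilates constants).
            U = P * (1.0 - S)[:, None]
            if not observed:
                # Q-function: no W term; row sums are still -P(1-S).
                pass
            H[ia, ix] = -(U.T @ self.X)
            H[it, ix] = -(self.A.T @ ((U * g[:, None]).T @ self.X))
            H[ix, ia] = H[ia, ix].T
            H[ix, it] = H[it, ix].T
            s = S * S - S
            H[ix, ix] = (self.X * s[:, None]).T @ self.X
        return H

    # -- initialization ---------------------------------------------------
    def _start(self) -> np.ndarray:
        n_ctrl = max(int((~self.is_case).sum()), 1)
        # smoothed per-cell case counts from pattern mass spread uniformly
        frac = self.mask / np.maximum(self.mask.sum(axis=1, keepdims=True), 1)
        counts = frac[self.is_case].sum(axis=0)
        alpha0 = np.log(np.maximum(counts, 0.5) / n_ctrl)
        return self.pack(alpha0, np.zeros(self.p))

    # -- fitting ----------------------------------------------------------
    def fit(self, method: str = "newton", start=None, maxiter: int = 200,
            gtol: float = 1e-6, ftol: float = 1e-10, em_maxiter: int = 500,
            diverge_norm: float = 50.0):
        """Maximize the observed-data log-likelihood.

        method 'newton' — direct Newton iterations with exact Hessian and
        backtracking line search; method 'em' — EM over unobserved cell
        membership (monotone in the observed log-likelihood), with M-steps
        solved by Newton on the Q-function.
        """
        from .results import TwoStageResults

        vec = self._start() if start is None else np.asarray(start, dtype=float).copy()
        if method == "newton":
            vec, ll, n_iter, converged, trace = self._fit_newton(
                vec, maxiter, gtol, ftol, diverge_norm)
        elif method == "em":
            vec, ll, n_iter, converged, trace = self._fit_em(
                vec, em_maxiter, gtol, ftol, diverge_norm)
        else:
            raise ValueError(f"unknown method {method!r}")
        H = self.hessian(vec)
        info = -H
        # Flat or weakly identified directions (e.g. a marker missing for
        # every case) leave the observed information near-singular or even
        # indefinite; invert on the identified eigenspace and assign the
        # weak directions a huge variance so SEs are visibly inflated.
        evals, evecs = np.linalg.eigh(0.5 * (info + info.T))
        lam_max = max(float(evals.max()), 1e-300)
        floor = lam_max * 1e-8
        weak = evals < floor
        cov = (evecs / np.where(weak, floor, evals)) @ evecs.T
        cov = 0.5 * (cov + cov.T)
        # a second-stage parameter running off to +-inf with vanishing
        # curvature is separation: the MLE does not exist
        th = vec[self.Ma: self.Ma + self.p]
        th_se = np.sqrt(np.maximum(np.diag(cov)[self.Ma: self.Ma + self.p], 0))
        sep = (np.abs(th) > 12.0) & (th_se > 100.0)
        if sep.any():
            labs = [self.design.labels[j] for j in np.flatnonzero(sep)]
            raise ConvergenceError(
                f"separation: unbounded genotype log-OR for {labs} "
                f"(|theta| > 12 with no curvature)")
        res = TwoStageResults(
            model=self, params_vec=vec, cov_params=cov, loglik=ll,
            n_iter=n_iter, converged=converged, method=method,
            loglik_trace=trace)
        res.weakly_identified = bool(weak.any())
        return res

    def _newton_step(self, vec, ll, grad, H, ridge=0.0):
        npar = self.nparams
        A = H - ridge * np.eye(npar) if ridge else H
        try:
            step = np.linalg.solve(A, -grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(A, -grad, rcond=None)[0]
        if grad @ step <= 0:  # not an ascent direction: steepest ascent
            step = grad / max(np.abs(grad).max(), 1.0)
        t = 1.0
        for _ in range(40):
            new = vec + t * step
            ll_new = self.loglike(new)
            if ll_new >= ll - 1e-12:
                return new, ll_new
            t *= 0.5
        return vec, ll

    def _conv_tol(self, gtol):
        # score magnitudes scale with n; the flag uses a scaled criterion
        return max(gtol, 1e-7 * self.status.shape[0])

    _ALPHA_FLOOR = -30.0  # boundary MLE guard: empty-cell intercepts -> -inf

    def _guard(self, vec, diverge_norm):
        """Clamp boundary intercepts; detect genuine parameter divergence.

        A cell intercept drifting to -inf is a legitimate boundary optimum
        (the cell carries no posterior case mass) and is clamped where its
        probability is already ~1e-13.  Divergence of the second-stage or
        covariate parameters (or a +inf intercept) signals separation.
        """
        vec[: self.Ma] = np.maximum(vec[: self.Ma], self._ALPHA_FLOOR)
        worst = max(np.abs(vec[self.Ma:]).max(initial=0.0),
                    vec[: self.Ma].max(initial=0.0))
        if worst > diverge_norm:
            raise ConvergenceError(
                "parameter divergence (likely separation: a cell's log-OR "
                "is unbounded); max |param| = %.1f" % worst)
        return vec

    def _fit_newton(self, vec, maxiter, gtol, ftol, diverge_norm):
        ll = self.loglike(vec)
        trace = [ll]
        converged = False
        it = 0
        for it in range(1, maxiter + 1):
            grad = self.score(vec)
            if np.abs(grad).max() < gtol:
                converged = True
                break
            H = self.hessian(vec)
            vec, ll_new = self._newton_step(vec, ll, grad, H)
            vec = self._guard(vec, diverge_norm)
            ll_new = max(ll_new, self.loglike(vec)) if vec[: self.Ma].min() <= self._ALPHA_FLOOR else ll_new
            if ll_new - ll < ftol * (abs(ll) + 1.0) and it > 3:
                converged = np.abs(self.score(vec)).max() < self._conv_tol(gtol)
                ll = ll_new
                trace.append(ll)
                break
            ll = ll_new
            trace.append(ll)
        return vec, ll, it, converged, trace

    def _fit_em(self, vec, maxiter, gtol, ftol, diverge_norm):
        ll = self.loglike(vec)
        trace = [ll]
        converged = False
        it = 0
        for it in range(1, maxiter + 1):
            W = self._weights(self.linpred(vec))  # E-step
            # M-step: Newton on Q(.; W) until its gradient is small
            for _ in range(25):
                grad_q = self.score(vec, W=W)
                if np.abs(grad_q).max() < 0.1 * gtol:
                    break
                Hq = self.hessian(vec, observed=False)
                vec_new = self._m_step_newton(vec, W, grad_q, Hq)
                vec = vec_new
            vec = self._guard(vec, diverge_norm)
            ll_new = self.loglike(vec)
            trace.append(ll_new)
            gmax = np.abs(self.score(vec)).max()
            if gmax < gtol:
                ll = ll_new
                converged = True
                break
            if (ll_new - ll) < 1e-13 * (abs(ll_new) + 1.0):  # numerical stall
                ll = ll_new
                converged = gmax < self._conv_tol(gtol)
                break
            ll = ll_new
        if not converged:
            # EM converges linearly near boundary optima; refine the final
            # iterate with monotone Newton steps on the observed likelihood
            # (line-searched, so the recorded trace stays non-decreasing).
            for _ in range(50):
                grad = self.score(vec)
                if np.abs(grad).max() < gtol:
                    converged = True
                    break
                H = self.hessian(vec)
                vec, ll = self._newton_step(vec, ll, grad, H)
                vec = self._guard(vec, diverge_norm)
                trace.append(ll)
            converged = converged or np.abs(self.score(vec)).max() < self._conv_tol(gtol)
        return vec, ll, it, converged, trace

    def _m_step_newton(self, vec, W, grad_q, Hq):
        """One damped Newton ascent step on the Q-function."""
        try:
            step = np.linalg.solve(Hq, -grad_q)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(Hq, -grad_q, rcond=None)[0]
        if grad_q @ step <= 0:
            step = grad_q / max(np.abs(grad_q).max(), 1.0)
        q0 = self._qfun(vec, W)
        t = 1.0
        for _ in range(40):
            new = vec + t * step
            if self._qfun(new, W) >= q0 - 1e-12:
                return new
            t *= 0.5
        return vec

    def _qfun(self, vec, W):
        eta = self.linpred(vec)
        _, logD = self._probs(eta)
        return float((W * eta).sum() - logD.sum())


# -- schema-aware constructors -------------------------------------------

def build_model(data: CohortData, variant, design_kind: str = "main_effects",
                design: SecondStageDesign | None = None) -> TwoStagePolytomousModel:
    """Assemble a TwoStagePolytomousModel for one variant of a cohort."""
    if design is None:
        design = second_stage_design(data.schema, design_kind)
    g = data.dosage(variant) if not isinstance(variant, np.ndarray) else variant
    if np.ptp(g) == 0:
        raise ValueError("no genotype variation for this variant")
    cells = enumerate_cells(data.schema)
    return TwoStagePolytomousModel(
        status=data.status, dosage=g, mask=data.pattern_mask(),
        design=design, covariates=data.covariates,
        cell_labels=["_".join(c.levels) for c in cells])


def estep_weights(model: TwoStagePolytomousModel, vec: np.ndarray) -> np.ndarray:
    """Posterior cell-membership weights (E-step), rows summing to 1 for cases."""
    return model._weights(model.linpred(vec))


def fit_complete_case_polytomous(data: CohortData, variant,
                                 categories: str = "intrinsic5",
                                 method: str = "newton", **fit_kw):
    """Standard polytomous fit on cases classifiable from observed markers.

    Cases whose observed pattern is consistent with more than one category
    are dropped; the rest enter a multinomial logistic model (one saturated
    genotype log-OR per category vs controls).  This is the no-EM
    sensitivity analysis: with missing markers it discards information and
    is expected to be similar, but less precise, than the EM fit.

    Returns (results, n_dropped).
    """
    schema = data.schema
    if categories == "intrinsic5":
        labels = list(SUBTYPE_LABELS)
        def assign(pattern):
            s = consistent_intrinsic(pattern, schema)
            return labels.index(next(iter(s))) if len(s) == 1 else None
    elif categories == "cells":
        cells = enumerate_cells(schema)
        labels = ["_".join(c.levels) for c in cells]
        def assign(pattern):
            s = consistent_cells(pattern, schema)
            return next(iter(s)) if len(s) == 1 else None
    else:
        raise ValueError(f"unknown categorization {categories!r}")

    K = len(labels)
    n = data.n
    cat = np.full(n, -1)
    for i in range(n):
        if data.status[i] == 1:
            a = assign(data.patterns[i])
            cat[i] = -2 if a is None else a
    keep = cat != -2
    n_dropped = int((~keep).sum())
    mask = np.zeros((keep.sum(), K), dtype=bool)
    kept_cat = cat[keep]
    case_rows = kept_cat >= 0
    mask[np.flatnonzero(case_rows), kept_cat[case_rows]] = True
    g = data.dosage(variant) if not isinstance(variant, np.ndarray) else variant
    design = SecondStageDesign(kind="saturated", matrix=np.eye(K), labels=tuple(labels))
    model = TwoStagePolytomousModel(
        status=data.status[keep], dosage=g[keep], mask=mask, design=design,
        covariates=data.covariates[keep], cell_labels=labels)
    res = model.fit(method=method, **fit_kw)
    return res, n_dropped
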