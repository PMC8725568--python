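"""Synthetic case-control cohorts with correlated, partially missing markers.

The generator emulates the statistical structure the two-stage analysis
assumes, at configurable scale:

* Tumor markers of cases follow a latent-Gaussian threshold model: a
  4-variate standard normal is dichotomized (ER, PR, HER2) or double-
  thresholded (grade) at cutpoints set by the reference marker prevalences.
  The latent correlations are calibrated so that the plain Pearson
  correlations of the coded markers reproduce the reference values
  (r(ER,PR)=0.61, r(ER,HER2)=-0.16, r(ER,grade)=-0.39); the remaining
  pairs use clinically plausible defaults tuned so the implied
  intrinsic-like-subtype mix matches the reference shares.
* Controls carry Hardy-Weinberg genotype dosages; case genotypes are drawn
  exactly from the three-point law P(g | case in cell m) proportional to
  f(g) * exp(beta_m * g) with beta = A @ theta_true, so fitted models are
  correctly specified with the configured second-stage effects.
* Tumor markers of cases are masked missing-at-random: per-marker Bernoulli
  masking whose rate may depend on stratum and on the *observed* ER status,
  never on the masked value itself.
* Ancestry-PC covariates are standard normal per stratum (null effects by
  default) and strata are generated independently.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from . import calibration
from .markers import (
    MarkerSchema,
    ObservedPattern,
    default_schema,
    enumerate_cells,
    map_intrinsic,
    second_stage_design,
)
from .model import CohortData

MARKERS = ("ER", "PR", "HER2", "grade")

# Latent correlations are calibrated (calibrate_latent_corr) to these
# observed-scale Pearson targets.  The ER pairs are the reference values;
# the remaining pairs have no reference value and use clinically plausible
# defaults chosen so the implied intrinsic-like-subtype mix matches the
# reference shares within +/-2 percentage points.
DEFAULT_OBSERVED_TARGETS = {
    ("ER", "PR"): 0.61,
    ("ER", "HER2"): -0.16,
    ("ER", "grade"): -0.39,
    ("PR", "HER2"): -0.05,
    ("PR", "grade"): -0.42,
    ("HER2", "grade"): 0.16,
}


@dataclass
class MarkerModel:
    """Latent-Gaussian threshold model for the case marker joint law."""

    prevalences: dict = field(default_factory=calibration.marker_prevalences)
    latent_corr: np.ndarray | None = None
    observed_targets: dict = field(default_factory=lambda: dict(DEFAULT_OBSERVED_TARGETS))

    def __post_init__(self):
        if self.latent_corr is None:
            self.latent_corr = calibrate_latent_corr(
                self.prevalences, self.observed_targets)
        self.latent_corr = np.asarray(self.latent_corr, dtype=float)
        np.linalg.cholesky(self.latent_corr)  # PD check

    def thresholds(self) -> dict:
        """Latent cutpoints per marker (positive/higher side above)."""
        pv = self.prevalences
        return {
            "ER": np.array([stats.norm.ppf(pv["ER"]["neg"])]),
            "PR": np.array([stats.norm.ppf(pv["PR"]["neg"])]),
            "HER2": np.array([stats.norm.ppf(pv["HER2"]["neg"])]),
            "grade": np.array([
                stats.norm.ppf(pv["grade"]["1"]),
                stats.norm.ppf(pv["grade"]["1"] + pv["grade"]["2"]),
            ]),
        }


def _pair_pearson(rho, marker_i, marker_j, thresholds):
    """Observed-scale Pearson correlation implied by latent correlation rho."""
    cuts_i, cuts_j = thresholds[marker_i], thresholds[marker_j]

    def codes_and_moments(cuts):
        # coded values 0..len(cuts); grade coded 1,2,3 shifts cancel in r
        edges = np.concatenate([[-np.inf], cuts, [np.inf]])
        probs = np.diff(stats.norm.cdf(edges))
        vals = np.arange(len(probs), dtype=float)
        mu = (vals * probs).sum()
        sd = np.sqrt(((vals - mu) ** 2 * probs).sum())
        return edges, vals, probs, mu, sd

    ei, vi, pi_, mi, si = codes_and_moments(cuts_i)
    ej, vj, pj_, mj, sj = codes_and_moments(cuts_j)
    cov = np.array([[1.0, rho], [rho, 1.0]])
    mvn = stats.multivariate_normal(mean=[0.0, 0.0], cov=cov)

    def rect(a0, a1, b0, b1):
        # P(a0 < Z1 <= a1, b0 < Z2 <= b1) by inclusion-exclusion on the CDF
        def F(x, y):
            if np.isinf(x) and x < 0 or np.isinf(y) and y < 0:
                return 0.0
            xx = min(x, 8.5)
            yy = min(y, 8.5)
            return float(mvn.cdf([xx, yy]))
        return F(a1, b1) - F(a0, b1) - F(a1, b0) + F(a0, b0)

    exy = 0.0
    for a in range(len(vi)):
        for b in range(len(vj)):
            if vi[a] == 0.0 or vj[b] == 0.0:
                continue
            exy += vi[a] * vj[b] * rect(ei[a], ei[a + 1], ej[b], ej[b + 1])
    return (exy - mi * mj) / (si * sj)


def calibrate_latent_corr(prevalences: dict, observed_targets: dict) -> np.ndarray:
    """Solve pairwise latent correlations matching observed-scale targets."""
    mm = MarkerModel.__new__(MarkerModel)
    mm.prevalences = prevalences
    thresholds = MarkerModel.thresholds(mm)
    R = np.eye(4)
    for (mi, mj), target in observed_targets.items():
        i, j = MARKERS.index(mi), MARKERS.index(mj)
        f = lambda r: _pair_pearson(r, mi, mj, thresholds) - target
        rho = optimize.brentq(f, -0.97, 0.97, xtol=1e-6)
        R[i, j] = R[j, i] = rho
    return R


# ---------------------------------------------------------------------------
# Simulation primitives
# ---------------------------------------------------------------------------

def simulate_markers(n: int, marker_model: MarkerModel | None = None,
                     seed=0) -> np.ndarray:
    """Draw fully observed case markers; returns (n, 4) level-index codes.

    Columns are (ER, PR, HER2, grade) with ER/PR/HER2 in {0, 1} and grade
    in {0, 1, 2} (i.e. histologic grade 1-3).
    """
    marker_model = marker_model or MarkerModel()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    L = np.linalg.cholesky(marker_model.latent_corr)
    Z = rng.standard_normal((n, 4)) @ L.T
    cuts = marker_model.thresholds()
    out = np.empty((n, 4), dtype=int)
    for j, mk in enumerate(MARKERS):
        out[:, j] = np.searchsorted(cuts[mk], Z[:, j], side="right")
    return out


def marker_codes_to_cells(codes: np.ndarray, schema: MarkerSchema | None = None) -> np.ndarray:
    """Map (n, 4) level indices to lexicographic cell ids."""
    schema = schema or default_schema()
    sizes = [len(lv) for _, lv in schema.markers]
    cid = np.zeros(codes.shape[0], dtype=int)
    for j, sz in enumerate(sizes):
        cid = cid * sz + codes[:, j]
    return cid


def simulate_genotypes(n: int, maf: float, seed=0, noise: float | None = None) -> np.ndarray:
    """Hardy-Weinberg genotypes; optional beta imputation noise in [0, 2].

    With ``noise`` set, hard calls g are replaced by draws from
    2*Beta(kappa*g/2, kappa*(1-g/2)) (boundary genotypes slightly shrunk),
    emulating imputed dosages; kappa = 1/noise controls the jitter.
    """
    if not (0.0 < maf <= 0.5):
        raise ValueError("maf must lie in (0, 0.5]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    g = rng.binomial(2, maf, size=n).astype(float)
    if noise:
        kappa = 1.0 / noise
        mu = np.clip(g / 2.0, 0.02, 0.98)
        g = 2.0 * rng.beta(kappa * mu, kappa * (1.0 - mu))
    return g


def hwe_probs(maf: float) -> np.ndarray:
    q = 1.0 - maf
    return np.array([q * q, 2 * maf * q, maf * maf])


def case_genotypes(cell_ids: np.ndarray, beta: np.ndarray, maf: float,
                   seed=0, noise: float | None = None) -> np.ndarray:
    """Exact three-point sampling of P(g | case in cell m) ~ f(g) e^{beta_m g}."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    f = hwe_probs(maf)
    gvals = np.arange(3.0)
    w = f[None, :] * np.exp(np.outer(beta[cell_ids], gvals))
    w /= w.sum(axis=1, keepdims=True)
    u = rng.random(cell_ids.shape[0])
    g = (u[:, None] > np.cumsum(w, axis=1)[:, :2]).sum(axis=1).astype(float)
    if noise:
        kappa = 1.0 / noise
        mu = np.clip(g / 2.0, 0.02, 0.98)
        g = 2.0 * rng.beta(kappa * mu, kappa * (1.0 - mu))
    return g


def apply_mar(codes: np.ndarray, rates: dict, seed=0, stratum=None,
              er_observed_factors: dict | None = None) -> np.ndarray:
    """Mask case markers missing-at-random; returns float array with NaN.

    ``rates`` maps marker name to a base masking probability, or to a
    per-stratum dict of probabilities.  ``er_observed_factors`` optionally
    multiplies the PR/HER2/grade rates by a factor depending on the
    *observed* ER level ({0: f_neg, 1: f_pos}); subjects with ER itself
    masked keep the base rate.  Dependence on a masked value (an MNAR
    mechanism) is therefore impossible by construction; requesting a
    factor for the ER marker raises.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = codes.shape[0]
    out = codes.astype(float)

    def rate_vec(marker):
        r = rates.get(marker, 0.0)
        if isinstance(r, dict):
            if stratum is None:
                raise ValueError("per-stratum rates need stratum labels")
            return np.array([r[s] for s in stratum], dtype=float)
        return np.full(n, float(r))

    if er_observed_factors and "ER" in er_observed_factors:
        raise ValueError("masking rates may not depend on the ER value being "
                         "masked; only observed drivers are allowed (MAR)")
    # mask ER first, independently
    er_rate = rate_vec("ER")
    er_mask = rng.random(n) < er_rate
    for j, mk in enumerate(MARKERS):
        if mk == "ER":
            out[er_mask, 0] = np.nan
            continue
        r = rate_vec(mk)
        if er_observed_factors:
            fac = np.ones(n)
            obs = ~er_mask
            fpos = er_observed_factors.get(1, 1.0)
            fneg = er_observed_factors.get(0, 1.0)
            fac[obs] = np.where(codes[obs, 0] == 1, fpos, fneg)
            r = np.clip(r * fac, 0.0, 0.999)
        out[rng.random(n) < r, j] = np.nan
    return out


def codes_to_patterns(masked: np.ndarray, schema: MarkerSchema | None = None):
    """Convert possibly-NaN coded markers to ObservedPattern objects."""
    schema = schema or default_schema()
    levels = [lv for _, lv in schema.markers]
    pats = []
    for row in masked:
        vals = tuple(None if np.isnan(v) else levels[j][int(v)]
                     for j, v in enumerate(row))
        pats.append(ObservedPattern(vals))
    return pats


# ---------------------------------------------------------------------------
# Cohort-level generation
# ---------------------------------------------------------------------------

@dataclass
class VariantSpec:
    """One simulated variant: allele frequency and true second-stage effects."""
    variant_id: str
    maf: float
    theta: np.ndarray = None
    design_kind: str = "main_effects"

    def __post_init__(self):
        if not (0.0 < self.maf <= 0.5):
            raise ValueError(f"maf for {self.variant_id} must lie in (0, 0.5]")
        if self.theta is None:
            self.theta = np.zeros(5)
        self.theta = np.asarray(self.theta, dtype=float)


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic cohort.

    Defaults mirror the reference two-array consortium population: stratum
    sizes, case marker joint distribution, per-marker missingness, ten
    ancestry PCs with null effects.
    """

    strata: dict = field(default_factory=lambda: dict(calibration.STRATUM_SIZES))
    variants: list = field(default_factory=lambda: [VariantSpec("rs_null", 0.25)])
    marker_model: MarkerModel = field(default_factory=MarkerModel)
    missing_rates: dict = field(default_factory=calibration.missingness_rates)
    er_observed_factors: dict | None = None
    n_pcs: int = 10
    dosage_noise: float | None = None
    seed: int = 0

    def __post_init__(self):
        for mk, r in self.missing_rates.items():
            vals = r.values() if isinstance(r, dict) else [r]
            if any(not (0.0 <= v < 1.0) for v in vals):
                raise ValueError(f"missing rate for {mk} outside [0, 1)")


@dataclass
class TruthRecord:
    """Ground truth for recovery tests."""
    theta_true: dict            # variant -> theta vector
    beta_true: dict             # variant -> per-cell log-ORs (24,)
    subtype_logor: dict         # variant -> case-mass-weighted subtype log-ORs
    design_kind: dict
    cell_freqs: np.ndarray      # empirical case cell distribution


def simulate_cohort(config: SimulationConfig):
    """Generate a cohort and its truth record.

    Returns (CohortData, TruthRecord).
    """
    schema = default_schema()
    cells = enumerate_cells(schema)
    rng = np.random.default_rng(config.seed)
    designs = {v.variant_id: second_stage_design(schema, v.design_kind)
               for v in config.variants}
    betas = {v.variant_id: designs[v.variant_id].matrix @ v.theta
             for v in config.variants}

    status_l, strat_l, pcs_l, pats_l = [], [], [], []
    dos_l = {v.variant_id: [] for v in config.variants}
    all_cells = []
    for sname, (n_cases, n_controls) in config.strata.items():
        codes = simulate_markers(n_cases, config.marker_model, rng)
        cid = marker_codes_to_cells(codes, schema)
        all_cells.append(cid)
        masked = apply_mar(codes, config.missing_rates, rng,
                           stratum=np.full(n_cases, sname),
                           er_observed_factors=config.er_observed_factors)
        pats_l.extend(codes_to_patterns(masked, schema))
        pats_l.extend([ObservedPattern((None,) * 4)] * n_controls)
        status_l.append(np.concatenate([np.ones(n_cases, int),
                                        np.zeros(n_controls, int)]))
        strat_l.append(np.full(n_cases + n_controls, sname))
        pcs_l.append(rng.standard_normal((n_cases + n_controls, config.n_pcs)))
        for v in config.variants:
            g_case = case_genotypes(cid, betas[v.variant_id], v.maf, rng,
                                    noise=config.dosage_noise)
            g_ctrl = simulate_genotypes(n_controls, v.maf, rng,
                                        noise=config.dosage_noise)
            dos_l[v.variant_id].append(np.concatenate([g_case, g_ctrl]))

    status = np.concatenate(status_l)
    stratum = np.concatenate(strat_l)
    dosages = np.vstack([np.concatenate(dos_l[v.variant_id])
                         for v in config.variants])
    data = CohortData(status=status, patterns=pats_l,
                      covariates=np.vstack(pcs_l), stratum=stratum,
                      dosages=dosages,
                      variant_ids=[v.variant_id for v in config.variants],
                      schema=schema)

    cid_all = np.concatenate(all_cells)
    cell_freqs = np.bincount(cid_all, minlength=len(cells)) / cid_all.shape[0]
    subtype_logor = {}
    for v in config.variants:
        beta = betas[v.variant_id]
        by_sub = {}
        for lab in set(map_intrinsic(c) for c in cells):
            idx = [c.cell_id for c in cells if map_intrinsic(c) == lab]
            w = cell_freqs[idx]
            by_sub[lab] = float((beta[idx] * w).sum() / w.sum()) if w.sum() > 0 else np.nan
        subtype_logor[v.variant_id] = by_sub
    truth = TruthRecord(
        theta_true={v.variant_id: v.theta.copy() for v in config.variants},
        beta_true=betas,
        subtype_logor=subtype_logor,
        design_kind={v.variant_id: v.design_kind for v in config.variants},
        cell_freqs=cell_freqs,
    )
    return data, truth
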