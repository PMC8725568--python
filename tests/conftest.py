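import numpy as np
import pytest

from tumorhet import MarkerModel, SimulationConfig, VariantSpec, simulate_cohort

FLAT_PREVALENCES = {
    "ER": {"neg": 0.5, "pos": 0.5},
    "PR": {"neg": 0.5, "pos": 0.5},
    "HER2": {"neg": 0.5, "pos": 0.5},
    "grade": {"1": 1 / 3, "2": 1 / 3, "3": 1 / 3},
}


def flat_marker_model():
    """Independent markers with flat margins: every cell well populated.

    Used for saturated-design oracle tests, where rare cells of the
    realistic marker mix would sit at boundary (separation-like) optima.
    """
    return MarkerModel(prevalences=FLAT_PREVALENCES, latent_corr=np.eye(4))


def make_cohort(n_cases=2000, n_controls=2000, theta=None, maf=0.25,
                missing_rates=None, n_pcs=0, seed=0, strata=None, flat=False,
                **kwargs):
    """One-stratum synthetic cohort with a single variant 'v'."""
    theta = np.zeros(5) if theta is None else np.asarray(theta, float)
    if flat:
        kwargs["marker_model"] = flat_marker_model()
    cfg = SimulationConfig(
        strata=strata or {"s": (n_cases, n_controls)},
        variants=[VariantSpec("v", maf, theta)],
        missing_rates={} if missing_rates is None else missing_rates,
        n_pcs=n_pcs, seed=seed, **kwargs)
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def complete_cohort():
    """Fully observed markers, modest heterogeneity."""
    return make_cohort(theta=[0.1, 0.1, -0.05, 0.05, 0.03], seed=101)


@pytest.fixture(scope="session")
def mar_cohort():
    """Reference missingness rates, modest heterogeneity."""
    rates = {"ER": 0.19, "PR": 0.27, "HER2": 0.46, "grade": 0.27}
    return make_cohort(theta=[0.1, 0.1, -0.05, 0.05, 0.03],
                       missing_rates=rates, n_pcs=2, seed=102)
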