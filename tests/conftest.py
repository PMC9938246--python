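import numpy as np
import pytest

from ferromr.simulate import SimulationParams, make_two_sample_dataset, simulate_cohort
from ferromr.summary import HarmonisedInstrument


@pytest.fixture(scope="session")
def small_params():
    """Cheap parameters for unit tests that only need structural behaviour."""
    return SimulationParams(
        n_exposure_sample=4000, n_outcome_sample=4000, n_snps=8,
        outcome_prevalence=0.05, seed=42,
    )


@pytest.fixture(scope="session")
def small_cohort(small_params):
    return simulate_cohort(small_params, "outcome")


@pytest.fixture(scope="session")
def medium_dataset():
    """One realistic-size two-sample dataset reused across recovery tests."""
    params = SimulationParams(seed=7)
    return params, make_two_sample_dataset(params)


def make_instruments(gamma, Gamma, gamma_se=0.01, Gamma_se=0.01):
    """Hand-built harmonised instruments for estimator arithmetic tests."""
    gamma = np.asarray(gamma, dtype=float)
    Gamma = np.asarray(Gamma, dtype=float)
    gse = np.broadcast_to(np.asarray(gamma_se, dtype=float), gamma.shape)
    Gse = np.broadcast_to(np.asarray(Gamma_se, dtype=float), Gamma.shape)
    return [
        HarmonisedInstrument(f"s{i}", float(g), float(gs), float(G), float(Gs), "kept")
        for i, (g, gs, G, Gs) in enumerate(zip(gamma, gse, Gamma, Gse))
    ]
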