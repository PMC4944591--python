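"""Shared fixture models for the test suite.

These are the seeded study-condition models used throughout: a single
exponential phase without PA (mean activity time 20, so ~20 contacts per
day), a two-phase model with moderate attachment (tau = 0.05, mean ~6.8
contacts, finite second moment, divergent third — a realistically heavy
contact tail), and a three-phase light-tail model.
"""

import numpy as np
import pytest

from prefattach import PAModel, PhaseTypeSpec


def single_nopa(mu: float = 0.05) -> PAModel:
    return PAModel(PhaseTypeSpec.single(mu))


def two_phase_pa(tau: float = 0.05) -> PAModel:
    spec = PhaseTypeSpec(
        nu=np.array([0.6, 0.4]),
        mu=np.array([0.5, 0.15]),
        Q=np.array([[0.0, 0.2], [0.0, 0.0]]),
    )
    return PAModel(spec, tau=tau, pa=tau > 0)


def three_phase_pa(tau: float = 0.02) -> PAModel:
    spec = PhaseTypeSpec(
        nu=np.array([0.5, 0.3, 0.2]),
        mu=np.array([0.4, 0.1, 0.6]),
        Q=np.array([[0.0, 0.3, 0.1], [0.0, 0.0, 0.2], [0.0, 0.0, 0.0]]),
    )
    return PAModel(spec, tau=tau, pa=tau > 0)


def random_model(rng: np.random.Generator, m: int, tau_max: float = 0.1) -> PAModel:
    """A random valid model with light enough tails for numeric oracles."""
    nu = rng.dirichlet(np.ones(m))
    mu = np.exp(rng.uniform(np.log(0.2), np.log(2.0), size=m))
    Q = np.zeros((m, m))
    iu = np.triu_indices(m, k=1)
    Q[iu] = np.exp(rng.uniform(np.log(0.05), np.log(1.0), size=len(iu[0])))
    tau = rng.uniform(0.0, tau_max)
    return PAModel(PhaseTypeSpec(nu=nu, mu=mu, Q=Q), tau=tau, pa=tau > 0)


@pytest.fixture(scope="session")
def fixture_models() -> dict[str, PAModel]:
    return {
        "single_nopa": single_nopa(),
        "two_phase_pa": two_phase_pa(),
        "three_phase_pa": three_phase_pa(),
    }
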