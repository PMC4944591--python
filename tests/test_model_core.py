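"""Unit and property tests for the conditional contact process and the
phase-type stopping-time law."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad

from prefattach import (
    DegreeCounts,
    PAModel,
    PhaseTypeSpec,
    count_parameters,
    holding_time_cdf,
    holding_time_pdf,
    moment_conditional,
    pgf_conditional,
    pmf_conditional,
)

from conftest import random_model


# ---------------------------------------------------------------------------
# specification validation
# ---------------------------------------------------------------------------

def test_minimal_single_phase_valid():
    spec = PhaseTypeSpec(nu=[1.0], mu=[0.05], Q=np.zeros((1, 1)))
    assert spec.m == 1
    assert spec.total_exit[0] == pytest.approx(0.05)


def test_erlang_chain_valid_when_exit_via_transition_only():
    spec = PhaseTypeSpec(nu=[1, 0], mu=[0, 1.0], Q=[[0, 1.0], [0, 0]])
    assert spec.total_exit[0] == pytest.approx(1.0)


@pytest.mark.parametrize(
    "kwargs, match",
    [
        (dict(nu=[1, 0], mu=[0, 1.0], Q=np.zeros((2, 2))), "zero exit rate"),
        (dict(nu=[0.5, 0.4], mu=[1, 1], Q=np.zeros((2, 2))), "sum to 1"),
        (dict(nu=[1, 0], mu=[-1, 1], Q=np.zeros((2, 2))), "non-negative"),
        (dict(nu=[1, 0], mu=[1, 1], Q=[[0, 0], [1.0, 0]]), "upper triangular"),
        (dict(nu=[1, 0], mu=[1, 1], Q=[[0, -1.0], [0, 0]]), "non-negative"),
    ],
)
def test_invalid_specs_name_the_broken_invariant(kwargs, match):
    with pytest.raises(ValueError, match=match):
        PhaseTypeSpec(**kwargs)


def test_no_pa_model_requires_tau_zero():
    spec = PhaseTypeSpec.single(1.0)
    with pytest.raises(ValueError, match="tau = 0"):
        PAModel(spec, tau=0.5, pa=False)
    with pytest.raises(ValueError, match=">= 0"):
        PAModel(spec, tau=-0.1, pa=True)


def test_degree_counts_reject_zero_and_negative_degrees():
    with pytest.raises(ValueError, match="censored"):
        DegreeCounts(counts={0: 5, 1: 2})
    with pytest.raises(ValueError, match="censored|impossible"):
        DegreeCounts(counts={-1: 5})
    y = DegreeCounts(counts={1: 3, 2: 1})
    assert y.n == 4 and y.max_degree == 2


# ---------------------------------------------------------------------------
# parameter counting (free parameters per model)
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "m, pa, expected",
    [(1, False, 1), (2, False, 4), (3, False, 8), (4, False, 13), (5, False, 19),
     (6, False, 26), (1, True, 2), (2, True, 5), (3, True, 9), (4, True, 14),
     (5, True, 20), (6, True, 27)],
)
def test_count_parameters_full_grid(m, pa, expected):
    """(m-1) simplex + m stop rates + m(m-1)/2 transitions (+1 for tau)."""
    nu = np.zeros(m)
    nu[0] = 1.0
    spec = PhaseTypeSpec(nu=nu, mu=np.ones(m), Q=np.zeros((m, m)))
    model = PAModel(spec, tau=0.01 if pa else 0.0, pa=pa)
    assert count_parameters(model) == expected


# ---------------------------------------------------------------------------
# conditional PGF / pmf / moments
# ---------------------------------------------------------------------------

def test_pgf_normalization_and_degenerate_time():
    for tau in (0.0, 0.3, 1.0):
        assert pgf_conditional(tau, 2.5, 1.0) == pytest.approx(1.0)
        assert pgf_conditional(tau, 0.0, 0.37) == pytest.approx(1.0)


def test_pgf_hand_value_at_tau_one():
    # (0.5 - (0.5 - 1) * 2)^{-1} = 1 / 1.5
    assert pgf_conditional(1.0, math.log(2.0), 0.5) == pytest.approx(2.0 / 3.0)


def test_pgf_rejects_domain_violations():
    with pytest.raises(ValueError):
        pgf_conditional(0.5, -1.0, 0.5)
    with pytest.raises(ValueError):
        pgf_conditional(0.5, 1.0, 1.5)
    with pytest.raises(ValueError):
        pgf_conditional(-0.5, 1.0, 0.5)


@given(
    tau=st.sampled_from([0.0, 1e-12, 0.02, 0.5, 1.0, 2.0]),
    t=st.floats(0.0, 20.0),
    s=st.floats(0.0, 1.0),
)
@settings(deadline=None, max_examples=80, derandomize=True)
def test_pgf_is_a_probability_generating_function(tau, t, s):
    val = pgf_conditional(tau, t, s)
    assert 0.0 < val <= 1.0 + 1e-12


def test_pmf_poisson_limit_without_attachment():
    ks = np.arange(30)
    from scipy.special import gammaln

    expected = np.exp(-2.0 + ks * math.log(2.0) - gammaln(ks + 1.0))
    np.testing.assert_allclose(pmf_conditional(0.0, 2.0, ks), expected, atol=1e-14)
    # tiny tau routes through the same analytic limit
    np.testing.assert_allclose(pmf_conditional(1e-12, 2.0, ks), expected, atol=1e-12)


def test_pmf_geometric_at_tau_one():
    t = 1.3
    ks = np.arange(40)
    expected = math.exp(-t) * (1.0 - math.exp(-t)) ** ks
    np.testing.assert_allclose(pmf_conditional(1.0, t, ks), expected, atol=1e-14)


@pytest.mark.parametrize(
    "tau, t",
    # combinations whose conditional mean keeps direct summation feasible
    [(0.0, 0.5), (0.0, 5.0), (0.0, 50.0), (0.02, 0.5), (0.02, 5.0), (0.02, 50.0),
     (0.5, 0.5), (0.5, 5.0), (1.0, 0.5), (1.0, 5.0), (2.0, 0.5), (2.0, 5.0)],
)
def test_pmf_sums_to_one(tau, t):
    # adaptive truncation: extend until the summand is negligible
    total, k0, block = 0.0, 0, 4096
    while True:
        chunk = pmf_conditional(tau, t, np.arange(k0, k0 + block))
        total += chunk.sum()
        k0 += block
        if chunk[-1] < 1e-18 * max(total, 1e-300) or k0 > 5_000_000:
            break
    assert total == pytest.approx(1.0, abs=5e-10)


@pytest.mark.parametrize("tau, t", [(0.5, 50.0), (1.0, 50.0), (2.0, 50.0)])
def test_pmf_partial_sums_match_negative_binomial_cdf(tau, t):
    """In the regime where the conditional mean is astronomically large,
    direct summation to 1 is infeasible; instead the partial sums must
    match the negative-binomial CDF (independent library implementation
    of the same law: 1/tau successes with probability e^{-tau t})."""
    from scipy.stats import nbinom

    ks = np.arange(0, 3000, 97)
    partial = np.cumsum(pmf_conditional(tau, t, np.arange(3000)))[ks]
    oracle = nbinom.cdf(ks, 1.0 / tau, math.exp(-tau * t))
    np.testing.assert_allclose(partial, oracle, rtol=1e-9, atol=1e-300)


def _taylor_coefficients_via_fft(tau, t, n_coeff, radius=0.5, n_grid=4096):
    """Independent series-extraction oracle: Cauchy-integral coefficients
    of g(t, s) on the complex circle |s| = radius, via FFT."""
    theta = 2.0 * np.pi * np.arange(n_grid) / n_grid
    s = radius * np.exp(1j * theta)
    vals = pgf_conditional(tau, t, s)
    coeffs = np.fft.fft(vals) / n_grid
    return (coeffs[:n_coeff] / radius ** np.arange(n_coeff)).real


@pytest.mark.parametrize("tau, t", [(0.0, 3.0), (0.05, 10.0), (0.7, 2.0), (2.0, 1.0)])
def test_pmf_matches_taylor_coefficients_of_pgf(tau, t):
    oracle = _taylor_coefficients_via_fft(tau, t, 31)
    np.testing.assert_allclose(pmf_conditional(tau, t, np.arange(31)), oracle, atol=1e-8)


def test_conditional_moments_closed_forms():
    tau, t = 0.5, 2.0
    m1 = (math.exp(tau * t) - 1.0) / tau
    assert moment_conditional(tau, t, 1) == pytest.approx(m1, rel=1e-12)
    assert moment_conditional(tau, t, 2) == pytest.approx(m1 + (tau + 1) * m1**2, rel=1e-12)
    assert moment_conditional(0.0, 7.3, 1) == pytest.approx(7.3)


@pytest.mark.parametrize("r", [1, 2, 3, 4])
def test_conditional_moments_match_truncated_pmf_sums(r):
    tau, t = 0.3, 2.0
    ks = np.arange(4000)
    s = float((ks.astype(float) ** r) @ pmf_conditional(tau, t, ks))
    assert moment_conditional(tau, t, r) == pytest.approx(s, rel=1e-6)


def test_third_moment_matches_mgf_finite_differences():
    tau, t = 0.2, 3.0
    h = 1e-3
    # 5-point central third derivative of M(z) = g(t, e^z) at z = 0
    zs = np.array([-2, -1, 1, 2]) * h
    vals = np.array([pgf_conditional(tau, t, math.exp(z)) if z <= 0
                     else float((math.exp(z) - (math.exp(z) - 1) * math.exp(tau * t)) ** (-1 / tau))
                     for z in zs])
    d3 = (-0.5 * vals[0] + vals[1] - vals[2] + 0.5 * vals[3]) / h**3
    assert moment_conditional(tau, t, 3) == pytest.approx(d3, rel=1e-4)


# ---------------------------------------------------------------------------
# phase-type stopping-time density
# ---------------------------------------------------------------------------

def test_single_phase_density_is_exponential():
    spec = PhaseTypeSpec.single(0.05)
    ts = np.array([0.0, 1.0, 10.0, 40.0])
    np.testing.assert_allclose(holding_time_pdf(spec, ts), 0.05 * np.exp(-0.05 * ts), rtol=1e-12)


def test_two_phase_chain_gives_erlang_density():
    lam = 2.0
    spec = PhaseTypeSpec(nu=[1, 0], mu=[0, lam], Q=[[0, lam], [0, 0]])
    ts = np.linspace(0.1, 5.0, 7)
    np.testing.assert_allclose(
        holding_time_pdf(spec, ts), lam**2 * ts * np.exp(-lam * ts), rtol=1e-10
    )


@pytest.mark.parametrize("m_seed", [(1, 0), (2, 1), (3, 2)])
def test_density_integrates_to_one_and_matches_cdf(m_seed):
    m, seed = m_seed
    model = random_model(np.random.default_rng(seed), m)
    spec = model.phases
    total, err = quad(lambda t: holding_time_pdf(spec, t), 0, np.inf, limit=200)
    assert total == pytest.approx(1.0, abs=1e-8)
    t0 = 3.0
    part, _ = quad(lambda t: holding_time_pdf(spec, t), 0, t0, limit=200)
    assert holding_time_cdf(spec, t0) == pytest.approx(part, abs=1e-8)
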