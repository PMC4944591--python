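"""Core model objects for the preferential-attachment contact process.

An individual starts with zero contacts and gains contacts one at a time:
with ``k`` contacts already made, a new contact arrives at rate
``f_k = 1 + tau * k``.  Time is measured in units of the baseline
contact-making rate, so the only free attachment parameter is ``tau``;
preferential attachment (PA) is the hypothesis ``tau > 0``.

The time an individual spends making contacts is a phase-type random
variable: a continuous-time Markov chain over ``m`` activity "phases"
that can only move forward (phase indices increase) and is absorbed
("stops making contacts") at a per-phase rate.  Phase-type laws are dense
in the positive distributions, so this family can approximate essentially
any stopping-time distribution while remaining cheap to fit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from functools import lru_cache

import numpy as np
from scipy.linalg import expm
from scipy.special import gammaln

__all__ = [
    "TAU_EPS",
    "PhaseTypeSpec",
    "PAModel",
    "DegreeCounts",
    "validate",
    "count_parameters",
    "pgf_conditional",
    "pmf_conditional",
    "moment_conditional",
    "holding_time_pdf",
    "holding_time_cdf",
]

#: below this value of tau all 1/tau expressions switch to their analytic
#: tau -> 0 limits (Poisson / polynomial forms) to avoid catastrophic
#: cancellation.
TAU_EPS = 1e-8


@dataclass(frozen=True)
class PhaseTypeSpec:
    """Specification of the phase-type stopping-time machine.

    Parameters
    ----------
    nu : array of shape (m,)
        Initial-phase probabilities; must sum to one.
    mu : array of shape (m,)
        Per-phase stop (absorption) rates, per unit time.
    Q : array of shape (m, m)
        Phase-transition rates ``Q[a, b]`` for moving from phase ``a`` to
        phase ``b``.  Strictly upper triangular: phases are visited in
        increasing order only.
    """

    nu: np.ndarray
    mu: np.ndarray
    Q: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "nu", np.asarray(self.nu, dtype=float))
        object.__setattr__(self, "mu", np.asarray(self.mu, dtype=float))
        q = np.asarray(self.Q, dtype=float)
        if q.size == 0:
            q = np.zeros((len(self.mu), len(self.mu)))
        object.__setattr__(self, "Q", q)
        validate(self)

    @property
    def m(self) -> int:
        """Number of phases."""
        return len(self.mu)

    @property
    def total_exit(self) -> np.ndarray:
        """Total exit rate of each phase, ``M_a = mu_a + sum_{b>a} Q[a,b]``."""
        return self.mu + self.Q.sum(axis=1)

    @property
    def generator(self) -> np.ndarray:
        """Lower-triangular generator ``G`` of the phase-occupancy ODE.

        The occupancy vector ``pi(t)`` (probability of still being active
        and in each phase) satisfies ``dpi/dt = G pi`` with ``pi(0) = nu``:
        ``G[a, a] = -M_a`` and ``G[a, b] = Q[b, a]`` for ``b < a``.
        """
        return self.Q.T - np.diag(self.total_exit)

    def reachable(self) -> np.ndarray:
        """Boolean mask of phases visited with positive probability."""
        reach = self.nu > 0
        for a in range(self.m):
            if reach[a]:
                reach |= self.Q[a] > 0
        return reach

    @classmethod
    def single(cls, mu: float) -> "PhaseTypeSpec":
        """Convenience: one exponential phase with stop rate ``mu``."""
        return cls(nu=np.array([1.0]), mu=np.array([float(mu)]), Q=np.zeros((1, 1)))


def validate(spec: PhaseTypeSpec) -> PhaseTypeSpec:
    """Check every invariant of a :class:`PhaseTypeSpec`.

    Returns the spec unchanged if valid; raises :class:`ValueError` naming
    the violated invariant otherwise.
    """
    nu, mu, Q = spec.nu, spec.mu, spec.Q
    m = len(mu)
    if m < 1:
        raise ValueError("at least one phase is required")
    if nu.shape != (m,):
        raise ValueError(f"nu has shape {nu.shape}, expected ({m},)")
    if Q.shape != (m, m):
        raise ValueError(f"Q has shape {Q.shape}, expected ({m}, {m})")
    if np.any(nu < 0):
        raise ValueError("initial probabilities nu must be non-negative")
    if abs(nu.sum() - 1.0) > 1e-9:
        raise ValueError(f"initial probabilities must sum to 1 (got {nu.sum():g})")
    if np.any(mu < 0):
        raise ValueError("stop rates mu must be non-negative")
    if np.any(Q < 0):
        raise ValueError("transition rates Q must be non-negative")
    if np.any(np.tril(Q) != 0):
        raise ValueError("Q must be strictly upper triangular (forward phase moves only)")
    total = mu + Q.sum(axis=1)
    for a, M_a in enumerate(total):
        if M_a <= 0:
            raise ValueError(
                f"phase {a + 1} has zero exit rate: the process would never stop"
            )
    return spec


@dataclass(frozen=True)
class PAModel:
    """A phase-type stopping model plus the attachment coefficient tau.

    ``pa`` records whether tau is a free parameter of the model (the PA
    hypothesis); a no-PA model has ``tau == 0`` exactly.
    """

    phases: PhaseTypeSpec
    tau: float = 0.0
    pa: bool | None = None

    def __post_init__(self) -> None:
        if self.pa is None:
            object.__setattr__(self, "pa", self.tau > 0)
        if self.tau < 0:
            raise ValueError("attachment coefficient tau must be >= 0")
        if not self.pa and self.tau != 0:
            raise ValueError("a no-PA model must have tau = 0 exactly")

    @property
    def m(self) -> int:
        return self.phases.m

    def contact_rate(self, k: int | np.ndarray) -> np.ndarray:
        """Rate ``f_k = 1 + tau k`` of forming the next contact."""
        return 1.0 + self.tau * np.asarray(k, dtype=float)

    def without_pa(self) -> "PAModel":
        """The same phase machine with the attachment term switched off."""
        return PAModel(phases=self.phases, tau=0.0, pa=False)


def count_parameters(model: PAModel) -> int:
    """Number of free parameters of a model.

    ``m - 1`` for the initial distribution (simplex constraint), ``m`` stop
    rates, ``m (m - 1) / 2`` strictly upper-triangular transition rates,
    plus one for tau when PA is included.
    """
    m = model.m
    return (m - 1) + m + m * (m - 1) // 2 + (1 if model.pa else 0)


@dataclass(frozen=True)
class DegreeCounts:
    """Observed contact-count data: ``counts[k]`` respondents reported
    ``k`` contacts.  Zero counts are censored (respondents reporting no
    contacts are absent from the data), so all degrees are >= 1; the
    zero-truncated likelihood never sees them.  ``zeros`` can carry the
    number of zero reports as metadata (e.g. from an uncensored
    simulation) but they are not part of ``counts`` or ``n``."""

    counts: dict[int, int] = field(default_factory=dict)
    zeros: int = 0

    def __post_init__(self) -> None:
        clean: dict[int, int] = {}
        for k, y in sorted(self.counts.items()):
            ki, yi = int(k), int(y)
            if ki != k or yi != y:
                raise ValueError(f"degree and count must be integers (got {k}: {y})")
            if ki <= 0:
                raise ValueError(
                    "degree 0 is censored in contact-count data (and negative "
                    "degrees are impossible); remove zero rows from the input"
                )
            if yi < 0:
                raise ValueError(f"negative count for degree {ki}")
            if yi > 0:
                clean[ki] = yi
        object.__setattr__(self, "counts", clean)
        if not clean:
            raise ValueError("no respondents with positive counts")

    @property
    def n(self) -> int:
        """Total number of respondents."""
        return sum(self.counts.values())

    @property
    def max_degree(self) -> int:
        return max(self.counts)

    def arrays(self) -> tuple[np.ndarray, np.ndarray]:
        """Degrees and counts as aligned integer arrays."""
        ks = np.fromiter(self.counts.keys(), dtype=np.int64)
        ys = np.fromiter(self.counts.values(), dtype=np.int64)
        return ks, ys

    def expand(self) -> np.ndarray:
        """Per-respondent degree vector (for resampling)."""
        ks, ys = self.arrays()
        return np.repeat(ks, ys)

    @classmethod
    def from_degrees(cls, degrees) -> "DegreeCounts":
        """Tabulate a raw vector of per-respondent degrees."""
        vals, cnts = np.unique(np.asarray(degrees, dtype=np.int64), return_counts=True)
        return cls(counts={int(k): int(c) for k, c in zip(vals, cnts)})


# ---------------------------------------------------------------------------
# Conditional (fixed stopping time t) distribution of the pure-birth process
# ---------------------------------------------------------------------------

def pgf_conditional(tau: float, t: float, s):
    """Probability generating function ``g(t, s)`` of the contact count at
    time ``t``, ``g(t, s) = (s - (s - 1) e^{tau t})^{-1/tau}``.

    At ``tau = 0`` the analytic limit is the Poisson PGF ``exp(t (s - 1))``.
    ``s`` may be real in [0, 1] or complex (used by series-extraction
    oracles); domain checks apply to real input only.
    """
    if t < 0:
        raise ValueError("time t must be >= 0")
    if tau < 0:
        raise ValueError("tau must be >= 0")
    s = np.asarray(s)
    if not np.iscomplexobj(s) and (np.any(s < 0) or np.any(s > 1)):
        raise ValueError("pgf argument s must lie in [0, 1]")
    if tau < TAU_EPS:
        out = np.exp(t * (s - 1.0))
    else:
        out = (s - (s - 1.0) * math.exp(tau * t)) ** (-1.0 / tau)
    return out if out.ndim else out[()]


def pmf_conditional(tau: float, t: float, k) -> np.ndarray:
    """Probability of holding exactly ``k`` contacts at time ``t``.

    The Taylor expansion of the PGF gives a negative-binomial law: the
    number of failures before ``1/tau`` successes with success probability
    ``e^{-tau t}``,

        p_k(t) = e^{-t} * C(k + 1/tau - 1, k) * (1 - e^{-tau t})^k,

    which reduces to Poisson(t) as tau -> 0 and to the geometric
    ``e^{-t} (1 - e^{-t})^k`` at tau = 1.  Evaluated in log space.
    """
    if t < 0:
        raise ValueError("time t must be >= 0")
    if tau < 0:
        raise ValueError("tau must be >= 0")
    k = np.asarray(k)
    if np.any(k < 0) or not np.issubdtype(k.dtype, np.integer):
        raise ValueError("degree k must be a non-negative integer")
    kf = k.astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        if tau < TAU_EPS:
            # Poisson(t); log(0 * t) handled below for t == 0
            logp = -t + kf * np.log(t) - gammaln(kf + 1.0) if t > 0 else np.where(k == 0, 0.0, -np.inf)
        else:
            r = 1.0 / tau
            logq = np.log(-np.expm1(-tau * t)) if t > 0 else -np.inf
            logp = np.where(
                (k == 0) & (t == 0.0),
                0.0,
                -t + kf * logq + gammaln(kf + r) - gammaln(r) - gammaln(kf + 1.0),
            )
    out = np.exp(logp)
    return out if out.ndim else float(out)


@lru_cache(maxsize=None)
def _stirling2(r: int, j: int) -> int:
    """Stirling numbers of the second kind, S(r, j)."""
    if r == j:
        return 1
    if j == 0 or j > r:
        return 0
    return j * _stirling2(r - 1, j) + _stirling2(r - 1, j - 1)


def moment_conditional(tau: float, t: float, r: int) -> float:
    """``r``-th raw moment of the contact count at fixed time ``t``.

    Computed from negative-binomial factorial moments via Stirling numbers:
    ``E[K^r] = sum_j S(r, j) * Gamma(1/tau + j)/Gamma(1/tau) * (e^{tau t}-1)^j``.
    Reproduces ``m_1 = (e^{tau t} - 1)/tau`` and
    ``m_2 = m_1 + (tau + 1) m_1^2``; as tau -> 0 the factorial moments
    degenerate to ``t^j`` (Poisson/Touchard form).
    """
    if r < 1 or int(r) != r:
        raise ValueError("moment order r must be a positive integer")
    if t < 0 or tau < 0:
        raise ValueError("t and tau must be >= 0")
    total = 0.0
    for j in range(1, int(r) + 1):
        if tau < TAU_EPS:
            fm = t**j
        else:
            R = 1.0 / tau
            poch = math.exp(gammaln(R + j) - gammaln(R))
            fm = poch * math.expm1(tau * t) ** j
        total += _stirling2(int(r), j) * fm
    return total


# ---------------------------------------------------------------------------
# Phase-type stopping-time distribution
# ---------------------------------------------------------------------------

def holding_time_pdf(spec: PhaseTypeSpec, t) -> np.ndarray:
    """Density ``rho(t) = mu^T exp(G t) nu`` of the stopping time.

    ``G`` is the lower-triangular occupancy generator whose diagonal entry
    for phase ``a`` is ``-M_a`` (total exit rate); with that convention
    ``rho`` integrates to one.
    """
    t_arr = np.atleast_1d(np.asarray(t, dtype=float))
    if np.any(t_arr < 0):
        raise ValueError("time t must be >= 0")
    G = spec.generator
    out = np.array([spec.mu @ expm(G * ti) @ spec.nu for ti in t_arr])
    return out if np.ndim(t) else float(out[0])


def holding_time_cdf(spec: PhaseTypeSpec, t) -> np.ndarray:
    """Distribution function of the stopping time,
    ``F(t) = 1 - 1^T exp(G t) nu`` (one minus the still-active mass)."""
    t_arr = np.atleast_1d(np.asarray(t, dtype=float))
    if np.any(t_arr < 0):
        raise ValueError("time t must be >= 0")
    G = spec.generator
    ones = np.ones(spec.m)
    out = np.array([1.0 - ones @ expm(G * ti) @ spec.nu for ti in t_arr])
    return out if np.ndim(t) else float(out[0])
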