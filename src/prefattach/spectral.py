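"""Unconditional degree distribution via the triangular spectral recursion.

Mixing the pure-birth contact process over the phase-type stopping time
gives the degree distribution ``d_k`` of a randomly selected individual.
Laplace-transforming the phase/degree occupancy ODEs and taking the
zero-frequency limit yields a *triangular* linear system in the auxiliary
quantities ``A_{a,k}`` (time-integrated occupancy of phase ``a`` at degree
``k``), which is solved by forward substitution in increasing (a, k)
order at cost O(m^2 kmax) — no matrix inversion, no quadrature:

    A_{a,0} = (nu_a + sum_{b<a} Q[b,a] A_{b,0}) / (f_0 + M_a)
    A_{a,k} = (f_{k-1} A_{a,k-1} + sum_{b<a} Q[b,a] A_{b,k}) / (f_k + M_a)
    d_k     = sum_a mu_a A_{a,k}

Moments of ``d`` and the divergence diagnostic come from the triangular
resolvent: the r-th moment involves ``I_r = int e^{r tau t} rho(t) dt``,
which is finite exactly when ``r tau < M_a`` for every reachable phase a.
A divergent second moment would mean unbounded degree heterogeneity and,
epidemiologically, loss of control by untargeted vaccination.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace

import numpy as np
from numba import njit
from scipy.linalg import solve_triangular

from .model_core import TAU_EPS, PAModel

__all__ = [
    "DegreeDistribution",
    "DivergenceReport",
    "degree_pmf",
    "censor_zero",
    "moment",
    "lowest_divergent_moment",
]


@dataclass(frozen=True)
class DegreeDistribution:
    """Degree pmf up to a truncation index.

    ``d[k]`` is the probability of degree ``k`` for ``k = 0..kmax``;
    ``tail_mass`` is the probability beyond ``kmax``.  A censored
    distribution is zero-truncated (``d[0] = 0``, remaining mass
    renormalized), matching how the survey data exclude respondents who
    reported no contacts.
    """

    d: np.ndarray
    tail_mass: float
    censored: bool = False

    @property
    def kmax(self) -> int:
        return len(self.d) - 1

    def mean(self) -> float:
        """Mean of the truncated part (ignores tail mass)."""
        return float(np.arange(len(self.d)) @ self.d)

    def truncated_moment(self, r: int) -> float:
        """``sum_{k<=kmax} k^r d_k``; a lower bound on the r-th moment."""
        return float((np.arange(len(self.d), dtype=float) ** r) @ self.d)


@dataclass(frozen=True)
class DivergenceReport:
    """Which degree moments are infinite: moment r diverges iff
    ``r * tau >= M_a`` for some phase a reachable with positive
    probability (the boundary case is classified divergent)."""

    per_moment: dict[int, bool]
    lowest_divergent: int | None

    def is_divergent(self, r: int) -> bool:
        return self.per_moment[r]


@njit(cache=True)
def _a_recursion(nu, mu, Q, M, tau, kmax):  # pragma: no cover - jitted
    m = nu.shape[0]
    A = np.zeros((m, kmax + 1))
    d = np.zeros(kmax + 1)
    for k in range(kmax + 1):
        f_k = 1.0 + tau * k
        f_km1 = 1.0 + tau * (k - 1)
        for a in range(m):
            if k == 0:
                acc = nu[a]
            else:
                acc = f_km1 * A[a, k - 1]
            for b in range(a):
                acc += Q[b, a] * A[b, k]
            A[a, k] = acc / (f_k + M[a])
        for a in range(m):
            d[k] += mu[a] * A[a, k]
    return A, d


def degree_pmf(
    model: PAModel,
    kmax: int | None = None,
    *,
    tail_tol: float = 1e-10,
    kmax_cap: int = 100_000,
    tail_warn: float = 1e-6,
) -> DegreeDistribution:
    """Degree distribution ``d_k`` of the model.

    With ``kmax=None`` the truncation index is chosen adaptively: it is
    doubled until the tail mass drops below ``tail_tol`` or ``kmax_cap``
    is reached.  An explicit ``kmax`` (e.g. the largest observed degree
    when fitting) is honoured as given; if it leaves more than
    ``tail_warn`` probability in the tail a warning is issued.  The tail
    is never silently renormalized away.
    """
    spec = model.phases
    nu, mu, Q, M = spec.nu, spec.mu, spec.Q, spec.total_exit
    if kmax is not None:
        if kmax < 0:
            raise ValueError("kmax must be >= 0")
        _, d = _a_recursion(nu, mu, Q, M, model.tau, int(kmax))
        tail = max(1.0 - d.sum(), 0.0)
        if tail > tail_warn:
            warnings.warn(
                f"truncation at kmax={kmax} leaves tail mass {tail:.3g}; "
                "consider a larger kmax",
                stacklevel=2,
            )
        return DegreeDistribution(d=d, tail_mass=tail)
    k = 256
    while True:
        _, d = _a_recursion(nu, mu, Q, M, model.tau, k)
        tail = max(1.0 - d.sum(), 0.0)
        if tail < tail_tol or k >= kmax_cap:
            break
        k = min(2 * k, kmax_cap)
    if tail >= tail_tol:
        warnings.warn(
            f"adaptive truncation hit the cap kmax={k} with tail mass "
            f"{tail:.3g} (heavy tail; check moment divergence)",
            stacklevel=2,
        )
    return DegreeDistribution(d=d, tail_mass=tail)


def censor_zero(dist: DegreeDistribution) -> DegreeDistribution:
    """Zero-truncate a degree distribution:
    ``d~_0 = 0`` and ``d~_k = d_k / (1 - d_0)`` for k > 0.

    Idempotent; fails when all mass sits at zero."""
    if dist.censored:
        return dist
    d0 = dist.d[0] if len(dist.d) else 0.0
    if d0 >= 1.0:
        raise ValueError("d_0 = 1: every individual reports zero contacts")
    d = dist.d.copy()
    d[0] = 0.0
    d /= 1.0 - d0
    return DegreeDistribution(d=d, tail_mass=dist.tail_mass / (1.0 - d0), censored=True)


def _resolvent_integral(model: PAModel, r: int) -> float:
    """``I_r = int_0^inf e^{r tau t} rho(t) dt = mu^T (-(G + r tau I))^{-1} nu``
    via a single triangular solve (G is lower triangular)."""
    spec = model.phases
    B = -(spec.generator + r * model.tau * np.eye(spec.m))
    x = solve_triangular(B, spec.nu, lower=True)
    return float(spec.mu @ x)


def lowest_divergent_moment(model: PAModel, r_max: int) -> DivergenceReport:
    """Scan moments r = 1..r_max for divergence.

    Moment r is infinite iff ``r tau >= M_a`` for some reachable phase a;
    phases never visited (``nu_a = 0`` and no inbound transitions) are
    ignored.  The boundary ``r tau = M_a`` is counted divergent.
    """
    if r_max < 1:
        raise ValueError("r_max must be >= 1")
    spec = model.phases
    M_reach = spec.total_exit[spec.reachable()]
    per: dict[int, bool] = {}
    lowest: int | None = None
    for r in range(1, int(r_max) + 1):
        div = bool(model.tau > 0 and np.any(r * model.tau >= M_reach))
        per[r] = div
        if div and lowest is None:
            lowest = r
    return DivergenceReport(per_moment=per, lowest_divergent=lowest)


def moment(model: PAModel, r: int) -> float:
    """``r``-th raw moment of the degree distribution (r in {1, 2}).

    Combines the conditional moment polynomials with the resolvent
    integrals ``I_r``:

        m1 = (I_1 - 1) / tau
        m2 = m1 + (tau + 1) (I_2 - 2 I_1 + 1) / tau^2

    with analytic tau -> 0 limits (iterated triangular solves giving
    ``mu^T G^{-2} nu`` and ``-2 mu^T G^{-3} nu``).  Returns ``inf`` when
    the divergence criterion declares the moment infinite.
    """
    if r not in (1, 2):
        raise ValueError("only moments r = 1 and r = 2 are implemented")
    if lowest_divergent_moment(model, r).per_moment[r]:
        return math.inf
    spec = model.phases
    tau = model.tau
    if tau < TAU_EPS:
        G = spec.generator
        x1 = solve_triangular(G, spec.nu, lower=True)
        x2 = solve_triangular(G, x1, lower=True)
        m1 = float(spec.mu @ x2)  # mu^T G^{-2} nu = E[T]
        if r == 1:
            return m1
        x3 = solve_triangular(G, x2, lower=True)
        return m1 + float(-2.0 * spec.mu @ x3)  # E[T] + E[T^2]
    i1 = _resolvent_integral(model, 1)
    m1 = (i1 - 1.0) / tau
    if r == 1:
        return m1
    i2 = _resolvent_integral(model, 2)
    return m1 + (tau + 1.0) * (i2 - 2.0 * i1 + 1.0) / tau**2
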