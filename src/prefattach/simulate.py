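"""Exact Gillespie simulation of the contact-formation process.

Each individual carries a phase ``a`` (initially drawn from ``nu``) and a
contact count ``K`` (initially 0).  Three event families compete with
exponential clocks: make a contact at rate ``1 + tau K``, move to a later
phase ``b`` at rate ``Q[a, b]``, stop at rate ``mu_a``.  Sampling is by
the direct method — total rate, then a categorical event choice — so the
draws are exact, which matters because this module is the independent
oracle against which the spectral solver and the fitted likelihood are
cross-checked.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model_core import DegreeCounts, PAModel

__all__ = ["SimConfig", "simulate_individual", "simulate_degrees", "simulate_counts"]


@dataclass(frozen=True)
class SimConfig:
    """Simulation settings.

    ``censor_zero`` mirrors the survey's reporting convention: respondents
    with zero contacts are discarded *after* simulation (the dynamics are
    not conditioned), and ``n`` then refers to simulated individuals, not
    retained ones.  With ``censor_zero=False`` the zero reports are kept
    as the ``zeros`` metadata field of the returned counts (the count
    table itself always holds positive degrees).
    """

    model: PAModel
    n: int
    seed: int
    censor_zero: bool = True

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("need at least one individual")


def simulate_individual(
    model: PAModel, rng: np.random.Generator, *, return_time: bool = False
):
    """Simulate one individual; returns the final contact count ``k``
    (or ``(k, stopping_time)`` with ``return_time=True``)."""
    spec = model.phases
    tau = model.tau
    mu = spec.mu
    Q = spec.Q
    m = spec.m
    a = int(rng.choice(m, p=spec.nu)) if m > 1 else 0
    k = 0
    t = 0.0
    while True:
        move_rates = Q[a]
        total = 1.0 + tau * k + mu[a] + move_rates.sum()
        if return_time:
            t += rng.exponential(1.0 / total)
        u = rng.random() * total
        if u < 1.0 + tau * k:
            k += 1
        elif u < 1.0 + tau * k + mu[a]:
            return (k, t) if return_time else k
        else:
            u -= 1.0 + tau * k + mu[a]
            b = a + 1
            acc = move_rates[b]
            while acc < u:
                b += 1
                acc += move_rates[b]
            a = b


def simulate_degrees(model: PAModel, n: int, rng: np.random.Generator) -> np.ndarray:
    """Final degrees of ``n`` independent individuals (uncensored)."""
    spec = model.phases
    tau, mu, Q, m = model.tau, spec.mu, spec.Q, spec.m
    move_sum = Q.sum(axis=1)
    out = np.empty(n, dtype=np.int64)
    # flat inner loop; rng.random() per event keeps the draw exact and cheap
    starts = rng.choice(m, size=n, p=spec.nu) if m > 1 else np.zeros(n, dtype=np.int64)
    random = rng.random
    for i in range(n):
        a = starts[i]
        k = 0
        while True:
            contact = 1.0 + tau * k
            total = contact + mu[a] + move_sum[a]
            u = random() * total
            if u < contact:
                k += 1
            elif u < contact + mu[a]:
                out[i] = k
                break
            else:
                u -= contact + mu[a]
                row = Q[a]
                b = a + 1
                acc = row[b]
                while acc < u:
                    b += 1
                    acc += row[b]
                a = b
    return out


def simulate_counts(config: SimConfig) -> DegreeCounts:
    """Tabulated contact counts for a cohort of ``config.n`` individuals.

    With ``censor_zero`` (the default, matching the survey data) zero-
    degree individuals are dropped and the returned ``n`` is the retained
    count.
    """
    rng = np.random.default_rng(config.seed)
    degrees = simulate_degrees(config.model, config.n, rng)
    n_zero = int((degrees == 0).sum())
    degrees = degrees[degrees > 0]
    if degrees.size == 0:
        raise RuntimeError("all simulated individuals had zero contacts")
    y = DegreeCounts.from_degrees(degrees)
    if not config.censor_zero and n_zero:
        y = DegreeCounts(counts=y.counts, zeros=n_zero)
    return y
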