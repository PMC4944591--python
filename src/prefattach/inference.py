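"""Maximum-likelihood fitting of the contact-formation model.

The data are a zero-truncated multinomial sample: ``y_k`` respondents
report ``k >= 1`` contacts, each degree drawn independently from the
censored model pmf ``d~_k``.  Up to a data-only combinatorial constant the
log-likelihood is ``sum_k y_k log d~_k``, evaluated with the spectral
solver truncated at the largest observed degree.

Optimization happens in an unconstrained transformed space — log for the
rates (tau, mu, Q) and a pinned-logit softmax for the initial-phase
simplex — using simulated annealing from multiple starting points
followed by a derivative-free polish.  Uncertainty is quantified by the
nonparametric bootstrap (percentile intervals from resampled respondents)
and a parametric bootstrap envelope for the predicted pmf; no Hessian
standard errors are produced.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import dual_annealing, minimize

from .model_core import DegreeCounts, PAModel, PhaseTypeSpec, count_parameters
from .spectral import _a_recursion, censor_zero, degree_pmf
from .simulate import SimConfig, simulate_counts

__all__ = [
    "FitSettings",
    "FitResult",
    "BootstrapResult",
    "PmfBand",
    "log_likelihood",
    "fit_mle",
    "bootstrap_ci",
    "parametric_bootstrap_band",
    "model_to_params",
]

#: objective value returned when a trial parameter point assigns zero
#: probability to an observed degree; finite so annealing can move away.
IMPOSSIBLE = 1e12

_LOG_RATE_LO, _LOG_RATE_HI = np.log(1e-4), np.log(50.0)
_LOG_TAU_LO, _LOG_TAU_HI = np.log(1e-6), np.log(5.0)
_LOGIT_LIM = 8.0


@dataclass(frozen=True)
class FitSettings:
    """Optimizer and bootstrap configuration.

    Defaults: 20 annealing starts with a budget of 2e4 objective
    evaluations each (the annealer proposes globally; a Nelder-Mead polish
    finishes locally), and 200 bootstrap replicates.  Bootstrap refits
    polish from the original optimum by default — resampled data sit close
    to the original, so a local refit is both fast and accurate.
    """

    n_starts: int = 20
    maxfun: int = 20_000
    polish_maxiter: int = 2_000
    seed: int = 0
    B: int = 200
    bootstrap_polish_only: bool = True
    bootstrap_polish_maxiter: int = 800

    def __post_init__(self) -> None:
        if self.n_starts < 1:
            raise ValueError("n_starts must be >= 1")
        if self.B < 1:
            raise ValueError("B must be >= 1")


@dataclass(frozen=True)
class FitResult:
    """A fitted model with its maximized (constant-dropped) log-likelihood."""

    model: PAModel
    loglik: float
    n_params: int
    converged: bool
    n_obs: int
    ci: dict[str, tuple[float, float]] | None = None
    x_opt: np.ndarray = field(default=None, repr=False)  # packed optimum

    def with_ci(self, ci: dict[str, tuple[float, float]]) -> "FitResult":
        return FitResult(
            model=self.model,
            loglik=self.loglik,
            n_params=self.n_params,
            converged=self.converged,
            n_obs=self.n_obs,
            ci=ci,
            x_opt=self.x_opt,
        )


# ---------------------------------------------------------------------------
# parameter packing: unconstrained vector <-> PAModel
# ---------------------------------------------------------------------------

def n_free(m: int, pa: bool) -> int:
    return (m - 1) + m + m * (m - 1) // 2 + (1 if pa else 0)


def pack(model: PAModel) -> np.ndarray:
    """Map a model to the unconstrained optimizer space."""
    spec = model.phases
    m = spec.m
    nu = np.clip(spec.nu, 1e-12, None)
    logits = np.log(nu[1:] / nu[0])
    log_mu = np.log(np.clip(spec.mu, 1e-12, None))
    iu = np.triu_indices(m, k=1)
    log_q = np.log(np.clip(spec.Q[iu], 1e-12, None))
    x = np.concatenate([logits, log_mu, log_q])
    if model.pa:
        x = np.append(x, np.log(max(model.tau, 1e-12)))
    return np.clip(
        x,
        _bounds(m, model.pa)[:, 0],
        _bounds(m, model.pa)[:, 1],
    )


def unpack(x: np.ndarray, m: int, pa: bool) -> PAModel:
    """Inverse of :func:`pack`."""
    x = np.asarray(x, dtype=float)
    logits = np.concatenate([[0.0], x[: m - 1]])  # nu_1's logit pinned at 0
    z = logits - logits.max()
    nu = np.exp(z)
    nu /= nu.sum()
    mu = np.exp(x[m - 1 : 2 * m - 1])
    Q = np.zeros((m, m))
    iu = np.triu_indices(m, k=1)
    Q[iu] = np.exp(x[2 * m - 1 : 2 * m - 1 + m * (m - 1) // 2])
    tau = float(np.exp(x[-1])) if pa else 0.0
    spec = PhaseTypeSpec(nu=nu, mu=mu, Q=Q)
    return PAModel(phases=spec, tau=tau, pa=pa)


def _bounds(m: int, pa: bool) -> np.ndarray:
    b = []
    b += [(-_LOGIT_LIM, _LOGIT_LIM)] * (m - 1)
    b += [(_LOG_RATE_LO, _LOG_RATE_HI)] * (m + m * (m - 1) // 2)
    if pa:
        b += [(_LOG_TAU_LO, _LOG_TAU_HI)]
    return np.array(b)


def model_to_params(model: PAModel) -> dict[str, float]:
    """Named natural-scale parameters (for reports and bootstrap CIs)."""
    spec = model.phases
    out: dict[str, float] = {}
    if model.pa:
        out["tau"] = float(model.tau)
    for a in range(spec.m):
        out[f"nu[{a + 1}]"] = float(spec.nu[a])
    for a in range(spec.m):
        out[f"mu[{a + 1}]"] = float(spec.mu[a])
    for a in range(spec.m):
        for b in range(a + 1, spec.m):
            out[f"Q[{a + 1},{b + 1}]"] = float(spec.Q[a, b])
    return out


# ---------------------------------------------------------------------------
# likelihood
# ---------------------------------------------------------------------------

def log_likelihood(model: PAModel, y: DegreeCounts, kmax: int | None = None) -> float:
    """Zero-truncated multinomial log-likelihood ``sum_k y_k log d~_k``
    (combinatorial constant dropped).  Returns ``-inf`` when the model
    assigns zero probability to an observed degree."""
    ks, ys = y.arrays()
    if kmax is None:
        kmax = y.max_degree
    if kmax < y.max_degree:
        raise ValueError(
            f"solver truncation kmax={kmax} below largest observed degree "
            f"{y.max_degree}"
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        dist = degree_pmf(model, kmax=kmax)
    dt = censor_zero(dist).d[ks]
    if np.any(dt <= 0.0) or not np.all(np.isfinite(dt)):
        return -np.inf
    return float(ys @ np.log(dt))


def _objective(x, m, pa, ks, ys, kmax, nu_arr, mu_arr, q_arr):
    # hot path: unpack by hand and call the jitted recursion directly
    logits0 = x[: m - 1]
    zmax = max(0.0, logits0.max()) if m > 1 else 0.0
    nu_arr[0] = np.exp(-zmax)
    if m > 1:
        nu_arr[1:] = np.exp(logits0 - zmax)
    nu_arr /= nu_arr.sum()
    mu_arr[:] = np.exp(x[m - 1 : 2 * m - 1])
    q_arr[:] = 0.0
    idx = 2 * m - 1
    for a in range(m):
        for b in range(a + 1, m):
            q_arr[a, b] = np.exp(x[idx])
            idx += 1
    tau = float(np.exp(x[-1])) if pa else 0.0
    M = mu_arr + q_arr.sum(axis=1)
    _, d = _a_recursion(nu_arr, mu_arr, q_arr, M, tau, kmax)
    d0 = d[0]
    if d0 >= 1.0:
        return IMPOSSIBLE
    dt = d[ks] / (1.0 - d0)
    if np.any(dt <= 0.0) or not np.all(np.isfinite(dt)):
        return IMPOSSIBLE
    return -float(ys @ np.log(dt))


def _make_objective(y: DegreeCounts, m: int, pa: bool):
    ks, ys = y.arrays()
    kmax = int(ks.max())
    nu_arr = np.empty(m)
    mu_arr = np.empty(m)
    q_arr = np.zeros((m, m))
    ys = ys.astype(float)

    def f(x):
        return _objective(x, m, pa, ks, ys, kmax, nu_arr, mu_arr, q_arr)

    return f


def _random_start(rng: np.random.Generator, m: int, pa: bool) -> np.ndarray:
    # rates log-uniform on [1e-3, 10]; nu uniform on the simplex
    nu = rng.dirichlet(np.ones(m))
    nu = np.clip(nu, 1e-6, None)
    logits = np.clip(np.log(nu[1:] / nu[0]), -_LOGIT_LIM, _LOGIT_LIM)
    n_rates = m + m * (m - 1) // 2
    log_rates = rng.uniform(np.log(1e-3), np.log(10.0), size=n_rates)
    x = np.concatenate([logits, log_rates])
    if pa:
        x = np.append(x, rng.uniform(np.log(1e-3), np.log(2.0)))
    return x


def fit_mle(
    y: DegreeCounts,
    m: int,
    pa: bool,
    settings: FitSettings | None = None,
    warm_starts: list[PAModel] | None = None,
) -> FitResult:
    """Maximum-likelihood fit of an ``m``-phase model with or without PA.

    Runs ``n_starts`` simulated-annealing searches from random starting
    points (plus a local polish each), together with polish-only runs from
    any supplied warm-start models, and returns the best.  Deterministic
    given ``settings.seed``.
    """
    settings = settings or FitSettings()
    if m < 1:
        raise ValueError("m must be >= 1")
    f = _make_objective(y, m, pa)
    bounds = _bounds(m, pa)
    ss = np.random.SeedSequence(settings.seed)
    children = ss.spawn(settings.n_starts)
    best_fun, best_x, best_ok = np.inf, None, False

    def _polish(x0, maxiter):
        res = minimize(
            f,
            x0,
            method="Nelder-Mead",
            options={"maxiter": maxiter, "xatol": 1e-6, "fatol": 1e-8},
        )
        return res

    for child in children:
        rng = np.random.default_rng(child)
        x0 = _random_start(rng, m, pa)
        if settings.maxfun > 0:
            sa = dual_annealing(
                f,
                bounds=bounds,
                maxfun=settings.maxfun,
                maxiter=max(10, settings.maxfun),
                no_local_search=True,
                x0=np.clip(x0, bounds[:, 0], bounds[:, 1]),
                rng=rng,
            )
            x0 = sa.x
        res = _polish(x0, settings.polish_maxiter)
        if res.fun < best_fun:
            best_fun, best_x, best_ok = res.fun, res.x, bool(res.success)
    for wm in warm_starts or []:
        res = _polish(pack(wm), settings.polish_maxiter)
        if res.fun < best_fun:
            best_fun, best_x, best_ok = res.fun, res.x, bool(res.success)
    model = unpack(best_x, m, pa)
    converged = bool(best_ok and best_fun < IMPOSSIBLE / 2)
    if not converged:
        warnings.warn(
            f"fit for (m={m}, pa={pa}) did not converge cleanly "
            f"(objective {best_fun:.6g})",
            stacklevel=2,
        )
    return FitResult(
        model=model,
        loglik=float(-best_fun),
        n_params=count_parameters(model),
        converged=converged,
        n_obs=y.n,
        x_opt=best_x,
    )


# ---------------------------------------------------------------------------
# bootstrap
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BootstrapResult:
    """Replicate estimates and percentile intervals, keyed by parameter
    name (see :func:`model_to_params`).  ``failed`` lists indices of
    replicates whose refit failed."""

    estimates: dict[str, np.ndarray]
    intervals: dict[str, tuple[float, float]]
    failed: list[int]
    level: float = 0.95


def _refit(
    y_b: DegreeCounts,
    m: int,
    pa: bool,
    settings: FitSettings,
    base: FitResult,
    seed_child,
) -> FitResult:
    if settings.bootstrap_polish_only:
        f = _make_objective(y_b, m, pa)
        res = minimize(
            f,
            base.x_opt,
            method="Nelder-Mead",
            options={"maxiter": settings.bootstrap_polish_maxiter, "xatol": 1e-6, "fatol": 1e-8},
        )
        model = unpack(res.x, m, pa)
        return FitResult(
            model=model,
            loglik=-res.fun,
            n_params=count_parameters(model),
            converged=bool(res.fun < IMPOSSIBLE / 2),
            n_obs=y_b.n,
            x_opt=res.x,
        )
    sub = FitSettings(
        n_starts=max(1, settings.n_starts // 4),
        maxfun=settings.maxfun // 4,
        polish_maxiter=settings.polish_maxiter,
        seed=int(seed_child.generate_state(1)[0] % 2**31),
        B=1,
    )
    return fit_mle(y_b, m, pa, sub, warm_starts=[base.model])


def bootstrap_ci(
    y: DegreeCounts,
    m: int,
    pa: bool,
    settings: FitSettings | None = None,
    fit: FitResult | None = None,
    level: float = 0.95,
) -> tuple[FitResult, BootstrapResult]:
    """Nonparametric bootstrap percentile intervals for every parameter.

    Respondents' degrees are resampled with replacement ``B`` times and
    each resample is refit.  Returns the (possibly freshly computed)
    point fit with its ``ci`` attached, plus the full replicate table.
    """
    settings = settings or FitSettings()
    if fit is None:
        fit = fit_mle(y, m, pa, settings)
    ss = np.random.SeedSequence(settings.seed).spawn(settings.B + 1)
    degrees = y.expand()
    rows: list[dict[str, float]] = []
    failed: list[int] = []
    for b in range(settings.B):
        rng = np.random.default_rng(ss[b])
        resample = rng.choice(degrees, size=len(degrees), replace=True)
        try:
            y_b = DegreeCounts.from_degrees(resample)
            fb = _refit(y_b, m, pa, settings, fit, ss[b])
            if not fb.converged:
                raise RuntimeError("replicate refit did not converge")
            rows.append(model_to_params(fb.model))
        except Exception:
            failed.append(b)
    if not rows:
        raise RuntimeError(f"every bootstrap replicate failed: indices {failed}")
    if failed:
        warnings.warn(f"bootstrap replicates failed at indices {failed}", stacklevel=2)
    names = list(rows[0])
    estimates = {p: np.array([r[p] for r in rows]) for p in names}
    alpha = (1.0 - level) / 2.0
    intervals = {
        p: (float(np.quantile(v, alpha)), float(np.quantile(v, 1.0 - alpha)))
        for p, v in estimates.items()
    }
    result = BootstrapResult(
        estimates=estimates, intervals=intervals, failed=failed, level=level
    )
    return fit.with_ci(intervals), result


@dataclass(frozen=True)
class PmfBand:
    """Pointwise parametric-bootstrap envelope of the censored model pmf."""

    k: np.ndarray
    lo: np.ndarray
    hi: np.ndarray
    point: np.ndarray
    failed: list[int]


def parametric_bootstrap_band(
    fit: FitResult,
    n: int,
    B: int | None = None,
    settings: FitSettings | None = None,
    kmax: int | None = None,
) -> PmfBand:
    """Uncertainty band for the predicted degree distribution.

    ``B`` datasets of ``n`` respondents are simulated from the fitted
    model (zero-censored, like the data), each is refit, and the band is
    the pointwise min/max of the refitted censored pmfs.
    """
    settings = settings or FitSettings()
    B = settings.B if B is None else B
    m, pa = fit.model.m, fit.model.pa
    ss = np.random.SeedSequence(settings.seed).spawn(B)
    if kmax is None:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ref = degree_pmf(fit.model)
        kmax = min(ref.kmax, max(50, 2 * int(np.argmax(np.cumsum(ref.d) > 0.999))))
    pmfs: list[np.ndarray] = []
    failed: list[int] = []
    for b in range(B):
        seed = int(ss[b].generate_state(1)[0] % 2**31)
        try:
            y_b = simulate_counts(SimConfig(model=fit.model, n=n, seed=seed))
            fb = _refit(y_b, m, pa, settings, fit, ss[b])
            if not fb.converged:
                raise RuntimeError("replicate refit did not converge")
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                pmfs.append(censor_zero(degree_pmf(fb.model, kmax=kmax)).d)
        except Exception:
            failed.append(b)
    if not pmfs:
        raise RuntimeError(f"every parametric replicate failed: indices {failed}")
    stack = np.vstack(pmfs)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        point = censor_zero(degree_pmf(fit.model, kmax=kmax)).d
    return PmfBand(
        k=np.arange(kmax + 1),
        lo=stack.min(axis=0),
        hi=stack.max(axis=0),
        point=point,
        failed=failed,
    )
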