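"""Model selection across the (phases, PA) grid.

Candidate models differ in the number of activity phases ``m`` and in
whether preferential attachment is included.  Three complementary
criteria are computed: AIC, BIC (different fit/complexity trade-offs) and
likelihood-ratio tests on nested pairs.  A no-PA model is nested in its
PA counterpart (set tau = 0), and an m-phase model is nested in the
(m+1)-phase model with the same PA status (the extra phase collapses when
its inbound rates vanish); other pairs are not informative and are
refused.

The LRT for PA sits on the boundary of the parameter space (tau >= 0),
where the usual chi-square reference is conservative; the asymptotic null
is a 50:50 mixture of a point mass at zero and chi-square(1).  The plain
chi-square is the default for comparability with standard practice; the
mixture correction is available via a flag.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .model_core import DegreeCounts, PAModel, PhaseTypeSpec
from .inference import FitResult, FitSettings, fit_mle
from .spectral import lowest_divergent_moment, moment

__all__ = [
    "aic",
    "bic",
    "LRTResult",
    "lrt",
    "SelectionRow",
    "SelectionTable",
    "selection_grid",
    "pa_contribution",
]


def aic(loglik: float, n_params: int) -> float:
    """Akaike information criterion, ``2 p - 2 logL``."""
    return 2.0 * n_params - 2.0 * loglik


def bic(loglik: float, n_params: int, n: int) -> float:
    """Bayesian information criterion, ``p log n - 2 logL``."""
    if n < 1:
        raise ValueError("sample size n must be >= 1")
    return n_params * np.log(n) - 2.0 * loglik


@dataclass(frozen=True)
class LRTResult:
    statistic: float
    df: int
    p_value: float
    boundary_corrected: bool = False


def _nested(null: FitResult, alt: FitResult) -> bool:
    m0, p0 = null.model.m, null.model.pa
    m1, p1 = alt.model.m, alt.model.pa
    if m0 == m1 and not p0 and p1:
        return True
    if m1 == m0 + 1 and p0 == p1:
        return True
    return False


def lrt(
    fit_null: FitResult, fit_alt: FitResult, boundary_correction: bool = False
) -> LRTResult:
    """Likelihood-ratio test of a nested model pair on the same data.

    The statistic ``2 (logL_alt - logL_null)`` (clamped at zero, since a
    bounded optimizer can leave the alternative a hair below the null) is
    referred to chi-square with ``df`` equal to the parameter difference.
    ``boundary_correction`` applies the 50:50 bar(chi-square) mixture for
    the single-parameter tau-boundary test.
    """
    if fit_null.n_obs != fit_alt.n_obs:
        raise ValueError("fits compare different datasets (n differs)")
    if not _nested(fit_null, fit_alt):
        raise ValueError(
            f"models (m={fit_null.model.m}, pa={fit_null.model.pa}) and "
            f"(m={fit_alt.model.m}, pa={fit_alt.model.pa}) are not nested: "
            "the test is informative only for (m,no)⊂(m,yes) or (m,·)⊂(m+1,·)"
        )
    df = fit_alt.n_params - fit_null.n_params
    if df < 1:
        raise ValueError("alternative must have strictly more parameters")
    stat = max(0.0, 2.0 * (fit_alt.loglik - fit_null.loglik))
    pa_pair = fit_null.model.m == fit_alt.model.m and df == 1
    if boundary_correction:
        if not pa_pair:
            raise ValueError(
                "boundary correction applies only to the tau-boundary pair "
                "(m, no PA) vs (m, PA)"
            )
        p = 1.0 if stat == 0.0 else 0.5 * float(chi2.sf(stat, 1))
    else:
        p = float(chi2.sf(stat, df))
    return LRTResult(statistic=stat, df=df, p_value=p, boundary_corrected=boundary_correction)


@dataclass(frozen=True)
class SelectionRow:
    m: int
    pa: bool
    n_params: int
    loglik: float
    aic: float
    bic: float
    d_aic: float
    d_bic: float
    lowest_divergent: int | None
    converged: bool
    error: str | None = None
    fit: FitResult | None = None


@dataclass(frozen=True)
class SelectionTable:
    """Grid of fitted (phases, PA) models with relative AIC/BIC.

    Exactly one successful row has ``d_aic == 0`` and one has
    ``d_bic == 0`` (the respective preferred models).
    """

    rows: list[SelectionRow]
    n: int

    @property
    def preferred_aic(self) -> SelectionRow:
        return min(self._ok(), key=lambda r: r.aic)

    @property
    def preferred_bic(self) -> SelectionRow:
        return min(self._ok(), key=lambda r: r.bic)

    def _ok(self) -> list[SelectionRow]:
        rows = [r for r in self.rows if r.error is None]
        if not rows:
            raise RuntimeError("no model in the grid was fitted successfully")
        return rows

    def row(self, m: int, pa: bool) -> SelectionRow:
        for r in self.rows:
            if r.m == m and r.pa == pa:
                return r
        raise KeyError((m, pa))

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "phases": r.m,
                    "pa": r.pa,
                    "n_params": r.n_params,
                    "loglik": r.loglik,
                    "aic": r.aic,
                    "bic": r.bic,
                    "d_aic": r.d_aic,
                    "d_bic": r.d_bic,
                    "diverge": r.lowest_divergent,
                    "converged": r.converged,
                    "error": r.error,
                }
                for r in self.rows
            ]
        )

    def to_json(self) -> str:
        df = self.to_dataframe()
        payload = {
            "n": self.n,
            "preferred_aic": {"phases": self.preferred_aic.m, "pa": self.preferred_aic.pa},
            "preferred_bic": {"phases": self.preferred_bic.m, "pa": self.preferred_bic.pa},
            "rows": json.loads(df.to_json(orient="records")),
        }
        return json.dumps(payload, indent=2)

    def render_text(self) -> str:
        """Aligned text table: phases, PA, params, ΔAIC, ΔBIC, diverge."""
        lines = [f"{'Phases':>6} {'PA':>3} {'Params':>6} {'dAIC':>10} {'dBIC':>10} {'Diverge':>8}"]
        pa_row = self.preferred_aic
        pb_row = self.preferred_bic
        for r in self.rows:
            if r.error is not None:
                lines.append(f"{r.m:>6} {('Yes' if r.pa else 'No'):>3}  failed: {r.error}")
                continue
            mark = ""
            if (r.m, r.pa) == (pa_row.m, pa_row.pa):
                mark += " [AIC]"
            if (r.m, r.pa) == (pb_row.m, pb_row.pa):
                mark += " [BIC]"
            div = "-" if r.lowest_divergent is None else str(r.lowest_divergent)
            lines.append(
                f"{r.m:>6} {('Yes' if r.pa else 'No'):>3} {r.n_params:>6} "
                f"{r.d_aic:>10.2f} {r.d_bic:>10.2f} {div:>8}{mark}"
            )
        return "\n".join(lines)


def _extend_model(model: PAModel, eps: float = 1e-3) -> PAModel:
    """Embed an m-phase model into m+1 phases as a warm start: the new
    last phase gets tiny initial mass and inbound rates, unit stop rate."""
    spec = model.phases
    m = spec.m
    nu = np.append(spec.nu * (1.0 - eps), eps)
    mu = np.append(spec.mu, 1.0)
    Q = np.zeros((m + 1, m + 1))
    Q[:m, :m] = spec.Q
    Q[:m, m] = eps
    return PAModel(phases=PhaseTypeSpec(nu=nu, mu=mu, Q=Q), tau=model.tau, pa=model.pa)


def _with_pa(model: PAModel, tau0: float = 1e-4) -> PAModel:
    return PAModel(phases=model.phases, tau=tau0, pa=True)


def selection_grid(
    y: DegreeCounts,
    m_max: int,
    settings: FitSettings | None = None,
) -> SelectionTable:
    """Fit all ``2 m_max`` models and tabulate AIC/BIC differences.

    Each cell's annealing starts are supplemented with warm starts built
    from the best nested simpler models (same-m no-PA optimum with a tiny
    tau, and the (m-1)-phase optimum embedded with a weak extra phase),
    which also enforces the nested log-likelihood ordering up to optimizer
    tolerance.  Per-cell failures are recorded in the table, not raised.
    """
    settings = settings or FitSettings()
    if m_max < 1:
        raise ValueError("m_max must be >= 1")
    fits: dict[tuple[int, bool], FitResult] = {}
    cells: list[tuple[int, bool, FitResult | None, str | None]] = []
    for m in range(1, m_max + 1):
        for pa in (False, True):
            warm: list[PAModel] = []
            if pa and (m, False) in fits:
                warm.append(_with_pa(fits[(m, False)].model))
            if (m - 1, pa) in fits:
                warm.append(_extend_model(fits[(m - 1, pa)].model))
            sub = FitSettings(
                n_starts=settings.n_starts,
                maxfun=settings.maxfun,
                polish_maxiter=settings.polish_maxiter,
                seed=int(
                    np.random.SeedSequence([settings.seed, m, int(pa)]).generate_state(1)[0]
                    % 2**31
                ),
                B=settings.B,
                bootstrap_polish_only=settings.bootstrap_polish_only,
                bootstrap_polish_maxiter=settings.bootstrap_polish_maxiter,
            )
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    fit = fit_mle(y, m, pa, sub, warm_starts=warm)
                fits[(m, pa)] = fit
                cells.append((m, pa, fit, None))
            except Exception as exc:  # per-cell failure is a row, not a crash
                cells.append((m, pa, None, str(exc)))
    ok = [(m, pa, f) for m, pa, f, err in cells if err is None]
    aics = {(m, pa): aic(f.loglik, f.n_params) for m, pa, f in ok}
    bics = {(m, pa): bic(f.loglik, f.n_params, y.n) for m, pa, f in ok}
    amin, bmin = min(aics.values()), min(bics.values())
    rows = []
    for m, pa, fit, err in cells:
        if err is not None:
            rows.append(
                SelectionRow(
                    m=m, pa=pa, n_params=0, loglik=np.nan, aic=np.nan, bic=np.nan,
                    d_aic=np.nan, d_bic=np.nan, lowest_divergent=None,
                    converged=False, error=err,
                )
            )
            continue
        div = lowest_divergent_moment(fit.model, r_max=10).lowest_divergent if pa else None
        rows.append(
            SelectionRow(
                m=m,
                pa=pa,
                n_params=fit.n_params,
                loglik=fit.loglik,
                aic=aics[(m, pa)],
                bic=bics[(m, pa)],
                d_aic=aics[(m, pa)] - amin,
                d_bic=bics[(m, pa)] - bmin,
                lowest_divergent=div,
                converged=fit.converged,
                fit=fit,
            )
        )
    return SelectionTable(rows=rows, n=y.n)


def pa_contribution(fit: FitResult | PAModel) -> float:
    """Fraction of the mean contact count attributable to the phase
    machinery alone: mean with tau set to 0 (other parameters fixed)
    divided by the fitted mean.  1 - ratio is the share of contacts
    attributable to preferential attachment."""
    model = fit.model if isinstance(fit, FitResult) else fit
    m1 = moment(model, 1)
    if not np.isfinite(m1):
        raise ValueError("fitted first moment diverges; the ratio is undefined")
    m1_0 = moment(model.without_pa(), 1)
    return m1_0 / m1
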