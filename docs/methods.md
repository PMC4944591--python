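# Methods

## Model

An individual's contact count `K(t)` is a pure-birth Markov chain
started at 0 with birth rate `f_k = 1 + τ k`.  The baseline rate is
fixed at exactly 1: time is measured in units of the contact-making
rate, because a phase that makes contacts faster is observationally
indistinguishable (in final counts) from a phase that lasts longer, so
per-phase contact rates are deliberately not parameters.  Preferential
attachment is the hypothesis τ > 0; τ is a dimensionless gain per
existing contact.

Conditional on stopping time `t`, the generating function is

    g(t, s) = (s − (s − 1) e^{τt})^{−1/τ},

whose Taylor expansion in `s` is a negative-binomial law with `1/τ`
"successes" of probability `e^{−τt}`:

    p_k(t) = e^{−t} C(k + 1/τ − 1, k) (1 − e^{−τt})^k.

This is the form the package implements (in log space via `gammaln`);
it reduces to Poisson(t) as τ → 0 and to the geometric
`e^{−t}(1 − e^{−t})^k` at τ = 1, and it is validated against
series-extraction of `g` by FFT on a complex circle and against
`scipy.stats.nbinom`.  Conditional moments use Stirling-number
conversion of the negative-binomial factorial moments, reproducing
`m₁ = (e^{τt} − 1)/τ` and `m₂ = m₁ + (τ+1)m₁²` exactly.

The stopping time follows a phase-type law over `m` forward-ordered
phases: start in phase `a` with probability ν_a, stop at rate μ_a, move
`a → b > a` at rate `Q[a,b]` (Q strictly upper triangular, which pins
the free-parameter count at `(m−1) + m + m(m−1)/2`, plus 1 for τ).  The
occupancy generator `G` is lower triangular with diagonal
`−M_a = −(μ_a + Σ_{b>a} Q[a,b])`; the density `ρ(t) = μᵀ e^{Gt} ν`
integrates to one with this convention (verified by quadrature).  Every
phase must have `M_a > 0` so the process stops almost surely.

## Degree distribution: triangular recursion

The unconditional pmf `d_k = ∫ ρ(t) p_k(t) dt` is computed without
quadrature.  Laplace-transforming the occupancy ODEs and taking the
zero-frequency limit yields a triangular linear system in
`A[a,k] = lim_{s↓0} ∫ e^{−st} p_{a,k}(t) dt`, solved by forward
substitution in increasing `(a, k)`:

    A[a,0] = (ν_a + Σ_{b<a} Q[b,a] A[b,0]) / (f_0 + M_a)
    A[a,k] = (f_{k−1} A[a,k−1] + Σ_{b<a} Q[b,a] A[b,k]) / (f_k + M_a)
    d_k    = Σ_a μ_a A[a,k]

(the initial condition enters with a positive sign — that is what makes
all `A ≥ 0` and `Σ d_k = 1`, both asserted in tests).  The inner loop is
JIT-compiled (numba), giving microsecond evaluations even at
`kmax` in the hundreds; this recursion sits inside every likelihood
evaluation, so its cost dominates fitting.  Truncation: by default
`kmax` doubles adaptively from 256 until tail mass < 1e−10 (hard cap
1e5); the fitting path uses `kmax =` largest observed degree and warns —
never silently renormalizes — if the tail mass above it exceeds 1e−6.

## Moments and divergence

The r-th degree moment combines the conditional moment polynomial with
resolvent integrals `I_r = ∫ e^{rτt} ρ(t) dt = μᵀ(−(G + rτI))^{−1}ν`
(one triangular solve):

    m̄₁ = (I₁ − 1)/τ,
    m̄₂ = m̄₁ + (τ+1)(I₂ − 2I₁ + 1)/τ².

`I_r` exists iff `rτ < M_a` for every phase `a` reachable with positive
probability; moment r is therefore reported divergent iff `rτ ≥ M_a`
for some reachable phase.  Two deliberate choices: the boundary
`rτ = M_a` is classified divergent (the integrand is asymptotically
constant there), and unreachable phases (ν_a = 0, no inbound rates) are
excluded from the scan since they cannot influence the distribution.
For τ below 1e−8 all `1/τ` expressions switch to analytic limits
(Poisson forms; `m̄₁ = μᵀG⁻²ν`, `m̄₂ = m̄₁ − 2μᵀG⁻³ν`) to avoid
catastrophic cancellation.

A divergent second moment is the epidemiologically critical case
(`R₀ ∝ E[K²]` in the simplified network setting): the package surfaces
the lowest divergent moment for every fitted PA model so this reading is
immediate.

## Likelihood, fitting, uncertainty

Data are `y_k` respondents reporting `k ≥ 1` contacts; zero reports are
censored, so the model pmf is zero-truncated (`d̃_k = d_k/(1 − d_0)`) and
the log-likelihood is `Σ_k y_k log d̃_k` (multinomial combinatorial
constant dropped — it does not depend on parameters).  A parameter point
that assigns zero probability to an observed degree returns a finite
sentinel (−1e12) instead of raising, so the annealer can move away.

Optimization is over an unconstrained space: log(τ), log(μ_a),
log(Q[a,b]), and softmax logits for ν with the first logit pinned at 0
(simplex identifiability).  Each fit runs `n_starts` dual-annealing
searches (rates started log-uniform on [1e−3, 10], ν uniform on the
simplex; search bounds [1e−4, 50] for rates, [1e−6, 5] for τ) followed
by a Nelder-Mead polish; warm starts from nested simpler models are
polished as extra candidates, which also enforces the nested
log-likelihood ordering up to optimizer tolerance.  Library defaults are
20 starts × 2e4 evaluations; the test and acceptance runs pass smaller
explicit budgets (2–4 starts, a few thousand evaluations) — at those
problem sizes (m ≤ 2, kmax of a few hundred) the likelihood surface is
mild enough that the small budgets reach the same optima as larger ones,
which the transformed-vs-constrained-space test checks directly.

Phases are only weakly ordered by the triangular Q, so labels can swap
between fits; tests and reports compare models by likelihood and pmf,
never by raw parameter vectors (single-phase recovery aside).

Uncertainty: nonparametric bootstrap (resample the n respondents'
degrees, refit, percentile intervals) and a parametric bootstrap band
for the predicted pmf (simulate from the fitted model, refit, pointwise
envelope).  Bootstrap refits default to polishing from the original
optimum — resamples sit close to the original data, so a local refit is
accurate at a fraction of the cost; a full multi-start refit is
available by flag.  All randomness flows from one seed through
`numpy.random.SeedSequence` spawning, so replicates are independent and
every run is reproducible.

## Selection

AIC (`2p − 2logL`), BIC (`p log n − 2logL`) and LRTs.  Nesting map:
(m, no-PA) ⊂ (m, PA), and (m, ·) ⊂ (m+1, ·) (the extra phase collapses
when its inbound rates vanish); other pairs are refused as
uninformative.  The PA test puts τ on the boundary of its range, where
the plain chi-square reference is conservative (asymptotic null: 50:50
mixture of a point mass and χ²₁).  The plain chi-square with
df = Δparams is the default for comparability with common practice; the
mixture correction is available via `boundary_correction=True`.  The
type-I-error acceptance test confirms the conservativeness empirically.

The counterfactual PA contribution reports
`m̄₁(τ=0, other parameters fixed) / m̄₁(fitted)` — the fraction of mean
contacts the phase machinery alone would produce; 1 minus it is the
share attributable to attachment.

## Simulator

Exact Gillespie (direct method: total rate, then categorical event
choice) over the competing clocks contact/stop/phase-move.  Exactness
matters because the simulator is the independent oracle: tests require
the empirical degree distribution to pass a chi-square GoF against the
spectral solver at 1e5 draws, stopping times to pass a KS test against
`ρ(t)`, and sample moments to match the analytic ones within Monte-Carlo
error.  Zero-censoring is applied by discarding after simulation (the
dynamics are not conditioned), mirroring a survey that simply contains
no zero-contact respondents; uncensored runs keep the number of zero
reports as metadata alongside the positive-degree count table.

## Synthetic study conditions

The generator's fixture models, fixed once:

* **1 phase, no PA**: μ = 0.05 (mean activity time 20 → ~20 contacts).
* **2 phases, PA**: ν = (0.6, 0.4), μ = (0.5, 0.15), Q₁₂ = 0.2,
  τ = 0.05.  Mean ≈ 6.8 contacts/day, finite second moment
  (2τ = 0.10 < M₂ = 0.15) but divergent third — a realistic heavy
  contact tail that still permits epidemic control.
* **3 phases, PA**: ν = (0.5, 0.3, 0.2), μ = (0.4, 0.1, 0.6),
  Q₁₂ = 0.3, Q₁₃ = 0.1, Q₂₃ = 0.2, τ = 0.02 — light-tailed, used where
  finite higher moments are needed (Monte-Carlo standard errors).

Recovery and error-rate studies use cohorts of 5,000 simulated
individuals (survey scale) with 50-replicate bootstraps, 200 null
replicates for the LRT size check, and cohorts of 10,000 for the AIC
power/null checks — sizes chosen so the whole validation suite runs in
about a minute while leaving the statistical margins wide.

What the synthetic data do **not** emulate: reporting error and heaping
(respondents rounding to 10, 20, 50...), household/group reporting
structure, demographic covariates, and any network dependence between
respondents (degrees are i.i.d. draws).  Passing tests therefore show
the machinery is correct for the generative model, not that the model
captures every feature of real survey data.

## Numerical notes and limitations

* τ < 1e−8 routes through analytic τ=0 limits everywhere (pmf, moments,
  resolvent); mid-range small τ (≥1e−6, the optimizer's lower bound) is
  handled by the general formulas with acceptable cancellation error.
* The recursion is backward-stable in practice: closed-form comparisons
  (geometric, Beta-integral) hold to better than 1e−12 absolute at
  k ≤ 200.
* Moments are implemented for r ∈ {1, 2} (the epidemiologically relevant
  orders); the divergence scan covers arbitrary r.
* `fit_mle` reports `converged=False` (with a warning, never silently)
  when the polish fails or the best objective is the impossibility
  sentinel.
* The LRT mixture correction is implemented only for the τ-boundary
  pair; boundary effects of rate parameters at 0 in phase-nesting tests
  are not corrected (the plain chi-square is used, as is conventional).
* Very heavy tails (near-boundary second moments) make the adaptive
  truncation hit its 1e5 cap with a warning; moments remain exact
  (resolvent-based) but truncated sums converge slowly there.
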