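# prefattach

A likelihood-based test for **preferential attachment (PA)** in integer
contact-count data, built for epidemiologically relevant social-contact
surveys but applicable to any count data where "the connected get more
connected" is the hypothesis of interest.

## The problem and the model

Surveys of person-to-person contacts consistently show very heavy right
tails: a few respondents report enormous numbers of daily contacts.
Whether that heterogeneity reflects preferential attachment matters,
because the basic reproductive ratio of a directly transmitted pathogen
scales with the *second moment* of the contact-degree distribution —
if it diverges, no untargeted vaccination programme can control the
disease.  Testing PA through asymptotic power-law fits is notoriously
fragile; this package instead fits a mechanistic generative model to the
full count distribution and tests PA directly.

Each individual starts the day with `K = 0` contacts and gains them one
at a time at rate

```
f_k = 1 + τ k ,          PA  ⇔  τ > 0 ,
```

with time measured in units of the baseline contact-making rate.  The
time spent making contacts is a phase-type random variable: a
forward-moving continuous-time Markov chain over `m` activity phases
(initial probabilities ν, stop rates μ, transition rates Q), which is
dense in the positive distributions and has a mechanistic reading as the
sequence of activities in a day.  Mixing the pure-birth process over the
stopping time gives the degree distribution `d_k`, computed here by a
triangular recursion at cost `O(m² kmax)` — no quadrature, no matrix
inversion:

```
A[a,k] = ( f_{k-1} A[a,k-1] + ν_a δ_{k0} + Σ_{b<a} Q[b,a] A[b,k] ) / (f_k + M_a)
d_k    = Σ_a μ_a A[a,k] ,       M_a = μ_a + Σ_{b>a} Q[a,b] .
```

Zero counts are censored (respondents reporting no contacts are absent),
so fitting maximizes the zero-truncated multinomial likelihood
`Σ_k y_k log d̃_k` with `d̃_k = d_k / (1 − d_0)`, by simulated annealing
from multiple starts.  Models across `(m, PA)` are compared with AIC,
BIC and likelihood-ratio tests; uncertainty comes from nonparametric and
parametric bootstraps.  The `r`-th degree moment is infinite exactly when
`r τ ≥ M_a` for some reachable phase — the package reports the lowest
divergent moment for every fitted PA model, which is the epidemiological
bottom line.

An exact Gillespie simulator of the same process doubles as the
synthetic-data generator and as the independent oracle for the solver
and the inference machinery.

## Worked example

Simulate a survey-sized cohort from a two-phase PA model
(ν = (0.6, 0.4), μ = (0.5, 0.15), Q₁₂ = 0.2, τ = 0.05), then refit it:

```bash
prefattach simulate --mu 0.5,0.15 --nu 0.6,0.4 --q 1,2,0.2 --tau 0.05 \
    -n 5000 --seed 42 --out example.csv
# wrote example.csv (3847 respondents) and example.csv.meta.json

prefattach fit example.csv -m 2 --pa --seed 0 --starts 4 --maxfun 2000 \
    --bootstrap 50 --format text
```

```
loglik -11435.4872  params 5  converged True
       tau = 0.0391128   95% CI [0.0205474, 0.0597857]
     nu[1] = 0.534713   95% CI [0.521798, 0.560523]
     nu[2] = 0.465287   95% CI [0.439477, 0.478202]
     mu[1] = 0.549966   95% CI [0.470195, 0.66119]
     mu[2] = 0.132128   95% CI [0.103872, 0.17071]
    Q[1,2] = 0.0754945   95% CI [5.67055e-05, 0.293343]
```

The generating τ = 0.05 lies inside the bootstrap interval (note that
phase labels may swap between fits: only ν, μ, Q *jointly* are
identified).  The JSON report additionally gives the counterfactual PA
contribution — here switching τ to 0 with the other parameters fixed
drops the mean contact count to 73% of its fitted value.  Model
selection on the same file:

```bash
prefattach select example.csv --max-phases 2 --seed 1 --starts 4 \
    --maxfun 2000 --format text
```

```
Phases  PA Params       dAIC       dBIC  Diverge
     1  No      1    1084.00    1058.98        -
     1 Yes      2      22.42       3.65        2
     2  No      4      95.36      89.11        -
     2 Yes      5       0.00       0.00        4 [AIC] [BIC]
```

Both criteria recover the generating model class (2 phases, with PA);
the `Diverge` column is the lowest divergent degree moment of each
fitted PA model (the fitted optimum here has a divergent fourth moment
but a finite second — heterogeneous, yet controllable).  `prefattach
diagnose` prints the pmf, moments and divergence report for any fully
specified model, and `prefattach simulate` writes counts plus a JSON
sidecar with the parameters and seed, so every run is replayable.

To analyse real survey data, supply a file with either one degree per
line or a `degree,count` CSV; zero-degree rows are rejected (the model
is zero-truncated by construction).

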