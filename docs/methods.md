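# Methods

## Problem setting

Given an ODE model `f(x | θ)` observed at discrete times with known noise,
*practical identifiability analysis* asks whether a finite, noisy dataset
pins each parameter down to a finite confidence interval.  The package
implements a sequential experimental-design loop that proposes the next
measurement time most likely to establish practical identifiability, judged
by the profile likelihood:

* a parameter `θ_i` with MLE value is practically identifiable at
  confidence level `1 - α` when its profile negative log-likelihood exceeds

      threshold = nLL(θ_MLE) + χ²(1 - α, df = 1) / 2

  on *both* sides of the MLE (pointwise likelihood-ratio criterion);
* the two crossings of the profile with the threshold delimit the
  pointwise confidence interval.

Because the algorithm only needs the profile *at the search bounds* to issue
a verdict, each iteration costs one MLE fit plus `2N` constrained
("boundary") fits for `N` free parameters, rather than a full profile scan.

## The active-learning loop

Each replication starts from a single observation at a user-chosen first
time, then alternates:

1. **Estimation.**  Multi-start box-constrained L-BFGS-B produces the MLE
   and the `2N` boundary models (one parameter pinned at each bound,
   nuisance parameters re-optimised).  The boundary fits are exactly the
   profile values `pl_min`, `pl_max` used for the verdict.
2. **Verdict.**  Assessed from the second data point onwards.  A run is
   *reliably* identifiable at the second of two consecutive iterations
   whose per-parameter verdicts are all positive — a single verdict can be
   an artefact of one noisy observation.
3. **Acquisition.**  The candidate models are weighted by normalized
   likelihood, `w_i ∝ exp(-nLL_i)` (computed in the log domain), and each
   candidate grid time `x` receives the scaled weighted disagreement

       score(x) = Σ_j (1/σ̂_j²(x)) Σ_i w_i (f_j(x|θ_i) - f_j(x|θ_MLE))²

   where `σ̂_j²(x)` is the predicted observation variance of output `j`
   along the MLE trajectory under the truncated-normal noise model.  The
   argmax is measured next (ties break to the earliest time; replicate
   measurements are allowed — the pool is not depleted).
4. **Stop** at reliable identifiability (confidence intervals are then
   located by bisection) or at the observation cap (default 50).

A separate *fixed-budget* mode never stops early and always collects an
exact observation count (default 20), so that precision (CI width) and
accuracy (trajectory deviation) comparisons across strategies use equal
data; this mode finishes with a fresh multi-start MLE and a final verdict,
assigning the full search-box width to any parameter not identifiable at
the budget.

### Benchmark strategies

The comparison strategies score the grid by the variability of an ensemble
of profile models: 10 evenly spaced pin values per free parameter, each
constrained-fit; single-output models use the population variance across
the ensemble, multi-output models the determinant of the across-ensemble
output covariance (generalized variance), optionally divided by the product
of predicted noise variances (*scaled* benchmark / relative variance).
When a parameter is currently identifiable only pin values inside its most
recent profile-likelihood CI are kept (its CI midpoint if none fall
inside).  Random sampling draws uniformly from the grid.

Two open design points were resolved as follows:

* **Pin values are interior**: `linspace(lower, upper, 12)[1:-1]`.  A pin
  exactly at a bound can produce a degenerate ensemble member — a zero
  decay rate yields a trajectory that never decays — whose variance
  contribution dwarfs everything at late, uninformative times; after noise
  scaling this locks the scaled benchmark onto pure-noise measurements and
  it never achieves identifiability on the two-exponential study.  Interior
  pins restore the intended behaviour of both benchmark variants.
* **Replicates allowed**: depleting the candidate pool forces the
  selection into uninformative regions once the informative ones are used
  up; in a sensitivity run on the two-exponential study it roughly doubled
  the mean iterations to identifiability and produced frequent failures.

## Noise model

Observations are non-negative: `y = f + e` with `e ~ N(0, σ²)` truncated
below at `-f`, i.e. `y` follows a normal distribution truncated to
`[0, ∞)`:

    p(y) = φ((y-f)/σ) / (σ Φ(f/σ)),  y ≥ 0.

The likelihood uses the truncation point of the *candidate* parameter
vector (`-f(x|θ)`), since the truth is unavailable to the estimator, while
the simulator truncates at `-f(x|θ_true)`.  `log Φ` is evaluated through
`scipy.special.log_ndtr`, stable up to the `f/σ ≈ 60` values that occur in
the two-exponential study.  The predicted observation variance used for
noise scaling is the closed form `σ²(1 + αλ(α) - λ(α)²)` with `α = -f/σ`
and hazard `λ = φ/(1-Φ)`; it equals the half-normal variance `σ²(1-2/π)`
at `f = 0` and rises monotonically to `σ²`.

A consequence worth knowing: the normalizer `Φ(f/σ)` makes the MLE on
noise-free data *not* exactly the generating parameters wherever the signal
falls below `σ` — smaller predicted means are rewarded by a smaller
normalizer (up to `log 2` per observation).  On the two-exponential model
with `σ = 0.005` this shifts the noise-free MLE of the fast rate by ~0.17.
This is a property of the model, not an optimiser artefact (verified by a
dense likelihood scan), and it disappears as `σ → 0` relative to the
signal.

## Estimation details

* Optimisation runs in unit-box coordinates (`[0,1]^d` mapped affinely to
  the bounds) so finite-difference steps are comparable across parameters
  whose scales differ by orders of magnitude; L-BFGS-B with `ftol 1e-9`,
  finite-difference step `1e-6` in unit coordinates (large enough to sit
  above the integrator's `1e-8` relative tolerance noise).
* Multi-start: the MLE warm-starts from the previous iteration's MLE plus
  Latin-hypercube draws (8 starts for the analytic study, 6 for the ODE
  studies); boundary and profile-pin fits use 3 starts — the current MLE,
  the previous fit of the same profile point, and LHS fill.  Warm
  continuity matters: the microbial-growth likelihood is strongly
  multimodal (a flat high-`μMax` basin attracts most random starts), and
  the sequential loop tracks the good basin from the early, easy fits.
* Candidate weights are normalized with log-sum-exp; a raw softmax
  underflows once `nLL` differences exceed ~700 nats, which happens within
  a few dozen observations at `σ = 0.005`.

## ODE integration

The Monod bioreactor model

    d(BG)/dt = μMax · SC/(KS+SC) · BG - KD · BG
    d(SC)/dt = -(1/YieldC) · μMax · SC/(KS+SC) · BG,   BG(0)=1, SC(0)=30

is integrated by an adaptive Dormand–Prince RK45 compiled with numba
(`rtol 1e-8`, `atol 1e-10`), stepping exactly onto each requested output
time.  Against an LSODA reference at `1e-12` tolerances the solution agrees
to ≤5e-9 relative at the study parameter values and ≤2e-5 at the most
extreme corner of the bounds box (`μMax = 50 h⁻¹`).  The system is only
transiently fast — after the substrate crashes the dynamics are a slow
linear decay — so an explicit adaptive method with a step-budget guard is
adequate; step-size collapse raises a distinct `IntegrationError`, which
fitting treats as an infinitely bad parameter vector.  Tiny negative
substrate excursions are clipped inside the Monod term only.  At roughly
5–75 µs per solve, a full replicated study fits in minutes on one core.

## Confidence intervals

Bisection between each bound and the MLE value locates the threshold
crossing of the (assumed unimodal) profile, to a per-parameter tolerance
`ε_i = 1e-3 × (upper_i - lower_i)`; the relative rule keeps the probe
count comparable between boxes of width 3 (decay rates) and width ~50
(saturation constant).  Each probe is a constrained fit warm-started from
the MLE and the nearest accepted profile point; a failed probe counts as
above-threshold, widening the interval conservatively.  Probe count per
side is bounded by `ceil(log2(width/ε))` ≈ 10 at the default tolerance.

## Simulation studies and default conditions

Three presets reproduce the published study conditions exactly:

| | model | free parameters (truth) | σ | grid (h) | first obs |
|-|-------|------------------------|---|----------|-----------|
| 1 | two-exponential decay | β1=2, β2=4 (bounds [0,3], [3,6] hr⁻¹) | 0.005 | 1:0.1:10 | t=3 |
| 2 | Monod, BG observed | μMax=1, KD=0.1, YieldC=0.5; KS fixed 30 | 2.0 | 1:0.5:60 | t=10 |
| 3 | Monod, BG+SC observed | μMax=0.5, KS=30, KD=0.05, YieldC=0.6 | 0.5 / 1.6 | 1:0.5:60 | t=10 |

Replication `r` of a study derives three independent RNG streams (noise,
optimiser starts, random selection) from `(seed, r)`, so strategies
compared under one seed face identical noise wherever their datasets
coincide and paired tests (Wilcoxon signed-rank; exact for n ≤ 25) are
meaningful.

The generator emulates exactly the synthetic conditions above; it does not
emulate real-data artefacts (missing samples, batch effects, correlated or
heteroscedastic errors beyond the mean-dependent truncation).  Passing
tests therefore demonstrate correctness of the algorithmic machinery under
the stated noise model, not robustness on wet-lab data.

### Problem sizes

The test suite reruns the studies at reduced replication counts (12–20 for
the analytic study, 3–6 for the ODE studies) and the acceptance script at
100 / 25 / 25 replications for studies 1 / 2 / 3; these sizes keep a full
rerun in the tens of minutes on one core while leaving Monte-Carlo standard
errors small relative to the published between-method differences for the
precision and accuracy metrics.

## Known limitations and observed deviations

* **Unimodal profiles assumed.**  The bisection CI search can return
  intervals that are too wide on strongly multimodal profiles; no
  multi-interval scan is attempted.
* **Verdict-speed calibration.**  Random sampling and the fixed-budget
  precision/accuracy metrics reproduce the published values closely
  (random mean iterations ~49 vs 49.2; CI(β1) ~0.13 vs 0.115 ± 0.003;
  trajectory deviation ~1.5e-4 vs 1.59e-4 ± 1e-5).  The mean iterations to
  *reliable identifiability* of the active strategies, however, run
  consistently above the published means (e.g. ~12.5–13 vs 9.46 on the
  analytic study).  Three lines of evidence locate this in the
  profile-likelihood implementation details rather than in acquisition:
  an oracle sweep over fixed sampling patterns shows no pattern achieves a
  mean below ~13 under this package's verdict machinery, the adaptive
  algorithm already selects the best such pattern, and dense well-optimised
  profile scans confirm the slow verdicts (the saturation constant's
  profile is genuinely flat toward its upper bound early on, absorbed by
  the μMax ridge).  More deeply optimised nuisance fits make profiles
  flatter and verdicts more conservative; the package errs on the side of
  optimisation quality.
* **Scalability.**  Per iteration the loop performs `2N+1` fits (the
  benchmarks ~`10N`); no parallelism is used, and models beyond a handful
  of parameters or two outputs have not been exercised.
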