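# ealpipe

Active learning of measurement time points for **practical identifiability**
of ODE models, via profile likelihood.

In systems-biology and bioengineering models, parameters estimated from
sparse, noisy time courses are often *practically non-identifiable*: the
data admit a whole range of parameter values with near-equal likelihood.
`ealpipe` implements a sequential experimental-design loop (E-ALPIPE) that,
given the model, the noise model and the data collected so far, recommends
the next measurement time most likely to make all parameters identifiable —
together with the generalized-variance benchmark strategies, random
sampling, and a fully seeded simulation/evaluation harness for comparing
them.

## The method in brief

A parameter θᵢ is practically identifiable at 95% confidence when its
profile negative log-likelihood exceeds

    threshold = nLL(θ_MLE) + χ²(0.95, 1)/2

on both sides of the MLE; the crossings bound the pointwise confidence
interval (located here by bisection).  Each iteration, the loop fits the
MLE plus the 2N *boundary models* (each free parameter pinned at a search
bound, nuisance parameters re-optimised — exactly the profile values at the
bounds), weights them by normalized likelihood wᵢ ∝ exp(−nLLᵢ), and scores
every candidate time x by the scaled weighted disagreement

    score(x) = Σⱼ (1/σ̂ⱼ²(x)) Σᵢ wᵢ (fⱼ(x|θᵢ) − fⱼ(x|θ_MLE))²,

where σ̂ⱼ²(x) is the predicted variance of output j under the
lower-truncated normal noise model (observations are non-negative).  The
argmax is measured next; the loop stops once every parameter is
identifiable on two consecutive iterations, or at an observation cap.

Two model families ship built in: an analytic two-exponential decay
y(t) = e^(−β₁t) + e^(−β₂t), and a Monod-kinetics bioreactor (bacterial
growth BG and substrate SC, one- and two-output variants) integrated by a
numba-compiled adaptive RK45.  User models register a forward callable
under a string id.  See `docs/methods.md` for the full model and design
notes.

## Worked example

```python
import numpy as np
from ealpipe import experiment_preset, run_replication

cfg = experiment_preset(1)           # two-exponential study, truth (2, 4)
trace = run_replication(cfg, rep=1)

print("stopped after", trace.n_obs, "observations:", trace.termination)
print("MLE:", np.round(trace.final_mle_theta, 3))
for name, ci in trace.final_report.ci.items():
    print(f"  {name}: CI [{ci.lower:.3f}, {ci.upper:.3f}] width {ci.width:.3f}")
```

prints

```
stopped after 8 observations: reliable_identifiability
MLE: [2.01  3.841]
  beta1: CI [1.917, 2.167] width 0.251
  beta2: CI [3.139, 5.052] width 1.914
```

i.e. starting from one observation at t = 3 h, seven adaptively chosen
measurements sufficed to certify both decay rates identifiable at 95%
confidence; β₁ (the slow rate, which dominates the observable signal) is
pinned roughly eight times more tightly than β₂, whose fast component
decays below the noise floor within a couple of hours — exactly the
asymmetry the profile likelihood quantifies.

The same loop is available from the shell:

```
ealpipe run --experiment 1 --method ealpipe --reps 10 --seed 0 --out runs/
ealpipe report --in runs/ --out report/
```

`report/` then holds delimited-text tables of the three study metrics:
mean iterations to reliable identifiability (failures scored at the cap),
per-parameter CI widths at a fixed 20-observation budget (full search-box
width assigned when not identifiable), and the mean absolute deviation
between fitted and true trajectories over the candidate grid.

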