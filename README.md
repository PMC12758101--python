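# prtddm

Reinforcement-learning drift-diffusion modeling of the Probabilistic
Reward Task (PRT).

The PRT is a signal-detection task used throughout clinical and
computational psychiatry to measure reward responsiveness: correct
identifications of one ambiguous stimulus (the "rich" stimulus) are
rewarded three times more often than the other ("lean"), and healthy
participants gradually develop a bias toward the rich response.  Classic
analyses summarize this with signal-detection statistics; this package
additionally implements the **Action-DDM**, a model in which delta-rule
learning of *response-outcome* values drives a drift-diffusion choice
process:

    Q_{t+1}(chosen) = Q_t(chosen) + α (r − Q_t(chosen)),   r ∈ {0, 1}
    ΔQ_t  = Q_t(rich) − Q_t(lean)
    v_t   = s · v_intercept + B_v ΔQ_t        (s = +1 rich / −1 lean stimulus)
    z_t   = e^{B_z Q_t(rich)} / (e^{B_z Q_t(rich)} + e^{B_z Q_t(lean)})

with the Wiener first-passage-time distribution supplying the likelihood
of each (choice, RT) pair between the lean (lower) and rich (upper)
boundaries.  ΔQ thus modulates both the evidence-accumulation rate (via
B_v) and the pre-stimulus starting-point bias (via B_z) — separating
*how fast* people learn from rewards (α) from *how strongly* learned
values bias their decisions (B_v, B_z) and from baseline processing
efficiency (v_intercept), caution (a) and motor/encoding time (t).

The package is aimed at researchers running PRT (or PRT-like) studies
who want trial-level computational modeling with a validation story:
everything the model claims is checked on simulated data generated by
the package itself.

## What's inside

| module | contents |
| --- | --- |
| `prtddm.task` | data model, 2×100-trial schedule generation (Bernoulli or queued 3:1 reward rules), quality control, CSV IO |
| `prtddm.core` | Action-DDM equations, WFPT log-density, sequential subject likelihood, the six-model variant lattice |
| `prtddm.simulate` | first-passage sampling, forward simulation, synthetic cohorts with group-level distributions and injected group effects |
| `prtddm.inference` | hierarchical Bayesian MCMC (adaptive Metropolis-within-Gibbs, numba-compiled), split-chain R-hat, WAIC model comparison |
| `prtddm.stats` | response bias / discriminability (Eq.-style ½·log₁₀ with 0.5 correction), RT-speed contrasts, Spearman-Brown and ICC reliability, group tests |
| `prtddm.validate` | posterior predictive checks, parameter recovery |
| `prtddm.cli` | `prt` command: `simulate-schedule`, `simulate-cohort`, `fit`, `stats`, `validate` |

## Worked example

Simulate a 20-subject cohort, fit the hierarchical Action-DDM, and look
at one subject's behavior:

```python
import numpy as np
from prtddm import CohortSpec, simulate_cohort
from prtddm.inference import MCMCConfig, fit_hierarchical, extract_subject_estimates
from prtddm.stats import behavioral_summary

subjects, truth = simulate_cohort(CohortSpec(groups={"NC": 20}, seed=3))

summ = behavioral_summary(subjects[0])
print(summ.table.loc["average", ["response_bias", "discriminability", "rich_acc", "lean_acc"]])

draws, report = fit_hierarchical(subjects, "full", MCMCConfig.fast(seed=4))
print(f"max R-hat: {report.max_rhat:.3f}")

est = extract_subject_estimates(draws)
r = np.corrcoef(truth["t"], est["t"])[0, 1]
print(f"non-decision-time truth-vs-estimate r: {r:.3f}")
```

prints (seeds as above):

```
response_bias       0.049177
discriminability    0.308508
rich_acc            0.696970
lean_acc            0.646465
Name: average, dtype: float64
max R-hat: 1.017
non-decision-time truth-vs-estimate r: 0.998
```

The first block is the subject's session-average signal detection
profile: a small positive response bias (log₁₀ units) from a subject at
the lower end of the cohort's discriminability range.  The fit converges (R-hat well under the 1.1
threshold), and the fitted non-decision times track the generating ones
almost perfectly — the learning-side parameters (α, B_v, B_z) recover
more loosely, which is expected from a single 200-trial session (see
`docs/methods.md`).

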