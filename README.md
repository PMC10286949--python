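# bmbu — boundary updating and the repulsive bias in binary classification

When people repeatedly sort stimuli into two classes ("small" vs "large"),
their choices are repelled by recent history: after a large ring, the next
ring is more often called small. Two mechanisms can produce this repulsive
bias — adaptation of the sensory representation, or an internal class
boundary that is attracted toward recent stimuli. This package implements a
Bayesian model of boundary updating (BMBU) together with the full analysis
chain used to arbitrate between the two mechanisms: model fitting and
comparison, trial-to-trial latent-state estimation with a recovery battery,
behavioral history-bias statistics, average-marginal-effect (AME) mediation
contrasts, V1-style size readouts with sensory adaptation, and a model-based
searchlight decoding/validation pipeline. Everything runs on synthetic
cohorts with known ground truth; no external data are required.

It is written for computational-neuroscience and psychophysics researchers
who want to fit boundary-updating observers to binary-classification data,
or to stress-test a model-based decoding pipeline end to end.

## The model

An observer with parameters Θ = {μ₀, σ₀, σₘ, κ} classifies the ring size
S(t) on trial t:

* **Stimulus inference.** A noisy measurement m(t) ~ N(S(t), σₘ) is combined
  with the prior N(μ₀, σ₀²), giving the inferred size s(t) with
  μₛ = (σ₀²·m + σₘ²·μ₀)/(σ₀² + σₘ²) and σₛ = σ₀σₘ/√(σ₀² + σₘ²).
* **Boundary inference.** Measurements retrieved from up to 7 preceding
  trials of the same run carry decayed precision, σᵣ(t−i) = σₘ(1+κ)ⁱ. The
  boundary b(t) is the posterior mode of the typical size given those
  retrievals: b(t) = β₀μ₀ + Σᵢ βᵢ r(t−i), with precision weights
  β₀ ∝ σ₀⁻², βᵢ ∝ σᵣ(t−i)⁻² normalised to sum to 1. Because recent memories
  are more precise, the boundary is attracted to recent stimuli — which
  repels the choice.
* **Decision.** v(t) = Φ[(s−b)/√(σₛ²+σᵦ²)]; the choice is *large* iff
  v > 0.5, and the decision uncertainty is u = Φ[−|s−b|/√(σₛ²+σᵦ²)].

Marginalising the measurement and retrieval noise yields a closed-form
choice probability, P(large) = Φ[(E μₛ − E μᵦ)/√(Var μₛ + Var μᵦ)], which is
the per-trial likelihood used for maximum-likelihood fitting (a Monte-Carlo
likelihood is retained as a test oracle). The control model holds the
boundary constant at μ₀.

## Worked example

```python
from bmbu import ObserverParams, choice_probability
from bmbu.synth import CohortSpec, make_cohort
from bmbu.behavior import fit_history_kernel
from bmbu.fitting import FitConfig, fit_bmbu, fit_constant, compare_models

# a small ring one trial ago pushes the current choice toward "large"
p = ObserverParams(mu0=0.0, sigma0=5.0, sigma_m=1.0, kappa=0.5)
print(choice_probability(0.0, [-1.0], p))        # 0.7076332078292232

# simulate an observer cohort and quantify its repulsive bias
rec = make_cohort(CohortSpec(n_subjects=1, seed=11))[0]
kernel = fit_history_kernel(rec.table)
print(round(kernel.coef["stimulus"], 3),          # 1.113  (stimulus drive)
      round(kernel.coef["stim_lag1"], 3))         # -0.599 (repulsive lag-1)

# the updating model beats the constant-boundary control on its own data
fit_b = fit_bmbu(rec.table, FitConfig(n_starts=50, n_top=10, seed=0))
fit_c = fit_constant(rec.table, FitConfig(seed=0))
cmp = compare_models(fit_b, fit_c, rec.table)
print(round(cmp.delta_aic, 2))                    # -15.92
```

The choice probability above 0.5 is the repulsive bias in closed form; the
negative lag-1 kernel coefficient is the same bias measured from simulated
choices; and the negative AIC difference says the 4-parameter updating model
explains those choices better than the 2-parameter constant-boundary model
even after the complexity penalty.

## The analysis pipeline

Numbered drivers under `analysis/` run the full study on synthetic data and
write tables to `results/`:

| script | what it does |
| --- | --- |
| `01_task_design.py` | m-sequence run schedules; staircase + Weibull threshold calibration |
| `02_simulate_cohort.py` | boundary-updating cohort with ground truth |
| `03_fit_models.py` | per-observer ML fits, AIC and Nagelkerke R² comparison |
| `04_behavior_stats.py` | conditioned P(large) differences and history kernels |
| `05_latent_recovery.py` | 16-set parameter grid latent-state recovery |
| `06_v1_adaptation.py` | V1-style readouts, adaptation regression, AME contrasts |
| `07_searchlight_battery.py` | searchlight SVR decoding and the regression battery |
| `08_network_scan.py` | BIC scan over three-node causal networks |

On the default cohorts these reproduce the qualitative structure of the
phenomenon: a negative previous-stimulus effect on P(large) (−0.26) with a
null previous-choice effect (+0.01), history kernels significant to two lags
(S(t−1) −0.62, S(t−2) −0.30), AIC favoring boundary updating in every
observer, a regression battery that passes exactly in the brain regions
where the matching latent variable was embedded, and a causal scan whose
best graph is b→v←s with every b–s-linked graph at ΔBIC > 2.

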