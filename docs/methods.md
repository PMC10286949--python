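# Methods

## The observer model

The observer classifies a ring size S(t) as *small* or *large* relative to
an internal boundary. The generative account has four parameters:

| parameter | meaning | units | typical range used here |
| --- | --- | --- | --- |
| μ₀ | prior mean of the typical size | coded size (Δ) | −0.3 … 0.3 |
| σ₀ | prior sd of the typical size | Δ | 1.5 … 3 |
| σₘ | sensory measurement noise | Δ | 0.6 … 1.0 |
| κ | memory-decay rate per trial | — | 0.5 … 0.9 |

Sizes are coded in threshold units: S ∈ {−1, 0, +1} for the small, medium
and large rings, with Δ the calibrated contrast. A measurement retrieved
from i trials back has noise σᵣ(t−i) = σₘ(1+κ)ⁱ; at most 7 retrievals are
used and retrieval never crosses a run boundary (runs are separated by long
gaps). Retrievals are drawn fresh every trial, so the latent states at
trial t depend on the stimulus history only — never on the observer's own
past choices. The boundary posterior is conjugate-normal; its mean is the
precision-weighted combination of the prior and the retrievals
(weights β₀, β₁ > β₂ > … when κ > 0, summing to 1) and its dispersion
equals the conjugate form 1/√(σ₀⁻² + Σσᵣ⁻²).

The typical ranges were pinned to the behavioral regime the task enforces:
μ₀ near 0 because the overall proportion of *large* responses sits near
0.5; σₘ such that accuracy sits at or somewhat above the calibrated
70.7%-correct point; and κ such that the ratio of lag-2 to lag-1
history-kernel weights, (1+κ)⁻², falls in the 0.25–0.45 band this task
produces. The default cohort draws each subject's parameters uniformly from
these ranges.

Decision rule: v = Φ[(s−b)/√(σₛ²+σᵦ²)], *large* iff v > 0.5. The
measure-zero tie v = 0.5 is resolved by a seeded fair coin so simulations
are reproducible. u = Φ[−|s−b|/√(σₛ²+σᵦ²)] equals min(v, 1−v).

## Likelihood and fitting

Because d = *large* ⟺ μₛ > μᵦ and both posterior means are linear-Gaussian
in the measurement and the retrievals, the per-trial choice probability has
the closed form Φ[(E μₛ − E μᵦ)/√(Var μₛ + Var μᵦ)]. A Monte-Carlo
likelihood exists only as a test oracle; the two agree within 0.005 at 10⁶
draws across random parameter sweeps.

Fitting maximises the summed log-likelihood of the valid choices
(probabilities floored at 1e−12) with a three-stage bounded Nelder–Mead
multistart: many short searches (50 function evaluations) from uniform
random initial points within bounds, refinement of the best 20 candidates at
tolerance 1e−7 (cap 10⁵ evaluations), and one repeat of the refinement from
its own optima. Default bounds: μ₀ ∈ [−3, 3] Δ around the design mean,
σ₀ ∈ (0, 10], σₘ ∈ (0, 5], κ ∈ [0, 3]. The library default is 50 starts
(desk scale); the recovery battery and the acceptance script use 100.

Excluded as outcomes (but kept as history): the first trial of each run
(no previous trial) and trials with RT < 0.3 s (the bound is strict:
RT = 0.30 s is kept). The constant-boundary control (b ≡ μ₀, σᵦ = 0,
parameters μ₀ and σₘ) is fitted the same way; it is the κ → ∞ limit of the
updating model, so the updating fit never scores a worse log-likelihood
beyond optimizer tolerance. Model comparison uses AIC (k = 4 vs k = 2) and
the Nagelkerke pseudo-R² against an intercept-only null.

At a single-session size (208 trials of binary outcomes) the likelihood
surface is flat along μ₀/σ₀/κ trade-offs: refits often land on
likelihood-equivalent optima whose individual parameters sit far from the
generating values, sometimes at the bounds. This is an information limit of
the data, not of the optimizer — more starts find the same optima — and it
is the binding constraint on the recovery battery below.

## Latent-state estimation and recovery

Given parameters and an observed choice sequence, the per-trial states of
s, b, v, u are estimated by simulating the observer many times on the same
stimulus sequence (default 10⁵ repetitions; the batteries here use 2×10⁴)
and averaging, per trial, over the repetitions whose simulated choice
matches the observed one. Conditioning is per-trial because the latents are
independent of past choices. Simulation proceeds in fixed-size blocks to
bound memory. If a trial's observed choice has probability below the
budget's resolution (which happens under degenerate refits that assign an
observed choice ~10⁻⁶), the estimate for that trial falls back to the exact
conditional mean: (μₛ, μᵦ) are jointly Gaussian and the choice conditions on
the sign of μₛ − μᵦ, so E[s|D] and E[b|D] follow from truncated-Gaussian
formulas and E[v|D] from a one-dimensional quadrature. The simulation
averages converge on these same quantities; the tests verify the agreement.

The recovery battery asks how robust the state estimates are to
parameter-estimation error. For each generating parameter set on a 16-point
factorial grid (the corners of the ranges above): simulate one synthetic
session on an 8-run × 26-trial design, refit by maximum likelihood,
estimate the states under the fitted parameters, and score them against the
estimates under the generating parameters by squared Pearson correlation
across valid trials (an SSE-based R² is reported alongside; the two differ
when a degenerate refit changes the scale of the boundary series). The
figure of merit is deliberately estimate-vs-estimate: the realized
single-draw latent trajectory contains irreducible trial-wise retrieval
noise of variance ≈ σᵦ², which at threshold-level σₘ is comparable to the
history-driven signal variance, so no estimator conditioned only on the
choices can track it (the battery reports that reference R² too — it
averages ≈ 0.44 for b). On the default grid the battery averages
R² ≈ 0.94 (b), 0.96 (s), 0.996 (v); the occasional low-scoring set is a
refit that landed on a likelihood-equivalent optimum with κ̂ ≈ 0, which
flattens the lag profile of the boundary series. Averaging each set over
many independent sessions would dilute such draws, but the battery keeps
one session per set to match its desk scale.

## Behavioral statistics

* **PL differences.** The previous-stimulus effect is the mean, over the
  (current stimulus × previous choice) cells, of P(large | previous L) −
  P(large | previous S); the previous-choice effect is defined analogously
  over (current × previous stimulus) cells. Cells missing either flank are
  dropped from the mean.
* **History kernel.** Per-subject logistic regression of the choice on
  z-scored {S(t), S(t−1..5), D(t−1..5)}; trials with fewer than five prior
  same-run trials are dropped, so lagged regressors never cross runs.
  Perfect separation falls back to an L2-regularized fit and is flagged.
* **AME.** For a focal trial signal X, the logistic model
  D(t) ~ X + D(t−1) + controls is fitted per subject and the AME of X is
  β_X · mean(p(1−p)) — the analytic derivative of the logistic mean, which a
  finite-difference oracle reproduces to 1e−6. The suite computes the four
  control variants (none / S(t−1) / S(t) / both; D(t−1) always controlled)
  and paired two-tailed t tests across subjects on the four change
  contrasts. A signal that mediates the previous stimulus loses AME when
  S(t−1) is controlled; one that mediates the current stimulus loses it when
  S(t) is controlled. Group inference here is by paired t tests, not a
  mixed model.

## V1-style size readout and adaptation

Eccentricity tuning is a Gaussian g_e(ε) = exp(−(ε−e)²/2σ²); a voxel's
predicted series is the stimulus movie projected through g_e, convolved with
the hemodynamic kernel (default: unit-sum double gamma sampled at the frame
rate; injectable), scaled and offset. Gain and baseline are profiled by
linear least squares while (e, σ) are grid-initialised and refined by
simplex. Flat series and zero-gain voxels are flagged, and voxels whose
variance exceeds 10× the median are excluded as vessel artifacts.

The tuned response subtracts the across-bin mean at every frame (21 bins by
default). Readout weights follow the three schemes — uniform sign around
the medium-ring radius, tuned-response discriminability g(r_L) − g(r_S)
minus its across-bin mean, and the Gaussian log-likelihood-ratio form — and
the per-trial signal is the weighted bin sum at the chosen within-trial
frame (default the fourth; frame timing is a configuration knob because the
trial spans ~6 frames and the response peak sits near frame 4).

The synthetic V1 generator injects gain·g(r(S(t))) − λ·gain·g(r(S(t−1)))
per bin, convolved over the trial window, plus noise. For the
pipeline-level mediation analysis the working point is λ = 0.2 with bin
noise sd 1.0 at 8 subjects: adaptation is then reliably present in the
direct regression (the lag-1 coefficient drops in every subject when λ is
switched on with identical noise draws) while the AME of the V1 signal on
choice is *not* significantly reduced by controlling S(t−1) but is abolished
by controlling S(t). That asymmetry is a power statement, and deliberately
so: the adaptation-mediation path contributes a second-order effect
(adaptation share × history-kernel strength) that sits below the paired-test
resolution at this cohort size, exactly the regime in which a direct
regression detects adaptation while the mediation contrast stays null.
Raising λ or the cohort size far enough makes the mediation contrast
significant — the dissociation is a property of realistic effect sizes, not
of the arithmetic.

## Searchlight decoding and the validation battery

Searchlights collect all voxels within a Euclidean radius of a gray-matter
center (radius 3 voxels ⇒ at most 123 members) and drop CSF/white-matter
members. Decoding is linear support-vector regression (C = 1, ε-tube 0.1)
with features and target z-scored on the training folds of a
leave-one-run-out cross-validation; constant feature columns are dropped
with a warning. Decoded per-trial maps are smoothed with a unit-sum 5 mm
FWHM Gaussian, reflective borders (which preserves the map mean); off a
full support the smoothing is renormalised by the smoothed support mask.
Passing centers are clustered by face adjacency (6-connectivity) with a
minimum cluster size of 12 centers.

The battery encodes the regression conditions a decoded signal must satisfy
to count as the brain signal of b, s or v — 14, 14 and 17 conditions
respectively: positive coverage of the claimed variable (also after
orthogonalizing it to its causal offspring, and at a stricter 0.001
threshold for the primary condition), the correct signed relations to the
other latents and the choice, no relation where the causal graph forbids
one, and the correct multiple-regression profile on
[S(t), S(t−1), S(t−2), D(t−1), D(t−2)] (plus D(t) for v). "Must not be
significant" conditions pass when the tail p exceeds the threshold. The
condition flagged for false-discovery-rate control is meaningful when the
battery sweeps many centers; on a single series the BH-adjusted p equals the
raw p, so the battery evaluates it unadjusted and exposes raw p-values for a
map-level caller to adjust. Group coefficients come from a linear mixed
model with subject as the grouping factor — random intercept plus a random
slope for the focal regressor in the simple models, intercept-only in the
multiple model and as a fallback on convergence failure, with
cluster-robust pooled OLS as the last resort.

One property of the method deserves emphasis: the choice-conditioned
estimates of b and s are not orthogonal even though the underlying states
are — conditioning on the same binary choice induces a cross-correlation of
roughly −0.25 between them. A decoded signal that tracks the true boundary
*too* faithfully therefore shows a statistically significant (negative)
association with the s estimate and fails the "no association with s"
condition. The battery is informative in the moderate-fidelity regime real
fMRI decoding occupies; the synthetic embedding default (per-voxel SNR
≈ 0.11, searchlight decode fidelity r ≈ 0.2–0.3) is chosen to sit there,
and at that working point each battery passes exactly in the region
embedding its variable and fails everywhere else.

## Causal-network scan

Every pair among {b, s, v} carries →, ← or no edge: 27 edge structures per
node combination (× the number of candidate signals per variable; 3 × 2 × 1
signals give 162 networks). Each acyclic structure is scored as a
linear-Gaussian network — each node regressed on its parents, BIC =
k·ln N − 2·loglik with k counting intercepts, slopes and residual variances
— and ranked; the two fully cyclic orientations admit no valid
factorization and are enumerated but unscored. Graphs more than 2 BIC units
above the best are flagged as decisively worse. Candidate signals for this
scan must be readouts of the *realized* states (as brain signals are): the
conditioned estimates carry the cross-correlation described above and would
manufacture a spurious b–s edge.

## Task design and calibration

The stimulus order within a run is one period (26 trials) of a base-3,
power-3 maximal-length shift-register sequence — every nonzero length-3
window occurs exactly once, the zero symbol 8 times and each nonzero symbol
9 times — rotated to begin with two zero symbols (two medium rings; two
such rotations always exist). Distinct runs draw, seeded, among the
primitive polynomials (found by exhaustive full-period search) and the
valid rotations. Session-level lag-1 autocorrelation of the coded sizes is
below 0.05 by construction.

Threshold calibration interleaves four one-up-two-down staircases (two from
the easiest, two from the hardest of 20 levels) with veridical feedback,
then fits a Weibull P(correct|x) = γ + (1−γ−λ)(1−exp(−(x/α)^β)) by maximum
likelihood with γ = 0.5 and λ = 0.02 fixed, and reads the threshold Δ at
P = 0.707. The one-up-two-down rule converges at √½ = 70.7% correct
provided the ladder step is small relative to the psychometric spread; with
a steep observer (spread comparable to the step) the equal-step rule
converges measurably below that point, so the synthetic calibration
observer uses a cumulative-Gaussian psychometric with spread 0.8 on the
0.1-step ladder. Convergence is estimated as the mean presented level at
the late reversals, pooled across staircases after discarding the first two
reversals of each.

## What the synthetic data do and do not show

The generators reproduce the task's design structure (m-sequence order,
run/trial counts, threshold-level accuracy), choices governed by the
boundary-updating process with known parameters, and volumetric signals
whose only structure is the linear embedding of a chosen latent at a chosen
frame. They omit everything else about real fMRI: hemodynamic
nonlinearity, spatial autocorrelation of noise, physiological confounds,
registration error, and subject-level variation in hemodynamics. Passing
tests therefore demonstrate that the pipeline is correct and specific — it
finds embedded latents and rejects mismatched ones under known conditions —
not that it would detect such signals at any particular real-data effect
size. Likewise the behavioral signatures (negative previous-stimulus
kernel, null previous-choice kernel) are consequences of the generative
model, shown in sign and structure rather than magnitude.

## Problem sizes and numerics

The test suite and the acceptance script run the recovery battery at 16
parameter sets × one 208-trial session, 100-start refits and 2×10⁴
conditioning repetitions; the decoding battery uses 6 subjects on a
14×14×10 voxel grid with 27-voxel regions and radius-2 searchlights.
Probabilities are floored at 1e−12 before logs; boundary weights are exact
rationals of precisions; the σᵦ identity (β-form vs conjugate form) holds to
1e−10 and is property-tested; seeded generators make every simulation,
fit and battery bit-reproducible under a master seed.

## Known limitations

* Parameter non-identifiability at single-session size is the dominant
  error source in recovery; pooling sessions per fit resolves it but
  changes the battery's meaning.
* The memory-decay law is fixed to exponential; hyperbolic or power decay,
  choice-history (motor) kernels and lapse rates are out of scope.
* The battery's map-level FDR condition and cluster rule are implemented,
  but the shipped analyses exercise them at region centers rather than over
  whole-brain maps, to stay at desk scale.
* The alternative 87-voxel searchlight has no Euclidean-lattice radius that
  produces it and is not implemented.
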