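# Methods

## Model

`burstfit` infers the kinetics of stochastic transcription from population
snapshots of smFISH data: per-cell counts of mRNA molecules (m) and active
transcription sites (TS), sampled at one pre-stimulus and several
post-stimulus times. The default model is the two-state (telegraph) promoter
in a diploid, post-mitotic cell: each of the two independently regulated
alleles switches on with rate k1 and off with rate k0 (min⁻¹), synthesizes
mRNA at mu1 when on and mu0 when off (mRNA·min⁻¹), and every transcript
decays with rate delta (min⁻¹). Because alleles are exchangeable, the cell
state is x = (rho1, m) with rho1 ∈ {0,1,2} the number of active alleles.
The four reactions and their propensities are

| reaction      | change       | propensity              |
|---------------|--------------|-------------------------|
| activation    | rho1 → rho1+1 | k1 · (2 − rho1)        |
| inactivation  | rho1 → rho1−1 | k0 · rho1              |
| synthesis     | m → m+1       | mu0·(2 − rho1) + mu1·rho1 |
| degradation   | m → m−1       | delta · m              |

Reactions are data (stoichiometry + rate rule over named parameters), so
other single-gene architectures can be declared without touching the
solvers; the package does not model replicated (3–4 copy) genomes,
inter-allele correlation, or nascent-mRNA intensity.

A *parameter–stimulus model* is a hypothesis about which parameters jump at
the stimulus (t = 0): theta^U before, theta^S after, identical elsewhere.
Each stimulated parameter contributes two free values; delta is normally
fixed to an independently measured value.

## Distributions

The chemical master equation dP/dt = A(theta)·P is solved on the state
space truncated at m ≤ M (N = p(M+1) states, default M = 500, indexed
rho1·(M+1)+m). The sparse generator keeps columns summing to zero:
reactions that would cross the m = M boundary are removed outright, so the
truncated process conserves probability.

* **Stationary law** (pre-stimulus): the null vector of A(theta^U). In
  promoter-fastest ordering the generator is banded (bandwidth p), so the
  default solver is inverse iteration with a tiny negative shift
  (−10⁻¹⁰·max|A_ii|) and a banded LAPACK factorization — deterministic and
  O(N p²). An Arnoldi route (dominant eigenvector of A + cI with
  c = max|A_ii|; Gershgorin maps the null eigenvalue to the dominant one)
  and a dense null-space solve (N ≤ 5000) back it up; all routes must meet
  ‖A·P*‖∞ ≤ 10⁻¹⁰. Entries in (−10⁻¹⁴, 0) are clipped and renormalized;
  anything more negative raises.
* **Transients** (post-stimulus): P(tau) = exp(A(theta^S)·tau)·P* by
  uniformization — the Poisson-weighted series over the uniformized
  stochastic matrix S = I + A/Lambda, truncated when the Poisson tail drops
  below 10⁻¹⁴ and segmented so Lambda·dt ≤ 350 stays in floating range. The
  series is nonnegative and mass-preserving term by term; tests verify
  agreement with SciPy's independent `expm_multiply` to ~10⁻¹⁵. Checkpoint
  times are evolved in one increasing pass.
* **Truncation error**: the conserving truncation keeps the total mass at 1
  up to roundoff, so the mass deficit of `evolve` only monitors solver
  health. The certified finite-state-projection bound comes from
  `fsp_error`, which propagates under the *absorbing* generator variant
  (boundary outflow kept on the diagonal); 1 − sum is then exactly the
  escaped probability. With the real-data-scale parameters of the worked
  example this is ≲10⁻¹³ at M = 500, tau = 25 min.

## Likelihood and posterior

Each time point is one multinomial draw of n_t cells over states: ln L sums
ln(n_t!) − Σ ln(Y!_k) + Σ Y_i ln P(x_i, tau_t), with t = 0 scored against
the theta^U stationary law and t > 0 against the theta^S transients, all
via log-gamma. The theta-independent coefficient is included so stored
likelihoods feed information criteria on a common scale. Probabilities at
or below 10⁻³⁰⁰ make the proposal impossible (−inf, auto-rejected).

The prior is flat with Heaviside bounds: components below 10⁻⁸ are
non-physiological; transcription rates are capped at mu_max = 18 mRNA/min
(polymerase-traffic ceiling; plausible range 12–18, configurable).
Switching rates are unbounded above. The evidence P(Y) is never computed;
reported values are unnormalized log-posteriors.

Sampling is plain random-walk Metropolis on the linear parameter scale with
a fixed diagonal covariance; rejected proposals repeat the state, proposals
outside the prior box skip the likelihood, and runs are bitwise reproducible
from the seed. Burn-in is detected as the first iteration whose
log-likelihood is within 0.5% of the chain maximum (capped at T/2 with a
warning) — for negative log-likelihoods the "99.5% of maximum" rule is read
as a band of width 0.005·|L_max| below the maximum.

### Initialization and proposal calibration

With T = 10⁵ iterations a blind random start eventually burns in, but the
two-state likelihood has a label-swapped mirror basin (mu0 ↔ mu1 with
k1 ↔ k0 roles exchanged) that small-step Metropolis cannot leave, and at
reduced iteration budgets burn-in dominates the run. `fit_mcmc` therefore:

1. builds a method-of-moments start — TS fractions at the first/last time
   give the burst fractions p = k1/(k1+k0); the TS-fraction relaxation over
   the first interval gives k1^S + k0; pre-stimulus and extrapolated
   post-stimulus mRNA means give (mu0, mu1) by a 2×2 linear solve — clamped
   into the prior box;
2. polishes it with Nelder-Mead on log-parameters to the approximate MLE;
3. sets the proposal covariance by a Laplace estimate at that point:
   central-difference curvature of −ln L per component, proposal sd =
   2.4/√m of the implied scale (the classic Metropolis scaling), frozen
   before sampling. Components with non-positive curvature fall back to the
   historical defaults (variance 10⁻⁵ for k1, k0, mu0 and 10⁻³ for mu1,
   which remain `default_sigma` for direct `metropolis_run` use).

The recorded chain itself is non-adaptive Metropolis. Replica fits jitter
the start multiplicatively (`init_jitter`) so chains are independent.

## Model selection

BIC = −2 ln L̂ + m ln n and AICc = −2 ln L̂ + 2m + 2m(m+1)/(n−m−1) use the
maximum likelihood seen in the run; n is the total number of cells over all
time points (each cell is one draw; a per-time-point convention can be
computed by the caller). A legacy variant with the 2m term negated is
available as `aicc(..., as_printed=True)` for comparison with sources that
print the formula that way. DIC = 2·D̄ − D(θ̄) uses the post-burn-in mean
deviance and one extra likelihood evaluation at the post-burn-in mean
parameters (means on the linear sampling scale). Ties in rankings break
toward fewer free parameters.

## Synthetic data and the SSA oracle

`simulate_snapshots` samples n cells per time point multinomially from the
model's own distributions — exactly the population-snapshot measurement
process, with sampling error as the only replicate-to-replicate difference.
Defaults mirror the validation experiments: times (0, 5, 15, 25) min and
n = 100 cells per time point. `truth_presets` returns the two ground-truth
models used throughout: the k1-stimulus model (k1: 0.01→1, k0 = 0.1,
mu1 = 2, mu0 = 0.01, delta = 0.05) and the (k1,k0,mu1)-stimulus model
(k1: 0.01→1, k0: 1→0.01, mu1: 0.2→2, mu0 = 0.01, delta = 0.05).

What the generator does *not* emulate: detection noise on spot counts,
partial probe hybridization, segmentation errors, cell-cycle allele
duplication, and inter-allele correlation. Passing recovery tests therefore
demonstrates correctness of the inference machinery under the model's own
assumptions, not robustness to those experimental artifacts.

`gillespie_ssa` is an independent brute-force oracle: exact stochastic
simulation of the *untruncated* reaction system, vectorized across
trajectories (each trajectory follows the exact Gillespie law; snapshots at
checkpoint times exploit the memorylessness of exponential waiting times).
Oracle comparisons equilibrate trajectories under theta^U for 400 min from
the empty state, then switch to theta^S — no master-equation input at all.
Agreement is measured in total variation over the joint (TS, mRNA) state.
With 2×10⁵ trajectories the multinomial sampling-noise floor of that TV
distance is ≈0.008 for the wide post-stimulus distributions, which is why
oracle tests use 2×10⁵ trajectories against a 0.01 bound (at 10⁵ the noise
floor alone would exceed the bound).

## Test and validation scales

The shipped test suite runs everything at desk scale on one CPU: parameter
recovery uses one replicate of n = 1000 cells/time point with T = 10⁴
iterations at M = 200; the six-model selection screen uses n = 100,
T = 5×10³, M = 150, required to succeed in at least 2 of 3 replicate data
sets; property tests use M = 15–100. `scripts/acceptance.py` re-runs the
recovery experiment end to end from a user seed and prints the posterior
means with their 95% intervals. These sizes are the package's validation
protocol; production analyses should use the full defaults (M = 500,
T = 10⁵, ≥3 replicas).

## Known limitations

* Diagonal proposal covariance ignores posterior correlations (e.g., the
  k1^S–k0 ridge); strongly correlated posteriors mix slowly.
* The Laplace calibration assumes a locally quadratic log-likelihood; for
  boundary-hugging parameters (a nearly-zero mu0) the step can be
  underscaled, and the weakly identified basal rate is the slowest-mixing
  coordinate in practice.
* Fixed truncation M with deficit reporting (no adaptive expansion).
* Time-varying kinetics beyond the single pre→post switch are out of scope.
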