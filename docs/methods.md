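# Methods

This note records the models implemented in `mechsbi`, the numerical and
design choices behind them, and what the bundled synthetic problems do and
do not establish about real-data use.

## Posterior estimation

`mechsbi` performs Bayesian inference for simulator models: given a prior
p(θ), a stochastic simulator x ~ p(x|θ) and an observation x_o, it trains a
conditional neural density estimator q_φ(θ|x) on simulated pairs (θ_j, x_j)
by minimizing the weighted negative log-density

    L(φ) = Σ_j w_j · ( −log q_φ(θ_j | x_j) ),

and reads off the posterior as q_φ(θ|x_o). With a single round the
parameters are drawn from the prior, all w_j = 1, and the trained network is
*amortized*: it returns a posterior for any observation covered by the
prior by a single forward pass. With multiple rounds, parameters are drawn
from the current posterior estimate at x_o (truncated to the prior
support), and the weights w_j = p(θ_j)/p̃_r(θ_j) correct for the proposal
(the importance-weighted multi-round variant). Post-hoc-corrected and
classifier-based multi-round variants are deliberate extension points, not
implemented.

Two estimator families are provided:

* **Mixture density network (MDN).** A feedforward network (tanh
  nonlinearities) maps features to the parameters of a K-component Gaussian
  mixture. Mixture weights are normalized exponentials. Each component's
  Gaussian is parameterized by its mean and a lower-triangular factor U of
  the **precision** matrix (P = U Uᵀ) with softplus-positive diagonal, so
  the log-density is an explicit quadratic form in the network outputs;
  sampling uses one triangular solve. A factor of the precision rather than
  the covariance was chosen because it makes the training loss a closed
  composition of elementary operations — no matrix inversion in the
  gradient path. Each hidden layer must have at least
  K(1 + N + N(N+1)/2) − 1 units (the number of mixture quantities over N
  parameters); configurations below this floor are rejected.
* **Masked autoregressive flow (MAF).** A stack of masked autoregressive
  bijections (default five) over a standard-normal base. Each bijection's
  masked network respects a strict autoregressive ordering; the ordering
  reverses between bijections. Conditioning features are "degree zero":
  they feed every hidden layer and both output heads densely, so even the
  first autoregressive dimension is conditioned. The log-scale outputs pass
  through a smooth tanh clamp (±5) for numerical stability.

Both families z-score parameters and features with training-set statistics
stored in the estimator; reported log-densities include the z-scoring
Jacobian, so they always refer to the original parameter space.

Training uses adaptive-moment gradient descent (Adam) with default
settings (learning rate 10⁻³, β = 0.9/0.999), minibatches of 100, early
stopping on a held-out 10% split with patience 20–40 epochs depending on
the experiment, and a cap of 500 epochs. Weighted losses are normalized by
the sum of weights so that duplicating rows at half weight leaves the loss
surface unchanged. All weight initialization, shuffling and sampling flows
from explicit integer seeds; training is bit-reproducible on one machine.

The estimators and the reverse-mode gradient engine under them
(`mechsbi._ad`) are implemented directly on numpy. The engine covers the
operations the networks need (broadcast arithmetic, matrix products,
smooth nonlinearities, reductions, slicing, a fused triangular quadratic
form) and also supplies gradients of log-densities with respect to the
*parameters*, which is what makes the posterior differentiable for the
geometry tools below.

## Priors and supports

`PriorSpec` covers box-uniform and Gaussian priors with optional
per-dimension transforms (log; generalized logit l_{a,b}(x) =
log((x−a)/(b−x))). Densities on the transformed side include the Jacobian.
Posterior objects truncate to the prior support: log-probability is −∞
outside, and sampling rejects draws outside the support with a cap of 10⁴
attempts. Rows of a simulation table whose features contain non-finite
entries are flagged invalid and excluded from training but never dropped
from storage.

## Simulators

**Conjugate-Gaussian toy.** θ ~ N(m₀, S₀), x = θ + ε, ε ~ N(0, S_n). The
closed-form posterior N(S(S₀⁻¹m₀ + S_n⁻¹x_o), S), S = (S₀⁻¹+S_n⁻¹)⁻¹, is
the oracle for recovery, calibration and relative-KL tests.

**Temporal Bernoulli GLM.** T = 100 bins; spike probability
σ(vᵢᵀf + β) with a length-9 filter f over the white-noise input of the
preceding bins. Summary features are the spike count N and the
spike-triggered average Vz/N — jointly sufficient for this model, which is
why a 10-dimensional feature vector loses nothing. The filter prior is
zero-mean Gaussian with covariance σ²(FᵀF)⁻¹ where F is the second-
difference operator with Dirichlet boundary conditions (the boundary
choice makes FᵀF invertible); σ = 2 gives filter draws of order unity. The
bias prior is N(0, 1). The exact Bernoulli likelihood is exposed for MCMC
reference posteriors.

**Gabor Poisson GLM.** Spike counts are Poisson with rate exp(vᵢᵀh + β) per
Δt = 0.025 s frame; h is a Gabor filter over a 41×41 grid on [−1,1]²
(16×16 in the desk-scale tests), with gain, spatial frequency, aspect
ratio, octave bandwidth w, phase ∈ (0,π), orientation ∈ (0,2π) and
location ∈ (−1,1)². The envelope width follows the octave-bandwidth
relation σ = √(2 ln 2)/(2πf) · (2^w+1)/(2^w−1). Bounded parameters map to
an unconstrained space by log/generalized-logit transforms, where the
prior is a factorizing Gaussian with standard deviations
[0.5, 0.5, 0.5, 0.5, 1.9, 1.78, 1.78, 1.78] (≈ uniform after the logit
back-transform) and a N(−0.57, 1.63) bias (≈ unit-rate exponential prior
on the baseline rate). Bins whose rate overflows are flagged invalid.

**Potassium-channel family ("Omnimodel").** An 8-parameter kinetics family:
Boltzmann steady state m∞(V) = 1/(1+e^{−θ₁V+θ₂}) and bell-shaped time
constant τ_m = θ₄/(e^{−[θ₅Δ+θ₆Δ²]} + e^{[θ₇Δ+θ₈Δ²]}), Δ = V−θ₃, with a
wide uniform prior (θ₁∈(0,1), θ₂∈(−10,10), θ₃∈(−120,120), θ₄∈(0,2000),
θ₅,θ₇∈(0,0.5), θ₆,θ₈∈(0,0.05)). Exponent arguments are clamped at ±60;
beyond the clamp τ underflows smoothly toward zero. The gating ODE is
integrated by exponential Euler (exact for piecewise-constant commands),
dt ≤ 0.1 ms, and the current I_K = m(V−E_K) with E_K = −107 mV and unit
conductance is max-normalized. Five voltage-clamp protocols (activation
steps, a holding-potential ladder, deactivation steps, a ramp, and a
stereotyped action-potential template; definitions in
`omnimodel.default_protocols`) carry 0.5 mV Gaussian noise per sample.
These waveforms are desk-scale stand-ins — the original database protocols
are not reproduced here. Responses reduce to 55 features: per protocol,
10 principal-component coefficients (PCA fit on prior-predictive
responses; ≥ 99% variance explained on the desk protocols) plus the trace
mean, the least-squares coefficient on a constant regressor. A noise-free
switch exists solely so convergence and relaxation oracles can isolate
integration error; all inference uses the noisy protocols.

**Hodgkin–Huxley neuron.** Single compartment with leak, transient Na,
delayed-rectifier K, and slow (M-type) K currents, C_m = 1 µF/cm²,
E_Na = 53 mV, E_K = −107 mV, and Gaussian voltage noise σ·η(t)/√dt.
Gating kinetics follow the standard cortical-neuron rate functions with a
spike-threshold shift V_T and an adaptation scale τ_max; they live in one
replaceable function (`hh.gating_rates`). The 8-parameter uniform prior is
[0.5,10⁻⁴,10⁻⁴,10⁻⁴,50,40,10⁻⁴,35] to [80,15,0.6,0.6,3000,90,0.15,100]
over (g_Na, g_K, g_l, g_M, τ_max, V_T, σ, E_l); V_T and E_l are sampled as
positive magnitudes and applied with negative sign (the printed ranges
only make physical sense as magnitudes of negative quantities). The
stimulus is an 80 ms square pulse of 5 µA/cm² inside a 120 ms window
(amplitude chosen so mid-range conductances spike regularly); integration
is exponential-Euler for gates, forward-Euler for voltage, dt = 0.025 ms.
Features: spike count (upward crossings of −20 mV with 1 ms refractory),
resting mean and SD (pre-stimulus window), and mean/SD/skewness/kurtosis
of the stimulus-window voltage.

**Pyloric circuit.** Three single-compartment neurons (AB/PD, LP, PY),
each with Na, CaT, CaS, A, KCa, Kd, H and leak currents following the
published pyloric-network kinetics (in `stg.membrane_gates`, again one
replaceable unit), intracellular calcium driving the KCa current and a
Nernstian calcium reversal, and seven graded synapses
I_s = g_s·s·(V_post−E_s) with ds/dt = (s̄(V_pre)−s)/τ_s,
s̄ = 1/(1+exp((V_th−V_pre)/δ)), τ_s = (1−s̄)/k₋; glutamatergic synapses
(from AB, LP, PY) use E_s = −70 mV, k₋ = 1/40 ms, cholinergic (from PD)
E_s = −80 mV, k₋ = 1/100 ms; V_th = −35 mV, δ = 5 mV. Membrane area
0.628·10⁻³ cm². The 31-dimensional prior is the printed per-neuron
conductance box plus log₁₀-uniform synapse conductances in
[0.01, 1000] nS ([0.01, 10⁴] for AB→LP); synapses are handled in log space
throughout. Per-step voltage noise has SD 0.001 mV·ms^−1/2. Integration:
exponential Euler for gates, calcium and synapses, forward Euler for
voltage, dt = 0.025 ms; the inner loop is compiled with numba when
available, with a bit-compatible vectorized numpy fallback (agreement
to ~10⁻⁸, accumulated rounding only). Desk-scale simulations run 3 s with
the first 1 s discarded (the full setting of 10 s remains available);
traces are recorded at 0.25 ms.

Eighteen summary features: cycle period (mean AB/PD burst-start interval),
per-neuron burst durations, gaps (reference burst end to follower start),
delays (start to start), duty cycles, phase gaps, LP and PY start phases,
plus per-neuron plateau durations (longest run above −30 mV, floored at
5 ms). Spikes are local maxima above −20 mV (merged within 2 ms); bursts
come from a two-threshold gap classifier — an inter-spike interval is an
inter-burst gap when it exceeds half the mean inter-burst interval, found
by fixed-point iteration, with tonic trains (max ISI < 2× min ISI)
classified as non-bursting; a burst needs ≥ 2 spikes, a neuron ≥ 2
bursts. The 15 rhythm features are undefined (NaN, row invalid) unless
every neuron bursts rhythmically; plateau features are always computed.
Under the stated prior, roughly 1–2% of desk-scale draws yield a valid
triphasic rhythm, which matches the sparsity the full-scale study reports.

## Baselines and metrics

Rejection ABC accepts prior draws whose features fall within a tolerance
(or keeps the closest population) under a scaled Euclidean distance.
SMC-ABC follows a population Monte Carlo scheme: Gaussian perturbation
kernel with twice the weighted population covariance, tolerance schedule
at the 0.5 acceptance quantile, importance weights prior/kernel-mixture,
early stop on budget exhaustion or effective sample size < 10.
The MCMC reference is adaptive random-walk Metropolis (proposal covariance
adapted to 2.38²/d times the running covariance during burn-in, global
scale tuned toward ~0.3 acceptance).

The relative Kullback–Leibler error
D_KL(p_ref‖p̂) / D_KL(p_ref‖prior) ∈ [0, ~1] is estimated by Monte Carlo
over reference-posterior samples; it requires a *normalized* reference
log-density. For the temporal GLM the reference is the moment-matched
Gaussian of the MCMC samples — adequate because that posterior is
log-concave and near-Gaussian; for ABC populations the candidate density
is likewise a moment-matched Gaussian fit. The genetic-algorithm objective
score is ε_j = |x_j − x_oj|/σ_j per feature with σ_j from prior-predictive
simulations, summed over features.

## Posterior geometry

Conditional correlations: fix all but two parameters at a conditioning
point, evaluate the posterior on a 50×50 grid spanning the prior range,
normalize, and take the Pearson correlation; 1-D conditionals are
trapezoid-normalized before moments. Averaging the per-condition matrices
over posterior-sampled conditioning points (default 50 at desk scale; the
full-scale analysis used 500) summarizes compensation structure; for a
Gaussian posterior this equals the partial-correlation matrix, which the
tests exploit.

High-probability paths: a curve γ(s) between two parameter sets is
parameterized by sinusoidal basis functions (K = 2 per dimension: sin(πks)
and sin²(πks) terms) added to the straight line, so the endpoints are
pinned for any coefficients (the basis is forced to exact zero at
s ∈ {0,1} to keep this true in floating point). The loss is the
discretized integral of −log p(γ(s)|x_o) times speed over 80 points with
trapezoid weights and central-difference velocities (one-sided at the
ends), minimized by gradient descent on the coefficients (default step
10⁻³, 2000 iterations, best-so-far kept, abort on divergence). Because
the integral is a line integral, coefficients along the path direction
only reparameterize the same curve; optimality claims refer to the curve.

Orthogonal perturbations: Δθ = −P∇logp/(∇logpᵀP∇logp) with
P = I − nnᵀ/nᵀn for path tangent n, iterated until the cumulative step
length reaches a set fraction of the path length (the full-scale analysis
used 1/27).

## What the synthetic problems establish

The bundled generators reproduce the *structure* of the original
experiments — dimensionalities, priors, noise models, feature maps — at
desk-scale simulation budgets (10³–2·10⁴ draws rather than 10⁵–10⁷).
Passing tests therefore demonstrate: correctness of the simulators against
closed forms; correctness and calibration of the estimators on problems
with analytic posteriors; and the qualitative orderings the full-scale
study reports (neural posterior estimation beating SMC-ABC on the GLM;
posteriors tightening as features accumulate; a sparse pyloric-rhythm
region under the circuit prior). They do not demonstrate performance on
experimental recordings, robustness to model misspecification, or the
full-scale posterior geometry of the 31-parameter circuit.

Known estimator limitation: for parameters whose conditional width
collapses to ~1% of the prior range, single-Gaussian fits at desk budgets
carry relative errors of tens of percent in that width; comparisons of
such near-degenerate widths across feature sets are correspondingly noisy
(this is visible in the Hodgkin–Huxley constraint-tightening analysis and
documented there).

## Reproducibility

Every stochastic component takes an explicit integer seed; a master seed
expands into named per-component seeds through a counter-based scheme
(`workbench.spawn_seeds`), so adding components never perturbs existing
streams. Simulation tables carry per-row seeds; estimator checkpoints
store architecture, weights, normalization statistics and loss traces and
reload bit-exactly.
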