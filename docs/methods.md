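# Methods

## Network model

The reservoir is a sparse random recurrent network of N sigmoid rate
neurons obeying Dale's law: a fraction f_E of neurons is excitatory (all
outgoing weights enter the non-negative matrix A^E) and f_I = 1 − f_E
inhibitory (outgoing weights in A^I). The discrete-time dynamics are

    V(t+Δt) = λ V(t) + α (A^E − A^I) r(t) + W_in u(t)
    r(t+Δt) = Sig(V(t+Δt) − θ),  Sig(x) = 1/(1 + e^{−cx})

One reservoir step equals one input sample; Δt is dimensionless for the
discrete benchmarks and equals the sampling time for the chaotic ones
(0.1 s Mackey–Glass, 0.02 s Lorenz). With leakage λ = 0 (default), all
memory is carried by the recurrent state, none by individual neurons.

Default parameters (the standard study configuration):

| parameter | symbol | default | meaning |
|---|---|---|---|
| neurons | N | 500 | 400 excitatory, 100 inhibitory |
| excitatory fraction | f_E | 0.8 | cortical-like 4:1 E:I ratio |
| mean in-degree | k | 50 | 10% connectivity |
| mean excitatory strength | μ_E | 1/(k f_E) = 0.025 | unit total excitation per neuron |
| strength spreads | σ_E = σ_I | 0.2 μ_E | Gaussian synaptic variability |
| global balance | β | 0 | balanced; tuned via inhibition only |
| scaling factor | α | 1 | overall recurrent gain |
| threshold | θ | 0 | shared activation threshold |
| sigmoid steepness | c | 10 | spiking limit c→∞, linear c→0 |
| input fraction | f_in | 0.3 | neurons receiving external drive |
| input link spread | σ_in | 0.1 | W_in entries uniform on ±σ_in/2 |
| ridge penalty | η | 10⁻⁷ | readout regularization |
| plasticity rate | δ | 10⁻³ | inhibitory adaptation step |

σ_in is a per-task quantity with no single canonical value; the package
default of 0.1 is the low-input-scaling setting appropriate for the
memory benchmark, which is the default task throughout (memory-intensive
tasks favor near-linear reservoir operation, reached at small input
weights; nonlinear tasks such as Lorenz forecasting need roughly
100-fold larger σ_in, which callers set explicitly).

### Connectivity construction

Each neuron receives k·f_E excitatory partners drawn without replacement
from the excitatory population and k·f_I inhibitory partners from the
inhibitory one (non-integer products are rounded stochastically so the
expectation is exact; self-loops are allowed). This stratified fixed
in-degree is the reading of "average degree k" under which a
zero-spread (σ = 0) network realizes any requested β *exactly*, a
property the test suite relies on. Excitatory strengths are
Gaussian(μ_E, σ_E) truncated at zero; with the default 5σ gap to zero
the truncation bias is negligible.

The global balance β = ⟨Σ_j α(A^E_ij − A^I_ij)⟩ is set through the signed
mean inhibitory strength

    w̄_I = (β/α − k f_E μ_E) / (k f_I),

so β = 0 gives the familiar w̄_I = −(f_E/f_I) μ_E = −0.1. Inhibitory
magnitudes are drawn Gaussian(|w̄_I|, σ_I), truncated at zero, and entered
into A^I with the sign of w̄_I folded in: for β beyond the total
excitation (w̄_I > 0) the labeled-inhibitory links act excitatory and A^I
entries are stored negative. At exactly w̄_I = 0 the draws are symmetric
around zero and left untruncated, since truncating a zero-mean Gaussian
would bias the balance.

## Homeostatic tuning

**Inhibitory plasticity.** Every structurally present inhibitory synapse
into neuron i is updated once per reservoir step,
A^I_ij += δ (r_i − ρ_i). Over-active neurons recruit inhibition,
under-active ones shed it; r_i = ρ_i for all i is a fixed point.
Magnitudes may cross zero (the sign lives in the effective matrix), which
is what lets over-excited initializations (β > 1) recover; a config flag
`clamp_inhibitory_at_zero` enforces strict non-negativity instead. During
adaptation the reservoir is driven by the downstream task's input
distribution (uniform [0, 1] by default). Because the update adds one
scalar per postsynaptic neuron to all of its inhibitory inputs, the
unclamped implementation tracks the per-neuron cumulative correction
C_i(t) instead of rewriting the N×N matrix each step — algebraically
identical (verified against the dense per-step update in tests) and about
an order of magnitude faster. Performance evaluated mid-adaptation is
measured with plasticity frozen, on a fresh input segment, with a freshly
trained readout.

**One-step design.** Requiring the mean-field fixed point — every
presynaptic rate at its target, input at its mean — to satisfy
Sig(V_i − θ) = ρ_i gives the per-neuron inhibitory rescaling

    Ω_i = (α Σ_j A^E_ij ρ_j + W_in,i ⟨u⟩ − θ − Sig⁻¹(ρ_i)) / (α Σ_j A^I_ij ρ_j).

This orientation makes the balanced zero-spread default exactly invariant
(Ω_i = 1) and is verified by simulation: the designed network settles
within machine precision of homogeneous targets under constant mean
input. Neurons with zero target-weighted inhibitory input are left
unscaled with a warning; a negative Ω_i (inhibition must flip sign to
reach the target) is allowed but warned about.

**Targets.** Homogeneous targets share ρ_T; ρ_T = 0.5 encodes exact local
balance at the sigmoid midpoint and maximizes memory capacity.
Heterogeneous targets are i.i.d. Beta(a, a) draws — symmetric about 0.5,
bounded in (0, 1). The default shape a = 5 (SD ≈ 0.15) provides
substantial but not extreme rate diversity; it is exposed in the API.

## Benchmarks

* **Memory capacity** — i.i.d. uniform [0, 1] input; one ridge readout per
  delay d = 1..70 reconstructs u(t − d); MC = Σ_d R²(d) with R² the squared
  Pearson correlation on the test window (zero-variance outputs score 0: a
  silent reservoir has no recall).
* **NARMA-10** — y(t) = 0.3 y(t−1) + 0.05 y(t−1) Σ_{i=1..10} y(t−i)
  + 1.5 u(t−10) u(t−1) + 0.1 with u uniform on [0, 0.5], zero initial
  history, first 10 steps burn-in; scored by open-loop test RMSE. The
  recursion occasionally diverges; such series are regenerated from a
  fresh seed segment (logged).
* **Mackey–Glass** — dx/dt = 0.2 x(t−17)/(1 + x(t−17)¹⁰) − 0.1 x,
  integrated by fixed-step RK4 at the 0.1 s sampling step with a delay
  ring buffer. The delayed term at the RK4 half-step stages is linearly
  interpolated between buffer entries (switchable to held-constant).
  Pre-history is constant 1.2 (the common convention); 1000 samples are
  discarded; the emitted window is min–max normalized to [0, 1].
* **Partially observed Lorenz** — ẋ = 10(y−x), ẏ = −xz + 28x − y,
  ż = xy − 8z/3; RK4 at 0.01 s sampled every 0.02 s, initial condition
  (1, 1, 1), 500 samples discarded; only the normalized x coordinate is
  exposed to the reservoir.

Both integrators reproduce their linear-limit closed forms to better than
1e−8 relative error, and the Lorenz integrator agrees with an independent
adaptive integrator before chaotic error amplification takes over.

Chaotic tasks run **closed-loop**: a one-step-ahead readout is trained
with teacher forcing, then the prediction is fed back through the same
input weights for an autonomous forecast (with teacher forcing restored,
the closed loop reproduces the open loop exactly — a test invariant).
Scored by valid prediction time: the first time the running NRMSE
(cumulative RMSE over the forecast so far, normalized by the true series'
SD over the window) exceeds 0.4, with a pointwise-error variant available;
never exceeding is reported as censored at the horizon.

## Readout

Ridge regression with unpenalized intercept (states and targets
mean-centered). The sigmoid keeps states strictly positive, so an
intercept-free readout would waste capacity absorbing the state mean; a
`fit_intercept=False` flag restores the stricter convention. The solve is
delegated to scikit-learn's cholesky path and is tested against a
hand-coded normal-equations oracle at 1e−10 relative tolerance. Default
penalty η = 10⁻⁷.

## Dynamical characterization

Per-neuron differential entropy uses the Kozachenko–Leonenko
first-nearest-neighbor estimator on the scalar rate series,
H ≈ ψ(T) − ψ(1) + (1/T) Σ ln(2 nn_i), with ±1e−12 uniform jitter to break
ties and deterministic subsampling to 5,000 points for speed; it matches
the uniform (0 nats) and Gaussian (½ ln 2πeσ²) closed forms within 0.05
nats. A constant series returns −∞ (silent/saturated neuron). Regimes:
silent (mean rate < 0.05), saturated (> 0.95), synchronized (mean
pairwise correlation > 0.9 at intermediate rates), otherwise active —
mutually exclusive and exhaustive by construction.

## Experiment designs and problem sizes

The experiments module reruns three designs: a (β, θ) characterization
sweep, an exhaustive grid search for the best globally tuned non-adaptive
reservoir (β ∈ {−3, −2.5, …, 1} × θ ∈ {−1, −0.5, 0, 0.5, 1}), and
matched-seed comparisons against the locally tuned methods (adaptive or
designed; homogeneous ρ_T selected from {0.3, 0.4, 0.5, 0.6, 0.7},
heterogeneous targets fixed). Percent improvement is
100·(method − baseline)/baseline for maximized scores and sign-flipped
for RMSE. Every cell records its integer seed list so it can be
reproduced in isolation.

Problem sizes are chosen for interactive, single-process work: memory and
NARMA evaluations use a 200-step washout, 2,500 training and 1,000 test
steps; chaotic tasks 300/3,000 with a 1,000-step forecast horizon;
comparisons use 5 repetitions and 10⁴ adaptation steps. The library-level
`SplitSpec` default (500/20,000/5,000) is the full-scale setting. At the
interactive scale the balanced-default memory capacity is ≈ 30 of the
70-delay maximum and the locally tuned improvement over the grid-tuned
baseline measures ≈ 15–20%; longer training windows reduce readout
overfitting noise and widen this margin.

## What the generators do and do not emulate

All inputs are synthetic and fully specified: uniform noise, the NARMA-10
recursion, and the two chaotic flows. They exercise linear memory,
nonlinear mixing, and closed-loop stability, but they are noiseless,
stationary, and low-dimensional; passing tests say nothing about
measurement noise, nonstationarity, or high-dimensional real-world
series. Chaotic repetitions differ only through perturbed initial
conditions (Mackey–Glass pre-history 1.2 ± 0.1, Lorenz initial state
jittered by σ = 0.5), so "repetitions" sample the same attractor, not
different systems.

## Numerical choices and limitations

Potentials are checked finite every step (a divergence raises with the
step index). The activation uses the numerically safe logistic from
scipy. Initial state is V = 0, r = Sig(−θ); a washout discards the
transient. Normalization parameters for chaotic series are fitted on the
generated (training) window and reused, never refitted on test data.
Thresholds are constant per run and shared across neurons; time-varying
or per-neuron thresholds, spiking (c → ∞) dynamics, excitatory
plasticity, structured topologies, and online (RLS) readout training are
out of scope. The balance-versus-inhibition formula assumes the
excitatory side stays fixed; at β > k f_E μ_E α the "inhibitory"
population is effectively excitatory, which the sign convention
represents but which leaves the network in the brittle over-excited
regime the study characterizes.
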