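# eireservoir

Excitatory–inhibitory reservoir computing with homeostatic inhibitory
plasticity.

Reservoir computers (echo state networks) train only a linear readout on
top of a fixed random recurrent network, which makes them cheap to train
but sensitive to how that network is initialized. This package implements
a brain-inspired variant in which the reservoir obeys **Dale's law** —
each neuron is either excitatory or inhibitory, with all outgoing synapses
of its own sign — so the relative strength of excitation and inhibition
becomes an explicit, tunable quantity. It is written for computational
neuroscientists and machine-learning researchers studying how E–I balance
shapes network computation.

## Model

Firing rates of the N sigmoid neurons evolve in discrete time:

```
V_i(t+Δt) = λ V_i(t) + Σ_j α (A^E_ij − A^I_ij) r_j(t) + W^in_i u(t)
r_i(t+Δt) = Sig(V_i(t+Δt) − θ),     Sig(x) = 1 / (1 + e^(−c x))
```

with `A^E`, `A^I` the non-negative excitatory and inhibitory weight
matrices. The **global balance** is the population mean of the signed
input sums, `β = ⟨β_i⟩ = ⟨Σ_j (A^E_ij − A^I_ij)⟩`; β = 0 is balanced,
β < 0 inhibition-dominated. β is controlled through the mean inhibitory
strength `w̄_I = (β/α − k f_E μ_E)/(k f_I)` at fixed excitation.

Two mechanisms tune each neuron's *local* balance toward a target firing
rate ρ_i:

* **inhibitory plasticity** — `A^I_ij(t+1) = A^I_ij(t) + δ (r_i(t) − ρ_i)`
  on every existing inhibitory synapse into neuron i (learning rate
  δ = 10⁻³), a homeostatic rule needing only local information;
* **one-step design** — each neuron's inhibitory inputs are multiplied by
  the factor Ω_i that places the mean-field fixed point exactly at the
  targets, `Ω_i = (Σ_j A^E_ij ρ_j + W^in_i ⟨u⟩ − θ − Sig⁻¹(ρ_i)) / Σ_j A^I_ij ρ_j`.

Targets are homogeneous (a shared ρ_T, with 0.5 at the sigmoid's linear
midpoint) or heterogeneous (drawn from a symmetric Beta distribution,
mimicking cortical firing-rate diversity).

Benchmarks and metrics: delayed-recall memory capacity (sum of R² over
delays 1..70), NARMA-10 (RMSE), and closed-loop Mackey–Glass and Lorenz
forecasting (valid prediction time), plus per-neuron differential entropy
(Kozachenko–Leonenko estimator), mean pairwise correlation, and a
silent / saturated / synchronized / active regime classifier.

## Worked example

`examples/adapt_balance.py` starts from a strongly over-inhibited network
(β = −2) and lets the plasticity rule run while the reservoir is driven by
uniform random input:

```
global balance during adaptation:
  step     0: beta = -1.994
  step   500: beta = -0.732
  step  1000: beta = -0.013
  step  2000: beta = -0.000
  step  5000: beta = -0.001
  step  9999: beta = -0.001
memory capacity: 1.6 -> 35.5 (sum of R^2 over delays 1..70; higher = longer input recall)
```

The network converges to global balance within ~2,000 steps because the
target rate 0.5 can only be met when excitation and inhibition cancel, and
its memory capacity rises from 1.6 to 35.5 (out of a maximum of 70): the
rule removes the locally imbalanced, silent-or-saturated neurons that
contribute nothing to recall. The other scripts in `examples/` demonstrate
regime classification, the memory benchmark, chaotic forecasting, and the
one-step designed reservoir, each printing the quantities it computes.

A thin CLI mirrors the experiment functions:
`eirc sweep|adapt|compare|scaling|tasks generate --help`.

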