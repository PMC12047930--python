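"""Self-tune a mis-balanced reservoir with the inhibitory plasticity rule.

Starts from a strongly over-inhibited network (global balance -2), runs the
homeostatic rule that nudges every inhibitory synapse into a neuron by
delta*(rate - target), and prints the global balance trajectory: the
network converges toward balance (beta = 0) because the target firing rate
0.5 sits exactly at the sigmoid's midpoint, and its memory capacity rises.
"""

from eireservoir import ReservoirConfig, build_connectivity, global_balance, \
    run_adaptation, sample_target_rates
from eireservoir.experiments import evaluate_memory_task
from eireservoir.plasticity import HOMOGENEOUS

cfg = ReservoirConfig(balance=-2.0)
conn = build_connectivity(cfg, rng_seed=0)
targets = sample_target_rates(HOMOGENEOUS, cfg.n_neurons, rho_T=0.5)

mc_before = evaluate_memory_task(conn, cfg, rng_seed=1)
final, trace = run_adaptation(conn, cfg, targets, n_steps=10_000, rng_seed=2)
mc_after = evaluate_memory_task(final, cfg, rng_seed=1)

print("global balance during adaptation:")
for step in (0, 500, 1000, 2000, 5000, 9999):
    print(f"  step {step:>5}: beta = {trace.beta[step]:+.3f}")
print(f"memory capacity: {mc_before:.1f} -> {mc_after:.1f} "
      "(sum of R^2 over delays 1..70; higher = longer input recall)")
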