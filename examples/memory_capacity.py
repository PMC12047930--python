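"""Score a reservoir on the delayed-recall memory benchmark.

Drives the reservoir with i.i.d. uniform [0, 1] input, trains one ridge
readout per delay d = 1..70 to reconstruct the input d steps in the past,
and prints the R^2-versus-delay curve head and its sum (the memory
capacity). R^2 near 1 means the reservoir still holds that sample; the
capacity is the area under the curve.
"""

from eireservoir import ReservoirConfig, build_connectivity
from eireservoir.experiments import evaluate_memory_task

cfg = ReservoirConfig()  # balanced 500-neuron network
conn = build_connectivity(cfg, rng_seed=0)
mc, r2_curve, _ = evaluate_memory_task(conn, cfg, rng_seed=1, return_details=True)

print("delay  R^2")
for d in (1, 5, 10, 20, 30, 40, 50):
    print(f"{d:5d}  {r2_curve[d - 1]:.3f}")
print(f"memory capacity (sum over delays 1..70): {mc:.1f}")
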