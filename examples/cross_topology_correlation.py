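"""Is the cascade outcome a property of the rule or of the network?

Runs DCC and simple cascades (constant strong-belief broadcast, 5 replicates)
on ER and WS topologies and correlates the replicate-mean per-level
timeseries between the two graphs.  Cognitive cascades barely feel the
topology change; simple cascades do.
"""

import numpy as np

from podsim import GraphSpec, SimulationConfig, avg_pearson, chi2_timeseries, preset, run_batch

for method in ("dcc", "simple"):
    batches = {}
    for family in ("ER", "WS"):
        cfg = SimulationConfig(graph_spec=GraphSpec(family=family),
                               contagion_spec=preset(method), replicates=5)
        batches[family] = run_batch(cfg, base_seed=77)
    r = avg_pearson(batches["ER"].mean_fractions, batches["WS"].mean_fractions)
    chi = chi2_timeseries(
        np.round(batches["ER"].mean_counts).astype(int),
        np.round(batches["WS"].mean_counts).astype(int),
    )
    print(f"{method:7s} ER vs WS: mean Pearson r = {r:.3f}, "
          f"chi-square non-rejection fraction = {chi:.2f}")

print()
print("r near 1 means the per-level belief trajectories are nearly identical")
print("across topologies; the chi-square score is the share of timesteps whose")
print("belief distributions are statistically indistinguishable.")
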