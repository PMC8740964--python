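"""How broadcast strategy decides whether a population can be swayed.

Runs the DCC cascade model on an ER graph under the three message schedules:
constant strong-belief messaging ("single"), a mid-run polarity flip
("split"), and a stepwise walk from one pole to the other ("gradual").
Only the gradual schedule moves everyone: each step stays within the
believable distance of the agents it just converted.
"""

import numpy as np

from podsim import SimulationConfig, preset, run_batch

for schedule in ("single", "split", "gradual"):
    cfg = SimulationConfig(contagion_spec=preset("dcc"), schedule_name=schedule,
                           replicates=5)
    batch = run_batch(cfg, base_seed=11)
    final = batch.mean_fractions[-1]
    print(f"{schedule:8s} mean final % per level:",
          " ".join(f"{100 * f:5.1f}" for f in final))

print()
print("levels are 0 (strong disbelief) .. 6 (strong belief); rows are the")
print("replicate-mean population share at t=100.  single/split only capture")
print("agents who started at levels 4-6; gradual walks ~100% down to level 0.")
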