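n_agents: 500
n_institutions: 1
institution_belief: 6
epsilon: 0
horizon: 100
belief_resolution: 7
graph_spec:
  family: ER
  er_rho: 0.05
  ws_k: 5
  ws_rho: 0.5
  ba_m: 3
  path: null
contagion_spec:
  variant: sigmoid
  p: 0.15
  ratio_alpha: 0.35
  lin_gamma: 1.0
  lin_alpha: 1.0
  thr_gamma: 1.0
  sig_alpha: 4.0
  sig_gamma: 2.0
schedule_name: single
schedule_params: {}
replicates: 10
seed: null
trial_mode: once
proportional_snapshot: false
event_log: false
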