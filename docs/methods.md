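# Methods

## Model

`podsim` implements a public opinion diffusion (POD) model: `N` networked
agents, each holding a single integer belief level about one proposition,
plus a separate set of institutional broadcaster agents.  Beliefs live on a
discrete scale `{0, ..., R-1}` (default `R = 7`, mirroring 7-point survey
scales): 0 is strong disbelief, the midpoint `(R-1)//2` uncertainty, `R-1`
strong belief.  Initial beliefs are i.i.d. uniform over the scale.

An institution has a perceived leaning `b_i` and a frozen subscriber set:
every agent with `|b_u - b_i| <= epsilon` at wiring time (default
`epsilon = 0`, i.e. exact-match subscribers).  Each timestep `t = 1..T`
(default `T = 100`) the institution broadcasts the message its schedule
prescribes; a message is a belief level with a globally unique id.  Message
handling within a timestep:

1. the message is delivered to all subscribers;
2. a delivered agent that has not yet believed this id runs one adoption
   trial (rule below); on success its belief jumps to the message level (a
   discrete jump, never an average — positive and negative moves are
   symmetric) and it shares the *original* message with all its neighbors;
3. sharing continues breadth-first until no new believers appear.  An agent
   believes and shares a given id at most once.

Because a believing agent's belief equals the message content at share time,
agents only ever relay content congruous with what they currently believe.

### Adoption rules

* simple: `P = p` per trial (default `p = 0.15`), beliefs irrelevant.
* proportional threshold: adopt (deterministically) iff the fraction of the
  receiver's neighbors currently at the message level is `>= alpha`
  (default `alpha = 0.35`).  Agents without neighbors never adopt.
* cognitive `beta(d)` of the belief distance `d = |b_u - b_m|`:
  inverse-linear `min(1, 1/(gamma + alpha d))`, hard threshold
  `1{d <= gamma}`, or sigmoid `1/(1 + e^{alpha (d - gamma)})`.  The default
  is the "stubborn" sigmoid `alpha = 4, gamma = 2` — the defensive cognitive
  contagion (DCC) rule.  The sigmoid is evaluated with `scipy.special.expit`
  and is exactly 0.5 at `d = gamma` for any steepness.

### Exposure accounting (trial mode)

By default (`trial_mode="once"`) an agent gets **one adoption trial per
message id** — the first delivery decides, later copies of the same id are
ignored.  Exposure therefore accumulates across *distinct* messages over
time, not across fan-in within one cascade.  This choice is what produces
the observed dynamics at the defaults: agents two or more levels below the
midpoint stay essentially untouched by constant opposite-pole messaging
(their per-timestep adoption chance is `beta(4) ~ 3e-4` or less), while
midpoint agents (`d = 3`, `beta = 0.018` per timestep) convert slowly over
many timesteps.  Under the alternative `trial_mode="per-delivery"` (an
independent trial on every delivery until belief), agents with many
believing neighbors would receive ~10 trials per timestep, and even
distance-4 agents would flip with ~30% probability within 100 steps —
qualitatively different, much "leakier" dynamics.  Both modes are available;
"once" is the default.

### Message schedules

Over horizon `T` with one message per timestep:

* **single** — a constant level (default the top of the scale);
* **split** — one level for `t <= T/2`, another afterwards (default 6 then 0);
* **gradual** — step one level toward the target every `interval` timesteps
  (default 6 → 0, interval 10), holding the terminal level once reached; at
  the defaults level 0 is held from `t = 61`.  A `hold_from` option forces
  the terminal level from a chosen timestep instead, for the reading where
  the tail is fixed-length.
* **custom** — explicit `(timestep, level)` runs.

## Networks

Four generators, all reproducible bit-identically under a seed:

* ER `G(n, rho)`, default `rho = 0.05` (mean degree ~25 at `n = 500`);
* WS small world, `k = 5` initial neighbors total (the ring-lattice
  construction links each node to `floor(k/2)` neighbors per side, so odd
  `k` yields degree `k-1`; results are sensitive to the alternative
  per-side reading of `k`, which would double the density — the sparse
  reading is the one consistent with the path-census results below),
  rewiring probability 0.5;
* BA preferential attachment, `m = 3` edges per new node;
* MAG, single belief attribute: each pair `(u, v)` is an edge independently
  with probability `theta[b_u][b_v]`, where the default affinity is the
  distance kernel `theta = 1/(6 + 50 (b_u - b_v)^2)` (diagonal 0.167 decaying
  to 0.0006 at distance 6) — a deliberately extreme homophily ensemble.
  Beliefs are drawn before edges.  With a constant affinity matrix MAG
  reduces exactly to ER.

Homophily is scored as the mean `|b_u - b_v|` over adjacent pairs (undefined
on edgeless graphs).  For uniform beliefs on the 7-level scale the expected
score is `E|X - Y| = 112/49 ~ 2.29`; the default MAG ensemble scores ~0.29.

## Analysis apparatus

* **Adoption matrix** — `beta` tabulated over all belief pairs; symmetric,
  constant along diagonals.
* **Path probability** — a message survives a chain `w` of agents with
  probability `prod_{v in w} beta(b_v, b_m)`; one distance-3 agent caps a
  DCC chain at 0.018.
* **Believing neighbor set** — neighbors `v` of a target whose best
  institution-to-`v` path probability is `>= 1 - delta`; computed exactly by
  Dijkstra under negative-log weights (node weight `-log beta`), excluding
  the target, ties broken by ascending node id.  Verified against exhaustive
  simple-path enumeration on small graphs.
* **Qualifying-path census** — the fraction of freshly generated graphs in
  which some neighbor of a randomly chosen target agent is reachable from a
  subscriber through agents all within belief distance `tau` of the message.
  Implemented as exact reachability on the induced subgraph of qualifying
  agents (target removed).  A weighted-shortest-path heuristic can misjudge
  this existence question (a minimum-sum path may violate the per-node bound
  even when a bounded path exists), so reachability is used.  Graphs with no
  agent at the target level are resampled.
* **Timeseries similarity** — `avg_pearson`: per-level Pearson correlation
  between two fraction-believing timeseries, averaged over levels, excluding
  levels exactly constant in either input; returns "undefined" when every
  level is excluded (nothing changed from initial conditions).
  `chi2_timeseries`: at each timestep a 2 x R chi-square homogeneity test
  between the two count vectors (levels empty in both rows dropped;
  single-level tables count as homogeneous); the score is the fraction of
  timesteps not rejected at significance 0.05.  This statistic is one
  consistent interpretation of a timeseries chi-square measure; with counts
  of magnitude N = 500 it is sensitive to small distributional differences,
  so its absolute values run low even when curves look alike.

## Problem sizes and defaults

All defaults are the reference experimental conditions: `N = 500`, `T =
100`, one institution at the top belief level, `epsilon = 0`, `R = 7`, 10
replicates (replicate `r` uses seed `base_seed + r`, so extending a batch
never perturbs earlier runs), ensembles of 10 graphs for homophily and 100
graphs per census cell.  The full 3 (rule) x 3 (schedule) x 4 (topology)
grid at these sizes runs in well under a minute thanks to a vectorized,
round-synchronous cascade engine.  Unit tests use smaller graphs (tens of
agents) where the property under test does not depend on scale.

For non-default belief resolutions the distance parameters of cognitive
rules are rescaled so the probability profile over *relative* belief
distance is preserved: thresholds (`sig_gamma`, `thr_gamma`) scale by
`(R-1)/6`, per-unit-distance coefficients (`sig_alpha`, `lin_alpha`) by the
inverse.  Scaling both is what keeps e.g. the sigmoid's value at matching
relative positions identical across scales.

## Numerical and design choices

* Cascades are processed in synchronous rounds (BFS levels) with receivers
  handled in ascending-id order and RNG consumed per round; the adoption
  probability of a receiver depends only on its own current belief and the
  message (cognitive and simple rules), so round processing matches
  sequential delivery in distribution while running ~100x faster.  For the
  proportional rule, neighbor beliefs are read at round start;
  `proportional_snapshot=True` freezes them at cascade start instead.
* The sigmoid is computed overflow-safely; the inverse-linear form is
  clamped to 1 (it is a probability).
* Within a round, only a receiver's first successful delivery is a
  `believed` event; its remaining deliveries that round are
  `ignored-duplicate`, preserving the believe-once ledger exactly.
* Timesteps are 1-based in all interfaces; row `t = 0` of a timeseries is
  the pre-broadcast initial state.
* Event logs (optional, off by default — they are large) record every
  delivery as `(t, message_uid, sender, receiver, outcome)`; institutional
  senders are encoded as negative ids (`-(k+1)` for institution `k`).

## What the generators emulate — and what they do not

The synthetic networks reproduce stylized structural features (density,
small-world shortcuts, heavy-tailed degrees, belief homophily) but not
community structure fitted to data, degree–belief correlations, directed or
weighted ties, or dynamic rewiring; beliefs are initialized uniformly rather
than from empirical opinion distributions, and institutions broadcast fixed
schedules rather than reacting to the population.  Passing tests therefore
show that the *mechanisms* behave as specified under controlled conditions,
not that the model is calibrated to any real media ecosystem.

## Known limitations

* One proposition, one belief variable per agent; no in/out-group effects,
  source trust, emotion, or belief decay.
* Subscriber sets are frozen after wiring; agents never switch media
  sources and the graph never rewires.
* The optimal non-overlapping path-set selection implied by the
  believing-neighbor analysis (choosing a maximum-probability set of
  disjoint institution-to-neighbor paths) is not implemented; the census
  answers the existence question only.
* Simple cascades on the sparse WS (degree 4) and BA (`m = 3`) graphs do not
  fully saturate within `T = 100` at `p = 0.15` (final strong-belief
  fractions ~0.75 and ~0.98 respectively, vs 1.0 on ER and MAG); the
  saturation claim should be read as ER/MAG behavior, with spread on
  sparser topologies markedly slower.
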