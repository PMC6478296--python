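# sbmbench

A toolkit for comparing **stochastic block model (SBM) variants and their
inference algorithms** on planted-partition benchmarks.

Community detection with SBMs involves two largely independent choices: the
*objective function* — which SBM variant's (log-)likelihood a partition is
scored by — and the *maximizer* — the algorithm that searches partition
space. Published variants differ in degree correction, in whether the
number of blocks `K` is part of the model, and in flat vs. nested priors;
published algorithms range from Metropolis–Hastings sampling to
agglomerative merging and Kernighan–Lin-style local search. This package
implements both axes behind one interface so their effects can be measured
separately, for anyone studying module structure in networks (interaction
maps, regulatory networks, social graphs) or benchmarking new variants.

## What is implemented

**Objectives** (natural-log scores, maximized; all share one incremental
delta contract for single-node moves and block merges):

| name | model |
|---|---|
| `SKN`, `SPC_dense`, `SPC_sparse` | standard SBM profile likelihood `½ Σ_rs e_rs log(e_rs / n_r n_s)` and its entropy forms |
| `DCKN`, `DCP` | degree-corrected profile likelihood `Σ_rs e_rs log(e_rs / e_r e_s)` and its microcanonical form |
| `ICLexJ`, `ICLexU` | exact integrated complete likelihood (Jeffrey / uniform priors); includes K |
| `SNR`, `DCNR` | Newman–Reinert marginal likelihood (standard / degree-corrected); includes K, permits empty blocks |
| `SPC`, `DCPU`, `DCPUH` | microcanonical SBM `P(G|e,b) P(e|b) P(b)` with uniform or hyperprior degree priors; includes K |
| `HSPC`, `HDCPU`, `HDCPUH` | nested versions: the block multigraph of each level is itself SBM-distributed |

**Inference**: Metropolis (`MA`) and Metropolis–Hastings (`MHA`, with the
block-matrix proposal `p(r→s|t) = (e_ts + ε)/(e_t + εK)` and exact
Hastings correction), the agglomerative merge heuristic (`PAH`), and the
Kernighan–Lin family (`KL`, `KL_EM`, `KL_G`) — all generic over the
objective, all counting delta evaluations as their cost unit.

**Model selection** for the classic objectives: MDL, AIC, BIC penalties
plus exhaustive or golden-section sweeps over K.

**Generators**: Bernoulli/Poisson SBM and degree-corrected samplers; the
extended Girvan–Newman test (4 groups × 32 nodes, mean degree 16,
parameterised by the expected external degree `k_out ∈ [0, 16]`, covering
assortative *and* disassortative regimes); a native LFR-style benchmark
(1000 nodes, power-law degrees and community sizes, mixing `μ_t`).

**Evaluation**: max-normalized adjusted mutual information (AMI), the
area-under-the-AMI-curve summary (AUMIC), selected-K diagnostics, and a
benchmark driver producing tidy pandas tables.

## Worked example

Recover the planted partition of a Girvan–Newman test network with the
degree-corrected microcanonical SBM and Metropolis–Hastings inference:

```python
import numpy as np
from sbmbench import (GNConfig, gn_network, get_objective,
                      InferenceConfig, best_of_restarts, ami)

rng = np.random.default_rng(7)
graph, planted = gn_network(GNConfig(k_out=4.0), rng)   # 128 nodes, 4 groups

spec = get_objective("DCPU")
config = InferenceConfig(algorithm="MHA", steps=50_000, restarts=5)
result = best_of_restarts(graph, spec, K=4, config=config, rng=rng)

print(f"objective = {result.objective:.1f}")
print(f"AMI vs planted = {ami(result.state.labels, planted):.3f}")
print(f"delta evaluations = {result.n_deltas}")
print("block sizes =", result.state.n_r.tolist())
```

prints

```
objective = -2902.5
AMI vs planted = 1.000
delta evaluations = 250000
block sizes = [32, 32, 32, 32]
```

i.e. the best of five 50 000-step chains (250 000 scored moves in total)
attains log-probability −2902.5 under the DCPU model and reproduces the
planted four groups of 32 exactly (AMI = 1). At `k_out = 4`, each node has
four of its sixteen expected edges leaving its group — comfortably inside
the recoverable regime; pushing `k_out` toward 8 makes the same call
degrade gracefully, which is exactly what the benchmark driver measures.

The same thing from the shell:

```sh
sbmbench generate gn --kout 4 --seed 7 --out g.edges --partition planted.csv
sbmbench fit --graph g.edges --model DCPU --algorithm mha --steps 50000 \
             --k 4 --restarts 5 --seed 1 --out fitted.csv --report run.json
sbmbench benchmark gn --models SKN,DCKN,DCPU --steps 50000 --restarts 5 \
             --networks 5 --kout 0:8:0.5 --seed 7 --out results.csv \
             --summary aumic.json
```

## Layout

```
src/sbmbench/
  graph.py            # Graph / Partition containers and I/O
  state.py            # BlockState sufficient statistics, moves, merges
  objectives.py       # the twelve flat objectives + delta contract
  hierarchy.py        # nested objectives and the level-wise fitter
  model_selection.py  # MDL / AIC / BIC, sweeps, golden section
  inference.py        # MA, MHA, PAH, KL, KL-EM, KL-G, restarts
  generators.py       # SBM/DC-SBM samplers, GN test, LFR benchmark
  evaluation.py       # AMI, AUMIC, benchmark driver
  cli.py              # `sbmbench` command
docs/methods.md       # model definitions, conventions, design choices
```
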