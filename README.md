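# linknull

**Null-model analysis of link prediction in weighted networks.**

In a weighted network — air routes weighted by flight frequency, neural
wiring weighted by synapse counts, collaborations weighted by joint
papers — a similarity index can exploit two distinct kinds of signal when
guessing missing links: the *topology* (who is connected to whom) and the
*placement of weights* on that topology. `linknull` separates the two by
comparing prediction accuracy on the original network against randomized
surrogates ("null models") that each scramble one feature while conserving
others. The accuracy lost when a feature is scrambled measures how much
that feature contributed. The same logic extends to specific statistics:
rewiring that builds or destroys the rich club, or that biases the
strength mixing pattern, quantifies what those structures are worth to a
predictor.

The package is for network scientists and systems biologists who want to
attribute predictive signal, not just maximize it.

## What it computes

**Similarity indices.** For a candidate pair $(x, y)$ with common
neighbors $z \in \Gamma(x) \cap \Gamma(y)$:

| index | score $S_{xy}$ |
|---|---|
| CN  | $\lvert\Gamma(x)\cap\Gamma(y)\rvert$ |
| AA  | $\sum_z 1/\log k(z)$ |
| RA  | $\sum_z 1/k(z)$ |
| WCN | $\sum_z \left(w(x,z)^\alpha + w(z,y)^\alpha\right)$ |
| WAA | $\sum_z \left(w(x,z)^\alpha + w(z,y)^\alpha\right)/\log(1+s(z))$ |
| WRA | $\sum_z \left(w(x,z)^\alpha + w(z,y)^\alpha\right)/s(z)$ |

where $k(z)$ is degree, $s(z)$ strength (sum of incident weights), and
the exponent $\alpha$ tunes the role of weights: $\alpha>0$ amplifies
strong ties, $\alpha<0$ amplifies weak ties, $\alpha=0$ recovers
unweighted scoring ($\mathrm{WCN} = 2\,\mathrm{CN}$ exactly).

**Evaluation.** A random 10% of edges is hidden (probe set $E^T$), an
equal number of non-edges is sampled ($E^N$), and candidates are scored
on the training graph alone. Accuracy is reported as
$\mathrm{AUC} = (n' + 0.5\,n'')/n$ (probability a probe edge outscores a
non-edge, ties worth half) and $\mathrm{Precision} = m/L$ (the fraction
of the top-$L$ candidates that are probe edges, $L = |E^T|$).

**Null models.** Five seeded rewiring constructions, each returning a new
graph plus swap counters and conservation diagnostics:

- `rewire_1k` — double edge swaps; conserves the degree sequence and the
  weight multiset, scrambles everything else;
- `shuffle_structure` — endpoint swaps restricted to equal-weight edge
  pairs; additionally conserves every node's strength (a `nearest` mode
  relaxes equality to a relative tolerance);
- `shuffle_weights` — exchanges weights between edges on a fixed
  topology;
- `rewire_rich_club` — targeted swaps that monotonically raise or lower
  the density of links inside the top-strength node set;
- `rewire_assortativity` — targeted swaps that push the strength
  correlation of connected pairs up (assortative) or down.

Strong/weak-tie experiments (hide probes from only one weight class, or
1k-scramble only one class) attribute signal to heavy versus light edges.

## Worked example

```python
import linknull as ln

# the 4-node worked example: A-C:1, B-C:2, A-D:3, B-D:1
g0 = ln.toy_g0()
ln.score_pair(g0, "A", "B", ln.IndexSpec("CN"))         # 2.0
ln.score_pair(g0, "A", "B", ln.IndexSpec("WCN", 1.0))   # 7.0  = (1+2)+(3+1)
ln.score_pair(g0, "A", "B", ln.IndexSpec("WRA", 1.0))   # 2.0  = 3/s(C) + 4/s(D)

# a synthetic study network: scale-free + clustered topology, long-tailed
# integer weights, strong planted topology-weight coupling
net = ln.generate(ln.FixtureSpec(n_nodes=150, attachment=5, coupling=0.9, seed=7))

variants = {
    "original":  None,
    "weight":    lambda g, s: ln.shuffle_weights(g, rng_seed=s).graph,
    "structure": lambda g, s: ln.shuffle_structure(g, rng_seed=s).graph,
    "1k":        lambda g, s: ln.rewire_1k(g, rng_seed=s).graph,
}
table = ln.run_sweep(net, index_names=["WCN"], alpha_grid=[-1.0, -0.5, 0.0, 0.5, 1.0],
                     repeats=10, variants=variants, rng_seed=1)
print(ln.max_over_alpha(table).round(3).to_string())
```

```
                 auc_max  auc_argmax_alpha  precision_max  precision_argmax_alpha
variant   index
1k        WCN      0.626               0.5          0.588                     0.0
original  WCN      0.797              -0.5          0.728                    -0.5
structure WCN      0.674               1.0          0.630                     0.5
weight    WCN      0.812               0.5          0.736                    -1.0
```

Reading the table: the original network predicts at AUC ≈ 0.80 (best at
α = −0.5, i.e. weak ties amplified). Shuffling the *weights* barely
matters (0.81), but scrambling the *topology* — even while conserving
every node's strength (`structure`, 0.67) or the degree sequence
(`1k`, 0.63) — costs most of the accuracy: on this network topology
carries far more predictive signal than weight placement.

The same experiments are available from a shell:

```sh
linknull fixture --n-nodes 150 --coupling 0.9 --seed 7 --out net.txt
linknull nullmodel 1k net.txt --seed 1 --out net_1k.txt
linknull predict --input net.txt --variants original,1k,structure,weight \
    --repeats 10 --seed 1 --out run/
```

`predict` archives its configuration as `run/run_config.yaml`; re-running
with `--config run/run_config.yaml` reproduces the CSVs byte-identically.

## Layout

- `linknull.graph_core` — validated weighted graph, edge-list and Pajek I/O
- `linknull.similarity` — the six indices
- `linknull.null_models` — the five rewiring constructions + rich-club /
  assortativity measures
- `linknull.ties` — strong/weak partition, subset-restricted 1k
- `linknull.evaluation` — splits, AUC, Precision, sweeps, summaries
- `linknull.fixtures` — synthetic generators and single-move micro-cases
- `linknull.cli` — the `linknull` command

See `docs/methods.md` for the modelling choices and their rationale.
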