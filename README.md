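# switchscan

Genome-scale mining of **bistable gene switches** from expression
compendia.

Gene switches — genes held in one of two stable expression states by
regulatory feedback (cooperative self-activation, or the mutual
repression of a toggle circuit) — leave a statistical fingerprint when a
compendium samples many conditions: their expression profile is
*bimodal*, because each sample settles near one attractor or the other.
switchscan detects that fingerprint and follows it through a complete
screening pipeline. It is aimed at systems-biology and expression-analysis
practitioners who want candidate bistable genes (and their ON/OFF sample
partition) from a genes × samples matrix, plus circuit simulators for
generating ground-truth benchmarks.

## The statistics

For each gene profile x₁…x_n the package fits a single Gaussian and a
two-component Gaussian mixture (EM), and compares them with the Akaike
information criterion, AIC = 2k − 2 log L (k = 2 and k = 5 free
parameters respectively). The bimodality score is

    ΔAIC = AIC₁ − AIC₂

large positive values mean two expression states explain the profile
decisively better than one. A collapsed EM restart guarantees
ΔAIC ≥ −6 on any input, and the fitting is exactly invariant to sample
order and to affine rescaling of the data.

For a target condition (say, a tumor phenotype) the conditional
separation

    D = |μ₁ − μ₂| / sqrt((σ₁² + σ₂²)/2)

between target samples and all others flags a condition-specific state
(screen threshold D > 1.8). A gene's predictive value for a phenotype is
its percentage information gain, 100·(H(X) − H(X|Y))/H(X), with the
expression discretized into equal-frequency bins.

The pipeline ranks genes by ΔAIC, takes the top 10%, screens by D,
validates survivors on an independent paired tumor/normal dataset
(mode-occupancy Fisher test, BH-adjusted), and classifies validated
switches: **type 1** — bimodal *within* the target samples; **type 2** —
one mode throughout the target samples with everything else in the
opposite mode.

## Worked example

Simulate a 100-sample compendium from a toggle switch with two graded
control genes (20% parameter noise between clones, random initial
conditions straddling both basins), then score every gene:

```python
from switchscan import (SimulationConfig, delta_aic, generate_dataset,
                        make_toggle_switch, score_matrix, uniform_stimulus)
from switchscan.circuits import with_graded_genes

model = with_graded_genes(make_toggle_switch(), n_graded=2)
config = SimulationConfig(n_clones=100, cells_per_clone=1, param_cv=0.2,
                          init_high=12.0, seed=7, t_end=200.0)
dataset = generate_dataset(model, config, uniform_stimulus(0.0, 35.0))
scores = score_matrix(dataset.matrix, seed=7)
print(scores[["gene_id", "n_used", "delta_aic", "rank",
              "mu_low", "mu_high", "weight_high"]].sort_values("rank"))
```

```
  gene_id  n_used  delta_aic  rank  mu_low  mu_high  weight_high
        A     100    404.632     1   0.147    3.524        0.450
        B     100    364.292     2   0.135    3.436        0.550
G2_graded     100     26.981     3   1.356    2.626        0.485
G1_graded     100     22.144     4   0.779    1.825        0.534
```

Both toggle genes score an order of magnitude above the graded genes:
their profiles split into a low mode near log2-expression 0.15 and a
high mode near 3.5, with roughly half the samples in each state — the
two basins of the toggle. Per-gene detail, including the ON/OFF
assignment of every sample:

```python
res = delta_aic(dataset.matrix.gene_values("A"), gene_id="A", rng=7)
print(f"gene A: dAIC={res.delta_aic:.1f}  modes at "
      f"{res.fit2.means[0]:.2f} / {res.fit2.means[1]:.2f}  "
      f"high-mode fraction={res.high_mode.mean():.2f}")
# gene A: dAIC=404.6  modes at 0.15 / 3.52  high-mode fraction=0.45
```

The same operations are available from the shell:

```sh
switchscan simulate --circuit toggle --n-clones 100 --seed 7 --out demo
switchscan score --matrix demo_matrix.tsv --seed 7 --out demo_scores.tsv
switchscan screen --scores demo_scores.tsv --matrix demo_matrix.tsv \
    --annotations demo_annotations.tsv --target cancer --out demo_calls.tsv
```

(plus `infogain`, `validate`, `classify`, and `enrich` subcommands; see
`switchscan --help`).

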