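# panelsim

Simulation toolkit for a central question in plant and animal breeding:
**how does the linkage disequilibrium (LD) between a marker panel and the
causal loci of a quantitative trait shape genomic-prediction accuracy?**

Marker-assisted selection wants few, functional markers; genomic selection
uses many, mostly neutral ones.  `panelsim` quantifies the middle ground on
an inbred (selfing) diversity panel: it simulates soybean-like genotypes,
plants additive QTL at a chosen heritability, builds seven marker panels
that differ only in their LD to those QTL, fits whole-genome regression
models implemented from scratch, and reports replicated validation-set
accuracies.

## The model

A trait with `q` QTL and heritability h² is simulated as

    y = Z_q u + e,      e ~ N(0, I σe²),   σe² = var(Z_q u)·(1−h²)/h²

where `Z_q` is the column-centered QTL dosage matrix and `u` the additive
effects (standard normal by default).  Prediction uses one of

* **RR-BLUP / GBLUP** — ridge BLUP of marker effects, variance components
  by REML via a single spectral decomposition (identical to kernel GBLUP);
* **Bayes-C** — spike-and-slab with a common slab variance;
* **Bayes-B** — spike-and-slab with locus-specific (scaled-t) variances;

fitted on a random 400-individual training half and scored by the Pearson
correlation between predicted and true genetic values in the other half.

The seven panels, for a trait with `q` QTL (HLD = highest-LD marker):

| panel | contents |
|-------|----------|
| mp1   | the q QTL themselves |
| mp2   | QTL + one HLD marker per QTL |
| mp3   | all genome-wide loci (QTL included) |
| mp4   | one HLD marker per QTL (no QTL) |
| mp5   | all loci minus the QTL |
| mp6   | 2 random picks per QTL from its top-20 r² loci |
| mp7   | mp6 + one random marker per QTL |

## Worked example

```python
from panelsim import (MCMCSettings, ScenarioConfig, generate_panel,
                      run_scenario, soybean_like_config)

panel = generate_panel(soybean_like_config(seed=11))   # 800 x 20,000 inbred
scenario = ScenarioConfig(
    n_qtl=50, h2=0.5,
    panels=("mp1", "mp4", "mp6"), models=("bayesB",),
    n_replicates=5, train_size=400, master_seed=3,
    mcmc=MCMCSettings(n_iter=5000, burn_in=1000, thin=5),
)
table = run_scenario(panel, scenario)
print(table.format_table("bayesB"))
```

prints

```
QTL50 (h2=0.5)
  mp1 (50 loci): 0.95 (0.02)
  mp4 (50 loci): 0.89 (0.01)
  mp6 (99 loci): 0.78 (0.02)
```

Read: with 50 causal loci at h² = 0.5 and n = 400 training lines, observing
the QTL directly predicts the validation half at r ≈ 0.95 (close to the
n/p-limited ceiling); replacing each QTL by its best LD proxy costs ~0.06;
relaxing to random picks from each QTL's top-20 LD partners costs ~0.17 —
still far above the ≈0.65 of a genome-wide panel, whose accuracy is capped
by the effective number of independent segments rather than by q.

The same machinery runs from the shell:

```sh
panelsim simulate-genotypes --out panel.tsv --seed 1
panelsim run-experiment --config examples/experiment.yaml --out results/
```

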