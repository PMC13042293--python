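# metsel

Training-set optimization for genomic selection in **multi-environment trials
(METs)**: pick which genotypes to phenotype in which environments so that
genomic BLUP predicts — and correctly *ranks* — the remaining candidates as
well as possible.

The package is aimed at quantitative geneticists and breeding-program
analysts who have a SNP panel for a candidate population and a phenotyping
budget split across several environments, and who want a principled,
reproducible way to choose the training set before any phenotyping happens.

## The model and criteria

Phenotypes of the training set stacked over `T` environments follow the
marker-by-environment (MGE) mixed model

```
y = mu + g + e,    g ~ N(0, G_tr),    e ~ N(0, blockdiag(sigma2_Ej * I))
```

where `G_tr` couples a compound-symmetric environment covariance
`Omega_G` (diagonal `sigma2_GxJ`, off-diagonal `tau0`) with the genomic
relationship matrix `K = (1/p) W W'` built from column-standardized marker
scores. Candidate genotypic values over all environments have covariance
`G_cp = Omega_G ⊗ K`, and their BLUP has the data-free prediction covariance

```
A = Var(h_hat) = G_cp.tr (M G_tr + I)^-1 M G_cp.tr'
```

with `M` the residual-weighted per-environment centering matrix. Two design
criteria score a candidate training set (with fixed criterion components
`sigma2_G = sigma2_E = 1`, `tau0 = 0.5`):

* **CDmean(v2)** = Σ_l `A_ll / B_ll` over all genotype-environment cells
  (`B = G_cp`) — the mean squared correlation between true and estimated
  genotypic values;
* **CDmean.MET** = Σ_i `Ai* / Bi*` over genotypes, pooling each genotype's
  `T × T` block — the same quantity for environment-averaged values.

A genetic algorithm (tournament selection, per-environment union crossover,
swap mutation, elitism, 12,000-iteration floor) searches the space of
per-environment subsets. A simulation harness draws true breeding values
from the model, predicts GEBVs (known components or REML), and scores
designs with ranking metrics at `k = floor(0.05 * ncp)`: **NDCG@k**,
**SRC@k** and **RSratio@k**, per environment and for environment-averaged
("overall") performance.

## Worked example

```python
import numpy as np
import metsel as ms

# synthetic diversity panel: 100 inbred lines, 3 subpopulations, Fst 0.3
markers = ms.simulate_marker_matrix(ncp=100, p=1000, n_subpops=3, fst=0.3, seed=7)
K = ms.grm_from_markers(markers, maf_threshold=0.05)

# optimize a (20, 20) two-environment training design
result = ms.optimize_design(
    K, sizes=(20, 20), criterion=ms.CriterionSpec("cdmean_v2"),
    cfg=ms.GAConfig(seed=1, population_size=40, min_iterations=300, patience=100),
)
rand = ms.random_design(100, (20, 20), seed=1)

# evaluate both designs by simulation under the MGE model
truth = ms.VarianceComponents.from_heritability([20.0, 20.0], tau0=10.0, heritability=0.5)
cfg = ms.SimulationConfig(env_means=[100.0, 150.0], vc=truth, n_replicates=200, master_seed=42)
reports = ms.run_experiment(K, {"optimized": result.best_design, "random": rand}, cfg)
```

This prints (via the obvious `print` statements):

```
GRM: 100 genotypes, trace = 99.000
optimized CDmean(v2) = 45.5233 (mean CD = 0.2276) after 584 iterations
random design CDmean(v2) = 43.0950 (mean CD = 0.2155)
genetic correlation rho = 0.500
k = 5 (top 5% of 100)
optimized: overall NDCG@k = 0.9708 (0.0108), SRC@k = 0.2496 (0.4543), RSratio@k = 0.1622 (0.0774)
   random: overall NDCG@k = 0.9704 (0.0113), SRC@k = 0.3003 (0.4421), RSratio@k = 0.1650 (0.0897)
```

Reading the output: the optimizer raises the mean CD (per-cell squared
correlation between true and predicted genotypic values) from 0.216 to
0.228, i.e. the optimized design lets the model recover genotypic values
more precisely. `rho = 0.5` is the between-environment genetic correlation
implied by `tau0 = 10` and genetic variances (20, 20) — a moderate
genotype-by-environment interaction. The ranking metrics (mean and, in
parentheses, SD over 200 simulated trials) say how well each design
identifies the top-5 candidates by environment-averaged true breeding
value: NDCG near 1 because the large environment means dominate its gains,
while SRC and RSratio are far more dispersed and discriminating. On this
small panel the two designs perform within noise of each other — criterion
gains translate into ranking gains more visibly on larger, strongly
structured panels.

A command-line interface mirrors the library:

```sh
metsel grm --markers geno.tsv --maf 0.05 --out K.tsv
metsel optimize --grm K.tsv --sizes 50,75 --criterion cdmean_v2 --seed 1 --out design.csv
metsel score --grm K.tsv --design design.csv --report mean
metsel simulate --grm K.tsv --config experiment.yaml --out results/
```

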