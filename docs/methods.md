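# Methods

This note documents the statistical model, the numerical choices, and what
the synthetic-data experiments can and cannot show.

## Marker coding and the genomic relationship matrix

Markers are biallelic SNPs on inbred-line-like panels, coded −1/0/+1 with
+1 the major-allele homozygote. Input coded as 0/1/2 allele dosage is
oriented per column by allele frequency (frequency ties keep the file
orientation); −1/0/+1 input is likewise re-oriented so the coding
convention always holds, which guarantees minor allele frequency ≤ 0.5 and
makes the MAF filter well defined (`MAF = (2·#(−1) + #(0)) / (2·ncp)`).

Standardization divides each centered column by its *sample* standard
deviation (denominator `ncp − 1`). This choice makes two identities exact
for `K = (1/p) W W'`: `trace(K) = ncp − 1` and `K·1 = 0`; both are asserted
at 1e−8 throughout the suite and serve as cheap integrity checks on any
loaded panel. Monomorphic columns carry no information and are dropped with
a warning rather than raising, so pipelines that skip MAF filtering still
run. Missing genotypes are an error by default; `mean_impute` rounds the
column mean to the nearest valid score, which is adequate for the low
missingness typical of curated panels but is not a substitute for proper
imputation.

## The MGE model and its BLUP

The training-set model has fixed environment means, a pooled genotypic
effect with covariance built from the compound-symmetric environment
covariance `Omega_G` (per-environment genetic variances `sigma2_GxJ`,
common covariance `tau0`) crossed with the GRM, and heteroscedastic
independent residuals. Environment means are never estimated: the
residual-weighted centering matrix `M` annihilates them, and all BLUP
formulas are written through `(M G_tr + I)^{-1} M`, which avoids inverting
`G_tr` altogether. When `M G_tr + I` is singular (possible with duplicated
genotypes across environments and extreme components) a ridge of
`1e−8 · mean(diag(G_tr))` is added to `G_tr` and the solve retried.

Candidate effects use environment-major flat ordering
(`l = j·ncp + i`), so every genetic covariance block (`G_tr`, `G_cp.tr`) is
literally a submatrix of `G_cp = Omega_G ⊗ K`; the implementation slices
one precomputed Kronecker product rather than assembling blocks, which both
simplifies the code and makes criterion-guided search fast (one `ntr × ntr`
solve per design evaluation).

The prediction covariance `A = G_cp.tr (M G_tr + I)^{-1} M G_cp.tr'` equals
`Cov(h, h_hat)` by BLUP orthogonality; the suite verifies this identity by
brute-force simulation (200,000 replicates, agreement within 3 Monte-Carlo
standard errors entrywise) rather than trusting the algebra.

## CD criteria

`CDmean(v2)` sums `A_ll / B_ll` over all `N = T·ncp` cells and
`CDmean.MET` sums `Ai* / Bi*` over genotypes (each genotype's `T × T` block
pooled; the `1/T²` averaging factors cancel in the ratio). Both are exposed
as sums — the optimization objective — with `report_mean` dividing by `N`
(resp. `ncp`) for display; the two forms rank designs identically. The
criterion components are fixed at unit variances with `tau0 = 0.5`;
rankings of candidate designs are insensitive to this choice, and the suite
asserts rank concordance (Spearman > 0.9) across perturbed settings
(`tau0 ∈ {0.2, 0.8}`, unequal genetic and residual variances) on a strongly
structured panel. Concordance weakens on weakly structured panels where
equal-size random designs score almost identically — there the ranking is
dominated by noise-level differences, a caveat worth knowing when comparing
near-tied designs.

Cells with `B_ll = 0` (possible only for a degenerate GRM) are excluded
with a warning. An all-singleton design (one observation per environment)
has `A = 0` exactly — the centering matrix of a single observation is zero
— and scores 0 with a warning.

## REML

Variance components (`2T + 1` parameters) are estimated by maximizing the
restricted likelihood with the environment-mean incidence projected out.
Variances are optimized as logarithms with a floor of
`1e−6 × var(y)`; `tau0` is parameterized through a tanh-bounded
correlation-like parameter `r ∈ (−1, 1)`. For `T = 2` the map
`tau0 = r·sqrt(sigma2_G1 · sigma2_G2)` covers the exact positive-semidefinite
region of `Omega_G`. For `T ≥ 3` a sufficient (not exhaustive) bound is
used: `tau0 = r·min_j sigma2_Gj` for `r ≥ 0` and
`tau0 = r·min_j sigma2_Gj / (T−1)` for `r < 0`; compound-symmetric optima
near the PSD boundary with strongly unequal variances may be clipped, a
known limitation.

Optimization runs L-BFGS-B with numerical gradients from a
method-of-moments start (each environment's phenotypic variance split
evenly between genetic and residual parts, `r = 0.25`), followed by a
Nelder-Mead polish: the genetic/residual decomposition creates a flat ridge
on which finite-difference gradients stall short of the optimum, and the
derivative-free polish recovers the last few 1e−4 of log-likelihood — the
difference between matching and missing a grid-search oracle at three
significant figures. Non-convergence is flagged, not raised; the
simulation loop then falls back to known-component prediction and reports
the count.

Identifiability caveat: separating `sigma2_G` from `sigma2_E` requires
eigenvalue spread in `K`. On unstructured panels (near-identity GRM) the
two are nearly confounded and single-dataset REML estimates of individual
components can be far off even though the fit is likelihood-optimal. The
recovery tests therefore run on structured panels (3 subpopulations,
Fst 0.3 — the differentiation scale of real rice/barley diversity panels).

## Genetic-algorithm search

The search space is a product of per-environment subsets. The GA is
generational: tournament selection (size 3), per-environment union
crossover (child subset drawn without replacement from the union of the
parents' subsets), per-environment swap mutation (probability 0.1), and
elitism (1). The stopping rule enforces a floor of 12,000 iterations before
a 500-iteration non-improving patience applies; the floor reduces the risk
of settling into a poor local optimum. Fitness values are memoized by a
canonical design key, and when the memo provably covers the entire design
space (the product of binomial coefficients, only tracked when ≤ 1e6) the
incumbent is the certified global optimum and the search stops early. An
optional greedy swap refinement of the incumbent (`local_search_swaps`) is
off by default. Desk-scale tests and the scaled-down experiment use reduced
floors (150–300 iterations, population 40); the default floor is exercised
on the enumerable 784-design instance, where the GA recovers the
enumeration optimum.

## Simulation experiments and ranking metrics

A replicate draws `h ~ N(0, Omega_G ⊗ K)` through a PSD square root
(eigendecompositions of `Omega_G` and `K` separately, negative eigenvalues
clipped at 0), adds environment means `mu_j` to form TBVs, and independent
residuals `N(0, sigma2_Ej)` to form phenotypes. Residual variances default
to `sigma2_E = sigma2_G (1 − h²)/h²` given a heritability. Replicate seeds
are `master_seed + replicate`, so any single trial is reproducible in
isolation.

GEBVs for the "overall" context are per-candidate means of `h_hat` over
environments; environment means are omitted from GEBVs since per-context
constants cannot change a ranking (TBVs keep `mu_j` because NDCG's gains
are the TBVs themselves). Rankings break ties by ascending candidate index
for determinism. NDCG uses linear gains and `1/log2(i+1)` discounts and
requires positive gains; with trait means of 100–200 and genetic variances
≤ 30 this holds essentially always, and a guard shifts gains so the minimum
becomes 1 (with a warning) otherwise. `k = floor(0.05·ncp)`, clamped to at
least 1; SRC@k is undefined (NaN) at `k = 1`.

Default experiment conditions mirror the simulation study the package is
built around: `T = 2` environments with means (100, 150) (a third at 200
for `T = 3`), `tau0 = 10`, `sigma2_Gx1 = 20`, `sigma2_Gx2 ∈ {10, 20, 30}`
(implying between-environment genetic correlations 0.707, 0.5, 0.408),
heritability 0.5, and 2,000 replicates by default. The scaled-down
reproduction in the test suite uses a 120-genotype structured synthetic
panel, (30, 30) designs, 100 replicates and known-component prediction —
sizes chosen so the whole loop runs in seconds while the qualitative
findings (optimized ≥ random; performance non-increasing as the genetic
correlation drops; NDCG far less dispersed than SRC/RSratio when
environment means dominate) remain testable against 2-pooled-standard-error
bands. Random baselines use 20 fixed designs held constant across
replicates, matching how optimized designs are used.

## What the synthetic generator does and does not emulate

The generator draws per-marker ancestral frequencies uniformly on a MAF
range, per-subpopulation frequencies from a Balding–Nichols Beta at a given
Fst, and genotypes with inbreeding coefficient F = 0.9 (heterozygote
probability `0.1 × 2f(1−f)`), mimicking elite inbred panels. It does not
emulate linkage disequilibrium along chromosomes, pedigree relatedness
within subpopulations, selection signatures, or genotyping error. Passing
tests therefore demonstrate correctness of the machinery and qualitative
behavior under realistic relatedness structure — not quantitative
performance on any particular real panel, which depends on its specific
kinship spectrum.
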