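# ngsdesign

**How should a fixed sequencing budget be split between sample size and
per-sample depth?** `ngsdesign` answers this question for population-genetic
inference by simulation: it generates independent diallelic sites read at a
configurable depth and error rate, estimates nucleotide diversity, calls
SNPs and infers population structure *directly from genotype likelihoods*
(never from hard genotype calls), and scores every estimate against the
simulation's ground truth. It is aimed at researchers planning re-sequencing
studies of non-model organisms, where the choice between "many individuals
at 1X" and "few individuals at high depth" has to be made before any data
exist.

## The model

Each site is polymorphic in the population with probability `prob_variable`;
polymorphic sites draw a derived-allele frequency *f* from the expected
neutral-diffusion site frequency spectrum, density ∝ 1/f on (f_min, 1)
(exponential and expansion-skewed variants are available). Diploid genotypes
follow Hardy–Weinberg proportions, optionally deformed by an inbreeding
coefficient F; read depth per individual per site is Poisson(λ); each read
reports one parental allele and is miscalled uniformly at rate ε. Structured
scenarios draw subpopulation frequencies from the Balding–Nichols Beta
distribution (mean p, variance F_ST·p(1−p)) in a three-population hierarchy.

From the read counts, per-individual genotype likelihoods feed the sample
allele frequency (SAF) machinery: the likelihood of *j* derived chromosomes
among 2N, P(D | X=j), computed either by the exact O(N²) dynamic
programming, or — under the empirical-Bayes prior the pipeline uses, a
region-wide SFS mixture fitted by EM — in closed O(N) form per site. The
three published summary statistics are

- **S**, the proportion of segregating sites: mean per-site probability of
  being variable, 1 − p₀ − p₂N;
- **H**, the expected heterozygosity: posterior mean of 2(X/2N)(1 − X/2N);
- the **standardised bias** Δ = (estimate − truth)/truth per window, where
  the truth uses all 1,000 true genotypes.

SNPs are called when P(variable) exceeds either a fixed cut-off
(0.90/0.95/0.99) or a *dynamic* threshold chosen to match the number of
calls to the true number of variable sites; precision = TP/(TP+FP) and
recall = TP/(TP+FN) are averaged across 100 windows. Population structure is
summarised by the first two principal components of the P(variable)-weighted
covariance of posterior-mean genotypes, aligned by Procrustes to the
known-genotype solution, and compared through SVM decision maps on a common
grid (the mislabelled-cell fraction).

## Worked example

```python
from ngsdesign.experiments import ScenarioSpec, run_scenario

spec = ScenarioSpec(n_windows=20, sites_per_window=500, seed=11)
result = run_scenario(spec)
print(result.snp_summary().round(3).to_string(index=False))
```

```
 depth  n_individuals  precision_mean  precision_sd  recall_mean  recall_sd  fp_rate_mean  fn_rate_mean
   1.0           1000           0.771         0.057        0.771      0.057         0.025         0.229
   2.0            500           0.791         0.051        0.791      0.051         0.022         0.209
  10.0            100           0.757         0.057        0.749      0.064         0.026         0.251
  50.0             20           1.000         0.000        0.557      0.063         0.000         0.443
```

Each row is one design at the same total coverage (1,000 read-equivalents
per site). Precision and recall are means across windows of dynamic-threshold
SNP calls scored against population-level truth. The pattern is the study's
central result: precision saturates at high depth (50X/20 calls no false
positives) but recall collapses because rare variants are simply not present
in 20 individuals, while 1,000 individuals at 1X recover three quarters of
all population SNPs. `result.bias_summary()` shows the matching diversity
story — H is nearly unbiased at 2X/500 and S and H are systematically
underestimated at 50X/20.

The same sweeps are exposed on the command line (`ngsdesign simulate`,
`ngsdesign diversity`, `ngsdesign call-snps`, `ngsdesign structure`,
`ngsdesign experiment run spec.yaml`), writing TSV tables plus a JSON
manifest with the config hash and seed.

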