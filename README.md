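# zinba

A covariate-aware peak caller for DNA-seq enrichment assays (ChIP-seq,
FAIRE-seq, DNase-seq), built around a **three-component zero-inflated
negative binomial (ZINB) mixture regression** over genome-wide window read
counts.

## The model

Reads are extended to the average fragment length, reduced to their central
base, and counted into contiguous non-overlapping windows (default 250 bp,
with an additional 125-bp offset grid).  Each window count *yᵢ* is modeled
as coming from one of three latent components:

- **zero-inflated** — a point mass at zero, reachable only when *yᵢ* = 0,
  with covariate-dependent prior probability
  *π*ᵢ₀ = logit⁻¹(*X*ᵢ₀ᵀγ);
- **background** (*j* = 1) and **enrichment** (*j* = 2) — negative binomials
  with log-linear means *μ*ᵢⱼ = exp(*X*ᵢⱼᵀβⱼ), dispersions *θ*ⱼ
  (variance *μ* + *μ*²/*θ*), and conditional mixture proportions
  *π*₁ + *π*₂ = 1.

Per-window covariates *X* — G/C content, mappability score, a local
background estimate (reads per mappable base in sliding 100-kb windows,
change-point filtered against CNV edges), and optional input-control
counts — get their own formulation in each component, selected automatically
by BIC over all strong-heredity main-effect/interaction term sets.

The model is fit by EM: the E-step computes posterior membership
probabilities (τᵢ₀, τᵢ₁, τᵢ₂) by Bayes' rule; the M-step maximizes the
weighted likelihood with iteratively-reweighted-least-squares GLMs using the
τ's as weights, profiling each dispersion.  Windows with enrichment
posterior τᵢ₂ above a threshold (default 0.95) are merged into regions
(within 5 kb in the broad setting), and punctate peak boundaries inside
regions are refined by an R²-maximizing linear fit on each side of every
local maximum of the base-pair read-overlap profile.

## Worked example

Simulate a dataset of 20,000 windows in which G/C content *raises* the
background mean and zero-inflation probability but *lowers* the enrichment
mean (1% of windows enriched), then fit the mixture with G/C in all three
components:

```python
import zinba
from zinba.simulate import benchmark_scenarios, simulate_dataset, model_design, \
    evaluate_classification

cfg = benchmark_scenarios(seed=5, n_windows=20_000)[("tfbs", "neg")]
sim = simulate_dataset(cfg)
fit = zinba.fit_mixture(model_design(sim, 3))
print("background beta:", fit.params.beta1.round(3))
print("enrichment beta:", fit.params.beta2.round(3))
print("AUC vs truth:", round(evaluate_classification(sim.truth,
                                                     fit.posteriors.tau2).auc, 4))
```

Output:

```
background beta: [1.108 0.499]
enrichment beta: [ 2.902 -0.121]
AUC vs truth: 0.9822
```

The background coefficients recover the generating values (intercept 1.1,
G/C slope +0.5 per sd); the negative enrichment G/C slope recovers the
simulated inverse relationship; and thresholding τ₂ separates enriched from
background windows almost perfectly.

The same machinery is exposed on the command line:

```bash
zinba run --reads reads.tagAlign --chrom-sizes hg.sizes --fasta genome.fa \
    --starting gc,bg --chroms chr22 --threshold 0.95 --refine --out run/
zinba cnv --input input.tagAlign --chrom-sizes hg.sizes --out cnv/
zinba simulate --scenario faire --gc-effect neg --n 100000 --seed 7 --out sim/
```

`zinba run` writes plain-text intermediates (`counts.tsv`,
`covariates.tsv`, `best_model.json`, `posteriors.tsv`, `regions.bed`,
`peaks.bed`) plus a manifest with per-stage checksums; every stage can be
re-run independently from the previous stage's files.

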