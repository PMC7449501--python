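# kinmix

Infer the admixture proportions of an individual's **parents, grandparents,
or great-grandparents** from that individual's phased diploid genome alone,
given allele frequencies in two source populations and a recombination map.

The signal is in the admixture tract-length distribution: the genome is
modelled with a hidden Markov chain over *ancestral configurations* — a
phase bit, one population bit per generation-K founder, and one
recombination-arrow bit per internal meiosis of the K-generation pedigree
(8 / 128 / 32768 states for K = 1 / 2 / 3). Because every bit transitions
independently, the transition matrix is a Kronecker product of 2x2 factors
and a divide-and-conquer forward pass costs `O(N log N)` per site instead of
`O(N^2)`. Founder switch rates are estimated by L-BFGS with
central-difference gradients on logit-transformed rates; per-founder
admixture proportions are the stationary frequencies of the fitted ancestry
chains.

The package also ships the full experimental harness: a Wright–Fisher
admixture simulator with tract-exact ancestor truth records, SNP pruning
(frequency-based and windowed-r² LD thinning), phase-switch-error injection
and cleanup, and best-match error evaluation against simulator truth.

## Layout

| module | contents |
|---|---|
| `kinmix.ac` | ancestral-configuration encoding, arrow tracing |
| `kinmix.hmm` | transition/emission model, D&C forward pass, likelihood |
| `kinmix.inference` | maximum-likelihood rate fitting, proportions |
| `kinmix.preprocessing` | frequency/LD pruning, phase cleanup |
| `kinmix.simulate` | founders, genetic map, WF admixture, truth records |
| `kinmix.evaluation` | best-match error, random-guess baseline |
| `kinmix.io`, `kinmix.cli` | VCF/TSV/JSON formats and the CLI |

## CLI

```sh
# simulate an admixed cohort (VCF + frequency TSV + map TSV + truth JSON)
kinmix simulate --n-haplotypes 200 --length 1e8 --generations 10 \
    --n-individuals 5 --seed 1 --outdir data/

# prune SNPs (frequency- or LD-based)
kinmix prune --vcf data/genomes.vcf --freqs data/freqs.tsv --map data/map.tsv \
    --method freq --df 0.5 --out-prefix data/pruned

# infer ancestor proportions (K = 1 parents, 2 grandparents, 3 great-grandparents)
kinmix infer --vcf data/genomes.vcf --freqs data/freqs.tsv --map data/map.tsv \
    --generation 1 --df 0.5 --seed 1 --out fit.json

# score against simulator truth
kinmix evaluate --truth data/truth.json --fit fit.json --generation 1 \
    --out report.json
```

Input conventions: phased VCF (GT with `|`; the designated "1" allele is
ALT), frequency TSV with columns `chrom pos allele freqA freqB`, and a
HapMap-style genetic map (`chrom pos rate_cM_Mb cM`). Positions are 1-based
throughout.

## Library sketch

```python
import numpy as np
from kinmix import SimConfig, simulate, frequency_prune, fit_ml, FitOptions

res = simulate(SimConfig(n_h=200, L=1e8, g=10, n_i=1, seed=1))
sites, genomes, _ = frequency_prune(res.sites, res.genomes, 0.5)
fit = fit_ml(genomes[0], sites, K=1, pp=0.0, options=FitOptions(seed=7))
print(fit.m0_hat)                       # population-A proportion per parent
print(res.truths[0].proportions(1))     # simulator truth
```

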