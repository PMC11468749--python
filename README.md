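# grc — genome redundancy & compressibility

`grc` quantifies how compressible microbial genomes are and how their
compressibility relates to genome size, base composition and
oligonucleotide usage, for comparative genomicists studying genome
randomness, reductive evolution and selective pressure on DNA word
usage.

Microbial genomes span ~0.1–10 Mb and ~25–85% AT content. How well a
genome compresses is a practical measure of its redundancy — an
incompressible genome is close to random, a compressible one is
pattern-rich — and redundancy covaries with size, AT content and with
**oligonucleotide usage variance (OUV)**, the variance of genome-wide
tetranucleotide frequencies around what base composition alone
predicts:

```
OUV = 1/(N−1) · Σ_XYZW ( f(XYZW) − f(X)f(Y)f(Z)f(W) )² ,   N = 4⁴ = 256
```

where `f(XYZW)` is the genome-wide frequency of the tetranucleotide
`XYZW` and `f(X)` the single-nucleotide frequency. AT content is
`(A+T)/(A+C+G+T)` over unambiguous bases, and the compression ratio of
a genome is `size in bases / compressed size in bytes`.

The package provides, as importable modules and a `grc` command line:

* **Curation** (`grc.io_genomes`) — multi-FASTA reading, plasmid
  exclusion by header keyword, chromosome concatenation, per-species
  deduplication, dual-backend compression-ratio outlier removal, all
  logged in an exclusion ledger that conserves genome counts.
* **Composition** (`grc.composition`) — nucleotide and k-mer frequency
  tables, AT content and OUV (single-strand, overlapping windows,
  ambiguity-containing windows skipped; `k` configurable, default 4).
* **Compression** (`grc.compression`) — standard codecs plus an
  implemented adaptive order-k context-model arithmetic coder in two
  variants: `ctx` (literal strand; the general-purpose-compressor role)
  and `ctx-rc`, identical except that a DNA word and its reverse
  complement share model statistics (the DNA-aware-compressor role).
  The single design difference isolates the mechanism by which
  DNA-aware compressors exploit inverted repeats. External `zpaq` /
  `mbgc` binaries can be registered as optional backends.
* **Synthetic cohorts** (`grc.synthetic`) — order-3 Markov genomes with
  controllable size, AT content, tetranucleotide bias (the OUV driver),
  repeat density (the redundancy driver) and genus-structured
  size-effects, plus a per-genome truth table of latent parameters.
* **Regression** (`grc.gam`) — a statsmodels-style
  `CompressibilityGAM` fitting penalized cubic regression spline
  additive models with genus random slopes (shared-ridge
  parameterization), ML/REML smoothing-parameter selection, per-smooth
  effective degrees of freedom, approximate Wald tests and
  edf-penalized AIC; `compare_models` ranks the full /
  no-random-effects / null triple, and `fit_difference_model`
  regresses one backend's ratio on another's to estimate the mean
  ratio improvement.
* **Pipeline** (`grc.pipeline`, CLI `grc run`) — curate → composition
  → compress → analyze with TSV interchange, a manifest, and
  deterministic outputs for a given seed.

## Worked example

```python
import pandas as pd
from grc import CohortSpec, generate_cohort
from grc.pipeline import composition_table, compression_table
from grc.gam import compare_models, standard_specs, fit_gam, fit_difference_model

cohort = CohortSpec(n_genera=6, genomes_per_genus=8, size_range=(2e4, 1e5), seed=7)
records, truth = generate_cohort(cohort)
table = composition_table(records).merge(
    compression_table(records, ("ctx", "ctx-rc")), on="genome_id"
)
print(table.head(3))
print(compare_models(table, standard_specs("ratio_ctx")).table())
print(fit_gam(table, standard_specs("ratio_ctx")["full"], method="REML").summary())
```

prints (abridged):

```
genome_id  length_bases     at       ouv  ratio_ctx  ratio_ctx_rc
   G00_00         23054 0.6874 1.411e-06      4.123         4.099
   G00_01         47592 0.7633 4.468e-07      4.137         4.184
   G00_02         50826 0.6165 8.369e-07      4.156         4.165

            model     aic   edf  deviance
             full -148.68 12.47      0.07
no_random_effects -117.81  6.99      0.17
             null  -50.97  1.00      0.89

Smooth terms
term                             edf        chi2         p
s(at)                           5.11      44.123     <1e-4
s(log10_size)                   1.23      29.572     <1e-4
s(ouv)                          1.00       0.646    0.4215
```

Reading the output: ratios near 4 sit at the 2-bits-per-base floor
(nearly incompressible); the AIC table ranks the model with
genus-specific size slopes far ahead of the fixed-effects-only and
intercept-only models, so genus structure in the size effect is real in
this cohort (it was planted by the generator); the AT smooth is
strongly non-linear (edf 5.1) while size and OUV act near-linearly.
`fit_difference_model(table)` then estimates how much the
reverse-complement-aware coder improves on the plain coder at equal
covariates — its intercept — here 0.563 ± 0.317 with slope 0.872 on
`ratio_ctx`.

The same run from the shell:

```
grc run --config run.json --out results/run1 --seed 7
```

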