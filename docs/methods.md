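# Methods

This note records the models, conventions and numerical choices behind
`grc`, and what the synthetic experiments do and do not demonstrate.

## Composition statistics

AT content is `(A+T)/(A+C+G+T)` over unambiguous bases; ambiguity
letters (N and the IUPAC codes) are excluded from numerator and
denominator. K-mer counting is single-strand, linear and overlapping
(step one); any window containing a non-ACGT letter is skipped
entirely rather than redistributed — the simplest rule that keeps the
frequency table a proper distribution. A `circular` flag adds the k−1
wraparound windows for closed chromosomes; it is off by default and
changes OUV only at O(k/L).

OUV is the sample-variance-style average squared deviation of observed
k-mer frequencies from the products of their single-nucleotide
frequencies, normalized by N−1 with N = 4^k (default k = 4, N = 256).
The expected-frequency table is the k-fold Kronecker product of the
base-frequency vector, so package OUV and a brute-force loop over all
words agree to ~1e−15; the tests enforce 1e−12.

## Compression ratio and the context coders

A genome's compression ratio is its base count divided by the
compressed byte count. The numerator deliberately counts bases, not
FASTA file bytes: headers and line breaks are stripped before
compression so that ratios measure sequence redundancy, not format
overhead. `CompressionResult` keeps both integers; the ratio is their
exact quotient.

The built-in `ctx` backend is an adaptive order-k context-model
arithmetic coder: the next base is coded from Laplace-smoothed counts
(pseudo-count 1, configurable as a positive integer — the coder works
on integer frequencies) of the bases previously seen after the same
k-base context, with k = 8 by default. Order 8 keeps 4⁹ word counters
(~260k), small enough for desk-scale memory while long enough for
repeat segments to become predictable after eight matched bases;
orders 0–12 are supported. Counts for a context are halved when their
smoothed total exceeds 2¹⁶, bounding adaptation lag and keeping
cumulative frequencies inside the 32-bit coder registers. The
arithmetic coder itself is the classic binary scheme with
underflow-bit counting; encoding and decoding replay identical model
updates, so round-trip identity is exact by construction and fuzzed in
the tests. Non-ACGT letters are carried in a side block of the
compressed container (delta-coded positions plus literal bytes,
deflate-compressed) and re-interleaved on decode; the arithmetic-coded
payload covers only the A/C/G/T symbols. The container starts with an
8-byte header (order, flags, smoothing, stream length).

`ctx-rc` differs in exactly one respect: model counters are indexed by
the lexicographically smaller of each (k+1)-base word and its reverse
complement, so a DNA pattern and its opposite-strand form accumulate
and draw on the same statistics. Canonicalizing the full (k+1)-mer —
rather than the k-context alone — is the only scheme under which a
word and its reverse complement genuinely share a counter, because the
reverse complement of context+symbol is not the reverse-complemented
context followed by any symbol.

Two empirical consequences matter for interpretation. On genomes whose
repeats are reverse-complemented copies, `ctx-rc` predicts inside the
copies from statistics learned on the originals and beats `ctx`
(by ~8% of ratio at 100 kb, 40% inverted repeats — the package's
desk-scale analogue of a DNA-aware compressor beating a
general-purpose one). On purely direct repeats it has no advantage
and in fact pays a small penalty (~3–4% at 50–500 kb): each canonical
counter also pools opposite-orientation chance hits, which dilutes
direct-repeat statistics at these context densities. The property
tests assert this asymmetry (gain if and only if inverted repeats are
present) rather than exact parity on tandem repeats.

Code-length sanity anchors: an order-0 coder on uniform i.i.d. bases
codes within 1% of the 2 bits/base entropy floor at 100 kb; the
order-8 coder stays within [1.99, 2.10] bits/base there (no coder can
beat the floor; the excess is adaptation cost across 4⁸ contexts); a
homopolymer collapses to a few bytes. External `zpaq` (via lrzip) and
`mbgc` binaries can be registered as optional backends for users who
want the real tools; nothing in the package or its tests requires
them.

## Synthetic cohort generator

Each genome is drawn from an order-3 Markov source. Transition weights
start at the single-base distribution implied by the target AT content
with Chargaff parity built in (A = T, C = G within strand, mirroring
the near-universal within-strand parity of real genomes; a flag
disables it). Tetranucleotide bias — the OUV driver — multiplies the
weights by log-normal factors of strength `bias_strength` attached to
reverse-complement-canonical 4-mers, which keeps the source strand
symmetric while directly sculpting 4-mer statistics (an order-3 source
parameterizes exactly the 4-mer level that OUV measures). After
perturbation, every row's A+T transition mass is rescaled back to the
target, so realized AT content is Binomial(L, target) regardless of
bias strength — AT fidelity holds within binomial error even at
`bias_strength` 1.

Repeats — the redundancy driver — are appended after the core
sequence: `repeat_fraction` of the final length is produced by copying
earlier segments (geometric lengths, mean 500 bases, minimum 20),
each copy reverse-complemented with probability
`inverted_repeat_fraction`. Copying after generation keeps
`repeat_fraction` interpretable as the redundant fraction of the
genome.

Cohorts plant the couplings the analysis is meant to recover:
`bias_strength = bias_base + at_ouv_coupling · standardized AT +
noise` (negative coupling by default, so AT-rich genomes get lower
OUV) and `repeat_fraction = repeat_base + slope_genus · standardized
log size + noise` with per-genus slopes drawn around
`size_repeat_slope` with standard deviation `genus_slope_sd` (so
larger genomes are more redundant, genus-specifically). Defaults
emulate curated RefSeq-style cohorts: 20 genera × 10 genomes, sizes
log-uniform over 0.1–10 Mb, AT uniform over 25–85%. All randomness
flows from the spec seed through numpy `SeedSequence` spawning (one
child per stage, one per genome); identical specs give byte-identical
cohorts.

What the generator does not emulate: gene structure, codon usage, GC
skew, replication-strand asymmetries, mobile elements, real plasmid
biology, or realistic phylogenetic covariance beyond the genus
grouping. Passing tests therefore demonstrate that the pipeline
recovers structure it was designed to detect from sequences with that
structure planted — they do not validate the biological conclusions
one would draw from real cohorts.

Problem sizes: tests and the acceptance script run cohorts of 96
genomes of 20–200 kb and single sequences of 50–200 kb. These sizes
put the context coders and the mixed-model machinery in their
operating regime while keeping a full run in minutes on one CPU; the
couplings themselves are size-free, and the generator accepts
megabase-scale specs unchanged.

## Additive mixed models

The regression core is a Gaussian additive model: outcome (a backend's
compression ratio) on smooths of AT content, log₁₀ genome size and
OUV, optionally a linear term (the other backend's ratio in the
difference model), plus genus random effects.

*Basis.* Each smooth uses `basis_dim` (default 10) cubic B-spline
columns with interior knots at quantiles of the training values and
the integrated-squared-second-derivative penalty, computed exactly by
two-point Gauss–Legendre per knot span (the integrand is piecewise
quadratic). A sum-to-zero constraint over the training points is
absorbed by an orthonormal reparameterization, leaving `basis_dim − 1`
identifiable, centered columns per smooth (minimum `basis_dim` 4 —
the smallest cubic B-spline basis). Penalty matrices are normalized to
unit maximum entry so smoothing parameters are scale-free; without
this, a covariate spanning 1e−5 (OUV) and one spanning three decades
(log size) would differ by ~15 orders of magnitude in penalty scale
and destroy the optimizer's conditioning.

*Random effects.* The genus random slope (and optional random
intercept) uses the standard penalized-regression equivalence: one
column per genus (indicator × z-scored slope covariate) under a shared
ridge penalty whose smoothing parameter is estimated with the spline
penalties; the implied variance component is `scale/λ`. Exact
likelihood equivalence with dedicated mixed-model software is not
claimed; what is claimed — and tested — is structure recovery:
planted genus slopes make the full model win the AIC comparison, and
a homogeneous cohort does not. Whether the "full" model carries a
random slope only or also a random intercept is a modelling choice the
API exposes (`RandomEffect(include_intercept=...)`); the default full
model uses the slope alone.

*Smoothing-parameter selection.* For fixed λ the penalized least
squares problem is solved by Cholesky; λ is chosen by minimizing the
marginal −2 log-likelihood (ML) or its restricted version (REML) of
the Gaussian model, profiled over σ²: with A = XᵀX + S_λ, RSS and P
the residual and penalty quadratics, M the penalty null-space
dimension and V an orthonormal basis of the penalized space,

```
REML:  (n−M)(log 2πσ̂² + 1) + log|A| − log|VᵀS_λV|,   σ̂² = (RSS+P)/(n−M)
ML:    n(log 2πσ̂² + 1) + log|VᵀAV| − log|VᵀS_λV|,    σ̂² = (RSS+P)/n
```

minimized over log λ by Nelder–Mead (cheap: XᵀX is precomputed and p
stays below ~60). Numerical guards: σ̂² floored at 1e−12·(ȳ²+1) so
exact-fit degeneracies (a response identically equal to a covariate)
stay finite; log λ clipped to ±25 with a tiny quadratic pull-back
beyond the clip so flat directions cannot strand the simplex; a
convergence tolerance of 0.05 in log λ (λ within ~5%, far below the
sampling noise of any reported edf or AIC); escalating-jitter Cholesky
retries, with a rank-deficiency error if they fail. ML is used for all
AIC comparisons and REML for final reported fits.

*Diagnostics.* Effective degrees of freedom are traces of
(A⁻¹XᵀX) restricted to each term's columns (1 ≤ edf ≤ basis_dim − 1
for a smooth; edf ≈ 1 means linear). AIC is the conditional Gaussian
log-likelihood penalized by total edf + 1 (the scale), the
penalty-aware count. Per-smooth p-values are approximate Wald tests of
the term's coefficients against their Bayesian covariance with rank
limited to ⌈edf⌉, labeled approximate in the API; linear terms get
z-tests. No multiple-testing correction is applied. Partial effects
are centered curves with ±2 SE bands; grid points outside the training
range are flagged as extrapolated (spline values are clamped to the
boundary there). edf estimates inherit sampling noise — on
linear-truth data an unlucky draw shows spurious wiggle under any REML
fit (the mgcv cross-check in the test suite reproduces this on the
same draw) — so recovery tests judge the median over replicate draws.

*Difference model.* Regressing backend B's ratio on backend A's
(linear) plus the three smooths and the genus random slope makes the
intercept the mean ratio improvement of B over A at equal covariates,
and the smooths show where along AT, size and OUV the two backends
disagree. With measurement noise in A the slope shrinks below 1 and
the intercept absorbs the difference, so intercept and slope are
always reported together. The degenerate identities hold to machine
precision: B = A gives slope 1 and intercept 0; B = A + c recovers c.

## Known limitations

* The context coders are mechanism surrogates, not competitive genome
  compressors: no cross-genome referential matching, no 2-bit packing,
  no secondary modelling of the exception block.
* The ridge-parameterized random effects approximate, not replicate,
  dedicated GAMM software; AIC values are comparable within this
  package, not across implementations.
* Wald p-values for smooths are approximate, particularly at small n
  or edf near the basis ceiling.
* Curation identifies plasmids only by header keywords (configurable,
  default "plasmid"); unlabeled plasmids pass through.
* Synthetic cohorts validate machinery, not biology; conclusions about
  real genomes require real cohorts through the same pipeline.
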