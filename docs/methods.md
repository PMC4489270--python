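# Methods

## Model and assumptions

The package treats the top BLASTP bit score of protein `p` against
genome `g` as a continuous measure of orthologous conservation. Two
normalizations make these scores comparable:

* **Across genomes within a protein** — dividing by the self-score
  `s(p, q)` (the protein's top within-genome score) removes protein
  length and composition effects, yielding `v(p, g) ∈ [0, 1]`.
* **Across proteins within a genome** — standardizing each genome
  column against the distribution of normalized scores of all profiled
  proteins, `Z(p, g) = (v − μ_g)/σ_g`, absorbs the genome-wide shift
  caused by evolutionary distance: 50% identity to a yeast ortholog is
  strong conservation, the same identity to a mouse ortholog is fast
  divergence.

Co-evolution is then read from the Pearson correlation of Z-profiles.
The underlying assumption is that functional linkage manifests as
correlated retention/divergence across the panel; the method does not
model the phylogeny itself, and shared ancestry alone can correlate
profiles — hence the emphasis on the empirical significance estimate and
on treating it as a rough guide.

### The permutation null

For each compared pair, one profile's entries are shuffled uniformly at
random `N` times (default 1000, duplicates and the identity permutation
not excluded) and the observed `r` is standardized against the empirical
mean and standard deviation of the shuffled coefficients. The empirical
mean is used rather than zero because the permutation null of Pearson's
r has mean −1/(n−1); its standard deviation is ≈ 1/√(n−1), so Z grows
roughly like `r·√(n−1)`. The statistic is a *descriptive* significance
measure: profile entries are phylogenetically dependent, so Z is not a
calibrated p-value and no multiple-testing correction is attempted.

`exhaustive_permutation_z` enumerates all `n!` permutations for `n ≤ 7`
and is kept as an independent oracle; the sampled estimator converges to
it at the Monte-Carlo rate `1/√N`.

Each (query, subject) pair derives its own random stream from the master
seed via CRC32 of the two identifiers, so a pair's Z is identical
whatever `k` is requested or in whatever order pairs are evaluated.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `score_threshold` | 50 (bit score) | hits strictly below are treated as no homolog; 50 bits is a conventional noise floor for proteome-scale BLASTP |
| `min_fraction` | 0.25 | minimum fraction of genomes with a surviving hit; proteins below it have too little signal to profile (the workflow prescribes dropping proteins missing "across a portion of genomes" without fixing the portion — 0.25 is this package's configurable choice) |
| `cap` | on | clip normalized values at 1; a cross-genome hit can slightly exceed the self-score when domains are duplicated |
| `k` | 50 | number of reported partners (50/100/150/200 are conventional presets; any positive integer is accepted) |
| `n_shuffles` | 1000 | permutation-null size; the Z estimate has MC error ≈ √((1+Z²/2)/N) |
| `seed` | 0 | master seed for all randomness |

## Numerical choices and degenerate inputs

* Population standard deviation (÷ n) everywhere a column is
  standardized; at proteome scale the n vs n−1 distinction is
  irrelevant, but it is fixed for reproducibility.
* Missing orthologs enter the genome statistics as 0. Excluding them
  would bias `μ_g` upward and overstate divergence of everything else.
* The query-genome column normalizes to exactly 1 for every protein, so
  it is constant and has no defined Z-score. It is kept in the
  normalized matrix (and the rendered heatmap/table) but excluded from
  the genome statistics, the Z-matrix and hence the correlations.
* Zero-variance inputs raise (`DegenerateProfileError`) rather than
  returning NaN: a constant genome column means Z-scoring is undefined;
  a constant protein profile is skipped with a warning during ranking.
* Top-hit ties are broken by input-file order; ranking ties by protein
  id ascending. Both make repeated runs byte-identical.
* Pearson values are clipped to [−1, 1] against floating-point overshoot.

## The synthetic-data generator

`simulate.generate_module_matrix` emulates the statistical structure the
method assumes: each planted module shares one latent clade-structured
pattern — every subtaxon of the 4-taxon / 86-genome synthetic panel is
either retained (with a clade-level base conservation and per-species
jitter, sd 0.08) or lost wholesale with probability 1 − 0.85 — and
members add independent noise sized so two members' conservation values
correlate at `within_module_r` (0.9 by default; exactly identical
profiles at 1.0). Scores are the latent conservation times a per-protein
self-score drawn from the upper part of (50, 1000) bits, so a realistic
fraction of cells falls below the 50-bit filter.

What it does **not** emulate: real sequence evolution (no sequences are
generated), phylogenetic autocorrelation between clades beyond shared
loss, BLAST search artifacts (paralog confusion, partial alignments),
and annotation errors. Passing the recovery and calibration tests
therefore shows the machinery is correct under the model's own
assumptions, not that the biological discovery rate on real proteomes
matches.

`generate_correlated_pair` draws bivariate-normal pairs for the
calibration protocol. At panel size 86 with 1000 shuffles, the mean
permutation Z is ≈ 4.6 at true r = 0.5 and ≈ 8.8 at r = 0.95,
consistent with the working cutoffs of ~5 (marginal) and ~8 (highly
significant). The calibration runs use 2000 replicate pairs, which puts
the Monte-Carlo standard error of the reported mean near 0.02 while
finishing in seconds on one CPU.

## Problem sizes

Tests and the acceptance script run entirely on generated data: the
standard fixture is 100 proteins × 86 genomes (one 5-protein module),
calibration uses 2000 pairs × 1000 shuffles, null calibration 1000
pairs, and enumeration checks use length-6 profiles (720 permutations)
against 20 000-shuffle estimates. These sizes keep every check under a
few seconds while leaving Monte-Carlo error well inside the asserted
tolerances.

## Known limitations

* Z-scores are descriptive, not calibrated p-values; profiles of related
  species are dependent and the null ignores tree structure.
* Self-score normalization requires every profiled protein to have a
  within-genome hit; proteins without one are rejected rather than
  silently skipped.
* Sequence mode inherits the database's genome statistics; submitting a
  sequence from a very different proteome than the build's query genome
  stretches that assumption.
* The heatmap's intermediate color stops are this package's choice; only
  the endpoints (white→dark blue for similarity, yellow→dark red for
  r/Z) are fixed by convention.
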