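# Methods

## The experiment being modeled

TARDIS (Transgenic Arrays Resulting in Diversity of Integrated Sequences)
barcoding in *C. elegans* proceeds through a chain of stochastic
bottlenecks: a degenerate oligo library is amplified by complexing PCR,
injected, and assembled into a heritable extrachromosomal array; on
induction, single barcodes integrate from the array into a genomic landing
pad in F1 animals. Each stage is read out by UMI-tagged amplicon
sequencing of a 15 bp barcode. This package implements both a generative
model of that chain and the quantification pipeline that inverts it —
filtering, deduplicating and error-correcting reads, then estimating
diversity, jackpotting, overlap and the array→F1 frequency transfer.

## Generative model

**Barcode space.** The template `NNNCNNTNTNANNNN` (15 bp, 11 free
positions, fixed C/T/T/A at 1-based positions 4/7/9/11) encodes
4^11 = 4,194,304 sequences. Library synthesis draws molecules uniformly
over this space.

**PCR jackpotting.** Each template i receives a duplication probability
e_i ~ Beta(a, b) drawn once; over `cycles` rounds its count n grows by
Binomial(n, e_i). Heterogeneity in e_i compounds geometrically —
(1+e)^cycles spans more than an order of magnitude between e = 0.3 and
e = 1 at ten cycles — which is the simplest mechanism that yields a small
jackpotted minority carrying a disproportionate read share. Defaults
a = 8, b = 2 (mean 0.8, sd ≈ 0.12) with 10 cycles. With a deterministic
efficiency the stage preserves frequencies exactly, which the tests use
as an identity oracle.

**Array formation.** An array is founded by m distinct barcodes sampled
without replacement proportional to injection-mix frequency (observed
arrays spanned 91–3001 unique barcodes; m is a free parameter, default
1000 for the demo pipeline). Each founder's copy number is zero-truncated
Poisson(λ), default λ = 3. Independently, with probability `jackpot_prob`
(default 0.05) a founder's copy number is multiplied by
exp(N(0, `jackpot_factor_log_sd`)) and rounded up — a log-normal stand-in
for the early replication events that dominate low-diversity arrays; no
mechanistic claim is attached to that functional form. Injection-mix
jackpotting and array jackpotting are deliberately independent mechanisms.

**Integration.** F1 integrant counts are Multinomial(n, p) with
p_i ∝ f_i · bias_i; bias defaults to 1 everywhere and exists so that
planted-outlier experiments have a ground truth.

**Sequencing.** Each of `depth` molecules (sampled ∝ pool frequency) gets
a uniform random 10-mer UMI and 1 + Poisson(`duplicate_rate`) reads. A
read is `prefix + CAC + UMI + GAC + barcode + suffix` cropped to 87 bp;
the constant suffix stands in for the vector backbone. Substitutions are
i.i.d. per base per read (default 10⁻³); indels are available but off by
default, since the Levenshtein clusterer downstream handles them anyway.
Qualities are Gaussian (mean 36, sd 3) truncated to [2, 41], with an
optional low-quality 3′ tail to exercise quality trimming. Every run
writes a ground-truth sidecar (molecule, barcode, UMI, read count), and
identical parameters + seed give byte-identical FASTQ.

The generator emulates the statistical structure of the assay — abundance
skew, founder sampling, copy-number dispersion, UMI duplication,
substitution noise. It does not model index hopping, paired-end reads,
context-dependent error spectra, chimeric PCR products, or any wet-lab
biology (array maintenance selection, heat-shock physiology). Passing
tests therefore demonstrate correctness of the inference machinery under
the stated noise model, not robustness to every artifact of real
sequencing runs.

## Read processing

Stage order: optional two-color (NextSeq) poly-G-aware trim → 3′ quality
trim at Q30 by the running-sum minimum algorithm → discard reads
containing N → discard reads with expected errors Σ10^(−Q/10) > 1 → crop
to 87 bp → discard reads shorter than the 31-base minimal layout. A
strict mode (discard any read with a base < Q30) is provided as the
literal reading of "quality score < 30"; the default reproduces the
trimming semantics of the standard tools. The expected-error filter is
applied to the bases that survive trimming. Note one consequence of the
running-sum algorithm: a read uniformly at Q20 is trimmed away entirely
(nothing is above threshold), whereas the same read ending in a single
high-quality base survives trimming and passes the EE filter at 0.87 ≤ 1.

UMI extraction searches 5′→3′ for the first occurrence of
`CAC` + 10 bases + `GAC` (exact flanks by default; a one-mismatch budget
across both flanks is available) and removes the whole block.
Deduplication keys on (UMI, full post-UMI sequence) — not UMI alone — so
two true barcodes colliding on a UMI (probability ≈ n/4^10) are not
merged. Deduplicated sequences are trimmed to their first 15 bases.
Conformity to the template's fixed bases is reported as QC but never
filtered on; only final length is enforced, at the clustering stage.
Coordinates are 0-based half-open internally, 1-based inclusive in
user-facing reports.

## Error-correction clustering

Abundance-greedy sphere clustering: sequences sorted by count descending
(ties lexicographic, for determinism); each joins the candidate centroid
minimizing (edit distance, −count, sequence) among centroids within
Levenshtein radius r = 2 whose **running aggregated** count is ≥ 5× its
own; otherwise it founds a centroid. r = 2 suits 15-mers at ε ≈ 10⁻³
(double errors are ~10⁻⁴ per read); ratio 5 is the conventional
sphere-clustering default. After clustering, centroids whose length ≠ 15
are dropped with their mass, so indel-bearing reads can still be rescued
into 15-mer centroids. Distances use a banded early-exit Levenshtein
(edlib); an independent dynamic-programming implementation serves as the
oracle in the tests, and a brute-force re-implementation of the whole
greedy rule is checked against the production path on 200 random
instances. Mass is conserved exactly: centroid + dropped counts equal
raw counts.

## Statistics

**Plateau threshold.** u(c) = #{barcodes with count ≥ c}; the threshold
is the smallest c with (u(c) − u(c+3))/u(c) < 1%. The window and
tolerance formalize what was originally a visual plateau call. If no
plateau exists at or below the 99th-percentile count the stage falls back
to 5 reads with a warning — the conventional conservative cutoff — which
is also what happens on well-sampled synthetic data whose thresholded
counts decline smoothly rather than bimodally. The threshold is selected
on raw (pre-clustering) counts, where the error tail that creates the
plateau still exists, and applied to the corrected table.

**Jackpots.** Barcodes with raw count > 50, reported with their share of
reads and of unique barcodes. The cutoff is the injection-mix convention;
it is applied to arrays only on request.

**Logos.** Position probability matrices (rows = positions, columns
A/C/G/T, each row summing to 1), per-barcode ("unique", default) or
read-weighted. Fixed template positions must show probability 1.0 on
error-free input, a standing self-check.

**Zero-truncated Poisson fit.** λ̂ solves λ/(1−e^(−λ)) = sample mean,
found by bracketed root-finding on [10⁻¹², mean] to 10⁻¹² (the ZT mean
exceeds λ, so the bracket always contains the root). GOF is a chi-square
with tail bins merged until every expected count is ≥ 5 and one degree of
freedom charged for λ̂. A sample mean ≤ 1 is reported as the λ → 0
boundary with GOF skipped.

**Correlation.** Pearson r between array and F1 frequencies over the
union universe with zero fill (default; an intersection mode exists —
the choice matters when the two universes differ, and both per-replicate
and pooled r are reported because pooling convention is itself a choice).
The two-sided p uses t = r√((n−2)/(1−r²)); because this assay produces
p-values near 10⁻¹⁵⁰, the Student-t survival function is evaluated in log
space, switching to the incomplete-beta tail expansion
sf(t) = ½·I_x(ν/2, ½), x = ν/(ν+t²), when the direct log-sf underflows.
p-values are reported, never used for gating; no multiple-testing
correction is applied anywhere.

**Replicated outliers.** Per replicate, a least-squares line is fit to
(array frequency, F1 frequency); residuals are standardized by the
binomial sampling noise √(ŷ(1−ŷ)/N) of the fitted proportion (N = the
replicate's read total), floored by a robust MAD scale, with leverage
correction and one refit excluding first-pass flags. A barcode is a
replicated outlier if |standardized residual| > 3 in ≥ 3 replicates, with
its direction (over-/under-integrating) from the residual sign. The
binomial standardization is the key design choice: frequency noise grows
like √f, so a single global residual scale either misses the
under-integrating outlier (RMS, inflated by the large outlier) or
false-flags high-frequency barcodes (MAD, calibrated to the median
frequency). All three scale modes are exposed; z, the replicate quorum
and the scale mode are configurable.

## Problem sizes and numerical choices

Simulation-backed tests run at deliberately modest sizes — libraries of
10³–10⁴ molecules, arrays of 25–400 founders, read depths of 10³–5×10⁴,
20–200 seed replicates — chosen so each statistical check retains clear
power (assertions sit at 3–5 σ of the relevant sampling distribution)
while the whole suite stays fast. The planted-outlier recovery experiment
uses the full study geometry: 91 founders, ZT-Poisson(3), 4 replicates of
50,000 integrants, 100 seeds. Randomness flows from one top-level seed
through `numpy.random.SeedSequence` spawning, so stages are individually
reproducible and all derived seeds stay below 2³¹.

Degenerate inputs: empty count tables, single-barcode pools, all-ones
copy counts (λ boundary), zero-variance correlation inputs and m >
available barcodes all raise informative errors or documented boundary
results rather than propagating NaNs.

## Known limitations

* The amplicon layout outside the UMI block and barcode is an assumption
  (configurable); real primer structure is not modeled.
* The plateau rule presumes a bimodal raw-count histogram; on smoothly
  declining histograms it falls back to the conventional 5-read cutoff.
* The clusterer is quadratic in distinct sequences per sample; it is
  comfortable to ~10⁴–10⁵ distinct 15-mers but is not a general-purpose
  trie-indexed denoiser.
* The jackpot amplification form (log-normal multiplier) is a modeling
  convenience; only its qualitative effect (heavy-tailed array
  frequencies in low-diversity arrays) should be trusted.
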