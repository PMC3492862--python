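# Methods

`nascentcycle` analyses paired circadian time courses of nascent RNA
(chromatin-associated transcripts, a proxy for instantaneous transcription)
and steady-state mRNA, plus downstream CLK/BMAL1 ChIP-Seq peaks. This note
documents the models, the statistics, the synthetic-data generator and the
numerical choices, in that order.

## Study design

The design emulated throughout is two independent six-timepoint series per
assay, sampled every 4 h across a light:dark cycle: nascent RNA at ZT0, 4, 8,
12, 16, 20 and mRNA at ZT2, 6, 10, 14, 18, 22, two biological replicates
each. The two replicates are concatenated into a single 12-point series
treated as one equally spaced 48-h span. Phases are reported on the ZT clock,
so nascent and mRNA phases are directly comparable despite the 2-h grid
offset.

## Expression unit and normalization

Gene signal is rpbp (reads per base pair): the number of reads overlapping a
gene's exon union by at least one nucleotide (each read counted at most once
per gene; spliced reads by their blocks), divided by the exon-union length.
Raw rpbp is scaled by `40e6 / uniquely_mapped` to a common depth of 40
million uniquely mapped reads. Default expression filters are a maximum
sample value above 6 normalized rpbp for nascent data and 8 for mRNA data;
both are configuration knobs because reasonable alternatives exist on the
raw (un-normalized) scale.

The lane-reproducibility table quantifies counting noise between duplicate
sequencing lanes: per gene the fold difference max(a,b)/min(a,b), tabulated
in nested strict-`>` bins (>2, >1.5, >1.4, >1.3, >1.25, >1.1) plus the
complementary 1.0–1.1 bin, per rpbp-threshold column. Only the last two bins
partition the genes, so only their percentages sum to 100. A per-gene
dispersion score |a−b|/mean(a,b) is emitted alongside for plotting.

## Rhythm detection

For a 12-point series x the statistic is the 24-h spectral fraction

    F24 = P2 / (P1 + ... + P6),   Pk = |Xk|^2  (one-sided DFT power)

where k = 2 is the 24-h harmonic of the 48-h window. F24 is 1 for a pure
daily cosine and 0 by convention for an all-equal series; it is invariant to
positive scaling and DC offsets. The definition — the 24-h harmonic's share
of non-DC one-sided power — is our interpretation of "24-h spectral power in
the range 0–1"; published genome-scale gene counts obtained with other F24
codes are therefore not exact reproduction targets.

Phase is taken from the same coefficient: `phase = (−arg X2)·24/2π +
t_start (mod 24)`, the clock time at which the fitted 24-h cosine peaks. On
an equally spaced grid this equals the least-squares cosine fit. Amplitude
is the max/min ratio of the 12 values with the denominator floored at 0.1
normalized rpbp (genes silent at trough get a very large amplitude rather
than a division error) and capped at 10^4 for tabulation.

Significance is a permutation test: all 12 values are shuffled jointly
(10,000 permutations by default) and p = (#{F24_perm ≥ F24_obs} + 1)/(N + 1).
The +1 correction makes the p-value strictly positive and super-uniform
under the null at any N; an exhaustive-enumeration mode exists for short
series and is used as the exact reference in tests. Calls are strict:
medium = p < 0.05 and F24 > 0.45 and amplitude > 1.5; strong = p < 0.05 and
F24 > 0.6 and amplitude > 1.75. No multiple-testing correction is applied.
Per-gene permutation streams are derived from (master seed, gene row index),
so batch composition and order do not affect any gene's result.

## Four-way classification and concordance

"Rhythmic" for classification means a strong or medium call. Crossing the
nascent and mRNA calls on the genes expressed in both assays gives RR, RAR,
ARR and ARAR categories; by construction RR + RAR equals the
transcription-rhythmic count and RR + ARR the mRNA-rhythmic count, and the
summary percentages are recomputed from the counts (no drift). Phase
concordance uses the signed circular difference (mRNA − nascent) in
(−12, 12]; phase correlation is the Fisher–Lee circular correlation
(rotation-invariant, so a constant lag still gives r = 1), with plain
Pearson available as a cross-check; amplitude correlation is Pearson on
log2 amplitudes because amplitudes are ratios. The paper-style analyses
these statistics feed do not state the scale or circular estimator; both
choices are documented here as ours.

Transcriptional variability is the coefficient of variation (sample SD,
n−1, over mean) of the 12 values. Quintile analyses rank genes by CV
descending with a stable gene-id tie-break; q1 is the most variable 20%. A
single-timepoint burst is called when, in each replicate separately, the
maximum timepoint exceeds θ = 3 times the mean of the other five and the
argmax clock time matches across replicates. Readthrough flagging is a
heuristic: a rhythmic gene is flagged when a same-strand upstream neighbor
within 10 kb is rhythmic with phase agreement within 2 h and the intergenic
gap carries above-background signal (75th percentile of all gap signals) at
the neighbor's peak time. θ, the gap and the quantile are knobs; the
reference gene sets these heuristics emulate were manually curated, so no
count matching is attempted.

## ChIP peak analyses

Two peaks overlap when their half-open intervals intersect by ≥ 1 nt;
overlapping peaks merge into union intervals (connected components), making
the shared count symmetric. Overlap significance is a permutation placement
test — peaks of one set are re-placed uniformly at random on their
chromosomes, preserving widths — because the contingency table behind a
chi-square alternative is not recoverable. Peaks are assigned to the gene
whose genomic span contains the peak center (ties: smallest TSS distance,
then lexicographic id), otherwise to the nearest TSS genome-wide. Signal
profiles z-score the whole track ((x − mean)/SD over every base) before
extracting center ± 1 kb windows and averaging in 25-bp bins.

E-box enrichment scans peak-centered ± 500 bp windows for perfect CACGTG
(palindromic, so one strand suffices) and degenerate (Hamming distance
exactly 1) matches, both strands deduplicated by start position. Offsets are
motif start relative to peak center. The expected count per offset is the
mean over 100 (configurable) Altschul–Erickson dinucleotide shuffles of each
window, which preserves local composition; enrichment = observed/expected
where expected > 0. Whether offsets should be measured motif-start or
motif-center to peak-center is ambiguous in the source analyses; motif-start
is implemented.

## Synthetic-data generator

The generator is first-class, tested code and defines the conditions every
statistical guarantee is stated under.

Transcription is a 24-h cosine, `s(t) = b(1 + a·cos(ω(t − φ)))`, ω = 2π/24,
with class defaults: rhythmic genes a ∈ [0.4, 0.8] and uniform phases;
arrhythmic classes a = 0. mRNA follows the linear production–degradation
ODE `dM/dt = s(t) − δM`, δ = ln2/half-life, at periodic steady state: the
mRNA rhythm is attenuated by `1/√(1 + (ω/δ)²)` and delayed by
`arctan(ω/δ)/ω` hours (closed form, verified in tests against an
independent numerical ODE integration). RR genes draw half-lives of 0.5–3 h
(rhythm survives), RAR genes 10–24 h (attenuation pushes the mRNA amplitude
below the 1.5 cut-off). Burst genes multiply one timepoint by a 4–8-fold
factor at the same clock time in both replicates; their mRNA response is the
burst convolved with the exponential decay kernel, computed with the exact
piecewise-constant integrator on a 0.01-h grid iterated to periodic steady
state. mRNA series are rescaled by δ so a steady gene maps back to its
baseline, keeping the two assays on one scale.

Biological noise is multiplicative log-normal, mean-preserving, with σ set
so the coefficient of variation equals `noise_cv` — expression is strictly
positive, matching rpbp data; this is our choice, as is the linear coupling
model (the simplest mechanism producing the observed delay/attenuation
phenomenology). Defaults: CV 0.15 for cosine classes, 0.3 for the "variable
transcription" classes (burst, ARAR), 0.1 for steady genes — chosen once to
make planted classes separable, since no generative parameters exist for
these magnitudes. Sequencing noise is a separate Poisson layer
(`counts ~ Poisson(rpbp · exon_length · depth/40e6)`) with its own seed
stream, so replicate lanes can share biology but differ in counting noise.

The toy genome places equal-sized multi-exon genes with alternating strands
on a uniform-random sequence, scrubs accidental CACGTG occurrences so only
planted E-boxes exist, distributes reads wholly inside exons/introns/
intergenic zones at configured fractions (defaults 0.13/0.76/0.11, the
nascent-library signature), and plants peaks with optional centered E-boxes.

What the generator does not emulate — and hence what passing tests do not
show about real data: realistic sequence composition, isoform structure and
splicing intermediates, 5′–3′ polymerase gradients, non-sinusoidal waveforms
beyond single bursts, fragment-length effects in ChIP, and mapping
artifacts. Guarantees like "≥ 90% sensitivity at a = 0.5, CV = 0.1" are
statements about this generative model, not about any particular dataset.

## Numerical choices and degenerate inputs

- Coordinates are 0-based half-open internally; GTF converts on read.
- All RNGs are numpy Generators; child streams come from
  `SeedSequence((master, index))`, never from spawn order.
- Constant series: F24 = 0, p = 1, amplitude 1, phase NaN.
- Genes at zero in both duplicate lanes are excluded from the lane table;
  genes with zero mean mRNA are excluded from the nascent/mRNA ratio (both
  logged).
- Ratio outliers are taken at mean ± 2 SD of log2 ratios, with a 1e-9
  absolute floor on the deviation so float noise in degenerate inputs never
  flags an outlier.
- Profile windows that cross chromosome ends are clipped and the affected
  bins averaged over available bases (NaN when empty).

## Problem sizes

Default test and pipeline runs use 50–300 synthetic genes with 100–1,000
permutations; the type-I error analysis uses 2,000 pure-noise genes at 1,000
permutations, where the binomial standard error on the rejection rate is
about 0.5 percentage points. These sizes make every check reproducible on a
single CPU in seconds while keeping Monte-Carlo error well inside the stated
tolerances.
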