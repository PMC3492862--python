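# nascentcycle

Rhythm detection and transcriptional/post-transcriptional classification for
circadian nascent-RNA and mRNA sequencing time courses.

Around the clock, a large share of a tissue's mRNA rhythms is not explained
by rhythmic transcription: comparing nascent RNA (chromatin-associated,
polymerase-attached transcripts — a proxy for instantaneous transcription)
with steady-state mRNA over the day separates transcriptional from
post-transcriptional control. `nascentcycle` implements that comparison as a
tested, reusable library for computational biologists: gene-level
quantification from read intervals, spectral rhythm detection with a
permutation null, four-way rhythm classification, variability and burst
analyses, and CLK/BMAL1 ChIP-peak/E-box analyses — all exercisable on
synthetic data with known ground truth, no downloads required.

## The statistic at the core

Two replicate six-timepoint series (every 4 h) are concatenated into one
12-point, 48-h series *x*. Rhythmicity is scored by the 24-h spectral
fraction

> F24 = P₂ / Σₖ₌₁⁶ Pₖ,  Pₖ = |Xₖ|²,

the share of one-sided non-DC Fourier power in the 24-h harmonic (k = 2 of
the 48-h window): 1 for a pure daily cosine, 0 for no daily component.
Significance comes from shuffling the 12 values (p = (#{F24* ≥ F24} + 1)/(N + 1));
amplitude is the max/min ratio; phase is the peak time of the fitted 24-h
cosine, `(−arg X₂)·24/2π + t_start mod 24`. A gene is rhythmic (medium) when
p < 0.05, F24 > 0.45 and amplitude > 1.5; strong when F24 > 0.6 and
amplitude > 1.75. Crossing nascent and mRNA calls yields the categories
R-R, R-AR, AR-R, AR-AR.

The synthetic cohort couples each gene's mRNA to its transcription through
`dM/dt = s(t) − δM` (δ = ln2/half-life): at steady state the mRNA rhythm is
attenuated by 1/√(1 + (ω/δ)²) and delayed by arctan(ω/δ)/ω hours — short-lived
mRNAs inherit the rhythm, long-lived ones flatten it. See
[docs/methods.md](docs/methods.md) for the full model account.

## Worked example

`examples/four_way_classification.py` simulates 90 genes of five known
classes, detects rhythms in both assays and crosses the calls:

```text
category counts: {'RR': 29, 'RAR': 11, 'ARR': 13, 'ARAR': 37}
RR share of transcription-rhythmic genes: 72.5%
RR share of mRNA-rhythmic genes: 69.0%
mean mRNA-minus-transcription phase delay: 2.58 h (2-h half-life predicts 2.47 h)
```

Of the 40 genes with detected transcription rhythms, 72.5% keep a rhythmic
mRNA (the planted RR class; the RAR class's 10–24-h half-lives damp the mRNA
rhythm below the amplitude cut-off), while 13 genes are rhythmic at the mRNA
level only — bursty or variable transcription propagated through
degradation. The measured phase delay between mRNA and transcription matches
the production–degradation prediction for the planted half-lives.

The other examples each cover one capability:

- `examples/simulate_and_detect.py` — cohort simulation and F24 detection;
- `examples/quantify_from_reads.py` — rpbp from read intervals on a toy
  genome, read-category fractions, depth normalization;
- `examples/chip_ebox_analysis.py` — peak overlap, peak-to-gene assignment,
  positional E-box enrichment.

A YAML-configured orchestrator (`nascentcycle.pipeline.run_pipeline`) chains
simulate → quantify → rhythm → compare → chip and writes headered TSVs plus
a checksum manifest; identical config and seed reproduce byte-identical
outputs.

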