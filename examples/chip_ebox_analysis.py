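"""Peak overlap, gene assignment and E-box enrichment on a toy genome.

Plants E-boxes (CACGTG) at the centers of two of four peaks, then runs the
downstream ChIP analyses: 1-nt interval overlap between two peak subsets,
center-based peak-to-gene assignment, and positional E-box enrichment against
a dinucleotide-shuffled background.
"""

from nascentcycle import (
    GenomeFixtureConfig,
    assign_peak_to_gene,
    ebox_enrichment,
    peak_overlap,
    simulate_genome_fixture,
)

cfg = GenomeFixtureConfig(n_reads=100, n_peaks=4, n_peaks_with_ebox=2)
fixture = simulate_genome_fixture(cfg, seed=3)

# a second factor's peaks: two coincide (shifted 100 bp, still intersecting
# by >= 1 nt), two bind elsewhere
other = fixture.peaks.copy()
other.loc[:1, ["start", "end"]] += 100
other.loc[2:, ["start", "end"]] += 10_000
ovl = peak_overlap(fixture.peaks, other)
print(f"peak overlap: {ovl.n_shared} shared, {len(ovl.a_only)} A-only, "
      f"{len(ovl.b_only)} B-only")

assignments = assign_peak_to_gene(fixture.peaks, fixture.models)
print(assignments[["gene_id", "relation"]].to_string())

genome = fixture.genome[cfg.chrom]
windows = [
    genome[(p.start + p.end) // 2 - 500 : (p.start + p.end) // 2 + 501]
    for p in fixture.peaks.itertuples()
]
profile = ebox_enrichment(windows, n_shuffles=50, seed=3)
print("perfect E-boxes at offset 0:", int(profile.loc[0, "perfect_obs"]),
      "(planted in 2 of 4 peaks)")
print("perfect E-boxes elsewhere:", int(profile.drop(index=0)["perfect_obs"].sum()))
# Real CLK/BMAL1 peaks show exactly this shape: E-boxes pile up at the peak
# center and fall to the shuffled-background expectation within ~500 bp.
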