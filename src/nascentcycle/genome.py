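"""Toy genome fixtures: sequence, gene models, reads and peak sets with
fully known ground truth, for exercising the read-level and ChIP stages.

The layout is deliberately simple — equal-sized multi-exon genes separated by
intergenic spacers on one or more chromosomes, uniform random sequence, reads
placed wholly inside exons/introns/intergenic zones at configured fractions,
and CACGTG E-boxes planted at recorded positions inside peak intervals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .models import GeneModel, GeneModelSet

__all__ = ["GenomeFixtureConfig", "GenomeFixture", "simulate_genome_fixture"]

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class GenomeFixtureConfig:
    n_genes: int = 6
    n_exons: int = 3
    exon_bp: int = 200
    intron_bp: int = 800
    intergenic_bp: int = 2000
    chrom: str = "chrT"
    n_reads: int = 10_000
    read_bp: int = 50
    read_fractions: Tuple[float, float, float] = (0.13, 0.76, 0.11)  # exonic, intronic, intergenic
    strands: Optional[Sequence[str]] = None  # default alternating +/-
    #: allow a same-strand adjacent pair for readthrough tests
    same_strand_pair: bool = False
    #: peak centers as (gene index, offset from gene start); E-boxes planted
    #: at peak centers for the first `n_peaks_with_ebox` peaks
    n_peaks: int = 0
    peak_bp: int = 400
    n_peaks_with_ebox: int = 0

    def __post_init__(self):
        if self.n_genes < 1 or self.n_exons < 1:
            raise ValueError("need at least one gene with one exon")
        if abs(sum(self.read_fractions) - 1.0) > 1e-9:
            raise ValueError("read fractions must sum to 1")
        if self.read_bp >= min(self.exon_bp, self.intron_bp, self.intergenic_bp):
            raise ValueError("reads must fit inside the smallest feature")


@dataclass
class GenomeFixture:
    genome: Dict[str, str]
    models: GeneModelSet
    reads: pd.DataFrame  # chrom, start, end, read_id, strand, true_category
    peaks: pd.DataFrame  # chrom, start, end, source, has_ebox
    ebox_positions: List[Tuple[str, int]]  # (chrom, genomic start of CACGTG)
    config: GenomeFixtureConfig

    @property
    def chrom_sizes(self) -> Dict[str, int]:
        return {c: len(s) for c, s in self.genome.items()}


def _gene_layout(cfg: GenomeFixtureConfig) -> List[GeneModel]:
    gene_span = cfg.n_exons * cfg.exon_bp + (cfg.n_exons - 1) * cfg.intron_bp
    genes = []
    pos = cfg.intergenic_bp
    if cfg.strands is not None:
        strands = list(cfg.strands)
    else:
        strands = ["+" if i % 2 == 0 else "-" for i in range(cfg.n_genes)]
        if cfg.same_strand_pair and cfg.n_genes >= 2:
            strands[1] = strands[0]
    for i in range(cfg.n_genes):
        exons = [
            (pos + k * (cfg.exon_bp + cfg.intron_bp), pos + k * (cfg.exon_bp + cfg.intron_bp) + cfg.exon_bp)
            for k in range(cfg.n_exons)
        ]
        genes.append(GeneModel(f"gene{i:03d}", cfg.chrom, strands[i], exons))
        pos += gene_span + cfg.intergenic_bp
    return genes


def _scrub_motif(seq: np.ndarray, motif: str, rng: np.random.Generator) -> None:
    """Mutate accidental occurrences of a motif so only planted copies remain.

    CACGTG is palindromic, so a forward scan covers both strands. Mutating
    the middle base can create a new occurrence one step away, hence the
    rescan loop.
    """
    m = np.array(list(motif))
    k = len(m)
    while True:
        view = np.lib.stride_tricks.sliding_window_view(seq, k)
        hits = np.nonzero((view == m).all(axis=1))[0]
        if hits.size == 0:
            return
        for i in hits:
            current = seq[i + k // 2]
            seq[i + k // 2] = rng.choice([b for b in "ACGT" if b != current])


def simulate_genome_fixture(cfg: GenomeFixtureConfig, seed: int) -> GenomeFixture:
    """Build the toy genome; deterministic given the seed."""
    rng = np.random.default_rng(seed)
    genes = _gene_layout(cfg)
    models = GeneModelSet(genes)
    chrom_len = genes[-1].end + cfg.intergenic_bp
    seq = rng.choice(_BASES, size=chrom_len)
    _scrub_motif(seq, "CACGTG", rng)  # only planted E-boxes exist

    # feature zones for read placement
    exon_zones = [(s, e) for g in genes for (s, e) in g.exons]
    intron_zones = [(s, e) for g in genes for (s, e) in g.introns]
    intergenic_zones = [(0, genes[0].start)]
    for g_prev, g_next in zip(genes[:-1], genes[1:]):
        intergenic_zones.append((g_prev.end, g_next.start))
    intergenic_zones.append((genes[-1].end, chrom_len))

    zones = {"exonic": exon_zones, "intronic": intron_zones, "intergenic": intergenic_zones}
    cats = rng.choice(
        ["exonic", "intronic", "intergenic"], size=cfg.n_reads, p=list(cfg.read_fractions)
    )
    rows = []
    for rid, cat in enumerate(cats):
        zs = zones[cat]
        zi = rng.integers(len(zs))
        zstart, zend = zs[zi]
        start = int(rng.integers(zstart, zend - cfg.read_bp + 1))
        rows.append(
            {
                "chrom": cfg.chrom,
                "start": start,
                "end": start + cfg.read_bp,
                "read_id": f"r{rid}",
                "strand": "+" if rng.random() < 0.5 else "-",
                "true_category": cat,
            }
        )
    reads = pd.DataFrame(rows)

    # peaks in intergenic zones, E-box planted dead-center of the first few
    peak_rows = []
    ebox_positions: List[Tuple[str, int]] = []
    usable = [z for z in intergenic_zones if z[1] - z[0] > cfg.peak_bp + 2]
    for pi in range(cfg.n_peaks):
        zstart, zend = usable[pi % len(usable)]
        start = int(rng.integers(zstart, zend - cfg.peak_bp))
        center = start + cfg.peak_bp // 2
        has_ebox = pi < cfg.n_peaks_with_ebox
        if has_ebox:
            seq[center : center + 6] = list("CACGTG")
            ebox_positions.append((cfg.chrom, center))
        peak_rows.append(
            {
                "chrom": cfg.chrom,
                "start": start,
                "end": start + cfg.peak_bp,
                "source": "planted",
                "has_ebox": has_ebox,
            }
        )
    peaks = pd.DataFrame(
        peak_rows, columns=["chrom", "start", "end", "source", "has_ebox"]
    )

    return GenomeFixture(
        genome={cfg.chrom: "".join(seq)},
        models=models,
        reads=reads,
        peaks=peaks,
        ebox_positions=ebox_positions,
        config=cfg,
    )
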