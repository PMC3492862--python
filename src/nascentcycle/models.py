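"""Gene models on a shared genome coordinate system.

All coordinates are 0-based half-open internally; format converters in
:mod:`nascentcycle.io` translate on read (GTF is 1-based inclusive, BED is
native). TSS/TES are strand-resolved: for a minus-strand gene the TSS is the
genomic end.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from intervaltree import IntervalTree


def merge_intervals(intervals: Iterable[Tuple[int, int]]) -> List[Tuple[int, int]]:
    """Union of half-open intervals, sorted and non-overlapping."""
    ivs = sorted((int(s), int(e)) for s, e in intervals)
    merged: List[Tuple[int, int]] = []
    for s, e in ivs:
        if e <= s:
            raise ValueError(f"empty or inverted interval [{s}, {e})")
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


@dataclass
class GeneModel:
    gene_id: str
    chrom: str
    strand: str
    exons: List[Tuple[int, int]]  # merged, sorted, 0-based half-open

    def __post_init__(self):
        if self.strand not in "+-":
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        self.exons = merge_intervals(self.exons)
        if self.exon_union_length <= 0:
            raise ValueError(f"gene {self.gene_id} has empty exon union")

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end

    @property
    def tes(self) -> int:
        return self.end if self.strand == "+" else self.start

    @property
    def exon_union_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    @property
    def introns(self) -> List[Tuple[int, int]]:
        return [
            (self.exons[i][1], self.exons[i + 1][0]) for i in range(len(self.exons) - 1)
        ]


class GeneModelSet:
    """A collection of gene models with fast interval lookup."""

    def __init__(self, genes: Sequence[GeneModel]):
        if not genes:
            raise ValueError("empty gene model set")
        self.genes: Dict[str, GeneModel] = {}
        for g in genes:
            if g.gene_id in self.genes:
                raise ValueError(f"duplicate gene_id {g.gene_id}")
            self.genes[g.gene_id] = g
        self._exon_trees: Dict[str, IntervalTree] = {}
        self._body_trees: Dict[str, IntervalTree] = {}
        for g in self.genes.values():
            et = self._exon_trees.setdefault(g.chrom, IntervalTree())
            for s, e in g.exons:
                et.addi(s, e, g.gene_id)
            self._body_trees.setdefault(g.chrom, IntervalTree()).addi(
                g.start, g.end, g.gene_id
            )

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self):
        return iter(self.genes.values())

    def __getitem__(self, gene_id: str) -> GeneModel:
        return self.genes[gene_id]

    @property
    def chromosomes(self) -> List[str]:
        return sorted(self._body_trees)

    def exon_overlaps(self, chrom: str, start: int, end: int) -> set:
        """gene_ids whose exon union overlaps [start, end) by >= 1 nt."""
        tree = self._exon_trees.get(chrom)
        if tree is None:
            return set()
        return {iv.data for iv in tree.overlap(start, end)}

    def body_overlaps(self, chrom: str, start: int, end: int) -> set:
        tree = self._body_trees.get(chrom)
        if tree is None:
            return set()
        return {iv.data for iv in tree.overlap(start, end)}

    def exon_union_lengths(self) -> pd.Series:
        return pd.Series(
            {gid: g.exon_union_length for gid, g in self.genes.items()}, name="exon_union_bp"
        )

    def upstream_neighbor(self, gene_id: str, same_strand: bool = True) -> Optional[GeneModel]:
        """Nearest non-overlapping gene ending 5' of ``gene_id``'s TSS.

        "Upstream" is strand-aware: for a plus-strand gene the neighbor with
        the largest end <= its start; for minus strand, the smallest start >=
        its end.
        """
        g = self.genes[gene_id]
        best = None
        for other in self.genes.values():
            if other.gene_id == gene_id or other.chrom != g.chrom:
                continue
            if same_strand and other.strand != g.strand:
                continue
            if g.strand == "+":
                if other.end <= g.start:
                    if best is None or other.end > best.end:
                        best = other
            else:
                if other.start >= g.end:
                    if best is None or other.start < best.start:
                        best = other
        return best

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            {
                "gene_id": g.gene_id,
                "chrom": g.chrom,
                "start": g.start,
                "end": g.end,
                "strand": g.strand,
                "tss": g.tss,
                "tes": g.tes,
                "n_exons": len(g.exons),
                "exon_union_bp": g.exon_union_length,
            }
            for g in self.genes.values()
        ]
        return pd.DataFrame(rows).set_index("gene_id")
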