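"""Gene-level rpbp quantification, depth normalization and QC tables.

The expression unit throughout is rpbp (reads per base pair): the number of
reads overlapping a gene's exon union by at least one nucleotide, divided by
the exon-union length, then scaled to a common depth of 40 million uniquely
mapped reads per library.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .design import NORMALIZATION_TARGET, SamplingDesign
from .models import GeneModelSet

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionMatrix",
    "LaneReproducibilityTable",
    "compute_rpbp",
    "normalization_factor",
    "mapping_percentage",
    "categorize_read_positions",
    "lane_reproducibility",
    "nascent_mrna_ratio",
    "library_stats_table",
]

#: fold-difference bin labels of the lane-reproducibility table; the ">x"
#: bins are nested (a gene with fold 1.6 is counted in every bin up to >1.5)
#: and the bottom bin is the closed complement of >1.1.
FOLD_BINS = (2.0, 1.5, 1.4, 1.3, 1.25, 1.1)


class ExpressionMatrix:
    """Gene x sample rpbp matrix with sample metadata.

    ``values`` is a DataFrame (genes as index, samples as columns);
    ``samples`` a metadata frame indexed by sample with columns assay,
    replicate and timepoint_h (plus norm_factor once normalized).
    """

    def __init__(self, values: pd.DataFrame, samples: pd.DataFrame, normalized: bool):
        if list(values.columns) != list(samples.index):
            raise ValueError("sample metadata does not match matrix columns")
        if (values.values < 0).any():
            raise ValueError("rpbp values must be non-negative")
        self.values = values
        self.samples = samples
        self.normalized = normalized

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def assay(self) -> str:
        return str(self.samples["assay"].iloc[0])

    def normalize(self, factors: pd.Series) -> "ExpressionMatrix":
        """Apply per-sample multiplicative depth-normalization factors."""
        if self.normalized:
            raise ValueError("matrix is already normalized")
        factors = factors.reindex(self.values.columns)
        if factors.isna().any():
            raise ValueError("missing normalization factor for some samples")
        samples = self.samples.copy()
        samples["norm_factor"] = factors
        return ExpressionMatrix(self.values * factors, samples, normalized=True)

    def gene_means(self) -> pd.Series:
        return self.values.mean(axis=1)

    def filter_expressed(self, min_rpbp: float) -> "ExpressionMatrix":
        """Keep genes whose maximum sample value exceeds ``min_rpbp``."""
        keep = self.values.max(axis=1) > min_rpbp
        return ExpressionMatrix(self.values.loc[keep], self.samples, self.normalized)

    def series(self, gene_id: str) -> np.ndarray:
        return self.values.loc[gene_id].to_numpy(dtype=float)


def _read_blocks(reads: pd.DataFrame) -> pd.DataFrame:
    """Normalize a read table to one row per block with a read_id column."""
    required = {"chrom", "start", "end"}
    if not required.issubset(reads.columns):
        raise ValueError(f"read table must have columns {sorted(required)}")
    df = reads.copy()
    if "read_id" not in df.columns:
        df["read_id"] = np.arange(len(df))
    return df


def compute_rpbp(
    reads: pd.DataFrame,
    models: GeneModelSet,
    stranded: bool = False,
) -> pd.Series:
    """Raw rpbp per gene for one library.

    A read maps to a gene when any of its blocks overlaps the gene's exon
    union by >= 1 nt; each read is counted at most once per gene. Reads on
    chromosomes absent from the models are ignored (logged). With
    ``stranded=True`` only reads on the gene's strand are counted.
    """
    if len(models) == 0:
        raise ValueError("empty gene model set")
    df = _read_blocks(reads)
    if stranded and "strand" not in df.columns:
        raise ValueError("stranded counting requires a strand column")

    counts: Dict[str, set] = {gid: set() for gid in models.genes}
    skipped = 0
    strands = df["strand"] if stranded else None
    for i, (chrom, start, end, rid) in enumerate(
        zip(df["chrom"], df["start"], df["end"], df["read_id"])
    ):
        if chrom not in models._exon_trees:
            skipped += 1
            continue
        hits = models.exon_overlaps(chrom, int(start), int(end))
        if stranded:
            hits = {g for g in hits if models[g].strand == strands.iloc[i]}
        for g in hits:
            counts[g].add(rid)
    if skipped:
        logger.warning("ignored %d read blocks on chromosomes absent from models", skipped)

    lengths = models.exon_union_lengths()
    n = pd.Series({g: len(r) for g, r in counts.items()}, dtype=float)
    return (n / lengths).rename("rpbp")


def normalization_factor(uniquely_mapped: int, target: int = NORMALIZATION_TARGET) -> float:
    """Multiplicative factor bringing a library to the common target depth."""
    if uniquely_mapped <= 0:
        raise ValueError("uniquely_mapped must be > 0")
    return target / uniquely_mapped


def mapping_percentage(total: int, uniquely_mapped: int) -> float:
    """Percentage of library reads that mapped uniquely."""
    if total <= 0:
        raise ValueError("total read count must be > 0")
    if uniquely_mapped > total or uniquely_mapped <= 0:
        raise ValueError("need 0 < uniquely_mapped <= total")
    return 100.0 * uniquely_mapped / total


def library_stats_table(specs: Iterable) -> pd.DataFrame:
    """Per-library statistics: totals, mapping percentage, normalization factor."""
    rows = []
    for s in specs:
        rows.append(
            {
                "library_id": s.library_id,
                "total_sequences": s.total_reads,
                "uniquely_mapped": s.uniquely_mapped,
                "percent_uniquely_mapped": round(
                    mapping_percentage(s.total_reads, s.uniquely_mapped), 1
                ),
                "normalization_factor": round(
                    normalization_factor(s.uniquely_mapped), 3
                ),
            }
        )
    return pd.DataFrame(rows).set_index("library_id")


def categorize_read_positions(reads: pd.DataFrame, models: GeneModelSet) -> pd.Series:
    """Fractions of reads that are exonic, intronic and intergenic.

    Each read is assigned exactly one category, with precedence
    exon > intron > intergenic when it overlaps several annotations; a read
    inside a gene body that touches no exon is intronic.
    """
    df = _read_blocks(reads)
    cat_by_read: Dict[object, str] = {}
    rank = {"exonic": 0, "intronic": 1, "intergenic": 2}
    for chrom, start, end, rid in zip(df["chrom"], df["start"], df["end"], df["read_id"]):
        start, end = int(start), int(end)
        if models.exon_overlaps(chrom, start, end):
            cat = "exonic"
        elif models.body_overlaps(chrom, start, end):
            cat = "intronic"
        else:
            cat = "intergenic"
        prev = cat_by_read.get(rid)
        if prev is None or rank[cat] < rank[prev]:
            cat_by_read[rid] = cat
    cats = pd.Series(cat_by_read)
    fractions = cats.value_counts(normalize=True)
    return fractions.reindex(["exonic", "intronic", "intergenic"], fill_value=0.0)


@dataclass
class LaneReproducibilityTable:
    """Fold-difference distribution between duplicate lanes.

    ``counts``/``percentages``: rows are the nested fold bins ('>2' ...
    '>1.1') plus the complementary '1.0-1.1' bin; columns one per rpbp
    threshold. ``zscores``: per-gene |a-b|/mean(a,b) for plotting.
    """

    counts: pd.DataFrame
    percentages: pd.DataFrame
    totals: pd.Series
    zscores: pd.Series

    @property
    def thresholds(self) -> List[float]:
        return [float(c.split(">")[1]) for c in self.counts.columns]


def lane_reproducibility(
    lane_a: pd.Series,
    lane_b: pd.Series,
    thresholds: Sequence[float] = (3.0, 2.6786, 2.0),
) -> LaneReproducibilityTable:
    """Tabulate per-gene fold differences between two duplicate lanes.

    Lanes must be depth-normalized and index the same genes. Per threshold
    column, only genes with mean rpbp strictly above the threshold are
    counted; fold difference is max/min (infinite when one lane is zero);
    genes at zero in both lanes are excluded entirely.
    """
    if not lane_a.index.equals(lane_b.index):
        raise ValueError("lanes must index the same genes")
    a = lane_a.to_numpy(dtype=float)
    b = lane_b.to_numpy(dtype=float)
    both_zero = (a == 0) & (b == 0)
    if both_zero.any():
        logger.warning("excluding %d genes with zero signal in both lanes", both_zero.sum())
    a, b = a[~both_zero], b[~both_zero]
    idx = lane_a.index[~both_zero]

    mean = (a + b) / 2.0
    lo = np.minimum(a, b)
    with np.errstate(divide="ignore"):
        fold = np.where(lo > 0, np.maximum(a, b) / np.where(lo > 0, lo, 1.0), np.inf)
    z = pd.Series(np.abs(a - b) / mean, index=idx, name="lane_zscore")

    bin_labels = [f">{t:g}" for t in FOLD_BINS] + ["1.0-1.1"]
    counts = {}
    totals = {}
    for thr in thresholds:
        col = f">{thr:g}"
        sel = mean > thr
        totals[col] = int(sel.sum())
        col_counts = [int((fold[sel] > t).sum()) for t in FOLD_BINS]
        col_counts.append(int((fold[sel] <= FOLD_BINS[-1]).sum()))
        counts[col] = col_counts
    counts_df = pd.DataFrame(counts, index=bin_labels)
    totals_s = pd.Series(totals, name="total_genes")
    pct = 100.0 * counts_df / totals_s
    return LaneReproducibilityTable(counts_df, pct, totals_s, z)


def nascent_mrna_ratio(
    nascent: ExpressionMatrix,
    mrna: ExpressionMatrix,
    n_sd: float = 2.0,
) -> pd.DataFrame:
    """Per-gene nascent/mRNA signal ratio with outlier flags.

    The ratio of mean nascent to mean mRNA rpbp over the 12 samples proxies
    mRNA turnover (high ratio = short-lived mRNA). Outlier sets are taken at
    mean +/- ``n_sd`` SD of the log2 ratio distribution, which is roughly
    symmetric where the raw ratios are heavily right-skewed. Genes with zero
    mean mRNA are excluded (logged).
    """
    if not (nascent.normalized and mrna.normalized):
        raise ValueError("both matrices must be depth-normalized")
    genes = nascent.genes.intersection(mrna.genes)
    if genes.empty:
        raise ValueError("no genes shared between the two matrices")
    num = nascent.values.loc[genes].mean(axis=1)
    den = mrna.values.loc[genes].mean(axis=1)
    usable = den > 0
    if (~usable).any():
        logger.warning("excluding %d genes with zero mean mRNA", int((~usable).sum()))
    ratio = (num[usable] / den[usable]).rename("ratio")
    log2r = np.log2(ratio)
    mu, sd = log2r.mean(), log2r.std(ddof=1)
    out = pd.DataFrame({"ratio": ratio, "log2_ratio": log2r})
    # deviations below ~1e-9 on the log2 scale are numerical noise, never outliers
    cut = max(n_sd * sd, 1e-9)
    out["high_outlier"] = log2r > mu + cut
    out["low_outlier"] = log2r < mu - cut
    return out
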