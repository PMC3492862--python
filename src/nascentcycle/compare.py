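"""Nascent-vs-mRNA rhythm comparison: four-way categories, phase and
amplitude concordance, transcriptional variability, bursts and readthrough.

Genes are classified by the rhythmicity of their transcription (nascent RNA)
and their mRNA into RR (both rhythmic), RAR (transcription only), ARR (mRNA
only) and ARAR (neither); "rhythmic" means a strong or medium call. The ARR
class is the interesting one: rhythmic mRNA without detectably rhythmic
transcription points at variable/bursty transcription or post-transcriptional
control, probed here through the coefficient of variation, quintile
stratification and single-timepoint burst detection.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Iterable, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps

from .design import PERIOD_H, SamplingDesign
from .models import GeneModelSet

logger = logging.getLogger(__name__)

__all__ = [
    "CategoryTable",
    "four_way_classify",
    "phase_difference",
    "circular_phase_correlation",
    "amplitude_correlation",
    "coefficient_of_variation",
    "variability_quintile_analysis",
    "detect_single_burst",
    "flag_readthrough",
    "phase_histogram",
]

RHYTHMIC_CALLS = ("strong", "medium")

CATEGORIES = ("RR", "RAR", "ARR", "ARAR")


def _is_rhythmic(calls: pd.Series) -> pd.Series:
    return calls.isin(RHYTHMIC_CALLS)


@dataclass
class CategoryTable:
    """Per-gene four-way assignment plus reconciled summary fractions."""

    table: pd.DataFrame  # index gene_id; columns category, nascent_*, mrna_*
    counts: Dict[str, int]
    percentages: Dict[str, float]
    rr_of_nascent_rhythmic_pct: float
    rr_of_mrna_rhythmic_pct: float

    @property
    def n_genes(self) -> int:
        return int(sum(self.counts.values()))

    def phase_differences(self) -> pd.Series:
        """Signed mRNA-minus-nascent phase difference (h) for RR genes."""
        rr = self.table[self.table["category"] == "RR"]
        return pd.Series(
            phase_difference(rr["mrna_phase_h"].to_numpy(), rr["nascent_phase_h"].to_numpy()),
            index=rr.index,
            name="phase_diff_h",
        ).dropna()

    def phase_concordance_fraction(self, threshold_h: float = 2.0) -> float:
        """Percentage of RR genes with |mRNA - nascent phase| below threshold."""
        d = self.phase_differences()
        if d.empty:
            raise ValueError("no RR genes with defined phases")
        return float(100.0 * (d.abs() < threshold_h).mean())


def four_way_classify(nascent_calls: pd.DataFrame, mrna_calls: pd.DataFrame) -> CategoryTable:
    """Combine per-assay rhythm tables into the four-way classification.

    Both inputs are rhythm-result tables (index gene_id, columns including
    call, phase_h, amplitude, f24, p_f24) already restricted to genes
    sufficiently expressed in their assay; classification runs on the gene
    intersection. Summary percentages are rounded to one decimal.
    """
    genes = nascent_calls.index.intersection(mrna_calls.index)
    if genes.empty:
        raise ValueError("nascent and mRNA tables share no genes")
    n = nascent_calls.loc[genes]
    m = mrna_calls.loc[genes]
    nr = _is_rhythmic(n["call"])
    mr = _is_rhythmic(m["call"])
    category = pd.Series(
        np.select(
            [nr & mr, nr & ~mr, ~nr & mr],
            ["RR", "RAR", "ARR"],
            default="ARAR",
        ),
        index=genes,
        name="category",
    )
    table = pd.DataFrame({"category": category})
    for col in ("call", "phase_h", "amplitude", "f24", "p_f24"):
        if col in n.columns:
            table[f"nascent_{col}"] = n[col]
        if col in m.columns:
            table[f"mrna_{col}"] = m[col]

    counts = {c: int((category == c).sum()) for c in CATEGORIES}
    total = len(genes)
    percentages = {c: round(100.0 * counts[c] / total, 1) for c in CATEGORIES}
    nascent_rhythmic = counts["RR"] + counts["RAR"]
    mrna_rhythmic = counts["RR"] + counts["ARR"]
    return CategoryTable(
        table=table,
        counts=counts,
        percentages=percentages,
        rr_of_nascent_rhythmic_pct=(
            round(100.0 * counts["RR"] / nascent_rhythmic, 1) if nascent_rhythmic else float("nan")
        ),
        rr_of_mrna_rhythmic_pct=(
            round(100.0 * counts["RR"] / mrna_rhythmic, 1) if mrna_rhythmic else float("nan")
        ),
    )


def phase_difference(phase_mrna_h, phase_nascent_h):
    """Signed circular difference mRNA - nascent, in hours within (-12, 12].

    Positive values mean the mRNA rhythm peaks later than transcription.
    Accepts scalars or arrays; NaN phases propagate.
    """
    d = (np.asarray(phase_mrna_h, float) - np.asarray(phase_nascent_h, float)) % PERIOD_H
    d = np.where(d > PERIOD_H / 2, d - PERIOD_H, d)
    if np.ndim(d) == 0:
        return float(d)
    return d


def circular_phase_correlation(phases_a_h, phases_b_h) -> float:
    """Fisher-Lee circular correlation of two paired phase vectors (hours).

    r = sum_{i<j} sin(ai-aj) sin(bi-bj) /
        sqrt(sum_{i<j} sin^2(ai-aj) * sum_{i<j} sin^2(bi-bj))

    Invariant under rotation of either vector (a constant phase lag gives
    r = 1). Raises on fewer than 3 pairs or zero circular variance.
    """
    a = np.asarray(phases_a_h, float) * 2 * np.pi / PERIOD_H
    b = np.asarray(phases_b_h, float) * 2 * np.pi / PERIOD_H
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("phase vectors must be paired 1-D arrays")
    ok = np.isfinite(a) & np.isfinite(b)
    a, b = a[ok], b[ok]
    if a.size < 3:
        raise ValueError("need at least 3 defined phase pairs")
    sa = np.sin(a[:, None] - a[None, :])
    sb = np.sin(b[:, None] - b[None, :])
    denom = np.sqrt(np.sum(sa**2) * np.sum(sb**2))
    if denom == 0:
        raise ValueError("zero circular variance in at least one phase vector")
    return float(np.sum(sa * sb) / denom)


def amplitude_correlation(amps_a, amps_b, log_scale: bool = True) -> float:
    """Pearson correlation of paired peak-to-trough amplitudes.

    Amplitudes are ratios (multiplicative), so the default correlates log2
    amplitudes; ``log_scale=False`` gives plain Pearson on raw values for
    cross-checking.
    """
    a = np.asarray(amps_a, float)
    b = np.asarray(amps_b, float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 3:
        raise ValueError("need paired 1-D amplitude vectors of length >= 3")
    if np.any(a < 1) or np.any(b < 1):
        raise ValueError("amplitudes are max/min ratios and must be >= 1")
    if log_scale:
        a, b = np.log2(a), np.log2(b)
    if np.std(a) == 0 or np.std(b) == 0:
        raise ValueError("zero variance in at least one amplitude vector")
    return float(sps.pearsonr(a, b).statistic)


def coefficient_of_variation(series) -> float:
    """Sample SD (n-1 denominator) divided by the mean of the 12 values."""
    x = np.asarray(series, float)
    if x.size != 12:
        raise ValueError("expected the 12-sample series")
    mean = x.mean()
    if mean <= 0:
        raise ValueError("mean must be positive for a coefficient of variation")
    return float(x.std(ddof=1) / mean)


def variability_quintile_analysis(
    cv: pd.Series,
    mrna_rhythmic: pd.Series,
    nascent_amplitude: Optional[pd.Series] = None,
    mrna_amplitude: Optional[pd.Series] = None,
    expression: Optional[pd.Series] = None,
    n_bins: int = 5,
) -> pd.DataFrame:
    """Stratify a gene set into variability quintiles and summarize each.

    Genes are ranked by transcriptional CV descending (ties broken by
    gene_id ascending for reproducibility); q1 is the most variable 20%.
    Per quintile the fraction of mRNA-rhythmic genes and, when supplied,
    mean log2 amplitudes and mean expression (the expression column serves
    as the control stratification: rhythmic mRNA should track variability,
    not expression level).
    """
    if len(cv) < n_bins:
        raise ValueError(f"need at least {n_bins} genes")
    # stable sort: cv descending, ties broken by gene_id ascending
    order = cv.sort_index(kind="mergesort").sort_values(ascending=False, kind="mergesort").index
    # equal-size bins (+-1 gene)
    bins = np.array_split(np.arange(len(order)), n_bins)
    rows = []
    for q, idx in enumerate(bins, start=1):
        genes = order[idx]
        row = {
            "quintile": f"q{q}",
            "n": len(genes),
            "mean_cv": float(cv.loc[genes].mean()),
            "frac_mrna_rhythmic": float(mrna_rhythmic.loc[genes].astype(bool).mean()),
        }
        if nascent_amplitude is not None:
            row["mean_log2_nascent_amp"] = float(np.log2(nascent_amplitude.loc[genes]).mean())
        if mrna_amplitude is not None:
            row["mean_log2_mrna_amp"] = float(np.log2(mrna_amplitude.loc[genes]).mean())
        if expression is not None:
            row["mean_expression"] = float(expression.loc[genes].mean())
        rows.append(row)
    return pd.DataFrame(rows).set_index("quintile")


def detect_single_burst(rep1, rep2, theta: float = 3.0) -> bool:
    """True when both replicates spike at the same clock time.

    In each 6-point replicate the maximum must exceed ``theta`` times the
    mean of the other five timepoints, and the argmax timepoint must match
    across replicates — bursts in the data were reproducible across animals.
    """
    r1 = np.asarray(rep1, float)
    r2 = np.asarray(rep2, float)
    if r1.size != r2.size or r1.size < 3:
        raise ValueError("expected two replicate series of equal length >= 3")

    def spike(r):
        i = int(np.argmax(r))
        rest = np.delete(r, i)
        rest_mean = rest.mean()
        if rest_mean <= 0:
            return i, r[i] > 0
        return i, bool(r[i] > theta * rest_mean)

    i1, ok1 = spike(r1)
    i2, ok2 = spike(r2)
    return bool(ok1 and ok2 and i1 == i2)


def flag_readthrough(
    rhythm_table: pd.DataFrame,
    models: GeneModelSet,
    flank_signal: pd.DataFrame,
    design: SamplingDesign,
    max_gap_bp: int = 10_000,
    phase_tol_h: float = 2.0,
    background_quantile: float = 0.75,
) -> pd.Series:
    """Heuristically flag rhythms attributable to an upstream neighbor.

    Transcription that runs past a gene's 3' end can confer an apparent
    rhythm on the downstream gene. Gene g is flagged when (i) a same-strand
    upstream neighbor within ``max_gap_bp`` is rhythmic, (ii) the phases
    agree within ``phase_tol_h`` hours, and (iii) signal in the intergenic
    gap at the neighbor's peak time exceeds the ``background_quantile`` of
    all gap signals. ``flank_signal`` has one row per gene (signal in the
    gap upstream of its TSS) and one column per sample of ``design``; genes
    without a gap signal row are skipped (logged).
    """
    t = design.clock_times()
    flags = pd.Series(False, index=rhythm_table.index, name="readthrough")
    background = float(np.quantile(flank_signal.to_numpy(dtype=float), background_quantile))
    skipped = 0
    for gene_id in rhythm_table.index:
        row = rhythm_table.loc[gene_id]
        if row["call"] not in RHYTHMIC_CALLS or gene_id not in models.genes:
            continue
        neighbor = models.upstream_neighbor(gene_id, same_strand=True)
        if neighbor is None or neighbor.gene_id not in rhythm_table.index:
            continue
        g = models[gene_id]
        gap = g.start - neighbor.end if g.strand == "+" else neighbor.start - g.end
        if gap < 0 or gap > max_gap_bp:
            continue
        nrow = rhythm_table.loc[neighbor.gene_id]
        if nrow["call"] not in RHYTHMIC_CALLS:
            continue
        dphi = phase_difference(row["phase_h"], nrow["phase_h"])
        if not np.isfinite(dphi) or abs(dphi) > phase_tol_h:
            continue
        if gene_id not in flank_signal.index:
            skipped += 1
            continue
        sig = flank_signal.loc[gene_id].to_numpy(dtype=float)
        at_peak = np.abs(phase_difference(t, nrow["phase_h"])) <= design.interval_h / 2
        if not at_peak.any():
            at_peak = np.abs(phase_difference(t, nrow["phase_h"])) <= design.interval_h
        if sig[at_peak].mean() > background:
            flags.loc[gene_id] = True
    if skipped:
        logger.warning("skipped %d genes without gap-region signal", skipped)
    return flags


def phase_histogram(phases, bin_h: float = 2.0, double_plot: bool = False) -> pd.Series:
    """Counts of peak phases in half-open clock-time bins [0,2), [2,4), ...

    ``double_plot=True`` repeats the 24-h histogram over 48 h, the standard
    circadian double-plot presentation.
    """
    p = np.asarray(phases, float)
    p = p[np.isfinite(p)] % PERIOD_H
    edges = np.arange(0.0, PERIOD_H + bin_h, bin_h)
    counts, _ = np.histogram(p, bins=edges)
    if double_plot:
        counts = np.concatenate([counts, counts])
        edges = np.concatenate([edges[:-1], edges + PERIOD_H])
    labels = [f"[{edges[i]:g},{edges[i + 1]:g})" for i in range(len(counts))]
    return pd.Series(counts, index=labels, name="n_genes")
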