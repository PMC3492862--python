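"""ChIP-Seq downstream analysis: peak overlap, gene assignment, binned
signal profiles and positional E-box enrichment.

Peaks are half-open genomic intervals; two peaks overlap when they intersect
by at least one nucleotide. The E-box is the palindromic CACGTG element bound
by the CLOCK:BMAL1 activator; "degenerate" means exactly one mismatch.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .models import GeneModelSet, merge_intervals

logger = logging.getLogger(__name__)

__all__ = [
    "peak_overlap",
    "overlap_significance",
    "assign_peak_to_gene",
    "binned_signal_profile",
    "ebox_enrichment",
    "dinucleotide_shuffle",
    "scan_ebox",
]

EBOX = "CACGTG"
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def _validate_peaks(peaks: pd.DataFrame) -> pd.DataFrame:
    required = {"chrom", "start", "end"}
    if not required.issubset(peaks.columns):
        raise ValueError(f"peak table needs columns {sorted(required)}")
    if (peaks["end"] <= peaks["start"]).any():
        raise ValueError("malformed peak interval (end <= start)")
    return peaks


def peak_center(peaks: pd.DataFrame) -> pd.Series:
    """Summit if present, else the interval midpoint."""
    if "summit" in peaks.columns and peaks["summit"].notna().all():
        return peaks["summit"].astype(int)
    return ((peaks["start"] + peaks["end"]) // 2).astype(int)


@dataclass
class OverlapResult:
    shared: pd.DataFrame  # union intervals of each overlapping component
    a_only: pd.DataFrame
    b_only: pd.DataFrame
    n_shared: int  # overlapping components (symmetric in A and B)
    n_a_shared: int  # peaks of A touching any B peak
    n_b_shared: int


def peak_overlap(set_a: pd.DataFrame, set_b: pd.DataFrame) -> OverlapResult:
    """Split two peak sets into shared and set-exclusive peaks.

    A pair overlaps iff the half-open intervals intersect by >= 1 nt.
    Overlapping peaks are merged into union intervals (connected components
    across both sets), which makes the shared count symmetric.
    """
    a = _validate_peaks(set_a).reset_index(drop=True)
    b = _validate_peaks(set_b).reset_index(drop=True)
    trees_b: Dict[str, IntervalTree] = {}
    for i, row in b.iterrows():
        trees_b.setdefault(row["chrom"], IntervalTree()).addi(row["start"], row["end"], i)
    trees_a: Dict[str, IntervalTree] = {}
    for i, row in a.iterrows():
        trees_a.setdefault(row["chrom"], IntervalTree()).addi(row["start"], row["end"], i)

    a_hit = np.zeros(len(a), bool)
    b_hit = np.zeros(len(b), bool)
    for i, row in a.iterrows():
        tree = trees_b.get(row["chrom"])
        if tree and tree.overlap(row["start"], row["end"]):
            a_hit[i] = True
    for i, row in b.iterrows():
        tree = trees_a.get(row["chrom"])
        if tree and tree.overlap(row["start"], row["end"]):
            b_hit[i] = True

    shared_rows = []
    for chrom in sorted(set(a.loc[a_hit, "chrom"]) | set(b.loc[b_hit, "chrom"])):
        ivs = [
            (r["start"], r["end"])
            for _, r in a[a_hit & (a["chrom"] == chrom)].iterrows()
        ] + [
            (r["start"], r["end"])
            for _, r in b[b_hit & (b["chrom"] == chrom)].iterrows()
        ]
        for s, e in merge_intervals(ivs):
            shared_rows.append({"chrom": chrom, "start": s, "end": e})
    shared = pd.DataFrame(shared_rows, columns=["chrom", "start", "end"])
    return OverlapResult(
        shared=shared,
        a_only=a[~a_hit].reset_index(drop=True),
        b_only=b[~b_hit].reset_index(drop=True),
        n_shared=len(shared),
        n_a_shared=int(a_hit.sum()),
        n_b_shared=int(b_hit.sum()),
    )


def _count_a_in_b(starts, ends, chroms, b_by_chrom) -> int:
    n = 0
    for s, e, c in zip(starts, ends, chroms):
        merged = b_by_chrom.get(c)
        if merged is None:
            continue
        ms, me = merged
        # merged intervals are disjoint and sorted, so ends are increasing:
        # overlap iff some interval has start < e and end > s
        j = np.searchsorted(ms, e)
        if j > 0 and me[j - 1] > s:
            n += 1
    return n


def overlap_significance(
    set_a: pd.DataFrame,
    set_b: pd.DataFrame,
    chrom_sizes: Mapping[str, int],
    n_permutations: int = 999,
    seed: int = 0,
) -> Tuple[float, int]:
    """Permutation placement test for peak-set overlap.

    Peaks of set A are re-placed uniformly at random ``n_permutations``
    times, keeping their widths and their chromosome assignment, and the
    number of A peaks touching any B peak is recounted; the p-value is the
    +1/(N+1)-corrected fraction of placements reaching the observed count.
    Returns ``(p_value, observed_count)``.
    """
    a = _validate_peaks(set_a)
    b = _validate_peaks(set_b)
    for chrom, grp in a.groupby("chrom"):
        size = chrom_sizes.get(chrom)
        if size is None:
            raise ValueError(f"no size for chromosome {chrom}")
        if int((grp["end"] - grp["start"]).max()) > size:
            raise ValueError(f"peak wider than chromosome {chrom}")

    b_by_chrom: Dict[str, Tuple[np.ndarray, np.ndarray]] = {}
    for chrom, grp in b.groupby("chrom"):
        merged = merge_intervals(zip(grp["start"], grp["end"]))
        b_by_chrom[chrom] = (
            np.array([s for s, _ in merged]),
            np.array([e for _, e in merged]),
        )

    observed = _count_a_in_b(a["start"].to_numpy(), a["end"].to_numpy(), a["chrom"], b_by_chrom)
    widths = (a["end"] - a["start"]).to_numpy()
    chroms = a["chrom"].to_numpy()
    limits = np.array([chrom_sizes[c] for c in chroms])
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_permutations):
        starts = (rng.random(len(a)) * (limits - widths + 1)).astype(np.int64)
        if _count_a_in_b(starts, starts + widths, chroms, b_by_chrom) >= observed:
            exceed += 1
    return (exceed + 1) / (n_permutations + 1), observed


def assign_peak_to_gene(peaks: pd.DataFrame, models: GeneModelSet) -> pd.DataFrame:
    """Assign every peak to one gene by its center position.

    A peak whose center lies within a gene's genomic span [start, end) is
    genic and assigned to that gene (ties between overlapping genes go to the
    smallest TSS distance, then lexicographic gene_id). All other peaks are
    intergenic and go to the gene with the nearest TSS genome-wide.
    """
    if len(models) == 0:
        raise ValueError("empty gene model set")
    peaks = _validate_peaks(peaks)
    centers = peak_center(peaks)
    tss = pd.DataFrame(
        {
            "gene_id": list(models.genes),
            "chrom": [g.chrom for g in models],
            "tss": [g.tss for g in models],
        }
    )
    rows = []
    for (_, peak), center in zip(peaks.iterrows(), centers):
        chrom = peak["chrom"]
        genic = sorted(
            models.body_overlaps(chrom, center, center + 1),
            key=lambda gid: (abs(center - models[gid].tss), gid),
        )
        if genic:
            gid = genic[0]
            relation = "genic"
            if len(genic) > 1:
                logger.info("peak at %s:%d overlaps %d genes; tie to %s", chrom, center, len(genic), gid)
        else:
            cand = tss[tss["chrom"] == chrom] if (tss["chrom"] == chrom).any() else tss
            dist = (cand["tss"] - center).abs()
            best = cand.assign(dist=dist).sort_values(["dist", "gene_id"]).iloc[0]
            gid = best["gene_id"]
            relation = "intergenic-nearest-TSS"
        rows.append({"chrom": chrom, "center": int(center), "gene_id": gid, "relation": relation})
    return pd.DataFrame(rows, index=peaks.index)


def binned_signal_profile(
    track: Mapping[str, np.ndarray],
    centers: pd.DataFrame,
    half_window: int = 1000,
    bin_size: int = 25,
) -> pd.DataFrame:
    """Mean z-scored signal in fixed bins around peak centers.

    The per-base signal is z-scored over the entire track first
    (z = (x - mean)/SD of all bases), then windows of center +/- half_window
    are extracted (clipped at chromosome ends, logged), averaged within
    ``bin_size``-bp bins, and finally averaged across centers, per value of
    the optional ``group`` column. Returns a frame indexed by bin-start
    offset with one column per group.
    """
    if (2 * half_window) % bin_size:
        raise ValueError("window must be a whole number of bins")
    allbases = np.concatenate([np.asarray(v, float) for v in track.values()])
    mu, sd = allbases.mean(), allbases.std()
    if sd == 0:
        ztrack = {c: np.zeros_like(np.asarray(v, float)) for c, v in track.items()}
    else:
        ztrack = {c: (np.asarray(v, float) - mu) / sd for c, v in track.items()}

    n_bins = 2 * half_window // bin_size
    offsets = np.arange(-half_window, half_window, bin_size)
    groups = centers["group"] if "group" in centers.columns else pd.Series("all", index=centers.index)
    sums: Dict[str, np.ndarray] = {}
    counts: Dict[str, np.ndarray] = {}
    clipped = 0
    cvals = peak_center(centers) if "start" in centers.columns else centers["center"].astype(int)
    for (_, chrom), center, grp in zip(centers["chrom"].items(), cvals, groups):
        sig = ztrack[chrom]
        lo, hi = center - half_window, center + half_window
        window = np.full(2 * half_window, np.nan)
        s, e = max(lo, 0), min(hi, len(sig))
        if s > lo or e < hi:
            clipped += 1
        window[s - lo : e - lo] = sig[s:e]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN clipped bins
            binned = np.nanmean(window.reshape(n_bins, bin_size), axis=1)
        acc = sums.setdefault(grp, np.zeros(n_bins))
        cnt = counts.setdefault(grp, np.zeros(n_bins))
        ok = np.isfinite(binned)
        acc[ok] += binned[ok]
        cnt[ok] += 1
    if clipped:
        logger.warning("clipped %d windows at chromosome bounds", clipped)
    out = pd.DataFrame(index=pd.Index(offsets, name="offset_bp"))
    for grp in sums:
        with np.errstate(invalid="ignore"):
            out[grp] = sums[grp] / counts[grp]
    return out


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _seq_array(windows: Sequence[str]) -> np.ndarray:
    lengths = {len(w) for w in windows}
    if len(lengths) != 1:
        raise ValueError("windows must have uniform length")
    arr = np.frombuffer("".join(w.upper() for w in windows).encode(), dtype="S1")
    arr = arr.reshape(len(windows), lengths.pop())
    valid = np.isin(arr, np.array([b"A", b"C", b"G", b"T", b"N"]))
    if not valid.all():
        raise ValueError("windows contain non-ACGTN characters")
    return arr


def _mismatch_counts(arr: np.ndarray, motif: str) -> np.ndarray:
    """(n_windows, n_positions) Hamming distance to the motif at each start."""
    m = np.frombuffer(motif.encode(), dtype="S1")
    k = len(m)
    n, L = arr.shape
    windows = np.lib.stride_tricks.sliding_window_view(arr, k, axis=1)
    return (windows != m).sum(axis=2)


def scan_ebox(windows: Sequence[str]) -> Tuple[np.ndarray, np.ndarray]:
    """Per-position perfect and degenerate E-box counts over a window set.

    Perfect = CACGTG exactly; the motif is palindromic, so one strand scan
    finds every occurrence. Degenerate = Hamming distance exactly 1, scanned
    on both strands with a hit and its reverse complement at the same start
    deduplicated (for a palindromic motif the two strands agree position by
    position, so deduplication collapses them to a single count). Returns
    arrays of summed counts per motif-start position.
    """
    arr = _seq_array(windows)
    mm_fwd = _mismatch_counts(arr, EBOX)
    rc_rows = [reverse_complement(w.upper()) for w in windows]
    mm_rev = _mismatch_counts(_seq_array(rc_rows), EBOX)[:, ::-1]
    perfect = ((mm_fwd == 0) | (mm_rev == 0)).sum(axis=0)
    degenerate = (((mm_fwd == 1) | (mm_rev == 1)) & (mm_fwd > 0) & (mm_rev > 0)).sum(axis=0)
    return perfect.astype(int), degenerate.astype(int)


def dinucleotide_shuffle(seq: str, rng: np.random.Generator) -> str:
    """Altschul-Erickson shuffle preserving exact dinucleotide counts.

    Builds the multigraph whose edges are the sequence's dinucleotides,
    draws a random last edge toward the terminal vertex for every other
    vertex (accepted only if those last edges form a tree into the terminal
    vertex, which guarantees an Eulerian walk), shuffles the remaining edge
    lists, and reads off the walk.
    """
    s = seq.upper()
    if len(s) < 3:
        return s
    edges: Dict[str, List[str]] = {}
    for a, b in zip(s[:-1], s[1:]):
        edges.setdefault(a, []).append(b)
    last = s[-1]
    vertices = list(edges)

    def connected_to_last(last_edges: Dict[str, str]) -> bool:
        for v in vertices:
            u, steps = v, 0
            while u != last and steps <= len(vertices):
                u = last_edges.get(u)
                if u is None:
                    return False
                steps += 1
            if u != last:
                return False
        return True

    while True:
        last_edges = {
            v: edges[v][rng.integers(len(edges[v]))] for v in vertices if v != last
        }
        if connected_to_last(last_edges):
            break
    out_lists: Dict[str, List[str]] = {}
    for v in vertices:
        pool = list(edges[v])
        if v != last:
            pool.remove(last_edges[v])
        rng.shuffle(pool)
        if v != last:
            pool.append(last_edges[v])
        out_lists[v] = pool
    walk = [s[0]]
    pos = {v: 0 for v in vertices}
    u = s[0]
    for _ in range(len(s) - 1):
        nxt = out_lists[u][pos[u]]
        pos[u] += 1
        walk.append(nxt)
        u = nxt
    return "".join(walk)


def ebox_enrichment(
    windows: Sequence[str],
    n_shuffles: int = 100,
    seed: int = 0,
    window_radius: int = 500,
) -> pd.DataFrame:
    """Positional E-box enrichment in peak-centered sequence windows.

    ``windows`` are uniform-length (2*radius + 1 nt) reference-strand
    sequences centered on peak centers. Observed counts are tallied per
    motif-start offset from the center; the expected count per offset is the
    mean over ``n_shuffles`` dinucleotide-shuffled versions of each window,
    which preserves local composition while destroying motifs. Enrichment is
    observed/expected where expected > 0 (NaN elsewhere). Windows containing
    N are skipped (logged).
    """
    expected_len = 2 * window_radius + 1
    kept = []
    for w in windows:
        if len(w) != expected_len:
            raise ValueError(f"windows must be {expected_len} nt")
        if "N" in w.upper():
            continue
        kept.append(w)
    if len(kept) < len(windows):
        logger.warning("skipped %d windows containing N", len(windows) - len(kept))
    if not kept:
        raise ValueError("no usable windows")

    perfect_obs, degen_obs = scan_ebox(kept)
    rng = np.random.default_rng(seed)
    exp_perfect = np.zeros(len(perfect_obs))
    exp_degen = np.zeros(len(degen_obs))
    for _ in range(n_shuffles):
        shuffled = [dinucleotide_shuffle(w, rng) for w in kept]
        p, d = scan_ebox(shuffled)
        exp_perfect += p
        exp_degen += d
    exp_perfect /= n_shuffles
    exp_degen /= n_shuffles

    n_pos = expected_len - len(EBOX) + 1
    offsets = np.arange(n_pos) - window_radius  # motif start relative to center
    with np.errstate(divide="ignore", invalid="ignore"):
        enr_p = np.where(exp_perfect > 0, perfect_obs / exp_perfect, np.nan)
        enr_d = np.where(exp_degen > 0, degen_obs / exp_degen, np.nan)
    return pd.DataFrame(
        {
            "perfect_obs": perfect_obs,
            "degenerate_obs": degen_obs,
            "perfect_expected": exp_perfect,
            "degenerate_expected": exp_degen,
            "perfect_enrichment": enr_p,
            "degenerate_enrichment": enr_d,
        },
        index=pd.Index(offsets, name="offset_bp"),
    )
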