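"""Shared format readers/writers and the TSV lingua franca between stages.

Gene models are accepted as GTF (1-based inclusive, converted on read) or
BED12 (native 0-based half-open). Stage outputs are TSV with '#'-prefixed
header comment lines carrying the package version and the run seed, so every
table is diffable and self-describing.
"""

from __future__ import annotations

import hashlib
import io as _stdio
import json
import logging
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Tuple

import gffutils
import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .models import GeneModel, GeneModelSet

logger = logging.getLogger(__name__)

__all__ = [
    "read_gene_models",
    "read_bed_reads",
    "read_peaks",
    "write_fasta",
    "read_fasta",
    "write_bed12",
    "write_bed6",
    "write_tsv",
    "read_tsv",
    "config_hash",
]

BED6_COLUMNS = ["chrom", "start", "end", "read_id", "score", "strand"]


def read_gene_models(path, fmt: Optional[str] = None) -> GeneModelSet:
    """Parse gene models from GTF or BED12 into the internal convention.

    Format is inferred from the extension when not given. GTF exon records
    are grouped by their gene_id attribute and converted from 1-based
    inclusive to 0-based half-open; overlapping exons are unioned.
    """
    path = Path(path)
    if fmt is None:
        fmt = {"gtf": "GTF", "gff": "GTF", "gff3": "GTF", "bed": "BED12"}.get(
            path.suffix.lstrip(".").lower()
        )
    if fmt == "GTF":
        return _read_gtf(path)
    if fmt == "BED12":
        return _read_bed12(path)
    raise ValueError(f"unknown gene model format {fmt!r} for {path}")


def _read_gtf(path: Path) -> GeneModelSet:
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    exons: Dict[str, dict] = {}
    for feat in db.features_of_type("exon"):
        gid = feat.attributes.get("gene_id", [feat.id])[0]
        if feat.end < feat.start:
            raise ValueError(f"coordinate inversion at line for exon of {gid}")
        rec = exons.setdefault(gid, {"chrom": feat.seqid, "strand": feat.strand, "exons": []})
        rec["exons"].append((feat.start - 1, feat.end))  # GTF 1-based inclusive
    if not exons:
        raise ValueError(f"no exon records in {path}")
    return GeneModelSet(
        [GeneModel(gid, r["chrom"], r["strand"], r["exons"]) for gid, r in exons.items()]
    )


def _read_bed12(path: Path) -> GeneModelSet:
    genes = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 12:
                raise ValueError(f"{path}:{ln}: BED12 needs 12 columns")
            chrom, start, _end, name, _score, strand = parts[:6]
            start = int(start)
            sizes = [int(x) for x in parts[10].rstrip(",").split(",")]
            starts = [int(x) for x in parts[11].rstrip(",").split(",")]
            if len(sizes) != len(starts):
                raise ValueError(f"{path}:{ln}: block size/start count mismatch")
            exons = [(start + o, start + o + s) for o, s in zip(starts, sizes)]
            genes.append(GeneModel(name, chrom, strand, exons))
    if not genes:
        raise ValueError(f"no records in {path}")
    return GeneModelSet(genes)


def read_bed_reads(path) -> pd.DataFrame:
    """Read intervals from BED6 (one row per read) or BED12 (blocked reads).

    Blocked reads are expanded to one row per block sharing a read_id, which
    is how the quantifier counts spliced reads by their blocks.
    """
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            parts = line.rstrip("\n").split("\t")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            if end <= start:
                raise ValueError(f"{path}:{ln}: inverted interval")
            name = parts[3] if len(parts) > 3 else f"r{ln}"
            strand = parts[5] if len(parts) > 5 else "+"
            if len(parts) >= 12:
                sizes = [int(x) for x in parts[10].rstrip(",").split(",")]
                starts = [int(x) for x in parts[11].rstrip(",").split(",")]
                for o, s in zip(starts, sizes):
                    rows.append((chrom, start + o, start + o + s, name, strand))
            else:
                rows.append((chrom, start, end, name, strand))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "read_id", "strand"])


def read_peaks(path) -> pd.DataFrame:
    """Read a peak BED / MACS-style table (chrom, start, end[, summit offset])."""
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            parts = line.rstrip("\n").split("\t")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            summit = int(parts[3]) + start if len(parts) > 3 and parts[3].isdigit() else np.nan
            rows.append((chrom, start, end, summit))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "summit"])
    if df["summit"].isna().any():
        df = df.drop(columns=["summit"])
    return df


def write_fasta(genome: Dict[str, str], path) -> None:
    records = [SeqRecord(Seq(seq), id=chrom, description="") for chrom, seq in genome.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> Dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_bed12(models: GeneModelSet, path) -> None:
    with open(path, "w") as fh:
        for g in models:
            sizes = ",".join(str(e - s) for s, e in g.exons)
            starts = ",".join(str(s - g.start) for s, e in g.exons)
            fh.write(
                "\t".join(
                    map(
                        str,
                        [
                            g.chrom,
                            g.start,
                            g.end,
                            g.gene_id,
                            0,
                            g.strand,
                            g.start,
                            g.end,
                            "0,0,0",
                            len(g.exons),
                            sizes,
                            starts,
                        ],
                    )
                )
                + "\n"
            )


def write_bed6(reads: pd.DataFrame, path) -> None:
    df = reads.copy()
    if "score" not in df.columns:
        df["score"] = 0
    df[BED6_COLUMNS].to_csv(path, sep="\t", header=False, index=False)


def _header_lines(seed: Optional[int], cfg_hash: Optional[str]) -> List[str]:
    from . import __version__

    lines = [f"# nascentcycle v{__version__}"]
    if seed is not None:
        lines.append(f"# seed: {seed}")
    if cfg_hash is not None:
        lines.append(f"# config: {cfg_hash}")
    return lines


def write_tsv(df: pd.DataFrame, path, seed: Optional[int] = None, cfg_hash: Optional[str] = None) -> None:
    """Write a stage table as TSV with '#' header comment lines."""
    with open(path, "w") as fh:
        for line in _header_lines(seed, cfg_hash):
            fh.write(line + "\n")
        df.to_csv(fh, sep="\t", float_format="%.10g")


def read_tsv(path, index_col=0) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", index_col=index_col)


def config_hash(config) -> str:
    """Stable short hash of a configuration mapping."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]
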