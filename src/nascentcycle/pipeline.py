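"""End-to-end pipeline: simulate -> quantify -> rhythm -> compare -> chip.

The pipeline runs entirely on synthetic inputs declared in a YAML/dict
config, persists every stage table as headered TSV, and writes a run
manifest with the config hash and a checksum per output, so a rerun with the
same config and seed is byte-identical (timestamps live only in the
manifest).
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .chip import assign_peak_to_gene, ebox_enrichment, peak_overlap
from .compare import (
    coefficient_of_variation,
    four_way_classify,
    phase_histogram,
    variability_quintile_analysis,
)
from .design import RhythmParams, SamplingDesign
from .genome import GenomeFixtureConfig, simulate_genome_fixture
from .io import config_hash, write_bed6, write_bed12, write_fasta, write_tsv
from .quantify import categorize_read_positions, compute_rpbp
from .rhythm import detect_rhythms
from .simulate import generate_truth_set, simulate_expression_matrix, truth_table

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "DEFAULT_CONFIG"]

DEFAULT_CONFIG: Dict = {
    "n_per_class": {"RR": 30, "RAR": 20, "ARR_burst": 15, "ARR_smooth": 15, "ARAR": 40},
    "rhythm": {"n_permutations": 1000},
    "thresholds": {"nascent_min_rpbp": 6.0, "mrna_min_rpbp": 8.0},
    "genome": {"n_genes": 6, "n_reads": 20000, "n_peaks": 4, "n_peaks_with_ebox": 2},
    "ebox_shuffles": 20,
    "seed": 0,
}


@dataclass
class PipelineConfig:
    n_per_class: Dict[str, int]
    outdir: Path
    seed: int = 0
    rhythm: RhythmParams = field(default_factory=RhythmParams)
    nascent_min_rpbp: float = 6.0
    mrna_min_rpbp: float = 8.0
    genome: GenomeFixtureConfig = field(default_factory=GenomeFixtureConfig)
    ebox_shuffles: int = 20

    @classmethod
    def from_dict(cls, raw: Dict, outdir) -> "PipelineConfig":
        merged = {**DEFAULT_CONFIG, **raw}
        seed = int(merged["seed"])
        rhythm = RhythmParams(seed=seed, **merged.get("rhythm", {}))
        thresholds = merged.get("thresholds", {})
        return cls(
            n_per_class=dict(merged["n_per_class"]),
            outdir=Path(outdir),
            seed=seed,
            rhythm=rhythm,
            nascent_min_rpbp=float(thresholds.get("nascent_min_rpbp", 6.0)),
            mrna_min_rpbp=float(thresholds.get("mrna_min_rpbp", 8.0)),
            genome=GenomeFixtureConfig(**merged.get("genome", {})),
            ebox_shuffles=int(merged.get("ebox_shuffles", 20)),
        )

    @classmethod
    def from_yaml(cls, path, outdir) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {}, outdir)

    def hash(self) -> str:
        payload = {
            "n_per_class": self.n_per_class,
            "seed": self.seed,
            "rhythm": asdict(self.rhythm),
            "nascent_min_rpbp": self.nascent_min_rpbp,
            "mrna_min_rpbp": self.mrna_min_rpbp,
            "genome": asdict(self.genome),
            "ebox_shuffles": self.ebox_shuffles,
        }
        return config_hash(payload)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> Dict:
    """Run every stage and return the manifest (also written to disk)."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_hash = config.hash()
    manifest: Dict = {
        "version": __version__,
        "config_hash": cfg_hash,
        "seed": config.seed,
        "stages": {},
        "outputs": {},
    }

    def save(df: pd.DataFrame, name: str) -> Path:
        path = out / name
        write_tsv(df, path, seed=config.seed, cfg_hash=cfg_hash)
        manifest["outputs"][name] = _sha256(path)
        return path

    def stage_done(name: str) -> None:
        manifest["stages"][name] = {"completed_at": time.time()}
        # manifest is rewritten atomically after each stage
        tmp = out / "manifest.json.tmp"
        tmp.write_text(json.dumps(manifest, indent=2))
        tmp.replace(out / "manifest.json")

    # ---- simulate ----------------------------------------------------
    truths = generate_truth_set(config.n_per_class, config.seed)
    nascent = simulate_expression_matrix(truths, SamplingDesign.nascent(), config.seed)
    mrna = simulate_expression_matrix(truths, SamplingDesign.mrna(), config.seed)
    save(truth_table(truths), "truth.tsv")
    save(nascent.values, "nascent_rpbp.tsv")
    save(mrna.values, "mrna_rpbp.tsv")

    fixture = simulate_genome_fixture(config.genome, config.seed)
    write_fasta(fixture.genome, out / "genome.fa")
    write_bed12(fixture.models, out / "genes.bed")
    write_bed6(fixture.reads, out / "reads.bed")
    for name in ("genome.fa", "genes.bed", "reads.bed"):
        manifest["outputs"][name] = _sha256(out / name)
    stage_done("simulate")

    # ---- quantify ----------------------------------------------------
    nascent_f = nascent.filter_expressed(config.nascent_min_rpbp)
    mrna_f = mrna.filter_expressed(config.mrna_min_rpbp)
    rpbp = compute_rpbp(fixture.reads, fixture.models)
    save(rpbp.to_frame(), "fixture_rpbp.tsv")
    fractions = categorize_read_positions(fixture.reads, fixture.models)
    save(fractions.rename("fraction").to_frame(), "read_categories.tsv")
    stage_done("quantify")

    # ---- rhythm ------------------------------------------------------
    nascent_rhythms, nascent_summary = detect_rhythms(
        nascent_f, config.rhythm, SamplingDesign.nascent()
    )
    mrna_rhythms, mrna_summary = detect_rhythms(mrna_f, config.rhythm, SamplingDesign.mrna())
    save(nascent_rhythms, "nascent_rhythms.tsv")
    save(mrna_rhythms, "mrna_rhythms.tsv")
    (out / "rhythm_summary.json").write_text(
        json.dumps({"nascent": nascent_summary, "mrna": mrna_summary}, indent=2)
    )
    manifest["outputs"]["rhythm_summary.json"] = _sha256(out / "rhythm_summary.json")
    stage_done("rhythm")

    # ---- compare -----------------------------------------------------
    categories = four_way_classify(nascent_rhythms, mrna_rhythms)
    save(categories.table, "categories.tsv")
    summary = {
        "counts": categories.counts,
        "percentages": categories.percentages,
        "rr_of_nascent_rhythmic_pct": categories.rr_of_nascent_rhythmic_pct,
        "rr_of_mrna_rhythmic_pct": categories.rr_of_mrna_rhythmic_pct,
    }
    (out / "category_summary.json").write_text(json.dumps(summary, indent=2))
    manifest["outputs"]["category_summary.json"] = _sha256(out / "category_summary.json")
    rhythmic_phases = nascent_rhythms.loc[
        nascent_rhythms["call"].isin(("strong", "medium")), "phase_h"
    ]
    save(phase_histogram(rhythmic_phases).to_frame(), "phase_histogram.tsv")

    shared = categories.table.index
    cv = pd.Series(
        {g: coefficient_of_variation(nascent_f.series(g)) for g in shared}, name="cv_nascent"
    )
    if len(shared) >= 5:
        quintiles = variability_quintile_analysis(
            cv,
            mrna_rhythms.loc[shared, "call"].isin(("strong", "medium")),
            nascent_amplitude=nascent_rhythms.loc[shared, "amplitude"],
            mrna_amplitude=mrna_rhythms.loc[shared, "amplitude"],
            expression=nascent_f.values.loc[shared].mean(axis=1),
        )
        save(quintiles, "variability_quintiles.tsv")
    stage_done("compare")

    # ---- chip --------------------------------------------------------
    if len(fixture.peaks):
        half = fixture.peaks.iloc[: max(1, len(fixture.peaks) // 2)]
        other = fixture.peaks.iloc[max(1, len(fixture.peaks) // 2) :]
        if len(other):
            ovl = peak_overlap(half, other)
            save(ovl.shared, "shared_peaks.tsv")
        assignments = assign_peak_to_gene(fixture.peaks, fixture.models)
        save(assignments, "peak_assignments.tsv")
        chrom = fixture.config.chrom
        seqs = []
        genome_seq = fixture.genome[chrom]
        for _, p in fixture.peaks.iterrows():
            c = (p["start"] + p["end"]) // 2
            if c - 500 >= 0 and c + 501 <= len(genome_seq):
                seqs.append(genome_seq[c - 500 : c + 501])
        if seqs:
            profile = ebox_enrichment(seqs, n_shuffles=config.ebox_shuffles, seed=config.seed)
            save(profile, "ebox_profile.tsv")
    stage_done("chip")
    return manifest
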