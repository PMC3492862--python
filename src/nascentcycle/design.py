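"""Experimental design and generative ground-truth descriptions.

The study design emulated throughout the package is two independent
six-timepoint circadian series per assay, sampled every 4 h over one day and
concatenated into a single 12-point, 48-h series: nascent RNA at
ZT0,4,8,12,16,20 and mRNA at ZT2,6,10,14,18,22, two replicates each.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np

#: depth all libraries are normalized to (uniquely mapped reads)
NORMALIZATION_TARGET = 40_000_000

PERIOD_H = 24.0
OMEGA = 2.0 * np.pi / PERIOD_H

GENE_CLASSES = ("RR", "RAR", "ARR_burst", "ARR_smooth", "ARAR")


@dataclass(frozen=True)
class SamplingDesign:
    """Timepoint layout of one assay's concatenated replicate series.

    Samples are ordered replicate 1 ZT-ascending, then replicate 2
    ZT-ascending; the concatenation is treated as one equally spaced series
    spanning ``replicates * 24`` hours.
    """

    assay: str
    timepoints_h: Tuple[float, ...] = (0, 4, 8, 12, 16, 20)
    replicates: int = 2

    def __post_init__(self):
        if self.assay not in ("nascent", "mrna"):
            raise ValueError(f"unknown assay {self.assay!r}")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        tp = np.asarray(self.timepoints_h, dtype=float)
        if len(tp) < 2:
            raise ValueError("need at least two timepoints")
        steps = np.diff(tp)
        if not np.allclose(steps, steps[0]):
            raise ValueError("timepoints must be equally spaced")

    @classmethod
    def nascent(cls, replicates: int = 2) -> "SamplingDesign":
        return cls("nascent", (0, 4, 8, 12, 16, 20), replicates)

    @classmethod
    def mrna(cls, replicates: int = 2) -> "SamplingDesign":
        return cls("mrna", (2, 6, 10, 14, 18, 22), replicates)

    @property
    def interval_h(self) -> float:
        return float(self.timepoints_h[1] - self.timepoints_h[0])

    @property
    def n_timepoints(self) -> int:
        return len(self.timepoints_h)

    @property
    def n_samples(self) -> int:
        return self.n_timepoints * self.replicates

    @property
    def t_start_h(self) -> float:
        return float(self.timepoints_h[0])

    @property
    def total_span_h(self) -> float:
        return self.replicates * self.n_timepoints * self.interval_h

    def clock_times(self) -> np.ndarray:
        """Clock time (ZT, h) of each sample in concatenated order."""
        return np.tile(np.asarray(self.timepoints_h, float), self.replicates)

    def sample_labels(self) -> list:
        return [
            f"{self.assay}_rep{r + 1}_ZT{int(t):02d}"
            for r in range(self.replicates)
            for t in self.timepoints_h
        ]

    def sample_metadata(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "sample": self.sample_labels(),
                "assay": self.assay,
                "replicate": np.repeat(np.arange(1, self.replicates + 1), self.n_timepoints),
                "timepoint_h": self.clock_times(),
            }
        ).set_index("sample")


@dataclass(frozen=True)
class SyntheticTruth:
    """Generative parameters for one synthetic gene.

    Classes: RR (rhythmic transcription, short-lived mRNA, so the rhythm
    propagates), RAR (rhythmic transcription, long-lived mRNA damps it),
    ARR_burst (arrhythmic baseline with a reproducible single-timepoint
    transcription burst), ARR_smooth (steady transcription), ARAR
    (arrhythmic, noisy transcription and mRNA).
    """

    gene_id: str
    klass: str
    baseline: float
    rel_amplitude: float = 0.0
    phase_h: float = 0.0
    half_life_h: float = 2.0
    noise_cv: float = 0.0
    burst_timepoint: Optional[int] = None  # index into design.timepoints_h
    burst_fold: Optional[float] = None

    def __post_init__(self):
        if self.klass not in GENE_CLASSES:
            raise ValueError(f"unknown gene class {self.klass!r}")
        if self.baseline < 0:
            raise ValueError("baseline must be non-negative")
        if not 0 <= self.rel_amplitude < 1:
            raise ValueError("rel_amplitude must be in [0, 1)")
        if self.klass in ("ARR_burst", "ARR_smooth", "ARAR") and self.rel_amplitude != 0:
            raise ValueError(f"{self.klass} genes must have rel_amplitude 0")
        if self.half_life_h <= 0:
            raise ValueError("half_life_h must be > 0")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        if self.klass == "ARR_burst":
            if self.burst_timepoint is None or self.burst_fold is None:
                raise ValueError("ARR_burst genes need burst_timepoint and burst_fold")
            if self.burst_fold <= 1:
                raise ValueError("burst_fold must be > 1")
        elif self.burst_timepoint is not None or self.burst_fold is not None:
            raise ValueError("burst fields are only valid for ARR_burst genes")

    @property
    def degradation_rate(self) -> float:
        """First-order mRNA decay rate delta = ln2 / half-life (1/h)."""
        return float(np.log(2.0) / self.half_life_h)


@dataclass(frozen=True)
class LibrarySpec:
    """Sequencing-depth metadata for one library (one lane / one sample)."""

    library_id: str
    assay: str
    replicate: int
    timepoint_h: float
    total_reads: int
    uniquely_mapped: int

    def __post_init__(self):
        if self.total_reads <= 0 or self.uniquely_mapped <= 0:
            raise ValueError("read counts must be positive")
        if self.uniquely_mapped > self.total_reads:
            raise ValueError("uniquely_mapped cannot exceed total_reads")

    @property
    def depth_scaling(self) -> float:
        """Library depth relative to the common normalization target."""
        return self.uniquely_mapped / NORMALIZATION_TARGET


@dataclass(frozen=True)
class RhythmParams:
    """Cut-offs of the rhythmicity classifier.

    A gene is called medium-rhythmic when the permutation p-value is below
    ``p_cutoff``, the 24-h spectral fraction exceeds ``f24_cutoff_medium``
    and the max/min amplitude exceeds ``amp_cutoff_medium``; strong when the
    stricter F24/amplitude pair is exceeded. All inequalities are strict.
    """

    n_permutations: int = 10_000
    p_cutoff: float = 0.05
    f24_cutoff_medium: float = 0.45
    amp_cutoff_medium: float = 1.5
    f24_cutoff_strong: float = 0.6
    amp_cutoff_strong: float = 1.75
    zero_floor: float = 0.1  # rpbp floor for the amplitude denominator
    amplitude_cap: float = 1e4
    seed: int = 0

    def __post_init__(self):
        if self.f24_cutoff_strong < self.f24_cutoff_medium:
            raise ValueError("strong F24 cutoff must be >= medium cutoff")
        if self.amp_cutoff_strong < self.amp_cutoff_medium:
            raise ValueError("strong amplitude cutoff must be >= medium cutoff")
        if not 0 < self.p_cutoff < 1:
            raise ValueError("p_cutoff must be in (0, 1)")
        if self.zero_floor <= 0:
            raise ValueError("zero_floor must be > 0")
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")


def child_seed(master_seed: int, index: int) -> np.random.Generator:
    """Generator for stream ``index`` derived from a master seed.

    Child streams depend only on (master_seed, index), never on the order
    in which they are drawn, so batched results are order-independent.
    """
    return np.random.default_rng(np.random.SeedSequence((int(master_seed), int(index))))
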