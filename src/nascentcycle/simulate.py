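"""Synthetic expression time courses with known ground truth.

Transcription is modelled as a 24-h cosine, ``s(t) = b(1 + a cos(w(t - phi)))``
with ``w = 2*pi/24``; mRNA follows first-order production-degradation,
``dM/dt = s(t) - delta*M`` with ``delta = ln2 / half-life``. At periodic steady
state the mRNA rhythm keeps the transcription period but is attenuated by
``1/sqrt(1 + (w/delta)^2)`` and delayed by ``arctan(w/delta)/w`` hours — short
half-lives track transcription, long half-lives flatten and delay it.
Biological noise is multiplicative log-normal (mean-preserving); sequencing
noise is Poisson counting applied separately so that replicates can share
biology but differ in counting noise.
"""

from __future__ import annotations

from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .design import (
    GENE_CLASSES,
    OMEGA,
    PERIOD_H,
    LibrarySpec,
    SamplingDesign,
    SyntheticTruth,
    child_seed,
)

__all__ = [
    "simulate_transcription",
    "simulate_mrna",
    "simulate_read_counts",
    "mrna_attenuation",
    "mrna_phase_delay_h",
    "generate_truth_set",
    "simulate_expression_matrix",
    "truth_table",
]


def _lognormal_noise(rng: np.random.Generator, cv: float, size: int) -> np.ndarray:
    """Mean-1 multiplicative log-normal factors with coefficient of variation cv."""
    if cv == 0:
        return np.ones(size)
    sigma2 = np.log1p(cv * cv)
    return rng.lognormal(mean=-sigma2 / 2.0, sigma=np.sqrt(sigma2), size=size)


def _apply_burst(values: np.ndarray, design: SamplingDesign, truth: SyntheticTruth) -> np.ndarray:
    out = values.copy()
    idx = truth.burst_timepoint
    if idx is None:
        return out
    if not 0 <= idx < design.n_timepoints:
        raise ValueError("burst_timepoint out of range for design")
    for rep in range(design.replicates):
        out[rep * design.n_timepoints + idx] *= truth.burst_fold
    return out


def transcription_expectation(truth: SyntheticTruth, design: SamplingDesign) -> np.ndarray:
    """Noiseless transcription (rpbp units) at the design's sample times."""
    t = design.clock_times()
    base = truth.baseline * (
        1.0 + truth.rel_amplitude * np.cos(OMEGA * (t - truth.phase_h))
    )
    if truth.klass == "ARR_burst":
        base = _apply_burst(base, design, truth)
    return base


def simulate_transcription(
    truth: SyntheticTruth, design: SamplingDesign, seed: int
) -> np.ndarray:
    """Nascent RNA series (rpbp per sample) for one gene.

    Deterministic given ``seed``; the burst of an ARR_burst gene hits the same
    clock time in every replicate, as bursts in the data were reproducible
    across animals.
    """
    if design.assay != "nascent":
        raise ValueError("simulate_transcription expects a nascent design")
    expectation = transcription_expectation(truth, design)
    rng = np.random.default_rng(seed)
    return expectation * _lognormal_noise(rng, truth.noise_cv, design.n_samples)


def mrna_attenuation(half_life_h: float) -> float:
    """Relative-amplitude attenuation factor a_mRNA / a_transcription."""
    delta = np.log(2.0) / half_life_h
    return 1.0 / np.sqrt(1.0 + (OMEGA / delta) ** 2)


def mrna_phase_delay_h(half_life_h: float) -> float:
    """Steady-state phase delay (h) of the mRNA rhythm behind transcription."""
    delta = np.log(2.0) / half_life_h
    return float(np.arctan(OMEGA / delta) / OMEGA)


def _burst_mrna_expectation(
    truth: SyntheticTruth, design: SamplingDesign, dt_h: float = 0.01
) -> np.ndarray:
    """Periodic steady-state mRNA for a bursting gene, scaled to rpbp units.

    Production is the baseline plus a ``burst_fold`` pulse lasting one
    sampling interval; the linear ODE is advanced with the exact
    piecewise-constant update M <- M e^{-d dt} + (s/d)(1 - e^{-d dt}) until
    the daily profile converges, then sampled and multiplied by delta so a
    steady gene maps back to its baseline.
    """
    delta = truth.degradation_rate
    nascent_tp = np.asarray(design.timepoints_h, float) - design.t_start_h  # ZT0 grid
    burst_start = nascent_tp[truth.burst_timepoint] if truth.burst_timepoint is not None else None

    grid = np.arange(0.0, PERIOD_H, dt_h)
    s = np.full(grid.shape, truth.baseline)
    if burst_start is not None:
        in_burst = (grid >= burst_start) & (grid < burst_start + design.interval_h)
        s[in_burst] *= truth.burst_fold

    decay = np.exp(-delta * dt_h)
    gain = (1.0 - decay) / delta
    m = truth.baseline / delta
    profile = np.empty_like(grid)
    n_cycles = max(5, int(np.ceil(10 * truth.half_life_h / PERIOD_H)) + 2)
    for _ in range(n_cycles):
        for i in range(len(grid)):
            m = m * decay + s[i] * gain
            profile[i] = m
    t = design.clock_times()
    sampled = np.interp(t % PERIOD_H, grid, profile, period=PERIOD_H)
    return delta * sampled


def mrna_expectation(truth: SyntheticTruth, design: SamplingDesign) -> np.ndarray:
    """Noiseless mRNA series at the design's sample times (rpbp units).

    Scaled by delta so mean mRNA equals mean transcription; the attenuation
    and delay of the 24-h component follow the closed-form steady state.
    """
    if truth.klass == "ARR_burst":
        return _burst_mrna_expectation(truth, design)
    t = design.clock_times()
    a_m = truth.rel_amplitude * mrna_attenuation(truth.half_life_h)
    peak = truth.phase_h + mrna_phase_delay_h(truth.half_life_h)
    return truth.baseline * (1.0 + a_m * np.cos(OMEGA * (t - peak)))


def simulate_mrna(truth: SyntheticTruth, design: SamplingDesign, seed: int) -> np.ndarray:
    """mRNA series (rpbp per sample) coupled to the gene's transcription."""
    if design.assay != "mrna":
        raise ValueError("simulate_mrna expects an mrna design")
    if truth.half_life_h <= 0:
        raise ValueError("half_life_h must be > 0")
    expectation = mrna_expectation(truth, design)
    rng = np.random.default_rng(seed)
    return expectation * _lognormal_noise(rng, truth.noise_cv, design.n_samples)


def simulate_read_counts(
    series: np.ndarray,
    exon_length: int,
    spec: LibrarySpec,
    seed: int,
) -> Tuple[np.ndarray, np.ndarray]:
    """Poisson read counts and raw (un-normalized) rpbp for one gene.

    The Poisson mean per sample is ``rpbp_expectation * exon_length *
    depth_scaling`` with depth scaling = uniquely mapped / 40e6, so applying
    the library normalization factor downstream recovers the expectation.
    Returns ``(counts, raw_rpbp)``.
    """
    if exon_length <= 0:
        raise ValueError("exon_length must be > 0")
    series = np.asarray(series, dtype=float)
    if np.any(series < 0):
        raise ValueError("rpbp expectations must be non-negative")
    rng = np.random.default_rng(seed)
    mean = series * exon_length * spec.depth_scaling
    counts = rng.poisson(mean)
    return counts, counts / float(exon_length)


# ---------------------------------------------------------------------------
# cohort generation

_DEFAULTS = {
    # (rel_amplitude range, half_life range (h), noise_cv, burst_fold range)
    "RR": ((0.4, 0.8), (0.5, 3.0), 0.15, None),
    "RAR": ((0.4, 0.8), (10.0, 24.0), 0.15, None),
    "ARR_burst": ((0.0, 0.0), (1.0, 4.0), 0.3, (4.0, 8.0)),
    "ARR_smooth": ((0.0, 0.0), (1.0, 4.0), 0.1, None),
    "ARAR": ((0.0, 0.0), (1.0, 8.0), 0.3, None),
}


def generate_truth_set(
    n_per_class: Dict[str, int],
    seed: int,
    baseline_range: Tuple[float, float] = (5.0, 50.0),
) -> List[SyntheticTruth]:
    """Draw a cohort of gene truths, one entry per gene.

    Class defaults: rhythmic genes (RR, RAR) get relative amplitudes of
    0.4-0.8 and uniform phases; RR genes short half-lives (0.5-3 h) so the
    rhythm survives into mRNA, RAR genes long half-lives (10-24 h) that damp
    it below the amplitude cut-off; burst genes a 4-8-fold single-timepoint
    burst on a noisy (CV 0.3) baseline.
    """
    rng = np.random.default_rng(np.random.SeedSequence((int(seed), 0xC0))).spawn(1)[0]
    truths: List[SyntheticTruth] = []
    i = 0
    for klass in GENE_CLASSES:
        n = int(n_per_class.get(klass, 0))
        amp_rng, hl_rng, cv, burst_rng = _DEFAULTS[klass]
        for _ in range(n):
            g = child_seed(seed, i)
            baseline = float(np.exp(g.uniform(np.log(baseline_range[0]), np.log(baseline_range[1]))))
            truths.append(
                SyntheticTruth(
                    gene_id=f"g{i:05d}",
                    klass=klass,
                    baseline=baseline,
                    rel_amplitude=float(g.uniform(*amp_rng)) if amp_rng[1] > 0 else 0.0,
                    phase_h=float(g.uniform(0, 24)),
                    half_life_h=float(g.uniform(*hl_rng)),
                    noise_cv=cv,
                    burst_timepoint=int(g.integers(0, 6)) if burst_rng else None,
                    burst_fold=float(g.uniform(*burst_rng)) if burst_rng else None,
                )
            )
            i += 1
    return truths


def truth_table(truths: Sequence[SyntheticTruth]) -> pd.DataFrame:
    """Tabular view of a truth cohort (one row per gene)."""
    return pd.DataFrame(
        {
            "gene_id": [t.gene_id for t in truths],
            "klass": [t.klass for t in truths],
            "baseline": [t.baseline for t in truths],
            "rel_amplitude": [t.rel_amplitude for t in truths],
            "phase_h": [t.phase_h for t in truths],
            "half_life_h": [t.half_life_h for t in truths],
            "noise_cv": [t.noise_cv for t in truths],
        }
    ).set_index("gene_id")


def simulate_expression_matrix(
    truths: Sequence[SyntheticTruth],
    design: SamplingDesign,
    seed: int,
):
    """Normalized expression matrix (genes x samples) for a whole cohort.

    Per-gene noise streams are derived from (seed, assay, gene index) so a
    gene's values do not depend on cohort composition; nascent and mRNA
    noise streams are independent.
    """
    from .quantify import ExpressionMatrix

    assay_offset = 0 if design.assay == "nascent" else 1
    rows = []
    for i, truth in enumerate(truths):
        sub = int(np.random.SeedSequence((int(seed), assay_offset, i)).generate_state(1)[0])
        if design.assay == "nascent":
            rows.append(simulate_transcription(truth, design, sub))
        else:
            rows.append(simulate_mrna(truth, design, sub))
    values = pd.DataFrame(
        np.asarray(rows), index=[t.gene_id for t in truths], columns=design.sample_labels()
    )
    return ExpressionMatrix(values, design.sample_metadata(), normalized=True)
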