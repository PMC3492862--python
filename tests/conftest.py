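import math

import numpy as np
import pandas as pd
import pytest

from nascentcycle.design import SamplingDesign, SyntheticTruth


@pytest.fixture
def nascent_design():
    return SamplingDesign.nascent()


@pytest.fixture
def mrna_design():
    return SamplingDesign.mrna()


def cosine_series(baseline, rel_amplitude, phase_h, times_h):
    """Independent spreadsheet-style evaluation of the transcription model."""
    return np.array(
        [
            baseline * (1 + rel_amplitude * math.cos(2 * math.pi * (t - phase_h) / 24))
            for t in times_h
        ]
    )


def dft_power_oracle(x, k):
    """Direct-summation DFT power |X_k|^2, independent of numpy's FFT."""
    n = len(x)
    re = sum(x[j] * math.cos(-2 * math.pi * k * j / n) for j in range(n))
    im = sum(x[j] * math.sin(-2 * math.pi * k * j / n) for j in range(n))
    return re * re + im * im


def f24_oracle(x):
    total = sum(dft_power_oracle(x, k) for k in range(1, len(x) // 2 + 1))
    if total == 0:
        return 0.0
    return dft_power_oracle(x, 2) / total


@pytest.fixture
def rhythm_table_factory():
    """Build a minimal rhythm-result table from per-gene tuples."""

    def make(entries):
        # entries: dict gene_id -> (call, phase_h, amplitude)
        return pd.DataFrame(
            {
                "call": {g: e[0] for g, e in entries.items()},
                "phase_h": {g: e[1] for g, e in entries.items()},
                "amplitude": {g: e[2] for g, e in entries.items()},
                "f24": 0.8,
                "p_f24": 0.001,
            }
        ).rename_axis("gene_id")

    return make
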