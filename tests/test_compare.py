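"""Four-way classification, concordance statistics, variability and bursts."""

import math

import numpy as np
import pandas as pd
import pytest

from nascentcycle.design import RhythmParams, SamplingDesign
from nascentcycle.compare import (
    CATEGORIES,
    coefficient_of_variation,
    circular_phase_correlation,
    amplitude_correlation,
    detect_single_burst,
    flag_readthrough,
    four_way_classify,
    phase_difference,
    phase_histogram,
    variability_quintile_analysis,
)
from nascentcycle.models import GeneModel, GeneModelSet
from nascentcycle.rhythm import detect_rhythms
from nascentcycle.simulate import (
    generate_truth_set,
    mrna_phase_delay_h,
    simulate_expression_matrix,
)


class TestFourWay:
    def test_definition_table(self, rhythm_table_factory):
        nascent = rhythm_table_factory(
            {"a": ("strong", 4, 3), "b": ("medium", 6, 2), "c": ("arrhythmic", np.nan, 1.2),
             "d": ("arrhythmic", np.nan, 1.1)}
        )
        mrna = rhythm_table_factory(
            {"a": ("medium", 6, 2), "b": ("arrhythmic", np.nan, 1.2), "c": ("strong", 10, 4),
             "d": ("arrhythmic", np.nan, 1.0)}
        )
        ct = four_way_classify(nascent, mrna)
        assert ct.table.loc["a", "category"] == "RR"
        assert ct.table.loc["b", "category"] == "RAR"
        assert ct.table.loc["c", "category"] == "ARR"
        assert ct.table.loc["d", "category"] == "ARAR"

    def test_counts_reconcile_with_rhythmic_margins(self, rhythm_table_factory):
        rng = np.random.default_rng(0)
        genes = [f"g{i}" for i in range(200)]
        calls = ["strong", "medium", "arrhythmic"]
        nascent = rhythm_table_factory(
            {g: (calls[rng.integers(3)], float(rng.uniform(0, 24)), 2.0) for g in genes}
        )
        mrna = rhythm_table_factory(
            {g: (calls[rng.integers(3)], float(rng.uniform(0, 24)), 2.0) for g in genes}
        )
        ct = four_way_classify(nascent, mrna)
        nascent_rhythmic = nascent["call"].isin(("strong", "medium")).sum()
        mrna_rhythmic = mrna["call"].isin(("strong", "medium")).sum()
        assert ct.counts["RR"] + ct.counts["RAR"] == nascent_rhythmic
        assert ct.counts["RR"] + ct.counts["ARR"] == mrna_rhythmic
        assert sum(ct.counts.values()) == 200
        # percentages recompute exactly from counts
        for c in CATEGORIES:
            assert ct.percentages[c] == round(100 * ct.counts[c] / 200, 1)

    def test_printed_count_fractions(self, rhythm_table_factory):
        """Summary fractions from classification populated with known margins:
        822 transcription-rhythmic genes of which 342 also mRNA-rhythmic, and
        1204 mRNA-rhythmic genes."""
        entries_n, entries_m = {}, {}
        for i in range(342):  # RR
            entries_n[f"rr{i}"] = ("medium", 8.0, 2.0)
            entries_m[f"rr{i}"] = ("medium", 9.0, 2.0)
        for i in range(480):  # RAR
            entries_n[f"ra{i}"] = ("medium", 8.0, 2.0)
            entries_m[f"ra{i}"] = ("arrhythmic", np.nan, 1.2)
        for i in range(862):  # ARR
            entries_n[f"ar{i}"] = ("arrhythmic", np.nan, 1.2)
            entries_m[f"ar{i}"] = ("medium", 9.0, 2.0)
        ct = four_way_classify(
            pd.DataFrame({"call": {g: e[0] for g, e in entries_n.items()},
                          "phase_h": {g: e[1] for g, e in entries_n.items()},
                          "amplitude": {g: e[2] for g, e in entries_n.items()}}),
            pd.DataFrame({"call": {g: e[0] for g, e in entries_m.items()},
                          "phase_h": {g: e[1] for g, e in entries_m.items()},
                          "amplitude": {g: e[2] for g, e in entries_m.items()}}),
        )
        assert ct.rr_of_nascent_rhythmic_pct == 41.6  # 342/822
        assert ct.rr_of_mrna_rhythmic_pct == 28.4  # 342/1204

    def test_fully_coupled_short_half_life_yields_no_discordant_classes(self):
        truths = generate_truth_set({"RR": 40}, seed=8)
        truths = [
            type(t)(gene_id=t.gene_id, klass="RR", baseline=t.baseline,
                    rel_amplitude=t.rel_amplitude, phase_h=t.phase_h,
                    half_life_h=0.5, noise_cv=0.0)
            for t in truths
        ]
        params = RhythmParams(n_permutations=500, seed=0)
        nas, _ = detect_rhythms(
            simulate_expression_matrix(truths, SamplingDesign.nascent(), 0), params,
            SamplingDesign.nascent(),
        )
        mr, _ = detect_rhythms(
            simulate_expression_matrix(truths, SamplingDesign.mrna(), 0), params,
            SamplingDesign.mrna(),
        )
        ct = four_way_classify(nas, mr)
        assert ct.counts["RAR"] == 0 and ct.counts["ARR"] == 0

    def test_non_overlapping_gene_sets_error(self, rhythm_table_factory):
        a = rhythm_table_factory({"x": ("strong", 1, 2)})
        b = rhythm_table_factory({"y": ("strong", 1, 2)})
        with pytest.raises(ValueError):
            four_way_classify(a, b)


class TestPhaseDifference:
    @pytest.mark.parametrize(
        "m, n, expected", [(1, 23, 2), (23, 1, -2), (8, 8, 0), (20, 8, 12)]
    )
    def test_wraparound(self, m, n, expected):
        assert phase_difference(m, n) == pytest.approx(expected)

    def test_antisymmetric_and_bounded(self):
        rng = np.random.default_rng(0)
        a, b = rng.uniform(0, 24, 100), rng.uniform(0, 24, 100)
        d = phase_difference(a, b)
        assert np.allclose(d, -np.where(phase_difference(b, a) == 12, -12, phase_difference(b, a)))
        assert np.all(d > -12) and np.all(d <= 12)

    def test_coupled_data_recovers_ode_delay(self):
        """Mean mRNA-minus-nascent phase difference per half-life group equals
        arctan(omega/delta)/omega within 0.5 h on noiseless coupled genes."""
        for hl in (0.5, 2.0, 8.0):
            truths = generate_truth_set({"RR": 20}, seed=13)
            truths = [
                type(t)(gene_id=t.gene_id, klass="RR", baseline=t.baseline,
                        rel_amplitude=0.5, phase_h=t.phase_h, half_life_h=hl, noise_cv=0.0)
                for t in truths
            ]
            params = RhythmParams(n_permutations=200, seed=1)
            nas, _ = detect_rhythms(
                simulate_expression_matrix(truths, SamplingDesign.nascent(), 0),
                params, SamplingDesign.nascent())
            mr, _ = detect_rhythms(
                simulate_expression_matrix(truths, SamplingDesign.mrna(), 0),
                params, SamplingDesign.mrna())
            d = phase_difference(mr["phase_h"].to_numpy(), nas["phase_h"].to_numpy())
            assert np.nanmean(d) == pytest.approx(mrna_phase_delay_h(hl), abs=0.25)


class TestCorrelations:
    def test_identical_phases_give_one(self):
        a = np.array([1.0, 5.0, 9.0, 13.0, 20.0])
        assert circular_phase_correlation(a, a) == pytest.approx(1.0)

    def test_constant_lag_gives_one(self):
        a = np.array([1.0, 5.0, 9.0, 13.0, 20.0])
        assert circular_phase_correlation(a, (a + 3) % 24) == pytest.approx(1.0)

    def test_matches_frozen_double_loop_oracle(self):
        a = [1.0, 3.5, 7.2, 12.0, 15.5, 18.1, 21.0, 23.5]
        b = [2.0, 5.0, 6.8, 13.5, 14.9, 19.2, 20.5, 0.5]
        # frozen from an independently coded pairwise-sine double loop
        assert circular_phase_correlation(a, b) == pytest.approx(0.9546022771939415, abs=1e-12)

    def test_degenerate_input_errors(self):
        with pytest.raises(ValueError):
            circular_phase_correlation([3.0, 3.0, 3.0], [1.0, 2.0, 4.0])

    def test_amplitude_identity_and_log_linearity(self):
        a = np.array([1.2, 2.0, 3.5, 6.0, 9.0])
        assert amplitude_correlation(a, a) == pytest.approx(1.0)
        assert amplitude_correlation(a, a**2) == pytest.approx(1.0)

    def test_amplitude_matches_direct_formula_oracle(self):
        a = [1.2, 1.5, 2.0, 2.5, 3.0, 4.0, 5.5, 7.0, 8.5, 10.0]
        b = [1.1, 1.8, 1.9, 3.1, 2.7, 4.5, 5.0, 8.2, 7.9, 12.0]
        # frozen from a hand-coded covariance/variance computation on log2
        assert amplitude_correlation(a, b) == pytest.approx(0.984238072423905, abs=1e-12)


class TestVariability:
    def test_cv_constant_is_zero_and_scale_invariant(self):
        x = np.full(12, 3.0)
        assert coefficient_of_variation(x) == 0.0
        y = np.random.default_rng(0).uniform(1, 5, 12)
        assert coefficient_of_variation(2 * y) == pytest.approx(coefficient_of_variation(y))

    def test_consecutive_integers_closed_form(self):
        # sample variance of 1..12 is n(n+1)/12 = 13; mean 6.5
        assert coefficient_of_variation(np.arange(1, 13)) == pytest.approx(math.sqrt(13) / 6.5)

    def test_mean_zero_errors(self):
        with pytest.raises(ValueError):
            coefficient_of_variation(np.zeros(12))

    def test_quintiles_hand_enumeration(self):
        cv = pd.Series({f"g{i}": v for i, v in enumerate([0.9, 0.8, 0.7, 0.6, 0.5, 0.4, 0.3, 0.2, 0.15, 0.1])})
        rhythmic = pd.Series(
            {f"g{i}": r for i, r in enumerate([True, True, True, False, True, False, False, False, False, False])}
        )
        out = variability_quintile_analysis(cv, rhythmic)
        assert list(out["n"]) == [2, 2, 2, 2, 2]
        assert list(out["frac_mrna_rhythmic"]) == [1.0, 0.5, 0.5, 0.0, 0.0]
        assert out.loc["q1", "mean_cv"] == pytest.approx(0.85)

    def test_planted_monotone_relationship(self):
        rng = np.random.default_rng(5)
        n = 500
        cv = pd.Series(rng.uniform(0.05, 1.0, n), index=[f"g{i}" for i in range(n)])
        prob = (cv - 0.05) / 0.95
        rhythmic = pd.Series(rng.random(n) < prob, index=cv.index)
        out = variability_quintile_analysis(cv, rhythmic)
        fr = out["frac_mrna_rhythmic"].to_numpy()
        assert np.all(np.diff(fr) <= 0)  # q1 most variable -> highest fraction

    def test_tied_cv_uses_stable_gene_id_tiebreak(self):
        cv = pd.Series(0.5, index=[f"g{i}" for i in range(10)])
        flags = pd.Series(False, index=cv.index)
        out1 = variability_quintile_analysis(cv, flags)
        out2 = variability_quintile_analysis(cv.sample(frac=1, random_state=1), flags)
        pd.testing.assert_frame_equal(out1, out2)

    def test_too_few_genes_errors(self):
        with pytest.raises(ValueError):
            variability_quintile_analysis(
                pd.Series([0.1, 0.2], index=["a", "b"]),
                pd.Series([True, False], index=["a", "b"]),
            )


class TestSingleBurst:
    def test_reproducible_spike_detected(self):
        rep = np.array([1, 1, 10, 1, 1, 1.0])
        assert detect_single_burst(rep, rep)

    def test_replicate_disagreement_rejected(self):
        r1 = np.array([1, 1, 10, 1, 1, 1.0])
        r2 = np.array([1, 1, 1, 1, 10, 1.0])
        assert not detect_single_burst(r1, r2)

    def test_flat_series_rejected(self):
        assert not detect_single_burst(np.ones(6), np.ones(6))

    def test_threshold_respected(self):
        rep = np.array([1, 1, 2.5, 1, 1, 1.0])
        assert not detect_single_burst(rep, rep, theta=3.0)
        assert detect_single_burst(rep, rep, theta=2.0)


class TestReadthrough:
    @staticmethod
    def _setup(same_strand=True, rhythmic_upstream=True, gap_signal_high=True):
        strand_b = "+" if same_strand else "-"
        models = GeneModelSet(
            [
                GeneModel("up", "chr1", "+", [(0, 2000)]),
                GeneModel("down", "chr1", strand_b, [(4000, 6000)]),
                GeneModel("far", "chr1", "+", [(50_000, 52_000)]),
            ]
        )
        calls = pd.DataFrame(
            {
                "call": {
                    "up": "strong" if rhythmic_upstream else "arrhythmic",
                    "down": "medium",
                    "far": "medium",
                },
                "phase_h": {"up": 8.0, "down": 8.5, "far": 8.0},
            }
        )
        design = SamplingDesign.nascent()
        sig = pd.DataFrame(
            0.1, index=["up", "down", "far"], columns=design.sample_labels()
        )
        if gap_signal_high:
            peak_cols = [c for c in sig.columns if "ZT08" in c]
            sig.loc["down", peak_cols] = 10.0
        return models, calls, sig, design

    def test_planted_readthrough_flagged(self):
        models, calls, sig, design = self._setup()
        flags = flag_readthrough(calls, models, sig, design)
        assert flags["down"] and not flags["far"] and not flags["up"]

    def test_opposite_strand_not_flagged(self):
        models, calls, sig, design = self._setup(same_strand=False)
        assert not flag_readthrough(calls, models, sig, design)["down"]

    def test_arrhythmic_upstream_not_flagged(self):
        models, calls, sig, design = self._setup(rhythmic_upstream=False)
        assert not flag_readthrough(calls, models, sig, design)["down"]

    def test_quiet_gap_not_flagged(self):
        models, calls, sig, design = self._setup(gap_signal_high=False)
        assert not flag_readthrough(calls, models, sig, design)["down"]


class TestPhaseHistogram:
    def test_boundaries_half_open(self):
        out = phase_histogram([0.5, 1.9, 2.0])
        assert out["[0,2)"] == 2 and out["[2,4)"] == 1

    def test_matches_numpy_histogram_and_double_plot(self):
        rng = np.random.default_rng(42)
        phases = rng.uniform(0, 24, 936)
        out = phase_histogram(phases)
        oracle, _ = np.histogram(phases, bins=np.arange(0, 26, 2))
        assert list(out) == list(oracle)
        assert out.sum() == 936
        doubled = phase_histogram(phases, double_plot=True)
        assert len(doubled) == 24 and doubled.sum() == 2 * 936
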