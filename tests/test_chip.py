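"""Peak overlap, gene assignment, signal profiles and E-box enrichment."""

import numpy as np
import pandas as pd
import pytest

from nascentcycle.chip import (
    assign_peak_to_gene,
    binned_signal_profile,
    dinucleotide_shuffle,
    ebox_enrichment,
    overlap_significance,
    peak_overlap,
    reverse_complement,
    scan_ebox,
)
from nascentcycle.genome import GenomeFixtureConfig, simulate_genome_fixture
from nascentcycle.models import GeneModel, GeneModelSet


def peaks(*ivs, chrom="chr1"):
    return pd.DataFrame(
        [{"chrom": chrom, "start": s, "end": e} for s, e in ivs]
    )


class TestPeakOverlap:
    def test_single_nucleotide_overlap_counts(self):
        res = peak_overlap(peaks((100, 200)), peaks((199, 300)))
        assert res.n_shared == 1 and res.n_a_shared == 1 and res.n_b_shared == 1
        assert res.shared.iloc[0][["start", "end"]].tolist() == [100, 300]

    def test_half_open_boundary_does_not_overlap(self):
        res = peak_overlap(peaks((100, 200)), peaks((200, 300)))
        assert res.n_shared == 0
        assert len(res.a_only) == 1 and len(res.b_only) == 1

    @pytest.mark.parametrize("seed", range(3))
    def test_shared_count_matches_all_pairs_oracle(self, seed):
        rng = np.random.default_rng(seed)
        a = peaks(*[(s, s + rng.integers(50, 400)) for s in rng.integers(0, 100_000, 200)])
        b = peaks(*[(s, s + rng.integers(50, 400)) for s in rng.integers(0, 100_000, 300)])
        res = peak_overlap(a, b)
        # brute-force O(n*m) oracle on per-peak hit flags
        a_hits = sum(
            any(ra.start < rb.end and ra.end > rb.start for rb in b.itertuples())
            for ra in a.itertuples()
        )
        b_hits = sum(
            any(rb.start < ra.end and rb.end > ra.start for ra in a.itertuples())
            for rb in b.itertuples()
        )
        assert res.n_a_shared == a_hits and res.n_b_shared == b_hits
        assert res.n_a_shared <= min(len(a), res.n_a_shared)
        assert len(res.a_only) == len(a) - a_hits

    def test_symmetry_of_shared_components(self):
        rng = np.random.default_rng(9)
        a = peaks(*[(s, s + 100) for s in rng.integers(0, 50_000, 80)])
        b = peaks(*[(s, s + 100) for s in rng.integers(0, 50_000, 80)])
        assert peak_overlap(a, b).n_shared == peak_overlap(b, a).n_shared

    def test_malformed_interval_errors(self):
        with pytest.raises(ValueError):
            peak_overlap(peaks((200, 100)), peaks((0, 10)))


class TestOverlapSignificance:
    SIZES = {"chr1": 1_000_000, "chr2": 1_000_000}

    def test_identical_sets_minimal_p(self):
        a = peaks(*[(s, s + 200) for s in range(0, 20_000, 1000)])
        p, obs = overlap_significance(a, a, self.SIZES, n_permutations=199, seed=0)
        assert obs == len(a)
        assert p <= 0.05

    def test_disjoint_chromosomes_p_near_one(self):
        a = peaks(*[(s, s + 200) for s in range(0, 20_000, 1000)], chrom="chr1")
        b = peaks(*[(s, s + 200) for s in range(0, 20_000, 1000)], chrom="chr2")
        p, obs = overlap_significance(a, b, self.SIZES, n_permutations=99, seed=0)
        assert obs == 0 and p == 1.0

    def test_reproducible_given_seed(self):
        rng = np.random.default_rng(1)
        a = peaks(*[(s, s + 150) for s in rng.integers(0, 900_000, 50)])
        b = peaks(*[(s, s + 150) for s in rng.integers(0, 900_000, 60)])
        p1 = overlap_significance(a, b, self.SIZES, n_permutations=199, seed=7)
        p2 = overlap_significance(a, b, self.SIZES, n_permutations=199, seed=7)
        assert p1 == p2

    def test_peak_wider_than_chromosome_errors(self):
        with pytest.raises(ValueError):
            overlap_significance(
                peaks((0, 2_000_000)), peaks((0, 10)), self.SIZES, n_permutations=9
            )


class TestAssignPeakToGene:
    MODELS = GeneModelSet(
        [
            GeneModel("gA", "chr1", "+", [(1000, 1200), (1800, 2000)]),
            GeneModel("gB", "chr1", "-", [(10_000, 12_000)]),
        ]
    )

    def test_genic_center_assigned_to_that_gene(self):
        out = assign_peak_to_gene(peaks((1400, 1600)), self.MODELS)
        assert out.iloc[0]["gene_id"] == "gA" and out.iloc[0]["relation"] == "genic"

    def test_intergenic_goes_to_nearest_tss(self):
        # center 3000: 2000 from gA TSS (1000), 9000 from gB TSS (12000)
        out = assign_peak_to_gene(peaks((2900, 3100)), self.MODELS)
        assert out.iloc[0]["gene_id"] == "gA"
        assert out.iloc[0]["relation"] == "intergenic-nearest-TSS"
        # center 9000: 8000 from gA TSS, 3000 from gB TSS (strand-resolved = 12000)
        out = assign_peak_to_gene(peaks((8900, 9100)), self.MODELS)
        assert out.iloc[0]["gene_id"] == "gB"

    def test_equidistant_tie_breaks_lexicographically(self):
        models = GeneModelSet(
            [
                GeneModel("gB", "chr1", "+", [(0, 100)]),
                GeneModel("gA", "chr1", "+", [(2000, 2100)]),
            ]
        )
        # center 1000: distance 1000 to both TSSs (0 and 2000)
        out = assign_peak_to_gene(peaks((900, 1100)), models)
        assert out.iloc[0]["gene_id"] == "gA"

    def test_every_peak_assigned(self):
        rng = np.random.default_rng(0)
        p = peaks(*[(s, s + 100) for s in rng.integers(0, 20_000, 50)])
        out = assign_peak_to_gene(p, self.MODELS)
        assert len(out) == 50 and out["gene_id"].notna().all()


class TestBinnedSignalProfile:
    def test_flat_track_is_zero_after_zscoring(self):
        track = {"chr1": np.full(10_000, 5.0)}
        centers = pd.DataFrame({"chrom": ["chr1"], "center": [5000]})
        out = binned_signal_profile(track, centers)
        assert np.allclose(out["all"], 0.0)
        assert len(out) == 80

    def test_planted_bump_peaks_at_center(self):
        x = np.zeros(20_000)
        for c in (5000, 12_000):
            x[c - 100 : c + 100] += np.exp(-np.linspace(-3, 3, 200) ** 2)
        centers = pd.DataFrame({"chrom": ["chr1", "chr1"], "center": [5000, 12_000]})
        out = binned_signal_profile({"chr1": x}, centers)
        assert out["all"].idxmax() in (-25, 0)

    def test_matches_direct_per_base_oracle(self):
        rng = np.random.default_rng(3)
        x = rng.gamma(2.0, 1.0, 30_000)
        centers_pos = rng.integers(2000, 28_000, 10)
        centers = pd.DataFrame({"chrom": "chr1", "center": centers_pos})
        out = binned_signal_profile({"chr1": x}, centers, half_window=1000, bin_size=25)
        z = (x - x.mean()) / x.std()
        oracle = np.zeros(80)
        for c in centers_pos:
            win = z[c - 1000 : c + 1000].reshape(80, 25).mean(axis=1)
            oracle += win
        oracle /= len(centers_pos)
        assert np.allclose(out["all"].to_numpy(), oracle, atol=1e-12)

    def test_window_clipped_at_chromosome_bounds(self):
        track = {"chr1": np.arange(1500, dtype=float)}
        centers = pd.DataFrame({"chrom": ["chr1"], "center": [100]})
        out = binned_signal_profile(track, centers)
        assert out["all"].isna().sum() > 0  # leading bins outside the chromosome
        assert out["all"].notna().sum() > 0


class TestEbox:
    def test_planted_motif_at_center_counted_at_offset_zero(self):
        rng = np.random.default_rng(0)
        flank = "".join(rng.choice(list("AT"), 500))  # AT background, no E-box
        window = flank + "CACGTG" + flank[:495]
        perfect, degen = scan_ebox([window])
        assert perfect[500] == 1 and perfect.sum() == 1

    def test_one_mismatch_is_degenerate_not_perfect(self):
        flank = "A" * 500
        window = flank + "CACGTT" + "A" * 495
        perfect, degen = scan_ebox([window])
        assert perfect.sum() == 0
        assert degen[500] == 1

    def test_palindrome_reverse_complement_symmetry(self):
        rng = np.random.default_rng(2)
        window = "".join(rng.choice(list("ACGT"), 1001))
        perfect_fwd, _ = scan_ebox([window])
        perfect_rev, _ = scan_ebox([reverse_complement(window)])
        assert perfect_fwd.sum() == perfect_rev.sum()

    def test_dinucleotide_shuffle_preserves_composition(self):
        from collections import Counter

        rng = np.random.default_rng(4)
        seq = "".join(rng.choice(list("ACGT"), 400))
        sh = dinucleotide_shuffle(seq, rng)
        assert Counter(zip(seq, seq[1:])) == Counter(zip(sh, sh[1:]))
        assert sh[0] == seq[0] and sh[-1] == seq[-1]

    def test_planted_enrichment_at_center_exceeds_flanks(self):
        rng = np.random.default_rng(5)
        windows = []
        for _ in range(50):
            seq = list(rng.choice(list("ACGT"), 1001))
            seq[500:506] = list("CACGTG")
            windows.append("".join(seq))
        prof = ebox_enrichment(windows, n_shuffles=20, seed=0)
        assert prof.loc[0, "perfect_obs"] == 50
        # enrichment is defined only where the shuffled expectation is > 0;
        # at flank offsets expected counts are near zero, so compare observed
        flank_max = prof.drop(index=0)["perfect_obs"].max()
        assert prof.loc[0, "perfect_obs"] > 5 * max(flank_max, 1)
        center_enr = prof.loc[0, "perfect_enrichment"]
        assert np.isnan(center_enr) or center_enr > 5

    def test_profile_matches_brute_force_scan(self):
        rng = np.random.default_rng(6)
        windows = ["".join(rng.choice(list("ACGT"), 1001)) for _ in range(10)]
        prof = ebox_enrichment(windows, n_shuffles=2, seed=0)
        # brute-force per-position string scan
        for off in (-500, -100, 0, 250, 494):
            i = off + 500
            expect = sum(w[i : i + 6] == "CACGTG" for w in windows)
            assert prof.loc[off, "perfect_obs"] == expect
            expect_d = sum(
                sum(a != b for a, b in zip(w[i : i + 6], "CACGTG")) == 1 for w in windows
            )
            assert prof.loc[off, "degenerate_obs"] == expect_d

    def test_zero_planted_eboxes_in_fixture(self):
        cfg = GenomeFixtureConfig(n_peaks=3, n_peaks_with_ebox=0, n_reads=100)
        fx = simulate_genome_fixture(cfg, seed=1)
        g = fx.genome[cfg.chrom]
        seqs = [
            g[(p.start + p.end) // 2 - 500 : (p.start + p.end) // 2 + 501]
            for p in fx.peaks.itertuples()
        ]
        perfect, _ = scan_ebox(seqs)
        assert perfect.sum() == 0

    def test_shuffled_background_expected_flat(self):
        """Expected counts per offset from the dinucleotide-shuffle null are
        flat across the window up to Monte-Carlo error."""
        rng = np.random.default_rng(7)
        windows = ["".join(rng.choice(list("ACGT"), 1001)) for _ in range(20)]
        prof = ebox_enrichment(windows, n_shuffles=50, seed=1)
        exp = prof["perfect_expected"].to_numpy()
        # binomial-ish MC error around a small flat mean
        assert exp.std() < 5 * np.sqrt(max(exp.mean(), 1e-6) / 50 / 20) + 0.05

    def test_non_acgtn_errors_and_n_skipped(self):
        with pytest.raises(ValueError):
            scan_ebox(["ACGTX" + "A" * 996])
        windows = ["N" * 1001, "A" * 1001]
        prof = ebox_enrichment(windows, n_shuffles=1, seed=0)
        assert prof["perfect_obs"].sum() == 0  # N window skipped, A window scanned
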