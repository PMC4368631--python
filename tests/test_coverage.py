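import numpy as np
import pytest

from promdiff.coverage import (
    CoverageTrack,
    build_coverage,
    deduplicate_reads,
    extend_reads,
    meta_profile,
    normalize_per_million,
    quantile_normalize,
    smooth,
)
from promdiff.io_formats import AlignedRead, GenomicInterval, ValidationError

SIZES = {"chr1": 10_000}


def read(chrom, start, end, strand="+", name="r"):
    return AlignedRead(chrom, start, end, strand, name)


class TestDeduplicate:
    def test_same_5prime_position_collapses(self):
        reads = [read("chr1", 100, 150), read("chr1", 100, 150, name="dup")]
        assert len(deduplicate_reads(reads)) == 1

    def test_opposite_strands_both_kept(self):
        reads = [read("chr1", 100, 150, "+"), read("chr1", 51, 101, "-")]
        # the - read's 5' base is 100 too, but the key is strand-aware
        assert len(deduplicate_reads(reads)) == 2

    def test_empty_input(self):
        assert deduplicate_reads([]) == []

    def test_output_sorted_and_first_kept(self):
        reads = [read("chr1", 500, 550, name="late"), read("chr1", 100, 150, name="a"),
                 read("chr1", 100, 150, name="b")]
        out = deduplicate_reads(reads)
        assert [r.name for r in out] == ["a", "late"]


class TestExtendReads:
    @pytest.mark.parametrize(
        "r,frag,expected",
        [
            (read("chr1", 100, 150, "+"), 200, (100, 300)),
            (read("chr1", 250, 300, "-"), 200, (100, 300)),
            (read("chr1", 100, 150, "+"), 50, (100, 150)),  # never shorter than the read
        ],
    )
    def test_5prime_anchored_extension(self, r, frag, expected):
        (iv,) = extend_reads([r], frag, SIZES)
        assert (iv.start, iv.end) == expected

    def test_clipped_to_chromosome(self):
        (iv,) = extend_reads([read("chr1", 9950, 9990, "+")], 200, SIZES)
        assert (iv.start, iv.end) == (9950, 10_000)

    def test_read_outside_chromosome_rejected(self):
        with pytest.raises(ValidationError):
            extend_reads([read("chr1", 9990, 10_050, "+")], 200, SIZES)


class TestBuildCoverage:
    def test_single_fragment_pileup(self):
        track = build_coverage([GenomicInterval("chr1", 2, 5)], {"chr1": 8})
        np.testing.assert_array_equal(track.data["chr1"], [0, 0, 1, 1, 1, 0, 0, 0])

    def test_additivity(self):
        frags = [GenomicInterval("chr1", 2, 5)] * 2
        track = build_coverage(frags, {"chr1": 8})
        np.testing.assert_array_equal(track.data["chr1"], [0, 0, 2, 2, 2, 0, 0, 0])

    def test_total_equals_sum_of_lengths_and_matches_naive_loop(self):
        rng = np.random.default_rng(4)
        frags = []
        naive = np.zeros(10_000)
        for _ in range(1000):
            s = int(rng.integers(0, 9_800))
            e = s + int(rng.integers(1, 200))
            frags.append(GenomicInterval("chr1", s, e))
            for b in range(s, e):
                naive[b] += 1
        track = build_coverage(frags, SIZES)
        np.testing.assert_array_equal(track.data["chr1"], naive)
        assert track.total() == sum(len(f) for f in frags)


class TestPerMillion:
    def test_library_of_one_million_is_identity(self):
        t = CoverageTrack({"chr1": np.arange(5.0)}, library_size=10**6)
        np.testing.assert_array_equal(normalize_per_million(t).data["chr1"], np.arange(5.0))

    def test_double_library_halves_values(self):
        t = CoverageTrack({"chr1": np.arange(5.0)}, library_size=2 * 10**6)
        np.testing.assert_allclose(normalize_per_million(t).data["chr1"], np.arange(5.0) / 2)

    def test_conservation_identity(self):
        t = CoverageTrack({"chr1": np.random.default_rng(0).random(100)}, library_size=12345)
        out = normalize_per_million(t)
        assert out.total() == pytest.approx(t.total() * 1e6 / 12345, rel=1e-12)

    def test_zero_library_rejected(self):
        t = CoverageTrack({"chr1": np.ones(5)}, library_size=0)
        with pytest.raises(ValidationError):
            normalize_per_million(t)


class TestSmooth:
    def test_constant_vector_unchanged(self):
        t = CoverageTrack({"chr1": np.full(500, 3.0)}, library_size=1, state="per_million")
        np.testing.assert_allclose(smooth(t, 101).data["chr1"], 3.0)

    def test_interior_impulse_spreads_to_window(self):
        v = np.zeros(2001)
        v[1000] = 1.0
        t = CoverageTrack({"chr1": v}, library_size=1, state="per_million")
        out = smooth(t, 101).data["chr1"]
        np.testing.assert_allclose(out[950:1051], 1 / 101)
        assert out[949] == 0 and out[1051] == 0

    def test_even_window_widens_to_odd(self):
        v = np.zeros(3001)
        v[1500] = 1.0
        t = CoverageTrack({"chr1": v}, library_size=1, state="per_million")
        out = smooth(t, 1000).data["chr1"]
        np.testing.assert_allclose(out[1000:2001], 1 / 1001)

    def test_interior_mass_preserved(self):
        rng = np.random.default_rng(5)
        core = rng.random(300)
        v = np.concatenate([np.zeros(101), core, np.zeros(101)])
        t = CoverageTrack({"chr1": v}, library_size=1, state="per_million")
        out = smooth(t, 101).data["chr1"]
        assert out.sum() == pytest.approx(v.sum(), rel=1e-10)


class TestQuantileNormalize:
    def _track(self, values, state="smoothed"):
        return CoverageTrack({"chr1": np.asarray(values, dtype=float)}, library_size=1, state=state)

    def test_identical_tracks_are_fixed_point(self):
        v = np.random.default_rng(6).random(100)
        out = quantile_normalize([self._track(v), self._track(v)])
        for t in out:
            np.testing.assert_allclose(t.data["chr1"], v, atol=1e-14)

    def test_rank_mean_hand_example(self):
        out = quantile_normalize([self._track([1, 2, 3]), self._track([4, 5, 6])])
        np.testing.assert_allclose(out[0].data["chr1"], [2.5, 3.5, 4.5])
        np.testing.assert_allclose(out[1].data["chr1"], [2.5, 3.5, 4.5])

    def test_sorted_vectors_identical_after_normalization(self):
        rng = np.random.default_rng(7)
        tracks = [self._track(rng.random(500)) for _ in range(4)]
        out = quantile_normalize(tracks)
        ref = np.sort(out[0].data["chr1"])
        for t in out[1:]:
            np.testing.assert_allclose(np.sort(t.data["chr1"]), ref, atol=1e-12)

    def test_idempotent_on_tie_free_tracks(self):
        rng = np.random.default_rng(8)
        tracks = [self._track(rng.random(400)) for _ in range(3)]
        once = quantile_normalize(tracks)
        for t in once:
            t.state = "smoothed"  # re-enter the state machine for a second pass
        twice = quantile_normalize(once)
        for a, b in zip(once, twice):
            np.testing.assert_allclose(a.data["chr1"], b.data["chr1"], atol=1e-12)

    def test_ties_get_mean_of_spanned_quantiles(self):
        out = quantile_normalize([self._track([1, 1, 3]), self._track([4, 5, 6])])
        # ranks 0 and 1 of sample 1 are tied: both get mean(ref[0], ref[1])
        ref = np.sort(np.mean([np.sort([1, 1, 3]), [4, 5, 6]], axis=0))
        expected = np.mean(ref[:2])
        np.testing.assert_allclose(out[0].data["chr1"][:2], expected)

    def test_rank_order_preserved_within_sample(self):
        rng = np.random.default_rng(9)
        v = rng.random(200)
        out = quantile_normalize([self._track(v), self._track(rng.random(200))])
        assert (np.argsort(v) == np.argsort(out[0].data["chr1"], kind="stable")).all()

    def test_mismatched_genomes_rejected(self):
        a = self._track(np.ones(10))
        b = CoverageTrack({"chr2": np.ones(10)}, library_size=1, state="smoothed")
        with pytest.raises(ValidationError):
            quantile_normalize([a, b])


class TestStateMachine:
    def test_states_advance_forward_only(self):
        t = CoverageTrack({"chr1": np.ones(10)}, library_size=10, state="quantile_normalized")
        with pytest.raises(ValidationError):
            smooth(t, 3)
        with pytest.raises(ValidationError):
            normalize_per_million(t)
        t2 = CoverageTrack({"chr1": np.ones(10)}, library_size=10, state="per_million")
        with pytest.raises(ValidationError):
            normalize_per_million(t2)


class TestMetaProfile:
    def test_uniform_track_gives_constant_profile(self):
        t = CoverageTrack({"chr1": np.full(10_000, 2.5)}, state="quantile_normalized")
        prof = meta_profile({"s": t}, [("chr1", 5000, "+")], flank_bp=1000, bin_bp=50)
        assert prof.bin_centers.size == 40
        np.testing.assert_allclose(prof.profiles["s"], 2.5)

    def test_bin_count_arithmetic(self):
        t = CoverageTrack({"chr1": np.zeros(10_000)}, state="quantile_normalized")
        prof = meta_profile({"s": t}, [("chr1", 5000, "+")], flank_bp=1000, bin_bp=50)
        assert prof.bin_centers.size == 2 * 1000 // 50
        assert prof.bin_centers[0] == -975 and prof.bin_centers[-1] == 975

    def test_minus_strand_profile_mirrors_plus(self):
        # asymmetric signal: reflected minus-strand gene must give the
        # mirrored plus-strand profile
        rng = np.random.default_rng(10)
        v = rng.random(4000)
        L = 4000
        t_plus = CoverageTrack({"chr1": v}, state="quantile_normalized")
        t_minus = CoverageTrack({"chr1": v[::-1].copy()}, state="quantile_normalized")
        tss_plus = 1700
        tss_minus = L - 1 - tss_plus
        p_plus = meta_profile({"s": t_plus}, [("chr1", tss_plus, "+")], 1000, 50)
        p_minus = meta_profile({"s": t_minus}, [("chr1", tss_minus, "-")], 1000, 50)
        np.testing.assert_allclose(p_minus.profiles["s"], p_plus.profiles["s"], atol=1e-12)

    def test_near_edge_tss_skipped_with_warning(self):
        t = CoverageTrack({"chr1": np.ones(3000)}, state="quantile_normalized")
        with pytest.warns(UserWarning, match="skipped"):
            prof = meta_profile({"s": t}, [("chr1", 100, "+"), ("chr1", 1500, "+")], 1000, 50)
        assert prof.n_sites == 1

    def test_empty_tss_set_rejected(self):
        t = CoverageTrack({"chr1": np.ones(100)}, state="quantile_normalized")
        with pytest.raises(ValidationError):
            meta_profile({"s": t}, [], 50, 50)

    def test_flank_must_be_multiple_of_bin(self):
        t = CoverageTrack({"chr1": np.ones(100)}, state="quantile_normalized")
        with pytest.raises(ValidationError):
            meta_profile({"s": t}, [("chr1", 50, "+")], 55, 50)
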