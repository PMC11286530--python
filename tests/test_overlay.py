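"""Signal normalization, region scoring, profile averaging, clustering."""

import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from carna.contacts_io import GenomeAssembly, GenomicInterval, SignalTrack
from carna.overlay import (
    EnrichmentMatrix,
    average_profile,
    cluster_regions,
    compare_conditions,
    cpm_normalize,
    score_regions,
)
from carna.synthetic import make_genome, make_regions, simulate_tracks

MARKS = ["H3K4me3", "H3K27ac", "H3K9ac", "H3K36me3", "H3K27me3", "BRD4"]


@pytest.fixture
def asm():
    return GenomeAssembly(("chr1", "chr2"), (10_000, 8_000))


def uniform_track(asm, value, bin_size=100, normalization="raw"):
    return SignalTrack(
        asm, bin_size,
        {c: np.full(asm.n_bins(c, bin_size), float(value)) for c in asm.chrom_names},
        normalization,
    )


class TestCpmNormalize:
    def test_scaling(self, asm):
        track = uniform_track(asm, 10.0)
        out = cpm_normalize(track, 2e6)
        assert out.values["chr1"][0] == pytest.approx(5.0)
        assert out.normalization == "CPM"
        assert track.normalization == "raw"  # input untouched

    def test_unit_library_identity(self, asm):
        out = cpm_normalize(uniform_track(asm, 5.0), 1e6)
        assert out.values["chr1"][0] == pytest.approx(5.0)

    def test_all_zero_track(self, asm):
        out = cpm_normalize(uniform_track(asm, 0.0), 1e6)
        assert out.normalization == "CPM"
        assert np.all(out.values["chr1"] == 0)

    def test_double_normalization_rejected(self, asm):
        out = cpm_normalize(uniform_track(asm, 1.0), 1e6)
        with pytest.raises(ValueError, match="normaliz"):
            cpm_normalize(out, 1e6)


class TestScoreRegions:
    def test_uniform_track_scores_uniform(self, asm):
        tracks = {"m": uniform_track(asm, 3.5)}
        regions = [GenomicInterval("chr1", 130, 470), GenomicInterval("chr2", 0, 8000)]
        m = score_regions(regions, tracks)
        np.testing.assert_allclose(m.scores, 3.5)

    def test_empty_region_list(self, asm):
        m = score_regions([], {"m": uniform_track(asm, 1.0)})
        assert m.scores.shape == (0, 1)

    def test_region_outside_assembly_rejected(self, asm):
        with pytest.raises(ValueError):
            score_regions([GenomicInterval("chrX", 0, 10)], {"m": uniform_track(asm, 1.0)})

    def test_normalization_mismatch_rejected(self, asm):
        tracks = {"a": uniform_track(asm, 1.0), "b": uniform_track(asm, 1.0, normalization="CPM")}
        with pytest.raises(ValueError, match="normaliz"):
            score_regions([GenomicInterval("chr1", 0, 100)], tracks)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_per_base_oracle(self, seed):
        rng = np.random.default_rng(seed)
        chrom_len = int(rng.integers(500, 5_000))
        asm = GenomeAssembly(("chr1", "chr2"), (chrom_len, 1_000))
        bin_size = int(rng.integers(1, 300))
        track = SignalTrack(
            asm, bin_size,
            {c: rng.uniform(0, 10, asm.n_bins(c, bin_size)) for c in asm.chrom_names},
        )
        regions = []
        for _ in range(20):
            start = int(rng.integers(0, chrom_len - 1))
            end = int(rng.integers(start + 1, chrom_len + 1))
            regions.append(GenomicInterval("chr1", start, end))
        m = score_regions(regions, {"m": track})
        per_base = np.repeat(track.values["chr1"], bin_size)[:chrom_len]
        expected = [per_base[r.start : r.end].mean() for r in regions]
        np.testing.assert_allclose(m.scores[:, 0], expected, atol=1e-9)


class TestAverageProfile:
    def test_uniform_track_flat_profile(self, asm):
        track = uniform_track(asm, 2.0)
        regions = [GenomicInterval("chr1", 100, 600), GenomicInterval("chr2", 0, 300)]
        np.testing.assert_allclose(average_profile(track, regions, 0, 25), 2.0)

    def test_single_region_recovers_bin_values(self, asm):
        track = uniform_track(asm, 0.0, bin_size=100)
        track.values["chr1"][1:5] = [1.0, 2.0, 3.0, 4.0]
        region = [GenomicInterval("chr1", 100, 500, "+")]
        np.testing.assert_allclose(
            average_profile(track, region, 0, 4), [1.0, 2.0, 3.0, 4.0]
        )

    def test_strand_flip_reverses_profile(self, asm):
        rng = np.random.default_rng(4)
        track = uniform_track(asm, 0.0, bin_size=50)
        track.values["chr1"] = rng.uniform(0, 5, len(track.values["chr1"]))
        plus = [GenomicInterval("chr1", 200, 1200, "+")]
        minus = [GenomicInterval("chr1", 200, 1200, "-")]
        np.testing.assert_allclose(
            average_profile(track, plus, 100, 20),
            average_profile(track, minus, 100, 20)[::-1],
        )

    def test_symmetric_peak_gives_symmetric_profile(self, asm):
        track = uniform_track(asm, 0.0, bin_size=100)
        track.values["chr1"][10:20] = [1, 2, 3, 4, 5, 5, 4, 3, 2, 1]
        prof = average_profile(track, [GenomicInterval("chr1", 1000, 2000, "+")], 0, 10)
        np.testing.assert_allclose(prof, prof[::-1])

    def test_empty_regions_zero_profile(self, asm):
        np.testing.assert_allclose(average_profile(uniform_track(asm, 9.0), [], 0, 5), 0.0)


def planted_fixture(seed=0, n_regions=200, noise_sd=1.0, separation=8.0):
    patterns = np.array(
        [[1, 1, 1, 1, 0, 1], [1, 1, 0, 0, 0, 0], [0, 0, 1, 1, 1, 0], [0, 0, 0, 0, 1, 1]],
        dtype=float,
    )
    signatures = 3.0 + separation * noise_sd * patterns
    asm = make_genome(2, 2_000_000, seed=seed)
    regions = make_regions(asm, n_regions, 1000, seed=seed + 1, bin_size=100)
    tracks, labels = simulate_tracks(
        asm, regions, 4, signatures, MARKS, noise_sd=noise_sd, seed=seed + 2, bin_size=100
    )
    return score_regions(regions, tracks), labels, regions


class TestClusterRegions:
    def test_k1_everything_is_c1(self):
        matrix, _, _ = planted_fixture()
        assignment = cluster_regions(matrix, k=1)
        assert set(assignment.labels) == {"C1"}

    def test_planted_clusters_fully_recovered(self):
        matrix, labels, _ = planted_fixture()
        assignment = cluster_regions(matrix, k=4, seed=7)
        assert adjusted_rand_score(labels, assignment.as_int()) == 1.0

    def test_c1_has_highest_labeling_mark(self):
        matrix, _, _ = planted_fixture()
        assignment = cluster_regions(matrix, k=4, seed=7)
        means = assignment.cluster_means
        assert means["C1"] == max(means.values())
        assert [means[f"C{i+1}"] for i in range(4)] == sorted(means.values(), reverse=True)

    def test_duplicated_regions_get_identical_labels(self):
        matrix, _, regions = planted_fixture(n_regions=50)
        doubled = EnrichmentMatrix(
            matrix.regions + matrix.regions,
            matrix.marks,
            np.vstack([matrix.scores, matrix.scores]),
        )
        assignment = cluster_regions(doubled, k=4, seed=3)
        n = len(matrix.regions)
        assert assignment.labels[:n] == assignment.labels[n:]

    def test_seed_reproducible_and_stable_across_seeds(self):
        matrix, labels, _ = planted_fixture()
        a = cluster_regions(matrix, k=4, seed=11)
        b = cluster_regions(matrix, k=4, seed=11)
        assert a.labels == b.labels
        for seed in (0, 1, 2, 3):
            other = cluster_regions(matrix, k=4, seed=seed)
            assert adjusted_rand_score(a.as_int(), other.as_int()) >= 0.95

    def test_permuting_regions_permutes_labels(self):
        matrix, _, _ = planted_fixture(n_regions=60)
        perm = np.random.default_rng(2).permutation(60)
        permuted = EnrichmentMatrix(
            [matrix.regions[i] for i in perm], matrix.marks, matrix.scores[perm]
        )
        base = cluster_regions(matrix, k=4, seed=5)
        shuffled = cluster_regions(permuted, k=4, seed=5)
        assert [base.labels[i] for i in perm] == shuffled.labels

    def test_constant_matrix_rejected_with_advice(self, asm):
        regions = [GenomicInterval("chr1", i * 100, i * 100 + 100) for i in range(10)]
        matrix = EnrichmentMatrix(regions, ["H3K27ac"], np.ones((10, 1)))
        with pytest.raises(ValueError, match="k=1"):
            cluster_regions(matrix, k=2)

    def test_k_exceeding_regions_rejected(self):
        matrix, _, _ = planted_fixture(n_regions=3)
        with pytest.raises(ValueError, match="exceeds"):
            cluster_regions(matrix, k=4)

    def test_missing_labeling_mark_rejected(self):
        matrix, _, _ = planted_fixture(n_regions=10)
        with pytest.raises(ValueError, match="labeling mark"):
            cluster_regions(matrix, k=2, labeling_mark="H3K9me3")


class TestCompareConditions:
    def test_identical_tracks_all_zero(self, asm):
        rng = np.random.default_rng(6)
        track = uniform_track(asm, 0.0, normalization="CPM")
        track.values["chr1"] = rng.uniform(0, 100, len(track.values["chr1"]))
        regions = [GenomicInterval("chr1", i * 500, i * 500 + 400) for i in range(10)]
        for pc in (0.1, 1.0, 10.0):
            comp = compare_conditions(regions, track, track, pseudocount=pc)
            np.testing.assert_array_equal(comp.log2_ratios, 0.0)

    def test_doubled_signal_approaches_log2_of_two(self, asm):
        a = uniform_track(asm, 1000.0, normalization="CPM")
        b = uniform_track(asm, 2000.0, normalization="CPM")
        comp = compare_conditions([GenomicInterval("chr1", 0, 1000)], a, b)
        assert comp.log2_ratios[0] == pytest.approx(1.0, abs=2e-3)

    def test_matches_direct_formula(self, asm):
        rng = np.random.default_rng(12)
        a = uniform_track(asm, 0.0, normalization="CPM")
        b = uniform_track(asm, 0.0, normalization="CPM")
        a.values["chr1"] = rng.uniform(0, 50, len(a.values["chr1"]))
        b.values["chr1"] = rng.uniform(0, 50, len(b.values["chr1"]))
        regions = [GenomicInterval("chr1", 0, 100), GenomicInterval("chr1", 300, 1000)]
        comp = compare_conditions(regions, a, b, pseudocount=2.0)
        expected = np.log2((comp.scores_b + 2.0) / (comp.scores_a + 2.0))
        np.testing.assert_allclose(comp.log2_ratios, expected)
        assert comp.mean_log2_ratio == pytest.approx(float(expected.mean()))

    def test_raw_tracks_rejected(self, asm):
        a, b = uniform_track(asm, 1.0), uniform_track(asm, 1.0, normalization="CPM")
        with pytest.raises(ValueError, match="mismatch"):
            compare_conditions([GenomicInterval("chr1", 0, 10)], a, b)
        with pytest.raises(ValueError, match="CPM"):
            compare_conditions([GenomicInterval("chr1", 0, 10)], uniform_track(asm, 1.0), a)
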