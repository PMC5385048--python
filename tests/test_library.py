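import numpy as np
import pytest

from synthnorm import (
    build_bin_grid,
    build_library,
    classify_bins,
    cluster_normals,
    exon_coverage_matrix,
    knn_synthetic,
    mssd,
    read_ratio,
    select_synthetic,
)
from synthnorm.coverage import RatioTrack
from synthnorm.intervals import GenomicInterval
from synthnorm.library import NormalLibrary, SyntheticEntry
from synthnorm.simulate import SimScenario, simulate_normal


def small_scenario(seed=0, **kw):
    kw.setdefault("chrom_lengths", {"chr1": 6_000_000})
    kw.setdefault("truth_segments", [])
    return SimScenario(seed=seed, **kw)


def track_of(rr, grid):
    return RatioTrack(rr=np.asarray(rr, dtype=float), grid=grid)


class TestMssd:
    def test_constant_track_is_zero(self):
        grid = build_bin_grid({"chr1": 400_000}, 100_000)
        assert mssd(track_of([1, 1, 1, 1], grid)).value == 0.0

    def test_direct_evaluation(self):
        grid = build_bin_grid({"chr1": 300_000}, 100_000)
        s = mssd(track_of([1, 2, 1], grid))
        assert s.value == pytest.approx(1.0)
        assert s.n_pairs == 2

    def test_pairs_confined_to_chromosomes(self):
        grid = build_bin_grid({"chr1": 200_000, "chr2": 200_000}, 100_000)
        s = mssd(track_of([0, 1, 0, 1], grid))
        assert s.value == pytest.approx(1.0)
        assert s.n_pairs == 2

    def test_no_pairs_is_an_error(self):
        grid = build_bin_grid({"chr1": 300_000}, 100_000)
        with pytest.raises(ValueError, match="insufficient bins"):
            mssd(track_of([1, np.nan, 2], grid))

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(42)
        grid = build_bin_grid({"chr1": 2_500_000, "chr2": 2_500_000}, 100_000)
        for _ in range(30):
            rr = rng.lognormal(0, 0.3, grid.n_bins)
            rr[rng.random(grid.n_bins) < 0.2] = np.nan
            # brute force: explicit double loop over chromosomes and positions
            sq, n = 0.0, 0
            for chrom in grid.chroms:
                sl = grid.chrom_slice(chrom)
                vals = rr[sl]
                for i in range(len(vals) - 1):
                    if not (np.isnan(vals[i]) or np.isnan(vals[i + 1])):
                        sq += (vals[i + 1] - vals[i]) ** 2
                        n += 1
            if n == 0:
                continue
            s = mssd(track_of(rr, grid))
            assert s.n_pairs == n
            assert s.value == pytest.approx(sq / n)


class TestClusterNormals:
    def test_planted_protocols_separate_exactly(self):
        sc = small_scenario(seed=3, protocol_dropout_fraction=0.2)
        grid = sc.build_grid()
        normals = [simulate_normal(sc, i, grid) for i in range(12)]
        labels = cluster_normals(exon_coverage_matrix(normals, grid), 2)
        protocols = np.array([i % 2 for i in range(12)])
        agree = (labels == protocols).mean()
        assert agree in (0.0, 1.0)  # exact partition up to label swap

    def test_single_cluster(self):
        sc = small_scenario(seed=0)
        grid = sc.build_grid()
        normals = [simulate_normal(sc, i, grid) for i in range(4)]
        labels = cluster_normals(exon_coverage_matrix(normals, grid), 1)
        assert set(labels) == {0}

    def test_more_clusters_than_samples_rejected(self):
        sc = small_scenario(seed=0)
        grid = sc.build_grid()
        normals = [simulate_normal(sc, i, grid) for i in range(3)]
        with pytest.raises(ValueError, match="exceeds"):
            cluster_normals(exon_coverage_matrix(normals, grid), 4)

    def test_deterministic_on_identical_samples(self):
        sc = small_scenario(seed=0)
        grid = sc.build_grid()
        base = simulate_normal(sc, 0, grid)
        import copy

        normals = [copy.deepcopy(base) for _ in range(4)]
        for i, p in enumerate(normals):
            p.sample_id = f"n{i}"
        l1 = cluster_normals(exon_coverage_matrix(normals, grid), 2)
        l2 = cluster_normals(exon_coverage_matrix(normals, grid), 2)
        np.testing.assert_array_equal(l1, l2)

    def test_top_variance_selection_bounded(self):
        sc = small_scenario(seed=0)
        grid = sc.build_grid()
        normals = [simulate_normal(sc, i, grid) for i in range(4)]
        m = exon_coverage_matrix(normals, grid, top_variance_k=5)
        assert m.values.shape == (4, 5)
        # retained columns have maximal variance and are mean-centred
        np.testing.assert_allclose(m.values.mean(axis=0), 0, atol=1e-12)


def _manual_profile(grid, counts, sample_id, ls, fe):
    from synthnorm.coverage import CoverageProfile

    p = CoverageProfile(
        sample_id=sample_id, role="normal", counts=np.asarray(counts, dtype=float),
        library_size=ls, grid=grid, fold_enrichment=fe,
    )
    return p


class TestBuildLibrary:
    def _grid(self):
        grid = build_bin_grid({"chr1": 600_000}, 100_000)
        return classify_bins(grid, [GenomicInterval("chr1", 0, 600_000)])

    def test_nine_singletons_preserved(self):
        grid = self._grid()
        rng = np.random.default_rng(0)
        normals = []
        for i in range(9):
            counts = rng.integers(100, 200, grid.n_bins).astype(float)
            ls = float(1e6 * (1 + i // 3))
            fe = float(1 + i % 3)
            normals.append(_manual_profile(grid, counts, f"n{i}", ls, fe))
        lib = build_library(normals, grid, n_clusters=1, grid_spec=(3, 3), min_members=1)
        assert len(lib) == 9
        by_member = {e.members[0]: e for e in lib.entries if len(e.members) == 1}
        for p in normals:
            np.testing.assert_allclose(by_member[p.sample_id].profile.counts, p.counts)

    def test_mean_of_identical_members(self):
        grid = self._grid()
        counts = np.full(grid.n_bins, 50.0)
        normals = [
            _manual_profile(grid, counts, f"n{i}", 1e6, 2.0) for i in range(2)
        ]
        lib = build_library(normals, grid, n_clusters=1, grid_spec=(1, 1), min_members=1)
        assert len(lib) == 1
        np.testing.assert_allclose(lib.entries[0].profile.counts, counts)

    def test_provenance_partitions_the_pool(self):
        sc = small_scenario(seed=5)
        grid = sc.build_grid()
        normals = [simulate_normal(sc, i, grid) for i in range(12)]
        lib = build_library(normals, grid, n_clusters=2, grid_spec=(2, 2), min_members=3)
        assert len(lib) <= 8
        all_members = [m for e in lib.entries for m in e.members]
        assert sorted(all_members) == sorted(p.sample_id for p in normals)

    def test_zero_normals_rejected(self):
        grid = self._grid()
        with pytest.raises(ValueError, match="zero normals"):
            build_library([], grid)


class TestSelectSynthetic:
    def test_identical_synthetic_has_zero_mssd(self, profile_factory):
        grid = build_bin_grid({"chr1": 500_000}, 100_000)
        counts = np.full(5, 1000.0)
        tumor = profile_factory(grid, counts, sample_id="t", role="tumor")
        tumor.fold_enrichment = 1.0
        synth = profile_factory(grid, counts, sample_id="syn", role="synthetic")
        entry = SyntheticEntry(
            cluster=0, cell=(0, 0), ls_range=(0, 1e9), fe_range=(0, 10),
            profile=synth, members=["n0"],
        )
        lib = NormalLibrary(entries=[entry], cluster_labels={"n0": 0}, grid=grid)
        prof, score = select_synthetic(tumor, lib, min_normal_count=1)
        assert prof.sample_id == "syn"
        assert score.value == 0.0

    def test_tie_breaks_to_smallest_cluster(self, profile_factory):
        grid = build_bin_grid({"chr1": 500_000}, 100_000)
        counts = np.full(5, 1000.0)
        tumor = profile_factory(grid, counts, sample_id="t", role="tumor")
        tumor.fold_enrichment = 1.0
        entries = []
        for cl in (1, 0):  # deliberately out of order
            synth = profile_factory(grid, counts, sample_id=f"syn{cl}", role="synthetic")
            entries.append(
                SyntheticEntry(cl, (0, 0), (0, 1e9), (0, 10), synth, [f"n{cl}"])
            )
        lib = NormalLibrary(entries=entries, cluster_labels={}, grid=grid)
        prof, _ = select_synthetic(tumor, lib, min_normal_count=1)
        assert prof.sample_id == "syn0"

    def test_planted_protocol_recovered(self):
        from synthnorm.simulate import simulate_tumor

        sc = small_scenario(seed=7, protocol_dropout_fraction=0.2)
        grid = sc.build_grid()
        normals = [simulate_normal(sc, i, grid) for i in range(16)]
        tumor, _, _ = simulate_tumor(sc, matched_protocol=0, grid=grid, with_maf=False)
        lib = build_library(normals, grid, n_clusters=2)
        prof, score = select_synthetic(tumor, lib)
        members = next(e.members for e in lib.entries if e.profile.sample_id == prof.sample_id)
        protos = [int(m.replace("normal", "")) % 2 for m in members]
        assert np.mean(protos) < 0.5  # majority from the tumor's protocol


class TestKnnSynthetic:
    def test_generating_normal_wins_at_k1(self, profile_factory):
        grid = build_bin_grid({"chr1": 4_000_000}, 100_000)
        rng = np.random.default_rng(1)
        rates = rng.lognormal(np.log(5000), 0.4, grid.n_bins)
        tumor = profile_factory(grid, rng.poisson(rates), sample_id="t", role="tumor")
        generating = profile_factory(grid, rates, sample_id="gen")
        others = [
            profile_factory(
                grid, rng.poisson(rng.lognormal(np.log(5000), 0.4, grid.n_bins)),
                sample_id=f"o{i}",
            )
            for i in range(6)
        ]
        out = knn_synthetic(tumor, [*others[:3], generating, *others[3:]], k=1,
                            min_normal_count=1)
        assert out.meta["members"] == ["gen"]

    def test_median_of_identical_normals(self, profile_factory):
        grid = build_bin_grid({"chr1": 500_000}, 100_000)
        counts = np.array([10.0, 20, 30, 40, 50])
        tumor = profile_factory(grid, counts * 2, sample_id="t", role="tumor")
        normals = [profile_factory(grid, counts, sample_id=f"n{i}") for i in range(3)]
        out = knn_synthetic(tumor, normals, k=3, min_normal_count=1)
        np.testing.assert_allclose(out.counts, counts)

    def test_k_equals_pool_is_whole_pool_median(self, profile_factory):
        grid = build_bin_grid({"chr1": 500_000}, 100_000)
        rng = np.random.default_rng(2)
        tumor = profile_factory(grid, rng.integers(50, 150, 5), role="tumor")
        normals = [
            profile_factory(grid, rng.integers(50, 150, 5), sample_id=f"n{i}")
            for i in range(5)
        ]
        out = knn_synthetic(tumor, normals, k=5, min_normal_count=1)
        norm = np.stack([p.counts / p.library_size for p in normals])
        expected = np.median(norm, axis=0) * np.mean([p.library_size for p in normals])
        np.testing.assert_allclose(out.counts, expected)

    def test_k_exceeding_pool_rejected(self, profile_factory):
        grid = build_bin_grid({"chr1": 200_000}, 100_000)
        tumor = profile_factory(grid, [1, 1], role="tumor")
        with pytest.raises(ValueError, match="exceeds"):
            knn_synthetic(tumor, [tumor], k=2)
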