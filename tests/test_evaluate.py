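import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from synthnorm import build_bin_grid, frequency_landscape, gene_concordance, overlap_stats
from synthnorm.calling import SegmentCall
from synthnorm.cbs import Segment
from synthnorm.evaluate import (
    altered_intervals,
    direction_aware_stats,
    intersect_intervals,
    merge_intervals,
    percent_overlap,
    subtract_intervals,
    total_length,
)
from synthnorm.intervals import GenomicInterval


def iv(s, e, chrom="chr1"):
    return GenomicInterval(chrom, s, e)


def per_base_oracle(calls, truth, space, length=10_000):
    """Confusion matrix over individual bases."""
    def mask(ivs):
        m = np.zeros(length, dtype=bool)
        for i in ivs:
            m[i.start : i.end] = True
        return m

    c, t, s = mask(calls), mask(truth), mask(space)
    c, t = c & s, t & s
    inter = (c & t).sum()
    union = (c | t).sum()
    tn = (s & ~c & ~t).sum()
    not_t = (s & ~t).sum()
    return (
        inter / union if union else 1.0,
        inter / t.sum() if t.sum() else 1.0,
        tn / not_t if not_t else 1.0,
    )


class TestIntervalOps:
    @given(
        spans=st.lists(
            st.tuples(st.integers(0, 95), st.integers(1, 30)), min_size=0, max_size=8
        )
    )
    def test_merge_matches_per_base_cover(self, spans):
        ivs = [iv(s, min(s + ln, 100)) for s, ln in spans]
        merged = merge_intervals(ivs) if ivs else []
        cover = np.zeros(100, dtype=bool)
        for i in ivs:
            cover[i.start : i.end] = True
        got = np.zeros(100, dtype=bool)
        for m in merged:
            got[m.start : m.end] = True
        assert (got == cover).all()
        # disjoint and sorted
        for a, b in zip(merged, merged[1:]):
            assert a.end < b.start or a.chrom != b.chrom

    @given(
        a=st.lists(st.tuples(st.integers(0, 95), st.integers(1, 30)), max_size=5),
        b=st.lists(st.tuples(st.integers(0, 95), st.integers(1, 30)), max_size=5),
    )
    def test_intersect_and_subtract_match_per_base(self, a, b):
        ia = [iv(s, min(s + ln, 100)) for s, ln in a]
        ib = [iv(s, min(s + ln, 100)) for s, ln in b]
        ca = np.zeros(100, dtype=bool)
        cb = np.zeros(100, dtype=bool)
        for i in ia:
            ca[i.start : i.end] = True
        for i in ib:
            cb[i.start : i.end] = True
        if ia and ib:
            assert total_length(intersect_intervals(ia, ib)) == (ca & cb).sum()
        if ia:
            assert total_length(subtract_intervals(ia, ib)) == (ca & ~cb).sum()


class TestOverlapStats:
    def test_perfect_agreement(self):
        r = overlap_stats([iv(0, 100)], [iv(0, 100)], [iv(0, 200)])
        assert (r.jaccard, r.sensitivity, r.specificity) == (1.0, 1.0, 1.0)

    def test_half_shifted_call(self):
        r = overlap_stats([iv(50, 150)], [iv(0, 100)], [iv(0, 200)])
        assert r.jaccard == pytest.approx(50 / 150)
        assert r.sensitivity == pytest.approx(0.5)
        assert r.specificity == pytest.approx(0.5)

    def test_empty_calls(self):
        r = overlap_stats([], [iv(0, 100)], [iv(0, 200)])
        assert (r.jaccard, r.sensitivity, r.specificity) == (0.0, 0.0, 1.0)

    def test_both_empty(self):
        r = overlap_stats([], [], [iv(0, 200)])
        assert (r.jaccard, r.sensitivity, r.specificity) == (1.0, 1.0, 1.0)

    def test_interval_outside_space_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            overlap_stats([iv(150, 250)], [], [iv(0, 200)])

    def test_matches_per_base_oracle_on_random_cases(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            space = merge_intervals(
                [iv(int(s), int(s) + int(l))
                 for s, l in zip(rng.integers(0, 8000, 3), rng.integers(200, 2000, 3))]
            )

            def sample_inside():
                out = []
                for sp in space:
                    for _ in range(rng.integers(0, 3)):
                        s = int(rng.integers(sp.start, sp.end))
                        e = min(int(s + rng.integers(1, 800)), sp.end)
                        if s < e:
                            out.append(iv(s, e))
                return out

            calls, truth = sample_inside(), sample_inside()
            r = overlap_stats(calls, truth, space)
            ji, sens, spec = per_base_oracle(calls, truth, space)
            assert r.jaccard == pytest.approx(ji, abs=1e-12)
            assert r.sensitivity == pytest.approx(sens, abs=1e-12)
            assert r.specificity == pytest.approx(spec, abs=1e-12)

    def test_jaccard_symmetry(self):
        a, b, sp = [iv(0, 120)], [iv(60, 180)], [iv(0, 300)]
        assert overlap_stats(a, b, sp).jaccard == overlap_stats(b, a, sp).jaccard


def call_of(s, e, direction, chrom="chr1"):
    seg = Segment(interval=iv(s, e, chrom), n_bins=1, mean_log2=0.0, p_value=1.0,
                  bin_indices=np.array([0]))
    return SegmentCall(segment=seg, integer_cn=2, posterior=1.0, direction=direction)


class TestDirectionAwareStats:
    def test_direction_mismatch_scores_zero_sensitivity(self):
        out = direction_aware_stats(
            [call_of(0, 100, -1)], [call_of(0, 100, 1)], [iv(0, 200)]
        )
        assert out["gain"].sensitivity == 0.0

    def test_identical_labelled_sets(self):
        calls = [call_of(0, 100, 1), call_of(120, 160, -1)]
        out = direction_aware_stats(calls, calls, [iv(0, 200)])
        assert out["gain"].jaccard == 1.0 and out["loss"].jaccard == 1.0

    def test_decomposes_into_per_direction_overlap(self):
        calls = [call_of(0, 80, 1), call_of(100, 150, -1)]
        truth = [call_of(40, 120, 1)]
        out = direction_aware_stats(calls, truth, [iv(0, 200)])
        direct = overlap_stats(
            altered_intervals(calls, 1), altered_intervals(truth, 1), [iv(0, 200)]
        )
        assert out["gain"].jaccard == direct.jaccard


class TestGeneConcordance:
    def _matrix(self, data, samples=20):
        return pd.DataFrame(
            data, index=[f"g{i}" for i in range(len(data))],
            columns=[f"s{j}" for j in range(samples)],
        )

    def test_identical_matrices_fully_concordant(self):
        rng = np.random.default_rng(0)
        a = self._matrix(rng.choice([-1, 0, 1], size=(10, 20)))
        table, discordant = gene_concordance(a, a.copy())
        assert discordant == []
        assert (table["p"] == 1.0).all()
        assert percent_overlap(table) == 100.0

    def test_systematically_flipped_gene_detected(self):
        rng = np.random.default_rng(1)
        a = self._matrix(rng.choice([-1, 0, 1], size=(10, 20)))
        b = a.copy()
        b.iloc[0] = 1
        a.iloc[0] = -1
        table, discordant = gene_concordance(a, b, fdr=0.05)
        assert "g0" in discordant
        assert len(discordant) == 1

    def test_symmetric_under_matrix_exchange(self):
        rng = np.random.default_rng(2)
        a = self._matrix(rng.choice([-1, 0, 1], size=(6, 20)))
        b = self._matrix(rng.choice([-1, 0, 1], size=(6, 20)))
        ta, _ = gene_concordance(a, b)
        tb, _ = gene_concordance(b, a)
        np.testing.assert_allclose(ta["p"], tb["p"])

    def test_mismatched_dimensions_rejected(self):
        a = self._matrix(np.zeros((3, 20)))
        b = self._matrix(np.zeros((4, 20)))
        with pytest.raises(ValueError, match="share"):
            gene_concordance(a, b)

    def test_too_few_samples_rejected(self):
        a = self._matrix(np.zeros((3, 4)), samples=4)
        with pytest.raises(ValueError, match=">= 6"):
            gene_concordance(a, a.copy())


class TestFrequencyLandscape:
    def _cohort_calls(self, grid, directions_per_sample):
        cohort = []
        for dirs in directions_per_sample:
            calls = []
            for b, d in enumerate(dirs):
                seg = Segment(
                    interval=grid.interval_of(b), n_bins=1, mean_log2=0.0,
                    p_value=1.0, bin_indices=np.array([b]),
                )
                calls.append(SegmentCall(segment=seg, integer_cn=2, posterior=1.0,
                                         direction=d))
            cohort.append(calls)
        return cohort

    def test_unanimous_gain(self):
        grid = build_bin_grid({"chr1": 200_000}, 100_000)
        fl = frequency_landscape(self._cohort_calls(grid, [[1, 0]] * 4), grid)
        assert fl.gain_freq[0] == 1.0 and fl.loss_freq[0] == 0.0

    def test_quarter_loss(self):
        grid = build_bin_grid({"chr1": 100_000}, 100_000)
        fl = frequency_landscape(self._cohort_calls(grid, [[-1], [0], [0], [0]]), grid)
        assert fl.loss_freq[0] == 0.25

    def test_unsegmented_bin_reports_zero(self):
        grid = build_bin_grid({"chr1": 200_000}, 100_000)
        cohort = self._cohort_calls(grid, [[1]])  # second bin never covered
        fl = frequency_landscape(cohort, grid)
        assert fl.gain_freq[1] == 0.0 and fl.loss_freq[1] == 0.0

    def test_empty_cohort_rejected(self):
        grid = build_bin_grid({"chr1": 100_000}, 100_000)
        with pytest.raises(ValueError):
            frequency_landscape([], grid)
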