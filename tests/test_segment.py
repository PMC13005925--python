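import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from _oracles import oracle_cbs

from ridgecnv.segment import (
    CbsParams,
    PresegConfig,
    SmootherConfig,
    _cbs_chrom,
    cbs_segment,
    kernel_weights,
    max_arc_statistic,
    presegment_zscore,
    segment_profile,
    smooth_segment,
)


# ---------------------------------------------------------------------------
# pre-segmentation
# ---------------------------------------------------------------------------


class TestPresegment:
    def test_constant_profile_single_segment_per_chrom(self, profile_factory):
        prof, panel = profile_factory(np.zeros(40), n_per_chrom=20, chroms=("chr1", "chr2"))
        segs = presegment_zscore(prof, panel)
        assert len(segs) == 2
        assert [s.chrom for s in segs] == ["chr1", "chr2"]
        assert all(s.n_targets == 20 for s in segs)

    def test_threshold_boundary_with_floored_sd(self, profile_factory):
        # window of constant 1.0 (sd 0) floored at min_sd=0.05:
        # x = 1.15 gives z = 3.0 exactly -> NOT a breakpoint; 1.151 is
        cfg = PresegConfig(z_thresh=3.0, min_sd=0.05, min_window=5)
        prof, panel = profile_factory(np.array([1.0] * 8 + [1.15]))
        assert len(presegment_zscore(prof, panel, cfg)) == 1
        prof2, panel2 = profile_factory(np.array([1.0] * 8 + [1.151]))
        segs = presegment_zscore(prof2, panel2, cfg)
        assert len(segs) == 2
        # the triggering point begins the NEW segment
        assert segs[1].first_index == 8 and segs[1].n_targets == 1

    def test_stats_reset_after_breakpoint(self, profile_factory):
        # after the jump the window restarts; the second level is one segment
        v = np.array([0.0] * 10 + [2.0] * 10)
        prof, panel = profile_factory(v)
        segs = presegment_zscore(prof, panel)
        assert [s.n_targets for s in segs] == [10, 10]
        assert segs[1].mean_log2 == pytest.approx(2.0)

    def test_step_located_accurately_under_noise(self, profile_factory):
        cfg = PresegConfig(z_thresh=3.0, min_sd=0.05, min_window=5)
        hits = 0
        for seed in range(100):
            rng = np.random.default_rng(1000 + seed)
            v = np.concatenate([np.zeros(50), np.full(50, 2.0)]) + rng.normal(0, 0.1, 100)
            prof, panel = profile_factory(v)
            segs = presegment_zscore(prof, panel, cfg)
            starts = [s.first_index for s in segs]
            hits += any(abs(s - 50) <= 2 for s in starts)
        assert hits >= 95

    def test_empty_profile_not_an_error(self, profile_factory):
        prof, panel = profile_factory(np.zeros(5))
        segs = presegment_zscore(prof, panel)
        assert len(segs) == 1


# ---------------------------------------------------------------------------
# kernel smoothing
# ---------------------------------------------------------------------------


class TestKernel:
    def test_single_target(self):
        assert np.allclose(kernel_weights(np.array([123.0])), [[1.0]])

    def test_two_targets_rows_mirror(self):
        W = kernel_weights(np.array([0.0, 100.0]))
        assert np.allclose(W.sum(axis=1), 1.0)
        assert W[0, 0] == pytest.approx(W[1, 1])
        assert W[0, 1] == pytest.approx(W[1, 0])

    def test_three_equally_spaced_hand_oracle(self):
        # coords 0,100,200: lambda = 200/4 + 1 = 51
        lam = 51.0
        e = np.exp(-100.0 / lam)
        e2 = np.exp(-200.0 / lam)
        expected = np.array(
            [[1.0, e, e2], [e, 1.0, e], [e2, e, 1.0]]
        )
        expected /= expected.sum(axis=1, keepdims=True)
        W = kernel_weights(np.array([0.0, 100.0, 200.0]))
        assert np.allclose(W, expected)

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(
        st.lists(
            st.floats(min_value=0.0, max_value=1e8, allow_nan=False),
            min_size=1,
            max_size=25,
        )
    )
    def test_rows_always_sum_to_one(self, coords):
        W = kernel_weights(np.array(coords))
        assert np.all(W > 0)
        assert np.allclose(W.sum(axis=1), 1.0)


class TestSmoother:
    def test_alpha_zero_is_identity(self, rng):
        v = rng.normal(size=12)
        W = kernel_weights(np.arange(12.0) * 500)
        out = smooth_segment(v, W, SmootherConfig(alpha_smooth=0.0))
        assert np.array_equal(out, v)

    def test_full_smoothing_preserves_constants(self):
        W = kernel_weights(np.arange(8.0) * 100)
        out = smooth_segment(np.full(8, 3.3), W, SmootherConfig(alpha_smooth=1.0))
        assert np.allclose(out, 3.3)

    def test_mean_preserved_on_two_point_fixture(self, rng):
        # two targets: the kernel matrix is symmetric and doubly
        # stochastic by distance symmetry, so full smoothing keeps the mean
        v = rng.normal(size=2)
        W = kernel_weights(np.array([0.0, 700.0]))
        out = smooth_segment(v, W, SmootherConfig(alpha_smooth=1.0))
        assert out.mean() == pytest.approx(v.mean(), abs=1e-12)

    def test_smoothing_contracts_toward_local_average(self, rng):
        v = rng.normal(size=30)
        W = kernel_weights(np.arange(30.0) * 200)
        out = smooth_segment(v, W, SmootherConfig(alpha_smooth=0.5))
        assert out.std() < v.std()


# ---------------------------------------------------------------------------
# circular binary segmentation
# ---------------------------------------------------------------------------


class TestCbs:
    def test_flat_profile_single_segment(self, profile_factory):
        prof, panel = profile_factory(np.zeros(30))
        segs = cbs_segment(prof, panel, seed=0)
        assert len(segs) == 1
        assert segs[0].n_targets == 30

    def test_single_step_found_exactly(self, profile_factory, rng):
        v = np.concatenate([np.zeros(15), np.full(15, 2.0)]) + rng.normal(0, 0.1, 30)
        prof, panel = profile_factory(v)
        segs = cbs_segment(prof, panel, seed=1)
        assert [s.first_index for s in segs] == [0, 15]
        # breakpoint equals the argmax of an exhaustive single-change scan
        best = max(
            range(2, 29),
            key=lambda k: abs(v[:k].mean() - v[k:].mean())
            / np.sqrt(1.0 / k + 1.0 / (30 - k)),
        )
        assert best == 15

    def test_nested_steps_three_segments(self, profile_factory):
        rng = np.random.default_rng(7)
        v = np.concatenate([np.zeros(20), np.ones(20), np.zeros(20)])
        v = v + rng.normal(0, 0.08, 60)
        prof, panel = profile_factory(v)
        segs = cbs_segment(prof, panel, seed=2)
        assert [s.first_index for s in segs] == [0, 20, 40]
        means = [s.mean_log2 for s in segs]
        assert means[0] == pytest.approx(0.0, abs=0.1)
        assert means[1] == pytest.approx(1.0, abs=0.1)
        assert means[2] == pytest.approx(0.0, abs=0.1)

    @pytest.mark.parametrize("case", range(6))
    def test_matches_exhaustive_oracle(self, case):
        """CBS on n <= 40 equals the brute-force oracle under a shared
        permutation seed (early stopping disabled on both sides)."""
        rng = np.random.default_rng(900 + case)
        n = int(rng.integers(12, 41))
        v = rng.normal(0, 0.15, n)
        if case % 3 == 1:
            a, b = sorted(rng.integers(2, n - 2, 2))
            v[a:b] += rng.choice([-1.0, 1.0]) * rng.uniform(0.5, 1.5)
        elif case % 3 == 2:
            v[: n // 3] += 0.9
        params = CbsParams(alpha=0.05, nperm=200, early_stop=False)
        got = _cbs_chrom(v, np.random.default_rng(55), params)
        want = oracle_cbs(v, 55, params)
        assert got == want

    def test_min_width_respected(self, profile_factory, rng):
        v = rng.normal(0, 0.1, 40)
        v[17] += 5.0  # single-point outlier
        prof, panel = profile_factory(v)
        segs = cbs_segment(prof, panel, CbsParams(min_width=2), seed=3)
        assert all(s.n_targets >= 2 for s in segs)

    def test_deterministic_under_seed(self, profile_factory, rng):
        v = rng.normal(0, 0.3, 50)
        v[10:30] += 1.0
        prof, panel = profile_factory(v)
        a = cbs_segment(prof, panel, seed=7).to_dataframe()
        b = cbs_segment(prof, panel, seed=7).to_dataframe()
        assert a.equals(b)


class TestSegmentProfile:
    def test_identity_chain_on_constant(self, profile_factory):
        prof, panel = profile_factory(np.full(25, 0.4))
        final, smoothed, preseg = segment_profile(prof, panel, seed=0)
        assert len(final) == 1
        assert final[0].mean_log2 == pytest.approx(0.4)
        assert np.allclose(smoothed.values, 0.4)

    def test_partition_covers_all_targets_once(self, profile_factory, rng):
        v = rng.normal(0, 0.2, 80)
        v[30:50] += 1.2
        prof, panel = profile_factory(v, n_per_chrom=40, chroms=("chr1", "chr2"))
        final, _, _ = segment_profile(prof, panel, seed=4)
        covered = []
        for s in final:
            covered.extend(range(s.first_index, s.last_index + 1))
        assert sorted(covered) == list(range(80))
        # segments are ordered and non-overlapping within chromosomes
        for a, b in zip(final, list(final)[1:]):
            if a.chrom == b.chrom:
                assert b.first_index == a.last_index + 1

    def test_event_recovered_at_full_purity(self, profile_factory, rng):
        v = rng.normal(0, 0.2, 60)
        v[20:40] += 1.0  # CN 4 at purity 1
        prof, panel = profile_factory(v)
        final, _, _ = segment_profile(prof, panel, seed=5)
        hit = [
            s for s in final
            if min(40, s.last_index + 1) - max(20, s.first_index)
            >= 0.5 * max(20, s.n_targets)
        ]
        assert hit and hit[0].mean_log2 == pytest.approx(1.0, abs=0.15)

    def test_low_purity_event_mean(self, profile_factory, rng):
        shift = np.log2(1.2)  # CN 4 at purity 0.2
        v = rng.normal(0, 0.05, 60)
        v[20:40] += shift
        prof, panel = profile_factory(v)
        final, _, _ = segment_profile(prof, panel, seed=6)
        hit = [
            s for s in final
            if min(40, s.last_index + 1) - max(20, s.first_index)
            >= 0.5 * max(20, s.n_targets)
        ]
        assert hit and hit[0].mean_log2 == pytest.approx(shift, abs=0.15)

    def test_detection_rate_monotone_in_amplitude(self, profile_factory):
        rates = []
        for amp in [0.15, 0.4, 0.8, 1.6]:
            found = 0
            for rep in range(10):
                rng = np.random.default_rng(40_000 + rep)  # same noise per amp
                v = rng.normal(0, 0.25, 80)
                v[30:50] += amp
                prof, panel = profile_factory(v)
                final, _, _ = segment_profile(prof, panel, seed=rep)
                found += any(
                    min(50, s.last_index + 1) - max(30, s.first_index)
                    >= 0.5 * max(20, s.n_targets)
                    and s.mean_log2 > amp / 2
                    for s in final
                )
            rates.append(found)
        assert all(a <= b for a, b in zip(rates, rates[1:]))


def test_max_arc_statistic_trivia():
    t, pair = max_arc_statistic(np.zeros(10))
    assert t == 0.0
    t, pair = max_arc_statistic(np.array([0.0, 0, 0, 5, 5, 0, 0, 0]))
    assert pair == (3, 5)
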