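"""Remove-and-redecompose causality: distances, ratios, profiles, validation."""

import numpy as np
import pytest

from causaldecomp import (
    EEMDParams,
    TimeSeries,
    absolute_strengths,
    causal_profile,
    eemd,
    leave_one_out,
    legacy_component_index,
    redecompose_without,
    relative_strength_pair,
    relative_strengths,
    weighted_coherence_distance,
    white_noise_pairs,
)


class TestDistanceAndRatio:
    def test_weighted_distance_hand_case(self):
        # m=2, W={0.5,0.5}, base={0.9,0.8}, after={0.5,0.8}
        d = weighted_coherence_distance([0.5, 0.5], [0.9, 0.8], [0.5, 0.8])
        assert d == pytest.approx(np.sqrt(0.5 * 0.16))

    def test_identical_profiles_give_zero_distance(self):
        base = np.array([0.9, 0.3, 0.5])
        assert weighted_coherence_distance(np.full(3, 1 / 3), base, base) == 0.0

    @pytest.mark.parametrize("d_ab,d_ba,expected", [
        (0.3, 0.1, 0.75),                 # plain ratio
        (0.0, 0.0, 0.5),                  # both zero -> (D+1) rule
        (0.04, 0.02, 1.04 / 2.06),        # both below 0.05 -> (D+1) rule
        (0.05, 0.0, 1.0),                 # one at threshold -> plain ratio
    ])
    def test_relative_strength_rules(self, d_ab, d_ba, expected):
        c_ab, c_ba = relative_strength_pair(d_ab, d_ba)
        assert c_ab == pytest.approx(expected)
        assert c_ab + c_ba == pytest.approx(1.0, abs=1e-12)

    def test_strengths_sum_to_one_generally(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            c_ab, c_ba = relative_strength_pair(*rng.uniform(0, 1, 2))
            assert c_ab + c_ba == pytest.approx(1.0, abs=1e-12)
            assert 0.0 <= c_ab <= 1.0


@pytest.fixture(scope="module")
def tone_decomp(two_tone):
    params = EEMDParams(noise_level=0.1, ensemble_size=100)
    return params, eemd(two_tone, 0.1, 100, seed=3)


@pytest.fixture(scope="module")
def noisy_pair():
    rng = np.random.default_rng(11)
    t = np.arange(300.0)
    base = np.sin(2 * np.pi * t / 16)
    a = TimeSeries(base + 0.5 * rng.standard_normal(300), "a")
    b = TimeSeries(base + 0.5 * rng.standard_normal(300), "b")
    return a, b


class TestRedecomposition:
    def test_remainder_reconstruction(self, two_tone, tone_decomp):
        params, d = tone_decomp
        rd = redecompose_without(two_tone, d, 1, params, seed=9)
        target = two_tone.values - d.imfs[0]
        tol = 10 * params.noise_level * np.std(target) / np.sqrt(params.ensemble_size)
        assert np.abs(rd.reconstruction() - target).max() < tol
        assert rd.n_imfs == d.n_imfs

    def test_removed_tone_energy_does_not_reappear(self, two_tone, tone_decomp):
        # removing the fast-tone IMF: the redecomposed first component must
        # not recreate the period-8 oscillation
        params, d = tone_decomp
        rd = redecompose_without(two_tone, d, 1, params, seed=9)

        def band_energy(s, period, width=0.02):
            f = np.fft.rfftfreq(s.size)
            p = np.abs(np.fft.rfft(s)) ** 2
            return p[np.abs(f - 1 / period) < width].sum()

        assert band_energy(rd.imfs[0], 8) < 0.1 * band_energy(d.imfs[0], 8)

    def test_invalid_index_rejected(self, two_tone, tone_decomp):
        params, d = tone_decomp
        with pytest.raises(ValueError, match="outside"):
            redecompose_without(two_tone, d, 0, params)
        with pytest.raises(ValueError, match="outside"):
            redecompose_without(two_tone, d, d.n_imfs + 1, params)


class TestCausalStrengths:
    def test_weights_normalised(self, noisy_pair, fast_params):
        a, b = noisy_pair
        da = eemd(a, 0.15, 50, seed=1)
        db = eemd(b, 0.15, 50, seed=2)
        res = absolute_strengths(a, b, da, db, 1, fast_params, 3, 4)
        assert res.weights.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.all(res.weights >= 0.0)

    def test_swap_antisymmetry_with_mirrored_seeds(self, noisy_pair, fast_params):
        a, b = noisy_pair
        da = eemd(a, 0.15, 50, seed=1)
        db = eemd(b, 0.15, 50, seed=2)
        fwd = absolute_strengths(a, b, da, db, 2, fast_params, 30, 40)
        rev = absolute_strengths(b, a, db, da, 2, fast_params, 40, 30)
        assert fwd.d_ab == pytest.approx(rev.d_ba, abs=1e-12)
        assert fwd.d_ba == pytest.approx(rev.d_ab, abs=1e-12)
        cf, cr = relative_strengths(fwd), relative_strengths(rev)
        assert cf.c_ab == pytest.approx(cr.c_ba, abs=1e-12)

    def test_identical_series_are_symmetric(self, fast_params):
        rng = np.random.default_rng(5)
        a = TimeSeries(np.sin(2 * np.pi * np.arange(200) / 12)
                       + 0.3 * rng.standard_normal(200))
        d = eemd(a, 0.15, 50, seed=7)
        # same decomposition and same removal stream on both sides:
        # the procedure is exactly symmetric
        res = relative_strengths(absolute_strengths(a, a, d, d, 1, fast_params, 9, 9))
        assert res.d_ab == res.d_ba
        assert res.c_ab == pytest.approx(0.5, abs=1e-12)

    def test_degenerate_weights_rejected(self, fast_params):
        from causaldecomp import IMFSet
        flat = IMFSet(imfs=np.zeros((2, 64)), residual=np.zeros(64))
        a = TimeSeries(np.zeros(64) + 1.0)
        with pytest.raises(ValueError, match="degenerate"):
            absolute_strengths(a, a, flat, flat, 1, fast_params)

    def test_single_pair_distance_mode(self, noisy_pair, fast_params):
        a, b = noisy_pair
        da = eemd(a, 0.15, 50, seed=1)
        db = eemd(b, 0.15, 50, seed=2)
        full = absolute_strengths(a, b, da, db, 1, fast_params, 3, 4)
        single = absolute_strengths(a, b, da, db, 1, fast_params, 3, 4,
                                    distance_mode="single_pair")
        expected = abs(single.baseline.values[0]
                       - single.profile_after_removal_from_b.values[0])
        assert single.d_ab == pytest.approx(expected)
        assert single.d_ab != full.d_ab


class TestCausalProfile:
    def test_profile_covers_every_removable_imf(self, fast_params):
        rng = np.random.default_rng(1)
        a = TimeSeries(rng.standard_normal(128))
        b = TimeSeries(rng.standard_normal(128))
        p = causal_profile(a, b, fast_params, loo_runs=0, seed=2)
        assert p.pair_count >= 4
        assert [r.removed_index for r in p.per_imf] == list(range(1, p.pair_count + 1))
        assert 1 <= p.dominant <= p.pair_count

    def test_profile_deterministic_under_seed(self, fast_params):
        rng = np.random.default_rng(8)
        a = TimeSeries(rng.standard_normal(100))
        b = TimeSeries(rng.standard_normal(100))
        p1 = causal_profile(a, b, fast_params, loo_runs=5, seed=3)
        p2 = causal_profile(a, b, fast_params, loo_runs=5, seed=3)
        assert np.array_equal(p1.strengths_ab(), p2.strengths_ab())
        assert np.array_equal(p1.loo[1].values, p2.loo[1].values)

    def test_white_noise_mean_strength_near_half(self):
        params = EEMDParams(noise_level=0.15, ensemble_size=30)
        cs = []
        for k, (a, b) in enumerate(white_noise_pairs(6, 128, seed=21)):
            p = causal_profile(a, b, params, loo_runs=0, seed=100 + k)
            cs.extend(p.strengths_ab())
        assert abs(np.mean(cs) - 0.5) < 0.1

    def test_serialisation_records(self, fast_params):
        rng = np.random.default_rng(4)
        a = TimeSeries(rng.standard_normal(100))
        b = TimeSeries(rng.standard_normal(100))
        p = causal_profile(a, b, fast_params, loo_runs=5, seed=1)
        rows = p.to_records()
        assert len(rows) == p.pair_count
        for row in rows:
            assert set(row) == {"imf_index", "d_ab", "d_ba", "c_ab", "c_ba",
                                "loo_median", "loo_q025", "loo_q975", "flagged"}
            assert row["c_ab"] + row["c_ba"] == pytest.approx(1.0, abs=1e-12)
            assert row["loo_q025"] <= row["loo_median"] <= row["loo_q975"]


class TestLeaveOneOut:
    SMALL = EEMDParams(noise_level=0.1, ensemble_size=10, max_imfs=2)

    def test_short_record_uses_every_deletion_point(self):
        rng = np.random.default_rng(2)
        a = TimeSeries(rng.standard_normal(71))
        b = TimeSeries(rng.standard_normal(71))
        res = leave_one_out(a, b, 1, self.SMALL, seed=0)
        assert res.values.size == 71
        assert np.array_equal(np.sort(res.deletion_indices), np.arange(71))

    def test_long_record_caps_at_max_runs(self):
        rng = np.random.default_rng(3)
        a = TimeSeries(rng.standard_normal(120))
        b = TimeSeries(rng.standard_normal(120))
        res = leave_one_out(a, b, 1, self.SMALL, max_runs=100, seed=0)
        assert res.values.size == 100
        assert np.unique(res.deletion_indices).size == 100

    def test_explicit_cap_honoured(self):
        rng = np.random.default_rng(4)
        a = TimeSeries(rng.standard_normal(150))
        b = TimeSeries(rng.standard_normal(150))
        res = leave_one_out(a, b, 1, self.SMALL, max_runs=7, seed=1)
        assert res.values.size == 7

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(5)
        a = TimeSeries(rng.standard_normal(40))
        b = TimeSeries(rng.standard_normal(40))
        r1 = leave_one_out(a, b, 1, self.SMALL, max_runs=10, seed=9)
        r2 = leave_one_out(a, b, 1, self.SMALL, max_runs=10, seed=9)
        assert np.array_equal(r1.values, r2.values)

    def test_too_short_rejected(self):
        a = TimeSeries(np.random.default_rng(0).standard_normal(18))
        with pytest.raises(ValueError, match="too short"):
            leave_one_out(a, a, 1, self.SMALL)


def test_legacy_component_numbering():
    # the classic Matlab ensemble-EMD output stores the input signal first,
    # so published component indices in that lineage are offset by one
    assert legacy_component_index(1) == 2
    assert legacy_component_index(4) == 5
    with pytest.raises(ValueError):
        legacy_component_index(0)
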