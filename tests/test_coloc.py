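"""Unit and property tests for the co-localization module."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import marrowmap as mm

from conftest import make_correlated_pair


def costes_oracle(pair, band=0.02):
    """Exhaustive per-level scan: the independent reference for the Costes
    threshold search (naive masking + np.corrcoef at every level)."""
    g = pair.green[pair.roi].astype(float)
    r = pair.red[pair.roi].astype(float)
    slope, intercept = np.polyfit(g, r, 1)
    levels = np.unique(g)[::-1]
    for level in levels:
        t_red = intercept + slope * level
        below = (g < level) & (r < t_red)
        n = int(below.sum())
        if n < 3:
            return level, "flagged"
        gb, rb = g[below], r[below]
        if gb.std() == 0 or rb.std() == 0:
            return level, "flagged"
        c = np.corrcoef(gb, rb)[0, 1]
        if c <= 0:
            return level, "ok"
        if c <= max(band, 2.0 / math.sqrt(n)):
            return level, "flagged"
    return levels[-1], "flagged"


class TestPearson:
    def test_self_correlation_is_one(self, rng):
        a = rng.integers(0, 100, (30, 30)).astype(np.uint16)
        pair = mm.ChannelPair(green=a, red=a.copy())
        assert mm.pearson(pair) == pytest.approx(1.0)

    def test_anticorrelation_is_minus_one(self, rng):
        a = rng.integers(0, 100, (30, 30)).astype(np.uint16)
        pair = mm.ChannelPair(green=a, red=(120 - a).astype(np.uint16))
        assert mm.pearson(pair) == pytest.approx(-1.0)

    def test_recovers_mixing_coefficient(self, rng):
        n = 100
        common = rng.normal(100, 20, (n, n))
        g = np.clip(common + rng.normal(0, 20, (n, n)), 0, None)
        r = np.clip(common + rng.normal(0, 20, (n, n)), 0, None)
        pair = mm.ChannelPair(green=g, red=r)
        rho = 0.5  # corr of two noisy copies: var_c/(var_c+var_n) = 400/800
        assert abs(mm.pearson(pair) - rho) < 3 / math.sqrt(n * n)

    def test_zero_variance_raises(self):
        g = np.full((10, 10), 7, dtype=np.uint16)
        r = np.arange(100, dtype=np.uint16).reshape(10, 10)
        with pytest.raises(ValueError, match="variance"):
            mm.pearson(mm.ChannelPair(green=g, red=r))

    @settings(max_examples=20, deadline=None)
    @given(
        scale=st.floats(0.1, 50),
        offset=st.floats(0, 100),
        data=st.integers(0, 2**31 - 1),
    )
    def test_invariant_to_positive_affine_rescaling(self, scale, offset, data):
        rng = np.random.default_rng(data)
        g = rng.random((20, 20)) * 100
        r = g + rng.random((20, 20)) * 40
        p1 = mm.pearson(mm.ChannelPair(green=g, red=r))
        p2 = mm.pearson(mm.ChannelPair(green=g * scale + offset, red=r))
        assert p1 == pytest.approx(p2, abs=1e-9)


class TestCostes:
    def test_exact_linear_relation_recovers_slope(self):
        rng = np.random.default_rng(0)
        g = rng.integers(1, 200, (32, 32)).astype(np.uint16)
        r = (2 * g).astype(np.uint16)
        th = mm.costes_thresholds(mm.ChannelPair(green=g, red=r))
        assert th.slope == pytest.approx(2.0, abs=1e-9)
        assert th.intercept == pytest.approx(0.0, abs=1e-6)

    def test_threshold_relation_holds(self, rng):
        pair = make_correlated_pair(rng)
        th = mm.costes_thresholds(pair)
        assert th.T_red == pytest.approx(th.intercept + th.slope * th.T_green)

    def test_independent_channels_stop_near_scan_start(self):
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            g = rng.integers(0, 256, (64, 64)).astype(np.uint16)
            r = rng.integers(0, 256, (64, 64)).astype(np.uint16)
            th = mm.costes_thresholds(mm.ChannelPair(green=g, red=r))
            # uncorrelated pair: the scan should stop in the top decile of
            # the intensity range
            if th.T_green >= 0.9 * g.max():
                hits += 1
        assert hits >= 9

    def test_matches_bruteforce_oracle(self):
        for seed in range(10):
            rng = np.random.default_rng(seed)
            pair = make_correlated_pair(rng, rho=0.8)
            th = mm.costes_thresholds(pair)
            level, status = costes_oracle(pair)
            assert th.T_green == level
            assert th.status == status

    def test_constant_green_raises(self):
        g = np.full((10, 10), 5, dtype=np.uint16)
        r = np.arange(100, dtype=np.uint16).reshape(10, 10)
        with pytest.raises(ValueError, match="distinct"):
            mm.costes_thresholds(mm.ChannelPair(green=g, red=r))


class TestManders:
    def test_identical_channels_full_overlap(self, rng):
        a = rng.integers(1, 200, (20, 20)).astype(np.uint16)
        m1, m2 = mm.manders(mm.ChannelPair(green=a, red=a.copy()), 0, 0)
        assert m1 == 1.0 and m2 == 1.0

    def test_disjoint_supports_zero(self):
        g = np.zeros((20, 20), dtype=np.uint16)
        r = np.zeros((20, 20), dtype=np.uint16)
        g[:10] = 50
        r[10:] = 50
        m1, m2 = mm.manders(mm.ChannelPair(green=g, red=r), 10, 10)
        assert m1 == 0.0 and m2 == 0.0

    def test_matches_mask_count_oracle_on_rendered_rings(self):
        patch = mm.render_vessel("NCLT", 3.0, False, 1, 0.5)
        g = (1000 * patch["channels"]["nestin"]).astype(np.uint16)
        r = (1000 * patch["channels"]["endothelial"]).astype(np.uint16)
        pair = mm.ChannelPair(green=g, red=r)
        m1, m2 = mm.manders(pair, 0.0, 0.0)
        # binary masks: M1 reduces to the fraction of red mass on
        # green-positive pixels, countable directly on the masks
        gm = g > 0
        rm = r > 0
        assert m1 == pytest.approx(r[gm].sum() / r.sum())
        assert m2 == pytest.approx(g[rm].sum() / g.sum())

    def test_scale_invariance(self, rng):
        pair = make_correlated_pair(rng)
        m1, m2 = mm.manders(pair, 50, 60)
        scaled = mm.ChannelPair(
            green=pair.green.astype(float) * 3.7, red=pair.red.astype(float)
        )
        m1s, m2s = mm.manders(scaled, 50 * 3.7, 60)
        assert m1 == pytest.approx(m1s) and m2 == pytest.approx(m2s)

    def test_zero_total_intensity_raises(self):
        g = np.zeros((10, 10), dtype=np.uint16)
        g[0, 0] = 1
        r = np.zeros((10, 10), dtype=np.uint16)
        with pytest.raises(ValueError, match="zero total"):
            mm.manders(mm.ChannelPair(green=g, red=r), 0, 0)


class TestTranslatedControl:
    def test_zero_offset_is_identity(self, rng):
        pair = make_correlated_pair(rng)
        ctrl = mm.translated_control(pair, 0, 0)
        assert np.array_equal(ctrl.green, pair.green)
        assert np.array_equal(ctrl.red, pair.red)

    def test_overlap_geometry(self, rng):
        g = rng.integers(0, 100, (512, 512)).astype(np.uint16)
        pair = mm.ChannelPair(green=g, red=g.copy())
        ctrl = mm.translated_control(pair, 100, 100)
        assert ctrl.green.shape == (412, 412)

    def test_double_translation_restores_alignment(self, rng):
        pair = make_correlated_pair(rng, n=64)
        fwd = mm.translated_control(pair, 11, 7)
        back = mm.translated_control(fwd, -11, -7)
        # over the common region the original pairing is restored
        h, w = back.green.shape
        assert np.array_equal(back.green, pair.green[7 : 7 + h, 11 : 11 + w])
        assert np.array_equal(back.red, pair.red[7 : 7 + h, 11 : 11 + w])
        # identical pixel pairing implies identical coefficients
        sub = mm.ChannelPair(
            green=pair.green[7 : 7 + h, 11 : 11 + w],
            red=pair.red[7 : 7 + h, 11 : 11 + w],
        )
        r_back = mm.pearson(mm.ChannelPair(green=back.green, red=back.red))
        assert mm.pearson(sub) == pytest.approx(r_back, abs=1e-12)

    def test_offset_larger_than_image_raises(self, rng):
        pair = make_correlated_pair(rng, n=64)
        with pytest.raises(ValueError):
            mm.translated_control(pair, 64, 0)


class TestColocAnalysis:
    def test_control_reduces_correlation_on_correlated_fixtures(self):
        wins = 0
        for seed in range(20):
            cfg = mm.nclt_coloc_config(seed, n_vessels=8)
            sets, _ = mm.generate_dataset(cfg)
            ms = sets[0]
            res = mm.coloc_analysis(
                mm.ChannelPair(
                    green=ms.channels["nestin"], red=ms.channels["endothelial"]
                )
            )
            if res.tR < res.R:
                wins += 1
        assert wins == 20

    def test_segregated_signal_gives_zero_m1(self):
        rng = np.random.default_rng(4)
        g = (rng.random((64, 64)) * 3).astype(np.uint16)
        r = (rng.random((64, 64)) * 3).astype(np.uint16)
        g[10:20, 10:20] += 200
        r[40:50, 40:50] += 200
        res = mm.coloc_analysis(
            mm.ChannelPair(green=g, red=r), offsets=(10, 10)
        )
        assert res.M1 < 0.1
        assert res.R <= 0.1


class TestCompareGroups:
    def test_identical_groups_no_effect(self):
        g = [1.0, 2.0, 3.0, 4.0, 5.0]
        res = mm.compare_groups([g, list(g)])
        assert res.p > 0.9

    def test_all_tied_degenerate(self):
        res = mm.compare_groups([[1.0, 1.0, 1.0], [1.0, 1.0]])
        assert res.degenerate
        assert res.p == 1.0

    def test_power_on_shifted_normals(self):
        hits = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            a = rng.normal(0, 1, 30)
            b = rng.normal(3, 1, 30)
            if mm.compare_groups([a, b]).p < 0.001:
                hits += 1
        assert hits >= 95

    def test_dunn_flags_only_shifted_group(self):
        flags = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            groups = [rng.normal(0, 1, 30), rng.normal(0, 1, 30), rng.normal(8, 1, 30)]
            res = mm.compare_groups(groups)
            flags.append(
                (
                    res.dunn_p[(0, 2)] < 0.05,
                    res.dunn_p[(1, 2)] < 0.05,
                    res.dunn_p[(0, 1)] >= 0.05,
                )
            )
        assert sum(all(f) for f in flags) >= 18

    def test_dunn_matches_independent_computation(self):
        # frozen 3-group example; z recomputed from rank algebra by hand
        from scipy import stats

        groups = [np.array([1.0, 2, 3, 4]), np.array([3.0, 5, 6, 7]), np.array([8.0, 9, 10, 11])]
        res = mm.compare_groups(groups)
        pooled = np.concatenate(groups)
        ranks = stats.rankdata(pooled)
        mr = [ranks[:4].mean(), ranks[4:8].mean(), ranks[8:].mean()]
        n = 12
        var = n * (n + 1) / 12 - (2**3 - 2) / (12 * (n - 1))
        z01 = (mr[0] - mr[1]) / math.sqrt(var * (1 / 4 + 1 / 4))
        p01 = min(1.0, 2 * stats.norm.sf(abs(z01)) * 3)
        assert res.dunn_z[(0, 1)] == pytest.approx(z01)
        assert res.dunn_p[(0, 1)] == pytest.approx(p01)
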