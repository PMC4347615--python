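"""Overlapped segmented density and autocorrelation features.

Brute-force oracles are written as plain Python loops with math.fsum so they
share no code path with the vectorized implementation.
"""

import math

import numpy as np
import pytest

import pssmloc as pl
from tests.conftest import make_attr_seq


def oracle_osd(values, cfg):
    """Independent prefix-sum implementation of the 31 OSD features."""
    L = len(values)

    def boundary(vals, pct):
        if cfg.boundary_mode == "length_fraction":
            return min(L, max(1, math.floor(pct / 100 * L)))
        total = math.fsum(vals)
        run = 0.0
        for n, v in enumerate(vals, start=1):
            run += v
            if run >= pct / 100 * total - 1e-12:
                return n
        return L

    out = [math.fsum(values) / L]
    for side_vals in (list(values), list(values)[::-1]):
        for pct in cfg.osd_percents:
            b = boundary(side_vals, pct)
            s = math.fsum(side_vals[:b])
            out.append(s / b if cfg.normalize_osd_by_length else s)
    return np.array(out)


def oracle_osa(values, cfg):
    """Naive double-loop implementation of the 15*DF OSA features."""
    L = len(values)
    DF = cfg.distance_factor

    def boundary(vals, pct):
        if cfg.boundary_mode == "length_fraction":
            return min(L, max(1, math.floor(pct / 100 * L)))
        total = math.fsum(vals)
        run = 0.0
        for n, v in enumerate(vals, start=1):
            run += v
            if run >= pct / 100 * total - 1e-12:
                return n
        return L

    def block(vals, D):
        coeffs = []
        for lag in range(1, DF + 1):
            n = D - lag
            if n <= 0:
                coeffs.append(0.0)
            else:
                coeffs.append(math.fsum(vals[j] * vals[j + lag] for j in range(n)) / n)
        return coeffs

    out = []
    for side_vals in (list(values), list(values)[::-1]):
        for pct in cfg.osa_percents:
            out.extend(block(side_vals, boundary(side_vals, pct)))
    out.extend(block(list(values), L))
    return np.array(out)


class TestSegmentBoundary:
    @pytest.mark.parametrize(
        "L,pct,expected", [(100, 5, 5), (10, 5, 1), (100, 75, 75), (3, 99, 2)]
    )
    def test_length_fraction(self, L, pct, expected):
        seq = make_attr_seq(np.full(L, 0.5))
        assert pl.segment_boundary(seq, pct, "left", "length_fraction") == expected

    def test_mass_fraction_uniform_values(self):
        seq = make_attr_seq(np.full(10, 0.3))
        assert pl.segment_boundary(seq, 50, "left", "mass_fraction") == 5

    def test_mass_fraction_skewed_values(self):
        # mass concentrated at the front: one residue already holds 50%
        seq = make_attr_seq([0.8, 0.2, 0.2, 0.2, 0.2])
        assert pl.segment_boundary(seq, 50, "left", "mass_fraction") == 1
        assert pl.segment_boundary(seq, 50, "right", "mass_fraction") == 4


class TestGlobalDensity:
    def test_constant_and_arithmetic_mean(self):
        assert pl.global_density(make_attr_seq(np.ones(7))) == 1.0
        assert pl.global_density(make_attr_seq([0.2, 0.4, 0.6])) == pytest.approx(0.4)

    def test_matches_fsum_oracle(self, rng):
        vals = rng.uniform(0, 1, size=200)
        assert pl.global_density(make_attr_seq(vals)) == pytest.approx(
            math.fsum(vals) / 200, abs=1e-12
        )


class TestOSD:
    def test_all_ones_length_100(self):
        feats = pl.osd_features(make_attr_seq(np.ones(100)))
        assert feats.global_density == 1.0
        np.testing.assert_allclose(feats.left, np.arange(5, 76, 5))
        np.testing.assert_allclose(feats.right, np.arange(5, 76, 5))

    def test_right_equals_left_of_reversed(self, rng):
        vals = rng.uniform(0, 1, size=73)
        fwd = pl.osd_features(make_attr_seq(vals))
        rev = pl.osd_features(make_attr_seq(vals[::-1]))
        np.testing.assert_allclose(fwd.right, rev.left, atol=1e-12)

    def test_feature_count_is_31(self, rng):
        for L in (1, 2, 7, 137):
            feats = pl.osd_features(make_attr_seq(rng.uniform(0, 1, size=L)))
            assert feats.values.size == 31

    @pytest.mark.parametrize("mode", ["length_fraction", "mass_fraction"])
    def test_matches_bruteforce_oracle(self, rng, mode):
        cfg = pl.SegmentationConfig(boundary_mode=mode)
        vals = rng.uniform(0, 1, size=137)
        got = pl.osd_features(make_attr_seq(vals), cfg).values
        np.testing.assert_allclose(got, oracle_osd(vals, cfg), atol=1e-12)

    def test_scale_equivariance(self, rng):
        vals = rng.uniform(0, 0.2, size=60)
        base = pl.osd_features(make_attr_seq(vals)).values
        scaled = pl.osd_features(make_attr_seq(3.0 * vals)).values
        np.testing.assert_allclose(scaled, 3.0 * base, atol=1e-12)


class TestOSA:
    def test_all_ones_gives_unit_coefficients(self):
        # every defined coefficient is 1; a lag equal to the segment length
        # (e.g. lag 10 in the 10-residue segment of L=100) is undefined -> 0
        feats = pl.osa_features(make_attr_seq(np.ones(100)))
        expected = []
        for D in [*range(10, 71, 10), *range(10, 71, 10), 100]:
            expected.extend(1.0 if D - lag > 0 else 0.0 for lag in range(1, 11))
        np.testing.assert_allclose(feats.values, np.array(expected))

    def test_short_segment_lag_is_zero(self):
        # L=5: the 10% segment has D=1, so every lag exceeds it
        feats = pl.osa_features(make_attr_seq(np.full(5, 0.7)))
        np.testing.assert_allclose(feats.left[:10], np.zeros(10))

    def test_feature_count_is_15_DF(self, rng):
        feats = pl.osa_features(make_attr_seq(rng.uniform(0, 1, size=60)))
        assert feats.values.size == 150
        cfg = pl.SegmentationConfig(distance_factor=4)
        feats = pl.osa_features(make_attr_seq(rng.uniform(0, 1, size=60)), cfg)
        assert feats.values.size == 60

    def test_reflection_symmetry(self, rng):
        vals = rng.uniform(0, 1, size=81)
        fwd = pl.osa_features(make_attr_seq(vals))
        rev = pl.osa_features(make_attr_seq(vals[::-1]))
        np.testing.assert_allclose(fwd.right, rev.left, atol=1e-12)

    @pytest.mark.parametrize("mode", ["length_fraction", "mass_fraction"])
    def test_matches_bruteforce_oracle(self, rng, mode):
        cfg = pl.SegmentationConfig(boundary_mode=mode)
        vals = rng.uniform(0, 1, size=60)
        got = pl.osa_features(make_attr_seq(vals), cfg).values
        np.testing.assert_allclose(got, oracle_osa(vals, cfg), atol=1e-12)

    def test_quadratic_scale_equivariance(self, rng):
        vals = rng.uniform(0, 0.5, size=60)
        base = pl.osa_features(make_attr_seq(vals)).values
        scaled = pl.osa_features(make_attr_seq(1.4 * vals)).values
        np.testing.assert_allclose(scaled, 1.4**2 * base, atol=1e-12)
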