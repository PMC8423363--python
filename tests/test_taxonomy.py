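"""Sequential/single classification, refractory threshold, cycle segmentation."""

import numpy as np
import pytest
from scipy import optimize, stats

from remcycle.conditional_gmm import gaussian_intersection
from remcycle.hypnogram import Hypnogram, SleepCycle
from remcycle.taxonomy import (
    SEQUENTIAL,
    SINGLE,
    UNDEFINED,
    classify_cycle,
    intersection_threshold,
    propensity_at_rem_onset,
    refractory_threshold,
    segment_cycle,
    sequence_lengths,
)


def _cycle(rem_pre, n_total, w_total=0.0, start=0):
    return SleepCycle(
        rem_pre=rem_pre,
        n_total=n_total,
        w_total=w_total,
        wake_episode_durations=(w_total,) if w_total else (),
        rem_post=30.0,
        start_index=start,
    )


class TestIntersection:
    def test_symmetric_case_is_midpoint(self):
        x = gaussian_intersection(0.5, 4.0, 0.5, 0.5, 6.0, 0.5)
        assert x == pytest.approx(5.0, abs=1e-12)

    def test_matches_dense_grid_scan(self, rng):
        for _ in range(30):
            mu_s = rng.uniform(3.5, 4.8)
            mu_l = mu_s + rng.uniform(0.8, 2.5)
            s_s, s_l = rng.uniform(0.2, 0.7, 2)
            k = rng.uniform(0.2, 0.9)
            x = gaussian_intersection(1 - k, mu_s, s_s, k, mu_l, s_l)
            if x is None:
                continue
            grid = np.linspace(mu_s, mu_l, 200_001)[1:-1]
            d = (1 - k) * stats.norm.pdf(grid, mu_s, s_s) - k * stats.norm.pdf(grid, mu_l, s_l)
            sign_changes = grid[np.flatnonzero(np.diff(np.sign(d)))]
            assert np.min(np.abs(sign_changes - x)) < 1e-4

    def test_unimodal_rem_pre_rejected(self, model):
        with pytest.raises(ValueError, match="unimodal"):
            intersection_threshold(model, 200.0)

    def test_threshold_lies_between_means(self, model):
        p = model.parameters(45.0)
        x = intersection_threshold(model, 45.0)
        assert p.mu_short < x < p.mu_long


class TestClassifyCycle:
    def test_below_domain_is_undefined(self, model):
        assert classify_cycle(model, _cycle(model.domain_min - 2.5, 100.0)) == UNDEFINED

    def test_unimodal_region_is_single(self, model):
        # above 150 s the long weight is 1: everything is a single cycle
        assert classify_cycle(model, _cycle(180.0, 30.0)) == SINGLE

    def test_short_n_is_sequential(self, model):
        assert classify_cycle(model, _cycle(45.0, 80.0)) == SEQUENTIAL

    def test_long_n_is_single(self, model):
        assert classify_cycle(model, _cycle(45.0, 700.0)) == SINGLE

    def test_zero_n_rejected(self, model):
        with pytest.raises(ValueError):
            classify_cycle(model, _cycle(45.0, 0.0))

    def test_agrees_with_weighted_density_argmax(self, model, rng):
        # the intersection rule is equivalent to comparing the weighted
        # component densities at ln(|N|)
        n_pts = 2000
        xs = rng.uniform(model.domain_min, 239.0, n_pts)
        ns = np.exp(rng.uniform(3.0, 8.0, n_pts))
        for x, n in zip(xs, ns):
            p = model.parameters(x)
            got = classify_cycle(model, _cycle(float(x), float(n)))
            if p.k_long >= 1.0:
                assert got == SINGLE
                continue
            d_s = p.k_short * stats.norm.pdf(np.log(n), p.mu_short, p.sigma_short)
            d_l = p.k_long * stats.norm.pdf(np.log(n), p.mu_long, p.sigma_long)
            if d_s == d_l:
                continue
            assert got == (SEQUENTIAL if d_s > d_l else SINGLE)


class TestRefractoryThreshold:
    def test_closed_form_example(self, model):
        # exp(mu + sigma * z_0.01) with mu=6, sigma=0.5
        thr = np.exp(6.0 + 0.5 * stats.norm.ppf(0.01))
        assert thr == pytest.approx(126.1, abs=0.1)

    def test_matches_bisection_inversion(self, model, rng):
        for _ in range(50):
            x = rng.uniform(model.domain_min, 239.0)
            p = model.parameters(x)
            thr = refractory_threshold(model, x)
            f = lambda n: stats.norm.cdf(np.log(n), p.mu_long, p.sigma_long) - 0.01
            root = optimize.brentq(f, 1e-6, 1e6, xtol=1e-6)
            assert abs(thr - root) < 0.01

    def test_increasing_in_rem_pre(self, model):
        # mu_long increases and sigma_long decreases on the fixture, so the
        # 1%-quantile threshold must rise with REM_pre
        grid = np.arange(model.domain_min, 240, 2.5)
        thr = np.array([refractory_threshold(model, x) for x in grid])
        assert np.all(np.diff(thr) > 0)

    def test_roughly_twice_rem_pre_midrange(self, model):
        # soft property: refractory duration ~ 2x REM_pre over mid-range values
        for x in np.arange(60, 180, 10.0):
            ratio = refractory_threshold(model, float(x)) / x
            assert 1.0 < ratio < 3.0


class TestSegmentCycle:
    def test_hand_trace_with_wake_gap(self):
        h = Hypnogram(("R", "R", "N", "N", "W", "N", "N", "N", "R"))
        c = _cycle(5.0, 12.5, w_total=2.5, start=0)
        ref, perm = segment_cycle(c, h, threshold=10.0)
        assert ref == [2, 3, 5, 6]  # wake epoch 4 belongs to neither
        assert perm == [7]

    def test_threshold_above_n_total_all_refractory(self):
        h = Hypnogram(("R", "N", "N", "N", "R"))
        ref, perm = segment_cycle(_cycle(2.5, 7.5, start=0), h, threshold=100.0)
        assert ref == [1, 2, 3] and perm == []

    def test_zero_threshold_all_permissive(self):
        h = Hypnogram(("R", "N", "N", "N", "R"))
        ref, perm = segment_cycle(_cycle(2.5, 7.5, start=0), h, threshold=0.0)
        assert ref == [] and perm == [1, 2, 3]

    def test_ma_epochs_accumulate(self):
        h = Hypnogram(("R", "N", "M", "N", "R"))
        ref, perm = segment_cycle(_cycle(2.5, 7.5, start=0), h, threshold=5.0)
        assert ref == [1, 2] and perm == [3]


class TestPropensity:
    def test_zero_n_gives_zero(self, model):
        assert propensity_at_rem_onset(model, _cycle(45.0, 0.0)) == 0.0

    def test_large_n_approaches_one(self, model):
        assert propensity_at_rem_onset(model, _cycle(45.0, 50_000.0)) > 0.999

    def test_matches_cdf(self, model):
        c = _cycle(45.0, 300.0)
        assert propensity_at_rem_onset(model, c) == pytest.approx(float(model.cdf(45.0, 300.0)))

    def test_long_only_uses_long_component(self, model):
        c = _cycle(45.0, 300.0)
        p = model.parameters(45.0)
        expect = float(stats.norm.cdf(np.log(300.0), p.mu_long, p.sigma_long))
        assert propensity_at_rem_onset(model, c, long_only=True) == pytest.approx(expect)


def test_sequence_lengths_tabulation():
    labels = [SEQUENTIAL, SEQUENTIAL, SINGLE, SEQUENTIAL, SINGLE, SINGLE, SEQUENTIAL]
    assert sequence_lengths(labels) == [2, 1, 1]
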