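"""Circular statistics, 4PL dose-response and rank-based comparisons."""

import itertools
import math

import numpy as np
import pytest

from circabeam import stats as cstats


class TestAngles:
    def test_zt6_maps_to_quarter_circle(self):
        assert cstats.zt_to_angle(6.0) == pytest.approx(np.pi / 2)

    def test_zt0_and_zt24_coincide(self):
        assert cstats.zt_to_angle(0.0) == cstats.zt_to_angle(24.0)

    def test_round_trip_exact(self, rng):
        zt = rng.uniform(0, 24, 1000)
        back = cstats.angle_to_zt(cstats.zt_to_angle(zt))
        np.testing.assert_allclose(back, zt, atol=1e-12)


class TestRayleigh:
    def test_identical_angles_give_r_one(self):
        r, p = cstats.rayleigh_test(np.full(12, 1.3))
        assert r == pytest.approx(1.0)
        assert p < 1e-6

    def test_equally_spaced_angles_give_r_zero(self):
        angles = np.arange(8) * 2 * np.pi / 8
        r, _ = cstats.rayleigh_test(angles)
        assert r == pytest.approx(0.0, abs=1e-12)

    def test_von_mises_sample_matches_direct_sum_oracle(self, rng):
        a = rng.vonmises(1.0, 2.0, 32) % (2 * np.pi)
        r, p = cstats.rayleigh_test(a)
        # independent oracle: direct complex summation
        r_direct = abs(sum(math.cos(t) for t in a) + 1j * sum(math.sin(t) for t in a)) / len(a)
        assert r == pytest.approx(r_direct, abs=1e-12)

    def test_p_value_cross_checked_against_pingouin(self, rng):
        pingouin = pytest.importorskip("pingouin")
        a = rng.vonmises(1.0, 1.5, 40) % (2 * np.pi)
        _, p = cstats.rayleigh_test(a)
        _, p_ref = pingouin.circ_rayleigh(a)
        assert p == pytest.approx(p_ref, rel=1e-3, abs=1e-6)

    def test_needs_two_angles(self):
        with pytest.raises(ValueError):
            cstats.rayleigh_test([1.0])


class TestVTest:
    def test_perfect_concentration_at_mu0(self):
        res = cstats.v_test(np.full(8, 2.0), 2.0)
        assert res.v == pytest.approx(1.0)
        assert res.p < 1e-3

    def test_antipodal_concentration(self):
        res = cstats.v_test(np.full(10, 2.0 + np.pi), 2.0)
        assert res.v == pytest.approx(-1.0)
        assert res.p > 0.99

    def test_agrees_with_rayleigh_r_when_mu0_is_sample_mean(self, rng):
        a = rng.vonmises(0.7, 2.0, 25) % (2 * np.pi)
        mu = cstats.circ_mean(a)
        res = cstats.v_test(a, mu)
        r, _ = cstats.rayleigh_test(a)
        assert res.v == pytest.approx(r, abs=1e-12)

    def test_rotation_invariance(self, rng):
        a = rng.vonmises(1.0, 3.0, 20) % (2 * np.pi)
        base = cstats.v_test(a, 1.0)
        for shift in (0.5, 2.0, 4.5):
            rotated = cstats.v_test((a + shift) % (2 * np.pi), 1.0 + shift)
            assert rotated.v == pytest.approx(base.v, abs=1e-10)
            assert rotated.p == pytest.approx(base.p, abs=1e-10)


class TestCircularMedian:
    def test_median_of_concentrated_sample(self):
        zt = np.array([22.0, 23.0, 0.5, 1.0, 2.0])  # straddles midnight
        med = cstats.angle_to_zt(cstats.circ_median(cstats.zt_to_angle(zt)))
        assert med == pytest.approx(0.5)

    def test_rotation_equivariance(self, rng):
        a = rng.vonmises(2.0, 1.0, 15) % (2 * np.pi)
        m0 = cstats.circ_median(a)
        m1 = cstats.circ_median((a + 1.1) % (2 * np.pi))
        d = (m1 - m0 - 1.1) % (2 * np.pi)
        assert min(d, 2 * np.pi - d) < 1e-9


class TestPhaseControl:
    def test_locked_release_is_significant(self, rng):
        entrained = cstats.angle_to_zt(rng.vonmises(cstats.zt_to_angle(19.0), 8.0, 24))
        release = cstats.angle_to_zt(rng.vonmises(cstats.zt_to_angle(19.2), 8.0, 24))
        res = cstats.assess_phase_control(entrained, release)
        assert res.p < 0.01

    def test_scattered_release_is_not_significant(self, rng):
        entrained = cstats.angle_to_zt(rng.vonmises(cstats.zt_to_angle(19.0), 8.0, 24))
        release = rng.uniform(0, 24, 24)
        res = cstats.assess_phase_control(entrained, release)
        assert res.p > 0.05

    def test_duplicated_phase_at_mu0(self):
        res = cstats.assess_phase_control([19.0], [19.0] * 8)
        assert res.p < 0.01

    def test_empty_inputs_rejected(self):
        with pytest.raises(ValueError):
            cstats.assess_phase_control([], [1.0])


class TestLogistic4:
    def test_parameter_recovery(self, rng):
        x = rng.uniform(5, 60, 90)
        y = cstats.logistic4(x, 23.9, 3.4, 0.15, 30.0) + rng.normal(0, 0.2, 90)
        fit = cstats.fit_logistic4(x, y, seed=1)
        assert fit.converged
        assert fit.alpha_l == pytest.approx(23.9, abs=0.1)
        assert fit.delta == pytest.approx(3.4, rel=0.10)
        assert fit.eta == pytest.approx(0.15, rel=0.10)

    def test_noiseless_data_interpolated(self):
        x = np.linspace(5, 60, 40)
        y = cstats.logistic4(x, 24.0, 3.0, 0.2, 28.0)
        fit = cstats.fit_logistic4(x, y, seed=0)
        assert fit.rss < 1e-10

    def test_flat_data_gives_zero_span(self, rng):
        x = np.repeat([16.0, 30.0, 50.0], 10)
        y = np.full(30, 24.2) + rng.normal(0, 1e-6, 30)
        fit = cstats.fit_logistic4(x, y, seed=0)
        flat_rss = float(((y - y.mean()) ** 2).sum())
        assert abs(fit.delta) < 0.01
        assert fit.rss <= flat_rss + 1e-12

    def test_degenerate_dose_set_rejected(self):
        with pytest.raises(ValueError):
            cstats.fit_logistic4([1.0, 1.0, 2.0, 2.0], [1, 2, 3, 4])


class TestAnovaVsFlat:
    def test_equal_rss_gives_f_zero_p_one(self):
        y = np.array([1.0, 2.0, 3.0, 2.0, 1.0, 2.0])
        fit = cstats.DoseResponseFit(
            alpha_l=y.mean(), delta=0, eta=1, phi_m=0,
            rss=float(((y - y.mean()) ** 2).sum()), n=len(y), converged=True,
        )
        f, p = cstats.anova_vs_flat(fit, y)
        assert f == 0.0
        assert p == 1.0

    def test_strong_dose_effect_rejects_flat(self, rng):
        x = np.repeat([16.0, 30.0, 50.0], 30)
        y = cstats.logistic4(x, 23.9, 3.4, 0.15, 30.0) + rng.normal(0, 0.2, 90)
        fit = cstats.fit_logistic4(x, y, seed=2)
        _, p = cstats.anova_vs_flat(fit, y)
        assert p < 1e-3


def kruskal_oracle(groups):
    """Direct rank-formula H with tie correction."""
    pooled = np.concatenate(groups)
    n = len(pooled)
    order = np.argsort(pooled, kind="mergesort")
    ranks = np.empty(n)
    sorted_vals = pooled[order]
    i = 0
    pos = 1
    while i < n:
        j = i
        while j < n and sorted_vals[j] == sorted_vals[i]:
            j += 1
        ranks[order[i:j]] = (pos + pos + (j - i) - 1) / 2.0
        pos += j - i
        i = j
    h = 0.0
    start = 0
    for g in groups:
        r = ranks[start : start + len(g)]
        h += r.sum() ** 2 / len(g)
        start += len(g)
    h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
    _, counts = np.unique(pooled, return_counts=True)
    tie = 1.0 - (counts**3 - counts).sum() / (n**3 - n)
    return h / tie


class TestKruskal:
    def test_identical_groups_share_a_letter(self):
        h, p, letters = cstats.kruskal_with_letters(
            {"a": np.array([1.0, 2, 3]), "b": np.array([1.0, 2, 3])}
        )
        assert h == pytest.approx(0.0, abs=1e-9)
        assert letters["a"] == letters["b"]

    def test_separated_groups_get_distinct_letters(self, rng):
        groups = {
            "low": rng.normal(0, 0.1, 8),
            "mid": rng.normal(5, 0.1, 8),
            "high": rng.normal(10, 0.1, 8),
        }
        _, p, letters = cstats.kruskal_with_letters(groups)
        assert p < 0.01
        assert len({letters[g] for g in groups}) == 3

    def test_h_matches_direct_rank_oracle(self):
        groups = [
            np.array([1.0, 4.0, 7.0, 9.0, 2.0]),
            np.array([3.0, 3.0, 8.0, 6.0, 5.0]),
            np.array([10.0, 11.0, 2.0, 6.0, 12.0]),
        ]
        h, _, _ = cstats.kruskal_with_letters(
            {"g1": groups[0], "g2": groups[1], "g3": groups[2]}
        )
        assert h == pytest.approx(kruskal_oracle(groups), rel=1e-10)

    def test_degenerate_group_rejected(self):
        with pytest.raises(ValueError):
            cstats.kruskal_with_letters({"a": np.array([1.0]), "b": np.array([1.0, 2])})


def wilcoxon_enumeration_oracle(a, b):
    """Exact two-sided p: enumerate all assignments of pooled ranks."""
    pooled = np.concatenate([a, b])
    n1 = len(a)
    ranks = np.argsort(np.argsort(pooled)) + 1.0
    observed = ranks[:n1].sum()
    total = 0
    as_extreme = 0
    mean = n1 * (len(pooled) + 1) / 2.0
    for combo in itertools.combinations(range(len(pooled)), n1):
        s = ranks[list(combo)].sum()
        total += 1
        if abs(s - mean) >= abs(observed - mean) - 1e-9:
            as_extreme += 1
    return as_extreme / total


class TestWilcoxon:
    def test_fully_separated_small_samples_match_enumeration(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        b = np.array([10.0, 11.0, 12.0, 13.0])
        w, p = cstats.wilcoxon_rank_sum(a, b)
        assert w == 0.0  # a entirely below b: U = 0
        assert p == pytest.approx(wilcoxon_enumeration_oracle(a, b), rel=1e-9)

    def test_random_small_samples_match_enumeration(self, rng):
        a = rng.normal(0, 1, 5)
        b = rng.normal(0.5, 1, 6)
        _, p = cstats.wilcoxon_rank_sum(a, b)
        assert p == pytest.approx(wilcoxon_enumeration_oracle(a, b), rel=1e-9)

    def test_identical_samples_give_p_one(self):
        a = np.array([1.0, 2.0, 3.0])
        _, p = cstats.wilcoxon_rank_sum(a, a.copy())
        assert p == pytest.approx(1.0)

    def test_three_hour_shift_is_overwhelming(self, rng):
        a = 23.8 + rng.normal(0, 0.3, 32)
        b = 26.8 + rng.normal(0, 0.4, 32)
        _, p = cstats.wilcoxon_rank_sum(a, b)
        assert p < 1e-6

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            cstats.wilcoxon_rank_sum([], [1.0])
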