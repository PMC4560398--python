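"""Curve smoothing, derivatives, event ordering, correlations, styles."""

import numpy as np
import pytest

from leadersim import ArenaConfig, GAConfig
from leadersim.controller import random_genotype
from leadersim.evolution import ReplicationResult
from leadersim.temporal import (TemporalCurve, classify_style, derivative,
                                distance_among_barycenter_curves, event_order,
                                pearson, smooth, temporal_curves)

G = np.arange(0, 300, 10.0)


def _curve(values):
    return TemporalCurve(G, np.asarray(values, dtype=float))


class TestSmooth:
    def test_linear_passthrough(self):
        c = _curve(0.7 * G - 3.0)
        assert np.allclose(smooth(c).values, c.values, atol=1e-6)

    def test_constant_passthrough(self):
        c = _curve(np.full(G.size, 4.2))
        assert np.allclose(smooth(c).values, 4.2, atol=1e-9)

    def test_noisy_sigmoid_rmse_below_noise(self):
        sigma = 0.1
        true = 1 / (1 + np.exp(-(G - 150) / 30))
        rng = np.random.default_rng(3)
        rmses = []
        for _ in range(10):
            noisy = true + rng.normal(0, sigma, G.size)
            sm = smooth(_curve(noisy)).values
            rmses.append(np.sqrt(np.mean((sm - true) ** 2)))
        assert np.mean(rmses) < sigma

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            smooth(TemporalCurve(np.arange(5.0), np.arange(5.0)))

    def test_trend_sign_preserved_on_noisy_monotone_curves(self):
        """Smoothing a monotone curve with 10%-of-range noise keeps the
        overall trend direction in at least 95 of 100 simulations."""
        rng = np.random.default_rng(11)
        ok = 0
        for k in range(100):
            span = rng.uniform(20, 60)
            true = 1 / (1 + np.exp(-(G - rng.uniform(80, 220)) / span))
            sign = 1 if k % 2 == 0 else -1
            noisy = sign * true + rng.normal(0, 0.1, G.size)
            sm = smooth(_curve(noisy)).values
            if np.sign(sm[-1] - sm[0]) == sign:
                ok += 1
        assert ok >= 95


class TestDerivative:
    def test_linear_slope(self):
        d = derivative(_curve(3.0 * G + 1.0))
        assert np.allclose(d.values, 3.0)

    def test_quadratic_maximum_at_right_end(self):
        d = derivative(_curve(G ** 2))
        assert np.all(np.diff(d.values) >= 0)
        assert d.values.argmax() == len(G) - 1

    def test_logistic_inflection_located(self):
        c = _curve(1 / (1 + np.exp(-(G - 150) / 25)))
        d = derivative(c)
        g_star = d.generations[d.values.argmax()]
        assert abs(g_star - 150) <= 10  # within one sample of the inflection


class TestEventOrder:
    def test_skill_before_status_true(self):
        fit = _curve(1 / (1 + np.exp(-(G - 100) / 20)))
        bary = _curve(1 - 1 / (1 + np.exp(-(G - 200) / 20)))
        assert event_order(fit, bary) is True

    def test_reversed_centering_false(self):
        fit = _curve(1 / (1 + np.exp(-(G - 200) / 20)))
        bary = _curve(1 - 1 / (1 + np.exp(-(G - 100) / 20)))
        assert event_order(fit, bary) is False

    def test_tie_is_false(self):
        fit = _curve(1 / (1 + np.exp(-(G - 150) / 20)))
        bary = _curve(1 - fit.values)
        assert event_order(fit, bary) is False


class TestCurveDistance:
    def test_identical_curves_zero(self):
        curves = [_curve(np.sin(G / 40))] * 4
        assert np.allclose(distance_among_barycenter_curves(curves).values, 0)

    def test_single_offset_curve(self):
        c0 = _curve(np.zeros(G.size))
        c1 = _curve(np.full(G.size, 8.0))
        out = distance_among_barycenter_curves([c0, c0, c0, c1])
        # 3 of 6 pairs differ by 8 -> mean gap 4 everywhere
        assert np.allclose(out.values, 4.0)

    def test_translation_invariance(self, rng):
        curves = [_curve(rng.normal(size=G.size)) for _ in range(4)]
        shifted = [c.with_values(c.values + 100.0) for c in curves]
        assert np.allclose(distance_among_barycenter_curves(curves).values,
                           distance_among_barycenter_curves(shifted).values)

    def test_misaligned_grids_rejected(self):
        c0 = _curve(np.zeros(G.size))
        c1 = TemporalCurve(G + 1.0, np.zeros(G.size))
        with pytest.raises(ValueError):
            distance_among_barycenter_curves([c0, c0, c0, c1])


class TestPearson:
    def test_perfect_correlations(self):
        x = np.arange(10.0)
        assert pearson(x, 2 * x + 1)[0] == pytest.approx(1.0)
        assert pearson(x, -x)[0] == pytest.approx(-1.0)

    def test_matches_textbook_formula_on_fixture_table(self):
        """30-point fixture against the direct covariance/sigma formula."""
        rng = np.random.default_rng(30)
        x = rng.normal(10, 3, 30)
        y = 0.5 * x + rng.normal(0, 2, 30)
        rho, p = pearson(x, y)
        xc, yc = x - x.mean(), y - y.mean()
        rho_direct = (xc @ yc) / np.sqrt((xc @ xc) * (yc @ yc))
        assert rho == pytest.approx(rho_direct, abs=1e-12)
        # two-sided t-based p-value
        from scipy import stats
        t = rho_direct * np.sqrt(28 / (1 - rho_direct ** 2))
        p_direct = 2 * stats.t.sf(abs(t), 28)
        assert p == pytest.approx(p_direct, rel=1e-9)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError):
            pearson([1, 1, 1, 1], [1, 2, 3, 4])


class TestClassifyStyle:
    def test_three_clusters_by_largest_gaps(self):
        out = classify_style([10, 12, 500, 520, 2500, 2600])
        assert out.labels == ["passive", "passive", "weak_active",
                              "weak_active", "strong_active", "strong_active"]

    def test_order_of_input_preserved(self):
        out = classify_style([2600, 10, 520, 12, 2500, 500])
        assert out.labels == ["strong_active", "passive", "weak_active",
                              "passive", "strong_active", "weak_active"]

    def test_degenerate_all_equal(self):
        out = classify_style([7.0, 7.0, 7.0, 7.0])
        assert out.degenerate
        assert len(set(out.labels)) == 1

    def test_scale_invariance(self):
        a = classify_style([10, 12, 500, 520, 2500, 2600])
        b = classify_style([30, 36, 1500, 1560, 7500, 7800])
        assert a.labels == b.labels

    def test_manual_thresholds(self):
        out = classify_style([5, 50, 5000], thresholds=(10, 100))
        assert out.labels == ["passive", "weak_active", "strong_active"]

    def test_too_few_replications(self):
        with pytest.raises(ValueError):
            classify_style([1.0, 2.0])


class TestTemporalCurves:
    def _fake_rep(self, arena, teams_by_gen):
        Gn = len(teams_by_gen)
        best = np.stack(teams_by_gen)
        group = np.arange(Gn, dtype=float)
        return ReplicationResult(
            seed=0, arena=arena, ga=GAConfig(generations=Gn),
            fitness=np.zeros((Gn, 4, 20)), group_best=group,
            group_mean=group, best_teams=best,
            final_populations=np.tile(best[-1][:, None, :], (1, 20, 1)))

    def test_collective_curve_reads_stored_series(self, arena, rng):
        team = np.stack([random_genotype(rng) for _ in range(4)])
        rep = self._fake_rep(arena, [team] * 40)
        out = temporal_curves(rep, arena, np.random.default_rng(1),
                              sample_step=10, n_trials=1, steps=20)
        assert np.array_equal(out.collective_fitness.generations,
                              [0, 10, 20, 30, 39])
        assert np.array_equal(out.collective_fitness.values,
                              [0, 10, 20, 30, 39])
        assert len(out.barycenter) == 4 and len(out.individual_fitness) == 4

    def test_step_change_only_after_changepoint(self, arena, rng):
        """With a stored fitness series stepping at generation 20, the
        collective curve changes only at/after the changepoint."""
        team = np.stack([random_genotype(rng) for _ in range(4)])
        rep = self._fake_rep(arena, [team] * 40)
        rep.group_best = np.where(np.arange(40) >= 20, 500.0, 0.0)
        out = temporal_curves(rep, arena, np.random.default_rng(1),
                              sample_step=10, n_trials=1, steps=20)
        v = out.collective_fitness.values
        assert np.all(v[:2] == 0.0) and np.all(v[2:] == 500.0)
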