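"""Descriptives, rank correlations, partial correlations and resampling
inference."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from emotrack.association import (
    DEFAULT_PLAN,
    bonferroni,
    bootstrap_partial,
    correlation_battery,
    descriptives,
    partial_spearman,
    permutation_test,
    spearman,
)
from emotrack.errors import UndefinedCorrelationError, ValidationError


def moments_oracle(x):
    """Brute-force bias-corrected moment estimators."""
    x = np.asarray(x, dtype=float)
    n = x.size
    m = x.mean()
    m2 = np.sum((x - m) ** 2) / n
    m3 = np.sum((x - m) ** 3) / n
    m4 = np.sum((x - m) ** 4) / n
    g1 = m3 / m2 ** 1.5
    G1 = g1 * np.sqrt(n * (n - 1)) / (n - 2)
    g2 = m4 / m2 ** 2 - 3
    G2 = ((n + 1) * g2 + 6) * (n - 1) / ((n - 2) * (n - 3))
    return G1, G2


class TestDescriptives:
    def test_symmetric_triplet(self):
        row = descriptives([1, 2, 3])
        assert row["mean"] == 2 and row["median"] == 2
        assert row["sd"] == pytest.approx(1.0)
        assert row["skewness"] == pytest.approx(0.0)

    def test_affine_invariance_of_shape_moments(self, rng):
        x = rng.gamma(2.0, 1.0, size=40)
        a, b = 3.7, -2.1
        r1, r2 = descriptives(x), descriptives(a * x + b)
        assert r1["skewness"] == pytest.approx(r2["skewness"], abs=1e-10)
        assert r1["kurtosis"] == pytest.approx(r2["kurtosis"], abs=1e-10)

    def test_matches_brute_force_moments(self, rng):
        x = rng.normal(10, 3, size=20)
        row = descriptives(x)
        G1, G2 = moments_oracle(x)
        assert row["skewness"] == pytest.approx(G1, abs=1e-10)
        assert row["kurtosis"] == pytest.approx(G2, abs=1e-10)

    def test_too_small_sample(self):
        with pytest.raises(ValidationError):
            descriptives([1, 2])


class TestSpearman:
    def test_monotone_pair_is_one(self):
        x = np.array([1.0, 2.5, 4.0, 9.0, 20.0])
        assert spearman(x, np.exp(x)).rho == pytest.approx(1.0)

    def test_hand_ranked_example(self):
        assert spearman([1, 2, 3, 4], [3, 1, 2, 4]).rho == pytest.approx(
            stats.spearmanr([1, 2, 3, 4], [3, 1, 2, 4]).statistic
        )

    def test_matches_scipy_oracle_with_ties(self, rng):
        x = rng.integers(0, 8, size=60).astype(float)
        y = 0.5 * x + rng.integers(0, 5, size=60)
        ours = spearman(x, y)
        ref = stats.spearmanr(x, y)
        assert ours.rho == pytest.approx(ref.statistic, abs=1e-12)
        assert ours.p_uncorrected == pytest.approx(ref.pvalue, rel=1e-6)

    def test_rank_invariance_under_monotone_map(self, rng):
        x = rng.normal(size=30)
        y = rng.normal(size=30)
        assert spearman(x, y).rho == pytest.approx(
            spearman(np.exp(x), y).rho, abs=1e-12
        )

    def test_constant_variable_undefined(self):
        with pytest.raises(UndefinedCorrelationError):
            spearman([1, 1, 1, 1], [1, 2, 3, 4])


class TestBonferroni:
    @pytest.mark.parametrize("p,m,expect", [(0.01, 17, 0.17), (0.1, 17, 1.0),
                                            (0.0, 5, 0.0)])
    def test_examples(self, p, m, expect):
        assert bonferroni(p, m) == pytest.approx(expect)

    def test_invalid_p(self):
        with pytest.raises(ValidationError):
            bonferroni(1.5)


class TestPartialSpearman:
    def test_empty_covariates_equals_spearman_exactly(self, rng):
        x = rng.normal(size=40)
        y = rng.normal(size=40)
        assert partial_spearman(x, y, []).rho == spearman(x, y).rho

    def test_matches_recursive_formula_one_covariate(self, rng):
        n = 80
        z = rng.normal(size=n)
        x = 0.5 * z + rng.normal(size=n)
        y = -0.3 * z + rng.normal(size=n)
        r_xy = spearman(x, y).rho
        r_xz = spearman(x, z).rho
        r_yz = spearman(y, z).rho
        expect = (r_xy - r_xz * r_yz) / np.sqrt((1 - r_xz ** 2) * (1 - r_yz ** 2))
        got = partial_spearman(x, y, [z]).rho
        assert got == pytest.approx(expect, abs=1e-10)

    def test_removes_confound(self, rng):
        n = 500
        z = rng.normal(size=n)
        x = rng.normal(size=n)
        y = z + 0.3 * rng.normal(size=n)
        raw = spearman(x, y).rho
        part = partial_spearman(x, y, [z]).rho
        assert abs(part) < 0.1
        assert abs(part) <= abs(raw) + 0.05

    def test_collinear_covariates_rejected(self, rng):
        x = rng.normal(size=30)
        y = rng.normal(size=30)
        z = rng.normal(size=30)
        with pytest.raises(ValidationError, match="collinear"):
            partial_spearman(x, y, [z, 2 * z + 1])


class TestBootstrapPartial:
    def test_identity_pair_has_high_ci(self, rng):
        x = rng.normal(size=100)
        z = rng.normal(size=100)
        res = bootstrap_partial(x, x.copy(), [z], B=500, seed=3)
        assert res.ci95[0] > 0.9

    def test_fixed_seed_bitwise_deterministic(self, rng):
        x = rng.normal(size=50)
        y = 0.4 * x + rng.normal(size=50)
        a = bootstrap_partial(x, y, B=400, seed=11)
        b = bootstrap_partial(x, y, B=400, seed=11)
        assert a.rho == b.rho and a.ci95 == b.ci95


class TestPermutationTest:
    def test_identical_series_gives_minimal_p(self, rng):
        x = rng.normal(size=50)
        res = permutation_test(x, x.copy(), B=999, seed=0)
        assert res.p_uncorrected == pytest.approx(1.0 / 1000.0)

    def test_sampled_matches_exact_enumeration(self, rng):
        x = np.array([0.3, 1.2, -0.5, 2.0, 0.1])
        y = np.array([0.5, 0.9, -1.0, 0.7, 0.2])
        exact = permutation_test(x, y, exact=True)
        sampled = permutation_test(x, y, B=20000, seed=4)
        assert sampled.p_uncorrected == pytest.approx(exact.p_uncorrected, abs=0.02)

    def test_constant_variable_rejected(self):
        with pytest.raises(UndefinedCorrelationError):
            permutation_test([1, 1, 1, 1, 1], [1, 2, 3, 4, 5], B=10, seed=0)


class TestBattery:
    @staticmethod
    def _tables(rng, n=60):
        pid = [f"P{i:03d}" for i in range(n)]
        scores = pd.DataFrame({
            "participant_id": pid,
            "iet_valence": rng.normal(0.6, 0.15, n),
            "iet_arousal": rng.normal(0.5, 0.15, n),
        })
        quests = pd.DataFrame({
            "participant_id": pid,
            "aq": rng.integers(9, 34, n),
            "eq": rng.integers(15, 69, n),
            "eyes_test": rng.integers(5, 34, n),
            "films_task": rng.integers(10, 33, n),
            "matrices": rng.integers(12, 36, n),
            "vocabulary": rng.integers(1, 21, n),
        })
        return scores, quests

    def test_single_comparison_plan_uncorrected(self, rng):
        scores, quests = self._tables(rng)
        out = correlation_battery(scores, quests,
                                  plan=[{"x": "iet_valence", "y": "aq"}])
        assert len(out) == 1
        assert out[0].p_bonferroni == out[0].p_uncorrected

    def test_default_plan_size_is_17(self, rng):
        scores, quests = self._tables(rng)
        out = correlation_battery(scores, quests)
        assert len(out) == len(DEFAULT_PLAN) == 17
        assert all(r.m_comparisons == 17 for r in out)

    def test_unknown_variable_rejected(self, rng):
        scores, quests = self._tables(rng)
        with pytest.raises(ValidationError):
            correlation_battery(scores, quests, plan=[{"x": "nope", "y": "aq"}])

    def test_all_missing_variable_rejected(self, rng):
        scores, quests = self._tables(rng)
        quests["aq"] = np.nan
        with pytest.raises(ValidationError):
            correlation_battery(scores, quests,
                                plan=[{"x": "iet_valence", "y": "aq"}])

    def test_generator_loading_detected_at_full_size(self, default_cohort,
                                                     default_scored):
        # trait loading -0.4 at n = 102: the valence-accuracy ~ AQ
        # comparison must come out negative and survive Bonferroni
        _, quests, _ = default_cohort
        val = default_scored.pooled_series("valence").rename("iet_valence")
        aro = default_scored.pooled_series("arousal").rename("iet_arousal")
        scores = pd.concat([val, aro], axis=1).reset_index()
        out = correlation_battery(scores, quests)
        head = next(r for r in out
                    if r.x == "iet_valence" and r.y == "aq" and not r.label)
        assert head.rho < 0
        assert head.p_bonferroni < 0.05
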