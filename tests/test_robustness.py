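"""Statistical engine: paired t-test, scenario battery, samplers."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from psmcred.robustness import (
    HrgvPanel,
    RobustnessConfig,
    count_assignments,
    cv_normal_sampling,
    exhaustive_fraction_significant,
    mc_fraction_significant,
    paired_t_one_sided,
    systematic_scenario_test,
    worst_case_test,
)


def closed_form_t_cdf_df2(t):
    """Student-t CDF at df = 2: F(t) = 1/2 + (t / (2 sqrt 2)) / sqrt(1 + t^2/2)."""
    return 0.5 + (t / (2 * np.sqrt(2.0))) / np.sqrt(1 + t * t / 2)


class TestPairedT:
    def test_hand_example_df2(self):
        t, p, degen = paired_t_one_sided([3, 4, 5], [2, 2, 2])
        assert not degen
        assert t == pytest.approx(3.4641, abs=1e-4)
        # one-sided upper tail against the closed-form df=2 CDF
        assert p == pytest.approx(1 - closed_form_t_cdf_df2(t), abs=1e-8)
        assert p == pytest.approx(0.0371, abs=5e-4)

    def test_identical_inputs_degenerate(self):
        t, p, degen = paired_t_one_sided([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert degen and p == 0.5 and t == 0.0

    def test_constant_positive_difference_degenerate(self):
        _, p, degen = paired_t_one_sided([2.0, 3.0], [1.0, 2.0])
        assert degen and p == 0.0

    def test_swap_antisymmetry(self):
        rng = np.random.default_rng(7)
        x, y = rng.random(8), rng.random(8)
        t1, p1, d1 = paired_t_one_sided(x, y)
        t2, p2, d2 = paired_t_one_sided(y, x)
        assert not d1 and not d2
        assert t2 == pytest.approx(-t1, rel=1e-12)
        assert p2 == pytest.approx(1 - p1, rel=1e-9)

    @pytest.mark.parametrize("k", [3, 5, 10, 31])
    def test_matches_scipy_ttest_rel(self, k):
        """Independent oracle: scipy's paired t-test, one-sided."""
        rng = np.random.default_rng(k)
        x = rng.random(k) + 0.3
        y = rng.random(k)
        t, p, _ = paired_t_one_sided(x, y)
        ref = stats.ttest_rel(x, y, alternative="greater")
        assert t == pytest.approx(ref.statistic, abs=1e-10)
        assert p == pytest.approx(ref.pvalue, abs=1e-8)

    def test_rejects_short_input(self):
        with pytest.raises(ValueError):
            paired_t_one_sided([1.0], [2.0])


def _random_panel(rng, k=5, v=3, effect=0.0):
    near = rng.random((k, v)) + effect
    far = rng.random((k, v))
    return HrgvPanel(near, far, tuple(f"v{i}" for i in range(v)))


class TestScenarios:
    def test_systematic_matches_direct_t(self):
        rng = np.random.default_rng(0)
        panel = _random_panel(rng, effect=0.5)
        cfg = RobustnessConfig()
        res = systematic_scenario_test(panel, "v1", cfg)
        t, p, _ = paired_t_one_sided(panel.near[:, 1], panel.far[:, 1])
        assert res.t == t and res.p == p
        assert res.significant == (p < cfg.alpha)

    def test_worst_case_extraction_vs_exhaustive_scan(self):
        rng = np.random.default_rng(1)
        panel = _random_panel(rng)
        x = np.array([max(panel.near[i]) for i in range(panel.n_patients)])
        y = np.array([min(panel.far[i]) for i in range(panel.n_patients)])
        res = worst_case_test(panel, RobustnessConfig())
        t_ref, p_ref, _ = paired_t_one_sided(x, y)
        assert res.t == pytest.approx(t_ref, rel=1e-12)
        assert res.p == pytest.approx(p_ref, rel=1e-12)
        assert "caveat" in res.detail

    def test_worst_case_bounds_single_variant_differences(self):
        rng = np.random.default_rng(2)
        panel = _random_panel(rng)
        wc = panel.near.max(axis=1) - panel.far.min(axis=1)
        for j in range(panel.n_variants):
            assert np.all(wc >= panel.near[:, j] - panel.far[:, j])

    def test_identical_variants_collapse_to_systematic(self):
        rng = np.random.default_rng(3)
        col_n = rng.random(5) + 1.0
        col_f = rng.random(5)
        panel = HrgvPanel(np.tile(col_n, (3, 1)).T, np.tile(col_f, (3, 1)).T,
                          ("a", "b", "c"))
        cfg = RobustnessConfig()
        wc = worst_case_test(panel, cfg)
        sys_b = systematic_scenario_test(panel, "b", cfg)
        assert wc.t == pytest.approx(sys_b.t) and wc.p == pytest.approx(sys_b.p)


class TestSamplers:
    def test_mc_matches_exhaustive_within_3se(self):
        rng = np.random.default_rng(42)
        near = rng.random((5, 3)) + 0.35
        far = rng.random((5, 3))
        panel = HrgvPanel(near, far, ("c", "o", "e"))
        cfg = RobustnessConfig(n_samples=100_000, seed=11)
        exact = exhaustive_fraction_significant(panel, cfg)
        mc = mc_fraction_significant(panel, cfg).fraction_significant
        se = np.sqrt(max(exact * (1 - exact), 1e-12) / cfg.n_samples)
        assert 0 < exact < 1  # panel chosen to be a mixed case
        assert abs(mc - exact) <= 3 * se + 1e-12

    def test_mc_seed_reproducibility(self):
        rng = np.random.default_rng(5)
        panel = _random_panel(rng, effect=0.2)
        cfg = RobustnessConfig(n_samples=2000, seed=99)
        f1 = mc_fraction_significant(panel, cfg).fraction_significant
        f2 = mc_fraction_significant(panel, cfg).fraction_significant
        assert f1 == f2

    def test_mc_all_degenerate_positive_gives_one(self):
        near = np.full((4, 3), 2.0)
        far = np.full((4, 3), 1.0)
        panel = HrgvPanel(near, far, ("a", "b", "c"))
        res = mc_fraction_significant(panel, RobustnessConfig(n_samples=500, seed=1))
        assert res.fraction_significant == 1.0

    def test_cv_sampling_constant_panel_is_all_or_nothing(self):
        rng = np.random.default_rng(8)
        col_n = rng.random(6) + 1.0
        col_f = rng.random(6)
        panel = HrgvPanel(np.tile(col_n, (3, 1)).T, np.tile(col_f, (3, 1)).T,
                          ("low", "base", "high"))
        cfg = RobustnessConfig(n_samples=500, seed=3,
                               cv_levels=(52.8, 66.0, 79.2))
        frac = cv_normal_sampling(panel, cfg).fraction_significant
        base_p = paired_t_one_sided(col_n, col_f)[1]
        assert frac == (1.0 if base_p < cfg.alpha else 0.0)

    def test_cv_sampling_interpolation_node_identity(self):
        """A draw exactly at a grid level must reproduce the panel column."""
        levels = np.array([50.0, 60.0, 70.0])
        near = np.array([[1.0, 2.0, 3.0]])
        x = np.interp(60.0, levels, near[0])
        assert x == 2.0

    def test_cv_sampling_self_consistency_large_n(self):
        rng = np.random.default_rng(12)
        base_n = rng.random(5) + 0.25
        base_f = rng.random(5)
        slope = rng.normal(0, 0.003, size=5)
        levels = np.array([52.8, 66.0, 79.2])
        near = base_n[:, None] + slope[:, None] * (levels - 66.0)[None, :]
        far = base_f[:, None] - slope[:, None] * (levels - 66.0)[None, :]
        panel = HrgvPanel(np.abs(near), np.abs(far), ("low", "base", "high"))
        ref = cv_normal_sampling(panel, RobustnessConfig(
            n_samples=400_000, seed=101, cv_levels=tuple(levels))).fraction_significant
        mc = cv_normal_sampling(panel, RobustnessConfig(
            n_samples=100_000, seed=7, cv_levels=tuple(levels))).fraction_significant
        se = np.sqrt(max(ref * (1 - ref), 1e-9) / 100_000)
        assert abs(mc - ref) <= 4 * se + 1e-9

    def test_cv_levels_must_increase(self):
        panel = _random_panel(np.random.default_rng(0))
        with pytest.raises(ValueError):
            cv_normal_sampling(panel, RobustnessConfig(cv_levels=(70.0, 66.0, 60.0)))


@settings(max_examples=20, deadline=None, derandomize=True)
@given(st.integers(min_value=0, max_value=2**31 - 1))
def test_mc_converges_to_exhaustive_for_random_panels(seed):
    """MC fraction within 3 binomial SEs of exhaustive enumeration, K <= 6."""
    rng = np.random.default_rng(seed)
    k = int(rng.integers(3, 7))
    near = rng.random((k, 3)) + rng.uniform(0, 0.6)
    far = rng.random((k, 3))
    panel = HrgvPanel(near, far, ("a", "b", "c"))
    cfg = RobustnessConfig(n_samples=20_000, seed=seed % 100_000)
    exact = exhaustive_fraction_significant(panel, cfg)
    mc = mc_fraction_significant(panel, cfg).fraction_significant
    se = np.sqrt(exact * (1 - exact) / cfg.n_samples)
    assert abs(mc - exact) <= 3 * se + 1e-9


def test_monotonicity_in_effect_size():
    """Adding a positive constant to near values weakly decreases p."""
    rng = np.random.default_rng(21)
    panel = _random_panel(rng)
    cfg = RobustnessConfig()
    p0 = systematic_scenario_test(panel, "v0", cfg).p
    shifted = HrgvPanel(panel.near + 0.5, panel.far, panel.variant_names)
    p1 = systematic_scenario_test(shifted, "v0", cfg).p
    assert p1 <= p0


class TestCountAssignments:
    def test_cohort_of_24_with_3_variants(self):
        assert count_assignments(24, 3) == 3**24 == 282_429_536_481

    def test_edge_cases(self):
        assert count_assignments(0, 3) == 1
        assert count_assignments(5, 3) == 243

    def test_rejects_bad_args(self):
        with pytest.raises(ValueError):
            count_assignments(-1, 3)
        with pytest.raises(ValueError):
            count_assignments(3, 0)


class TestPanel:
    def test_roundtrip_through_frame(self):
        rng = np.random.default_rng(2)
        panel = _random_panel(rng)
        df = panel.to_frame()
        back = HrgvPanel.from_frame(df, panel.variant_names)
        np.testing.assert_allclose(back.near, panel.near)
        np.testing.assert_allclose(back.far, panel.far)

    def test_rejects_incomplete_panel(self):
        near = np.array([[1.0, np.nan, 2.0]])
        with pytest.raises(ValueError):
            HrgvPanel(near, np.ones_like(near), ("a", "b", "c"))
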