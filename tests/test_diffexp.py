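"""Differential expression: test gating, fold changes, BH correction."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from proteoage import (
    ComparisonSpec,
    DifferentialExpression,
    SimulationConfig,
    ValidationError,
    bh_adjust,
    choose_test,
    geometric_fold_change,
    simulate_cohort,
    validate_cohort,
)


def brute_force_bh(p):
    """Independent step-up implementation straight from the definition."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adjusted = np.empty(m)
    running_min = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        value = min(1.0, p[i] * m / rank_from_top)
        running_min = min(running_min, value)
        adjusted[i] = running_min
    return adjusted


class TestBHAdjust:
    def test_matches_brute_force_on_random_vectors(self):
        rng = np.random.default_rng(123)
        for _ in range(1000):
            p = rng.random(rng.integers(1, 40))
            assert np.allclose(bh_adjust(p), brute_force_bh(p), atol=1e-12)

    def test_hand_examples(self):
        assert bh_adjust([0.03]) == pytest.approx([0.03])
        assert np.allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)

    def test_dominance_and_range(self):
        rng = np.random.default_rng(7)
        p = rng.random(200)
        adj = bh_adjust(p)
        assert (adj >= p - 1e-15).all() and (adj <= 1.0).all()

    def test_rejects_out_of_range(self):
        with pytest.raises(ValidationError):
            bh_adjust([0.5, 1.5])


class TestGeometricFoldChange:
    def test_closed_forms(self):
        assert geometric_fold_change([5.0], [4.0]) == pytest.approx(2.0)
        assert geometric_fold_change([1.0, 3.0], [0.0, 2.0]) == pytest.approx(2.0)
        assert geometric_fold_change([2.2, 3.3], [2.2, 3.3]) == pytest.approx(1.0)

    @given(
        a=st.lists(st.floats(-10, 10), min_size=1, max_size=8),
        b=st.lists(st.floats(-10, 10), min_size=1, max_size=8),
        c=st.lists(st.floats(-10, 10), min_size=1, max_size=8),
    )
    @settings(max_examples=100, deadline=None)
    def test_transitivity(self, a, b, c):
        fc_ac = geometric_fold_change(a, c)
        fc_ab = geometric_fold_change(a, b)
        fc_bc = geometric_fold_change(b, c)
        assert fc_ac == pytest.approx(fc_ab * fc_bc, rel=1e-9)

    def test_empty_group_rejected(self):
        with pytest.raises(ValidationError):
            geometric_fold_change([], [1.0])


class TestChooseTest:
    def test_gaussian_data_mostly_routes_to_t_test(self):
        rng = np.random.default_rng(0)
        n_t = sum(
            choose_test(rng.normal(size=52), rng.normal(size=52), paired=False)
            == "t_independent"
            for _ in range(300)
        )
        # two Shapiro-Wilk gates at alpha 0.05 -> ~0.95^2 pass rate
        assert 0.85 <= n_t / 300 <= 0.97

    def test_lognormal_paired_differences_route_to_signed_rank(self):
        rng = np.random.default_rng(1)
        n_sr = sum(
            choose_test(
                rng.lognormal(0, 1, size=52), np.zeros(52), paired=True
            )
            == "wilcoxon_signedrank"
            for _ in range(100)
        )
        assert n_sr >= 99

    def test_constant_group_falls_back_to_rank_test_with_warning(self):
        with pytest.warns(UserWarning, match="constant"):
            assert (
                choose_test(np.ones(10), np.random.default_rng(0).normal(size=10),
                            paired=False)
                == "wilcoxon_ranksum"
            )

    def test_too_few_observations(self):
        with pytest.raises(ValidationError):
            choose_test([1.0, 2.0], [1.0, 2.0, 3.0], paired=False)


class TestRunComparison:
    def test_self_comparison_is_flat(self, small_cohort):
        """Comparing a group's pairs against themselves: fc 1, nothing called."""
        matrix, cohort, _ = small_cohort
        import pandas as pd

        oc = cohort[cohort["group"] == "OC"]
        dup = pd.concat([oc, oc.assign(sample_id=oc["sample_id"] + "_b",
                                       group="OP")])
        dup = validate_cohort(dup.reset_index(drop=True))
        data = matrix.data.loc[oc["sample_id"]]
        mirrored = pd.concat([data, data.set_axis(oc["sample_id"] + "_b")])
        from proteoage import NPXMatrix

        result = DifferentialExpression(
            NPXMatrix(mirrored), dup, ComparisonSpec("OP", "OC", paired=True)
        ).fit()
        assert np.allclose(result.table["fc_linear"], 1.0)
        assert not result.table["significant"].any()

    def test_planted_effects_have_high_power_52v52(self):
        """delta = 1 NPX at n = 52 vs 52: noncentral-t power is >= 0.99, the
        paired comparison should recover essentially all disease proteins."""
        cfg = SimulationConfig(
            n_proteins=200, effect_fractions=(0.6, 0.1, 0.15, 0.15), seed=21
        )
        matrix, cohort, truth = simulate_cohort(cfg)
        cohort = validate_cohort(cohort)
        result = DifferentialExpression(
            matrix, cohort, ComparisonSpec("OP", "OC", paired=True)
        ).fit()
        affected = truth["class"].isin(["disease_only", "both"]).to_numpy()
        sig = result.table.set_index("protein_id")["significant"]
        power = sig[truth.loc[affected, "protein_id"]].mean()
        # closed-form cross-check: ncp = 1/sqrt(2/52) = 5.1 -> power > 0.99
        se = np.sqrt(2.0 / 52.0)
        assert stats.norm.sf(stats.norm.isf(0.025) - 1.0 / se) > 0.99
        assert power >= 0.95

    def test_paired_test_beats_unpaired_under_strong_pair_effect(self):
        rng = np.random.default_rng(5)
        wins = 0
        for _ in range(30):
            pair = rng.normal(0, 2.0, size=40)
            a = pair + rng.normal(0.4, 0.5, size=40)
            b = pair + rng.normal(0.0, 0.5, size=40)
            p_paired = stats.ttest_rel(a, b).pvalue
            p_unpaired = stats.ttest_ind(a, b).pvalue
            wins += p_paired < p_unpaired
        assert wins >= 25

    def test_wilcoxon_invariant_to_monotone_transform(self):
        rng = np.random.default_rng(9)
        a = rng.lognormal(0.5, 1, size=15)
        b = rng.lognormal(0.0, 1, size=15)
        from proteoage.diffexp import _test_pvalue

        p1 = _test_pvalue(a, b, "wilcoxon_ranksum")
        p2 = _test_pvalue(np.log(a), np.log(b), "wilcoxon_ranksum")
        p3 = _test_pvalue(a**3, b**3, "wilcoxon_ranksum")
        assert p1 == pytest.approx(p2) == pytest.approx(p3)

    def test_volcano_columns_present(self, de_results):
        de_age, _ = de_results
        for col in ("neg_log10_p_adj", "log2_fc", "direction", "test_used"):
            assert col in de_age.table.columns
        assert set(de_age.table["direction"]) <= {"up", "down"}
        # direction consistent with fold change
        up = de_age.table["fc_linear"] > 1
        assert (de_age.table.loc[up, "direction"] == "up").all()
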