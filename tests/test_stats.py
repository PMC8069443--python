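"""Totals table, ANOVA, Dunnett comparisons and the wide report."""

import numpy as np
import pytest
from scipy import stats as sps

from woodlact import (
    compare_protocols,
    comparison_report,
    dunnett_vs_reference,
    normality_screen,
    one_way_glm,
    per_animal_totals,
)
from woodlact.simulate import simulate_herd
from woodlact.stats import METHOD_ORDER, TRAIT_ORDER

from conftest import tiny_profiles


class TestPerAnimalTotals:
    def test_noiseless_animal_has_identical_wood_totals(self, noiseless_herd):
        totals, _ = per_animal_totals(noiseless_herd.records)
        pivot = totals.pivot_table(
            index=["animal_id", "trait"], columns="method", values="total_kg"
        )
        # milk, fat and protein curves are exactly Wood, so any >= 3
        # informative points identify the same parameters; FCM is a sum
        # of two Wood curves (0.634*milk + 10.46*fat) and only nearly so
        exact = pivot.query("trait != 'fcm'")
        fcm = pivot.query("trait == 'fcm'")
        for method in ("B", "C"):
            np.testing.assert_allclose(exact["A"], exact[method], rtol=1e-6)
            np.testing.assert_allclose(fcm["A"], fcm[method], rtol=1e-4)

    def test_cardinality_on_default_herd(self, default_herd):
        totals, failures = per_animal_totals(default_herd.records)
        assert len(totals) == 465 * len(TRAIT_ORDER) * len(METHOD_ORDER) - len(failures)
        assert set(totals["trait"]) == set(TRAIT_ORDER)
        assert set(totals["method"]) == set(METHOD_ORDER)
        assert (totals["total_kg"] >= 0).all()

    def test_daily_sum_mode_close_to_integral(self, small_herd):
        a, _ = per_animal_totals(small_herd.records, traits=("milk",))
        b, _ = per_animal_totals(
            small_herd.records, traits=("milk",), totals_mode="daily_sum"
        )
        merged = a.merge(b, on=["animal_id", "trait", "method"], suffixes=("_i", "_s"))
        wood = merged[merged["method"] != "ICAR"]
        assert np.allclose(wood["total_kg_i"], wood["total_kg_s"], rtol=0.05)
        icar = merged[merged["method"] == "ICAR"]
        assert np.allclose(icar["total_kg_i"], icar["total_kg_s"], rtol=1e-12)


class TestOneWayGlm:
    def test_hand_computed_two_group_anova(self):
        res = one_way_glm({"g1": [1, 2, 3], "g2": [4, 5, 6]})
        assert res.f == pytest.approx(13.5)
        assert (res.df_between, res.df_within) == (1, 4)
        f, p = sps.f_oneway([1, 2, 3], [4, 5, 6])
        assert res.f == pytest.approx(f) and res.p == pytest.approx(p)

    def test_identical_groups_give_f_zero(self):
        res = one_way_glm({m: [1.0, 2.0, 3.0] for m in "ABCD"})
        assert res.f == pytest.approx(0.0)
        assert res.p == pytest.approx(1.0)

    def test_lsmeans_are_group_means_and_sem_pooled(self):
        rng = np.random.default_rng(0)
        groups = {m: rng.normal(10, 2, 40) for m in METHOD_ORDER}
        res = one_way_glm(groups)
        for m, x in groups.items():
            assert res.lsmeans[m] == pytest.approx(x.mean())
        assert res.sem == pytest.approx(np.sqrt(res.mse / 40))

    def test_shift_invariance_and_scaling(self):
        rng = np.random.default_rng(1)
        groups = {m: rng.normal(0, 1, 30) for m in "ABC"}
        base = one_way_glm(groups)
        shifted = one_way_glm({m: x + 100 for m, x in groups.items()})
        scaled = one_way_glm({m: 7 * x for m, x in groups.items()})
        assert shifted.f == pytest.approx(base.f, rel=1e-9)
        assert scaled.f == pytest.approx(base.f, rel=1e-9)
        assert scaled.mse == pytest.approx(49 * base.mse, rel=1e-9)

    def test_degenerate_variance_rejected(self):
        with pytest.raises(ValueError):
            one_way_glm({"a": [1.0, 1.0], "b": [2.0, 2.0]})


class TestDunnett:
    def test_single_contrast_reduces_to_pooled_t_test(self):
        rng = np.random.default_rng(2)
        control, treat = rng.normal(0, 1, 30), rng.normal(0.4, 1, 30)
        res = dunnett_vs_reference({"A": control, "B": treat})["B"]
        t_p = sps.ttest_ind(treat, control).pvalue
        assert res.p_adj == pytest.approx(t_p, abs=1e-12)

    def test_adjusted_p_never_below_raw_p(self):
        rng = np.random.default_rng(3)
        for rep in range(10):
            groups = {m: rng.normal(0, 1, 25) for m in METHOD_ORDER}
            for cmp_ in dunnett_vs_reference(groups, rng=rep).values():
                assert cmp_.p_adj >= cmp_.p_raw - 1e-12

    def test_adjusted_p_matches_scipy_dunnett(self):
        rng = np.random.default_rng(8)
        groups = {m: rng.normal(0, 1, 40) for m in "AXYZ"}
        ours = dunnett_vs_reference(groups, rng=0)
        ref = sps.dunnett(
            groups["X"], groups["Y"], groups["Z"],
            control=groups["A"], random_state=np.random.default_rng(1),
        )
        for name, p in zip("XYZ", ref.pvalue):
            assert ours[name].p_adj == pytest.approx(p, abs=5e-3)

    def test_near_identical_groups_all_nonsignificant(self):
        rng = np.random.default_rng(4)
        groups = {m: 100 + rng.normal(0, 1e-6, 20) for m in METHOD_ORDER}
        for cmp_ in dunnett_vs_reference(groups, rng=0).values():
            assert cmp_.sig_class == "n.s."

    def test_missing_reference_rejected(self):
        with pytest.raises(ValueError):
            dunnett_vs_reference({"B": [1, 2], "C": [3, 4]}, reference="A")


class TestComparisonReport:
    @pytest.fixture(scope="class")
    def comparison(self):
        herd = simulate_herd(tiny_profiles(n_animals=20), master_seed=3)
        totals, _ = per_animal_totals(herd.records)
        return compare_protocols(totals, rng=3)

    def test_row_counts(self, comparison):
        # 2 breeds x 4 traits x 4 methods
        assert len(comparison) == 2 * 4 * 4
        wide, text = comparison_report(comparison)
        assert len(wide) == 2 * 4
        assert text.count("==") == 2 * 4  # one block header per trait

    def test_reference_has_no_p_value(self, comparison):
        ref = comparison[comparison["method"] == "A"]
        assert ref["p_adj"].isna().all()
        assert (ref["sig_class"] == "").all()

    def test_significance_classes_follow_thresholds(self, comparison):
        rest = comparison[comparison["method"] != "A"]
        for _, row in rest.iterrows():
            expected = (
                "**" if row.p_adj < 0.01 else "*" if row.p_adj < 0.05 else "n.s."
            )
            assert row.sig_class == expected

    def test_report_sig_matches_comparison(self, comparison):
        wide, _ = comparison_report(comparison)
        for _, row in wide.iterrows():
            sub = comparison[
                (comparison["breed"] == row["breed"])
                & (comparison["trait"] == row["trait"])
            ].set_index("method")
            for m in ("ICAR", "B", "C"):
                assert row[f"{m}_sig"] == sub.loc[m, "sig_class"]


class TestNormalityScreen:
    def test_shape_and_skips(self, small_herd):
        out = normality_screen(small_herd.records)
        assert len(out) == 2 * 14 * 4  # breed x test day x trait
        ok = out[~out["skipped"]]
        assert ok["p"].between(0, 1).all()
        assert ok["W"].between(0, 1).all()

    def test_constant_cell_skipped(self, small_herd):
        records = small_herd.records.copy()
        records.loc[records["dim"] == 15, "milk_g"] = 1000.0
        out = normality_screen(records)
        cell = out[(out["dim"] == 15) & (out["trait"] == "milk")]
        assert cell["skipped"].all()
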