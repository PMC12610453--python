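import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats
from statsmodels.stats.multitest import multipletests
from statsmodels.stats.weightstats import ttest_ind as sm_ttest_ind

from mirpanel.diffexpr import (
    Contrast,
    DeltaCtTable,
    bh_adjust,
    covariate_adjustment,
    normalize_delta_ct,
    run_contrast,
    welch_test,
)
from mirpanel.panel_io import CtTable, PanelLayout, SampleMeta
from mirpanel.synthetic_data import (
    EffectSpec,
    SimConfig,
    default_study_config,
    make_layout,
    simulate_panel,
)


def _tiny_table(ct_rows, lod=35.0):
    layout = PanelLayout(
        ("t1", "hk1", "hk2", "hk3"),
        ("target", "housekeeping", "housekeeping", "housekeeping"),
        lod_ct=lod,
    )
    sample_ids = tuple(f"S{i}" for i in range(len(ct_rows)))
    return CtTable(sample_ids, layout, np.asarray(ct_rows, dtype=float))


class TestNormalizeDeltaCt:
    def test_arithmetic(self):
        dct = normalize_delta_ct(_tiny_table([[26.0, 20.0, 22.0, 24.0]]))
        assert dct.dct.iloc[0, 0] == pytest.approx(4.0)
        assert dct.rel_expr.iloc[0, 0] == pytest.approx(0.0625)

    def test_identity_case(self):
        dct = normalize_delta_ct(_tiny_table([[22.0, 20.0, 22.0, 24.0]]))
        assert dct.dct.iloc[0, 0] == pytest.approx(0.0)
        assert dct.rel_expr.iloc[0, 0] == pytest.approx(1.0)

    def test_undetected_target_propagates_nan(self):
        table = _tiny_table([[36.0, 20.0, 22.0, 24.0], [26.0, 20.0, 22.0, 24.0]])
        dct = normalize_delta_ct(table)
        assert np.isnan(dct.dct.iloc[0, 0])
        assert dct.dct.iloc[1, 0] == pytest.approx(4.0)

    def test_no_detected_housekeeping_names_sample(self):
        table = _tiny_table([[26.0, 36.0, 37.0, 38.0]])
        with pytest.raises(ValueError, match="S0"):
            normalize_delta_ct(table)

    def test_partial_housekeeping_uses_detected_only(self):
        # hk3 undetected: mean of (20, 22) = 21
        dct = normalize_delta_ct(_tiny_table([[26.0, 20.0, 22.0, 40.0]]))
        assert dct.dct.iloc[0, 0] == pytest.approx(5.0)


class TestWelchTest:
    def test_frozen_example(self):
        t, df, p = welch_test([1, 2, 3], [2, 3, 4])
        assert t == pytest.approx(-1.224744871391589, rel=1e-12)
        assert df == pytest.approx(4.0, rel=1e-12)
        assert p == pytest.approx(0.28786413472669053, rel=1e-12)

    def test_identical_groups(self, rng):
        x = rng.standard_normal(6)
        t, _, p = welch_test(x, x)
        assert t == 0.0
        assert p == 1.0

    def test_equal_variance_equal_n_gives_pooled_df(self):
        # Satterthwaite reduces to n1+n2-2 exactly in this limit.
        a, b = [0.0, 1.0, 2.0, 3.0], [5.0, 6.0, 7.0, 8.0]
        _, df, _ = welch_test(a, b)
        assert df == pytest.approx(6.0, rel=1e-12)

    def test_zero_variance_conventions(self):
        t, _, p = welch_test([2.0, 2.0], [2.0, 2.0])
        assert (t, p) == (0.0, 1.0)
        t, _, p = welch_test([3.0, 3.0], [2.0, 2.0])
        assert np.isinf(t) and t > 0
        assert p == 0.0

    def test_insufficient_n_raises(self):
        with pytest.raises(ValueError):
            welch_test([1.0], [1.0, 2.0])

    def test_nan_values_dropped(self):
        t1 = welch_test([1, 2, 3, np.nan], [2, 3, 4])
        t2 = welch_test([1, 2, 3], [2, 3, 4])
        assert t1 == t2

    def test_matches_reference_implementation(self, rng):
        for _ in range(200):
            na, nb = rng.integers(2, 30, size=2)
            a = rng.standard_normal(na) * rng.uniform(0.5, 3)
            b = rng.standard_normal(nb) * rng.uniform(0.5, 3) + rng.uniform(-2, 2)
            t, df, p = welch_test(a, b)
            t_ref, p_ref, df_ref = sm_ttest_ind(a, b, usevar="unequal")
            assert t == pytest.approx(t_ref, rel=1e-10)
            assert df == pytest.approx(df_ref, rel=1e-10)
            assert p == pytest.approx(p_ref, rel=1e-10, abs=1e-300)


class TestBHAdjust:
    def test_frozen_example(self):
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_single_p_identity(self):
        np.testing.assert_allclose(bh_adjust([0.03]), [0.03])

    def test_all_ones_capped(self):
        np.testing.assert_allclose(bh_adjust([1.0, 1.0, 1.0]), [1.0, 1.0, 1.0])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])
        with pytest.raises(ValueError):
            bh_adjust([-0.1])

    def test_matches_reference_implementation(self, rng):
        for _ in range(200):
            p = rng.uniform(size=rng.integers(1, 100))
            ref = multipletests(p, method="fdr_bh")[1]
            np.testing.assert_allclose(bh_adjust(p), ref, rtol=1e-10)

    @given(
        st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=50)
    )
    @settings(max_examples=200, deadline=None)
    def test_properties(self, p):
        adj = bh_adjust(p)
        p = np.asarray(p)
        assert np.all(adj <= 1.0)
        assert np.all(adj >= p - 1e-15)
        order = np.argsort(p, kind="stable")
        assert np.all(np.diff(adj[order]) >= -1e-15)  # monotone in rank
        # tied raw p-values share an adjusted value
        for value in np.unique(p):
            tied = adj[p == value]
            assert np.allclose(tied, tied[0])


class TestRunContrast:
    def test_sign_convention(self):
        # group A delta-Ct lower by 2 cycles => +2 log2 fold regulation (up in A)
        dct = DeltaCtTable(
            pd.DataFrame(
                {"t1": [1.0, 1.1, 0.9, 3.0, 3.1, 2.9]},
                index=[f"S{i}" for i in range(6)],
            )
        )
        contrast = Contrast("c", ("S0", "S1", "S2"), ("S3", "S4", "S5"))
        de = run_contrast(dct, contrast)
        assert de["log2_fold_reg"].iloc[0] == pytest.approx(2.0)
        assert de["ddct"].iloc[0] == pytest.approx(-2.0)
        assert de["fold_reg"].iloc[0] == pytest.approx(4.0)

    def test_null_assay_not_significant(self):
        dct = DeltaCtTable(
            pd.DataFrame(
                {"t1": [1.0, 2.0, 3.0, 1.0, 2.0, 3.0]},
                index=[f"S{i}" for i in range(6)],
            )
        )
        de = run_contrast(dct, Contrast("c", ("S0", "S1", "S2"), ("S3", "S4", "S5")))
        assert de["ddct"].iloc[0] == pytest.approx(0.0)
        assert de["fold_reg"].iloc[0] == pytest.approx(1.0)
        assert not de["significant"].iloc[0]

    def test_fold_reg_identity(self, null_de):
        tested = null_de[null_de["tested"]]
        np.testing.assert_allclose(
            tested["fold_reg"] * 2.0 ** tested["ddct"], 1.0, rtol=1e-12
        )
        np.testing.assert_allclose(
            tested["log2_fold_reg"], -tested["ddct"], rtol=1e-12
        )

    def test_sparse_assay_flagged_and_excluded_from_bh(self):
        index = [f"S{i}" for i in range(6)]
        frame = pd.DataFrame(
            {
                "t1": [1.0, 2.0, 3.0, 4.0, 5.0, 6.0],
                "t2": [1.0, np.nan, np.nan, 4.0, 5.0, 6.0],
                "t3": [0.5, 1.5, 2.5, 4.0, 5.0, 6.0],
            },
            index=index,
        )
        de = run_contrast(
            DeltaCtTable(frame), Contrast("c", ("S0", "S1", "S2"), ("S3", "S4", "S5"))
        )
        sparse = de[de["mirna"] == "t2"].iloc[0]
        assert not sparse["tested"]
        assert not sparse["significant"]
        assert np.isnan(sparse["p"])
        tested = de[de["tested"]]
        np.testing.assert_allclose(
            tested["fdr"].to_numpy(), bh_adjust(tested["p"].to_numpy())
        )

    def test_planted_effect_mostly_unique_call(self):
        target = "hsa-miR-181a-5p"
        hits, unique = 0, 0
        n_rep = 20
        for seed in range(n_rep):
            config = default_study_config(seed=2000 + seed).with_effects(
                [EffectSpec(target, log2_effect=5.0)]
            )
            ct_table, meta = simulate_panel(config)
            a = tuple(m.sample_id for m in meta if m.group == "cancer")
            b = tuple(m.sample_id for m in meta if m.group == "healthy")
            de = run_contrast(normalize_delta_ct(ct_table), Contrast("c", a, b))
            sig = de[de["significant"]]["mirna"].tolist()
            hits += target in sig
            unique += sig == [target]
        assert hits == n_rep  # a +5 effect at this SNR is never missed
        assert unique >= int(0.7 * n_rep)

    def test_unknown_samples_rejected(self, null_dct):
        with pytest.raises(ValueError, match="absent"):
            run_contrast(
                null_dct, Contrast("c", ("nope1", "nope2"), ("C01", "C02"))
            )

    def test_degenerate_contrast_rejected(self):
        with pytest.raises(ValueError):
            Contrast("c", ("S1",), ("S2", "S3"))
        with pytest.raises(ValueError):
            Contrast("c", ("S1", "S2"), ("S2", "S3"))


class TestCovariateAdjustment:
    def test_independent_covariates_leave_group_effect(self):
        target = "hsa-miR-181a-5p"
        config = default_study_config(seed=21).with_effects(
            [EffectSpec(target, log2_effect=3.0)]
        )
        ct_table, meta = simulate_panel(config)
        dct = normalize_delta_ct(ct_table)
        a = tuple(m.sample_id for m in meta if m.group == "cancer")
        b = tuple(m.sample_id for m in meta if m.group == "healthy")
        de = run_contrast(dct, Contrast("c", a, b))
        unadj = float(de.loc[de["mirna"] == target, "log2_fold_reg"].iloc[0])
        adj = covariate_adjustment(
            dct, meta, [target], covariates=("age", "bmi")
        )
        row = adj.iloc[0]
        assert abs(row["group_log2_fold_reg"] - unadj) < 3 * row["group_se"]
        assert row["group_p"] < 1e-6

    def test_confounder_attenuates_group_effect(self):
        config = SimConfig(seed=23, bmi_group_shift=8.0, bmi_dct_slope=0.4)
        ct_table, meta = simulate_panel(config)
        dct = normalize_delta_ct(ct_table)
        a = tuple(m.sample_id for m in meta if m.group == "cancer")
        b = tuple(m.sample_id for m in meta if m.group == "healthy")
        de = run_contrast(dct, Contrast("c", a, b))
        mirnas = list(dct.dct.columns[:10])
        adj = covariate_adjustment(dct, meta, mirnas, covariates=("age", "bmi"))
        merged = de.set_index("mirna").loc[mirnas]
        unadj_mag = merged["log2_fold_reg"].abs().mean()
        adj_mag = adj["group_log2_fold_reg"].abs().mean()
        assert adj_mag < unadj_mag

    def test_constant_grade_rank_deficient(self):
        ct_table, meta = simulate_panel(default_study_config(seed=25))
        dct = normalize_delta_ct(ct_table)
        cancer = [m for m in meta if m.group == "cancer"]
        flat = [
            SampleMeta(m.sample_id, m.group, m.pole_status, m.age, m.bmi, "G2")
            for m in cancer
        ]
        contrast = Contrast(
            "pole",
            tuple(m.sample_id for m in cancer if m.pole_status == "mutant"),
            tuple(m.sample_id for m in cancer if m.pole_status == "wildtype"),
        )
        with pytest.raises(ValueError, match="grade"):
            covariate_adjustment(
                dct, flat, [dct.dct.columns[0]], contrast=contrast
            )

    def test_missing_covariate_rejected(self):
        ct_table, meta = simulate_panel(default_study_config(seed=27))
        dct = normalize_delta_ct(ct_table)
        # healthy samples have no grade, so the full covariate set must fail
        with pytest.raises(ValueError, match="grade"):
            covariate_adjustment(dct, meta, [dct.dct.columns[0]])
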