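"""Chi-square/Yates, Mann-Whitney U/PS/z and BH adjustment."""

import numpy as np
import pytest
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from sumosite import feature_encoding as fe
from sumosite import stats_tests as st


class TestChi2:
    def test_perfect_independence(self):
        stat, p, corrected = st.chi2_independence(st.ContingencyTable2x2(10, 10, 10, 10))
        assert stat == 0.0
        assert p == pytest.approx(1.0)
        assert corrected is False

    def test_hand_computed_uncorrected(self):
        # All expected counts are 12.5; statistic = 4 * 7.5^2 / 12.5 = 18.
        stat, p, corrected = st.chi2_independence(st.ContingencyTable2x2(20, 5, 5, 20))
        assert stat == pytest.approx(18.0)
        assert corrected is False

    def test_small_cell_triggers_yates(self):
        # A rare-feature table (observed cell 4 < 5) takes the corrected path.
        stat, p, corrected = st.chi2_independence(
            st.ContingencyTable2x2(4, 353, 712, 7197)
        )
        assert corrected is True

    def test_zero_column_untestable(self):
        with pytest.raises(st.UntestableError, match="constant"):
            st.chi2_independence(st.ContingencyTable2x2(0, 10, 0, 20))

    def test_empty_group_untestable(self):
        with pytest.raises(st.UntestableError, match="empty"):
            st.chi2_independence(st.ContingencyTable2x2(0, 0, 5, 20))

    @pytest.mark.parametrize("force_small_cell", [False, True])
    def test_agrees_with_scipy_on_random_tables(self, force_small_cell):
        rng = np.random.default_rng(42 + force_small_cell)
        checked = 0
        while checked < 300:
            if force_small_cell:
                table = np.array(
                    [
                        [rng.integers(0, 5), rng.integers(1, 500)],
                        [rng.integers(1, 500), rng.integers(1, 500)],
                    ]
                )
            else:
                table = rng.integers(5, 500, size=(2, 2))
            if table.sum(axis=0).min() == 0 or table.sum(axis=1).min() == 0:
                continue
            t = st.ContingencyTable2x2(*table.ravel())
            stat, p, corrected = st.chi2_independence(t)
            assert corrected == (table.min() < 5)
            ref = sps.chi2_contingency(table, correction=corrected)
            assert stat == pytest.approx(ref.statistic, abs=1e-9)
            assert p == pytest.approx(ref.pvalue, abs=1e-9)
            checked += 1


class TestMannWhitney:
    def test_identical_symmetric_groups(self):
        # U = n1*n2/2 by symmetry: z = 0, PS = 0.5, p = 1.
        res = st.mann_whitney([1, 2, 3, 4], [1, 2, 3, 4])
        assert res.u == pytest.approx(res.n1 * res.n2 / 2)
        assert res.ps == pytest.approx(0.5)
        assert res.z == pytest.approx(0.0)
        assert res.p == pytest.approx(1.0)

    def test_complete_separation(self):
        res = st.mann_whitney([10, 11, 12], [1, 2, 3])
        assert res.u == res.n1 * res.n2
        assert res.ps == 1.0

    def test_u_equals_pair_counting_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            pos = rng.integers(0, 6, size=4).astype(float)
            neg = rng.integers(0, 6, size=4).astype(float)
            res = st.mann_whitney(pos, neg)
            brute = sum(
                1.0 if a > b else 0.5 if a == b else 0.0 for a in pos for b in neg
            )
            assert res.u == pytest.approx(brute)

    def test_statistic_matches_scipy(self):
        rng = np.random.default_rng(6)
        for _ in range(200):
            pos = rng.normal(0.3, 1, size=rng.integers(3, 30))
            neg = rng.normal(0.0, 1, size=rng.integers(3, 30))
            res = st.mann_whitney(pos, neg)
            ref = sps.mannwhitneyu(pos, neg, alternative="two-sided")
            assert res.u == pytest.approx(ref.statistic, abs=1e-9)

    def test_z_formula_no_tie_correction(self):
        pos, neg = [1.0, 2.0, 2.0], [2.0, 3.0]
        res = st.mann_whitney(pos, neg)
        expected_z = (res.u - 3 * 2 / 2) / np.sqrt(3 * 2 * (3 + 2 + 1) / 12)
        assert res.z == pytest.approx(expected_z)

    def test_orientation_sum_property(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            a = rng.integers(0, 4, size=6).astype(float)
            b = rng.integers(0, 4, size=5).astype(float)
            ps_ab = st.mann_whitney(a, b).ps
            ps_ba = st.mann_whitney(b, a).ps
            assert ps_ab + ps_ba == pytest.approx(1.0)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            st.mann_whitney([], [1.0])


class TestBhAdjust:
    def test_single_p_unchanged(self):
        assert st.bh_adjust([0.03]) == pytest.approx([0.03])

    def test_hand_computed_stepup(self):
        # p * m / rank = [.04, .04, .04, .04]; cummin from the top changes nothing.
        assert st.bh_adjust([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)

    def test_bounds_property(self):
        rng = np.random.default_rng(8)
        p = rng.uniform(0, 1, 100)
        adj = st.bh_adjust(p)
        assert np.all(adj >= p) and np.all(adj <= 1.0)

    def test_matches_statsmodels(self):
        rng = np.random.default_rng(9)
        p = rng.uniform(0, 1, 137)
        ref = multipletests(p, method="fdr_bh")[1]
        assert np.allclose(st.bh_adjust(p), ref, atol=1e-12)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(10)
        p = rng.uniform(0, 1, 40)
        perm = rng.permutation(40)
        assert np.allclose(st.bh_adjust(p)[perm], st.bh_adjust(p[perm]), atol=1e-12)

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            st.bh_adjust([0.5, 1.5])


class TestRunComparisons:
    def test_full_screening_on_synthetic_data(self, small_dataset):
        _, df, _, _ = small_dataset
        results = st.run_comparisons(df)
        # One row per feature per strategy (testable or explicit placeholder).
        for strategy in st.STRATEGIES:
            assert (results["strategy"] == strategy).sum() == 137
        # The planted Glu-at-+2 enrichment is detected in strategy 1.
        row = results[
            (results.strategy == "pos_vs_neg") & (results.feature == "w+E_2")
        ].iloc[0]
        assert row["significant"]
        assert row["group1_stat"] > row["group2_stat"]
        # Consensus is the grouping variable of strategy 2: proportions 1 vs 0.
        cons = results[
            (results.strategy == "cons_pos_vs_noncons_pos")
            & (results.feature == "Consensus")
        ].iloc[0]
        assert (cons["group1_stat"], cons["group2_stat"]) == (1.0, 0.0)
        # Residues never observed in either small group yield explicit
        # untestable placeholders rather than silent omissions.
        strat2 = results[results.strategy == "cons_pos_vs_noncons_pos"]
        assert strat2["untestable"].any()
        # Both chi-square paths are exercised somewhere in the screening.
        tests_used = set(results.loc[~results.untestable, "test"])
        assert {"chi2", "chi2_yates", "mannwhitney"} <= tests_used

    def test_mannwhitney_columns_reported(self, small_dataset):
        _, df, _, _ = small_dataset
        results = st.run_comparisons(df, strategies=("pos_vs_neg",))
        mw = results[results.test == "mannwhitney"]
        assert len(mw) == 11
        assert mw["PS"].between(0, 1).all()
        assert mw["Z"].notna().all()

    def test_null_features_rarely_significant(self):
        # With no planted effects the BH-controlled significant fraction is low.
        rng = np.random.default_rng(123)
        n = 400
        rows = {"label": ["positive"] * (n // 2) + ["negative"] * (n // 2)}
        import pandas as pd

        df = pd.DataFrame(rows)
        for f in fe.FEATURE_NAMES:
            if f in fe.BINARY_FEATURES:
                df[f] = rng.integers(0, 2, n)
            else:
                df[f] = rng.normal(size=n)
        results = st.run_comparisons(df, strategies=("pos_vs_neg",))
        frac = results["significant"].mean()
        assert frac <= 0.10
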