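"""Moderated statistics, permutation FDR and volcano construction."""

import numpy as np
import pandas as pd
import pytest
from helpers import brute_force_permutation_fdr, make_design, make_table
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from qtap.diffstats import (
    FdrParams,
    moderated_t,
    permutation_fdr,
    differential_analysis,
    volcano_table,
)
from qtap.errors import ConfigError, StatisticError


class TestModeratedT:
    def test_identical_groups(self):
        r = moderated_t([1, 2, 3, 4], [1, 2, 3, 4], s0=0.1)
        assert r.difference == 0.0 and r.t == 0.0 and r.p == 1.0 and r.d_mod == 0.0

    def test_zero_variance_with_s0_regularization(self):
        r = moderated_t([10, 10, 10], [8, 8, 8], s0=0.1)
        assert r.difference == 2.0 and r.se == 0.0
        assert r.d_mod == pytest.approx(20.0)
        assert 0 < r.p <= 1

    def test_zero_variance_without_s0_is_undefined(self):
        with pytest.raises(StatisticError):
            moderated_t([10, 10, 10], [8, 8, 8], s0=0.0)

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(
        data=st.data(),
        n1=st.integers(2, 6),
        n2=st.integers(2, 6),
    )
    def test_unmoderated_matches_textbook_student(self, data, n1, n2):
        finite = st.floats(-30, 30, allow_nan=False)
        x = np.array(data.draw(st.lists(finite, min_size=n1, max_size=n1)))
        y = np.array(data.draw(st.lists(finite, min_size=n2, max_size=n2)))
        if np.var(x) == 0 and np.var(y) == 0:
            return
        r = moderated_t(x, y, s0=0.0)
        t_ref, p_ref = sps.ttest_ind(x, y)
        assert r.t == pytest.approx(t_ref, abs=1e-12, rel=1e-12)
        assert r.p == pytest.approx(p_ref, abs=1e-12, rel=1e-12)

    def test_welch_matches_scipy(self):
        rng = np.random.default_rng(21)
        for _ in range(50):
            x = rng.normal(0, 1, size=4)
            y = rng.normal(0.5, 2, size=6)
            r = moderated_t(x, y, s0=0.0, variant="welch")
            t_ref, p_ref = sps.ttest_ind(x, y, equal_var=False)
            assert r.t == pytest.approx(t_ref, rel=1e-12)
            assert r.p == pytest.approx(p_ref, rel=1e-12)

    def test_raising_s0_never_increases_dstar(self):
        rng = np.random.default_rng(22)
        x, y = rng.normal(0, 1, 4), rng.normal(1, 1, 4)
        mags = [abs(moderated_t(x, y, s0=s).d_mod) for s in (0.0, 0.1, 0.5, 1.0, 2.0)]
        assert all(a >= b for a, b in zip(mags, mags[1:]))

    def test_short_group_rejected(self):
        with pytest.raises(StatisticError):
            moderated_t([1.0], [1.0, 2.0])


class TestPermutationFdr:
    def _instance(self, n_rows=40, seed=0, effect_rows=3, n1=3, n2=3):
        rng = np.random.default_rng(seed)
        X = rng.normal(20, 1, size=(n_rows, n1 + n2))
        X[:effect_rows, :n1] += 4.0
        samples = [f"mock_r{i+1}" for i in range(n1)] + [f"treat_r{i+1}" for i in range(n2)]
        return make_table(X, samples=samples), make_design(n1, n2), X

    def test_exhaustive_null_matches_brute_force_enumeration(self):
        table, design, X = self._instance()
        params = FdrParams(s0=0.1, alpha=0.05, n_perm="exhaustive", seed=1)
        res = permutation_fdr(table, design, params)
        oracle = brute_force_permutation_fdr(X, mock_cols=(0, 1, 2), s0=0.1, alpha=0.05)
        assert res.null.assignments.shape[0] == oracle["n_assignments"] == 19
        frame, _ = differential_analysis(table, design, params)
        np.testing.assert_allclose(
            frame["d_mod"].to_numpy(), oracle["dstar_obs"], rtol=1e-12, atol=1e-12
        )
        np.testing.assert_allclose(res.null.thresholds, oracle["thresholds"], rtol=1e-12)
        np.testing.assert_allclose(res.null.fdr_raw, oracle["fdr_raw"], rtol=1e-12, atol=1e-12)
        np.testing.assert_allclose(res.null.fdr, oracle["fdr"], rtol=1e-12, atol=1e-12)
        assert res.threshold == pytest.approx(oracle["threshold"], rel=1e-12)
        np.testing.assert_array_equal(res.flags, oracle["flags"])

    def test_global_null_rarely_calls_anything(self):
        """Noise-only matrices: the estimator stays silent almost always."""
        fp = []
        for seed in range(50):
            rng = np.random.default_rng(seed)
            X = rng.normal(20, 0.3, size=(200, 8))
            table = make_table(X)
            res = permutation_fdr(table, make_design(4, 4), FdrParams(seed=seed))
            fp.append(int(res.flags.sum()))
        assert np.mean(fp) <= 0.5

    def test_single_planted_effect_is_called(self):
        """A D = 5 sigma, tiny-spread row among 499 null rows is flagged."""
        rng = np.random.default_rng(123)
        X = rng.normal(20, 0.3, size=(500, 8))
        X[0, :4] = 20 + 5 * 0.3 + rng.normal(0, 0.01, 4)
        X[0, 4:] = 20 + rng.normal(0, 0.01, 4)
        table = make_table(X)
        res = permutation_fdr(table, make_design(4, 4), FdrParams(seed=3))
        assert res.flags[0]
        assert res.flags.sum() <= 3

    def test_alpha_monotonicity(self):
        table, design, _ = self._instance(seed=5)
        sets = []
        for alpha in (0.01, 0.05, 0.1, 0.25):
            res = permutation_fdr(table, design, FdrParams(alpha=alpha, seed=2))
            sets.append({i for i in np.nonzero(res.flags)[0]})
        for small, big in zip(sets, sets[1:]):
            assert small <= big

    def test_fdr_curve_monotone_nonincreasing(self):
        table, design, _ = self._instance(seed=6)
        res = permutation_fdr(table, design, FdrParams(seed=2))
        assert (np.diff(res.null.fdr) <= 1e-15).all()

    def test_column_relabeling_invariance(self):
        """Reordering samples (design updated) leaves observed stats alone."""
        table, design, X = self._instance(n_rows=20, seed=7, n1=4, n2=4)
        params = FdrParams(seed=4)
        frame_a, _ = differential_analysis(table, design, params)
        order = [3, 0, 2, 1, 7, 5, 4, 6]
        cols = [table.sample_columns[i] for i in order]
        shuffled = make_table(X[:, order], samples=cols)
        frame_b, _ = differential_analysis(shuffled, design, params)
        np.testing.assert_allclose(
            frame_a["d_mod"].to_numpy(), frame_b["d_mod"].to_numpy(), atol=1e-12
        )
        np.testing.assert_allclose(
            frame_a["p_value"].to_numpy(), frame_b["p_value"].to_numpy(), atol=1e-12
        )

    def test_sampled_null_is_deterministic_under_seed(self):
        rng = np.random.default_rng(30)
        X = rng.normal(20, 1, size=(30, 12))
        X[:2, :6] += 3
        samples = [f"mock_r{i+1}" for i in range(6)] + [f"treat_r{i+1}" for i in range(6)]
        table = make_table(X, samples=samples)
        design = make_design(6, 6)
        params = FdrParams(n_perm=100, seed=11, exhaustive_cap=50)
        a = permutation_fdr(table, design, params)
        b = permutation_fdr(table, design, params)
        assert not a.null.exhaustive
        assert a.null.assignments.shape == (100, 12)
        np.testing.assert_array_equal(a.flags, b.flags)
        np.testing.assert_array_equal(a.null.assignments, b.null.assignments)

    def test_incomplete_matrix_rejected(self):
        X = np.ones((3, 8)) + np.arange(8)
        X[0, 0] = np.nan
        with pytest.raises(ConfigError, match="missing"):
            permutation_fdr(make_table(X), make_design(4, 4), FdrParams())

    def test_too_small_design_rejected(self):
        X = np.arange(8.0).reshape(2, 4)
        table = make_table(X, samples=["mock_r1", "treat_r1", "treat_r2", "treat_r3"])
        with pytest.raises(ConfigError):
            permutation_fdr(table, make_design(1, 3), FdrParams())

    def test_bh_on_null_p_values_controls_fdr(self):
        """Cross-method check: s0=0 p-values + BH keep empirical FDR <= alpha."""
        from statsmodels.stats.multitest import multipletests

        fdps = []
        design = make_design(4, 4)
        for seed in range(100):
            rng = np.random.default_rng(1000 + seed)
            X = rng.normal(0, 1, size=(200, 8))
            frame, _ = differential_analysis(
                make_table(X), design, FdrParams(s0=0.0, alpha=0.05, seed=seed)
            )
            reject, *_ = multipletests(frame["p_value"], alpha=0.05, method="fdr_bh")
            fdps.append(1.0 if reject.any() else 0.0)
        # all rows are null, so FDP = 1{any rejection}; BH bounds its mean by alpha
        assert np.mean(fdps) <= 0.05 + 2 * np.sqrt(0.05 * 0.95 / 100)


class TestVolcano:
    def test_table_and_sign_convention(self):
        table = make_table(
            np.array(
                [
                    [20.0, 20.1, 19.9, 20.0, 24.0, 24.1, 23.9, 24.0],  # treatment-enriched
                    [20.0, 20.2, 19.8, 20.1, 20.1, 19.9, 20.0, 20.2],
                ]
            ),
            ids=["D14", "BG"],
        )
        frame, _ = differential_analysis(table, make_design(4, 4), FdrParams(seed=1))
        v = volcano_table(frame)
        d14 = v.set_index("group_id").loc["D14"]
        # x = log2(mock/treatment): recruited-under-treatment sits left of zero
        assert d14["difference"] < 0
        assert bool(d14["significant"])

    def test_p_one_maps_to_zero_height(self):
        frame = pd.DataFrame(
            {
                "group_id": ["A"],
                "gene_label": ["a"],
                "difference": [0.0],
                "neg_log10_p": [-np.log10(1.0)],
                "significant": [False],
            }
        )
        assert volcano_table(frame)["neg_log10_p"].iloc[0] == 0.0

    def test_empty_significant_set_all_flags_false(self):
        rng = np.random.default_rng(17)
        table = make_table(rng.normal(20, 0.3, size=(50, 8)))
        frame, fdr = differential_analysis(table, make_design(4, 4), FdrParams(seed=2))
        if np.isinf(fdr.threshold):
            assert not volcano_table(frame)["significant"].any()
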