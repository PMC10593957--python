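"""Differential induction: normalization, dispersion, Wald test, TINPATs."""
import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

from tinpatneo.de import (
    bh_adjust,
    call_tinpats,
    delta_delta_ct,
    estimate_dispersion,
    size_factors,
    tpm,
    wald_test,
)


def nb_counts(rng, mu, alpha, shape):
    r = 1.0 / alpha
    return rng.negative_binomial(r, r / (r + mu), size=shape)


class TestSizeFactors:
    def test_identical_samples_give_unit_factors(self):
        counts = pd.DataFrame({"a": [10, 20, 5], "b": [10, 20, 5]})
        assert np.allclose(size_factors(counts), 1.0)

    def test_doubled_sample_has_double_factor(self):
        counts = pd.DataFrame({"a": [10, 20, 5], "b": [20, 40, 10]})
        sf = size_factors(counts)
        assert sf["b"] / sf["a"] == pytest.approx(2.0)

    def test_matches_literal_median_of_ratios(self):
        rng = np.random.default_rng(3)
        counts = pd.DataFrame(rng.integers(1, 500, size=(50, 6)))
        sf = size_factors(counts)
        mat = counts.to_numpy(float)
        gm = np.exp(np.log(mat).mean(axis=1))
        expected = [np.median(mat[:, j] / gm) for j in range(6)]
        assert np.allclose(sf, expected)

    def test_no_common_nonzero_transcript_is_an_error(self):
        counts = pd.DataFrame({"a": [0, 5], "b": [5, 0]})
        with pytest.raises(ValueError):
            size_factors(counts)


class TestDispersion:
    def test_recovers_planted_alpha(self):
        rng = np.random.default_rng(8)
        mu, alpha, n = 200.0, 0.1, 50
        counts = pd.DataFrame(nb_counts(rng, mu, alpha, (300, n)))
        cond = {c: "x" for c in counts.columns}
        est = estimate_dispersion(counts, cond)
        assert abs(est.median() - alpha) < 0.03

    def test_poisson_data_estimates_near_zero(self):
        rng = np.random.default_rng(9)
        counts = pd.DataFrame(rng.poisson(100, size=(300, 60)))
        cond = {c: "x" for c in counts.columns}
        assert estimate_dispersion(counts, cond).median() < 0.01

    def test_constant_counts_floor_at_alpha_min(self):
        counts = pd.DataFrame(np.full((5, 6), 50))
        cond = {c: "x" for c in counts.columns}
        assert (estimate_dispersion(counts, cond) == 1e-8).all()


class TestWald:
    def _cond(self, n):
        cols = [f"c{i}" for i in range(n)] + [f"t{i}" for i in range(n)]
        return cols, {c: ("treated" if c.startswith("t") else "control") for c in cols}

    def test_copied_columns_give_zero_lfc(self):
        rng = np.random.default_rng(1)
        half = rng.integers(10, 300, size=(20, 4))
        cols, cond = self._cond(4)
        counts = pd.DataFrame(np.hstack([half, half]), columns=cols)
        res = wald_test(counts, cond, ("treated", "control"))
        assert np.allclose(res["log2_fc"], 0.0, atol=1e-9)

    def test_recovers_planted_lfc(self):
        # 20 induced rows among 200 so normalization stays anchored on nulls
        rng = np.random.default_rng(2)
        G, n, lfc = 200, 3, 4.0
        mu = np.full(G, 100.0)
        mu_t = mu.copy()
        mu_t[:20] *= 2**lfc
        ctrl = nb_counts(rng, mu[:, None], 0.05, (G, n))
        trt = nb_counts(rng, mu_t[:, None], 0.05, (G, n))
        cols, cond = self._cond(n)
        counts = pd.DataFrame(np.hstack([ctrl, trt]), columns=cols)
        res = wald_test(counts, cond, ("treated", "control"))
        assert abs(np.median(res["log2_fc"].iloc[:20]) - lfc) < 0.5
        assert abs(np.median(res["log2_fc"].iloc[20:])) < 0.2

    def test_agrees_with_statsmodels_glm(self):
        """Independent oracle: statsmodels NB GLM with the same fixed alpha."""
        rng = np.random.default_rng(4)
        n, alpha = 5, 0.08
        cols, cond = self._cond(n)
        counts = pd.DataFrame(
            np.hstack([nb_counts(rng, 150.0, alpha, (10, n)),
                       nb_counts(rng, 450.0, alpha, (10, n))]),
            columns=cols,
        )
        sf = pd.Series(1.0, index=cols)
        disp = pd.Series(alpha, index=counts.index)
        res = wald_test(counts, cond, ("treated", "control"), dispersion=disp, sf=sf)
        X = sm.add_constant(np.array([0.0] * n + [1.0] * n))
        for i in range(len(counts)):
            fit = sm.GLM(
                counts.iloc[i].to_numpy(), X,
                family=sm.families.NegativeBinomial(alpha=alpha),
            ).fit()
            assert res["log2_fc"].iloc[i] == pytest.approx(fit.params[1] / np.log(2), abs=1e-5)
            assert res["se"].iloc[i] == pytest.approx(fit.bse[1] / np.log(2), rel=1e-4)

    def test_all_zero_treated_group_flagged_na(self):
        rng = np.random.default_rng(5)
        cols, cond = self._cond(3)
        mat = rng.integers(20, 200, size=(5, 6))
        mat[0, 3:] = 0  # separation: no treated counts at all
        counts = pd.DataFrame(mat, columns=cols)
        res = wald_test(counts, cond, ("treated", "control"))
        assert np.isnan(res["p_value"].iloc[0])
        assert res["p_value"].iloc[1:].notna().all()

    def test_covariate_adjusts_cell_line_offsets(self):
        """The condition effect is recovered despite large per-line baselines."""
        rng = np.random.default_rng(6)
        lines = ["A"] * 4 + ["B"] * 4
        cond = {}
        cov = {}
        cols = []
        mu_line = {"A": 50.0, "B": 800.0}
        G, lfc, n_eff = 150, 3.0, 25  # effect planted in the first 25 rows only
        mats = []
        for j, line in enumerate(lines):
            treated = j % 2 == 1
            c = f"s{j}"
            cols.append(c)
            cond[c] = "treated" if treated else "control"
            cov[c] = line
            m = np.full(G, mu_line[line])
            if treated:
                m[:n_eff] *= 2**lfc
            mats.append(nb_counts(rng, m[:, None], 0.05, (G, 1)))
        counts = pd.DataFrame(np.hstack(mats), columns=cols)
        res = wald_test(counts, cond, ("treated", "control"), covariate=cov)
        assert abs(np.median(res["log2_fc"].iloc[:n_eff]) - lfc) < 0.3
        assert abs(np.median(res["log2_fc"].iloc[n_eff:])) < 0.2


class TestBH:
    def test_hand_computed_step_up(self):
        assert np.allclose(bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_single_and_degenerate_inputs(self):
        assert bh_adjust([0.2]) == pytest.approx([0.2])
        assert np.allclose(bh_adjust([1.0, 1.0, 1.0]), 1.0)

    def test_na_passthrough_and_statsmodels_agreement(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(size=40)
        assert np.allclose(bh_adjust(p), multipletests(p, method="fdr_bh")[1])
        with_na = np.concatenate([p, [np.nan]])
        adj = bh_adjust(with_na)
        assert np.isnan(adj[-1]) and np.allclose(adj[:-1], multipletests(p, method="fdr_bh")[1])

    def test_monotone_in_ranks(self):
        rng = np.random.default_rng(1)
        p = rng.uniform(size=100)
        adj = bh_adjust(p)
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-12).all()


class TestCallTinpats:
    def _frame(self, lfc, padj):
        return pd.DataFrame({"log2_fc": [lfc], "p_value": [padj], "p_adj": [padj]}, index=["t1"])

    def test_novel_significant_is_tinpat(self):
        out = call_tinpats(self._frame(3.0, 0.001), {"t1": "non_chimeric"})
        assert bool(out["tinpat"].iloc[0]) and bool(out["induced"].iloc[0])

    def test_known_significant_is_induced_not_tinpat(self):
        out = call_tinpats(self._frame(3.0, 0.001), {"t1": "known"})
        assert bool(out["induced"].iloc[0]) and not bool(out["tinpat"].iloc[0])

    def test_thresholds_are_strict(self):
        out = call_tinpats(self._frame(2.0, 0.001), {"t1": "chimeric"})
        assert not bool(out["tinpat"].iloc[0])
        out = call_tinpats(self._frame(3.0, 0.01), {"t1": "chimeric"})
        assert not bool(out["tinpat"].iloc[0])

    def test_missing_class_excluded_with_warning(self):
        with pytest.warns(UserWarning):
            out = call_tinpats(self._frame(3.0, 0.001), {})
        assert not bool(out["tinpat"].iloc[0])


class TestTpm:
    def test_single_transcript_takes_all(self):
        out = tpm(pd.DataFrame({"s": [7]}), pd.Series([100]))
        assert out.iloc[0, 0] == pytest.approx(1e6)

    def test_hand_computed_two_transcript_case(self):
        out = tpm(pd.DataFrame({"s": [10, 10]}), pd.Series([100.0, 200.0]))
        assert np.allclose(out["s"], [666666.6667, 333333.3333], rtol=1e-6)

    def test_columns_sum_to_one_million(self):
        rng = np.random.default_rng(2)
        counts = pd.DataFrame(rng.integers(0, 1000, size=(30, 4)))
        counts.iloc[:, 0] += 1
        out = tpm(counts, pd.Series(rng.integers(200, 5000, size=30)))
        assert np.allclose(out.sum(axis=0), 1e6)


class TestDeltaDeltaCt:
    def _table(self):
        return pd.DataFrame(
            {
                "condition": ["treated", "control"],
                "ct_target": [20.0, 24.0],
                "ct_housekeeping": [15.0, 15.0],
            }
        )

    def test_sixteen_fold_change(self):
        out = delta_delta_ct(self._table(), "control")
        assert out.loc[0, "relative_expression"] == pytest.approx(16.0)
        assert out.loc[1, "relative_expression"] == pytest.approx(1.0)

    def test_invariance_to_shared_ct_shift(self):
        t = self._table()
        t2 = t.copy()
        t2["ct_target"] += 1
        t2["ct_housekeeping"] += 1
        a = delta_delta_ct(t, "control")["relative_expression"]
        b = delta_delta_ct(t2, "control")["relative_expression"]
        assert np.allclose(a, b)

    def test_missing_housekeeping_dropped(self):
        t = self._table()
        t.loc[0, "ct_housekeeping"] = np.nan
        with pytest.warns(UserWarning):
            out = delta_delta_ct(t, "control")
        assert len(out) == 1
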