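import numpy as np
import pandas as pd
import pytest
from scipy import stats

from chirpkit.lfq import (
    LFQMatrix,
    TestParams as SamParams,
    classify_enrichment,
    compartment_counts,
    impute,
    load_interactor_table,
    one_tailed_t_bonferroni,
    permutation_fdr,
    preprocess,
    s0_t_test,
)

SAMPLES = [f"fl_{i}" for i in range(1, 6)] + [f"mut_{i}" for i in range(1, 6)]
CONDITIONS = pd.Series(["fl"] * 5 + ["mut"] * 5, index=SAMPLES)


def mk_matrix(intens: dict[str, list], flags: dict[str, dict] | None = None) -> LFQMatrix:
    df = pd.DataFrame.from_dict(intens, orient="index", columns=SAMPLES, dtype=float)
    flag_df = pd.DataFrame(
        False, index=df.index, columns=["reverse", "contaminant", "identified_by_site"]
    )
    for pid, d in (flags or {}).items():
        for k, v in d.items():
            flag_df.loc[pid, k] = v
    return LFQMatrix(df, CONDITIONS, flag_df)


class TestPreprocess:
    def test_reverse_flag_dropped(self):
        m = mk_matrix({"a": [100.0] * 10, "b": [100.0] * 10}, {"a": {"reverse": True}})
        log2m, _ = preprocess(m)
        assert list(log2m.index) == ["b"]

    def test_five_of_five_exclusive(self):
        vals = [100.0] * 5 + [np.nan] * 5
        m = mk_matrix({"a": vals})
        log2m, exclusive = preprocess(m)
        assert list(log2m.index) == ["a"]
        assert bool(exclusive["a"])

    def test_four_of_five_both_dropped(self):
        vals = [100.0] * 4 + [np.nan] + [100.0] * 4 + [np.nan]
        m = mk_matrix({"a": vals, "keep": [50.0] * 10})
        log2m, exclusive = preprocess(m)
        assert list(log2m.index) == ["keep"]
        assert not bool(exclusive["keep"])

    def test_log2_applied(self):
        m = mk_matrix({"a": [8.0] * 10})
        log2m, _ = preprocess(m)
        np.testing.assert_allclose(log2m.loc["a"], 3.0)

    def test_wrong_design_is_error(self):
        df = pd.DataFrame([[1.0] * 8], index=["a"], columns=SAMPLES[:8])
        flags = pd.DataFrame(
            False, index=["a"], columns=["reverse", "contaminant", "identified_by_site"]
        )
        with pytest.raises(ValueError, match="5 vs 5"):
            preprocess(LFQMatrix(df, CONDITIONS[SAMPLES[:8]], flags))


class TestImpute:
    def test_no_missing_unchanged(self, rng):
        df = pd.DataFrame(rng.normal(25, 1, (20, 10)), columns=SAMPLES)
        out = impute(df, seed=0)
        pd.testing.assert_frame_equal(out, df)

    def test_moments_of_imputed_cells(self):
        rng = np.random.default_rng(1)
        n = 12_000
        observed = rng.normal(25, 1, n)
        col = np.concatenate([observed, np.full(10_000, np.nan)])
        df = pd.DataFrame({"c": col})
        mu, sd = np.nanmean(col), np.nanstd(col, ddof=1)
        out = impute(df, downshift=2, width=0.2, seed=7)
        imputed = out["c"].iloc[n:]
        se_mean = 0.2 * sd / np.sqrt(10_000)
        assert abs(imputed.mean() - (mu - 2 * sd)) < 3 * se_mean
        assert abs(imputed.std(ddof=1) - 0.2 * sd) < 3 * 0.2 * sd / np.sqrt(2 * 10_000)

    def test_observed_cells_untouched(self, rng):
        df = pd.DataFrame(rng.normal(25, 1, (50, 10)), columns=SAMPLES)
        mask = pd.DataFrame(rng.random((50, 10)) < 0.2, columns=SAMPLES)
        df = df.mask(mask)
        out = impute(df, seed=3)
        pd.testing.assert_frame_equal(out.where(~mask), df.where(~mask))
        assert not out.isna().any().any()

    def test_deterministic_under_seed(self, rng):
        df = pd.DataFrame(rng.normal(25, 1, (50, 10)), columns=SAMPLES).mask(
            rng.random((50, 10)) < 0.3
        )
        pd.testing.assert_frame_equal(impute(df, seed=5), impute(df, seed=5))

    def test_sparse_column_is_error(self):
        df = pd.DataFrame({"c": [25.0] + [np.nan] * 9})
        with pytest.raises(ValueError, match="observed"):
            impute(df, seed=0)


class TestS0Test:
    A = [0.9, 1.1, 1.0, 1.2, 0.8]
    B = [2.1, 1.9, 2.2, 1.8, 2.0]

    def test_equal_means(self):
        d, p = s0_t_test([1.0, 2.0, 3.0], [3.0, 2.0, 1.0], s0=0.1)
        assert d == 0.0
        assert p == 1.0

    def test_s0_zero_matches_pooled_t(self):
        d, p = s0_t_test(self.A, self.B, s0=0.0)
        t_ref = stats.ttest_ind(self.A, self.B, equal_var=True)
        assert d == pytest.approx(t_ref.statistic, abs=1e-10)
        assert p == pytest.approx(t_ref.pvalue, abs=1e-10)

    def test_s0_zero_oracle_1000_cases(self):
        rng = np.random.default_rng(0)
        for _ in range(1000):
            a = rng.normal(0, 1, 5)
            b = rng.normal(rng.normal(), 1, 5)
            d, p = s0_t_test(a, b, s0=0.0)
            ref = stats.ttest_ind(a, b, equal_var=True)
            assert d == pytest.approx(ref.statistic, abs=1e-10)
            assert p == pytest.approx(ref.pvalue, abs=1e-10)

    def test_d_decreases_in_s0(self):
        d_values = [s0_t_test(self.B, self.A, s0=s)[0] for s in (0.0, 0.1, 0.5, 1.0)]
        assert all(x > y > 0 for x, y in zip(d_values, d_values[1:]))

    def test_zero_variance_s0_zero_is_error(self):
        with pytest.raises(ValueError, match="variance"):
            s0_t_test([1.0, 1.0, 1.0], [1.0, 1.0, 1.0], s0=0.0)

    def test_permutation_p_in_range(self):
        d, p = s0_t_test(self.A, self.B, s0=0.1)
        assert d < 0
        assert 0 < p <= 1
        # strong separation: the observed split should be among the extremes
        assert p <= 2 / 252 + 1e-12


class TestPermutationFdr:
    def _null_matrix(self, n=500, seed=0):
        rng = np.random.default_rng(seed)
        return pd.DataFrame(rng.normal(25, 1, (n, 10)), columns=SAMPLES,
                            index=[f"P{i}" for i in range(n)])

    def test_null_calls_within_alpha(self):
        df = self._null_matrix()
        result, _ = permutation_fdr(df, CONDITIONS, SamParams())
        frac = result["significant"].mean()
        se = np.sqrt(0.05 * 0.95 / len(df))
        assert frac <= 0.05 + 3 * se

    def test_planted_effects_recovered(self):
        df = self._null_matrix(seed=2)
        planted = df.index[:10]
        df.loc[planted, [c for c in SAMPLES if c.startswith("fl")]] += 4.0
        result, _ = permutation_fdr(df, CONDITIONS, SamParams())
        assert result.loc[planted, "significant"].sum() >= 8

    def test_label_swap_leaves_null_invariant(self):
        df = self._null_matrix(seed=3)
        swapped = CONDITIONS.map({"fl": "mut", "mut": "fl"})
        r1, _ = permutation_fdr(df, CONDITIONS, SamParams())
        r2, _ = permutation_fdr(df, swapped, SamParams())
        np.testing.assert_allclose(np.abs(r1["d_s0"]), np.abs(r2["d_s0"]))
        pd.testing.assert_series_equal(r1["p_value"], r2["p_value"])

    def test_unbalanced_is_error(self):
        df = self._null_matrix().iloc[:, :9]
        with pytest.raises(ValueError, match="unbalanced"):
            permutation_fdr(df, CONDITIONS[df.columns], SamParams())

    def test_curve_is_symmetric_boundary(self):
        df = self._null_matrix(seed=4)
        df.loc[df.index[:20], [c for c in SAMPLES if c.startswith("fl")]] += 4.0
        _, curve = permutation_fdr(df, CONDITIONS, SamParams())
        if len(curve):
            neg = curve[curve.log2_ratio < 0]["neg_log10_p"].to_numpy()
            pos = curve[curve.log2_ratio > 0]["neg_log10_p"].to_numpy()
            np.testing.assert_allclose(neg[::-1], pos, rtol=1e-9)


class TestClassifyAndCompartments:
    def test_worked_example_rows(self):
        records = pd.DataFrame(
            {
                "log2_ratio": [-1.27, -0.5, -3.0],
                "neg_log10_p": [3.44, 5.0, 2.0],
            },
            index=["Brd2", "fc_gate", "p_gate"],
        )
        out = classify_enrichment(records)
        assert bool(out.loc["Brd2", "enriched_fl"])
        assert not out.loc["fc_gate", "enriched_fl"]  # |log2| < 1
        assert not out.loc["p_gate", "enriched_fl"]  # p = 0.01 > 0.002
        assert not out["enriched_mut"].any()

    def test_mutant_direction(self):
        records = pd.DataFrame({"log2_ratio": [2.0], "p_value": [1e-4]}, index=["x"])
        out = classify_enrichment(records)
        assert bool(out.loc["x", "enriched_mut"]) and not out.loc["x", "enriched_fl"]

    def test_fixture_compartment_counts(self):
        table = load_interactor_table()
        enriched = classify_enrichment(table)
        counts = compartment_counts(enriched)
        assert counts["Nuclear pore"] == 11
        assert counts["Nucleolus"] == 13
        assert counts["Nuclear lamin"] == 6

    def test_fixture_extrema_and_shape(self):
        table = load_interactor_table()
        assert len(table) == 48
        assert table["log2_ratio"].max() == pytest.approx(-1.08)
        assert table["neg_log10_p"].min() == pytest.approx(2.73)
        assert int(table["exclusive"].sum()) == 4

    def test_empty_records_all_zero(self):
        records = classify_enrichment(
            pd.DataFrame({"log2_ratio": [], "p_value": [], "compartment": []})
        )
        assert compartment_counts(records) == {}


class TestOneTailedT:
    def test_m_one_is_raw(self, rng):
        x = rng.normal(2, 1, 10)
        t, p1 = one_tailed_t_bonferroni(x, 0.0, m=1)
        ref = stats.ttest_1samp(x, 0.0, alternative="greater")
        assert t == pytest.approx(ref.statistic)
        assert p1 == pytest.approx(ref.pvalue)

    def test_all_equal_mu0_half(self):
        t, p = one_tailed_t_bonferroni([3.0, 3.0, 3.0], 3.0, m=1)
        assert (t, p) == (0.0, 0.5)

    def test_bonferroni_scaling(self, rng):
        x = rng.normal(2, 1, 10)
        _, p1 = one_tailed_t_bonferroni(x, 0.0, m=1)
        _, p3 = one_tailed_t_bonferroni(x, 0.0, m=3)
        assert p3 == pytest.approx(min(1.0, 3 * p1))

    def test_planted_shift_matches_t_cdf(self, rng):
        x = rng.normal(1.0, 1.0, 12)
        t, p = one_tailed_t_bonferroni(x, 0.0, m=1)
        expected = stats.t.sf(t, df=11)
        assert p == pytest.approx(expected)

    def test_zero_variance_off_mu0_is_error(self):
        with pytest.raises(ValueError, match="variance"):
            one_tailed_t_bonferroni([2.0, 2.0, 2.0], 0.0)
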