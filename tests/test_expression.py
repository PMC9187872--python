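import numpy as np
import pandas as pd
import pytest
from scipy import stats

from chirpkit.expression import (
    cluster_targets,
    de_status,
    de_status_table,
    lnc_target_correlation,
    normalize_to_control_day5,
    screen_candidates,
)


@pytest.fixture
def metadata():
    rows = []
    for cond in ("CON", "KD"):
        for day in (5, 7):
            for rep in (1, 2, 3, 4):
                rows.append((f"{cond}_d{day}_r{rep}", cond, day, rep))
    return pd.DataFrame(
        rows, columns=["sample", "condition", "day", "replicate"]
    ).set_index("sample")


class TestDeStatus:
    @pytest.mark.parametrize(
        "stat,fdr,expected",
        [
            (2.5, 0.01, "up"),
            (5.0, 0.2, "unchanged"),  # fails the FDR gate
            (-2.0, 0.04, "unchanged"),  # strict inequality at the boundary
            (2.0, 0.04, "unchanged"),
            (-2.01, 0.049, "down"),
            (0.5, 0.001, "unchanged"),
            (3.0, 0.05, "unchanged"),  # fdr boundary is strict too
        ],
    )
    def test_rule(self, stat, fdr, expected):
        assert de_status(stat, fdr) == expected

    def test_table_invariant_to_row_order(self, rng):
        de = pd.DataFrame(
            {"stat": rng.normal(0, 3, 200), "fdr": rng.uniform(0, 0.1, 200)},
            index=[f"g{i}" for i in range(200)],
        )
        a = de_status_table(de).value_counts()
        b = de_status_table(de.sample(frac=1, random_state=0)).value_counts()
        assert a.sort_index().equals(b.sort_index())


class TestNormalize:
    def test_control_day5_mean_is_one(self, metadata, rng):
        expr = pd.DataFrame(
            rng.lognormal(2, 1, size=(10, 16)),
            index=[f"g{i}" for i in range(10)],
            columns=metadata.index,
        )
        norm, bad = normalize_to_control_day5(expr, metadata)
        ref = metadata.index[(metadata.condition == "CON") & (metadata.day == 5)]
        np.testing.assert_allclose(norm[ref].mean(axis=1), 1.0)
        assert len(bad) == 0

    def test_doubling_reads_as_two(self, metadata):
        expr = pd.DataFrame(
            [[1.0] * 16], index=["g0"], columns=metadata.index, dtype=float
        )
        kd7 = metadata.index[(metadata.condition == "KD") & (metadata.day == 7)]
        expr.loc["g0", kd7] = 2.0
        norm, _ = normalize_to_control_day5(expr, metadata)
        np.testing.assert_allclose(norm.loc["g0", kd7], 2.0)

    def test_matches_direct_division(self, metadata, rng):
        expr = pd.DataFrame(
            rng.lognormal(2, 1, size=(30, 16)),
            index=[f"g{i}" for i in range(30)],
            columns=metadata.index,
        )
        norm, _ = normalize_to_control_day5(expr, metadata)
        ref = metadata.index[(metadata.condition == "CON") & (metadata.day == 5)]
        expected = expr.div(expr[ref].mean(axis=1), axis=0)
        pd.testing.assert_frame_equal(norm, expected)

    def test_zero_reference_excluded(self, metadata):
        expr = pd.DataFrame(
            np.ones((2, 16)), index=["ok", "zero"], columns=metadata.index
        )
        ref = metadata.index[(metadata.condition == "CON") & (metadata.day == 5)]
        expr.loc["zero", ref] = 0.0
        norm, bad = normalize_to_control_day5(expr, metadata)
        assert list(bad) == ["zero"]
        assert list(norm.index) == ["ok"]

    def test_no_reference_samples_is_error(self, metadata):
        meta = metadata[metadata.day == 7]
        expr = pd.DataFrame(
            np.ones((1, len(meta))), index=["g"], columns=meta.index
        )
        with pytest.raises(ValueError, match="CON day-5"):
            normalize_to_control_day5(expr, meta)


class TestClusterTargets:
    def _planted(self, metadata, rng, n_down=8, n_up=8):
        kd = metadata.condition == "KD"
        genes, names = [], []
        for i in range(n_down):
            base = np.full(16, 100.0)
            base[kd.to_numpy()] = 10.0
            genes.append(base * rng.normal(1, 0.05, 16))
            names.append(f"down{i}")
        for i in range(n_up):
            base = np.full(16, 100.0)
            base[kd.to_numpy()] = 800.0
            genes.append(base * rng.normal(1, 0.05, 16))
            names.append(f"up{i}")
        return pd.DataFrame(genes, index=names, columns=metadata.index)

    def test_planted_groups_recovered(self, metadata, rng):
        expr = self._planted(metadata, rng)
        labels, order = cluster_targets(expr, metadata)
        assert set(labels[labels.index.str.startswith("down")]) == {"I"}
        assert set(labels[labels.index.str.startswith("up")]) == {"II"}
        assert sorted(order) == sorted(expr.index)

    def test_duplicate_rows_same_label(self, metadata, rng):
        expr = self._planted(metadata, rng)
        expr.loc["down_copy"] = expr.loc["down0"]
        labels, _ = cluster_targets(expr, metadata)
        assert labels["down_copy"] == labels["down0"]

    def test_gene_permutation_invariant(self, metadata, rng):
        expr = self._planted(metadata, rng)
        labels1, _ = cluster_targets(expr, metadata)
        shuffled = expr.sample(frac=1, random_state=1)
        labels2, _ = cluster_targets(shuffled, metadata)
        assert labels1.sort_index().equals(labels2.sort_index())

    def test_constant_matrix_is_error(self, metadata):
        expr = pd.DataFrame(
            np.ones((4, 16)), index=list("abcd"), columns=metadata.index
        )
        with pytest.raises(ValueError, match="constant"):
            cluster_targets(expr, metadata)

    def test_single_gene_is_error(self, metadata):
        expr = pd.DataFrame(
            np.ones((1, 16)), index=["a"], columns=metadata.index
        )
        with pytest.raises(ValueError, match="two genes"):
            cluster_targets(expr, metadata)


class TestCorrelation:
    def test_scaled_copy_r_one(self):
        lnc = pd.Series([1.0, 2, 3, 4, 5, 6, 7, 8])
        assert lnc_target_correlation(lnc, 2 * lnc) == pytest.approx(1.0)

    def test_negated_r_minus_one(self):
        lnc = pd.Series([1.0, 2, 3, 4, 5, 6, 7, 8])
        assert lnc_target_correlation(lnc, -lnc) == pytest.approx(-1.0)

    def test_matches_textbook_formula(self, rng):
        x = pd.Series(rng.normal(0, 1, 8))
        y = pd.Series(rng.normal(0, 1, 8))
        r = lnc_target_correlation(x, y)
        xc, yc = x - x.mean(), y - y.mean()
        expected = (xc * yc).sum() / np.sqrt((xc**2).sum() * (yc**2).sum())
        assert r == pytest.approx(expected, abs=1e-12)

    def test_zero_variance_is_nan(self):
        lnc = pd.Series([1.0, 1, 1, 1])
        assert np.isnan(lnc_target_correlation(lnc, pd.Series([1.0, 2, 3, 4])))

    def test_too_few_samples_is_error(self):
        with pytest.raises(ValueError, match="3"):
            lnc_target_correlation(pd.Series([1.0, 2]), pd.Series([1.0, 2]))

    def test_day_subsetting(self, metadata, rng):
        expr_l = pd.Series(rng.normal(10, 1, 16), index=metadata.index)
        expr_t = pd.Series(rng.normal(10, 1, 16), index=metadata.index)
        r5 = lnc_target_correlation(expr_l, expr_t, metadata, 5)
        d5 = metadata.index[metadata.day == 5]
        expected = stats.pearsonr(expr_l[d5], expr_t[d5]).statistic
        assert r5 == pytest.approx(expected)


class TestScreen:
    def _inputs(self, rng):
        idx = pd.Index([f"t{i}" for i in range(6)], name="transcript")
        tissues = pd.DataFrame(
            0.1, index=idx, columns=["cortex", "hippocampus", "liver", "heart"]
        )
        cells = ["NE", "ERG", "MRG", "LRG"]
        before = pd.DataFrame(1.0, index=idx, columns=cells)
        after = pd.DataFrame(1.0, index=idx, columns=cells)
        cons = pd.Series(True, index=idx)
        # t0: good increasing candidate
        tissues.loc["t0", ["cortex"]] = 8.0
        after.loc["t0"] = [5.1, 4.9, 5.2, 5.0]
        # t1: expressed in liver
        tissues.loc["t1", ["cortex", "liver"]] = 8.0
        after.loc["t1"] = [5.1, 4.9, 5.2, 5.0]
        # t2: neural but flat
        tissues.loc["t2", ["hippocampus"]] = 8.0
        # t3: good but not conserved
        tissues.loc["t3", ["cortex"]] = 8.0
        after.loc["t3"] = [5.1, 4.9, 5.2, 5.0]
        cons["t3"] = False
        # t4: decreasing candidate
        tissues.loc["t4", ["cortex"]] = 8.0
        before.loc["t4"] = [5.1, 4.9, 5.2, 5.0]
        return tissues, before, after, cons

    def test_screen_criteria(self, rng):
        tissues, before, after, cons = self._inputs(rng)
        res = screen_candidates(
            tissues, ["cortex", "hippocampus"], before, after, cons
        )
        assert res.loc["t0", "candidate"] and res.loc["t0", "direction"] == "increase"
        assert not res.loc["t1", "candidate"]  # liver expression
        assert not res.loc["t2", "candidate"]  # flat
        assert not res.loc["t3", "candidate"]  # not conserved
        assert res.loc["t4", "candidate"] and res.loc["t4", "direction"] == "decrease"

    def test_missing_tissue_label_is_error(self, rng):
        tissues, before, after, cons = self._inputs(rng)
        with pytest.raises(ValueError, match="neural"):
            screen_candidates(tissues, ["cerebellum"], before, after, cons)
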