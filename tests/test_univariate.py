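from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mbfuse.data_model import PipelineOrderError, SampleMetadata
from mbfuse.univariate import (
    bh_adjust,
    top_k_heatmap_matrix,
    welch_screen,
    wilcoxon_screen,
)

from conftest import make_block, make_metadata


def exact_mwu_pvalue(a, b):
    """Brute-force two-sided Mann-Whitney p by enumerating every way of
    assigning the pooled observations to the first group (no ties)."""
    pooled = np.concatenate([a, b])
    n1 = len(a)
    u_obs = sum(x > y for x in a for y in b)
    center = n1 * (len(b)) / 2.0
    count = total = 0
    for idx in combinations(range(len(pooled)), n1):
        g1 = pooled[list(idx)]
        g2 = np.delete(pooled, list(idx))
        u = sum(x > y for x in g1 for y in g2)
        total += 1
        if abs(u - center) >= abs(u_obs - center) - 1e-12:
            count += 1
    return count / total


def screen_groups(a, b, test="wilcoxon"):
    """Run the screen on a single synthetic feature split A|B."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    mat = np.concatenate([a, b])[:, None]
    block = make_block(mat, state="imputed")
    md = make_metadata(len(mat))
    md = SampleMetadata(block.sample_ids,
                        {"group": tuple(["A"] * len(a) + ["B"] * len(b))})
    fn = wilcoxon_screen if test == "wilcoxon" else welch_screen
    return fn(block, md, "group", ("A", "B")).iloc[0]


class TestWilcoxon:
    def test_complete_separation_exact(self):
        row = screen_groups([1, 2, 3], [4, 5, 6])
        assert row["p"] == pytest.approx(0.1)
        assert row["method"] == "exact"
        assert row["statistic"] in (0.0, 9.0)
        assert row["direction"] == 1

    def test_identical_groups(self):
        row = screen_groups([1, 2, 3], [1, 2, 3])
        assert row["p"] == pytest.approx(1.0, abs=1e-9)

    def test_enumeration_oracle_small_samples(self):
        rng = np.random.default_rng(99)
        for _ in range(15):
            n1 = int(rng.integers(2, 7))
            n2 = int(rng.integers(2, 7))
            pooled = rng.permutation(rng.normal(size=n1 + n2) * 10)
            a, b = pooled[:n1], pooled[n1:]
            row = screen_groups(a, b)
            assert row["method"] == "exact"
            assert row["p"] == pytest.approx(exact_mwu_pvalue(a, b), abs=1e-12)

    def test_asymptotic_when_large_or_tied(self):
        rng = np.random.default_rng(3)
        a = rng.normal(size=12)
        b = rng.normal(size=12)
        assert screen_groups(a, b)["method"] == "asymptotic"
        assert screen_groups([1, 1, 2], [3, 4, 5])["method"] == "asymptotic"

    def test_log_invariance(self):
        # rank test: monotone transform of the data leaves p unchanged
        rng = np.random.default_rng(8)
        a = rng.lognormal(size=5)
        b = rng.lognormal(mean=1.0, size=6)
        p_raw = screen_groups(a, b)["p"]
        p_log = screen_groups(np.log10(a), np.log10(b))["p"]
        assert p_raw == pytest.approx(p_log, abs=1e-12)

    def test_requires_imputed_state(self):
        block = make_block([[1.0], [2.0], [3.0], [4.0]], state="raw")
        md = make_metadata(4)
        with pytest.raises(PipelineOrderError):
            wilcoxon_screen(block, md, "group", ("A", "B"))

    def test_missing_level_errors(self):
        block = make_block(np.arange(4.0)[:, None] + 1, state="imputed")
        md = make_metadata(4)
        with pytest.raises(ValueError):
            wilcoxon_screen(block, md, "group", ("A", "Z"))

    def test_small_groups_error(self):
        block = make_block(np.arange(3.0)[:, None] + 1, state="imputed")
        md = SampleMetadata(block.sample_ids, {"g": ("A", "B", "B")})
        with pytest.raises(ValueError, match=">= 2"):
            wilcoxon_screen(block, md, "g", ("A", "B"))


class TestWelch:
    def test_equal_groups_null(self):
        row = screen_groups([1, 2, 3, 4], [4, 3, 2, 1], test="welch")
        assert row["statistic"] == pytest.approx(0.0)
        assert row["p"] == pytest.approx(1.0)

    def test_satterthwaite_df_equal_n_equal_var(self):
        # closed form: equal n and equal sample variances -> df = 2n - 2
        a = np.array([1.0, 2.0, 3.0, 4.0])
        b = a + 10.0  # same variance, shifted
        row = screen_groups(a, b, test="welch")
        assert row["df"] == pytest.approx(2 * len(a) - 2)

    def test_type_one_error_rate(self):
        rng = np.random.default_rng(17)
        n_feat = 1000
        mat = rng.normal(size=(12, n_feat))
        block = make_block(mat, state="imputed")
        md = make_metadata(12)
        table = welch_screen(block, md, "group", ("A", "B"))
        frac = (table["p"] < 0.05).mean()
        assert frac == pytest.approx(0.05, abs=0.02)

    def test_degenerate_zero_variance(self, caplog):
        with caplog.at_level("WARNING"):
            row = screen_groups([2.0, 2.0], [2.0, 2.0], test="welch")
        assert row["p"] == 1.0 and row["degenerate"]
        row = screen_groups([2.0, 2.0], [3.0, 3.0], test="welch")
        assert row["p"] == 0.0 and row["degenerate"]


class TestBhAdjust:
    def test_hand_computed(self):
        np.testing.assert_allclose(bh_adjust(np.array([0.01, 0.02, 0.03])),
                                   [0.03, 0.03, 0.03])

    def test_textbook_step_up(self):
        p = np.array([0.01, 0.04, 0.03, 0.005])
        # sorted: .005,.01,.03,.04 -> m*p/j: .02,.02,.04,.04
        np.testing.assert_allclose(bh_adjust(p), [0.02, 0.04, 0.04, 0.02])

    def test_single_and_ones(self):
        np.testing.assert_allclose(bh_adjust(np.array([0.2])), [0.2])
        np.testing.assert_allclose(bh_adjust(np.ones(3)), 1.0)

    def test_out_of_range_errors(self):
        with pytest.raises(ValueError):
            bh_adjust(np.array([0.5, 1.5]))
        with pytest.raises(ValueError):
            bh_adjust(np.array([-0.1]))

    def test_against_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests
        for _ in range(10):
            p = rng.random(rng.integers(1, 40))
            q = bh_adjust(p)
            _, q_sm, _, _ = multipletests(p, method="fdr_bh")
            np.testing.assert_allclose(q, q_sm, atol=1e-12)

    def test_q_at_least_p_and_order_consistent(self, rng):
        p = rng.random(50)
        q = bh_adjust(p)
        assert (q >= p - 1e-15).all()
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-15).all()

    @given(st.data())
    @settings(max_examples=30, deadline=None)
    def test_monotonicity_property(self, data):
        # raising any p never increases the number of discoveries
        n = data.draw(st.integers(2, 20))
        p = np.array(data.draw(st.lists(
            st.floats(0.0, 1.0, allow_nan=False), min_size=n, max_size=n)))
        i = data.draw(st.integers(0, n - 1))
        bumped = p.copy()
        bumped[i] = data.draw(st.floats(float(p[i]), 1.0, allow_nan=False))
        alpha = 0.05
        assert (bh_adjust(bumped) < alpha).sum() <= (bh_adjust(p) < alpha).sum()


class TestHeatmapMatrix:
    def _fixture(self, rng, n_feat=80, n_samp=10):
        mat = rng.lognormal(size=(n_samp, n_feat))
        block = make_block(mat, state="imputed")
        table = pd.DataFrame({
            "feature_id": list(block.feature_ids),
            "p": rng.random(n_feat) * 0.1,
        })
        table["q"] = bh_adjust(table["p"].to_numpy())
        return block, table

    def test_truncates_to_smallest_p(self, rng):
        block, table = self._fixture(rng)
        table["p"] = np.linspace(0.0001, 0.04, len(table))  # all pass
        heat = top_k_heatmap_matrix(table, block, k=50, alpha=0.05)
        assert heat.shape == (50, 10)
        expected = set(table.nsmallest(50, "p")["feature_id"])
        assert set(heat.index) == expected

    def test_rows_standardized(self, rng):
        block, table = self._fixture(rng)
        heat = top_k_heatmap_matrix(table, block, k=20, alpha=0.05)
        vals = heat.to_numpy()
        np.testing.assert_allclose(vals.mean(axis=1), 0.0, atol=1e-10)
        np.testing.assert_allclose(vals.std(axis=1, ddof=1), 1.0, atol=1e-10)

    def test_k_larger_than_passers(self, rng):
        block, table = self._fixture(rng, n_feat=8)
        table["p"] = [0.01] * 3 + [0.9] * 5
        heat = top_k_heatmap_matrix(table, block, k=50, alpha=0.05)
        assert heat.shape[0] == 3

    def test_empty_selection_warns(self, rng, caplog):
        block, table = self._fixture(rng, n_feat=5)
        table["p"] = 0.9
        with caplog.at_level("WARNING"):
            heat = top_k_heatmap_matrix(table, block, k=50, alpha=0.05)
        assert heat.empty
        assert "no feature" in caplog.text

    def test_use_q_flag(self, rng):
        block, table = self._fixture(rng, n_feat=6)
        table["p"] = [0.001, 0.002, 0.003, 0.2, 0.3, 0.4]
        table["q"] = bh_adjust(table["p"].to_numpy())
        by_p = top_k_heatmap_matrix(table, block, k=50, alpha=0.01)
        by_q = top_k_heatmap_matrix(table, block, k=50, alpha=0.01,
                                    use_q=True)
        assert by_p.shape[0] == 3
        assert by_q.shape[0] == 3  # q = [.006,.006,.006,...] all < .01
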