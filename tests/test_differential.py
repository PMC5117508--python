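"""Relative transcriptograms, Welch tests, permutation FDR, volcano, gene sets."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from transcriptogram.differential import (
    DEFAULT_FDR_THRESHOLDS,
    gene_set_comparison,
    permutation_fdr,
    positionwise_welch,
    relative_transcriptogram,
    volcano,
)


def welch_p_closed_form(a, b):
    """Textbook Welch statistic + Welch-Satterthwaite df, two-tailed."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    na, nb = len(a), len(b)
    va, vb = a.var(ddof=1) / na, b.var(ddof=1) / nb
    t = (a.mean() - b.mean()) / np.sqrt(va + vb)
    df = (va + vb) ** 2 / (va**2 / (na - 1) + vb**2 / (nb - 1))
    return 2 * stats.t.sf(abs(t), df)


class TestPositionwiseWelch:
    def test_identical_classes_give_p_of_one(self):
        x = np.random.default_rng(0).normal(size=(3, 20))
        assert np.allclose(positionwise_welch(x, x), 1.0)

    def test_matches_closed_form_oracle(self):
        a = np.array([[1.0], [1.1], [0.9]])
        b = np.array([[2.0], [2.1], [1.9]])
        p = positionwise_welch(a, b)[0]
        assert p == pytest.approx(welch_p_closed_form(a.ravel(), b.ravel()), abs=1e-10)

    def test_zero_variance_positions_resolved_explicitly(self):
        a = np.ones((3, 2))
        b = np.ones((3, 2))
        b[:, 1] = 2.0  # constant but different
        p = positionwise_welch(a, b)
        assert p[0] == 1.0 and p[1] == 0.0

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError, match="2 samples"):
            positionwise_welch(np.ones((1, 5)), np.ones((3, 5)))

    def test_null_calibration_small_simulation(self):
        rng = np.random.default_rng(42)
        hits, total = 0, 0
        for _ in range(50):
            a = rng.normal(size=(3, 100))
            b = rng.normal(size=(3, 100))
            p = positionwise_welch(a, b)
            hits += np.sum(p < 0.05)
            total += p.size
        assert 0.03 < hits / total < 0.07


class TestRelativeTranscriptogram:
    def test_self_comparison_is_identity(self):
        x = np.random.default_rng(1).normal(8, 1, size=(3, 30))
        comp = relative_transcriptogram(x, x)
        assert np.allclose(comp.delta, 1.0)
        assert np.allclose(comp.p_values, 1.0)

    def test_constant_profiles_give_mean_ratio(self):
        p = np.full((3, 10), 2.0)
        r = np.full((3, 10), 1.0)
        comp = relative_transcriptogram(p, r)
        assert np.allclose(comp.delta, 2.0)

    def test_role_swap_inverts_delta_and_keeps_p(self):
        rng = np.random.default_rng(2)
        p = rng.normal(8, 1, size=(3, 25))
        r = rng.normal(8, 1, size=(3, 25))
        fwd = relative_transcriptogram(p, r)
        rev = relative_transcriptogram(r, p)
        assert np.allclose(fwd.delta * rev.delta, 1.0)
        assert np.allclose(fwd.p_values, rev.p_values)

    def test_zero_reference_mean_is_an_error(self):
        p = np.ones((2, 3))
        r = np.zeros((2, 3))
        with pytest.raises(ZeroDivisionError, match="position"):
            relative_transcriptogram(p, r)

    def test_planted_shift_puts_max_delta_in_block(self):
        rng = np.random.default_rng(3)
        n_pos = 100
        p = rng.normal(8, 0.05, size=(3, n_pos))
        r = rng.normal(8, 0.05, size=(3, n_pos))
        p[:, 40:60] += np.log2(1.5)
        comp = relative_transcriptogram(p, r)
        assert 40 <= np.argmax(comp.delta) < 60


class TestPermutationFdr:
    @staticmethod
    def _signal_data(seed=0, n_pos=120):
        rng = np.random.default_rng(seed)
        p = rng.normal(8, 0.1, size=(3, n_pos))
        r = rng.normal(8, 0.1, size=(3, n_pos))
        p[:, :30] += 1.5  # unmissable shift
        return p, r

    def test_seeded_reproducibility(self):
        p, r = self._signal_data()
        t1 = permutation_fdr(p, r, n_perm=50, seed=7)
        t2 = permutation_fdr(p, r, n_perm=50, seed=7)
        pd.testing.assert_series_equal(t1, t2)

    def test_matches_naive_ratio_oracle(self):
        p, r = self._signal_data(seed=5)
        table, null_p = permutation_fdr(p, r, n_perm=40, seed=3, return_null=True)
        observed = positionwise_welch(p, r)
        for thr in DEFAULT_FDR_THRESHOLDS:
            n_obs = sum(1 for q in observed if q <= thr)
            if n_obs == 0:
                assert np.isnan(table[thr])
                continue
            false_counts = [sum(1 for q in row if q <= thr) for row in null_p]
            assert table[thr] == pytest.approx(np.mean(false_counts) / n_obs, rel=1e-12)

    def test_pure_null_fdr_near_one(self):
        rng = np.random.default_rng(11)
        fdrs = []
        for rep in range(20):
            a = rng.normal(size=(3, 200))
            b = rng.normal(size=(3, 200))
            t = permutation_fdr(a, b, thresholds=(0.1,), n_perm=40, seed=rep)
            if not np.isnan(t[0.1]):
                fdrs.append(t[0.1])
        assert 0.7 < np.mean(fdrs) < 1.4

    def test_strong_signal_fdr_is_small(self):
        p, r = self._signal_data(seed=9, n_pos=300)
        t = permutation_fdr(p, r, thresholds=(0.01,), n_perm=100, seed=2)
        # label permutations that re-create the true split keep their signal,
        # so the floor is ~2/20 of positions, well below 1
        assert t[0.01] < 0.5


class TestVolcano:
    @staticmethod
    def _expr(seed=0, n_genes=50):
        rng = np.random.default_rng(seed)
        genes = [f"g{i:03d}" for i in range(n_genes)]
        cols = {f"A_{k}": rng.normal(8, 0.1, n_genes) for k in range(3)}
        cols |= {f"B_{k}": rng.normal(8, 0.1, n_genes) for k in range(3)}
        expr = pd.DataFrame(cols, index=genes)
        labels = pd.Series({c: c[0] for c in expr.columns})
        return expr, labels

    def test_large_shift_is_flagged_with_correct_fc(self):
        expr, labels = self._expr()
        expr.loc["g000", ["A_0", "A_1", "A_2"]] = [10.0, 10.01, 9.99]
        expr.loc["g000", ["B_0", "B_1", "B_2"]] = [8.0, 8.01, 7.99]
        res = volcano(expr, labels, "A", "B")
        row = res.table.loc["g000"]
        assert row["fold_change"] == pytest.approx(4.0, rel=0.01)
        assert row["significant"]

    def test_identical_classes_flag_nothing(self):
        expr, labels = self._expr(seed=4)
        res = volcano(expr, labels, "A", "B")
        assert res.table["significant"].sum() == 0

    def test_downregulation_flagged_two_sided(self):
        expr, labels = self._expr(seed=6)
        expr.loc["g001", ["A_0", "A_1", "A_2"]] -= 2.0  # FC = 1/4
        res = volcano(expr, labels, "A", "B")
        assert res.table.loc["g001", "significant"]
        assert res.table.loc["g001", "fold_change"] < 0.5

    def test_linear_scale_requires_positive_means(self):
        expr, labels = self._expr(seed=7)
        expr.loc["g002"] = -1.0
        with pytest.raises(ValueError, match="linear"):
            volcano(expr, labels, "A", "B", scale="linear")

    def test_linear_and_log_scales_agree_on_ratio(self):
        expr, labels = self._expr(seed=8)
        lin = volcano(2.0**expr, labels, "A", "B", scale="linear")
        # ratio of linear means differs from 2**mean-log-difference in general,
        # but both must flag the same obvious shift
        expr2 = expr.copy()
        expr2.loc["g003", ["A_0", "A_1", "A_2"]] += 3.0
        log = volcano(expr2, labels, "A", "B", scale="log2")
        assert log.table.loc["g003", "significant"]
        assert not lin.table["significant"].any()


class TestGeneSetComparison:
    @staticmethod
    def _expr(seed=0):
        rng = np.random.default_rng(seed)
        genes = [f"g{i:02d}" for i in range(30)]
        cols = {f"{c}_{k}": rng.normal(8, 0.2, 30) for c in ("R", "P") for k in range(3)}
        expr = pd.DataFrame(cols, index=genes)
        labels = pd.Series({c: c.split("_")[0] for c in expr.columns})
        return expr, labels

    def test_single_gene_set_matches_volcano_p(self):
        expr, labels = self._expr()
        res = gene_set_comparison(expr, labels, {"g05"}, classes=["P", "R"])
        v = volcano(expr, labels, "P", "R", p_threshold=1.1)
        assert res.p_values.loc["P", "R"] == pytest.approx(
            v.table.loc["g05", "p_value"], abs=1e-12
        )

    def test_global_shift_moves_every_set_mean_by_one(self):
        expr, labels = self._expr(seed=2)
        shifted = expr.copy()
        p_cols = labels.index[labels == "P"]
        shifted[p_cols] += 1.0
        for gene_set in ({"g00", "g01"}, set(expr.index[:10])):
            res = gene_set_comparison(shifted, labels, gene_set, classes=["R", "P"])
            base = gene_set_comparison(expr, labels, gene_set, classes=["R", "P"])
            diff = (res.class_means["P"] - res.class_means["R"]) - (
                base.class_means["P"] - base.class_means["R"]
            )
            assert diff == pytest.approx(1.0, abs=1e-12)

    def test_only_perturbed_set_reaches_strong_significance(self):
        expr, labels = self._expr(seed=3)
        perturbed = set(expr.index[:10])
        control = set(expr.index[10:20])
        p_cols = labels.index[labels == "P"]
        expr.loc[sorted(perturbed), p_cols] += 1.0
        res_p = gene_set_comparison(expr, labels, perturbed, classes=["R", "P"])
        res_c = gene_set_comparison(expr, labels, control, classes=["R", "P"])
        assert res_p.p_values.loc["R", "P"] < 0.01
        assert res_c.p_values.loc["R", "P"] > 0.05
        assert res_p.significance_marker("R", "P") == "**"

    def test_empty_intersection_is_an_error(self):
        expr, labels = self._expr(seed=4)
        with pytest.raises(ValueError, match="no genes"):
            gene_set_comparison(expr, labels, {"absent"}, classes=["R", "P"])
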