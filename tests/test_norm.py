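"""TMM factors, FPKM, replicate averaging, expression filter, Spearman QC."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from xdosage import (
    ConfigError,
    SimulationConfig,
    TissuePlan,
    average_replicates,
    compute_fpkm,
    filter_expressed,
    simulate_expression,
    simulate_genome,
    spearman_replicates,
    tmm_factors,
)
from xdosage.containers import TissueExpression
from conftest import make_count_matrix


class TestTmm:
    def test_identical_columns_give_unit_factors(self):
        cm = make_count_matrix({"F1": [10, 20, 30, 5], "M1": [10, 20, 30, 5]})
        np.testing.assert_allclose(tmm_factors(cm), 1.0)

    def test_pure_depth_change_gives_unit_factors(self):
        cm = make_count_matrix({"F1": [10, 20, 30, 5], "M1": [20, 40, 60, 10]})
        np.testing.assert_allclose(tmm_factors(cm), 1.0, atol=1e-12)

    def test_factors_multiply_to_one(self, tiny_counts):
        cm, _ = tiny_counts
        assert tmm_factors(cm).prod() == pytest.approx(1.0)

    def test_toy_matches_hand_computed_weighted_trimmed_mean(self):
        # 6 distinct genes, 2 samples; gene 1 dominates sample A
        a = np.array([1000, 20, 30, 40, 50, 60], dtype=float)
        b = np.array([100, 22, 28, 44, 46, 66], dtype=float)
        cm = make_count_matrix({"F1": a.astype(int), "M1": b.astype(int)})

        # oracle computed step by step from the published definition
        la, lb = a.sum(), b.sum()
        fa, fb = a / la, b / lb
        f75 = np.array([np.quantile(fa, 0.75), np.quantile(fb, 0.75)])
        ref = int(np.argmin(np.abs(f75 - f75.mean())))
        other = 1 - ref
        p_other = (a if other == 0 else b) / (la if other == 0 else lb)
        p_ref = (a if ref == 0 else b) / (la if ref == 0 else lb)
        m = np.log2(p_other / p_ref)
        av = 0.5 * np.log2(p_other * p_ref)
        y_o, l_o = (a, la) if other == 0 else (b, lb)
        y_r, l_r = (a, la) if ref == 0 else (b, lb)
        v = (l_o - y_o) / (l_o * y_o) + (l_r - y_r) / (l_r * y_r)
        n = len(m)
        lo_m = np.floor(n * 0.30) + 1
        hi_m = n + 1 - lo_m
        lo_a = np.floor(n * 0.05) + 1
        hi_a = n + 1 - lo_a
        rm, ra = stats.rankdata(m), stats.rankdata(av)
        keep = (rm >= lo_m) & (rm <= hi_m) & (ra >= lo_a) & (ra <= hi_a)
        w = 1.0 / v[keep]
        logf_other = (w * m[keep]).sum() / w.sum()
        # after product-1 rescaling the two factors are 2^(+-logf/2)
        expected = np.sort([2.0 ** (logf_other / 2), 2.0 ** (-logf_other / 2)])
        got = np.sort(tmm_factors(cm).to_numpy())
        np.testing.assert_allclose(got, expected, rtol=1e-10)

    def test_effective_sizes_recover_known_depth_multipliers(self):
        # deep libraries: with few genes in the dropout regime the
        # zero-in-either-sample exclusion cannot bias the trimmed mean
        cfg = SimulationConfig(
            n_autosomes=3, n_genes_per_chrom=500, n_windows_per_chrom=5,
            regime="complete_compensation",
            dispersion_true=0.0, libsize=2e7, seed=6,
        )
        genome = simulate_genome(cfg)
        mult = {"t_F_1": 1.0, "t_F_2": 2.0, "t_M_1": 0.5, "t_M_2": 1.0}
        cm, _ = simulate_expression(
            genome, cfg, [TissuePlan("t", 2)],
            libsizes={k: cfg.libsize * v for k, v in mult.items()},
        )
        eff = cm.library_sizes * tmm_factors(cm)
        rel = (eff / eff["t_F_1"]).to_numpy()
        np.testing.assert_allclose(rel, [1.0, 2.0, 0.5, 1.0], rtol=0.02)

    def test_single_sample_rejected(self):
        cm = make_count_matrix({"F1": [1, 2, 3]})
        with pytest.raises(Exception, match="2 samples"):
            tmm_factors(cm)


class TestFpkm:
    def test_direct_formula(self):
        # count 10, length 1000 bp, library 1e6 -> FPKM 10; count 0 -> 0
        cm = make_count_matrix(
            {"F1": [10, 0, 10**6 - 10], "M1": [10, 5, 10**6 - 15]},
            lengths=[1000, 500, 2000],
        )
        expr = compute_fpkm(cm, tmm=False)
        assert expr.fpkm.loc["g1", "F1"] == pytest.approx(10.0)
        assert expr.fpkm.loc["g2", "F1"] == 0.0

    def test_count_mass_conservation(self, tiny_counts):
        cm, _ = tiny_counts
        expr = compute_fpkm(cm, tmm=False)
        len_kb = cm.gene_lengths / 1e3
        for s in cm.counts.columns:
            recon = (expr.fpkm[s] * len_kb * cm.library_sizes[s] / 1e6).sum()
            assert recon == pytest.approx(cm.counts[s].sum())

    def test_linear_in_counts_at_fixed_library(self):
        cm = make_count_matrix({"F1": [10, 20], "M1": [5, 40]})
        expr = compute_fpkm(cm, tmm=False)
        doubled = make_count_matrix({"F1": [20, 40], "M1": [10, 80]})
        # same composition, double depth: FPKM unchanged
        np.testing.assert_allclose(
            compute_fpkm(doubled, tmm=False).fpkm, expr.fpkm
        )


class TestReplicateAveragingAndFilter:
    def _texpr(self, pairs):
        frame = pd.DataFrame(
            pairs, columns=["mean_F", "mean_M"],
            index=[f"g{i}" for i in range(len(pairs))],
        )
        frame["retained"] = True
        return TissueExpression(tissue="t", frame=frame)

    def test_mean_of_replicates(self):
        cm = make_count_matrix({"t_F_1": [2], "t_F_2": [4], "t_M_1": [6]})
        expr = compute_fpkm(cm, tmm=False)
        te = average_replicates(expr)["t"]
        manual = expr.fpkm[["t_F_1", "t_F_2"]].mean(axis=1)
        np.testing.assert_allclose(te.frame["mean_F"], manual)
        np.testing.assert_allclose(te.frame["mean_M"], expr.fpkm["t_M_1"])

    def test_replicate_order_irrelevant(self, tiny_counts):
        cm, _ = tiny_counts
        expr = compute_fpkm(cm, tmm=False)
        swapped = compute_fpkm(
            cm.subset_samples(list(cm.samples["sample_id"])[::-1]), tmm=False
        )
        a = average_replicates(expr)["gut"].frame
        b = average_replicates(swapped)["gut"].frame
        pd.testing.assert_frame_equal(a, b)

    @pytest.mark.parametrize(
        "pair,rule,kept",
        [
            ((0.5, 0.5), "both_below", False),
            ((5.0, 0.2), "both_below", True),
            ((5.0, 0.2), "either_below", False),
            ((1.0, 0.0), "both_below", True),  # threshold is strict <
        ],
    )
    def test_filter_rule_table(self, pair, rule, kept):
        out = filter_expressed(self._texpr([pair]), threshold=1.0, rule=rule)
        assert bool(out.frame["retained"].iloc[0]) is kept

    def test_zero_threshold_removes_nothing(self):
        out = filter_expressed(self._texpr([(0.0, 0.0), (5, 5)]), threshold=0.0)
        assert out.frame["retained"].all()

    @given(
        t1=st.floats(min_value=0, max_value=10),
        t2=st.floats(min_value=0, max_value=10),
    )
    @settings(max_examples=30, deadline=None)
    def test_filter_monotone_in_threshold(self, t1, t2):
        te = self._texpr([(0.3, 0.8), (1.5, 0.1), (2.0, 3.0), (0.0, 9.0)])
        lo, hi = sorted([t1, t2])
        kept_lo = filter_expressed(te, threshold=lo).frame["retained"]
        kept_hi = filter_expressed(te, threshold=hi).frame["retained"]
        assert (kept_hi <= kept_lo).all()  # raising threshold never adds genes

    def test_bad_rule_rejected(self):
        with pytest.raises(ConfigError, match="rule"):
            filter_expressed(self._texpr([(1, 1)]), rule="sometimes")


class TestSpearman:
    def test_identical_and_reversed_columns(self):
        cm = make_count_matrix(
            {"t_F_1": [1, 2, 3, 4, 5], "t_F_2": [1, 2, 3, 4, 5]}
        )
        out = spearman_replicates(cm)
        assert out["rho"].iloc[0] == pytest.approx(1.0)
        cm2 = make_count_matrix(
            {"t_F_1": [1, 2, 3, 4, 5], "t_F_2": [5, 4, 3, 2, 1]}
        )
        assert spearman_replicates(cm2)["rho"].iloc[0] == pytest.approx(-1.0)

    def test_matches_rank_then_pearson_oracle(self):
        a = [3, 10, 10, 1, 7]
        b = [9, 2, 5, 4, 4]
        cm = make_count_matrix({"t_F_1": a, "t_F_2": b})
        rho = spearman_replicates(cm)["rho"].iloc[0]
        oracle = np.corrcoef(stats.rankdata(a), stats.rankdata(b))[0, 1]
        assert rho == pytest.approx(oracle, abs=1e-12)

    def test_constant_column_is_missing_with_warning(self):
        cm = make_count_matrix({"t_F_1": [2, 2, 2], "t_F_2": [1, 2, 3]})
        with pytest.warns(UserWarning, match="constant"):
            out = spearman_replicates(cm)
        assert np.isnan(out["rho"].iloc[0])

    def test_simulated_replicates_correlate_strongly(self, tiny_counts):
        cm, _ = tiny_counts
        out = spearman_replicates(cm)
        assert (out["rho"] > 0.9).all()
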