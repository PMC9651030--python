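"""CPM, dispersion estimation, NB two-group tests, BH, bias calls, Fisher."""

import numpy as np
import pandas as pd
import pytest
from scipy import special

from xdosage import (
    ConfigError,
    SimulationConfig,
    TissuePlan,
    bh_adjust,
    call_sex_biased,
    cpm,
    cpm_filter,
    estimate_dispersion,
    fisher_enrichment,
    nb_two_group_test,
    sex_bias_analysis,
    simulate_expression,
    simulate_genome,
)
from conftest import make_count_matrix


class TestCpm:
    def test_direct_formula_and_column_sum(self):
        cm = make_count_matrix({"F1": [100, 10**6 - 100], "M1": [50, 10**6 - 50]})
        mat = cpm(cm)
        assert mat.loc["g1", "F1"] == pytest.approx(100.0)
        np.testing.assert_allclose(mat.sum(axis=0), 1e6)

    def test_doubling_library_halves_cpm(self):
        a = make_count_matrix({"F1": [10, 90], "M1": [10, 90]})
        b = make_count_matrix({"F1": [10, 190], "M1": [10, 90]})
        assert cpm(b).loc["g1", "F1"] == pytest.approx(
            cpm(a).loc["g1", "F1"] * 100 / 200
        )


class TestCpmFilter:
    def _mat(self, rows):
        df = pd.DataFrame(
            rows, columns=["t_F_1", "t_F_2", "t_M_1", "t_M_2"],
            index=[f"g{i}" for i in range(len(rows))],
        )
        meta = pd.DataFrame(
            {
                "sample_id": df.columns,
                "tissue": "t",
                "sex": ["F", "F", "M", "M"],
                "replicate": [1, 2, 1, 2],
            }
        )
        return df, meta

    def test_replicated_rule_table(self):
        mat, meta = self._mat(
            [
                (2.0, 3.0, 0.0, 0.0),   # F passes in both reps -> kept
                (2.0, 0.5, 0.5, 0.5),   # no sex passes in both reps -> removed
                (0.5, 0.5, 1.5, 1.2),   # M passes -> kept
            ]
        )
        keep = cpm_filter(mat, meta, threshold=1.0, design="replicated")
        assert keep.tolist() == [True, False, True]

    def test_unreplicated_any_sample_rule(self):
        mat, meta = self._mat([(2.0, 0.0, 0.0, 0.0), (0.5, 0.5, 0.5, 0.5)])
        keep = cpm_filter(
            mat[["t_F_1", "t_M_1"]], meta.iloc[[0, 2]], design="unreplicated"
        )
        assert keep.tolist() == [True, False]

    def test_zero_threshold_keeps_everything_nonzero(self):
        mat, meta = self._mat([(0.1, 0.1, 0.1, 0.1)])
        assert cpm_filter(mat, meta, threshold=0.0).all()


class TestDispersion:
    def test_unreplicated_is_fixed_bcv_squared(self, tiny_counts):
        cm, _ = tiny_counts
        phi = estimate_dispersion(cm, design="unreplicated", bcv=0.2)
        np.testing.assert_allclose(phi, 0.04)

    def test_poisson_counts_give_small_shrunk_dispersion(self):
        cfg = SimulationConfig(
            n_autosomes=7, n_genes_per_chrom=250, n_windows_per_chrom=5,
            dispersion_true=0.0, seed=13,
        )
        genome = simulate_genome(cfg)
        cm, truth = simulate_expression(genome, cfg, [TissuePlan("t", 4)])
        phi = estimate_dispersion(cm, design="replicated")
        high = truth.set_index("gene_id")["baseline_fpkm"] >= 20
        assert phi[high.to_numpy()].median() <= 0.01

    def test_nb_dispersion_recovered_within_band(self):
        # 2000 genes, 4 replicates per sex, true NB dispersion 0.1
        cfg = SimulationConfig(
            n_autosomes=7, n_genes_per_chrom=250, n_windows_per_chrom=5,
            dispersion_true=0.1, seed=14,
        )
        genome = simulate_genome(cfg)
        cm, _ = simulate_expression(genome, cfg, [TissuePlan("t", 4)])
        phi = estimate_dispersion(cm, design="replicated")
        assert 0.05 <= phi.median() <= 0.2

    def test_replicated_without_replicates_falls_back_with_warning(self):
        cm = make_count_matrix({"t_F_1": [5, 10], "t_M_1": [6, 9]})
        with pytest.warns(UserWarning, match="fixed BCV"):
            phi = estimate_dispersion(cm, design="replicated", bcv=0.2)
        np.testing.assert_allclose(phi, 0.04)


def nb_conditional_enumeration_p(sa, t, r_a, r_b):
    """Independent oracle: conditional NB law via exact log-binomial sums."""
    probs = []
    for a in range(t + 1):
        lp = (
            special.gammaln(a + r_a) - special.gammaln(a + 1) - special.gammaln(r_a)
            + special.gammaln(t - a + r_b) - special.gammaln(t - a + 1)
            - special.gammaln(r_b)
            - (special.gammaln(t + r_a + r_b) - special.gammaln(t + 1)
               - special.gammaln(r_a + r_b))
        )
        probs.append(np.exp(lp))
    probs = np.array(probs)
    probs /= probs.sum()
    return probs[probs <= probs[sa] * (1 + 1e-9)].sum()


class TestNbTwoGroupTest:
    def _frames(self, f_counts, m_counts):
        genes = [f"g{i}" for i in range(len(f_counts))]
        cf = pd.DataFrame(
            np.asarray(f_counts, dtype=float).reshape(len(genes), -1), index=genes
        )
        cf.columns = [f"F{j}" for j in range(cf.shape[1])]
        cm_ = pd.DataFrame(
            np.asarray(m_counts, dtype=float).reshape(len(genes), -1), index=genes
        )
        cm_.columns = [f"M{j}" for j in range(cm_.shape[1])]
        lib = pd.Series(1e6, index=list(cf.columns) + list(cm_.columns))
        return cf, cm_, lib

    def test_symmetric_null_gives_p_one_logfc_zero(self):
        cf, cm_, lib = self._frames([[10], [0]], [[10], [0]])
        phi = pd.Series(0.04, index=cf.index)
        for method in ("lrt", "exact"):
            res = nb_two_group_test(cf, cm_, lib, phi, method=method)
            assert res["p"].tolist() == pytest.approx([1.0, 1.0])
            assert res["logFC"].tolist() == pytest.approx([0.0, 0.0])

    def test_poisson_limit_exact_is_conditional_binomial(self):
        # counts (0, 10) at phi -> 0: two-sided p = 2/2^10
        cf, cm_, lib = self._frames([[0]], [[10]])
        phi = pd.Series(0.0, index=cf.index)
        res = nb_two_group_test(cf, cm_, lib, phi, method="exact")
        assert res["p"].iloc[0] == pytest.approx(2 / 1024, rel=1e-9)

    def test_exact_matches_enumeration_oracle_small_totals(self):
        pairs = [(0, 10), (3, 9), (7, 7), (1, 19), (12, 4)]
        cf, cm_, lib = self._frames(
            [[a] for a, _ in pairs], [[b] for _, b in pairs]
        )
        phi = pd.Series(0.04, index=cf.index)
        res = nb_two_group_test(cf, cm_, lib, phi, method="exact")
        for i, (a, b) in enumerate(pairs):
            oracle = nb_conditional_enumeration_p(a, a + b, 1 / 0.04, 1 / 0.04)
            assert res["p"].iloc[i] == pytest.approx(oracle, abs=1e-9)

    def test_lrt_detects_strong_fold_change(self):
        cf, cm_, lib = self._frames([[400, 380]], [[50, 45]])
        phi = pd.Series(0.05, index=cf.index)
        res = nb_two_group_test(cf, cm_, lib, phi, method="lrt")
        assert res["logFC"].iloc[0] == pytest.approx(3.0, abs=0.3)
        assert res["p"].iloc[0] < 1e-6

    def test_lrt_null_p_values_roughly_uniform(self):
        rng = np.random.default_rng(3)
        n = 400
        mu = 100.0
        phi_true = 0.1
        f = rng.negative_binomial(1 / phi_true, 1 / (1 + phi_true * mu), size=(n, 2))
        m = rng.negative_binomial(1 / phi_true, 1 / (1 + phi_true * mu), size=(n, 2))
        cf, cm_, lib = self._frames(f.tolist(), m.tolist())
        phi = pd.Series(phi_true, index=cf.index)
        res = nb_two_group_test(cf, cm_, lib, phi, method="lrt")
        assert 0.02 <= (res["p"] < 0.05).mean() <= 0.10

    def test_all_zero_gene_is_flat(self):
        cf, cm_, lib = self._frames([[0, 0]], [[0, 0]])
        phi = pd.Series(0.04, index=cf.index)
        res = nb_two_group_test(cf, cm_, lib, phi, method="lrt")
        assert res["p"].iloc[0] == 1.0 and res["logFC"].iloc[0] == 0.0


class TestBhAdjust:
    def test_textbook_example_all_collapse(self):
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04] * 4
        )

    def test_single_p_unchanged(self):
        assert bh_adjust([0.3])[0] == pytest.approx(0.3)

    def test_monotone_in_input_ranks(self):
        rng = np.random.default_rng(8)
        p = rng.uniform(size=50)
        fdr = bh_adjust(p)
        order = np.argsort(p)
        assert (np.diff(fdr[order]) >= -1e-12).all()

    def test_matches_statsmodels(self):
        multipletests = pytest.importorskip("statsmodels.stats.multitest").multipletests
        rng = np.random.default_rng(9)
        p = rng.uniform(size=200)
        np.testing.assert_allclose(
            bh_adjust(p), multipletests(p, method="fdr_bh")[1], atol=1e-12
        )


class TestCallSexBiased:
    def _res(self, logfc, fdr):
        return pd.DataFrame({"logFC": [logfc], "p": [fdr], "FDR": [fdr]})

    @pytest.mark.parametrize(
        "logfc,fdr,expected",
        [
            (3.0, 0.01, "female_biased"),
            (2.0, 0.001, "unbiased"),  # strict > threshold
            (-4.0, 0.2, "unbiased"),   # FDR gate
            (-2.5, 0.01, "male_biased"),
        ],
    )
    def test_rule(self, logfc, fdr, expected):
        out = call_sex_biased(self._res(logfc, fdr))
        assert out["label"].iloc[0] == expected


def fisher_enumeration_p(table):
    """Independent oracle: sum hypergeometric probabilities <= observed."""
    (a, b), (c, d) = table
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def prob(aa):
        return (
            special.comb(c1, aa, exact=True)
            * special.comb(n - c1, r1 - aa, exact=True)
            / special.comb(n, r1, exact=True)
        )

    p_obs = prob(a)
    lo, hi = max(0, r1 - (n - c1)), min(r1, c1)
    return sum(prob(x) for x in range(lo, hi + 1) if prob(x) <= p_obs * (1 + 1e-9))


class TestFisherEnrichment:
    def _bias_table(self, table):
        (a, b), (c, d) = table
        labels, chroms = [], []
        labels += ["female_biased"] * (a + b) + ["unbiased"] * (c + d)
        chroms += ["X"] * a + ["autosome"] * b + ["X"] * c + ["autosome"] * d
        df = pd.DataFrame(
            {"label": labels}, index=[f"g{i}" for i in range(len(labels))]
        )
        gene_labels = pd.Series(chroms, index=df.index)
        return df, gene_labels

    def test_small_table_matches_enumeration(self):
        df, gl = self._bias_table([[3, 1], [1, 3]])
        res = fisher_enrichment(df, gl, direction="female")
        assert res.p == pytest.approx(34 / 70, abs=1e-12)
        assert res.p == pytest.approx(fisher_enumeration_p([[3, 1], [1, 3]]), abs=1e-12)

    def test_equal_proportions_give_p_one_and_unit_odds(self):
        df, gl = self._bias_table([[2, 10], [4, 20]])
        res = fisher_enrichment(df, gl, direction="female")
        assert res.p == pytest.approx(1.0)
        assert res.odds_ratio == pytest.approx(1.0)
        assert res.enriched_on == "none"

    @pytest.mark.parametrize("seed", range(4))
    def test_random_small_margin_tables_match_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        table = rng.integers(0, 15, size=(2, 2)).tolist()
        if min(np.sum(table, axis=0).min(), np.sum(table, axis=1).min()) == 0:
            pytest.skip("empty margin drawn")
        df, gl = self._bias_table(table)
        res = fisher_enrichment(df, gl, direction="female")
        assert res.p == pytest.approx(fisher_enumeration_p(table), abs=1e-9)

    def test_empty_margin_returns_none_with_warning(self):
        df, gl = self._bias_table([[0, 0], [3, 3]])
        with pytest.warns(UserWarning, match="empty margin"):
            assert fisher_enrichment(df, gl, direction="female") is None


class TestEnrichmentRecovery:
    @pytest.mark.parametrize("seed", range(5))
    def test_x_concentrated_female_bias_detected(self, seed):
        cfg = SimulationConfig(
            n_autosomes=9, n_genes_per_chrom=300, n_windows_per_chrom=10,
            bias_fraction_female=0.05, bias_fold=8.0,
            bias_x_concentration=0.30, dispersion_true=0.1, seed=seed,
        )
        genome = simulate_genome(cfg)
        cm, _ = simulate_expression(genome, cfg, [TissuePlan("t", 2)])
        labels = pd.Series(
            np.where(cm.gene_chrom == "chrX", "X", "autosome"),
            index=cm.counts.index,
        )
        _, enrich = sex_bias_analysis(cm, "t", labels)
        res = enrich["female"]
        assert res is not None
        assert res.enriched_on == "X"
        assert res.p < 0.01
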