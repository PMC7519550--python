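import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import _oracles as oracle
from conftest import make_dataset, random_matrix
from qstab.data import CqValidationError, ExpressionMatrix
from qstab.simulate import SyntheticSpec, generate_reference_panel
from qstab.stability import (
    bestkeeper,
    comparative_delta_ct,
    cv_linear,
    describe_genes,
    expression_stability_from_counts,
    genorm,
    genorm_pairwise_variation,
    normfinder,
    passage_fold_change,
)

TOL = 1e-10


class TestDescribe:
    def test_constant_gene(self):
        ds = make_dataset({"A": [20.0, 20.0, 20.0], "B": [15, 16, 17]})
        row = describe_genes(ds).loc["A"]
        assert row["mean_cq"] == 20 and row["sd_cq"] == 0
        assert row["min_cq"] == row["max_cq"] == 20

    def test_two_point_formulas(self):
        ds = make_dataset({"A": [20.0, 22.0], "B": [15, 16]})
        row = describe_genes(ds).loc["A"]
        assert row["mean_cq"] == pytest.approx(21.0)
        assert row["sd_cq"] == pytest.approx(np.sqrt(2))
        assert row["geo_mean_cq"] == pytest.approx(np.sqrt(20 * 22))


class TestCv:
    def test_constant_gene_zero_cv(self):
        ds = make_dataset({"A": [20.0, 20.0], "B": [15, 16]})
        assert cv_linear(ds).scores["A"] == pytest.approx(0.0)

    def test_two_point_closed_form(self):
        ds = make_dataset({"A": [20.0, 21.0], "B": [15, 16]})
        assert cv_linear(ds).scores["A"] == pytest.approx(47.14, abs=0.005)

    def test_offset_invariance(self, rng):
        matrix = random_matrix(rng, 4, 6)
        shifted = dict(matrix)
        shifted["G00"] = [c + 3.7 for c in matrix["G00"]]
        a = cv_linear(make_dataset(matrix)).scores
        b = cv_linear(make_dataset(shifted)).scores
        assert abs(a["G00"] - b["G00"]) < 1e-9


class TestGenorm:
    def test_proportional_genes_have_zero_m(self):
        base = [20.0, 20.5, 21.0, 19.5]
        ds = make_dataset({"A": base, "B": [c + 2 for c in base], "C": [c - 3 for c in base]})
        assert genorm(ds).table.scores.to_numpy() == pytest.approx(0.0, abs=1e-12)

    def test_matches_brute_force(self, rng):
        matrix = random_matrix(rng, 5, 8)
        res = genorm(make_dataset(matrix))
        order, removal_m, pair = oracle.genorm_exclusion(matrix)
        assert res.exclusion_order == order
        assert sorted(res.stability_order[:2]) == pair
        for gene, m in removal_m.items():
            assert abs(res.table.scores[gene] - m) < TOL

    def test_full_m_matches_oracle(self, small_dataset):
        from qstab.data import to_matrix

        matrix_df = to_matrix(small_dataset)
        matrix = {g: list(matrix_df.loc[g]) for g in matrix_df.index}
        first_round = genorm(small_dataset).m_trace["round_1"].dropna()
        expected = oracle.genorm_m_full(matrix)
        for gene, m in expected.items():
            assert abs(first_round[gene] - m) < TOL

    def test_offset_invariance(self, rng):
        matrix = random_matrix(rng, 4, 6)
        shifted = dict(matrix)
        shifted["G01"] = [c + 5.0 for c in matrix["G01"]]
        a = genorm(make_dataset(matrix)).table.scores
        b = genorm(make_dataset(shifted)).table.scores
        pd.testing.assert_series_equal(a, b, atol=1e-12, rtol=0)

    def test_exclusion_is_greedy_on_m(self, rng):
        matrix = random_matrix(rng, 6, 9)
        res = genorm(make_dataset(matrix))
        for t, gene in enumerate(res.exclusion_order):
            round_m = res.m_trace[f"round_{t + 1}"].dropna()
            assert round_m[gene] == round_m.max()

    def test_final_pair_tied_rank_one(self, rng):
        res = genorm(make_dataset(random_matrix(rng, 5, 8)))
        ranks = res.table.ranks.sort_values()
        assert list(ranks.iloc[:3]) == [1.0, 1.0, 3.0]

    def test_needs_three_genes(self):
        with pytest.raises(CqValidationError):
            genorm(make_dataset({"A": [20, 21], "B": [15, 16]}))


class TestVSeries:
    def test_proportional_genes_give_zero_v(self):
        base = [20.0, 20.5, 21.0, 19.5]
        ds = make_dataset(
            {"A": base, "B": [c + 2 for c in base], "C": [c - 3 for c in base],
             "D": [c + 1 for c in base]}
        )
        assert genorm_pairwise_variation(ds).to_numpy() == pytest.approx(0.0, abs=1e-12)

    def test_matches_brute_force(self, rng):
        matrix = random_matrix(rng, 5, 8)
        ds = make_dataset(matrix)
        order = genorm(ds).stability_order
        got = genorm_pairwise_variation(ds, order)
        expected = oracle.v_series(matrix, order)
        for n, v in expected.items():
            assert abs(got[n] - v) < TOL

    def test_gene_matching_nf_gives_zero_v(self, rng):
        matrix = random_matrix(rng, 3, 6)
        order = ["G00", "G01", "G02"]
        # a 4th gene whose -Cq equals the mean of the first three's -> V_3/4 = 0
        matrix["G03"] = list(np.mean([matrix[g] for g in order], axis=0))
        got = genorm_pairwise_variation(make_dataset(matrix), order + ["G03"])
        assert got[3] == pytest.approx(0.0, abs=1e-12)


class TestNormFinder:
    def test_noise_free_additive_data_scores_zero(self):
        sample_eff = np.array([0.3, -0.2, 0.1, -0.4, 0.2, 0.0])
        ds = make_dataset(
            {g: list(mu + sample_eff) for g, mu in [("A", 20), ("B", 15), ("C", 25)]}
        )
        assert normfinder(ds).table.scores.to_numpy() == pytest.approx(0.0, abs=1e-9)

    def test_matches_published_residual_formula(self, medium_dataset):
        from qstab.data import to_matrix

        matrix_df = to_matrix(medium_dataset)
        matrix = {g: list(matrix_df.loc[g]) for g in matrix_df.index}
        expected = oracle.normfinder_single_group(matrix)
        got = normfinder(medium_dataset).table.scores
        for gene, sigma2 in expected.items():
            assert abs(got[gene] - np.sqrt(sigma2)) < TOL

    def test_best_pair_is_minimum(self, medium_dataset):
        res = normfinder(medium_dataset)
        assert res.pair_scores.index[0] == tuple(sorted(res.best_pair))
        assert res.pair_scores.is_monotonic_increasing

    def test_grouped_mode_penalises_diverging_gene(self, rng):
        # gene D shifts by +1 cycle in culture A2 only: inter-group bias
        base = {g: list(rng.normal(mu, 0.1, 8)) for g, mu in
                [("A", 20), ("B", 15), ("C", 25), ("D", 22)]}
        shifted = {g: list(np.array(v) + (1.0 if g == "D" else 0.0))
                   for g, v in base.items()}
        from qstab.data import merge_datasets

        merged = merge_datasets(make_dataset(base, "A1"), make_dataset(shifted, "A2"))
        res = normfinder(merged, groups="culture")
        assert res.grouped
        assert res.table.ranks["D"] == 4.0

    def test_two_genes_rejected(self):
        with pytest.raises(CqValidationError):
            normfinder(make_dataset({"A": [20, 21, 22], "B": [15, 16, 17]}))


class TestBestKeeper:
    def test_constant_gene(self):
        ds = make_dataset({"A": [20.0, 20.0, 20.0], "B": [15, 16, 17]})
        desc = bestkeeper(ds).descriptives.loc["A"]
        assert desc["sd_cp"] == 0 and desc["x_fold"] == 1
        assert not desc["inconsistent"]

    def test_perfectly_covarying_pair(self):
        base = [20.0, 20.5, 21.0, 19.5]
        ds = make_dataset({"A": base, "B": [c + 3 for c in base], "C": [25, 25.1, 24.9, 25.0]})
        assert bestkeeper(ds).gene_corr.loc["A", "B"] == pytest.approx(1.0)

    @pytest.mark.parametrize("dispersion", ["mad", "sd"])
    def test_matches_brute_force(self, rng, dispersion):
        matrix = random_matrix(rng, 4, 6)
        res = bestkeeper(make_dataset(matrix), dispersion=dispersion)
        desc, pair_r, index, index_r = oracle.bestkeeper(matrix, dispersion=dispersion)
        for gene, row in desc.items():
            for col, val in row.items():
                assert abs(res.descriptives.loc[gene, col] - val) < TOL
        for (a, b), r in pair_r.items():
            assert abs(res.gene_corr.loc[a, b] - r) < TOL
        assert np.allclose(res.index.to_numpy(), index, atol=TOL, rtol=0)
        for gene, r in index_r.items():
            assert abs(res.index_corr.loc[gene, "r"] - r) < TOL

    def test_dispersion_above_one_flagged(self):
        ds = make_dataset({"A": [18.0, 22.0, 18.0, 22.0], "B": [15, 15.1, 14.9, 15]})
        assert bool(bestkeeper(ds).descriptives.loc["A", "inconsistent"])


class TestDeltaCt:
    def test_constant_offsets_score_zero(self):
        base = [20.0, 20.5, 21.0]
        ds = make_dataset({"A": base, "B": [c + 2 for c in base]})
        assert comparative_delta_ct(ds).scores.to_numpy() == pytest.approx(0.0, abs=1e-12)

    def test_two_genes_share_score(self):
        ds = make_dataset({"A": [20.0, 21.0, 20.5], "B": [15.0, 15.2, 15.9]})
        scores = comparative_delta_ct(ds).scores
        assert scores["A"] == pytest.approx(scores["B"])

    def test_matches_brute_force(self, rng):
        matrix = random_matrix(rng, 5, 8)
        got = comparative_delta_ct(make_dataset(matrix)).scores
        expected = oracle.delta_ct_scores(matrix)
        for gene, s in expected.items():
            assert abs(got[gene] - s) < TOL


class TestOrderInvariance:
    @settings(derandomize=True, max_examples=10, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_sample_and_gene_order_never_change_scores(self, seed):
        rng = np.random.default_rng(seed)
        matrix = random_matrix(rng, 4, 6)
        ds = make_dataset(matrix)
        frame = ds.frame.sample(frac=1.0, random_state=seed)
        from qstab.data import CqDataset

        ds2 = CqDataset(frame, sample_unit="lysate_mean")
        for fn in (cv_linear, comparative_delta_ct):
            pd.testing.assert_series_equal(fn(ds).scores, fn(ds2).scores)
        pd.testing.assert_series_equal(
            genorm(ds).table.scores, genorm(ds2).table.scores
        )


class TestPassageFoldChange:
    def _panel(self, drift):
        spec = SyntheticSpec(
            genes=(("REF", 20.0, 0.1), ("X", 22.0, 0.1), ("Y", 24.0, 0.1)),
            passage_sd=0.0,
            lysate_sd=0.0,
            drift=drift,
            seed=9,
        )
        from qstab.data import collapse_replicates

        return collapse_replicates(generate_reference_panel(spec, "A1"))

    def test_calibrator_passage_mean_fold_is_one(self):
        res = passage_fold_change(self._panel({}), calibrator=1)
        cal = res.folds[res.folds["passage"] == 1]
        assert cal.groupby("gene")["fold"].mean().to_numpy() == pytest.approx(1.0, abs=1e-9)

    def test_one_cycle_below_calibrator_doubles(self):
        ds = make_dataset({"A": [20.0, 20.0, 19.0, 19.0], "B": [15, 15, 15, 15]})
        frame = ds.frame.copy()
        frame["passage"] = [1, 1, 2, 2] * 2
        frame["lysate"] = [1, 2, 1, 2] * 2
        from qstab.data import CqDataset

        res = passage_fold_change(CqDataset(frame, sample_unit="lysate_mean"), calibrator=1)
        a2 = res.folds.query("gene == 'A' and passage == 2")["fold"]
        assert a2.to_numpy() == pytest.approx(2.0)

    def test_drift_gene_significant_stable_gene_not(self):
        res = passage_fold_change(self._panel({"X": 0.5}), calibrator=1)
        assert res.tests.loc["X", "p_omnibus"] < 0.01
        assert res.tests.loc["REF", "p_omnibus"] > 0.05

    def test_unknown_calibrator_rejected(self):
        with pytest.raises(CqValidationError):
            passage_fold_change(self._panel({}), calibrator=99)


class TestExpressionScreens:
    def test_constant_tpm_32(self):
        m = ExpressionMatrix(pd.DataFrame({"s1": [32.0], "s2": [32.0], "s3": [32.0]},
                                          index=["G"]))
        row = expression_stability_from_counts(m, mode="tpm").loc["G"]
        assert row["mean_log2"] == pytest.approx(5.0)
        assert row["sd_log2"] == pytest.approx(0.0)
        assert not row["medium_to_high_expression"]  # > 5 strictly

    def test_counts_log2_plus_one(self):
        m = ExpressionMatrix(pd.DataFrame({"s1": [0.0], "s2": [1.0], "s3": [3.0]},
                                          index=["G"]))
        out = expression_stability_from_counts(m, mode="counts")
        assert out.loc["G", "mean_log2"] == pytest.approx(np.mean([0, 1, 2]))

    def test_tpm_mode_rejects_zeros(self):
        m = ExpressionMatrix(pd.DataFrame({"s1": [0.0, 5.0], "s2": [2.0, 5.0]},
                                          index=["G1", "G2"]))
        with pytest.raises(CqValidationError, match="counts"):
            expression_stability_from_counts(m, mode="tpm")

    def test_matches_direct_loops(self, rng):
        vals = rng.uniform(1.0, 500.0, size=(6, 20))
        m = ExpressionMatrix(pd.DataFrame(vals, index=[f"G{i}" for i in range(6)]))
        out = expression_stability_from_counts(m, mode="tpm")
        for i in range(6):
            logv = np.log2(vals[i])
            assert out.loc[f"G{i}", "mean_log2"] == pytest.approx(logv.mean())
            assert out.loc[f"G{i}", "sd_log2"] == pytest.approx(logv.std(ddof=1))
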