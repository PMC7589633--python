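import numpy as np
import pandas as pd
import pytest
from scipy import stats

from conftest import paired_study
from fflnet import expr, synthdata
from fflnet.fflcore import (
    NullDistribution,
    ScoreParams,
    ScoringError,
    TripleScorer,
    brute_force_ffls,
    cancer_gene_enrichment,
    dysregulated_network,
    edge_score,
    empirical_pvalues,
    enumerate_ffls,
    ffl_score,
    fisher_z,
    flag_dysregulated,
    hub_ffls,
    node_score,
    permutation_null,
    score_ffls,
)
from fflnet.netio import Regulation, build_network


def triple_set(ffls):
    return set(map(tuple, ffls[["tf", "mirna", "gene", "ffl_type"]].to_numpy()))


class TestEnumerate:
    def test_minimal_tf_ffl(self):
        net = build_network(
            [
                Regulation("T1", "m1", "tf_mirna"),
                Regulation("T1", "g1", "tf_gene"),
                Regulation("m1", "g1", "mirna_gene"),
            ]
        )
        assert triple_set(enumerate_ffls(net)) == {("T1", "m1", "g1", "TF_FFL")}

    def test_mutual_regulation_collapses_to_one_fb_record(self):
        net = build_network(
            [
                Regulation("T1", "m1", "tf_mirna"),
                Regulation("m1", "T1", "mirna_tf"),
                Regulation("T1", "g1", "tf_gene"),
                Regulation("m1", "g1", "mirna_gene"),
            ]
        )
        assert triple_set(enumerate_ffls(net)) == {("T1", "m1", "g1", "FB_FFL")}

    def test_mirna_ffl(self):
        net = build_network(
            [
                Regulation("m1", "T1", "mirna_tf"),
                Regulation("T1", "g1", "tf_gene"),
                Regulation("m1", "g1", "mirna_gene"),
            ]
        )
        assert triple_set(enumerate_ffls(net)) == {("T1", "m1", "g1", "MIRNA_FFL")}

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_on_random_networks(self, seed):
        net, _ = synthdata.synth_network(
            n_tf=12, n_mirna=12, n_gene=25, edge_density=0.08, n_planted_ffls=3, seed=seed
        )
        assert triple_set(enumerate_ffls(net)) == triple_set(brute_force_ffls(net))

    def test_each_triple_emitted_once(self, planted_run):
        ffls = enumerate_ffls(planted_run["network"])
        keys = list(map(tuple, ffls[["tf", "mirna", "gene"]].to_numpy()))
        assert len(keys) == len(set(keys))


class TestScorePrimitives:
    def test_node_score_values_against_normal_cdf(self):
        # Phi(1.959964) = 0.975 so the folded probability is 0.95
        assert node_score(1.959964) == pytest.approx(stats.norm.ppf(0.95), abs=1e-6)
        assert node_score(1.0) == pytest.approx(
            stats.norm.ppf(2 * stats.norm.cdf(1.0) - 1), abs=1e-12
        )
        assert node_score(1.0) == pytest.approx(0.4752, abs=1e-4)

    def test_node_score_floor_at_zero_diff(self):
        eps = 1e-15
        assert node_score(0.0, clamp_eps=eps) == pytest.approx(stats.norm.ppf(eps))
        assert np.isfinite(node_score(0.0, clamp_eps=eps))

    def test_node_score_monotone_and_rejects_negative(self):
        diffs = np.linspace(0.01, 5, 50)
        scores = node_score(diffs)
        assert np.all(np.diff(scores) > 0)
        with pytest.raises(ScoringError):
            node_score(-0.1)

    def test_fisher_z(self):
        assert fisher_z(0.0) == 0.0
        assert fisher_z(0.5) == pytest.approx(0.5 * np.log(3), abs=1e-12)
        assert fisher_z(0.5) == pytest.approx(0.549306, abs=1e-6)
        for r in (0.1, 0.5, 0.9):
            assert fisher_z(-r) == -fisher_z(r)

    def test_ffl_score_weighted_mean(self):
        assert ffl_score([1, 2, 3], [0, 1, 2], gamma=0.5) == pytest.approx(1.5)
        # equal node and edge means are a fixed point at gamma = 0.5
        assert ffl_score([2, 2, 2], [1, 2, 3], gamma=0.5) == pytest.approx(2.0)

    def test_ffl_score_invariant_to_edge_order(self):
        base = ffl_score([1, 2, 3], [0.3, 1.1, 2.2])
        assert ffl_score([3, 1, 2], [2.2, 0.3, 1.1]) == pytest.approx(base)

    def test_ffl_score_validation(self):
        with pytest.raises(ScoringError):
            ffl_score([1, 2, 3], [0, 1, 2], gamma=1.5)
        with pytest.raises(ScoringError):
            ffl_score([1, 2], [0, 1, 2])


class TestEdgeScore:
    # rank vectors with Spearman exactly +-0.9 at n = 5
    X = np.array([1.0, 2, 3, 4, 5])
    Y_POS = np.array([2.0, 1, 3, 4, 5])  # rho = +0.9
    Y_NEG = np.array([4.0, 5, 3, 2, 1])  # rho = -0.9

    def test_worked_example_d_value(self):
        parts = edge_score(self.X, self.Y_POS, self.X, self.Y_NEG)
        assert parts.r_case == pytest.approx(0.9)
        assert parts.r_control == pytest.approx(-0.9)
        # D = 2*F(0.9)/sqrt(1.06*(1/2+1/2)) = ln(19)/sqrt(1.06)
        assert parts.D == pytest.approx(np.log(19) / np.sqrt(1.06), abs=1e-9)
        assert parts.D == pytest.approx(2.8599, abs=1e-3)

    def test_equal_correlations_hit_floor(self):
        parts = edge_score(self.X, self.Y_POS, self.X, self.Y_POS)
        assert parts.D == 0.0
        assert parts.s_edge == pytest.approx(stats.norm.ppf(1e-15))

    def test_label_swap_flips_d_not_score(self):
        fwd = edge_score(self.X, self.Y_POS, self.X, self.Y_NEG)
        rev = edge_score(self.X, self.Y_NEG, self.X, self.Y_POS)
        assert rev.D == pytest.approx(-fwd.D)
        assert rev.s_edge == pytest.approx(fwd.s_edge)

    def test_constant_vector_warns_and_uses_zero(self):
        const = np.ones(5)
        with pytest.warns(UserWarning, match="constant"):
            parts = edge_score(const, self.Y_POS, self.X, self.Y_NEG)
        assert parts.r_case == 0.0

    def test_small_samples_rejected(self):
        with pytest.raises(ScoringError, match="> 3"):
            edge_score(self.X[:3], self.Y_POS[:3], self.X, self.Y_NEG)


class TestScoreFFLs:
    def test_fully_null_ffl_scores_at_floor(self):
        # identical case and control values: Diff = 0 and D = 0 everywhere
        rng = np.random.default_rng(0)
        half = rng.normal(8, 1, size=(3, 5))
        mat = np.hstack([half, half])
        study = paired_study(mat, n_mirna_rows=1)
        de = {
            "gene": expr.moderated_de(study, "gene"),
            "miRNA": expr.moderated_de(study, "miRNA"),
        }
        ffls = pd.DataFrame([{"tf": "F0", "mirna": "mF2", "gene": "F1", "ffl_type": "TF_FFL"}])
        scored = score_ffls(ffls, study, de)
        floor = stats.norm.ppf(1e-15)
        assert scored.loc[0, "score"] == pytest.approx(floor, rel=1e-9)

    def test_matches_scalar_primitives(self, planted_run):
        """Vectorised scorer agrees with the scalar node/edge/ffl functions."""
        run = planted_run
        row = run["flagged"].iloc[7]
        study, de = run["study"], run["de"]
        case_cols = study.condition_columns("case")
        ctrl_cols = study.condition_columns("control")

        def expvec(node, cols):
            cls = "miRNA" if node.startswith("miR") else "gene"
            return study.matrix(cls).loc[node, cols].to_numpy(float)

        nodes = [row["tf"], row["mirna"], row["gene"]]
        n_scores = []
        for node in nodes:
            cls = "miRNA" if node.startswith("miR") else "gene"
            n_scores.append(node_score(de[cls].loc[node, "diff_score"]))
        e_scores = []
        for a, b in [(nodes[0], nodes[1]), (nodes[0], nodes[2]), (nodes[1], nodes[2])]:
            parts = edge_score(
                expvec(a, case_cols), expvec(b, case_cols),
                expvec(a, ctrl_cols), expvec(b, ctrl_cols),
            )
            e_scores.append(parts.s_edge)
        assert row["score"] == pytest.approx(ffl_score(n_scores, e_scores), abs=1e-9)
        np.testing.assert_allclose(
            row[["s_node_tf", "s_node_mirna", "s_node_gene"]].to_numpy(float), n_scores, atol=1e-9
        )
        np.testing.assert_allclose(
            row[["s_edge_tm", "s_edge_tg", "s_edge_mg"]].to_numpy(float), e_scores, atol=1e-9
        )

    def test_missing_node_skipped_and_counted(self, planted_run):
        ffls = enumerate_ffls(planted_run["network"]).head(3).copy()
        ffls.loc[0, "gene"] = "NOT_MEASURED"
        scored = score_ffls(ffls, planted_run["study"], planted_run["de"])
        assert len(scored) == 2
        assert scored.attrs["n_skipped"] == 1

    def test_planted_ffls_score_above_null_quantile(self, planted_run):
        run = planted_run
        q95 = np.quantile(run["null"].scores, 0.95)
        planted = run["truth"].planted_keys()
        mask = [tuple(k) in planted for k in run["flagged"][["tf", "mirna", "gene"]].to_numpy()]
        planted_scores = run["flagged"]["score"][mask]
        assert (planted_scores > q95).mean() >= 0.8


class TestPermutationNull:
    def test_deterministic_given_seed(self, planted_run):
        run = planted_run
        a = permutation_null(run["network"], run["study"], run["de"], 50, seed=9, scorer=run["scorer"])
        b = permutation_null(run["network"], run["study"], run["de"], 50, seed=9, scorer=run["scorer"])
        np.testing.assert_array_equal(a.scores, b.scores)

    def test_single_draw(self, planted_run):
        run = planted_run
        null = permutation_null(run["network"], run["study"], run["de"], 1, seed=0, scorer=run["scorer"])
        assert null.scores.shape == (1,)

    def test_null_matches_real_distribution_without_effects(self):
        """Two-sample calibration: with nothing planted, real FFL scores and
        random-triple scores are draws from the same distribution."""
        net, truth = synthdata.synth_network(seed=31)
        study, truth = synthdata.synth_expression(
            net, truth, effect_lfc=0.0, coexpr_delta=0.0, seed=32
        )
        de = {
            "gene": expr.moderated_de(study, "gene"),
            "miRNA": expr.moderated_de(study, "miRNA"),
        }
        scorer = TripleScorer(study, de)
        scored = score_ffls(enumerate_ffls(net), study, de, scorer=scorer)
        null = permutation_null(net, study, de, n_draws=10_000, seed=33, scorer=scorer)
        ks = stats.ks_2samp(scored["score"], null.scores)
        assert ks.pvalue > 0.01


class TestEmpiricalP:
    def test_counting_example(self):
        null = NullDistribution(np.array([6.0, 6.0, 1.0, 1.0]), 4, 0)
        assert empirical_pvalues(np.array([5.0]), null)[0] == pytest.approx(0.5)

    def test_score_above_all_null(self):
        null = NullDistribution(np.arange(10.0), 10, 0)
        assert empirical_pvalues(np.array([99.0]), null)[0] == 0.0

    def test_pseudocount_variant_never_zero(self):
        null = NullDistribution(np.arange(10.0), 10, 0)
        p = empirical_pvalues(np.array([99.0]), null, pseudocount=True)
        assert p[0] == pytest.approx(1 / 11)

    def test_uniform_when_real_drawn_from_null(self):
        rng = np.random.default_rng(12)
        null = NullDistribution(rng.normal(size=20_000), 20_000, 12)
        real = rng.normal(size=500)
        p = empirical_pvalues(real, null)
        assert stats.kstest(p, "uniform").pvalue > 0.01


class TestDysregulatedNetwork:
    def flagged(self, rows):
        df = pd.DataFrame(rows)
        df["dysregulated"] = True
        return df

    def test_shared_gene_merges_nodes(self):
        net, counts = dysregulated_network(
            self.flagged(
                [
                    {"tf": "T1", "mirna": "m1", "gene": "g1", "ffl_type": "TF_FFL"},
                    {"tf": "T2", "mirna": "m2", "gene": "g1", "ffl_type": "TF_FFL"},
                ]
            )
        )
        assert len(net.nodes) == 5
        assert counts["total"] == 2

    def test_counts_partition_by_type(self, planted_run):
        _, counts = dysregulated_network(planted_run["flagged"])
        assert counts["TF_FFL"] + counts["MIRNA_FFL"] + counts["FB_FFL"] == counts["total"]

    def test_fb_ffl_contributes_both_directions(self):
        net, _ = dysregulated_network(
            self.flagged([{"tf": "T1", "mirna": "m1", "gene": "g1", "ffl_type": "FB_FFL"}])
        )
        assert net.has_edge("T1", "m1", "tf_mirna") and net.has_edge("m1", "T1", "mirna_tf")


class TestHubFFLs:
    def toy(self):
        rows = [
            {"tf": "T1", "mirna": "m1", "gene": "g1", "ffl_type": "TF_FFL"},
            {"tf": "T1", "mirna": "m1", "gene": "g2", "ffl_type": "TF_FFL"},
            {"tf": "T2", "mirna": "m2", "gene": "g3", "ffl_type": "TF_FFL"},
        ]
        df = pd.DataFrame(rows)
        df["dysregulated"] = True
        return df

    def test_threshold_and_strictness(self):
        ffls = self.toy()
        merged, _ = dysregulated_network(ffls)
        hubs2, subnet = hub_ffls(ffls, merged, min_degree=2)
        # hand degrees: T1=3, m1=3, T2=2, m2=2, g1=g2=g3=2 -> all FFLs pass at 2
        assert len(hubs2) == 3 and subnet is not None
        hubs3, _ = hub_ffls(ffls, merged, min_degree=3)
        assert len(hubs3) == 0  # genes have degree 2 = min_degree - 1: strict "no fewer than"

    def test_hub_set_shrinks_with_min_degree(self, planted_run):
        flagged = planted_run["flagged"]
        merged, _ = dysregulated_network(flagged)
        previous = None
        for k in range(1, 6):
            hubs, _ = hub_ffls(flagged, merged, min_degree=k)
            keys = set(map(tuple, hubs[["tf", "mirna", "gene"]].to_numpy()))
            if previous is not None:
                assert keys <= previous
            previous = keys


class TestCancerGeneEnrichment:
    def test_matches_hypergeometric_summation(self):
        # table [[4,1],[1,14]]: subset of 5 from a background of 20 with 5 known
        subset = {f"s{i}" for i in range(5)}
        background = subset | {f"b{i}" for i in range(15)}
        known = {f"s{i}" for i in range(4)} | {"b0"}
        res = cancer_gene_enrichment(subset, background, known)
        assert res["table"].tolist() == [[4, 1], [1, 14]]
        # oracle: two-sided Fisher = sum of hypergeometric point probabilities
        # no larger than the observed one
        M, K, n = 20, 5, 5
        probs = [stats.hypergeom.pmf(k, M, K, n) for k in range(6)]
        p_obs = probs[4]
        expected = sum(p for p in probs if p <= p_obs * (1 + 1e-9))
        assert res["p_value"] == pytest.approx(expected, rel=1e-9)

    def test_no_contrast_gives_p_one(self):
        genes = {"a", "b", "c"}
        assert cancer_gene_enrichment(genes, genes, {"a"})["p_value"] == pytest.approx(1.0)
        assert cancer_gene_enrichment({"a"}, genes, set())["p_value"] == pytest.approx(1.0)

    def test_subset_must_be_in_background(self):
        with pytest.raises(ScoringError):
            cancer_gene_enrichment({"x"}, {"a"}, set())


class TestFlagging:
    def test_alpha_controls_flag(self, planted_run):
        run = planted_run
        strict = flag_dysregulated(run["flagged"], run["null"], alpha=0.01)
        loose = flag_dysregulated(run["flagged"], run["null"], alpha=0.10)
        assert strict["dysregulated"].sum() <= loose["dysregulated"].sum()
        assert ((run["flagged"]["empirical_p"] <= 0.05) == run["flagged"]["dysregulated"]).all()
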