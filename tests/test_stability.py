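import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from refstab.core import RQMatrix, cq_to_rq
from refstab.stability import (
    bestkeeper,
    delta_ct_stability,
    genorm_cv,
    genorm_m_values,
    genorm_ranking,
    normfinder_stability,
    pairwise_variation,
    run_all_methods,
    stability_index,
)
from refstab.simulate import default_config, simulate_study

from conftest import make_cq


def make_rq(values, genes=None) -> RQMatrix:
    cq = make_cq(np.asarray(values, dtype=float) * 0 + 20.0, genes=genes)
    return RQMatrix(
        pd.DataFrame(np.asarray(values, dtype=float), index=cq.cq.index, columns=cq.cq.columns),
        cq.annotations,
    )


class TestStabilityIndex:
    def test_slope_matches_closed_form_ols(self, toy_cq):
        res = stability_index(toy_cq)
        overall = toy_cq.cq.mean(axis=0).to_numpy()
        for gene in toy_cq.genes:
            y = toy_cq.cq.loc[gene].to_numpy()
            slope = np.cov(overall, y, ddof=1)[0, 1] / np.var(overall, ddof=1)
            assert res.scores.loc[gene, "slope"] == pytest.approx(slope, rel=1e-12)
            cv = 100 * y.std(ddof=1) / y.mean()
            assert res.scores.loc[gene, "si"] == pytest.approx(cv * abs(slope), rel=1e-12)

    def test_constant_gene_ranks_first_with_zero_si(self, toy_cq):
        res = stability_index(toy_cq)
        assert res.scores.loc["g3", "sd"] == 0.0
        assert res.scores.loc["g3", "cv"] == 0.0
        assert res.scores.loc["g3", "si"] == 0.0
        assert res.ranking[0] == "g3"

    def test_degenerate_overall_mean_gives_zero_slope_with_warning(self):
        # gene deviations cancel so every per-reaction overall mean is equal
        cq = make_cq([[20.0, 21.0, 22.0], [22.0, 21.0, 20.0]])
        with pytest.warns(UserWarning, match="overall means"):
            res = stability_index(cq)
        assert (res.scores["slope"] == 0.0).all()

    def test_si_uses_absolute_slope(self):
        # one gene moves against the panel: its slope is negative, SI must
        # still penalize the sensitivity
        cq = make_cq(
            [
                [20.0, 21.0, 22.0, 23.0],
                [20.1, 21.2, 21.9, 23.1],
                [25.0, 24.0, 23.0, 22.0],
            ]
        )
        res = stability_index(cq)
        assert res.scores.loc["g3", "slope"] < 0
        assert res.scores.loc["g3", "si"] > 0


class TestGeNorm:
    def test_hand_computed_m_values(self):
        rq = make_rq(
            [
                [1.0, 0.5, 0.25, 0.125],
                [1.0, 0.5, 0.25, 0.125],
                [1.0, 1.0, 1.0, 1.0],
            ]
        )
        m = genorm_m_values(rq)
        expected_g3 = np.std([0.0, 1.0, 2.0, 3.0], ddof=1)  # sqrt(5/3)
        assert m["g3"] == pytest.approx(expected_g3, rel=1e-12)
        assert m["g1"] == pytest.approx(expected_g3 / 2, rel=1e-12)
        assert m["g2"] == pytest.approx(expected_g3 / 2, rel=1e-12)

    def test_proportional_genes_have_zero_m(self):
        rq = make_rq([[1.0, 0.5, 0.25], [0.5, 0.25, 0.125]])
        assert genorm_m_values(rq).tolist() == [0.0, 0.0]

    def test_scaling_one_gene_leaves_m_unchanged(self, rng):
        vals = rng.uniform(0.1, 1.0, size=(4, 8))
        m0 = genorm_m_values(make_rq(vals))
        vals2 = vals.copy()
        vals2[1] *= 7.3
        m1 = genorm_m_values(make_rq(vals2))
        pd.testing.assert_series_equal(m0, m1, rtol=1e-12)

    def test_ranking_excludes_least_stable_first(self):
        rq = make_rq(
            [
                [1.0, 0.5, 0.25, 0.125],
                [1.0, 0.5, 0.25, 0.125],
                [1.0, 1.0, 1.0, 1.0],
            ]
        )
        res = genorm_ranking(rq)
        assert res.ranking[-1] == "g3"  # highest M excluded first
        assert res.scores.loc["g3", "m_a"] == pytest.approx(np.sqrt(5 / 3), rel=1e-12)
        assert res.extra["all_acceptable"] is False  # g3's M_A exceeds 1

    def test_identical_genes_tie_breaks_to_label_order(self):
        vals = np.vstack([[1.0, 0.5, 0.25]] * 4) * np.array([[1], [2], [4], [8]])
        with pytest.warns(UserWarning, match="tied M"):
            res = genorm_ranking(make_rq(vals))
        assert res.ranking == ["g1", "g2", "g3", "g4"]
        assert (res.scores["m_a"] == 0.0).all()

    @pytest.mark.parametrize(
        "z, expected",
        [((1.0, 1.0, 2.0), np.std([1, 1, 2], ddof=1) / np.mean([1, 1, 2]))],
    )
    def test_cv_norm_hand_value(self, z, expected):
        rq = make_rq([list(z), [1.0, 1.0, 1.0]])
        cv = genorm_cv(rq, ["g2"])
        assert cv["g1"] == pytest.approx(expected, rel=1e-12)
        assert cv["g2"] == 0.0  # self-normalization

    def test_gene_proportional_to_nf_has_zero_cv(self):
        rq = make_rq([[1.0, 0.5, 0.25], [0.5, 0.25, 0.125], [0.8, 0.4, 0.2]])
        cv = genorm_cv(rq, ["g1", "g2"])
        assert cv["g3"] == pytest.approx(0.0, abs=1e-14)


class TestPairwiseVariation:
    def test_shared_profile_gives_all_zero_v_and_minimal_two(self):
        vals = np.vstack([[1.0, 0.5, 0.25, 0.125]] * 4) * np.array([[1], [2], [4], [8]])
        pv = pairwise_variation(make_rq(vals), ["g1", "g2", "g3", "g4"])
        assert (pv.v == 0.0).all()
        assert pv.minimal_n == 2

    def test_v_matches_hand_computation(self, rng):
        vals = rng.uniform(0.1, 1.0, size=(4, 6))
        order = ["g1", "g2", "g3", "g4"]
        pv = pairwise_variation(make_rq(vals), order)
        log2 = np.log2(vals)
        nf2 = log2[:2].mean(axis=0)
        nf3 = log2[:3].mean(axis=0)
        assert pv.v[2] == pytest.approx(np.std(nf2 - nf3, ddof=1), rel=1e-12)

    def test_scalar_multiple_of_nf_yields_exactly_zero_v(self):
        # log2 quantities are integers and scale sums divide evenly, so the
        # geometric means are exact in floating point and V is bitwise zero
        shared = np.array([0.0, 3.0, 1.0, 5.0, 2.0, 4.0])
        vals = np.array([2.0 ** (shared + b) for b in (0.0, 0.0, 3.0, 8.0)])
        pv = pairwise_variation(make_rq(vals), ["g1", "g2", "g3", "g4"])
        assert pv.v[2] == 0.0
        assert pv.v[3] == 0.0

    def test_minimal_n_honors_cutoff(self):
        # two agreeing genes, a third deviating with SD(log2) = 0.6 so that
        # V(2/3) = 0.6/3 = 0.2 >= 0.15, then a fourth tracking NF3 exactly
        shared = np.array([0.0, 1.0, 2.0, 3.0])
        dev = np.array([0.6, -0.6, 0.6, -0.6]) / np.std([1, -1, 1, -1], ddof=1)
        log2 = np.vstack([shared, shared, shared + dev])
        log2 = np.vstack([log2, log2.mean(axis=0)])
        pv = pairwise_variation(make_rq(2.0**log2), ["g1", "g2", "g3", "g4"])
        assert pv.v[2] == pytest.approx(np.std(dev, ddof=1) / 3, rel=1e-12)
        assert pv.v[2] >= 0.15
        assert pv.v[3] == pytest.approx(0.0, abs=1e-12)
        assert pv.minimal_n == 3
        assert pv.optimal_n == 3


class TestNormFinder:
    def test_constant_gene_attains_minimum_rho(self, rng):
        vals = 20.0 + rng.normal(0, 0.5, size=(5, 40))
        vals[2] = 22.0  # perfectly stable gene
        res = normfinder_stability(cq_to_rq(make_cq(vals)))
        assert res.ranking[0] == "g3"
        assert res.scores["rho"].idxmin() == "g3"

    def test_noise_ladder_recovered(self):
        # 8 genes with noise SD rising 0.05..0.75; with 50 reactions the SD
        # estimates carry sampling error of roughly sigma/10, so adjacent
        # swaps are expected and perfect orderings are not; the rho ranking
        # must still track the ladder at Spearman >= 0.9 nearly always
        sigmas = np.linspace(0.05, 0.75, 8)
        hits = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            vals = 20.0 + rng.normal(0, sigmas[:, None], size=(8, 50))
            res = normfinder_stability(cq_to_rq(make_cq(vals)))
            rho = res.scores["rho"].to_numpy()
            hits += sps.spearmanr(rho, sigmas).statistic >= 0.9
        assert hits >= 95

    def test_group_shift_strictly_increases_rho(self, rng):
        vals = 20.0 + rng.normal(0, 0.3, size=(4, 24))
        groups = pd.Series(
            ["A"] * 12 + ["B"] * 12, index=[f"r{i + 1}" for i in range(24)]
        )
        base = normfinder_stability(cq_to_rq(make_cq(vals)), groups)
        shifted = vals.copy()
        shifted[1, 12:] += 1.0  # one-cycle treatment effect on gene 2
        after = normfinder_stability(cq_to_rq(make_cq(shifted)), groups)
        assert after.scores.loc["g2", "rho"] > base.scores.loc["g2", "rho"]

    def test_small_group_rejected(self, rng):
        vals = 20.0 + rng.normal(0, 0.3, size=(3, 5))
        groups = pd.Series(["A"] * 4 + ["B"], index=[f"r{i + 1}" for i in range(5)])
        with pytest.raises(ValueError, match="< 2 reactions"):
            normfinder_stability(cq_to_rq(make_cq(vals)), groups)


class TestBestKeeper:
    def test_hand_computed_dispersion(self):
        cq = make_cq([[19.0, 20.0, 21.0], [20.0, 20.0, 20.0]])
        res = bestkeeper(cq)
        geo = (19.0 * 20.0 * 21.0) ** (1.0 / 3.0)
        expected = np.mean(np.abs(np.array([19.0, 20.0, 21.0]) - geo))
        assert res.scores.loc["g1", "geo_mean_cq"] == pytest.approx(geo, rel=1e-12)
        assert res.scores.loc["g1", "sd_cp"] == pytest.approx(expected, rel=1e-12)
        assert res.scores.loc["g1", "cv_bk"] == pytest.approx(100 * expected / geo, rel=1e-12)

    def test_constant_gene_first_with_missing_correlation(self):
        cq = make_cq([[19.0, 20.0, 21.0], [20.0, 20.0, 20.0]])
        res = bestkeeper(cq)
        assert res.ranking[0] == "g2"
        # geometric mean via exp(mean(log)) leaves 1-ulp residue
        assert res.scores.loc["g2", "sd_cp"] == pytest.approx(0.0, abs=1e-12)
        assert np.isnan(res.scores.loc["g2", "r_index"])

    def test_identical_genes_correlate_perfectly_with_index(self):
        cq = make_cq([[19.0, 20.0, 21.0], [19.0, 20.0, 21.0]])
        res = bestkeeper(cq)
        assert res.scores["r_index"].tolist() == pytest.approx([1.0, 1.0])


class TestDeltaCt:
    def test_parallel_genes_have_zero_pairwise_sd(self):
        cq = make_cq([[20.0, 21.0, 22.0], [15.0, 16.0, 17.0]])
        res = delta_ct_stability(cq)
        assert (res.scores["mean_sd"] == 0.0).all()

    def test_toy_matches_hand_computed_pairwise_sds(self, toy_cq):
        res = delta_ct_stability(toy_cq)
        vals = toy_cq.cq.to_numpy()
        s12 = np.std(vals[0] - vals[1], ddof=1)
        s13 = np.std(vals[0] - vals[2], ddof=1)
        s23 = np.std(vals[1] - vals[2], ddof=1)
        assert res.scores.loc["g1", "mean_sd"] == pytest.approx((s12 + s13) / 2, rel=1e-12)
        assert res.scores.loc["g2", "mean_sd"] == pytest.approx((s12 + s23) / 2, rel=1e-12)
        assert res.scores.loc["g3", "mean_sd"] == pytest.approx((s13 + s23) / 2, rel=1e-12)


class TestCrossMethodProperties:
    def test_genorm_m_equals_mean_pairwise_dct_sd_at_perfect_efficiency(self, rng):
        # log2 ratios of E=2 relative quantities are Cq differences up to
        # sign and a constant, so the two statistics coincide gene by gene
        for _ in range(5):
            vals = rng.uniform(10, 30, size=(5, 12))
            cq = make_cq(vals)
            m = genorm_m_values(cq_to_rq(cq))
            d = delta_ct_stability(cq).scores["mean_sd"]
            np.testing.assert_allclose(m.to_numpy(), d.to_numpy(), rtol=1e-10)

    def test_additive_cq_offset_invariance(self, rng):
        vals = rng.uniform(15, 30, size=(4, 10))
        cq0, cq1 = make_cq(vals), make_cq(vals + np.array([[4.0], [0], [0], [0]]))
        m0, m1 = genorm_m_values(cq_to_rq(cq0)), genorm_m_values(cq_to_rq(cq1))
        np.testing.assert_allclose(m0, m1, rtol=1e-10)
        d0 = delta_ct_stability(cq0).scores["mean_sd"]
        d1 = delta_ct_stability(cq1).scores["mean_sd"]
        np.testing.assert_allclose(d0, d1, rtol=1e-10)
        r0 = normfinder_stability(cq_to_rq(cq0)).scores["rho"]
        r1 = normfinder_stability(cq_to_rq(cq1)).scores["rho"]
        np.testing.assert_allclose(r0, r1, rtol=1e-10)
        b0 = bestkeeper(cq0).scores["sd_cp"]
        b1 = bestkeeper(cq1).scores["sd_cp"]
        np.testing.assert_allclose(b0, b1, rtol=1e-10)
        # the stability index is the documented exception: CV has the mean
        # in its denominator, so a pure offset changes it
        s0 = stability_index(cq0).scores.loc["g1", "cv"]
        s1 = stability_index(cq1).scores.loc["g1", "cv"]
        assert not np.isclose(s0, s1)


def test_run_all_methods_produces_eight_scopes():
    cq, _ = simulate_study(default_config(seed=6, include_target=False))
    results = run_all_methods(cq)
    assert set(results) == {"RCF", "FCF", "FCC", "FCP", "FAP", "HCY", "HCC", "all"}
    for scope, by_method in results.items():
        assert set(by_method) == {"SI", "geNorm", "NormFinder", "BestKeeper", "dCt"}
        for res in by_method.values():
            assert sorted(res.ranking) == sorted(cq.genes)
        assert by_method["geNorm"].extra["pairwise_variation"].minimal_n >= 2
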