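import numpy as np
import pandas as pd
import pytest
from scipy.stats import beta as beta_dist
from scipy.stats import pearsonr

from pdxscreen import pathways
from pdxscreen.errors import InsufficientDataError, PdxScreenError
from pdxscreen.pathways import (correlate_drug_features, rank_consistency,
                                read_gmt, ssgsea_score, write_gmt)


def brute_force_es(expr_col, genes, members, alpha):
    """Independent cumulative-sum oracle for the ssGSEA score."""
    n = len(genes)
    order = sorted(range(n), key=lambda i: (-expr_col[i], i))
    member_set = set(members)
    total_in = sum((n - pos) ** alpha
                   for pos, i in enumerate(order) if genes[i] in member_set)
    n_out = n - len([g for g in genes if g in member_set])
    es = 0.0
    cum_in = 0.0
    cum_out = 0.0
    for pos, i in enumerate(order):
        if genes[i] in member_set:
            cum_in += (n - pos) ** alpha
        else:
            cum_out += 1.0
        es += cum_in / total_in - cum_out / n_out
    return es


class TestGmt:
    def test_round_trip(self, tmp_path):
        sets = {"S1": ["g1", "g2"], "S2": ["g3", "g2", "g4"]}
        path = tmp_path / "x.gmt"
        write_gmt(sets, path)
        assert read_gmt(path) == sets

    def test_short_row_rejected(self, tmp_path):
        path = tmp_path / "x.gmt"
        path.write_text("S1\tdesc\n")
        with pytest.raises(PdxScreenError, match=":1:"):
            read_gmt(path)

    def test_duplicate_set_rejected(self, tmp_path):
        path = tmp_path / "x.gmt"
        path.write_text("S1\td\tg1\nS1\td\tg2\n")
        with pytest.raises(PdxScreenError, match="duplicate"):
            read_gmt(path)


class TestSsgsea:
    def test_hand_computed_toy_alpha_zero(self):
        """5 genes, set = complement of the bottom gene, alpha = 0.

        With unit weights the running in-set CDF is i/4 for the first four
        positions and the out-of-set CDF jumps to 1 at the last position:
        ES = 1/4 + 2/4 + 3/4 + 4/4 + (1 - 1) = 2.5.
        """
        expr = pd.DataFrame({"s": [50.0, 40.0, 30.0, 20.0, 10.0]},
                            index=[f"g{i}" for i in range(1, 6)])
        scores = ssgsea_score(expr, {"S": ["g1", "g2", "g3", "g4"]},
                              alpha=0.0)
        assert scores.raw.loc["S", "s"] == pytest.approx(2.5, abs=1e-12)

    @pytest.mark.parametrize("alpha", [0.0, 0.25, 1.0])
    def test_matches_brute_force_oracle(self, rng, alpha):
        genes = [f"g{i}" for i in range(50)]
        expr = pd.DataFrame(rng.uniform(0, 100, size=(50, 4)),
                            index=genes, columns=list("abcd"))
        sets = {f"S{k}": list(rng.choice(genes, size=rng.integers(3, 20),
                                         replace=False))
                for k in range(20)}
        scores = ssgsea_score(expr, sets, alpha=alpha)
        for name, members in sets.items():
            for sample in "abcd":
                ref = brute_force_es(expr[sample].to_numpy(), genes,
                                     members, alpha)
                assert scores.raw.loc[name, sample] == pytest.approx(
                    ref, abs=1e-10)

    def test_identical_samples_identical_columns(self, rng):
        col = rng.uniform(0, 10, 30)
        expr = pd.DataFrame({"a": col, "b": col},
                            index=[f"g{i}" for i in range(30)])
        scores = ssgsea_score(expr, {"S": ["g1", "g5", "g9"]})
        assert scores.raw["a"].equals(scores.raw["b"])

    def test_gene_row_permutation_invariant(self, rng):
        genes = [f"g{i}" for i in range(40)]
        expr = pd.DataFrame(rng.uniform(1, 9, size=(40, 3)), index=genes,
                            columns=list("xyz"))
        # distinct values so the tie rule cannot differ between orderings
        sets = {"S": ["g3", "g7", "g11", "g20"]}
        a = ssgsea_score(expr, sets).raw
        b = ssgsea_score(expr.sample(frac=1, random_state=0), sets).raw
        pd.testing.assert_frame_equal(a, b)

    def test_negative_expression_rejected(self):
        expr = pd.DataFrame({"a": [-1.0, 2.0]}, index=["g1", "g2"])
        with pytest.raises(PdxScreenError):
            ssgsea_score(expr, {"S": ["g1"]})

    def test_empty_intersection_dropped_with_warning(self, rng):
        expr = pd.DataFrame(rng.uniform(0, 5, size=(10, 2)),
                            index=[f"g{i}" for i in range(10)],
                            columns=["a", "b"])
        with pytest.warns(UserWarning, match="dropped"):
            scores = ssgsea_score(expr, {"S": ["g1", "g2"],
                                         "GONE": ["zz1", "zz2"]})
        assert list(scores.raw.index) == ["S"]

    def test_all_equal_sample_warns_but_deterministic(self):
        expr = pd.DataFrame({"a": [3.0] * 6, "b": [1, 5, 2, 4, 6, 3]},
                            index=[f"g{i}" for i in range(6)])
        with pytest.warns(UserWarning, match="all-equal"):
            s1 = ssgsea_score(expr, {"S": ["g0", "g2"]})
        with pytest.warns(UserWarning):
            s2 = ssgsea_score(expr, {"S": ["g0", "g2"]})
        pd.testing.assert_frame_equal(s1.raw, s2.raw)

    def test_z_rows_standardized(self, rng):
        expr = pd.DataFrame(rng.uniform(0, 50, size=(60, 8)),
                            index=[f"g{i}" for i in range(60)],
                            columns=[f"s{i}" for i in range(8)])
        sets = {f"S{k}": [f"g{i}" for i in
                          rng.choice(60, size=10, replace=False)]
                for k in range(5)}
        scores = ssgsea_score(expr, sets)
        np.testing.assert_allclose(scores.z.mean(axis=1), 0.0, atol=1e-10)
        np.testing.assert_allclose(scores.z.std(axis=1, ddof=1), 1.0,
                                   rtol=1e-10)
        assert (scores.row_sd > 0).all()


class TestRankConsistency:
    def test_swapped_rows_swap_ranks(self):
        raw = pd.DataFrame({"s1": [5.0, 1.0], "s2": [6.0, 2.0]},
                           index=["hi", "lo"])
        swapped = raw.rename(index={"hi": "lo", "lo": "hi"})
        a = rank_consistency(pathways.PathwayScoreMatrix(raw=raw), "hi")
        b = rank_consistency(pathways.PathwayScoreMatrix(raw=swapped), "hi")
        assert a["rank_of_mean"] == 1 and b["rank_of_mean"] == 2

    def test_constant_set_sd_zero(self):
        raw = pd.DataFrame({"s1": [3.0, 1.0], "s2": [3.0, 2.0]},
                           index=["flat", "other"])
        res = rank_consistency(pathways.PathwayScoreMatrix(raw=raw), "flat")
        assert res["sd_score"] == 0.0

    def test_needs_two_samples(self):
        raw = pd.DataFrame({"s1": [3.0]}, index=["a"])
        with pytest.raises(InsufficientDataError):
            rank_consistency(pathways.PathwayScoreMatrix(raw=raw), "a")

    def test_planted_high_pathway_ranks_top(self, rng):
        """A uniformly boosted module lands in the top decile of set ranks."""
        genes = [f"g{i}" for i in range(400)]
        expr = pd.DataFrame(
            2.0 ** rng.normal(5, 1, size=(400, 10)), index=genes,
            columns=[f"s{i}" for i in range(10)])
        expr.iloc[:20] *= 2.0 ** 4  # module genes high in every sample
        sets = {"PLANTED": genes[:20]}
        for k in range(19):
            sets[f"S{k}"] = list(rng.choice(genes[20:], 20, replace=False))
        scores = ssgsea_score(expr, sets)
        res = rank_consistency(scores, "PLANTED")
        assert res["rank_of_mean"] <= max(1, res["n_sets"] // 10)


class TestCorrelate:
    def test_affine_feature_passes_with_r_one(self, rng):
        auc = pd.Series(rng.uniform(0, 1, 16),
                        index=[f"m{i}" for i in range(16)])
        feats = pd.DataFrame({"lin": 2.0 * auc + 0.1}).T
        res = correlate_drug_features(auc, feats)
        assert res.loc["lin", "pearson_r"] == pytest.approx(1.0)
        assert bool(res.loc["lin", "passes"])

    def test_residualized_feature_fails(self, rng):
        auc = pd.Series(rng.uniform(0, 1, 16),
                        index=[f"m{i}" for i in range(16)])
        noise = rng.normal(size=16)
        y = auc.to_numpy() - auc.mean()
        resid = noise - noise.mean() - (noise @ y) / (y @ y) * y
        res = correlate_drug_features(auc, pd.DataFrame({"orth": resid},
                                                        index=auc.index).T)
        assert res.loc["orth", "pearson_r"] == pytest.approx(0.0, abs=1e-10)
        assert not bool(res.loc["orth", "passes"])

    def test_zero_variance_feature_reported_not_nan_propagated(self, rng):
        auc = pd.Series(rng.uniform(0, 1, 8),
                        index=[f"m{i}" for i in range(8)])
        feats = pd.DataFrame({"flat": np.ones(8)}, index=auc.index).T
        res = correlate_drug_features(auc, feats)
        assert res.loc["flat", "note"] == "undefined"
        assert not bool(res.loc["flat", "passes"])

    def test_p_matches_t_distribution_closed_form(self, rng):
        n = 12
        auc = pd.Series(rng.uniform(0, 1, n),
                        index=[f"m{i}" for i in range(n)])
        feat = rng.normal(size=n)
        res = correlate_drug_features(
            auc, pd.DataFrame({"f": feat}, index=auc.index).T)
        r = res.loc["f", "pearson_r"]
        # closed form: under H0, r^2 ~ Beta(1/2, (n-2)/2)
        p_closed = float(beta_dist.sf(r * r, 0.5, (n - 2) / 2))
        assert res.loc["f", "p"] == pytest.approx(p_closed, rel=1e-9)

    def test_too_few_observations_rejected(self, rng):
        auc = pd.Series([0.1, 0.2], index=["m0", "m1"])
        feats = pd.DataFrame({"f": [1.0, 2.0]}, index=auc.index).T
        with pytest.raises(InsufficientDataError):
            correlate_drug_features(auc, feats)

    def test_log2_mode_matches_manual_transform(self, rng):
        n = 10
        auc = pd.Series(rng.uniform(0, 1, n),
                        index=[f"m{i}" for i in range(n)])
        tpm = pd.DataFrame({"g": rng.lognormal(3, 1, n)}, index=auc.index).T
        res = correlate_drug_features(auc, tpm, log2_transform=True)
        r_manual, _ = pearsonr(np.log2(tpm.loc["g"] + 1), auc)
        assert res.loc["g", "pearson_r"] == pytest.approx(r_manual)

    def test_screen_false_positive_rate_near_expectation(self, rng):
        """No planted pairs: pass count matches the null dual-threshold
        probability P(p < .05 and |r| >= .70) at n = 16."""
        n, n_feats = 16, 800
        auc = pd.Series(rng.uniform(0, 1, n),
                        index=[f"m{i}" for i in range(n)])
        feats = pd.DataFrame(rng.normal(size=(n_feats, n)),
                             columns=auc.index)
        res = correlate_drug_features(auc, feats)
        # |r| >= 0.70 at n=16 is rarer than p < 0.05, so the dual rule's
        # null rate equals P(|r| >= 0.70) = sf of Beta(1/2, 7) at 0.49
        p_null = float(beta_dist.sf(0.70 ** 2, 0.5, (n - 2) / 2))
        got = res["passes"].mean()
        se = np.sqrt(p_null * (1 - p_null) / n_feats)
        assert abs(got - p_null) < 4 * se + 1e-3
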