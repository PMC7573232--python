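import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

import nohelp as nh


class TestPearson:
    def test_self_correlation_is_one(self):
        assert nh.pearson([1, 2, 3], [1, 2, 3]) == pytest.approx(1.0)

    def test_negated_is_minus_one(self):
        x = np.array([1.0, 5.0, 2.0])
        assert nh.pearson(x, -x) == pytest.approx(-1.0)

    def test_matches_two_pass_formula(self):
        x, y = np.array([1.0, 2, 3]), np.array([2.0, 2, 5])
        # independent two-pass computation
        mx, my = x.mean(), y.mean()
        expected = float(
            np.sum((x - mx) * (y - my))
            / np.sqrt(np.sum((x - mx) ** 2) * np.sum((y - my) ** 2))
        )
        assert nh.pearson(x, y) == pytest.approx(expected, abs=1e-12)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            nh.pearson([1, 1, 1], [1, 2, 3])

    def test_short_vectors_rejected(self):
        with pytest.raises(ValueError):
            nh.pearson([1, 2], [3, 4])


class TestComputeCentroids:
    def test_single_replicate_centroid_equals_profile(self, default_signature):
        genes = default_signature.gene_ids[:20]
        rng = np.random.default_rng(1)
        df = pd.DataFrame(
            {"n1": rng.uniform(1, 100, 20), "h1": rng.uniform(1, 100, 20)},
            index=genes,
        )
        meta = nh.SampleMetadata(pd.DataFrame(
            {"sample_id": ["n1", "h1"], "condition": ["NoHelp", "Help"]}
        ))
        cents = nh.compute_centroids(
            nh.ExpressionMatrix(df), meta, default_signature
        )
        np.testing.assert_allclose(cents.centroid_nohelp,
                                   df.loc[cents.gene_ids, "n1"])

    def test_duplicated_replicates_leave_centroid_unchanged(
            self, default_reference, default_signature, default_centroids):
        m, meta, _ = default_reference
        expr = nh.cpm(nh.remove_zero_genes(m))
        dup = nh.ExpressionMatrix(
            pd.concat(
                [expr.data, expr.data.add_suffix("_dup")], axis=1
            )
        )
        meta2 = nh.SampleMetadata(pd.concat(
            [meta.table,
             meta.table.assign(sample_id=meta.table.sample_id + "_dup")],
        ))
        cents2 = nh.compute_centroids(dup, meta2, default_signature)
        np.testing.assert_allclose(cents2.centroid_nohelp,
                                   default_centroids.centroid_nohelp)

    def test_mean_of_three_replicates(self, default_reference,
                                      default_signature, default_centroids):
        m, meta, _ = default_reference
        expr = nh.cpm(nh.remove_zero_genes(m))
        g = default_centroids.gene_ids[0]
        by_hand = expr.data.loc[g, meta.samples_in("NoHelp")].mean()
        assert default_centroids.centroid_nohelp[0] == pytest.approx(by_hand)

    def test_low_overlap_rejected(self, default_signature):
        df = pd.DataFrame(
            {"n1": [1.0, 2.0], "h1": [2.0, 1.0]},
            index=default_signature.gene_ids[:2],
        )
        meta = nh.SampleMetadata(pd.DataFrame(
            {"sample_id": ["n1", "h1"], "condition": ["NoHelp", "Help"]}
        ))
        with pytest.raises(ValueError, match="overlap"):
            nh.compute_centroids(nh.ExpressionMatrix(df), meta,
                                 default_signature)


class TestNoHelpScore:
    def test_profile_at_nohelp_centroid(self, default_centroids):
        profile = pd.Series(default_centroids.centroid_nohelp,
                            index=default_centroids.gene_ids)
        r = nh.no_help_score(profile, default_centroids)
        assert r.r_nohelp == pytest.approx(1.0)
        assert r.no_help_score >= 0

    def test_centroid_swap_negates_score(self, default_centroids, rng):
        profile = pd.Series(
            rng.uniform(0, 100, len(default_centroids)),
            index=default_centroids.gene_ids,
        )
        a = nh.no_help_score(profile, default_centroids)
        b = nh.no_help_score(profile, default_centroids.swapped())
        assert a.no_help_score == pytest.approx(-b.no_help_score, abs=1e-15)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000),
           shift=st.floats(-50, 50, allow_nan=False),
           scale=st.floats(0.01, 100, allow_nan=False))
    def test_shift_scale_invariance_and_range(self, default_centroids, seed,
                                              shift, scale):
        rng = np.random.default_rng(seed)
        profile = pd.Series(
            rng.uniform(0, 100, len(default_centroids)),
            index=default_centroids.gene_ids,
        )
        base = nh.no_help_score(profile, default_centroids)
        moved = nh.no_help_score(profile * scale + shift, default_centroids)
        assert -2 <= base.no_help_score <= 2
        assert moved.no_help_score == pytest.approx(base.no_help_score,
                                                    abs=1e-10)

    def test_mixture_scores_increase_with_weight(self, default_centroids):
        weights = [0.0, 0.25, 0.5, 0.75, 1.0]
        ranks_ok = 0
        n_rep = 50
        for rep in range(n_rep):
            means = []
            for i, w in enumerate(weights):
                q = nh.simulate_query(default_centroids, w, 0.2, 4,
                                      seed=10_000 + rep * 10 + i)
                means.append(
                    nh.score_samples(q, default_centroids).no_help_score.mean()
                )
            rho = stats.spearmanr(weights, means).statistic
            ranks_ok += rho >= 0.95
        assert ranks_ok >= 0.95 * n_rep

    def test_reference_samples_score_with_correct_sign(
            self, default_reference, default_centroids):
        m, meta, _ = default_reference
        expr = nh.cpm(nh.remove_zero_genes(m))
        scores = nh.score_samples(expr, default_centroids)
        by_cond = scores.set_index("sample_id").no_help_score
        nohelp_mean = by_cond[meta.samples_in("NoHelp")].mean()
        help_mean = by_cond[meta.samples_in("Help")].mean()
        assert nohelp_mean > 0
        assert help_mean < 0

    def test_insufficient_overlap_rejected(self, default_centroids):
        profile = pd.Series([1.0, 2.0, 3.0],
                            index=default_centroids.gene_ids[:3])
        with pytest.raises(ValueError, match="overlap"):
            nh.no_help_score(profile, default_centroids)


class TestMapProfile:
    def test_identity_mapping(self):
        profile = pd.Series([1.0, 2.0], index=["g1", "g2"])
        mapping = [nh.GeneMapping("g1", "g1"), nh.GeneMapping("g2", "g2")]
        out = nh.map_profile(profile, mapping)
        pd.testing.assert_series_equal(out, profile)

    def test_partial_mapping_halves_profile(self):
        profile = pd.Series([1.0, 2.0, 3.0, 4.0],
                            index=["g1", "g2", "g3", "g4"])
        mapping = [nh.GeneMapping("g1", "X1"), nh.GeneMapping("g3", "X3")]
        out = nh.map_profile(profile, mapping)
        assert list(out.index) == ["X1", "X3"]
        assert len(out) == 2

    def test_renamed_species_scores_identical(self, default_centroids):
        q = nh.simulate_query(default_centroids, 0.75, 0.1, 2, seed=3)
        direct = nh.score_samples(q, default_centroids)
        renamed, mapping = nh.rename_species(q, "spB:")
        for s in renamed.sample_ids:
            mapped = nh.map_profile(renamed.profile(s), mapping)
            r = nh.no_help_score(mapped, default_centroids, sample_id=s)
            expected = direct.loc[direct.sample_id == s,
                                  "no_help_score"].iloc[0]
            assert r.no_help_score == pytest.approx(expected, abs=0)

    def test_empty_result_rejected(self):
        profile = pd.Series([1.0], index=["g1"])
        with pytest.raises(ValueError):
            nh.map_profile(profile, [nh.GeneMapping("other", "X")])


class TestTwoGroupComparison:
    def test_identical_groups(self):
        r = nh.compare_two_groups([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert r.statistic == pytest.approx(0.0)
        assert r.p_value == pytest.approx(1.0)

    def test_matches_closed_form_and_permutation_oracle(self):
        a, b = np.array([1.0, 2, 3]), np.array([4.0, 5, 6])
        r = nh.compare_two_groups(a, b)
        # closed form: pooled-variance t
        sp2 = (a.var(ddof=1) * 2 + b.var(ddof=1) * 2) / 4
        t_expected = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / 3 + 1 / 3))
        p_expected = 2 * stats.t.sf(abs(t_expected), 4)
        assert r.statistic == pytest.approx(t_expected, abs=1e-10)
        assert r.p_value == pytest.approx(p_expected, abs=1e-10)
        # permutation oracle on |t|: with 3 vs 3 there are C(6,3) = 20
        # splits and only the two extreme ones reach |t_obs|, so the exact
        # permutation p is 2/20; the Monte-Carlo estimate must agree
        rng = np.random.default_rng(0)
        pooled = np.concatenate([a, b])
        n_res = 100_000
        count = 0
        for _ in range(n_res):
            perm = rng.permutation(pooled)
            pa, pb = perm[:3], perm[3:]
            s2 = (pa.var(ddof=1) * 2 + pb.var(ddof=1) * 2) / 4
            tt = (pa.mean() - pb.mean()) / np.sqrt(s2 * (2 / 3))
            count += abs(tt) >= abs(t_expected) - 1e-12
        p_perm = count / n_res
        se = np.sqrt(0.1 * 0.9 / n_res)
        assert abs(p_perm - 2 / 20) < 4 * se
        # both routes call the difference significant at the 10% level
        assert r.p_value < 0.1 and p_perm <= 0.1 + 4 * se

    def test_scale_invariance(self):
        a, b = [1.0, 2, 4], [3.0, 6, 7]
        r1 = nh.compare_two_groups(a, b)
        r2 = nh.compare_two_groups(np.array(a) * 3.7, np.array(b) * 3.7)
        assert r1.statistic == pytest.approx(r2.statistic, abs=1e-12)
        assert r1.p_value == pytest.approx(r2.p_value, abs=1e-12)

    def test_degenerate_unequal_means_rejected(self):
        with pytest.raises(ValueError):
            nh.compare_two_groups([1.0, 1.0], [2.0, 2.0])


def rm_anova_oracle(x):
    """Independent sums-of-squares decomposition by explicit loops."""
    n, k = x.shape
    grand = x.mean()
    ss_cond = sum(n * (x[:, j].mean() - grand) ** 2 for j in range(k))
    ss_subj = sum(k * (x[i, :].mean() - grand) ** 2 for i in range(n))
    ss_tot = sum((x[i, j] - grand) ** 2 for i in range(n) for j in range(k))
    ss_err = ss_tot - ss_cond - ss_subj
    return (ss_cond / (k - 1)) / (ss_err / ((k - 1) * (n - 1)))


class TestMatchedComparison:
    def test_no_condition_effect_gives_zero_f(self):
        table = pd.DataFrame(
            {"c1": [1.0, 2, 3], "c2": [1.0, 2, 3], "c3": [1.0, 2, 3]},
        )
        # identical conditions per subject but subject variance present:
        # zero SS_cond and zero SS_err -> degenerate branch
        r = nh.compare_matched_groups(table)
        assert r.statistic == pytest.approx(0.0)
        assert r.p_value == pytest.approx(1.0)

    def test_f_matches_ss_decomposition_oracle(self, rng):
        x = rng.normal(10, 2, (4, 3))
        x[:, 1] += 1.5
        table = pd.DataFrame(x, columns=["lo", "mid", "hi"])
        r = nh.compare_matched_groups(table)
        assert r.statistic == pytest.approx(rm_anova_oracle(x), abs=1e-10)

    def test_matches_pingouin(self, rng):
        pingouin = pytest.importorskip("pingouin")
        x = rng.normal(0, 1, (6, 3))
        x[:, 2] += 0.8
        table = pd.DataFrame(x, columns=["a", "b", "c"])
        long = table.reset_index().melt(
            id_vars="index", var_name="cond", value_name="y"
        )
        res = pingouin.rm_anova(data=long, dv="y", within="cond",
                                subject="index")
        r = nh.compare_matched_groups(table)
        assert r.statistic == pytest.approx(float(res["F"].iloc[0]), abs=1e-8)
        assert r.p_value == pytest.approx(float(res["p_unc"].iloc[0]),
                                          abs=1e-8)

    def test_tukey_equal_pair_has_high_p(self, rng):
        noise = rng.normal(0, 1, (5, 3))
        noise[:, 2] += 5
        # make conditions a and b identical per subject
        noise[:, 1] = noise[:, 0]
        table = pd.DataFrame(noise, columns=["a", "b", "c"])
        r = nh.compare_matched_groups(table)
        pair = r.pairwise.set_index(["group_1", "group_2"])
        assert pair.loc[("a", "b"), "p_value"] >= 0.99

    def test_tukey_p_matches_monte_carlo_studentized_range(self, rng):
        # MC oracle: distribution of the range of k normal means over
        # sqrt(MS_err/n) with df error degrees of freedom
        k, df_err, n_subj = 3, 8, 5
        x = rng.normal(0, 1.0, (n_subj, k))
        x[:, 2] += 1.2
        table = pd.DataFrame(x, columns=["a", "b", "c"])
        r = nh.compare_matched_groups(table)
        n_mc = 200_000
        z = rng.normal(size=(n_mc, k))
        s = np.sqrt(rng.chisquare(df_err, n_mc) / df_err)
        q_null = (z.max(axis=1) - z.min(axis=1)) / s
        for row in r.pairwise.itertuples():
            p_mc = float((q_null >= row.q_statistic).mean())
            se = np.sqrt(p_mc * (1 - p_mc) / n_mc) + 1e-4
            assert abs(row.p_value - p_mc) <= 3 * se + 0.003

    def test_incomplete_table_rejected(self):
        table = pd.DataFrame({"a": [1.0, 2], "b": [3.0, np.nan]})
        with pytest.raises(ValueError, match="incomplete"):
            nh.compare_matched_groups(table)
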