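"""Perturbation statistics: log2fc matrices, Wilcoxon tests, FDR, hit
calling, correlation and clustering analyses."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from perturbtrace.screen import (
    ab_score_matrix,
    call_hits,
    cluster_hits,
    contact_test,
    correlate_effect_matrices,
    cross_feature_correlation,
    distance_test,
    fdr_correct,
    log2fc_distance_matrix,
    phenotype_table,
    screen_design_summary,
    short_long_range_split,
    z_score,
)
from perturbtrace.synthetic import EffectSpec, make_trace_stack

from conftest import random_trace


def stack(rng, n=30, n_tad=6, scale=400.0):
    return np.stack([random_trace(rng, n_tad, scale) for _ in range(n)])


def test_screen_design_summary_combinations():
    s = screen_design_summary()
    assert s["n_sgrnas"] == 420
    assert s["n_imaging_targets"] == 30
    assert s["n_combinations"] == 12_600


class TestLog2fcMatrix:
    def test_identity_groups_give_zero(self, rng):
        grp = stack(rng)
        mat = log2fc_distance_matrix(grp, grp, min_traces=10)
        off = mat[np.triu_indices(6, 1)]
        assert np.allclose(off, 0.0)

    def test_uniform_doubling_gives_one(self, rng):
        ctrl = stack(rng)
        mat = log2fc_distance_matrix(ctrl * 2.0, ctrl, min_traces=10)
        off = mat[np.triu_indices(6, 1)]
        assert np.allclose(off, 1.0)

    def test_hand_computed_medians_on_toy_groups(self):
        """4-TAD groups with hand-listed coordinates: entries equal
        log2(median perturb distance / median control distance)."""
        ctrl = np.stack([
            np.array([[0, 0, 0], [1, 0, 0], [3, 0, 0], [6, 0, 0]], float),
            np.array([[0, 0, 0], [2, 0, 0], [4, 0, 0], [8, 0, 0]], float) * 1.5,
            np.array([[0, 0, 0], [1.2, 0, 0], [3.1, 0, 0], [7, 0, 0]], float),
        ] * 4)
        pert = ctrl * 3.0
        mat = log2fc_distance_matrix(pert, ctrl, min_traces=3, min_pair_traces=3)
        off = mat[np.triu_indices(4, 1)]
        assert np.allclose(off, np.log2(3.0))

    def test_sparse_pairs_become_missing(self, rng):
        grp = stack(rng, n=25)
        grp[:21, 2] = np.nan          # pair (2, *) observed in only 4 traces
        mat = log2fc_distance_matrix(grp, stack(rng, n=25), min_traces=10)
        assert np.isnan(mat[2, 4])


class TestDistanceTest:
    def test_identical_groups_nonsignificant(self, rng):
        grp = batchify(stack(rng, n=25))
        res = distance_test(grp, grp)
        # identical per-pair medians: zero effect, p in the non-significant region
        assert res.log2fc == 0.0
        assert res.p > 0.9

    def test_uniform_scaling_all_351_pairs_unanimous(self, rng):
        ctrl = np.stack([random_trace(rng, 27) for _ in range(40)])
        pert = ctrl * 1.5
        from perturbtrace.traces import batch_pair_distances

        res = distance_test(batch_pair_distances(pert), batch_pair_distances(ctrl))
        assert res.n == 351
        assert res.log2fc == pytest.approx(np.log2(1.5))
        # unanimous signs over n=351: signed-rank p far below 1e-10
        assert res.p < 1e-10

    def test_alternating_differences_nonsignificant(self):
        base = np.full((10, 20), 100.0)
        pert = base.copy()
        pert[:, ::2] += 5.0
        pert[:, 1::2] -= 5.0
        res = distance_test(pert, base, min_pair_traces=5)
        assert res.p > 0.5

    def test_insufficient_pairs_flagged(self, rng):
        grp = stack(rng, n=25, n_tad=3)   # only 3 pairs
        res = distance_test(batchify(grp), batchify(stack(rng, n=25, n_tad=3)))
        assert np.isnan(res.p)
        assert res.insufficient_data


def batchify(traces):
    from perturbtrace.traces import batch_pair_distances

    return batch_pair_distances(traces)


class TestContactTest:
    def test_identical_distributions(self, rng):
        vals = rng.uniform(0, 1, 200)
        res = contact_test(vals, vals)
        assert res.log2fc == 0.0
        assert res.p > 0.9

    def test_exact_small_sample_permutation_value(self):
        """Disjoint-support shift at n1=n2=5: the rank-sum p equals the
        exact permutation value 2/binom(10,5) = 1/126."""
        a = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        b = a + 10.0
        res = contact_test(b, a, min_traces=5)
        assert res.p == pytest.approx(2 / 252)

    def test_log2fc_of_means(self):
        ctrl = np.full(50, 0.2)
        pert = np.full(50, 0.4)
        res = contact_test(pert, ctrl, min_traces=10)
        assert res.log2fc == pytest.approx(1.0, abs=0.01)

    def test_small_group_flagged(self, rng):
        res = contact_test(rng.uniform(size=5), rng.uniform(size=100), min_traces=20)
        assert res.insufficient_data


class TestFdrCorrect:
    def test_hand_computed_bh_step_up(self):
        got = fdr_correct([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(got, [0.04, 0.04, 0.04, 0.04])

    def test_fixed_points(self):
        assert np.allclose(fdr_correct([0.3, 0.3, 0.3]), 0.3)
        assert fdr_correct([0.123])[0] == pytest.approx(0.123)

    def test_missing_passthrough_and_dominance(self, rng):
        p = rng.uniform(size=20)
        p[[3, 7]] = np.nan
        q = fdr_correct(p)
        assert np.isnan(q[[3, 7]]).all()
        ok = ~np.isnan(p)
        assert (q[ok] >= p[ok] - 1e-12).all()

    def test_monotone_after_sorting_by_p(self, rng):
        p = rng.uniform(size=50)
        q = fdr_correct(p)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            fdr_correct([0.5, 1.5])


class TestAbScoreMatrix:
    def test_constant_and_mean(self, profile27):
        from perturbtrace.traces import CompartmentProfile

        prof = CompartmentProfile(("A", "B"), np.array([1.0, -1.0]), np.array([1, 2]))
        m = ab_score_matrix(prof)
        assert m[0, 1] == 0.0
        assert m[0, 0] == 1.0

    def test_matches_double_loop(self, profile27):
        m = ab_score_matrix(profile27)
        s = profile27.scores
        for i in range(profile27.n_tad):
            for j in range(profile27.n_tad):
                assert m[i, j] == pytest.approx((s[i] + s[j]) / 2)


class TestCorrelateEffectMatrices:
    def test_affine_invariance_and_sign(self, rng):
        m1 = rng.normal(size=(27, 27))
        m1 = (m1 + m1.T) / 2
        res = correlate_effect_matrices(m1, 2 * m1 + 3)
        assert res.r == pytest.approx(1.0)
        assert correlate_effect_matrices(m1, -m1).r == pytest.approx(-1.0)

    def test_chr22_shape_gives_351_points(self, rng):
        m1 = rng.normal(size=(27, 27))
        res = correlate_effect_matrices(m1, rng.normal(size=(27, 27)))
        assert res.n_points == 351
        assert res.ci_low <= res.r <= res.ci_high

    def test_textbook_pearson_by_independent_loop(self, rng):
        m1 = rng.normal(size=(10, 10))
        m2 = 0.6 * m1 + rng.normal(size=(10, 10))
        res = correlate_effect_matrices(m1, m2)
        xs, ys = [], []
        for i in range(10):
            for j in range(i + 1, 10):
                xs.append(m1[i, j])
                ys.append(m2[i, j])
        n = len(xs)
        mx, my = sum(xs) / n, sum(ys) / n
        num = sum((x - mx) * (y - my) for x, y in zip(xs, ys))
        den = (sum((x - mx) ** 2 for x in xs) * sum((y - my) ** 2 for y in ys)) ** 0.5
        assert res.r == pytest.approx(num / den, abs=1e-12)
        t_ref = stats.pearsonr(xs, ys)
        assert res.p == pytest.approx(t_ref.pvalue, rel=1e-6)

    def test_insufficient_points_flagged(self, rng):
        m = rng.normal(size=(4, 4))   # 6 pairs < 10
        res = correlate_effect_matrices(m, m)
        assert np.isnan(res.p)


class TestShortLongRangeSplit:
    def test_uniform_matrix(self, profile27):
        mat = np.full((27, 27), 0.3)
        out = short_long_range_split(mat, profile27)
        assert out["short_range"] == pytest.approx(0.3)
        assert out["long_range"] == pytest.approx(0.3)

    def test_pair_classification_by_enumerated_separations(self):
        from perturbtrace.traces import CompartmentProfile

        prof = CompartmentProfile(tuple("AB" * 5), np.tile([1.0, -1.0], 5),
                                  (np.arange(10) + 1) * 1_000_000)
        mat = np.zeros((10, 10))
        i, j = np.triu_indices(10, 1)
        short_mask = (j - i) < 3          # 1 Mb spacing: separations 1-2 Mb are short
        mat[i[short_mask], j[short_mask]] = 1.0
        mat[j[short_mask], i[short_mask]] = 1.0
        out = short_long_range_split(mat, prof, cutoff_bp=3_000_000)
        assert out["short_range"] == pytest.approx(1.0)
        assert out["long_range"] == pytest.approx(0.0)

    def test_zero_cutoff_leaves_short_class_empty(self, profile27, rng):
        mat = rng.normal(size=(27, 27))
        out = short_long_range_split(mat, profile27, cutoff_bp=0)
        assert np.isnan(out["short_range"])
        assert np.isfinite(out["long_range"])


class TestClusterHits:
    def test_identical_pair_merges_first(self, rng):
        base = rng.normal(size=(8, 8))
        base = (base + base.T) / 2
        res = cluster_hits({"sgA": base, "sgB": base.copy(), "sgC": -base})
        link = res["linkage"]
        first = sorted(res["sgrnas"][int(i)] for i in link[0, :2])
        assert first == ["sgA", "sgB"]
        assert np.allclose(np.diag(res["corr"]), 1.0)
        assert res["newick"].endswith(";")

    def test_planted_three_cluster_recovery(self, rng):
        groups = {}
        centers = [rng.normal(size=(12, 12)) for _ in range(3)]
        for g, c in enumerate(centers):
            for k in range(3):
                m = c + rng.normal(scale=0.2, size=(12, 12))
                groups[f"sg{g}_{k}"] = (m + m.T) / 2
        res = cluster_hits(groups)
        from scipy.cluster.hierarchy import fcluster

        labels = fcluster(res["linkage"], t=3, criterion="maxclust")
        planted = [name.split("_")[0] for name in res["sgrnas"]]
        # same planted group <=> same cluster label
        for a in range(len(planted)):
            for b in range(a + 1, len(planted)):
                assert (planted[a] == planted[b]) == (labels[a] == labels[b])

    def test_constant_matrix_excluded_with_warning(self, rng):
        base = rng.normal(size=(6, 6))
        mats = {"sgA": base, "sgB": base * 0.5, "sgC": -base, "sgflat": np.zeros((6, 6))}
        with pytest.warns(UserWarning):
            res = cluster_hits(mats)
        assert "sgflat" not in res["sgrnas"]


class TestCrossFeatureCorrelation:
    def test_duplicated_feature_perfectly_correlated(self, rng):
        df = pd.DataFrame({"a": rng.normal(size=18)})
        df["b"] = df["a"]
        df["c"] = rng.normal(size=18)
        out = cross_feature_correlation(df)
        row = out[(out.feature_a == "a") & (out.feature_b == "b")].iloc[0]
        assert row.r == pytest.approx(1.0)

    def test_null_features_rarely_significant(self, rng):
        df = pd.DataFrame(rng.normal(size=(18, 6)), columns=list("abcdef"))
        out = cross_feature_correlation(df)
        assert (out.fdr < 0.1).mean() <= 0.15

    def test_coupled_features_positive_sign(self, rng):
        compaction = rng.normal(size=30)
        sphericity = 0.8 * compaction + rng.normal(scale=0.3, size=30)
        df = pd.DataFrame({"overall_distance": -compaction, "sphericity": sphericity})
        df["freq_AA"] = compaction + rng.normal(scale=0.3, size=30)
        out = cross_feature_correlation(df)
        pair = {"freq_AA", "sphericity"}
        row = out[out[["feature_a", "feature_b"]].apply(set, axis=1) == pair].iloc[0]
        assert row.r > 0.5


class TestCallHitsAndRecovery:
    def test_threshold_zero_gives_empty_table(self, rng):
        table = pd.DataFrame({
            "sgrna": ["a", "b"], "phenotype": ["x", "x"],
            "log2fc": [1.0, -1.0], "p": [1e-5, 1e-5], "fdr": [1e-4, 1e-4],
            "is_control": [False, False],
        })
        assert len(call_hits(table, fdr_threshold=0.0)) == 0

    def test_controls_never_listed(self):
        table = pd.DataFrame({
            "sgrna": ["sgNT_1", "sgX"], "phenotype": ["x", "x"],
            "log2fc": [1.0, 1.0], "p": [1e-6, 1e-6], "fdr": [1e-5, 1e-5],
            "is_control": [True, False],
        })
        hits = call_hits(table)
        assert list(hits["sgrna"]) == ["sgX"]

    def test_injected_compactors_recovered_among_nulls(self, rng, profile27):
        """Parameter recovery: 3 planted compactors (20% distance change,
        well above the null noise floor at this group size) among 50 nulls
        are the only hits called on the overall-distance phenotype."""
        traces = {}
        for k in range(50):
            eff = EffectSpec(scale_global=0.8) if k < 3 else EffectSpec()
            traces[f"sg{k:02d}"] = make_trace_stack(eff, 250, profile27, rng)
        for c in range(4):
            traces[f"sgNT_{c}"] = make_trace_stack(EffectSpec(), 250, profile27, rng)
        table = phenotype_table(traces, [f"sgNT_{c}" for c in range(4)], profile27)
        hits = call_hits(table)
        overall = hits[hits.phenotype == "overall_distance"]
        assert set(overall["sgrna"]) == {"sg00", "sg01", "sg02"}
        assert (overall["log2fc"] < 0).all()


def test_z_score_definition(rng):
    ctrl = rng.normal(10, 2, 500)
    pert = rng.normal(12, 2, 100)
    z = z_score(pert, ctrl)
    expected = (pert.mean() - ctrl.mean()) / ctrl.std(ddof=1)
    assert z == pytest.approx(expected)
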