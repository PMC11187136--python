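"""Diversity summaries and distance-based permutation tests."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix
import skbio.stats.distance as sksd

from matneo.diversity import (
    alpha_diversity,
    bray_curtis,
    kruskal_trend,
    mean_split,
    mrpp,
    pcoa_coords,
    permanova,
    permdisp,
    tsne_embed,
)

from conftest import make_count_table


def random_dm(rng, n, dim=3):
    pts = rng.random((n, dim))
    return DistanceMatrix(squareform(pdist(pts)), ids=[f"s{i}" for i in range(n)])


def permanova_f_oracle(d, labels):
    """Pseudo-F via the direct within-group sum-of-squares identity."""
    d = np.asarray(d, dtype=float)
    n = len(labels)
    labels = np.asarray(labels)
    ss_total = (d[np.triu_indices(n, 1)] ** 2).sum() / n
    ss_within = 0.0
    levels, counts = np.unique(labels, return_counts=True)
    for lv, ng in zip(levels, counts):
        idx = np.flatnonzero(labels == lv)
        sub = d[np.ix_(idx, idx)]
        ss_within += (sub[np.triu_indices(ng, 1)] ** 2).sum() / ng
    df_between = len(levels) - 1
    df_within = n - len(levels)
    return ((ss_total - ss_within) / df_between) / (ss_within / df_within)


class TestAlphaDiversity:
    def test_uniform_four_taxa(self):
        t = make_count_table([[25], [25], [25], [25]])
        out = alpha_diversity(t)
        assert out["shannon"].iloc[0] == pytest.approx(np.log(4))
        assert out["evenness"].iloc[0] == pytest.approx(1.0)
        assert out["observed"].iloc[0] == 4

    def test_single_taxon(self):
        t = make_count_table([[100], [0]])
        out = alpha_diversity(t)
        assert out["shannon"].iloc[0] == 0.0
        assert out["observed"].iloc[0] == 1
        assert np.isnan(out["evenness"].iloc[0])

    def test_two_taxa_formula(self):
        t = make_count_table([[10], [30]])
        expected = -(0.25 * np.log(0.25) + 0.75 * np.log(0.75))
        assert alpha_diversity(t)["shannon"].iloc[0] == pytest.approx(expected)

    def test_entropy_bounded_by_richness(self):
        rng = np.random.default_rng(0)
        t = make_count_table(rng.integers(0, 50, size=(20, 10)) + 0)
        out = alpha_diversity(t)
        ok = out["observed"] >= 1
        assert (out.loc[ok, "shannon"] <= np.log(out.loc[ok, "observed"]) + 1e-12).all()


class TestBrayCurtis:
    def test_hand_values(self):
        t = make_count_table(np.array([[2, 1, 2, 0], [2, 3, 2, 5]]))
        dm = bray_curtis(t)
        assert dm["sample_0", "sample_1"] == pytest.approx(2 / 8)
        assert dm["sample_0", "sample_2"] == 0.0
        assert dm["sample_0", "sample_3"] == pytest.approx((2 + 3) / 9)

    def test_disjoint_supports(self):
        t = make_count_table([[5, 0], [0, 7]])
        assert bray_curtis(t)["sample_0", "sample_1"] == 1.0

    def test_range_and_symmetry(self):
        rng = np.random.default_rng(1)
        t = make_count_table(rng.integers(0, 100, size=(15, 8)) + 1)
        d = bray_curtis(t).data
        assert (d >= 0).all() and (d <= 1).all()
        assert np.allclose(d, d.T)


class TestTsne:
    def test_deterministic_and_shapes(self):
        rng = np.random.default_rng(2)
        dm = random_dm(rng, 30)
        a = tsne_embed(dm, seed=5, perplexity=5)
        b = tsne_embed(dm, seed=5, perplexity=5)
        pd.testing.assert_frame_equal(a, b)
        assert a.shape == (30, 2)

    def test_block_structure_preserved(self):
        # two tight, well-separated blocks of points
        n = 30
        rng = np.random.default_rng(7)
        pts = np.vstack([rng.normal(0, 0.3, (15, 3)), rng.normal(10, 0.3, (15, 3))])
        dm = DistanceMatrix(squareform(pdist(pts)), ids=[str(i) for i in range(n)])
        emb = tsne_embed(dm, seed=0, perplexity=5).to_numpy()
        within, between = [], []
        for i, j in itertools.combinations(range(n), 2):
            dist = np.linalg.norm(emb[i] - emb[j])
            (within if (i < 15) == (j < 15) else between).append(dist)
        thresh = np.median(between)
        assert np.mean(np.array(within) < thresh) >= 0.95

    def test_too_few_samples(self):
        rng = np.random.default_rng(3)
        with pytest.raises(ValueError):
            tsne_embed(random_dm(rng, 4), seed=0, perplexity=30)


class TestMeanSplit:
    def test_example(self):
        out = mean_split([1, 2, 3, 4])
        assert list(out) == ["low", "low", "high", "high"]

    def test_symmetric_values(self):
        out = mean_split([-2, -1, 1, 2])
        assert (out == "high").sum() == 2

    def test_constant_warns_all_low(self):
        with pytest.warns(UserWarning):
            out = mean_split([3.0, 3.0, 3.0])
        assert (out == "low").all()


class TestPermanova:
    def test_statistic_matches_skbio(self):
        rng = np.random.default_rng(4)
        dm = random_dm(rng, 24)
        labels = pd.Series(["a"] * 12 + ["b"] * 12, index=dm.ids)
        res = permanova(dm, labels, n_perm=99, seed=0)
        ref = sksd.permanova(dm, labels.to_numpy(), permutations=99)
        assert res.statistic == pytest.approx(ref["test statistic"])

    def test_exact_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(5):
            dm = random_dm(rng, 6)
            labels = pd.Series(list("aaabbb"), index=dm.ids)
            res = permanova(dm, labels, n_perm="exact")
            f_all = []
            for pos in itertools.combinations(range(6), 3):
                lab = np.array(["b"] * 6, dtype=object)
                lab[list(pos)] = "a"
                f_all.append(permanova_f_oracle(dm.data, lab))
            f_obs = permanova_f_oracle(dm.data, np.array(list("aaabbb")))
            p_oracle = np.mean(np.array(f_all) >= f_obs - 1e-12)
            assert res.statistic == pytest.approx(f_obs)
            assert res.p_value == pytest.approx(p_oracle)

    def test_margin_equals_overall_for_single_term(self):
        rng = np.random.default_rng(6)
        dm = random_dm(rng, 20)
        labels = pd.Series(rng.choice(["x", "y"], 20), index=dm.ids)
        overall = permanova(dm, labels, n_perm=199, seed=1, by="overall")
        margin = permanova(dm, labels, n_perm=199, seed=1, by="margin")
        assert margin.statistic == pytest.approx(overall.statistic)
        assert margin.p_value == overall.p_value

    def test_null_calibration(self):
        rng = np.random.default_rng(7)
        rejections = 0
        n_sim = 200
        for s in range(n_sim):
            dm = random_dm(rng, 16)
            labels = pd.Series(rng.permutation(["a"] * 8 + ["b"] * 8), index=dm.ids)
            res = permanova(dm, labels, n_perm=99, seed=s)
            rejections += res.p_value <= 0.05
        rate = rejections / n_sim
        se = np.sqrt(0.05 * 0.95 / n_sim)
        assert rate < 0.05 + 4 * se

    def test_maximal_separation(self):
        pts = np.vstack([np.zeros((8, 2)), np.full((8, 2), 50.0)])
        pts += np.random.default_rng(8).normal(0, 1e-3, pts.shape)
        dm = DistanceMatrix(squareform(pdist(pts)), ids=[str(i) for i in range(16)])
        labels = pd.Series(["a"] * 8 + ["b"] * 8, index=dm.ids)
        res = permanova(dm, labels, n_perm=999, seed=0)
        assert res.p_value <= 2 / (999 + 1)

    def test_p_never_zero(self):
        rng = np.random.default_rng(9)
        dm = random_dm(rng, 12)
        labels = pd.Series(["a"] * 6 + ["b"] * 6, index=dm.ids)
        res = permanova(dm, labels, n_perm=49, seed=0)
        assert res.p_value >= 1 / 50

    def test_constant_term_rejected(self):
        rng = np.random.default_rng(10)
        dm = random_dm(rng, 10)
        with pytest.raises(ValueError):
            permanova(dm, pd.Series(["a"] * 10, index=dm.ids))

    def test_two_term_margin(self):
        # planted effect in term A only; B is noise
        rng = np.random.default_rng(11)
        a = np.repeat(["g1", "g2"], 15)
        pts = rng.normal(size=(30, 3))
        pts[a == "g2"] += 2.0
        b = rng.choice(["u", "v"], 30)
        dm = DistanceMatrix(squareform(pdist(pts)), ids=[str(i) for i in range(30)])
        design = pd.DataFrame({"A": a, "B": b}, index=dm.ids)
        res = permanova(dm, design, n_perm=199, seed=2, by="margin")
        assert res.table.loc["A", "p_value"] <= 0.05
        assert res.table.loc["B", "p_value"] > 0.05


class TestPermdisp:
    def test_identical_groups_f_zero(self):
        pts = np.vstack([np.eye(4), np.eye(4)])
        dm = DistanceMatrix(squareform(pdist(pts)), ids=[str(i) for i in range(8)])
        labels = ["a"] * 4 + ["b"] * 4
        res = permdisp(dm, labels, n_perm=49, seed=0)
        assert res.statistic == pytest.approx(0.0, abs=1e-9)

    def test_detects_scaled_dispersion(self):
        rng = np.random.default_rng(12)
        pts = np.vstack([rng.normal(size=(20, 3)), 3.0 * rng.normal(size=(20, 3))])
        dm = DistanceMatrix(squareform(pdist(pts)), ids=[str(i) for i in range(40)])
        labels = ["a"] * 20 + ["b"] * 20
        res = permdisp(dm, labels, n_perm=199, seed=0)
        assert res.p_value <= 0.05

    def test_null_calibration(self):
        rng = np.random.default_rng(13)
        rejections = 0
        n_sim = 100
        for s in range(n_sim):
            pts = rng.normal(size=(20, 3))
            dm = DistanceMatrix(squareform(pdist(pts)), ids=[str(i) for i in range(20)])
            labels = rng.permutation(["a"] * 10 + ["b"] * 10)
            rejections += permdisp(dm, labels, n_perm=99, seed=s).p_value <= 0.05
        assert rejections / n_sim < 0.05 + 4 * np.sqrt(0.05 * 0.95 / n_sim)

    def test_singleton_group_rejected(self):
        rng = np.random.default_rng(14)
        dm = random_dm(rng, 5)
        with pytest.raises(ValueError):
            permdisp(dm, ["a", "a", "a", "a", "b"])


class TestMrpp:
    def test_null_a_centered_at_zero(self):
        rng = np.random.default_rng(15)
        a_vals = []
        for s in range(50):
            dm = random_dm(rng, 16)
            labels = rng.permutation(["a"] * 8 + ["b"] * 8)
            a_vals.append(mrpp(dm, labels, n_perm=99, seed=s).extra["A"])
        assert abs(np.mean(a_vals)) < 0.02

    def test_separated_clusters(self):
        pts = np.vstack([np.random.default_rng(16).normal(0, 0.1, (10, 2)),
                         np.random.default_rng(17).normal(10, 0.1, (10, 2))])
        dm = DistanceMatrix(squareform(pdist(pts)), ids=[str(i) for i in range(20)])
        res = mrpp(dm, ["a"] * 10 + ["b"] * 10, n_perm=199, seed=0)
        assert res.extra["A"] > 0
        # minimal up to chance group-preserving permutations
        assert res.p_value <= 2 / 200

    def test_delta_is_weighted_within_mean(self):
        rng = np.random.default_rng(18)
        dm = random_dm(rng, 12)
        labels = np.array(["a"] * 6 + ["b"] * 6)
        res = mrpp(dm, labels, n_perm=9, seed=0)
        d = dm.data
        expected = 0.0
        for lv in ("a", "b"):
            idx = np.flatnonzero(labels == lv)
            sub = d[np.ix_(idx, idx)]
            expected += (len(idx) / 12) * sub[np.triu_indices(len(idx), 1)].mean()
        assert res.statistic == pytest.approx(expected)


class TestKruskal:
    def test_shifted_group_detected(self):
        rng = np.random.default_rng(19)
        vals = np.r_[rng.normal(0, 1, 30), rng.normal(2, 1, 30)]
        groups = ["d0"] * 30 + ["d1"] * 30
        assert kruskal_trend(vals, groups).p_value < 0.01

    def test_all_tied(self):
        res = kruskal_trend([1.0] * 10, ["a"] * 5 + ["b"] * 5)
        assert res.p_value == 1.0

    def test_two_groups_matches_scipy_mwu_decision(self):
        rng = np.random.default_rng(20)
        for _ in range(5):
            x = rng.normal(0, 1, 25)
            y = rng.normal(0.8, 1, 25)
            kw = kruskal_trend(np.r_[x, y], ["a"] * 25 + ["b"] * 25).p_value
            mwu = stats.mannwhitneyu(x, y, alternative="two-sided").pvalue
            assert (kw <= 0.05) == (mwu <= 0.05)


class TestPcoa:
    def test_distances_recovered_for_euclidean_input(self):
        rng = np.random.default_rng(21)
        pts = rng.normal(size=(10, 4))
        dm = DistanceMatrix(squareform(pdist(pts)), ids=[str(i) for i in range(10)])
        coords, eigvals = pcoa_coords(dm)
        rec = squareform(pdist(coords))
        assert np.allclose(rec, dm.data, atol=1e-8)
        assert (eigvals > 0).all()
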