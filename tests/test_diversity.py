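import itertools
import math

import numpy as np
import pandas as pd
import pytest

import soilroot as sr
from soilroot.diversity import significance_stars


class TestChao1:
    def test_no_singletons_equals_observed(self):
        counts = [3] * 10
        assert sr.chao1(counts) == 10

    def test_hand_arithmetic(self):
        # S_obs=10, F1=4, F2=2 -> 10 + 4*3 / (2*3) = 12
        counts = [1, 1, 1, 1, 2, 2, 3, 3, 3, 5]
        assert sr.chao1(counts) == pytest.approx(12.0)

    def test_not_below_observed_richness(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            c = rng.integers(0, 5, size=30)
            if (c > 0).sum() == 0:
                continue
            assert sr.chao1(c) >= (c > 0).sum()

    def test_empty_sample_errors(self):
        with pytest.raises(sr.ValidationError):
            sr.chao1([0, 0, 0])


class TestShannon:
    def test_uniform_and_single(self):
        assert sr.shannon([5, 5, 5, 5]) == pytest.approx(math.log(4))
        assert sr.shannon([7, 0, 0]) == 0.0

    def test_bounded_by_log_richness(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            c = rng.integers(0, 40, size=25)
            if c.sum() == 0:
                continue
            assert sr.shannon(c) <= math.log((c > 0).sum()) + 1e-12


class TestAlphaCompare:
    def test_separated_groups_min_enumeration_p(self):
        # {1,2,3} vs {10,11,12}: the most extreme of the 20 rank assignments,
        # two-sided exact p = 2/20 = 0.1
        vals = pd.Series([1, 2, 3, 10, 11, 12], index=list("abcdef"), dtype=float)
        groups = pd.Series(["g1"] * 3 + ["g2"] * 3, index=list("abcdef"))
        out = sr.alpha_compare(vals, groups)
        assert out.loc[0, "statistic"] in (0.0, 9.0)
        assert out.loc[0, "pvalue"] == pytest.approx(0.1)

    def test_identical_groups_p_one(self):
        vals = pd.Series([1.0, 1.0, 1.0, 1.0], index=list("abcd"))
        groups = pd.Series(["x", "x", "y", "y"], index=list("abcd"))
        with pytest.warns(UserWarning, match="tied"):
            out = sr.alpha_compare(vals, groups)
        assert out.loc[0, "pvalue"] == 1.0

    @pytest.mark.parametrize(
        "p,stars", [(0.04, "*"), (0.004, "**"), (0.0004, "***"), (4e-5, "****"), (0.2, "ns")]
    )
    def test_star_legend(self, p, stars):
        assert significance_stars(p) == stars


class TestBrayCurtis:
    def test_hand_values(self):
        ra = sr.RelAbundanceMatrix(
            pd.DataFrame(
                [[0.5, 0.5, 0.0], [0.25, 0.25, 0.5], [0.5, 0.5, 0.0], [0.0, 0.0, 1.0]],
                index=["a", "b", "c", "d"],
                columns=["x", "y", "z"],
            )
        )
        d = sr.bray_curtis(ra)
        assert d.loc["a", "b"] == pytest.approx(0.5)  # 1 - (0.25 + 0.25)
        assert d.loc["a", "c"] == 0.0  # identical samples
        assert d.loc["a", "d"] == 1.0  # disjoint support
        np.testing.assert_allclose(d, d.T)
        assert np.diag(d).sum() == 0.0


class TestPCoA:
    def test_three_equidistant_samples(self):
        d = pd.DataFrame(1.0 - np.eye(3), index=list("abc"), columns=list("abc"))
        res = sr.pcoa(d)
        pos = res.eigenvalues[res.eigenvalues > 1e-12]
        assert len(pos) == 2
        assert pos[0] == pytest.approx(pos[1])
        np.testing.assert_allclose(res.variance_explained, [50.0, 50.0], atol=1e-9)

    def test_duplicate_samples_coincide(self):
        pts = np.array([[0.0, 0.0], [1.0, 0.0], [1.0, 0.0], [0.0, 2.0]])
        D = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        res = sr.pcoa(pd.DataFrame(D))
        np.testing.assert_allclose(
            res.coordinates.iloc[1], res.coordinates.iloc[2], atol=1e-9
        )

    def test_euclidean_distances_reproduced(self):
        # Gower: classical scaling of Euclidean distances is exact
        rng = np.random.default_rng(4)
        pts = rng.normal(size=(7, 3))
        D = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        res = sr.pcoa(pd.DataFrame(D))
        C = res.coordinates.to_numpy()
        D2 = np.sqrt(((C[:, None] - C[None]) ** 2).sum(-1))
        np.testing.assert_allclose(D2, D, atol=1e-8)

    def test_variance_explained_properties(self, gradient_ra):
        ra, _, _ = gradient_ra
        res = sr.pcoa(sr.bray_curtis(ra))
        v = res.variance_explained
        assert np.all(np.diff(v) <= 1e-9)  # non-increasing
        assert v.sum() == pytest.approx(100.0)
        assert np.all((v >= 0) & (v <= 100))

    def test_asymmetric_matrix_rejected(self):
        d = pd.DataFrame([[0, 1.0], [0.5, 0]])
        with pytest.raises(sr.ValidationError):
            sr.pcoa(d)


def brute_force_permanova(D, labels):
    """Independent oracle: Anderson's pseudo-F with exact permutation p."""
    D = np.asarray(D, dtype=float)
    labels = np.asarray(labels)
    n = len(labels)
    d2 = D ** 2
    ss_total = d2[np.triu_indices(n, 1)].sum() / n

    def stat(lab):
        ssw = 0.0
        for g in set(lab):
            idx = np.flatnonzero(lab == g)
            ssw += d2[np.ix_(idx, idx)][np.triu_indices(len(idx), 1)].sum() / len(idx)
        a = len(set(lab))
        ssb = ss_total - ssw
        return (ssb / (a - 1)) / (ssw / (n - a)), ssb / ss_total

    f_obs, r2 = stat(labels)
    f_all = [stat(np.asarray(perm))[0] for perm in set(itertools.permutations(labels))]
    p_exact = sum(f >= f_obs - 1e-12 for f in f_all) / len(f_all)
    return f_obs, r2, p_exact


class TestPermanova:
    def test_matches_exhaustive_enumeration_n6(self):
        rng = np.random.default_rng(6)
        pts = np.vstack([rng.normal(0, 1, (3, 2)), rng.normal(2.5, 1, (3, 2))])
        D = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        labels = ["a", "a", "a", "b", "b", "b"]
        dist = pd.DataFrame(D, index=range(6), columns=range(6))
        res = sr.permanova(dist, pd.Series(labels, index=range(6)),
                           n_permutations=9999, seed=1)
        f_oracle, r2_oracle, p_exact = brute_force_permanova(D, labels)
        assert res.pseudo_f == pytest.approx(f_oracle, rel=1e-10)
        assert res.r_squared == pytest.approx(r2_oracle, rel=1e-10)
        assert res.pvalue == pytest.approx(p_exact, abs=0.02)

    def test_r2_identity(self, gradient_ra):
        ra, md, _ = gradient_ra
        d = sr.bray_curtis(ra)
        res = sr.permanova(d, md.table["compartment"], n_permutations=99, seed=0)
        assert 0 <= res.r_squared <= 1
        assert res.pvalue >= 1 / 100

    def test_strong_signal_near_minimal_p(self):
        # permutations recreating the original 6|6 split tie F exactly, so the
        # attainable p floor is ~1/1000 + 2/924, not 1/1000 itself
        rng = np.random.default_rng(8)
        pts = np.vstack([rng.normal(0, 0.1, (6, 3)), rng.normal(5, 0.1, (6, 3))])
        D = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        dist = pd.DataFrame(D, index=range(12), columns=range(12))
        labels = pd.Series(["x"] * 6 + ["y"] * 6, index=range(12))
        res = sr.permanova(dist, labels, n_permutations=999, seed=2)
        assert res.pvalue < 0.02
        assert res.r_squared > 0.5

    def test_sample_order_invariance(self, gradient_ra):
        ra, md, _ = gradient_ra
        d = sr.bray_curtis(ra)
        perm_ids = list(reversed(d.index))
        d2 = d.loc[perm_ids, perm_ids]
        a = sr.permanova(d, md.table["compartment"], n_permutations=49, seed=0)
        b = sr.permanova(d2, md.table["compartment"], n_permutations=49, seed=0)
        assert a.pseudo_f == pytest.approx(b.pseudo_f, rel=1e-10)

    def test_single_group_rejected(self):
        d = pd.DataFrame(1.0 - np.eye(4), index=range(4), columns=range(4))
        with pytest.raises(sr.ValidationError):
            sr.permanova(d, pd.Series(["g"] * 4, index=range(4)))


class TestCrossCheckSkbio:
    """Independent library cross-checks of the in-package implementations."""

    def test_pcoa_matches_skbio(self, gradient_ra):
        skbio = pytest.importorskip("skbio")
        ra, _, _ = gradient_ra
        d = sr.bray_curtis(ra)
        ours = sr.pcoa(d)
        theirs = skbio.stats.ordination.pcoa(
            skbio.DistanceMatrix(d.to_numpy(), ids=list(d.index))
        )
        np.testing.assert_allclose(
            ours.variance_explained[:3],
            theirs.proportion_explained.to_numpy()[:3] * 100,
            atol=1e-6,
        )
        # coordinates agree up to per-axis sign
        for k in range(2):
            a = ours.coordinates.iloc[:, k].to_numpy()
            b = theirs.samples.iloc[:, k].to_numpy()
            assert min(np.abs(a - b).max(), np.abs(a + b).max()) < 1e-6

    def test_permanova_f_matches_skbio(self, gradient_ra):
        skbio = pytest.importorskip("skbio")
        from skbio.stats.distance import permanova as sk_permanova

        ra, md, _ = gradient_ra
        d = sr.bray_curtis(ra)
        ours = sr.permanova(d, md.table["compartment"], n_permutations=99, seed=0)
        theirs = sk_permanova(
            skbio.DistanceMatrix(d.to_numpy(), ids=list(d.index)),
            md.table["compartment"].loc[d.index].to_numpy(),
            permutations=99,
        )
        assert ours.pseudo_f == pytest.approx(theirs["test statistic"], rel=1e-8)


class TestRarefy:
    def test_depth_and_subset(self, tiny_counts):
        out = sr.rarefy(tiny_counts, depth=5, seed=1)
        assert (out.depths == 5).all()
        assert (out.data.to_numpy() <= tiny_counts.data.to_numpy()).all()

    def test_shallow_sample_rejected(self, tiny_counts):
        with pytest.raises(sr.ValidationError):
            sr.rarefy(tiny_counts, depth=100)
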