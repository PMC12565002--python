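"""Community statistics: closed forms, classical-scaling identities, and
cross-checks against scikit-bio as an independent reference."""

import numpy as np
import pandas as pd
import pytest

from albisoil import ecology as eco
from albisoil.errors import DegenerateDataError, ValidationError


def random_distance(rng, n, dim=5):
    pts = rng.normal(0, 1, (n, dim))
    return eco.euclidean_distance(pts), pts


class TestAlphaDiversity:
    def test_chao1_closed_forms(self):
        assert eco.chao1([5, 3, 3, 10]) == 4.0  # no singletons/doubletons
        counts = [1, 1, 2] + [5] * 7  # F1=2, F2=1 -> S + 2*1/(2*2)
        assert eco.chao1(counts) == pytest.approx(10.5)
        n = 6
        assert eco.chao1([1] * n) == pytest.approx(n + n * (n - 1) / 2)

    def test_chao1_never_below_richness(self, rng):
        for _ in range(20):
            counts = rng.integers(0, 10, 30)
            if counts.sum() == 0:
                continue
            assert eco.chao1(counts) >= (counts > 0).sum()

    def test_chao1_integer_guard(self):
        with pytest.raises(ValidationError):
            eco.chao1([1.5, 2.0])
        assert eco.chao1([1.5, 2.0], rounding=True) == pytest.approx(2 + 0.0)

    def test_shannon_closed_forms(self):
        assert eco.shannon([0.25] * 4) == pytest.approx(np.log(4))
        assert eco.shannon([1.0]) == 0.0
        assert eco.shannon([0.5, 0.5, 0.0]) == pytest.approx(np.log(2))

    def test_shannon_bounded_by_log_richness(self, rng):
        for _ in range(20):
            p = rng.dirichlet(np.ones(12))
            assert eco.shannon(p) <= np.log(12) + 1e-12
        with pytest.raises(ValidationError):
            eco.shannon([0.7, -0.1, 0.4])


class TestBrayCurtis:
    def test_closed_forms(self):
        d = eco.bray_curtis(np.array([[2.0, 0.0], [0.0, 2.0], [1.0, 1.0], [1.0, 1.0]]))
        assert d.d[0, 1] == pytest.approx(1.0)  # disjoint supports
        assert d.d[2, 3] == 0.0  # identical rows
        assert d.d[0, 2] == pytest.approx(0.5)

    def test_range_and_symmetry(self, rng):
        x = rng.uniform(0, 1, (10, 6))
        d = eco.bray_curtis(x)
        assert d.d.max() <= 1.0 and d.d.min() >= 0.0
        np.testing.assert_allclose(d.d, d.d.T, atol=1e-15)

    def test_matches_scipy_reference(self, rng):
        from scipy.spatial.distance import pdist, squareform

        x = rng.uniform(0, 5, (8, 12))
        ours = eco.bray_curtis(x).d
        ref = squareform(pdist(x, metric="braycurtis"))
        np.testing.assert_allclose(ours, ref, atol=1e-12)

    def test_all_zero_sample_rejected(self):
        with pytest.raises(ValidationError):
            eco.bray_curtis(np.array([[1.0, 2.0], [0.0, 0.0]]))


class TestPcoa:
    def test_recovers_euclidean_geometry(self, rng):
        d, _ = random_distance(rng, 9, dim=3)
        res = eco.pcoa(d)
        rec = eco.euclidean_distance(res.scores.to_numpy())
        np.testing.assert_allclose(rec.d, d.d, atol=1e-9)

    def test_collinear_points_have_one_positive_eigenvalue(self):
        pts = np.array([[0.0], [1.0], [3.0]])
        res = eco.pcoa(eco.euclidean_distance(pts))
        assert len(res.eigenvalues) == 1

    def test_percent_explained_sums_to_100(self, rng):
        d, _ = random_distance(rng, 8)
        res = eco.pcoa(d)
        assert res.percent_explained.sum() == pytest.approx(100.0, abs=1e-9)

    def test_axes_orthogonal(self, rng):
        d, _ = random_distance(rng, 10)
        s = res = eco.pcoa(d).scores.to_numpy()
        gram = s.T @ s
        np.testing.assert_allclose(gram - np.diag(np.diag(gram)), 0, atol=1e-9)

    def test_matches_pca_scores_on_euclidean_distances(self, rng):
        x = rng.normal(0, 1, (10, 6))
        res = eco.pcoa(eco.euclidean_distance(x))
        xc = x - x.mean(axis=0)
        u, s, _ = np.linalg.svd(xc, full_matrices=False)
        pca_scores = u * s
        k = res.scores.shape[1]
        for j in range(k):
            a, b = res.scores.to_numpy()[:, j], pca_scores[:, j]
            assert min(np.abs(a - b).max(), np.abs(a + b).max()) < 1e-9

    def test_matches_skbio(self, rng):
        from skbio.stats.ordination import pcoa as sk_pcoa

        x = rng.uniform(0, 1, (9, 7))
        d = eco.bray_curtis(x)
        ours = eco.pcoa(d)
        theirs = sk_pcoa(d.d, number_of_dimensions=3)
        np.testing.assert_allclose(
            ours.eigenvalues[:3], theirs.eigvals.to_numpy()[:3], atol=1e-9
        )


class TestPermanova:
    def test_univariate_equals_anova_f(self, rng):
        from albisoil.stats import one_way_anova

        y = rng.normal(0, 1, 12)
        y[6:] += 1.0
        groups = ["a"] * 6 + ["b"] * 6
        d = eco.euclidean_distance(y[:, None])
        res = eco.permanova(d, groups, n_perm=99, seed=1)
        f_anova = one_way_anova(y, groups).table.loc["between", "F"]
        assert res.pseudo_f == pytest.approx(f_anova, abs=1e-9)

    def test_matches_skbio(self, rng):
        from skbio import DistanceMatrix as SkDM
        from skbio.stats.distance import permanova as sk_permanova

        x = rng.uniform(0, 1, (16, 8))
        groups = np.repeat(list("abcd"), 4)
        d = eco.bray_curtis(x)
        ours = eco.permanova(d, groups, n_perm=99, seed=3)
        theirs = sk_permanova(SkDM(d.d, ids=d.labels), groups, permutations=99)
        assert ours.pseudo_f == pytest.approx(theirs["test statistic"], abs=1e-9)

    def test_reproducible_and_estimator_floor(self, rng):
        d, _ = random_distance(rng, 12)
        groups = np.repeat(["a", "b", "c"], 4)
        r1 = eco.permanova(d, groups, n_perm=199, seed=11)
        r2 = eco.permanova(d, groups, n_perm=199, seed=11)
        assert (r1.pseudo_f, r1.p) == (r2.pseudo_f, r2.p)
        assert r1.p >= 1 / 200

    def test_equidistant_matrix_is_degenerate(self):
        d = eco.DistanceMatrix(labels=[str(i) for i in range(6)], d=np.ones((6, 6)) - np.eye(6))
        res = eco.permanova(d, ["a"] * 3 + ["b"] * 3, n_perm=99, seed=0, strict=False)
        assert res.status == "degenerate"

    def test_small_n_perm_refused_in_strict_mode(self, rng):
        d, _ = random_distance(rng, 8)
        with pytest.raises(ValidationError):
            eco.permanova(d, ["a"] * 4 + ["b"] * 4, n_perm=10)


class TestMantel:
    def test_self_correlation(self, rng):
        d, _ = random_distance(rng, 10)
        res = eco.mantel(d, d, n_perm=99, seed=5)
        assert res.r == pytest.approx(1.0)
        assert res.p == pytest.approx(1 / 100)

    def test_affine_invariance(self, rng):
        d, _ = random_distance(rng, 10)
        d2 = eco.DistanceMatrix(d.labels, 0.3 * d.d + 0.7 * (1 - np.eye(d.n)))
        res = eco.mantel(d, d2, n_perm=99, seed=5)
        assert res.r == pytest.approx(1.0, abs=1e-12)

    def test_relabeling_invariance(self, rng):
        d1, _ = random_distance(rng, 9)
        d2, _ = random_distance(rng, 9)
        perm = rng.permutation(9)
        r_orig = eco.mantel(d1, d2, n_perm=99, seed=1).r
        d1p = eco.DistanceMatrix([d1.labels[i] for i in perm], d1.d[np.ix_(perm, perm)])
        d2p = eco.DistanceMatrix([d2.labels[i] for i in perm], d2.d[np.ix_(perm, perm)])
        assert eco.mantel(d1p, d2p, n_perm=99, seed=1).r == pytest.approx(r_orig, abs=1e-12)

    def test_matches_skbio_statistic(self, rng):
        from skbio.stats.distance import mantel as sk_mantel

        d1, _ = random_distance(rng, 12)
        d2, _ = random_distance(rng, 12)
        ours = eco.mantel(d1, d2, n_perm=99, seed=2)
        r_ref, _, _ = sk_mantel(d1.d, d2.d, permutations=0)
        assert ours.r == pytest.approx(r_ref, abs=1e-9)

    def test_label_mismatch_rejected(self, rng):
        d1, _ = random_distance(rng, 6)
        d2, _ = random_distance(rng, 6)
        d2.labels = [f"x{i}" for i in range(6)]
        with pytest.raises(ValidationError):
            eco.mantel(d1, d2)


class TestRda:
    @staticmethod
    def _tables(rng, n=20, q=3, p=6, noise=0.0):
        x = rng.normal(0, 1, (n, q))
        b = rng.normal(0, 1, (q, p))
        y = x @ b + noise * rng.normal(0, 1, (n, p))
        idx = pd.Index([f"s{i}" for i in range(n)])
        return pd.DataFrame(y + 10, index=idx), pd.DataFrame(x, index=idx)

    def test_exact_linear_response_fully_explained(self, rng):
        y, x = self._tables(rng)
        res = eco.rda(y, x, transform="none")
        assert res.percent_explained.sum() == pytest.approx(100.0, abs=1e-9)
        assert res.kind == "rda-constrained"

    def test_two_path_eigenvalue_identity(self, rng):
        """Constrained eigenvalues equal PCA of explicitly formed fitted values."""
        y, x = self._tables(rng, noise=1.0)
        res = eco.rda(y, x, transform="none")
        yc = y.to_numpy() - y.to_numpy().mean(axis=0)
        xc = x.to_numpy() - x.to_numpy().mean(axis=0)
        fitted = xc @ np.linalg.lstsq(xc, yc, rcond=None)[0]
        cov_eig = np.sort(np.linalg.eigvalsh(fitted.T @ fitted / (len(y) - 1)))[::-1]
        np.testing.assert_allclose(res.eigenvalues, cov_eig[: len(res.eigenvalues)], atol=1e-9)

    def test_independent_x_explains_little(self, rng):
        y, _ = self._tables(rng, n=200, noise=1.0)
        x_indep = pd.DataFrame(rng.normal(0, 1, (200, 3)), index=y.index)
        res = eco.rda(y, x_indep, transform="none")
        # expectation under independence is about q/(n-1) of total variance
        assert res.percent_explained.sum() / 100 < 3 * 3 / 199 * 3

    def test_hellinger_matches_manual_transform(self, rng):
        y, x = self._tables(rng, noise=0.5)
        y = y.clip(lower=0.1)
        res_h = eco.rda(y, x, transform="hellinger")
        yh = pd.DataFrame(eco.hellinger(y.to_numpy()), index=y.index)
        res_manual = eco.rda(yh, x, transform="none")
        np.testing.assert_allclose(res_h.eigenvalues, res_manual.eigenvalues, atol=1e-9)

    def test_collinear_columns_named(self, rng):
        x = rng.normal(0, 1, (12, 2))
        xdf = pd.DataFrame(
            np.column_stack([x, x[:, 0] + x[:, 1]]), columns=["a", "b", "c"],
            index=[f"s{i}" for i in range(12)],
        )
        y = pd.DataFrame(rng.normal(0, 1, (12, 4)), index=xdf.index)
        with pytest.raises(ValidationError, match="collinear"):
            eco.rda(y, xdf, transform="none")


class TestEnvfit:
    def test_axis_score_gives_r2_one(self, rng):
        d, _ = random_distance(rng, 12)
        res = eco.pcoa(d)
        fit = eco.envfit(res, res.scores.iloc[:, 0].to_numpy(), n_perm=99, seed=0)
        assert fit.r2 == pytest.approx(1.0, abs=1e-9)
        assert fit.p == pytest.approx(1 / 100)

    def test_orthogonal_variable_gives_r2_zero(self, rng):
        d, _ = random_distance(rng, 12)
        res = eco.pcoa(d)
        # axis 3 scores are orthogonal to axes 1-2 by construction
        fit = eco.envfit(res, res.scores.iloc[:, 2].to_numpy(), n_perm=99, seed=0)
        assert fit.r2 == pytest.approx(0.0, abs=1e-9)

    def test_constant_variable_rejected(self, rng):
        d, _ = random_distance(rng, 8)
        with pytest.raises(DegenerateDataError):
            eco.envfit(eco.pcoa(d), np.ones(8))
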