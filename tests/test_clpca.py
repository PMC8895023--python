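"""Common-line similarity and CLPCA embedding."""

import numpy as np
import pytest
from scipy.stats import spearmanr

from spihetero import clpca as P
from spihetero import datasets as D
from spihetero import simulate as S
from spihetero.errors import ConfigurationError, UndefinedSimilarityError
from spihetero.geometry import make_geometry
from spihetero.rotations import quat_to_matrix


@pytest.fixture(scope="module")
def geom():
    return make_geometry(n=64)


def _polar(avg, geom, n_angular=180):
    return P.to_polar(avg.intensity, geom, n_angular=n_angular)


class TestToPolar:
    def test_azimuthally_uniform_ring(self, geom):
        r = geom.radius_px
        img = np.exp(-((r - 10.0) ** 2) / 16.0)
        pol = P.to_polar(img, geom, n_radial=30, n_angular=72)
        checked = 0
        for rb in range(5, 25):
            row = pol.intensity[rb][pol.valid[rb]]
            # assert only where the ring carries real intensity; in the
            # exponential tails bilinear anisotropy dominates the tiny values
            if len(row) > 10 and row.mean() > 0.1:
                assert row.std() < 0.02 * row.mean()
                checked += 1
        assert checked >= 3

    def test_angular_average_matches_radial_profile(self, geom):
        """Resampling then averaging over angles equals a direct radial mean."""
        rng = np.random.default_rng(0)
        img = rng.random(geom.shape)
        from scipy.ndimage import gaussian_filter

        img = gaussian_filter(img, 3.0)
        pol = P.to_polar(img, geom, n_radial=20, n_angular=360)
        r = geom.radius_px
        r_max = min(geom.shape) / 2.0 - 1.0
        for rb in (5, 10, 15):
            r0 = (rb + 0.5) * r_max / 20.0
            ring = (np.abs(r - r0) < 0.7) & geom.good
            direct = img[ring].mean()
            polar_mean = pol.intensity[rb][pol.valid[rb]].mean()
            assert polar_mean == pytest.approx(direct, rel=0.05)

    def test_rotation_becomes_circular_shift(self, geom):
        from scipy.ndimage import rotate as nd_rotate

        rng = np.random.default_rng(1)
        from scipy.ndimage import gaussian_filter

        img = gaussian_filter(rng.random(geom.shape), 3.0)
        n_ang = 90
        k = 7
        pol_a = P.to_polar(img, geom, n_radial=20, n_angular=n_ang)
        # scipy's rotate turns the image content counterclockwise in (y, x)
        # display coordinates, which is a shift toward smaller theta on the
        # (cos, sin) polar grid used here
        rot = nd_rotate(img, np.degrees(k * 2 * np.pi / n_ang), reshape=False, order=1)
        pol_b = P.to_polar(rot, geom, n_radial=20, n_angular=n_ang)
        shifted = np.roll(pol_a.intensity, -k, axis=1)
        sel = pol_a.valid & np.roll(pol_a.valid, -k, axis=1) & pol_b.valid
        sel[:, :] = sel & (np.arange(20) > 3)[:, None]
        err = np.abs(pol_b.intensity - shifted)[sel]
        assert np.median(err) < 0.02 * (img.max() - img.min())

    def test_odd_angular_count_rejected(self, geom):
        with pytest.raises(ConfigurationError):
            P.to_polar(np.ones(geom.shape), geom, n_angular=91)


class TestCommonLine:
    def test_self_similarity_is_one(self, geom):
        avgs, _ = D.melting_series_averages(1, geom, seed=0, n_morphs=1,
                                            m_values=np.array([0.0]))
        pol = _polar(avgs[0], geom)
        cc, (i, j) = P.common_line_similarity(pol, pol)
        assert cc == pytest.approx(1.0, abs=1e-6)
        assert i == j

    def test_argmax_matches_geometric_intersection(self, geom):
        """The best line pair coincides with a geometric plane intersection.

        For two slices of one cube volume at known orientations, the common
        lines are the intersections of slice plane A with the 24 octahedral
        images of slice plane B (the particle's symmetry makes all of them
        exact); the correlation argmax must land within ~one angular bin of
        one of the predicted pairs (mod pi, by Friedel symmetry).
        """
        from spihetero.rotations import octahedral_group_matrices

        vol = S.superball_volume(S.morph_spec(0.0), geometry=geom)
        rng = np.random.default_rng(4)
        n_ang = 180
        group = octahedral_group_matrices()
        hits = 0
        trials = 6
        for _ in range(trials):
            qa, qb = D.random_quats(2, rng)
            pa = _polar(D.synthetic_average(vol, qa, geom), geom, n_ang)
            pb = _polar(D.synthetic_average(vol, qb, geom), geom, n_ang)
            cc, (ia, ib) = P.common_line_similarity(pa, pb)
            ra, rb = quat_to_matrix(qa), quat_to_matrix(qb)
            step = 2 * np.pi / n_ang

            def circdist(x, y, n=n_ang // 2):
                return min((x - y) % n, (y - x) % n)

            found = False
            for g in group:
                # direction u shared by plane A and the g-image of plane B:
                # V(R_a t d_a) == V(R_b t d_b) when R_a d_a = g R_b d_b
                u = np.cross(ra[:, 2], g @ rb[:, 2])
                nu = np.linalg.norm(u)
                if nu < 1e-6:
                    continue
                u /= nu
                pred_a = (np.arctan2(ra[:, 1] @ u, ra[:, 0] @ u) % np.pi) / step
                db = (g @ rb).T @ u
                pred_b = (np.arctan2(db[1], db[0]) % np.pi) / step
                if circdist(ia, pred_a) <= 1.5 and circdist(ib, pred_b) <= 1.5:
                    found = True
                    break
            hits += found
        assert hits >= trials - 1

    def test_cube_sphere_cross_similarity_lower(self, geom):
        """Same-shape pairs correlate better than cube-sphere pairs."""
        avgs, labels, _ = D.shape_zoo_averages(
            10, geom, seed=2, classes=("cube", "sphere")
        )
        polars = [_polar(a, geom) for a in avgs]
        mat = P.similarity_matrix(polars)
        same = []
        cross = []
        for i in range(len(avgs)):
            for j in range(i + 1, len(avgs)):
                (same if labels[i] == labels[j] else cross).append(mat.cc[i, j])
        assert np.mean(same) > np.mean(cross)
        assert np.max(cross) < np.mean(same)

    def test_degenerate_pattern_raises(self, geom):
        pol = P.to_polar(np.ones(geom.shape), geom)
        pol.valid[:] = False
        with pytest.raises(UndefinedSimilarityError):
            P.common_line_similarity(pol, pol)


class TestSimilarityMatrix:
    def test_identical_patterns_all_ones(self, geom):
        avgs, _ = D.melting_series_averages(
            1, geom, seed=0, n_morphs=1, m_values=np.array([0.5]), total_photons=None
        )
        pol = _polar(avgs[0], geom)
        mat = P.similarity_matrix([pol, pol, pol])
        np.testing.assert_allclose(mat.cc, 1.0, atol=1e-9)

    def test_symmetry_by_construction(self, geom):
        avgs, _ = D.melting_series_averages(6, geom, seed=3, n_morphs=3)
        mat = P.similarity_matrix([_polar(a, geom) for a in avgs])
        np.testing.assert_array_equal(mat.cc, mat.cc.T)
        np.testing.assert_allclose(np.diag(mat.cc), 1.0, atol=1e-6)
        assert mat.cc.min() >= -1.0 - 1e-9 and mat.cc.max() <= 1.0 + 1e-9

    def test_pair_count_scales_quadratically(self, geom, monkeypatch):
        """Doubling N roughly quadruples the computed pair count."""
        avgs, _ = D.melting_series_averages(12, geom, seed=3, n_morphs=3)
        polars = [_polar(a, geom) for a in avgs]
        calls = {"n": 0}
        orig = P._masked_corr_matrix

        def counting(*args, **kw):
            calls["n"] += 1
            return orig(*args, **kw)

        monkeypatch.setattr(P, "_masked_corr_matrix", counting)
        P.similarity_matrix(polars[:6])
        n6 = calls["n"]
        calls["n"] = 0
        P.similarity_matrix(polars)
        n12 = calls["n"]
        assert n6 == 6 * 5 // 2
        assert n12 == 12 * 11 // 2
        assert n12 / n6 == pytest.approx(4.0, rel=0.15)

    def test_single_pattern_rejected(self, geom):
        avgs, _ = D.melting_series_averages(1, geom, seed=0, n_morphs=1)
        with pytest.raises(ConfigurationError):
            P.similarity_matrix([_polar(avgs[0], geom)])


class TestEmbed:
    def _random_matrix(self, n=10, seed=0):
        rng = np.random.default_rng(seed)
        base = rng.random((n, n))
        cc = (base + base.T) / 2.0
        np.fill_diagonal(cc, 1.0)
        return P.SimilarityMatrix(
            cc=cc, angles=np.zeros((n, n, 2), np.int32), defined=np.ones((n, n), bool)
        )

    def test_matches_dense_eigendecomposition(self):
        """PCA coordinates agree with an explicit covariance eigensolve."""
        mat = self._random_matrix(10)
        emb = P.embed(mat, 3)
        rows = mat.cc
        x = rows - rows.mean(axis=0)
        cov = x.T @ x / (len(rows) - 1)
        w, v = np.linalg.eigh(cov)
        order = np.argsort(w)[::-1]
        w, v = w[order], v[:, order]
        np.testing.assert_allclose(emb.explained_variance, w[:3], rtol=1e-10)
        for c in range(3):
            vec = v[:, c]
            if vec[np.argmax(np.abs(vec))] < 0:
                vec = -vec
            np.testing.assert_allclose(emb.coords[:, c], x @ vec, atol=1e-10)

    def test_zero_variance_rows(self):
        n = 5
        mat = P.SimilarityMatrix(
            cc=np.ones((n, n)), angles=np.zeros((n, n, 2), np.int32),
            defined=np.ones((n, n), bool),
        )
        with pytest.warns(UserWarning):
            emb = P.embed(mat, 3)
        assert np.allclose(emb.coords, 0.0)

    def test_components_ordered_by_variance(self):
        emb = P.embed(self._random_matrix(12, seed=5), 3)
        assert np.all(np.diff(emb.explained_variance) <= 1e-12)

    def test_four_class_cluster_purity(self, geom, zoo_embedding):
        """k-means on CLPCA coordinates recovers the planted shape classes."""
        emb, labels = zoo_embedding
        purity = _kmeans_purity(emb.coords, labels, 4)
        assert purity >= 0.9

    def test_sphere_size_axis(self, geom):
        """One CLPCA component tracks sphere diameter (|Spearman| >= 0.8)."""
        avgs, diams = D.graded_sphere_averages(8, 4, geom, seed=6)
        polars = [_polar(a, geom) for a in avgs]
        mat = P.similarity_matrix(polars)
        emb = P.embed(mat, 3)
        rhos = [
            abs(spearmanr(emb.coords[:, c], diams).statistic)
            for c in range(emb.coords.shape[1])
        ]
        assert max(rhos) >= 0.8


def _kmeans_purity(coords, labels, k):
    from scipy.optimize import linear_sum_assignment
    from sklearn.cluster import KMeans

    pred = KMeans(n_clusters=k, n_init=10, random_state=0).fit_predict(coords)
    conf = np.zeros((k, k))
    for p, t in zip(pred, labels):
        conf[p, t] += 1
    r, c = linear_sum_assignment(-conf)
    return conf[r, c].sum() / len(labels)


@pytest.fixture(scope="module")
def zoo_embedding(geom):
    avgs, labels, _ = D.shape_zoo_averages(20, geom, seed=7)
    polars = [P.to_polar(a.intensity, geom, n_angular=180) for a in avgs]
    mat = P.similarity_matrix(polars)
    return P.embed(mat, 3), labels


class TestAltEmbeddings:
    def test_pca_dispatch_identity(self):
        rng = np.random.default_rng(2)
        base = rng.random((8, 8))
        cc = (base + base.T) / 2
        np.fill_diagonal(cc, 1.0)
        mat = P.SimilarityMatrix(
            cc=cc, angles=np.zeros((8, 8, 2), np.int32), defined=np.ones((8, 8), bool)
        )
        a = P.embed(mat, 3)
        b = P.alt_embeddings(mat, "pca", 3)
        np.testing.assert_array_equal(a.coords, b.coords)

    def test_methods_agree_on_planted_classes(self, geom, zoo_embedding):
        """All four reductions separate the planted classes comparably."""
        avgs, labels, _ = D.shape_zoo_averages(20, geom, seed=7)
        polars = [P.to_polar(a.intensity, geom, n_angular=180) for a in avgs]
        mat = P.similarity_matrix(polars)
        purities = {}
        for method in ("pca", "isomap", "spectral", "tsne"):
            emb = P.alt_embeddings(mat, method, 3, seed=0)
            purities[method] = _kmeans_purity(emb.coords, labels, 4)
        base = purities["pca"]
        for method, pur in purities.items():
            assert pur >= base - 0.1, purities

    def test_tsne_seed_reproducible(self, geom):
        rng = np.random.default_rng(9)
        base = rng.random((30, 30))
        cc = (base + base.T) / 2
        np.fill_diagonal(cc, 1.0)
        mat = P.SimilarityMatrix(
            cc=cc, angles=np.zeros((30, 30, 2), np.int32),
            defined=np.ones((30, 30), bool),
        )
        a = P.alt_embeddings(mat, "tsne", 2, seed=5)
        b = P.alt_embeddings(mat, "tsne", 2, seed=5)
        np.testing.assert_array_equal(a.coords, b.coords)

    def test_unknown_method_rejected(self):
        mat = P.SimilarityMatrix(
            cc=np.eye(3), angles=np.zeros((3, 3, 2), np.int32),
            defined=np.ones((3, 3), bool),
        )
        with pytest.raises(ConfigurationError):
            P.alt_embeddings(mat, "umap")
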