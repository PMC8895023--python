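"""Rotation-invariant features and the absolute-embedding regressor."""

import numpy as np
import pytest
from scipy.ndimage import rotate as nd_rotate

from spihetero import clpca as P
from spihetero import datasets as D
from spihetero import embednet as E
from spihetero.classify2d import ClassAverage2D
from spihetero.errors import ConfigurationError, GeometryMismatchError
from spihetero.geometry import make_geometry


@pytest.fixture(scope="module")
def geom():
    return make_geometry(n=64)


@pytest.fixture(scope="module")
def extractor(geom):
    return E.FeatureExtractor(n_radial=min(geom.shape) // 2, n_angular=180)


def _avg(img):
    return ClassAverage2D(intensity=img, occupancy=1.0)


class TestExtractFeatures:
    def test_azimuthally_uniform_only_dc(self, geom, extractor):
        r = geom.radius_px
        img = np.exp(-((r - 12.0) ** 2) / 20.0) + 0.05
        feats = E.extract_features(_avg(img), geom, extractor=extractor)
        layout = extractor.layout
        dc = feats[[i for i, (r_, k) in enumerate(layout) if k == 0]]
        nondc = feats[[i for i, (r_, k) in enumerate(layout) if k > 0]]
        assert nondc.max() < 0.02 * dc.max()

    def test_cos2theta_ring_single_harmonic(self, geom, extractor):
        """A cos(2 theta)-modulated ring puts its energy at frequency 2.

        The feature is |FFT|/n_angular of log(1+I); for I = A(1 + eps cos
        2theta) with small eps the k=2 magnitude is ~A' eps/2 where A' is
        the log-slope, so the check is against the numerically exact FFT of
        the log-transformed modulation.
        """
        r = geom.radius_px
        cy, cx = geom.center
        yy, xx = np.mgrid[0 : geom.shape[0], 0 : geom.shape[1]]
        theta = np.arctan2(yy - cy, xx - cx)
        ring = np.exp(-((r - 14.0) ** 2) / 30.0)
        img = ring * (1.0 + 0.3 * np.cos(2.0 * theta))
        feats = E.extract_features(_avg(img), geom, extractor=extractor)
        layout = extractor.layout
        # pick the radial bin nearest the ring radius
        r_max = min(geom.shape) / 2.0 - 1.0
        rb = int(14.0 / (r_max / extractor.n_radial))
        by_k = {k: feats[i] for i, (r_, k) in enumerate(layout) if r_ == rb}
        # oracle: FFT of the analytic log-profile at that radius
        radius = (rb + 0.5) * (r_max / extractor.n_radial)
        amp = np.exp(-((radius - 14.0) ** 2) / 30.0)
        th = np.arange(extractor.n_angular) * (2 * np.pi / extractor.n_angular)
        prof = np.log1p(amp * (1 + 0.3 * np.cos(2 * th)))
        mags = np.abs(np.fft.rfft(prof)) / extractor.n_angular
        assert by_k[2] == pytest.approx(mags[2], rel=0.05)
        higher = [v for k, v in by_k.items() if k not in (0, 2, 4)]
        assert max(higher) < 0.1 * by_k[2]

    def test_rotation_invariance(self, geom, extractor, cube_volume):
        """Features of a pattern and its 37-degree rotation nearly coincide."""
        rng = np.random.default_rng(2)
        q = D.random_quats(1, rng)[0]
        avg = D.synthetic_average(cube_volume, q, geom, rng, None)
        rotated = _avg(
            np.clip(nd_rotate(avg.intensity, 37.0, reshape=False, order=1), 0, None)
        )
        fa = E.extract_features(avg, geom, extractor=extractor)
        fb = E.extract_features(rotated, geom, extractor=extractor)
        assert np.linalg.norm(fa - fb) < 0.01 * np.linalg.norm(fa)

    def test_band_limit_grows_with_radius(self, extractor):
        bls = [extractor.band_limit(r) for r in range(extractor.n_radial)]
        assert all(b2 >= b1 for b1, b2 in zip(bls, bls[1:]))
        assert bls[0] < bls[-1]


@pytest.fixture(scope="module")
def melting_features(geom, extractor, melting_data):
    avgs, truth = melting_data
    feats = np.stack(
        [E.extract_features(a, geom, extractor=extractor) for a in avgs]
    )
    return feats, truth


@pytest.fixture(scope="module")
def melting_embedding(geom, melting_data):
    avgs, _ = melting_data
    polars = [P.to_polar(a.intensity, geom, n_angular=180) for a in avgs]
    return P.embed(P.similarity_matrix(polars), 3)


class TestTrainRegressor:
    def test_zero_labels_learned(self, melting_features, extractor):
        feats, _ = melting_features
        labels = np.zeros((len(feats), 3))
        model = E.train_regressor(feats, labels, extractor, split=(300, 100), seed=0)
        assert model.validation_mse.max() < 1e-3

    def test_validation_mse_beats_variance(self, geom, extractor):
        """Per-component validation MSE is well below the label variance.

        Uses the four-shape planted set, whose CLPCA components all carry
        class structure (a single-family melting set leaves the third
        component mostly noise, which no regressor can predict).
        """
        avgs, _, _ = D.shape_zoo_averages(40, geom, seed=7)
        polars = [P.to_polar(a.intensity, geom, n_angular=180) for a in avgs]
        emb = P.embed(P.similarity_matrix(polars), 3)
        feats = np.stack(
            [E.extract_features(a, geom, extractor=extractor) for a in avgs]
        )
        model = E.train_regressor(feats, emb, extractor, split=(120, 40), seed=0)
        var = emb.coords.var(axis=0)
        assert (model.validation_mse <= 0.25 * var).all()

    def test_seed_reproducible(self, melting_features, melting_embedding, extractor):
        feats, _ = melting_features
        a = E.train_regressor(feats, melting_embedding, extractor, split=(300, 100), seed=4)
        b = E.train_regressor(feats, melting_embedding, extractor, split=(300, 100), seed=4)
        np.testing.assert_array_equal(a.validation_mse, b.validation_mse)

    def test_oversized_split_rejected(self, melting_features, extractor):
        feats, _ = melting_features
        with pytest.raises(ConfigurationError):
            E.train_regressor(feats, np.zeros((len(feats), 3)), extractor, split=(800, 200))


class TestEmbedAbsolute:
    @pytest.fixture(scope="class")
    def model(self, melting_features, melting_embedding, extractor):
        feats, _ = melting_features
        return E.train_regressor(feats, melting_embedding, extractor, split=(300, 100), seed=0)

    def test_training_average_lands_near_label(
        self, geom, model, melting_data, melting_embedding
    ):
        avgs, _ = melting_data
        idx = model.train_indices[:20]
        pred = E.embed_absolute(model, [avgs[i] for i in idx], geom)
        labels = melting_embedding.coords[idx]
        resid = np.sqrt(np.mean((pred - labels) ** 2, axis=0))
        scale = melting_embedding.coords.std(axis=0)
        assert (resid < 0.6 * scale).all()

    def test_new_cube_averages_land_in_cube_region(
        self, geom, model, melting_data, melting_embedding, cube_volume, sphere_volume
    ):
        """Freshly generated cube patterns map closer to the cube centroid."""
        avgs, truth = melting_data
        m = truth["morph"]
        coords = melting_embedding.coords
        cube_centroid = coords[m < 0.15].mean(axis=0)
        sphere_centroid = coords[m > 0.85].mean(axis=0)
        rng = np.random.default_rng(11)
        new = [
            D.synthetic_average(cube_volume, q, geom, rng, 3e6)
            for q in D.random_quats(10, rng)
        ]
        pred = E.embed_absolute(model, new, geom)
        closer = np.linalg.norm(pred - cube_centroid, axis=1) < np.linalg.norm(
            pred - sphere_centroid, axis=1
        )
        assert closer.mean() >= 0.9

    def test_empty_input(self, geom, model):
        out = E.embed_absolute(model, [], geom)
        assert out.shape[0] == 0

    def test_geometry_mismatch_rejected(self, model):
        small = make_geometry(n=32)
        img = np.ones(small.shape)
        with pytest.raises(GeometryMismatchError):
            E.embed_absolute(model, [_avg(img)], small)

    def test_end_to_end_rotation_invariance(
        self, geom, model, melting_data, melting_embedding
    ):
        """Embedding of a pattern and its in-plane rotation nearly coincide.

        The rotated copy is generated exactly (the orientation quaternion
        composed with an in-plane rotation), noiseless, so the probe
        isolates the model's registration invariance from photon noise and
        image-interpolation blur.  The mean displacement must stay below
        5% of the inter-class distance (cube-region centroid to
        sphere-region centroid); individual samples may reach twice that,
        which is the regressor's local roughness at its own noise floor,
        not a rotation-systematic.
        """
        from spihetero import simulate as S
        from spihetero.rotations import quat_multiply

        avgs, truth = melting_data
        m = truth["morph"]
        coords = melting_embedding.coords
        inter = np.linalg.norm(
            coords[m < 0.15].mean(axis=0) - coords[m > 0.85].mean(axis=0)
        )
        phi = np.deg2rad(53.0)
        qrot = np.array([np.cos(phi / 2), 0.0, 0.0, np.sin(phi / 2)])
        disps = []
        for i in range(8):
            vol = S.superball_volume(
                S.morph_spec(float(truth["morph"][i])), geometry=geom
            )
            a1 = D.synthetic_average(vol, truth["quat"][i], geom, None, None)
            a2 = D.synthetic_average(
                vol, quat_multiply(truth["quat"][i], qrot), geom, None, None
            )
            p = E.embed_absolute(model, [a1, a2], geom)
            disps.append(np.linalg.norm(p[0] - p[1]))
        disps = np.asarray(disps)
        assert disps.mean() < 0.05 * inter
        assert disps.max() < 0.10 * inter
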