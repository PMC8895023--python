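"""Absolute embedding: rotation-invariant features + MLP regression.

The CLPCA coordinates of an average are relative to the ensemble they were
computed with, and the similarity matrix scales quadratically with the
number of averages.  To place *new* averages into a frozen reference CLPCA
frame cheaply, each pattern is reduced to in-plane-rotation-invariant
features — per radial bin, the magnitudes of the FFT of the azimuthal
intensity variation — and a fully connected network (hidden layers 512,
128, 64, 32) is regressed from features to the reference CLPCA
coordinates.

Odd azimuthal frequencies vanish by Friedel symmetry and are dropped; at
small radii the azimuthal Nyquist limit of the speckle leaves only a few
meaningful frequencies, so each radius keeps even frequencies up to a band
limit that grows linearly with radius.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.neural_network import MLPRegressor
from sklearn.preprocessing import StandardScaler

from .classify2d import ClassAverage2D
from .clpca import Embedding, PolarPattern, to_polar
from .errors import ConfigurationError, GeometryMismatchError
from .geometry import DetectorGeometry

__all__ = [
    "FeatureExtractor",
    "extract_features",
    "EmbedRegressor",
    "train_regressor",
    "embed_absolute",
]


@dataclass
class FeatureExtractor:
    """Feature layout: which (radius, even frequency) pairs are kept."""

    n_radial: int
    n_angular: int
    log_domain: bool = True

    def band_limit(self, r_bin: int) -> int:
        """Highest azimuthal frequency kept at a radial bin (linear in r)."""
        return min(r_bin, self.n_angular // 2)

    @property
    def layout(self) -> list[tuple[int, int]]:
        """(radial bin, even frequency) pairs in feature order."""
        out = []
        for r in range(self.n_radial):
            for k in range(0, self.band_limit(r) + 1, 2):
                out.append((r, k))
        return out

    @property
    def n_features(self) -> int:
        return len(self.layout)

    def check_geometry(self, geometry: DetectorGeometry) -> None:
        if self.n_radial > min(geometry.shape) // 2:
            raise GeometryMismatchError(
                f"{self.n_radial} radial bins exceed the detector's "
                f"{min(geometry.shape) // 2}-bin radial Nyquist"
            )

    def __call__(self, polar: PolarPattern) -> np.ndarray:
        if polar.n_radial != self.n_radial or polar.n_angular != self.n_angular:
            raise GeometryMismatchError(
                f"polar grid {polar.intensity.shape} does not match extractor "
                f"({self.n_radial}, {self.n_angular})"
            )
        ints = polar.intensity
        if self.log_domain:
            ints = np.log1p(np.clip(ints, 0.0, None))
        # rows fully masked: zero-filled (flagged by zero DC term)
        rows = np.where(polar.valid, ints, 0.0)
        n_valid = polar.valid.sum(axis=1)
        fillable = n_valid > 0
        row_mean = rows.sum(axis=1) / np.maximum(n_valid, 1)
        filled = np.where(polar.valid, ints, row_mean[:, None])
        filled[~fillable] = 0.0
        mags = np.abs(np.fft.rfft(filled, axis=1)) / self.n_angular
        feats = np.empty(self.n_features)
        for i, (r, k) in enumerate(self.layout):
            feats[i] = mags[r, k]
        return feats


def extract_features(
    average: ClassAverage2D,
    geometry: DetectorGeometry,
    extractor: FeatureExtractor | None = None,
    n_radial: int | None = None,
    n_angular: int = 180,
) -> np.ndarray:
    """Rotation-invariant feature vector of one average."""
    if extractor is None:
        if n_radial is None:
            n_radial = min(geometry.shape) // 2
        extractor = FeatureExtractor(n_radial=n_radial, n_angular=n_angular)
    extractor.check_geometry(geometry)
    polar = to_polar(average.intensity, geometry, extractor.n_radial, extractor.n_angular)
    return extractor(polar)


@dataclass
class EmbedRegressor:
    """Fitted features -> CLPCA-coordinates regressor."""

    scaler: StandardScaler = field(repr=False)
    mlp: MLPRegressor = field(repr=False)
    extractor: FeatureExtractor
    validation_mse: np.ndarray
    train_indices: np.ndarray = field(repr=False)
    val_indices: np.ndarray = field(repr=False)
    label_provenance: str = ""
    label_mean: np.ndarray | None = field(default=None, repr=False)
    label_scale: np.ndarray | None = field(default=None, repr=False)


def train_regressor(
    features: np.ndarray,
    labels: np.ndarray | Embedding,
    extractor: FeatureExtractor,
    split: tuple[int, int] = (800, 200),
    seed: int = 0,
    hidden_layer_sizes: tuple[int, ...] = (512, 128, 64, 32),
    max_iter: int = 500,
    label_provenance: str = "",
) -> EmbedRegressor:
    """Fit the MLP on a train split and report per-component validation MSE.

    ``split`` = (n_train, n_val) partitions the shuffled dataset; features
    are z-scored with statistics from the training split only.  Training
    is early-stopped on an internal validation fraction; the reported MSE
    is measured on the held-out ``n_val`` patterns, per CLPCA component,
    on raw (unstandardized) coordinates.
    """
    if isinstance(labels, Embedding):
        labels = labels.coords
    features = np.asarray(features, dtype=float)
    labels = np.asarray(labels, dtype=float)
    n = len(features)
    n_train, n_val = split
    if n_train + n_val > n:
        raise ConfigurationError(f"split {split} exceeds dataset size {n}")
    if labels.ndim == 1:
        labels = labels[:, None]
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    tr, va = order[:n_train], order[n_train : n_train + n_val]
    scaler = StandardScaler().fit(features[tr])
    # standardize labels internally (training stability; a near-constant
    # component then costs nothing to learn); predictions are mapped back
    label_mean = labels[tr].mean(axis=0)
    label_scale = np.maximum(labels[tr].std(axis=0), 1e-9)
    mlp = MLPRegressor(
        hidden_layer_sizes=hidden_layer_sizes,
        activation="relu",
        solver="adam",
        random_state=int(seed),
        max_iter=max_iter,
        early_stopping=True,
        n_iter_no_change=20,
    )
    mlp.fit(scaler.transform(features[tr]), (labels[tr] - label_mean) / label_scale)
    model = EmbedRegressor(
        scaler=scaler,
        mlp=mlp,
        extractor=extractor,
        validation_mse=np.zeros(labels.shape[1]),
        train_indices=tr,
        val_indices=va,
        label_provenance=label_provenance,
        label_mean=label_mean,
        label_scale=label_scale,
    )
    pred = _predict(model, features[va])
    model.validation_mse = np.mean((pred - labels[va]) ** 2, axis=0)
    return model


def _predict(model: "EmbedRegressor", features: np.ndarray) -> np.ndarray:
    out = model.mlp.predict(model.scaler.transform(features))
    if out.ndim == 1:
        out = out[:, None]
    return out * model.label_scale + model.label_mean


def embed_absolute(
    model: EmbedRegressor,
    averages: list[ClassAverage2D],
    geometry: DetectorGeometry,
) -> np.ndarray:
    """Coordinates of new averages in the frozen reference CLPCA frame."""
    if not averages:
        n_out = getattr(model.mlp, "n_outputs_", 3)
        return np.zeros((0, n_out))
    feats = np.stack(
        [extract_features(a, geometry, extractor=model.extractor) for a in averages]
    )
    if feats.shape[1] != model.scaler.n_features_in_:
        raise GeometryMismatchError(
            f"feature length {feats.shape[1]} does not match the trained model "
            f"({model.scaler.n_features_in_})"
        )
    return _predict(model, feats)
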