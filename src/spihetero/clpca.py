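"""Common-line similarity and the CLPCA structural landscape.

By the Fourier slice theorem, two small-angle diffraction patterns of the
same object are central slices of one 3D intensity and intersect along a
line through q = 0.  The best Pearson correlation over all pairs of
full-diameter line profiles ("common-line similarity") is high for patterns
of similarly shaped objects in any orientations and lower across shapes.
The N x N matrix of best correlations is embedded with PCA on its rows; the
first three components span the CLPCA space in which proximity means 3D
structural similarity regardless of orientation.

Correlations are computed on log(1 + I) profiles standardized per radial
ring: the log compresses the dynamic range, and the ring standardization
removes the radial falloff shared by all compact particles, which would
otherwise push every pairwise correlation to ~1 regardless of structure
(see :meth:`PolarPattern.lines`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .errors import ConfigurationError, UndefinedSimilarityError
from .geometry import DetectorGeometry

__all__ = [
    "PolarPattern",
    "to_polar",
    "common_line_similarity",
    "SimilarityMatrix",
    "similarity_matrix",
    "Embedding",
    "embed",
    "alt_embeddings",
]

#: radial bins next to the beam centre excluded from line profiles --
#: all diameters trivially agree at q ~ 0
BEAMSTOP_EXCLUDE_BINS = 5
#: minimum number of valid samples for a line-pair correlation
MIN_VALID_SAMPLES = 10


@dataclass
class PolarPattern:
    """Pattern resampled on a (radius, angle) grid.

    ``intensity`` has shape (n_radial, n_angular) with uniform angle bins
    over [0, 2 pi); ``valid`` flags bins inside the detector and off the
    mask.  Friedel symmetry pairs bin(theta) with bin(theta + pi), so full
    diameters are built from n_angular // 2 distinct lines.
    """

    intensity: np.ndarray = field(repr=False)
    valid: np.ndarray = field(repr=False)
    q_values: np.ndarray
    angular_step: float

    @property
    def n_radial(self) -> int:
        return self.intensity.shape[0]

    @property
    def n_angular(self) -> int:
        return self.intensity.shape[1]

    def lines(
        self,
        r_min: int = BEAMSTOP_EXCLUDE_BINS,
        log: bool = True,
        ring_normalize: bool = True,
        ring_eps: float = 0.1,
    ):
        """Full-diameter profiles through q = 0 and their validity masks.

        Returns (L, M): L has shape (n_angular/2, 2*(n_radial - r_min));
        each row is the profile along theta glued to the one along
        theta + pi (radii reversed).

        By default profiles are log(1+I) standardized per radial ring
        (angular mean subtracted, angular spread divided out, softened by
        ``ring_eps`` times the mean spread).  Without ring normalization
        every line shares the steep radial falloff of a compact particle
        and Pearson coefficients saturate near 1 for *any* pair of
        patterns, hiding the structural signal; standardizing each ring
        makes the correlation sensitive to the azimuthal speckle that
        actually distinguishes 3D shapes, while fringe radii (size
        information) survive in the ring-to-ring sign structure.
        """
        half = self.n_angular // 2
        ints = np.log1p(np.clip(self.intensity, 0.0, None)) if log else np.asarray(
            self.intensity, dtype=float
        )
        if ring_normalize:
            valid = self.valid
            n_valid = valid.sum(axis=1)
            safe = np.maximum(n_valid, 1)
            masked = np.where(valid, ints, 0.0)
            mean = masked.sum(axis=1) / safe
            var = (np.where(valid, (ints - mean[:, None]) ** 2, 0.0)).sum(axis=1) / safe
            std = np.sqrt(var)
            soft = std + ring_eps * max(std[n_valid > 1].mean() if (n_valid > 1).any() else 1.0, 1e-12)
            ints = (ints - mean[:, None]) / soft[:, None]
            ints[n_valid == 0] = 0.0
        a = ints[r_min:, :half]  # (nr', half)
        b = ints[r_min:, half:]
        va = self.valid[r_min:, :half]
        vb = self.valid[r_min:, half:]
        lines = np.concatenate([b[::-1].T, a.T], axis=1)  # (half, 2 nr')
        masks = np.concatenate([vb[::-1].T, va.T], axis=1)
        return lines, masks


def to_polar(
    pattern: np.ndarray,
    geometry: DetectorGeometry,
    n_radial: int | None = None,
    n_angular: int = 180,
) -> PolarPattern:
    """Bilinear resampling of a detector pattern onto a polar grid.

    ``n_angular`` must be even so that opposite angle bins pair into full
    diameters.  Bins whose sampling point falls on a masked pixel or
    outside the detector are flagged invalid.
    """
    if n_angular % 2 != 0:
        raise ConfigurationError("n_angular must be even for inversion-symmetry pairing")
    h, w = geometry.shape
    cy, cx = geometry.center
    if n_radial is None:
        n_radial = int(min(h, w) // 2)
    r_max = min(h, w) / 2.0 - 1.0
    radii = (np.arange(n_radial) + 0.5) * (r_max / n_radial)
    angular_step = 2.0 * np.pi / n_angular
    thetas = np.arange(n_angular) * angular_step
    yy = cy + radii[:, None] * np.sin(thetas[None, :])
    xx = cx + radii[:, None] * np.cos(thetas[None, :])
    coords = np.stack([yy.ravel(), xx.ravel()])
    img = np.nan_to_num(np.asarray(pattern, dtype=float), nan=0.0)
    vals = ndimage.map_coordinates(img, coords, order=1, mode="constant", cval=0.0)
    bad = (geometry.mask != 0).astype(float)
    badness = ndimage.map_coordinates(bad, coords, order=0, mode="constant", cval=1.0)
    valid = (badness < 0.5).reshape(n_radial, n_angular)
    # q of each radial bin (q is linear in pixel radius to ~4e-4 here)
    q_values = radii * geometry.qmag[int(cy), -1] / (w - 1 - cx)
    return PolarPattern(
        intensity=vals.reshape(n_radial, n_angular),
        valid=valid,
        q_values=q_values,
        angular_step=angular_step,
    )


def _masked_corr_matrix(la, ma, lb, mb, min_valid: int = MIN_VALID_SAMPLES):
    """Pairwise Pearson correlations between rows of la and rows of lb.

    Masked samples are excluded pairwise; pairs with fewer than
    ``min_valid`` shared samples get -inf.
    """
    ma = ma.astype(float)
    mb = mb.astype(float)
    a = la * ma
    b = lb * mb
    n = ma @ mb.T
    sx = a @ mb.T
    sy = ma @ b.T
    sxy = a @ b.T
    sxx = (la**2 * ma) @ mb.T
    syy = ma @ (lb**2 * mb).T
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = n * sxy - sx * sy
        var = (n * sxx - sx**2) * (n * syy - sy**2)
        cc = cov / np.sqrt(np.clip(var, 0.0, None))
    cc[~np.isfinite(cc)] = -np.inf
    cc[n < min_valid] = -np.inf
    return cc


def common_line_similarity(
    a: PolarPattern,
    b: PolarPattern,
    q_range: tuple[int, int] | None = None,
) -> tuple[float, tuple[int, int]]:
    """Best common-line correlation between two patterns.

    Exhaustively correlates every full-diameter line of ``a`` against every
    line of ``b`` (log-intensity profiles, masked samples excluded
    pairwise) and returns the highest Pearson coefficient together with the
    (angle-bin, angle-bin) pair attaining it.
    """
    r_min = q_range[0] if q_range is not None else BEAMSTOP_EXCLUDE_BINS
    la, ma = a.lines(r_min)
    lb, mb = b.lines(r_min)
    if q_range is not None and q_range[1] is not None:
        keep = 2 * (q_range[1] - r_min)
        half = la.shape[1] // 2
        lo, hi = half - keep // 2, half + keep // 2
        la, ma, lb, mb = la[:, lo:hi], ma[:, lo:hi], lb[:, lo:hi], mb[:, lo:hi]
    cc = _masked_corr_matrix(la, ma, lb, mb)
    if not np.isfinite(cc).any():
        raise UndefinedSimilarityError("no line pair with enough valid samples")
    flat = int(np.argmax(cc))
    i, j = np.unravel_index(flat, cc.shape)
    return float(cc[i, j]), (int(i), int(j))


@dataclass
class SimilarityMatrix:
    """Symmetric matrix of best common-line correlations.

    ``angles`` holds the argmax line-index pair of each entry (diagnostic
    only); ``defined`` flags pairs where the similarity could be computed.
    """

    cc: np.ndarray = field(repr=False)
    angles: np.ndarray = field(repr=False)
    defined: np.ndarray = field(repr=False)

    @property
    def n(self) -> int:
        return self.cc.shape[0]


def similarity_matrix(
    patterns: list[PolarPattern], q_range: tuple[int, int] | None = None
) -> SimilarityMatrix:
    """All-pairs common-line similarity (computed once per pair, mirrored)."""
    n = len(patterns)
    if n < 2:
        raise ConfigurationError("need at least two patterns")
    r_min = q_range[0] if q_range is not None else BEAMSTOP_EXCLUDE_BINS
    lines = []
    for p in patterns:
        l, m = p.lines(r_min)
        lines.append((l, m.astype(float)))
    cc = np.eye(n)
    angles = np.zeros((n, n, 2), dtype=np.int32)
    defined = np.ones((n, n), dtype=bool)
    for i in range(n):
        la, ma = lines[i]
        for j in range(i + 1, n):
            lb, mb = lines[j]
            mat = _masked_corr_matrix(la, ma, lb, mb)
            if not np.isfinite(mat).any():
                defined[i, j] = defined[j, i] = False
                continue
            flat = int(np.argmax(mat))
            ii, jj = np.unravel_index(flat, mat.shape)
            cc[i, j] = cc[j, i] = mat[ii, jj]
            angles[i, j] = (ii, jj)
            angles[j, i] = (jj, ii)
    return SimilarityMatrix(cc=cc, angles=angles, defined=defined)


@dataclass
class Embedding:
    """Low-dimensional embedding of similarity-matrix rows."""

    coords: np.ndarray
    explained_variance: np.ndarray
    mean: np.ndarray = field(repr=False)
    components: np.ndarray | None = field(default=None, repr=False)
    method: str = "pca"


def _imputed_rows(matrix: SimilarityMatrix) -> np.ndarray:
    """Row vectors with undefined entries replaced by their column means."""
    rows = matrix.cc.copy()
    if not matrix.defined.all():
        if (~matrix.defined).all(axis=1).any():
            raise ConfigurationError("a row of the similarity matrix is fully undefined")
        col_mean = np.where(matrix.defined, rows, 0.0).sum(0) / np.maximum(
            matrix.defined.sum(0), 1
        )
        rows = np.where(matrix.defined, rows, col_mean[None, :])
    return rows


def embed(matrix: SimilarityMatrix, n_components: int = 3) -> Embedding:
    """PCA of the similarity-matrix rows (the CLPCA embedding).

    Components are ordered by decreasing explained variance; each
    component's sign is fixed so that its largest-magnitude loading is
    positive, making coordinates reproducible across runs.
    """
    rows = _imputed_rows(matrix)
    mean = rows.mean(axis=0)
    x = rows - mean
    rank = np.linalg.matrix_rank(x, tol=1e-10)
    k = min(n_components, rank) if rank > 0 else 1
    if k < n_components:
        import warnings

        warnings.warn(
            f"similarity matrix rank {rank} < {n_components}; returning {k} components",
            stacklevel=2,
        )
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    comps = vt[:k]
    # deterministic sign: largest-|loading| element of each component positive
    for c in range(k):
        jmax = int(np.argmax(np.abs(comps[c])))
        if comps[c, jmax] < 0:
            comps[c] = -comps[c]
    coords = x @ comps.T
    var = (s[:k] ** 2) / max(len(rows) - 1, 1)
    return Embedding(coords=coords, explained_variance=var, mean=mean, components=comps)


def alt_embeddings(
    matrix: SimilarityMatrix,
    method: str = "pca",
    n_components: int = 3,
    seed: int = 0,
) -> Embedding:
    """Alternative dimensionality reductions of the same similarity rows.

    ``method`` is one of {"pca", "isomap", "spectral", "tsne"}; PCA
    dispatches to :func:`embed` exactly.  Stochastic methods are seeded.
    """
    if method == "pca":
        return embed(matrix, n_components)
    rows = _imputed_rows(matrix)
    if method == "isomap":
        from sklearn.manifold import Isomap

        coords = Isomap(n_components=n_components).fit_transform(rows)
    elif method == "spectral":
        from sklearn.manifold import SpectralEmbedding

        coords = SpectralEmbedding(
            n_components=n_components, random_state=seed
        ).fit_transform(rows)
    elif method == "tsne":
        from sklearn.manifold import TSNE

        coords = TSNE(
            n_components=min(n_components, 3),
            random_state=seed,
            init="pca",
            perplexity=min(30.0, max(5.0, len(rows) / 5.0)),
        ).fit_transform(rows)
    else:
        raise ConfigurationError(f"unknown embedding method {method!r}")
    var = coords.var(axis=0)
    return Embedding(
        coords=coords,
        explained_variance=var,
        mean=rows.mean(axis=0),
        method=method,
    )
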