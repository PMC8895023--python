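"""Synthetic SPI data: superball intensity volumes, Fourier slices, photon frames.

The particle model is the superball family ``|x/a|^p + |y/a|^p + |z/a|^p <= 1``
which interpolates between a sphere (p = 2) and a cube (p -> inf).  A single
morph parameter ``m`` in [0, 1] emulates nanoparticle melting in two phases:

* ``m`` in [0, 1/2]: the exponent falls from ``P_MAX`` to 2 (corners and
  edges round off) at constant density, so the particle volume is constant
  while the shape changes;
* ``m`` in [1/2, 1]: the particle stays spherical while its density drops
  linearly from crystalline gold (19.32 g cm^-3) to molten / randomly
  close-packed gold (17.31 g cm^-3), expanding the volume by the density
  ratio (~11.6%) at constant mass.

The total mass is conserved along the whole morph, so the endpoint volumes
differ by exactly 19.32/17.31.

Intensity volumes are |FT(density)|^2 on an oversampled cubic grid with an
odd number of voxels per axis, so that the octahedral group acts on the grid
exactly and the zero-frequency voxel sits on a grid point.  Densities are
voxelized by supersampled partial-volume averaging and the exact transfer
function of the supersampling window is divided out of the Fourier
transform, leaving grid aliasing as the only discretization error.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.special import gammaln

from .errors import BandLimitError, ConfigurationError, SizeError
from .geometry import DetectorGeometry
from .rotations import quat_to_matrix

__all__ = [
    "RHO_SOLID",
    "RHO_MELT",
    "EDGE_NM",
    "P_MAX",
    "SuperballSpec",
    "morph_spec",
    "superball_mass",
    "IntensityVolume",
    "voxelize",
    "column_voxelize",
    "separable_voxelize",
    "superball_density",
    "intensity_from_density",
    "superball_volume",
    "ellipsoid_volume",
    "box_volume",
    "reference_cube_volume",
    "trilinear_sample",
    "trilinear_operator",
    "slice_volume",
    "PhotonFrameSet",
    "sample_frames",
    "scale_to_photons",
]

RHO_SOLID = 19.32  # g cm^-3, crystalline gold
RHO_MELT = 17.31  # g cm^-3, molten / randomly close packed
EDGE_NM = 42.0  # default cube edge
P_MAX = 200.0  # superball exponent standing in for the cube end


def _superball_volume_factor(p: float) -> float:
    """Volume of the unit superball (a=1): 8 Gamma(1+1/p)^3 / Gamma(1+3/p)."""
    if np.isinf(p):
        return 8.0
    return 8.0 * float(np.exp(3.0 * gammaln(1.0 + 1.0 / p) - gammaln(1.0 + 3.0 / p)))


@dataclass(frozen=True)
class SuperballSpec:
    """Shape/density description of one particle.

    ``half_width`` (nm) is the semi-axis a; ``exponent`` the superball p
    (p=2 sphere, larger values increasingly cubic, ``np.inf`` an exact
    cube); ``density`` a relative electron density (the gold g cm^-3 values
    are used directly as dimensionless density units).
    """

    half_width: float
    exponent: float
    density: float = RHO_SOLID

    def __post_init__(self):
        if self.half_width <= 0:
            raise ConfigurationError("half_width must be positive")
        if self.exponent < 2:
            raise ConfigurationError("superball exponent must be >= 2")

    @property
    def volume_nm3(self) -> float:
        return _superball_volume_factor(self.exponent) * self.half_width**3

    @property
    def mass(self) -> float:
        return self.density * self.volume_nm3


# reference mass: the m=0 particle is an exact cube of edge 42 nm
_MASS = RHO_SOLID * EDGE_NM**3


def morph_spec(m: float) -> SuperballSpec:
    """Superball spec at morph parameter ``m`` in [0, 1] (mass conserving)."""
    if not 0.0 <= m <= 1.0:
        raise ConfigurationError("morph parameter must lie in [0, 1]")
    if m <= 0.5:
        t = 2.0 * m
        p = np.inf if t <= 0 else min(2.0 / t, P_MAX)
        rho = RHO_SOLID
    else:
        p = 2.0
        rho = RHO_SOLID + (2.0 * m - 1.0) * (RHO_MELT - RHO_SOLID)
    a = (_MASS / rho / _superball_volume_factor(p)) ** (1.0 / 3.0)
    return SuperballSpec(half_width=a, exponent=p, density=rho)


def superball_mass(spec: SuperballSpec) -> float:
    return spec.mass


@dataclass
class IntensityVolume:
    """3D Fourier intensities on a cubic, odd-sized, zero-centred grid.

    ``voxel_size`` is the reciprocal-space voxel in nm^-1 (convention
    q = 2 pi s); the zero-frequency voxel is at index (n//2,)*3.
    """

    grid: np.ndarray = field(repr=False)
    voxel_size: float
    oversampling: float

    def __post_init__(self):
        n = self.grid.shape[0]
        if self.grid.ndim != 3 or len(set(self.grid.shape)) != 1:
            raise ConfigurationError("intensity volume must be cubic")
        if n % 2 != 1:
            raise ConfigurationError("intensity volume must have odd side length")

    @property
    def n(self) -> int:
        return self.grid.shape[0]

    @property
    def center(self) -> int:
        return self.n // 2

    @property
    def q_extent(self) -> float:
        """Largest |q| component representable on the grid (nm^-1)."""
        return self.center * self.voxel_size

    @property
    def real_voxel_nm(self) -> float:
        return 2.0 * np.pi / (self.n * self.voxel_size)

    @property
    def qmag(self) -> np.ndarray:
        ax = (np.arange(self.n) - self.center) * self.voxel_size
        qx, qy, qz = np.meshgrid(ax, ax, ax, indexing="ij")
        return np.sqrt(qx**2 + qy**2 + qz**2)

    def radial_profile(self, n_bins: int | None = None) -> tuple[np.ndarray, np.ndarray]:
        """Spherically averaged intensity: (bin centres in nm^-1, mean I)."""
        q = self.qmag.ravel()
        if n_bins is None:
            n_bins = self.center + 1
        edges = np.linspace(0, q.max() + 1e-12, n_bins + 1)
        idx = np.digitize(q, edges) - 1
        sums = np.bincount(idx, weights=self.grid.ravel(), minlength=n_bins)
        counts = np.bincount(idx, minlength=n_bins)
        prof = sums / np.maximum(counts, 1)
        centres = 0.5 * (edges[:-1] + edges[1:])
        return centres[:n_bins], prof[:n_bins]


def _grid_coords(fov_nm: float, n: int) -> tuple[float, np.ndarray]:
    if n % 2 != 1:
        raise ConfigurationError("grid side must be odd")
    voxel = fov_nm / n
    return voxel, (np.arange(n) - n // 2) * voxel


def voxelize(indicator, fov_nm: float, n: int, supersample: int = 4) -> np.ndarray:
    """Partial-volume fractions of ``indicator`` by 3D subsample counting.

    ``indicator(x, y, z)`` takes coordinate arrays in nm (origin at the grid
    centre) and returns a boolean in/out array.  Each voxel is subdivided
    ``supersample`` times per axis and the in-fractions averaged.  Use
    :func:`column_voxelize` when the x-extent of the body has a closed form;
    it is both faster and far more accurate.
    """
    k = int(supersample)
    voxel, coarse = _grid_coords(fov_nm, n)
    offsets = ((np.arange(k) + 0.5) / k - 0.5) * voxel
    fine = (coarse[:, None] + offsets[None, :]).ravel()  # n*k per axis
    out = np.empty((n, n, n))
    yy = fine[None, :, None]
    zz = fine[None, None, :]
    for ix in range(n):
        xs = coarse[ix] + offsets
        frac = indicator(xs[:, None, None], yy, zz)
        out[ix] = frac.reshape(k, n, k, n, k).mean(axis=(0, 2, 4))
    return out


def column_voxelize(xmax_fn, fov_nm: float, n: int, supersample: int = 8) -> np.ndarray:
    """Partial-volume fractions for a body symmetric in x about x = 0.

    ``xmax_fn(y, z)`` returns the half-extent of the body along x at a given
    (y, z) (zero outside).  The overlap of each voxel's x-interval with
    [-xmax, xmax] is computed exactly (a continuous box filter along x),
    while y and z are midpoint-supersampled ``supersample`` times.  The
    matching deconvolution windows are ('sinc', 'dirichlet', 'dirichlet').
    """
    k = int(supersample)
    voxel, coarse = _grid_coords(fov_nm, n)
    offsets = ((np.arange(k) + 0.5) / k - 0.5) * voxel
    fine = (coarse[:, None] + offsets[None, :]).ravel()
    xm = xmax_fn(fine[:, None], fine[None, :])  # (n*k, n*k)
    lo = coarse - voxel / 2.0
    hi = coarse + voxel / 2.0
    out = np.empty((n, n, n))
    for ix in range(n):
        overlap = np.minimum(hi[ix], xm) - np.maximum(lo[ix], -xm)
        np.clip(overlap, 0.0, None, out=overlap)
        out[ix] = overlap.reshape(n, k, n, k).mean(axis=(1, 3)) / voxel
    return out


def separable_voxelize(half_widths_nm, fov_nm: float, n: int) -> np.ndarray:
    """Exact partial-volume fractions of an axis-aligned box (outer product).

    The construction is an exact continuous box filter along every axis;
    deconvolve with ('sinc', 'sinc', 'sinc').
    """
    voxel, coarse = _grid_coords(fov_nm, n)
    ws = []
    for h in half_widths_nm:
        lo = coarse - voxel / 2.0
        hi = coarse + voxel / 2.0
        w = np.clip(np.minimum(hi, h) - np.maximum(lo, -h), 0.0, None) / voxel
        ws.append(w)
    return ws[0][:, None, None] * ws[1][None, :, None] * ws[2][None, None, :]


def _superball_xmax(spec: SuperballSpec):
    a, p = spec.half_width, spec.exponent

    def xmax(y, z):
        with np.errstate(over="ignore"):
            s = (np.abs(y) / a) ** p + (np.abs(z) / a) ** p
        s = np.where(np.isfinite(s), s, 2.0)
        return a * np.where(s < 1.0, (1.0 - np.minimum(s, 1.0)) ** (1.0 / p), 0.0)

    return xmax


def superball_density(
    spec: SuperballSpec, fov_nm: float, n: int, supersample: int = 8
) -> tuple[np.ndarray, tuple]:
    """Real-space density grid and the matching deconvolution windows.

    Exact cubes (p = inf) use the exact separable construction; finite
    exponents use exact-x column integration.  Nearly flat faces (large p)
    are resolved with a denser transverse supersampling.
    """
    if np.isinf(spec.exponent):
        frac = separable_voxelize((spec.half_width,) * 3, fov_nm, n)
        return spec.density * frac, ("sinc", "sinc", "sinc")
    k = int(supersample)
    if spec.exponent > 16:
        k = max(k, 24)
    frac = column_voxelize(_superball_xmax(spec), fov_nm, n, k)
    return spec.density * frac, ("sinc", ("dirichlet", k), ("dirichlet", k))


def _window_1d(n: int, kind) -> np.ndarray:
    """1D voxelization transfer function (fftshifted), f in radians/voxel."""
    f = 2.0 * np.pi * np.fft.fftshift(np.fft.fftfreq(n))
    w = np.ones(n)
    nz = f != 0
    if kind is None:
        return w
    if kind == "sinc":
        w[nz] = np.sin(f[nz] / 2.0) / (f[nz] / 2.0)
        return w
    if isinstance(kind, tuple) and kind[0] == "dirichlet":
        k = int(kind[1])
        w[nz] = np.sin(f[nz] / 2.0) / (k * np.sin(f[nz] / (2.0 * k)))
        return w
    raise ConfigurationError(f"unknown window kind {kind!r}")


def intensity_from_density(
    density: np.ndarray,
    voxel_nm: float,
    oversampling: float,
    windows: tuple | None = None,
) -> IntensityVolume:
    """|FT(density)|^2 with physical normalization F(0) = total mass.

    ``windows`` are the per-axis voxelization transfer functions to divide
    out (as returned by the voxelizers), leaving grid aliasing as the only
    remaining discretization error.
    """
    n = density.shape[0]
    f = np.fft.fftshift(np.fft.fftn(np.fft.ifftshift(density))) * voxel_nm**3
    if windows is not None:
        for ax, kind in enumerate(windows):
            w = _window_1d(n, kind)
            shape = [1, 1, 1]
            shape[ax] = n
            f = f / w.reshape(shape)
    q_voxel = 2.0 * np.pi / (n * voxel_nm)
    return IntensityVolume(
        grid=np.abs(f) ** 2, voxel_size=q_voxel, oversampling=oversampling
    )


def _choose_n(fov_nm: float, geometry: DetectorGeometry | None, n: int | None) -> int:
    if n is not None:
        if n % 2 != 1:
            raise ConfigurationError("volume grid side must be odd")
        return n
    q_voxel = 2.0 * np.pi / fov_nm
    q_target = geometry.q_max if geometry is not None else 2.0 * np.pi / fov_nm * 25
    half = int(np.ceil(q_target / q_voxel)) + 2
    return 2 * half + 1


def superball_volume(
    spec: SuperballSpec,
    geometry: DetectorGeometry | None = None,
    oversampling: float = 3.0,
    n: int | None = None,
    fov_nm: float | None = None,
    supersample: int = 8,
    refine: int = 1,
) -> IntensityVolume:
    """Fourier intensity volume of a superball particle.

    The field of view defaults to ``oversampling`` times the particle's axis
    extent (2a); when a geometry is given, the grid is made large enough for
    every detector pixel to fall inside the volume's band limit.

    ``refine`` (odd) voxelizes on a ``refine``-times finer grid with the
    same field of view and keeps only the central band of the transform,
    pushing grid aliases out to ``2 * refine`` times the band limit; use it
    when intensities are compared against closed forms.
    """
    extent = 2.0 * spec.half_width
    if fov_nm is None:
        fov_nm = oversampling * extent
    if extent >= fov_nm:
        raise SizeError(
            f"particle extent {extent:.1f} nm does not fit the {fov_nm:.1f} nm field of view"
        )
    n = _choose_n(fov_nm, geometry, n)
    if refine % 2 != 1 or refine < 1:
        raise ConfigurationError("refine must be an odd positive integer")
    n_f = n * refine
    rho, windows = superball_density(spec, fov_nm, n_f, supersample)
    vol = intensity_from_density(rho, fov_nm / n_f, fov_nm / extent, windows)
    if refine == 1:
        return vol
    c_f, c = vol.center, n // 2
    crop = vol.grid[c_f - c : c_f + c + 1, c_f - c : c_f + c + 1, c_f - c : c_f + c + 1]
    return IntensityVolume(
        grid=np.ascontiguousarray(crop),
        voxel_size=vol.voxel_size,
        oversampling=vol.oversampling,
    )


def ellipsoid_volume(
    half_axes_nm: tuple[float, float, float],
    density: float = RHO_SOLID,
    geometry: DetectorGeometry | None = None,
    oversampling: float = 3.0,
    n: int | None = None,
    supersample: int = 4,
) -> IntensityVolume:
    """Fourier intensity volume of a (generally triaxial) ellipsoid."""
    a, b, c = half_axes_nm
    fov = oversampling * 2.0 * max(half_axes_nm)
    n = _choose_n(fov, geometry, n)

    def xmax(y, z):
        s = (y / b) ** 2 + (z / c) ** 2
        return a * np.sqrt(np.clip(1.0 - s, 0.0, None))

    rho = density * column_voxelize(xmax, fov, n, supersample)
    windows = ("sinc", ("dirichlet", supersample), ("dirichlet", supersample))
    return intensity_from_density(rho, fov / n, oversampling, windows)


def box_volume(
    half_widths_nm: tuple[float, float, float],
    density: float = RHO_SOLID,
    geometry: DetectorGeometry | None = None,
    oversampling: float = 3.0,
    n: int | None = None,
    supersample: int = 4,
) -> IntensityVolume:
    """Fourier intensity volume of a rectangular box (e.g. a cube dimer)."""
    fov = oversampling * 2.0 * max(half_widths_nm)
    n = _choose_n(fov, geometry, n)
    rho = density * separable_voxelize(half_widths_nm, fov, n)
    return intensity_from_density(rho, fov / n, oversampling, ("sinc", "sinc", "sinc"))


def reference_cube_volume(
    geometry: DetectorGeometry | None = None,
    edge_nm: float = EDGE_NM,
    oversampling: float = 3.0,
    n: int | None = None,
    supersample: int = 4,
) -> IntensityVolume:
    """Intensity volume of the ideal cube used as the orientation reference."""
    spec = SuperballSpec(half_width=edge_nm / 2.0, exponent=np.inf)
    return superball_volume(
        spec, geometry=geometry, oversampling=oversampling, n=n, supersample=supersample
    )


# ---------------------------------------------------------------------------
# slicing


def trilinear_sample(grid: np.ndarray, pts_vox: np.ndarray) -> np.ndarray:
    """Trilinear interpolation of ``grid`` at fractional voxel coordinates."""
    idx, w = trilinear_operator(pts_vox, grid.shape)
    return (grid.ravel()[idx] * w).sum(axis=1)


def trilinear_operator(
    pts_vox: np.ndarray, shape: tuple[int, int, int]
) -> tuple[np.ndarray, np.ndarray]:
    """Flat indices and weights of the trilinear stencil for each point.

    Returns ``(idx, w)`` of shape (M, 8) such that sampling equals
    ``(grid.ravel()[idx] * w).sum(1)``.  Points must lie inside the grid.
    """
    pts = np.asarray(pts_vox, dtype=float)
    n0, n1, n2 = shape
    if (pts.min() < -1e-9) or np.any(pts.max(axis=0) > np.array(shape) - 1 + 1e-9):
        raise BandLimitError("sample points outside the volume extent")
    pts = np.clip(pts, 0, np.array(shape, dtype=float) - 1)
    base = np.minimum(np.floor(pts).astype(np.int64), np.array(shape) - 2)
    base = np.maximum(base, 0)
    frac = pts - base
    idx = np.empty((len(pts), 8), dtype=np.int64)
    w = np.empty((len(pts), 8))
    for c, (dx, dy, dz) in enumerate(
        [(i, j, k) for i in (0, 1) for j in (0, 1) for k in (0, 1)]
    ):
        idx[:, c] = ((base[:, 0] + dx) * n1 + (base[:, 1] + dy)) * n2 + (base[:, 2] + dz)
        wx = frac[:, 0] if dx else 1.0 - frac[:, 0]
        wy = frac[:, 1] if dy else 1.0 - frac[:, 1]
        wz = frac[:, 2] if dz else 1.0 - frac[:, 2]
        w[:, c] = wx * wy * wz
    return idx, w


def slice_pts_vox(
    volume: IntensityVolume, quat: np.ndarray, geometry: DetectorGeometry
) -> np.ndarray:
    """Voxel coordinates of the rotated flat detector slice through a volume."""
    q = np.asarray(quat, dtype=float)
    if abs(np.linalg.norm(q) - 1.0) > 1e-6:
        raise ConfigurationError("orientation quaternion must be normalized")
    rot = quat_to_matrix(q)
    pts = geometry.qmap.reshape(-1, 3) @ rot.T  # sample V at R q_px
    return pts / volume.voxel_size + volume.center


def slice_volume(
    volume: IntensityVolume, quat: np.ndarray, geometry: DetectorGeometry
) -> np.ndarray:
    """Flat central Fourier slice of a volume at one orientation.

    Valid at small scattering angles where Ewald-sphere curvature is
    negligible; masked detector pixels are set to NaN.
    """
    pts = slice_pts_vox(volume, quat, geometry)
    vals = trilinear_sample(volume.grid, pts).reshape(geometry.shape)
    vals[~geometry.good] = np.nan
    return vals


# ---------------------------------------------------------------------------
# photon sampling


@dataclass
class PhotonFrameSet:
    """Sparse per-frame photon counts with (synthetic-only) ground truth.

    ``counts`` is CSR of shape (n_frames, n_pixels); ``truth`` may hold
    per-frame arrays such as 'quat' (n, 4), 'morph', 'label', 'fluence'.
    """

    counts: sparse.csr_matrix = field(repr=False)
    geometry: DetectorGeometry
    truth: dict = field(default_factory=dict)

    @property
    def n_frames(self) -> int:
        return self.counts.shape[0]

    @property
    def photons_per_frame(self) -> np.ndarray:
        return np.asarray(self.counts.sum(axis=1)).ravel()

    def subset(self, idx: np.ndarray) -> "PhotonFrameSet":
        truth = {k: np.asarray(v)[idx] for k, v in self.truth.items()}
        return PhotonFrameSet(self.counts[idx], self.geometry, truth)


def scale_to_photons(
    pattern: np.ndarray, geometry: DetectorGeometry, mean_photons: float
) -> np.ndarray:
    """Rescale a pattern so its unmasked sum equals ``mean_photons``."""
    good = geometry.good
    total = np.nansum(np.where(good, pattern, 0.0))
    if total <= 0:
        raise ConfigurationError("pattern has no positive intensity on good pixels")
    return pattern * (mean_photons / total)


def sample_frames(
    patterns: np.ndarray,
    n_frames: int,
    geometry: DetectorGeometry,
    seed: int,
    fluence: float | np.ndarray = 1.0,
    fluence_sigma: float = 0.0,
    pattern_ids: np.ndarray | None = None,
    truth: dict | None = None,
) -> PhotonFrameSet:
    """Poisson photon frames from one or more rate patterns.

    ``patterns`` is (H, W) or (P, H, W); per-frame rates are
    ``fluence * patterns[pattern_ids]`` with masked pixels carrying no
    photons.  If ``fluence_sigma > 0`` the per-frame fluence is drawn
    lognormal with unit mean, emulating shot-to-shot pulse variation.
    """
    if n_frames < 1:
        raise ConfigurationError("n_frames must be >= 1")
    rng = np.random.default_rng(seed)
    patterns = np.asarray(patterns, dtype=float)
    if patterns.ndim == 2:
        patterns = patterns[None]
    rates = np.where(geometry.good[None], patterns, 0.0)
    rates = np.nan_to_num(rates, nan=0.0)
    n_pix = rates.shape[1] * rates.shape[2]
    if pattern_ids is None:
        pattern_ids = rng.integers(0, len(rates), size=n_frames)
    phi = np.broadcast_to(np.asarray(fluence, dtype=float), (n_frames,)).copy()
    if np.any(phi < 0) or (np.all(phi == 0) and fluence_sigma > 0):
        raise ConfigurationError("fluence must be non-negative")
    if np.isscalar(fluence) and fluence <= 0 and fluence_sigma > 0:
        raise ConfigurationError("fluence must be strictly positive")
    if fluence_sigma > 0:
        # lognormal with unit mean
        phi = phi * rng.lognormal(-0.5 * fluence_sigma**2, fluence_sigma, n_frames)
    flat = rates.reshape(len(rates), n_pix)
    indptr = [0]
    indices: list[np.ndarray] = []
    data: list[np.ndarray] = []
    for f in range(n_frames):
        lam = phi[f] * flat[pattern_ids[f]]
        counts = rng.poisson(lam)
        nz = np.nonzero(counts)[0]
        indices.append(nz)
        data.append(counts[nz])
        indptr.append(indptr[-1] + len(nz))
    counts = sparse.csr_matrix(
        (
            np.concatenate(data) if data else np.array([]),
            np.concatenate(indices) if indices else np.array([]),
            np.array(indptr),
        ),
        shape=(n_frames, n_pix),
        dtype=np.int64,
    )
    full_truth = {"fluence": phi, "pattern_id": np.asarray(pattern_ids)}
    if truth:
        for k, v in truth.items():
            full_truth[k] = np.asarray(v)[pattern_ids] if np.asarray(v).shape[0] == len(rates) else np.asarray(v)
    return PhotonFrameSet(counts=counts, geometry=geometry, truth=full_truth)
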