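"""Orientation and gain estimation against a reference intensity volume.

Each 2D class average is correlated (Pearson, log-intensity domain)
against flat central slices of a reference volume — by default an ideal
42 nm cube — over a quaternion grid restricted to the octahedral
fundamental domain.  The best-correlating orientation is recorded together
with the *gain*, the ratio of the best to the mean correlation over all
grid orientations.  Patterns from particles resembling the reference
correlate sharply at one orientation and poorly elsewhere, so the gain
doubles as a "cubicness" score; as a ratio of Pearson coefficients it is
invariant to affine rescaling of the average.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .classify2d import ClassAverage2D
from .errors import ConfigurationError, UndefinedSimilarityError
from .geometry import DetectorGeometry
from .rotations import QuaternionGrid, build_quaternion_grid
from .simulate import IntensityVolume, slice_pts_vox, trilinear_operator, trilinear_sample

__all__ = [
    "OrientationEstimate",
    "ReferenceSliceBank",
    "estimate_orientation",
    "estimate_orientations",
    "build_quaternion_grid",
]


@dataclass
class OrientationEstimate:
    """Best-matching orientation of one average against the reference."""

    quat: np.ndarray
    gain: float
    best_cc: float
    grid_index: int


class ReferenceSliceBank:
    """Ring-standardized reference slices for every grid orientation.

    Log intensities are standardized per radial annulus (same domain
    decision as the common-line similarity): the steep radial falloff is
    common to every compact particle and would otherwise saturate the
    correlation near 1 for any orientation, washing out the orientation
    signal.  Precomputing the bank makes orientation estimation for a
    whole set of averages a single matrix product per average set.
    """

    def __init__(
        self,
        reference: IntensityVolume,
        grid: QuaternionGrid,
        geometry: DetectorGeometry,
        n_annuli: int | None = None,
    ):
        self.grid = grid
        self.geometry = geometry
        good = geometry.good.ravel()
        if n_annuli is None:
            n_annuli = min(geometry.shape) // 2
        r = geometry.radius_px.ravel()[good]
        edges = np.linspace(0.0, r.max() + 1e-9, n_annuli + 1)
        self._annulus = np.digitize(r, edges) - 1
        self._n_annuli = n_annuli
        bank = np.empty((len(grid), int(good.sum())))
        qpix = geometry.qmap.reshape(-1, 3)[good]
        flat = reference.grid.ravel()
        c = reference.center
        from .rotations import quat_to_matrix

        chunk = 512
        for lo in range(0, len(grid), chunk):
            quats = grid.quats[lo : lo + chunk]
            rots = np.atleast_3d(quat_to_matrix(quats))
            # (B, n_good, 3) voxel coordinates of every chunk slice
            pts = np.einsum("pj,bij->bpi", qpix, rots) / reference.voxel_size + c
            idx, w = trilinear_operator(pts.reshape(-1, 3), reference.grid.shape)
            vals = (flat[idx] * w).sum(axis=1).reshape(len(quats), -1)
            for k in range(len(quats)):
                bank[lo + k] = self._standardize(vals[k])
        bank -= bank.mean(axis=1, keepdims=True)
        norms = np.linalg.norm(bank, axis=1, keepdims=True)
        if np.any(norms == 0):
            raise ConfigurationError("reference slice with zero variance")
        self.bank = bank / norms
        self._good = good

    def _standardize(self, vals: np.ndarray) -> np.ndarray:
        """log(1+I), then zero-mean unit-spread per radial annulus."""
        x = np.log1p(np.clip(vals, 0.0, None))
        idx = self._annulus
        cnt = np.bincount(idx, minlength=self._n_annuli).astype(float)
        mean = np.bincount(idx, weights=x, minlength=self._n_annuli) / np.maximum(cnt, 1)
        dev = x - mean[idx]
        var = np.bincount(idx, weights=dev**2, minlength=self._n_annuli) / np.maximum(cnt, 1)
        std = np.sqrt(var)
        soft = std + 0.1 * max(std[cnt > 1].mean() if (cnt > 1).any() else 1.0, 1e-12)
        return dev / soft[idx]

    def correlate(self, average: ClassAverage2D) -> np.ndarray:
        """Pearson CC of one average against every grid orientation."""
        x = np.asarray(average.intensity, dtype=float).ravel()[self._good]
        if np.ptp(x[np.isfinite(x)]) == 0:
            raise UndefinedSimilarityError("average has no intensity variance")
        x = self._standardize(np.nan_to_num(x, nan=0.0))
        x = x - x.mean()
        nx = np.linalg.norm(x)
        if nx == 0:
            raise UndefinedSimilarityError("average has no intensity variance")
        return self.bank @ (x / nx)


def estimate_orientation(
    average: ClassAverage2D,
    reference: IntensityVolume,
    grid: QuaternionGrid,
    geometry: DetectorGeometry,
    bank: ReferenceSliceBank | None = None,
) -> OrientationEstimate:
    """Best-CC orientation and gain of a single average."""
    if bank is None:
        bank = ReferenceSliceBank(reference, grid, geometry)
    cc = bank.correlate(average)
    i = int(np.argmax(cc))
    mean_cc = float(cc.mean())
    best = float(cc[i])
    gain = best / mean_cc if mean_cc != 0 else np.inf
    # grid quaternions are already fundamental-domain representatives
    return OrientationEstimate(quat=grid.quats[i], gain=gain, best_cc=best, grid_index=i)


def estimate_orientations(
    averages: list[ClassAverage2D],
    reference: IntensityVolume,
    grid: QuaternionGrid,
    geometry: DetectorGeometry,
) -> list[OrientationEstimate]:
    """Orientation estimates for a list of averages (shared slice bank)."""
    bank = ReferenceSliceBank(reference, grid, geometry)
    return [estimate_orientation(a, reference, grid, geometry, bank) for a in averages]
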