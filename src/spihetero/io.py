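"""File formats: sparse-photon HDF5, MRC volumes, HDF5 result tables.

Photon frames use the emc-file convention: per-frame lists of pixels with
exactly one photon (``place_ones``) and pixels with multiple photons
(``place_multi`` + ``count_multi``), plus ``num_pix``.  Synthetic ground
truth lives in a ``ground_truth`` group.  Volumes go to CCP4/MRC maps with
the voxel size in the cell header.
"""

from __future__ import annotations

import numpy as np
from scipy import sparse

from .classify2d import BootstrapEnsemble, ClassAverage2D
from .clpca import Embedding, SimilarityMatrix
from .geometry import DetectorGeometry
from .refmatch import OrientationEstimate
from .simulate import IntensityVolume, PhotonFrameSet

__all__ = [
    "write_photons",
    "read_photons",
    "write_mrc",
    "read_mrc",
    "write_averages",
    "read_averages",
    "write_similarity",
    "read_similarity",
    "write_embedding",
    "read_embedding",
    "write_orientations",
    "read_orientations",
]


def _geometry_to_group(grp, geometry: DetectorGeometry) -> None:
    grp.attrs["photon_energy_keV"] = geometry.photon_energy_keV
    grp.attrs["detector_distance_mm"] = geometry.detector_distance_mm
    grp.attrs["pixel_size_mm"] = geometry.pixel_size_mm
    grp.attrs["shape"] = geometry.shape
    grp.create_dataset("mask", data=geometry.mask, compression="gzip")
    grp.create_dataset("qmap", data=geometry.qmap, compression="gzip")


def _geometry_from_group(grp) -> DetectorGeometry:
    return DetectorGeometry(
        photon_energy_keV=float(grp.attrs["photon_energy_keV"]),
        detector_distance_mm=float(grp.attrs["detector_distance_mm"]),
        pixel_size_mm=float(grp.attrs["pixel_size_mm"]),
        shape=tuple(int(v) for v in grp.attrs["shape"]),
        mask=grp["mask"][...],
        qmap=grp["qmap"][...],
    )


def write_photons(path, frames: PhotonFrameSet) -> None:
    import h5py

    counts = frames.counts.tocsr()
    n_frames, n_pix = counts.shape
    vlen_i = h5py.vlen_dtype(np.int32)
    with h5py.File(path, "w") as f:
        f.attrs["num_pix"] = n_pix
        po = f.create_dataset("place_ones", (n_frames,), dtype=vlen_i)
        pm = f.create_dataset("place_multi", (n_frames,), dtype=vlen_i)
        cm = f.create_dataset("count_multi", (n_frames,), dtype=vlen_i)
        for i in range(n_frames):
            row = counts[i]
            pix = row.indices
            cnt = row.data
            ones = cnt == 1
            po[i] = pix[ones].astype(np.int32)
            pm[i] = pix[~ones].astype(np.int32)
            cm[i] = cnt[~ones].astype(np.int32)
        _geometry_to_group(f.create_group("geometry"), frames.geometry)
        gt = f.create_group("ground_truth")
        for k, v in frames.truth.items():
            gt.create_dataset(k, data=np.asarray(v))


def read_photons(path) -> PhotonFrameSet:
    import h5py

    with h5py.File(path, "r") as f:
        n_pix = int(f.attrs["num_pix"])
        po, pm, cm = f["place_ones"], f["place_multi"], f["count_multi"]
        n_frames = len(po)
        indptr = [0]
        indices, data = [], []
        for i in range(n_frames):
            pix = np.concatenate([po[i], pm[i]])
            cnt = np.concatenate([np.ones(len(po[i]), dtype=np.int64), cm[i]])
            order = np.argsort(pix)
            indices.append(pix[order])
            data.append(cnt[order])
            indptr.append(indptr[-1] + len(pix))
        counts = sparse.csr_matrix(
            (
                np.concatenate(data) if data else np.array([]),
                np.concatenate(indices) if indices else np.array([]),
                np.array(indptr),
            ),
            shape=(n_frames, n_pix),
            dtype=np.int64,
        )
        geometry = _geometry_from_group(f["geometry"])
        truth = {k: f["ground_truth"][k][...] for k in f["ground_truth"]}
    return PhotonFrameSet(counts=counts, geometry=geometry, truth=truth)


def write_mrc(path, volume: IntensityVolume) -> None:
    """Write a volume as a CCP4/MRC map; the cell encodes the q voxel size."""
    import gemmi

    n = volume.n
    grid = gemmi.FloatGrid(n, n, n)
    arr = np.array(grid, copy=False)
    arr[...] = volume.grid.astype(np.float32)
    cell = n * volume.voxel_size
    grid.set_unit_cell(gemmi.UnitCell(cell, cell, cell, 90, 90, 90))
    m = gemmi.Ccp4Map()
    m.grid = grid
    m.update_ccp4_header()
    m.write_ccp4_map(str(path))


def read_mrc(path, oversampling: float = 3.0) -> IntensityVolume:
    import gemmi

    m = gemmi.read_ccp4_map(str(path))
    arr = np.array(m.grid, copy=True).astype(float)
    n = arr.shape[0]
    voxel = m.grid.unit_cell.a / n
    return IntensityVolume(grid=arr, voxel_size=voxel, oversampling=oversampling)


def write_averages(path, averages: list[ClassAverage2D], extra: dict | None = None) -> None:
    import h5py

    with h5py.File(path, "w") as f:
        stack = np.stack([a.intensity for a in averages])
        f.create_dataset("intensity", data=stack, compression="gzip")
        f.create_dataset("occupancy", data=np.array([a.occupancy for a in averages]))
        if averages[0].gap_filled is not None:
            f.create_dataset("gap_filled", data=averages[0].gap_filled)
        if extra:
            g = f.create_group("extra")
            for k, v in extra.items():
                g.create_dataset(k, data=np.asarray(v))


def read_averages(path) -> tuple[list[ClassAverage2D], dict]:
    import h5py

    with h5py.File(path, "r") as f:
        stack = f["intensity"][...]
        occ = f["occupancy"][...]
        gap = f["gap_filled"][...] if "gap_filled" in f else None
        extra = {k: f["extra"][k][...] for k in f.get("extra", [])}
    averages = [
        ClassAverage2D(intensity=stack[i], occupancy=float(occ[i]), gap_filled=gap)
        for i in range(len(stack))
    ]
    return averages, extra


def write_similarity(path, matrix: SimilarityMatrix) -> None:
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("cc", data=matrix.cc, compression="gzip")
        f.create_dataset("angles", data=matrix.angles, compression="gzip")
        f.create_dataset("defined", data=matrix.defined)


def read_similarity(path) -> SimilarityMatrix:
    import h5py

    with h5py.File(path, "r") as f:
        return SimilarityMatrix(
            cc=f["cc"][...], angles=f["angles"][...], defined=f["defined"][...]
        )


def write_embedding(path, embedding: Embedding) -> None:
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("coords", data=embedding.coords)
        f.create_dataset("explained_variance", data=embedding.explained_variance)
        f.create_dataset("mean", data=embedding.mean)
        if embedding.components is not None:
            f.create_dataset("components", data=embedding.components)
        f.attrs["method"] = embedding.method


def read_embedding(path) -> Embedding:
    import h5py

    with h5py.File(path, "r") as f:
        return Embedding(
            coords=f["coords"][...],
            explained_variance=f["explained_variance"][...],
            mean=f["mean"][...],
            components=f["components"][...] if "components" in f else None,
            method=str(f.attrs.get("method", "pca")),
        )


def write_orientations(path, estimates: list[OrientationEstimate]) -> None:
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("quat", data=np.stack([e.quat for e in estimates]))
        f.create_dataset("gain", data=np.array([e.gain for e in estimates]))
        f.create_dataset("best_cc", data=np.array([e.best_cc for e in estimates]))
        f.create_dataset("grid_index", data=np.array([e.grid_index for e in estimates]))


def read_orientations(path) -> list[OrientationEstimate]:
    import h5py

    with h5py.File(path, "r") as f:
        quat, gain = f["quat"][...], f["gain"][...]
        cc, gi = f["best_cc"][...], f["grid_index"][...]
    return [
        OrientationEstimate(quat=quat[i], gain=float(gain[i]), best_cc=float(cc[i]), grid_index=int(gi[i]))
        for i in range(len(gain))
    ]
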