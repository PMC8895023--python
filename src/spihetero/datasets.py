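"""Planted synthetic ensembles with known ground truth.

These builders emulate the products of the upstream pipeline (class
averages, photon frame sets) directly from the particle models, so every
downstream stage can be tested against known shape, orientation, morph
parameter and fluence.  Synthetic class averages are noiseless Fourier
slices plus Poisson noise at a chosen effective photon budget, with gap
pixels filled from the noiseless model (emulating the model-filled gaps of
EMC averages).
"""

from __future__ import annotations

import numpy as np

from .classify2d import ClassAverage2D
from .geometry import DetectorGeometry
from .simulate import (
    EDGE_NM,
    IntensityVolume,
    PhotonFrameSet,
    SuperballSpec,
    box_volume,
    ellipsoid_volume,
    morph_spec,
    sample_frames,
    scale_to_photons,
    slice_volume,
    superball_volume,
)

__all__ = [
    "random_quats",
    "synthetic_average",
    "melting_series_averages",
    "shape_zoo_averages",
    "graded_sphere_averages",
    "planted_frames",
]


def random_quats(n: int, rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotations as scalar-first unit quaternions."""
    q = rng.normal(size=(n, 4))
    q /= np.linalg.norm(q, axis=1, keepdims=True)
    q[q[:, 0] < 0] *= -1
    return q


def synthetic_average(
    volume: IntensityVolume,
    quat: np.ndarray,
    geometry: DetectorGeometry,
    rng: np.random.Generator | None = None,
    total_photons: float | None = None,
) -> ClassAverage2D:
    """One synthetic class average: a Fourier slice with optional noise.

    ``total_photons`` sets the effective photon budget of the average (the
    summed counts of its notional member frames); None gives a noiseless
    average.  Gap/beamstop pixels carry the noiseless model value and are
    flagged, like the model-filled gaps of EMC output.
    """
    clean = slice_volume_nomask(volume, quat, geometry)
    if total_photons is not None:
        s = total_photons / np.where(geometry.good, clean, 0.0).sum()
        noisy = rng.poisson(np.clip(clean * s, 0, None)).astype(float) / s
        out = np.where(geometry.good, noisy, clean)
    else:
        out = clean
    return ClassAverage2D(
        intensity=out,
        occupancy=1.0,
        gap_filled=~geometry.good,
        meta={"synthetic": True},
    )


def slice_volume_nomask(volume, quat, geometry):
    from .simulate import slice_pts_vox, trilinear_sample

    pts = slice_pts_vox(volume, quat, geometry)
    return trilinear_sample(volume.grid, pts).reshape(geometry.shape)


def melting_series_averages(
    n_averages: int,
    geometry: DetectorGeometry,
    seed: int,
    n_morphs: int = 40,
    total_photons: float | None = 3.0e6,
    oversampling: float = 3.0,
    volume_n: int | None = None,
    m_values: np.ndarray | None = None,
) -> tuple[list[ClassAverage2D], dict]:
    """Synthetic melting series: superball morphs in random orientations.

    Morph parameters are drawn from ``n_morphs`` evenly spaced stages in
    [0, 1] (uniform occupation -- the stage distribution of a real melting
    ensemble is unknown and configurable); each average gets a random
    orientation.  Returns the averages and a ground-truth dict with
    'morph', 'quat' and 'volume_id'.
    """
    rng = np.random.default_rng(seed)
    if m_values is None:
        m_values = np.linspace(0.0, 1.0, n_morphs)
    volumes = [
        superball_volume(
            morph_spec(float(m)), geometry=geometry, oversampling=oversampling, n=volume_n
        )
        for m in m_values
    ]
    vol_ids = rng.integers(0, len(volumes), size=n_averages)
    quats = random_quats(n_averages, rng)
    averages = [
        synthetic_average(volumes[v], quats[i], geometry, rng, total_photons)
        for i, v in enumerate(vol_ids)
    ]
    truth = {
        "morph": np.asarray(m_values)[vol_ids],
        "quat": quats,
        "volume_id": vol_ids,
        "m_values": np.asarray(m_values),
    }
    return averages, truth


_ZOO_BUILDERS = {
    "cube": lambda geom, os_: superball_volume(
        morph_spec(0.0), geometry=geom, oversampling=os_
    ),
    "sphere": lambda geom, os_: superball_volume(
        morph_spec(1.0), geometry=geom, oversampling=os_
    ),
    "ellipsoid": lambda geom, os_: ellipsoid_volume(
        (27.0, 20.0, 15.0), geometry=geom, oversampling=os_
    ),
    "dimer": lambda geom, os_: box_volume(
        (30.0, 15.0, 15.0), geometry=geom, oversampling=os_
    ),
}


def shape_zoo_averages(
    n_per_class: int,
    geometry: DetectorGeometry,
    seed: int,
    classes: tuple[str, ...] = ("cube", "sphere", "ellipsoid", "dimer"),
    total_photons: float | None = 3.0e6,
    oversampling: float = 3.0,
) -> tuple[list[ClassAverage2D], np.ndarray, dict]:
    """Four-shape planted ensemble (cubes, spheres, ellipsoids, cube dimers).

    The ellipsoid and dimer classes emulate the 'contaminants' of a real
    nanoparticle run.  The dimer is built from 30 nm sub-cubes: a dimer of
    the primary 42 nm cubes would share an exact common line with every
    42 nm cube pattern (its central slice perpendicular to the long axis
    is the cube transform up to scale), making the two classes
    structurally inseparable for any common-line metric by construction.
    Returns (averages, integer labels, truth).
    """
    rng = np.random.default_rng(seed)
    averages: list[ClassAverage2D] = []
    labels = []
    quats_all = []
    for ci, cname in enumerate(classes):
        vol = _ZOO_BUILDERS[cname](geometry, oversampling)
        quats = random_quats(n_per_class, rng)
        for q in quats:
            averages.append(synthetic_average(vol, q, geometry, rng, total_photons))
            labels.append(ci)
        quats_all.append(quats)
    truth = {"classes": list(classes), "quat": np.concatenate(quats_all)}
    return averages, np.asarray(labels), truth


def graded_sphere_averages(
    n_diameters: int,
    n_per_diameter: int,
    geometry: DetectorGeometry,
    seed: int,
    diameter_range_nm: tuple[float, float] = (40.0, 64.0),
    total_photons: float | None = 3.0e6,
    oversampling: float = 3.0,
) -> tuple[list[ClassAverage2D], np.ndarray]:
    """Spheres of graded diameters (for the size-axis property of CLPCA)."""
    rng = np.random.default_rng(seed)
    diameters = np.linspace(*diameter_range_nm, n_diameters)
    averages: list[ClassAverage2D] = []
    diams = []
    for d in diameters:
        vol = superball_volume(
            SuperballSpec(half_width=d / 2.0, exponent=2.0),
            geometry=geometry,
            oversampling=oversampling,
        )
        for q in random_quats(n_per_diameter, rng):
            averages.append(synthetic_average(vol, q, geometry, rng, total_photons))
            diams.append(d)
    return averages, np.asarray(diams)


def planted_frames(
    n_frames: int,
    geometry: DetectorGeometry,
    seed: int,
    n_patterns: int = 4,
    mean_photons: float = 300.0,
    fluence_sigma: float = 0.3,
    n_inplane: int = 64,
    volumes: list[IntensityVolume] | None = None,
) -> PhotonFrameSet:
    """Sparse photon frames drawn from a few planted patterns.

    ``n_patterns`` distinct cube orientations provide the base patterns;
    each frame applies a random in-plane rotation (from a grid of
    ``n_inplane`` angles) and a lognormal fluence, then Poisson samples the
    photons.  Truth records pattern id, in-plane angle and fluence.
    """
    from scipy.ndimage import rotate as nd_rotate

    rng = np.random.default_rng(seed)
    if volumes is None:
        volumes = [superball_volume(morph_spec(0.0), geometry=geometry)]
    quats = random_quats(n_patterns, rng)
    base = []
    for i in range(n_patterns):
        vol = volumes[i % len(volumes)]
        pat = slice_volume(vol, quats[i], geometry)
        pat = np.nan_to_num(pat, nan=0.0)
        base.append(scale_to_photons(pat, geometry, mean_photons))
    angles = np.arange(n_inplane) * (360.0 / n_inplane)
    rotated = np.stack(
        [
            np.clip(nd_rotate(b, ang, reshape=False, order=1), 0, None)
            for b in base
            for ang in angles
        ]
    )
    ids = rng.integers(0, n_patterns, size=n_frames)
    rots = rng.integers(0, n_inplane, size=n_frames)
    flat_ids = ids * n_inplane + rots
    fs = sample_frames(
        rotated,
        n_frames,
        geometry,
        seed=int(rng.integers(2**31)),
        fluence_sigma=fluence_sigma,
        pattern_ids=flat_ids,
    )
    fs.truth["pattern_id"] = ids
    fs.truth["inplane_angle_deg"] = angles[rots]
    fs.truth["base_quat"] = quats[ids]
    return fs
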