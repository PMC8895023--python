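"""Detector geometry: pixel grid, mask and reciprocal-space mapping.

The default geometry emulates a small-angle SPI setup: 6 keV photons, the
detector 705 mm downstream, and only the central region (scattering angles
up to 1.8 degrees) used, where the Ewald sphere is flat to excellent
approximation.  The full-resolution grid is 185x185 pixels of 0.2 mm; for
fast runs the same angular range is covered by fewer, proportionally larger
pixels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["DetectorGeometry", "make_geometry", "PIXEL_GOOD", "PIXEL_GAP", "PIXEL_BEAMSTOP"]

PIXEL_GOOD = 0
PIXEL_GAP = 1
PIXEL_BEAMSTOP = 2

HC_KEV_NM = 1.2398420  # photon energy [keV] * wavelength [nm]


@dataclass
class DetectorGeometry:
    """Flat small-angle detector with a per-pixel reciprocal-space map.

    ``qmap`` holds the scattering vector (qx, qy, 0) of each pixel in nm^-1
    with the convention q = 2 pi s (angular frequency); the flat-slice
    approximation sets qz = 0, valid for the <= 1.8 degree angular range.
    """

    photon_energy_keV: float
    detector_distance_mm: float
    pixel_size_mm: float
    shape: tuple[int, int]
    mask: np.ndarray = field(repr=False)
    qmap: np.ndarray = field(repr=False)

    @property
    def wavelength_nm(self) -> float:
        return HC_KEV_NM / self.photon_energy_keV

    @property
    def center(self) -> tuple[float, float]:
        return ((self.shape[0] - 1) / 2.0, (self.shape[1] - 1) / 2.0)

    @property
    def qmag(self) -> np.ndarray:
        return np.linalg.norm(self.qmap, axis=-1)

    @property
    def good(self) -> np.ndarray:
        return self.mask == PIXEL_GOOD

    @property
    def radius_px(self) -> np.ndarray:
        cy, cx = self.center
        yy, xx = np.mgrid[0 : self.shape[0], 0 : self.shape[1]]
        return np.hypot(yy - cy, xx - cx)

    @property
    def q_max(self) -> float:
        return float(self.qmag.max())


def make_geometry(
    n: int = 185,
    photon_energy_keV: float = 6.0,
    detector_distance_mm: float = 705.0,
    max_angle_deg: float = 1.8,
    beamstop_radius_frac: float = 0.06,
    gap_rows: tuple[int, int] | None = "auto",
) -> DetectorGeometry:
    """Square central-detector geometry covering a fixed angular range.

    The pixel size is chosen so that ``n`` pixels span the full +-max_angle
    field regardless of ``n``, which lets tests run on coarse grids with the
    same q coverage.  The mask contains a central beamstop disc and, by
    default, one rectangular panel gap (a horizontal strip off centre).
    """
    half_extent_mm = detector_distance_mm * np.tan(np.deg2rad(max_angle_deg))
    pixel_size_mm = 2.0 * half_extent_mm / n
    cy = cx = (n - 1) / 2.0
    yy, xx = np.mgrid[0:n, 0:n]
    x_mm = (xx - cx) * pixel_size_mm
    y_mm = (yy - cy) * pixel_size_mm
    wavelength = HC_KEV_NM / photon_energy_keV
    # small-angle scattering vector, flat Ewald slice
    theta = np.arctan(np.hypot(x_mm, y_mm) / detector_distance_mm)
    qmag = 4.0 * np.pi * np.sin(theta / 2.0) / wavelength
    phi = np.arctan2(y_mm, x_mm)
    qmap = np.zeros((n, n, 3))
    qmap[..., 0] = qmag * np.cos(phi)
    qmap[..., 1] = qmag * np.sin(phi)

    mask = np.full((n, n), PIXEL_GOOD, dtype=np.uint8)
    r = np.hypot(yy - cy, xx - cx)
    mask[r <= beamstop_radius_frac * n / 2.0] = PIXEL_BEAMSTOP
    if gap_rows == "auto":
        # one panel gap: a horizontal strip ~1/4 above centre, ~2% of height
        width = max(1, int(round(0.02 * n)))
        start = int(round(0.62 * n))
        gap_rows = (start, start + width)
    if gap_rows is not None:
        mask[gap_rows[0] : gap_rows[1], :] = PIXEL_GAP
    return DetectorGeometry(
        photon_energy_keV=photon_energy_keV,
        detector_distance_mm=detector_distance_mm,
        pixel_size_mm=pixel_size_mm,
        shape=(n, n),
        mask=mask,
        qmap=qmap,
    )
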