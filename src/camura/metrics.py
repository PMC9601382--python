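"""Image-quality metrics: CBR, MSE and PSNR against ground truth.

CBR (contrast-to-background ratio) is computed from ROI means,

    CBR = (mean_lesion - mean_background) / mean_background,

with the lesion ROI taken from the known lesion geometry projected onto the
reconstruction grid and the background a concentric annulus 2-4 lesion radii
away, restricted to the breast support.  MSE is the plain mean squared
difference to the reference image and PSNR = 10 log10(peak^2 / MSE) with
``peak`` the reference maximum.  The reference is the ground-truth activity
slice resampled to the reconstruction grid and scaled to the evaluated
image's total intensity, so MSE is measured on the reconstruction's own
scale (PSNR is invariant to that common scale).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import SystemGeometry
from .phantom import BreastPhantom
from .projector import embed_center, resample_area

__all__ = [
    "QualityReport",
    "cbr",
    "mse",
    "psnr",
    "disk_mask",
    "lesion_background_rois",
    "rois_for_phantom",
    "reference_slice",
    "evaluate_slice",
]


def cbr(image: np.ndarray, lesion_roi: np.ndarray,
        background_roi: np.ndarray) -> float:
    """Contrast-to-background ratio from ROI means."""
    image = np.asarray(image, dtype=np.float64)
    lesion_roi = np.asarray(lesion_roi, dtype=bool)
    background_roi = np.asarray(background_roi, dtype=bool)
    if image.shape != lesion_roi.shape or image.shape != background_roi.shape:
        raise ValueError("image and ROI masks must share one shape")
    if not lesion_roi.any() or not background_roi.any():
        raise ValueError("ROIs must be non-empty")
    if (lesion_roi & background_roi).any():
        raise ValueError("lesion and background ROIs must be disjoint")
    mu_l = image[lesion_roi].mean()
    mu_b = image[background_roi].mean()
    if mu_b == 0:
        raise ValueError("background ROI mean is zero; CBR undefined")
    return float((mu_l - mu_b) / mu_b)


def mse(image: np.ndarray, reference: np.ndarray) -> float:
    """Mean squared error between an image and its reference."""
    image = np.asarray(image, dtype=np.float64)
    reference = np.asarray(reference, dtype=np.float64)
    if image.shape != reference.shape:
        raise ValueError("image and reference must share one shape")
    return float(np.mean((image - reference) ** 2))


def psnr(image: np.ndarray, reference: np.ndarray) -> float:
    """Peak signal-to-noise ratio in dB; infinite for identical images."""
    e = mse(image, reference)
    peak = float(np.max(np.asarray(reference, dtype=np.float64)))
    if e == 0:
        return float("inf")
    if peak <= 0:
        raise ValueError("reference peak must be positive")
    return float(10.0 * np.log10(peak * peak / e))


def disk_mask(shape: tuple[int, int], radius: float,
              center: tuple[float, float] | None = None) -> np.ndarray:
    """Boolean disk on a pixel grid (centre defaults to the image centre)."""
    ny, nx = shape
    cy, cx = center if center is not None else ((ny - 1) / 2.0,
                                                (nx - 1) / 2.0)
    yy, xx = np.mgrid[0:ny, 0:nx]
    return (yy - cy) ** 2 + (xx - cx) ** 2 <= radius ** 2


def lesion_background_rois(shape: tuple[int, int], lesion_radius_px: float,
                           breast_radius_px: float | None = None,
                           inner: float = 2.0, outer: float = 4.0,
                           center: tuple[float, float] | None = None
                           ) -> tuple[np.ndarray, np.ndarray]:
    """Lesion disk plus concentric background annulus (inner..outer radii).

    The annulus is clipped to the breast support disk when
    ``breast_radius_px`` is given, so the background never samples the empty
    field outside the organ.  Sub-pixel lesion radii are clamped to 0.8 px
    so the ROI always contains the nearest pixel(s) to the centre, even on
    even-sided grids where no pixel centre coincides with the image centre.
    """
    if lesion_radius_px <= 0:
        raise ValueError("lesion radius must be positive")
    lesion_radius_px = max(lesion_radius_px, 0.8)
    lesion = disk_mask(shape, lesion_radius_px, center)
    ring = disk_mask(shape, outer * lesion_radius_px, center) \
        & ~disk_mask(shape, inner * lesion_radius_px, center)
    if breast_radius_px is not None:
        ring &= disk_mask(shape, breast_radius_px, center)
    if not ring.any():
        raise ValueError("background annulus is empty; widen the radii")
    return lesion, ring


def rois_for_phantom(phantom: BreastPhantom, geometry: SystemGeometry,
                     shape: tuple[int, int], z: int
                     ) -> tuple[np.ndarray, np.ndarray]:
    """ROIs on the reconstruction grid of slice ``z`` from the known
    lesion and breast geometry (axis-centred lesion at half depth)."""
    m_obj = geometry.object_magnification_at(z)
    scale = m_obj / geometry.detector_pitch
    lesion_r = phantom.lesion_diameter / 2.0 * scale
    depth = (z - geometry.z_min + 0.5) * geometry.slice_thickness
    rx, _, h = phantom.semi_axes
    frac = 1.0 - (depth / h) ** 2
    breast_r = rx * np.sqrt(max(frac, 0.0)) * scale
    return lesion_background_rois(shape, lesion_r, breast_r)


def reference_slice(phantom: BreastPhantom, geometry: SystemGeometry, z: int,
                    shape: tuple[int, int],
                    match_total: float | None = None) -> np.ndarray:
    """Ground-truth activity of slice ``z`` mapped to the recon grid.

    The truth is resampled by the object magnification onto the detector
    pitch and inverted through the aperture centre -- the same mapping the
    forward model applies -- then optionally rescaled to a target total.
    """
    slices = phantom.slice_images(geometry)
    img = slices[z]
    m_obj = geometry.object_magnification_at(z)
    ref = resample_area(img, phantom.voxel_size * m_obj,
                        geometry.detector_pitch)
    ref = embed_center(ref[::-1, ::-1], shape)
    if match_total is not None and ref.sum() > 0:
        ref *= match_total / ref.sum()
    return ref


@dataclass
class QualityReport:
    """CBR/PSNR/MSE of one reconstructed slice against ground truth."""

    cbr: float
    psnr: float
    mse: float
    roi: dict = field(default_factory=dict)
    reference_id: str = ""

    def as_dict(self) -> dict:
        return {"cbr": self.cbr, "psnr": self.psnr, "mse": self.mse,
                "roi": self.roi, "reference_id": self.reference_id}


def evaluate_slice(recon_slice: np.ndarray, phantom: BreastPhantom,
                   geometry: SystemGeometry, z: int,
                   reference_id: str = "") -> QualityReport:
    """Score one reconstructed slice: CBR from geometric ROIs, MSE/PSNR
    against the total-matched ground-truth slice.

    A background-suppressed reconstruction can leave the background annulus
    exactly zero; its contrast is then reported as infinite and flagged in
    the ROI record rather than raising.
    """
    recon_slice = np.asarray(recon_slice, dtype=np.float64)
    lesion, ring = rois_for_phantom(phantom, geometry, recon_slice.shape, z)
    # reference brought to the reconstruction's own intensity scale
    ref = reference_slice(phantom, geometry, z, recon_slice.shape,
                          match_total=float(recon_slice.sum()))
    roi = {"lesion_px": int(lesion.sum()), "background_px": int(ring.sum()),
           "aggregation": "mean"}
    try:
        contrast = cbr(recon_slice, lesion, ring)
    except ValueError:
        contrast = float("inf")
        roi["empty_background"] = True
    return QualityReport(
        cbr=contrast,
        psnr=psnr(recon_slice, ref),
        mse=mse(recon_slice, ref),
        roi=roi,
        reference_id=reference_id,
    )
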