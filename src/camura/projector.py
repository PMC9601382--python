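"""Analytic forward model: mask-shadow formation, modulation, counting.

Each 1 mm slice of the source casts a magnified shadow of the mask on the
detector: a point at position ``s`` on the slice plane illuminates the
detector at ``X = u * m - s * b / a`` for every open mask element ``u``
(``m = (a+b)/a``).  The detector image of one slice is therefore the
convolution of the slice activity -- inverted and scaled by the object
magnification ``b/a`` -- with the mask pattern scaled by ``m``.  Summing over
slices, applying the near-field obliquity modulation ``cos^n(theta)``, and
drawing per-pixel Poisson counts yields a simulated acquisition.

All resampling is area-weighted (each output pixel collects the exact
geometric overlap of input pixels), never nearest-neighbour: the magnified
hole size is comparable to the detector pitch, and point sampling would
alias the pattern.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage
from scipy.signal import fftconvolve

from .geometry import SystemGeometry
from .mask import MaskPattern

__all__ = [
    "Projection",
    "resample_area",
    "mask_shadow",
    "project_slice",
    "near_field_modulation",
    "sample_counts",
    "ideal_projection",
    "project_phantom",
    "geometric_efficiency",
]


def _overlap_matrix(n_in: int, s_in: float, n_out: int,
                    s_out: float) -> np.ndarray:
    """1-D area-overlap matrix between two centred pixel grids.

    Entry (i, j) is the length fraction of input pixel j covered by output
    pixel i, so columns sum to <= 1 and total mass is conserved whenever the
    output grid covers the input grid.
    """
    in_edges = np.arange(n_in + 1) * s_in - n_in * s_in / 2.0
    out_edges = np.arange(n_out + 1) * s_out - n_out * s_out / 2.0
    lo = np.maximum.outer(out_edges[:-1], in_edges[:-1])
    hi = np.minimum.outer(out_edges[1:], in_edges[1:])
    return np.clip(hi - lo, 0.0, None) / s_in


def resample_area(img: np.ndarray, s_in: float, s_out: float,
                  n_out: int | None = None) -> np.ndarray:
    """Area-weighted resampling of a centred image to a new pixel size.

    Conserves the image total exactly when the output grid covers the input
    extent (the default output size guarantees this).
    """
    if s_in <= 0 or s_out <= 0:
        raise ValueError("pixel sizes must be positive")
    img = np.asarray(img, dtype=np.float64)
    ny, nx = img.shape
    if n_out is None:
        # smallest centred grid covering the input extent; when the extents
        # divide evenly the two pixel grids align exactly
        n_row = int(np.ceil(ny * s_in / s_out - 1e-9))
        n_col = int(np.ceil(nx * s_in / s_out - 1e-9))
    else:
        n_row = n_col = n_out
    a_row = _overlap_matrix(ny, s_in, n_row, s_out)
    a_col = _overlap_matrix(nx, s_in, n_col, s_out)
    return a_row @ img @ a_col.T


def embed_center(img: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Pad or crop an image symmetrically onto a canvas of ``shape``."""
    out = np.zeros(shape, dtype=np.float64)
    sy = min(img.shape[0], shape[0])
    sx = min(img.shape[1], shape[1])
    oy, ox = (shape[0] - sy) // 2, (shape[1] - sx) // 2
    iy, ix = (img.shape[0] - sy) // 2, (img.shape[1] - sx) // 2
    out[oy:oy + sy, ox:ox + sx] = img[iy:iy + sy, ix:ix + sx]
    return out


def mask_shadow(mask: MaskPattern, geometry: SystemGeometry,
                z: int = 0) -> np.ndarray:
    """Mask pattern magnified to the detector plane, on the detector pitch.

    The shadow of a mask element of size ``mask.hole_pitch`` from a source
    at slice ``z`` covers ``hole_pitch * m(z)`` mm on the detector; the
    pattern is resampled with area weighting onto the detector pixel grid.
    """
    m = geometry.magnification_at(z)
    s_in = mask.hole_pitch * m
    shadow = resample_area(mask.elements.astype(np.float64), s_in,
                           geometry.detector_pitch)
    return np.clip(shadow, 0.0, None)


def project_slice(activity_slice: np.ndarray, pixel_size: float,
                  mask: MaskPattern, geometry: SystemGeometry,
                  z: int) -> np.ndarray:
    """Ideal (noise-free) detector intensity cast by one source slice.

    The slice activity image (``pixel_size`` mm pixels) is scaled by the
    object magnification ``b/a(z)``, inverted through the aperture centre,
    and convolved with the magnified mask shadow.  The result is embedded on
    the detector grid.  Linear in activity by construction.
    """
    a = geometry.slice_distance(z)  # also validates z
    img = np.asarray(activity_slice, dtype=np.float64)
    if img.ndim != 2:
        raise ValueError("activity slice must be a 2-D image")
    if (img < 0).any():
        raise ValueError("activity must be non-negative")
    n_det = geometry.detector_pixels
    if not img.any():
        return np.zeros((n_det, n_det))
    obj = resample_area(img, pixel_size * geometry.b / a,
                        geometry.detector_pitch)
    obj = obj[::-1, ::-1]  # pinhole-style image inversion
    shadow = mask_shadow(mask, geometry, z)
    intensity = fftconvolve(obj, shadow, mode="full")
    return embed_center(np.clip(intensity, 0.0, None), (n_det, n_det))


def near_field_modulation(intensity: np.ndarray, geometry: SystemGeometry,
                          exponent: float = 3.0,
                          source_distance: float | None = None) -> np.ndarray:
    """Apply the ``cos^n`` obliquity falloff of near-field illumination.

    ``theta`` is the angle between the detector normal and the ray from the
    source-plane centre (at ``a_center + b`` unless overridden) to each
    detector pixel.  ``exponent = 0`` is the identity; the default 3 models
    the combined inverse-square and cosine projection falloff of a planar
    detector close to the source.
    """
    if exponent < 0:
        raise ValueError("modulation exponent must be non-negative")
    intensity = np.asarray(intensity, dtype=np.float64)
    if exponent == 0:
        return intensity.copy()
    L = source_distance if source_distance is not None \
        else geometry.a_center + geometry.b
    ny, nx = intensity.shape
    p = geometry.detector_pitch
    yy = (np.arange(ny) - (ny - 1) / 2.0) * p
    xx = (np.arange(nx) - (nx - 1) / 2.0) * p
    r2 = yy[:, None] ** 2 + xx[None, :] ** 2
    cos = L / np.sqrt(L * L + r2)
    return intensity * cos ** exponent


@dataclass
class Projection:
    """A 2-D detector image plus its exposure metadata.

    ``is_ideal`` distinguishes pre-noise expected intensity (float) from a
    sampled acquisition (integer counts).
    """

    counts: np.ndarray
    geometry: SystemGeometry
    exposure: float = 600.0            # s
    is_ideal: bool = False
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        if c.ndim != 2:
            raise ValueError("projection must be a 2-D image")
        if (c < 0).any():
            raise ValueError("projection counts must be non-negative")
        self.counts = c

    @property
    def total(self) -> float:
        return float(self.counts.sum())

    def to_tiff(self, path: str | Path) -> None:
        import tifffile

        dtype = np.float32 if self.is_ideal else np.int32
        tifffile.imwrite(str(path), self.counts.astype(dtype))

    @classmethod
    def from_tiff(cls, path: str | Path, geometry: SystemGeometry,
                  **kw) -> "Projection":
        import tifffile

        data = np.asarray(tifffile.imread(str(path)), dtype=np.float64)
        is_ideal = not np.allclose(data, np.round(data))
        return cls(counts=data, geometry=geometry, is_ideal=is_ideal, **kw)


def sample_counts(intensity: np.ndarray, total_expected: float,
                  blur_sigma: float, geometry: SystemGeometry,
                  seed: int | np.random.Generator | None = None,
                  exposure: float = 600.0) -> Projection:
    """Turn an ideal intensity into a noisy integer-count acquisition.

    The intensity is blurred by the detector position response (Gaussian,
    ``blur_sigma`` mm), scaled to the expected total, and per-pixel Poisson
    counts are drawn.  Blurring the expected intensity before sampling keeps
    the counts integer while leaving the count statistics of the blurred
    signal unchanged in the mean.
    """
    intensity = np.asarray(intensity, dtype=np.float64)
    if (intensity < 0).any():
        raise ValueError("intensity must be non-negative")
    if total_expected <= 0:
        raise ValueError("expected total count must be positive")
    if blur_sigma < 0:
        raise ValueError("blur sigma must be non-negative")
    s = intensity.sum()
    if s == 0:
        raise ValueError("cannot sample counts from an all-zero intensity")
    if blur_sigma > 0:
        intensity = ndimage.gaussian_filter(
            intensity, sigma=blur_sigma / geometry.detector_pitch,
            mode="constant")
    expected = intensity * (total_expected / intensity.sum())
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    counts = rng.poisson(expected)
    return Projection(counts=counts, geometry=geometry, exposure=exposure,
                      is_ideal=False,
                      meta={"total_expected": total_expected,
                            "blur_sigma_mm": blur_sigma})


def geometric_efficiency(mask: MaskPattern,
                         geometry: SystemGeometry) -> float:
    """Fraction of isotropic emissions that form the image.

    A photon must pass the open mask area and land on the detector, so the
    throughput is limited by whichever subtends the smaller solid angle from
    the breast centre (flat-plate approximation), times the open fraction.
    A larger mask of equal open fraction therefore collects proportionally
    more counts -- the sensitivity advantage of the mosaic over the plain
    base pattern.
    """
    a = geometry.a_center
    R = a + geometry.b
    mask_solid = mask.physical_side ** 2 / (4.0 * np.pi * a * a)
    det_solid = geometry.detector_side ** 2 / (4.0 * np.pi * R * R)
    return min(1.0, mask_solid, det_solid) * mask.open_fraction


def ideal_projection(slices: dict[int, np.ndarray], pixel_size: float,
                     mask: MaskPattern, geometry: SystemGeometry,
                     modulation_exponent: float = 3.0) -> np.ndarray:
    """Sum of per-slice shadows over the stack, obliquity-modulated."""
    n = geometry.detector_pixels
    total = np.zeros((n, n))
    for z, img in slices.items():
        if np.any(img):
            total += project_slice(img, pixel_size, mask, geometry, z)
    return near_field_modulation(total, geometry, modulation_exponent)


def project_phantom(phantom, mask: MaskPattern, geometry: SystemGeometry,
                    emissions: float = 7.5e8,
                    detected: float | None = None,
                    blur_sigma: float = 1.0,
                    modulation_exponent: float = 3.0,
                    seed: int | np.random.Generator | None = None,
                    exposure: float = 600.0) -> Projection:
    """Full acquisition of a phantom: project all slices, modulate, sample.

    ``emissions`` is the total number of gammas emitted into 4 pi; only the
    detector-subtended, mask-transmitted fraction (the geometric efficiency)
    forms the image.  ``detected``, if given, overrides the budget with an
    explicit expected detected-count total.
    """
    slices = phantom.slice_images(geometry)
    intensity = ideal_projection(slices, phantom.voxel_size, mask, geometry,
                                 modulation_exponent)
    eff = geometric_efficiency(mask, geometry)
    expected = detected if detected is not None else emissions * eff
    proj = sample_counts(intensity, expected, blur_sigma, geometry,
                         seed=seed, exposure=exposure)
    proj.meta.update({
        "geometric_efficiency": eff,
        "emissions": emissions,
        "modulation_exponent": modulation_exponent,
        "lesion_diameter_mm": getattr(phantom, "lesion_diameter", None),
    })
    return proj
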