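"""System geometry: distances, magnification, field of view, resolution.

The camera is a single-view coded-aperture system: a source plane (one slice
of the breast) at distance ``a`` in front of the mask, and the detector at a
fixed distance ``b`` behind it.  All magnification arithmetic lives here.

* mask-shadow magnification  ``m = (a + b) / a``
* object magnification      ``b / a`` (the reconstructed object is zoomed by
  this ratio on the detector plane)
* geometric resolution of a hole of size ``d``:  ``d * (a + b) / b`` in the
  object plane
* field of view: detector side divided by the object magnification,
  ``D * a / b``

Slices are indexed by an integer ``z``; +z points toward the mask, so the
closest slice has the smallest ``a`` and the largest magnification.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "SystemGeometry",
    "magnification",
    "object_magnification",
    "geometric_resolution",
    "field_of_view",
]


def magnification(a: float, b: float) -> float:
    """Mask-shadow magnification ``(a + b) / a``.

    ``a`` is the slice-to-mask distance, ``b`` the mask-to-detector distance
    (both mm).  ``b = 0`` is the degenerate contact geometry (factor 1).
    """
    if a <= 0 or b < 0:
        raise ValueError("distances must satisfy a > 0 and b >= 0")
    return (a + b) / a


def object_magnification(a: float, b: float) -> float:
    """Scale of the object's image on the detector plane, ``b / a``."""
    if a <= 0 or b < 0:
        raise ValueError("distances must satisfy a > 0 and b >= 0")
    return b / a


def geometric_resolution(d: float, a: float, b: float) -> float:
    """Object-plane size resolved by a mask hole of size ``d`` (mm)."""
    if d < 0:
        raise ValueError("hole size must be non-negative")
    if a <= 0 or b <= 0:
        raise ValueError("distances must be positive")
    return d * (a + b) / b


def field_of_view(D: float, a: float, b: float) -> float:
    """Object-plane extent imaged onto a detector of side ``D`` (mm)."""
    if D <= 0 or a <= 0 or b <= 0:
        raise ValueError("detector size and distances must be positive")
    return D * a / b


@dataclass(frozen=True)
class SystemGeometry:
    """Distances and detector parameters of the single-view camera.

    Defaults reproduce the reference design: detector 300 mm behind the mask,
    breast centre 100 mm in front of it, 40 slices of 1 mm indexed
    ``z = -20 .. +19`` spanning slice-to-mask distances 120 mm (farthest)
    down to 81 mm (closest).
    """

    mask_detector_distance: float = 300.0   # b, mm
    a_center: float = 100.0                 # slice-mask distance at z=0, mm
    hole_size: float = 1.0                  # mask element size, mm
    detector_side: float = 664.0            # D, mm
    detector_pitch: float = 1.0             # detector pixel size, mm
    slice_thickness: float = 1.0            # mm per slice index step
    z_min: int = -20
    z_max: int = 19

    def __post_init__(self) -> None:
        if self.mask_detector_distance <= 0 or self.a_center <= 0:
            raise ValueError("distances must be positive")
        if self.detector_pitch <= 0 or self.detector_side <= 0:
            raise ValueError("detector dimensions must be positive")
        if self.slice_thickness <= 0:
            raise ValueError("slice thickness must be positive")
        if self.z_min > self.z_max:
            raise ValueError("z_min must not exceed z_max")
        if self.slice_distance(self.z_max) <= 0:
            raise ValueError("closest slice would sit behind the mask")

    @property
    def b(self) -> float:
        return self.mask_detector_distance

    @property
    def n_slices(self) -> int:
        return self.z_max - self.z_min + 1

    @property
    def z_range(self) -> range:
        return range(self.z_min, self.z_max + 1)

    @property
    def detector_pixels(self) -> int:
        """Detector grid side in pixels."""
        return int(round(self.detector_side / self.detector_pitch))

    def slice_distance(self, z: int) -> float:
        """Slice-to-mask distance ``a(z) = a_center - z * slice_thickness``."""
        if not (self.z_min <= z <= self.z_max):
            raise ValueError(
                f"slice index {z} outside [{self.z_min}, {self.z_max}]")
        return self.a_center - z * self.slice_thickness

    def magnification_at(self, z: int) -> float:
        a = self.slice_distance(z)
        return magnification(a, self.b)

    def object_magnification_at(self, z: int) -> float:
        a = self.slice_distance(z)
        return object_magnification(a, self.b)

    def slice_distances(self) -> np.ndarray:
        """``a(z)`` for every slice, ordered from z_min to z_max."""
        return np.array([self.slice_distance(z) for z in self.z_range])

    def geometric_resolution_at(self, z: int = 0) -> float:
        return geometric_resolution(self.hole_size, self.slice_distance(z),
                                    self.b)

    def field_of_view_at(self, z: int = 0) -> float:
        return field_of_view(self.detector_side, self.slice_distance(z),
                             self.b)
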