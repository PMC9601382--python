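"""Voxelized half-ellipsoidal breast phantom with lesion and activity map.

The phantom emulates a small breast imaged in the prone position: a
half-ellipsoid with its flat face at the chest wall and its apex (nipple)
pointing toward the mask.  Tissues are integer labels only -- skin (a
one-voxel shell), an adipose outer layer, a glandular core, a stochastic
branching duct tree, and an optional spherical lesion at half the breast
depth.  Attenuation and elemental composition are out of scope; tissues
matter only through the specific activity assigned to their voxels.

Activity budgeting follows the usual scintimammography bookkeeping: a 20 mCi
systemic dose of 99mTc, apportioned to the breast by the breast-to-body
volume ratio (134 mL / 80 L -> 33.5 uCi), emitted isotropically over a
10 min acquisition (~750 million gammas).  Within the breast the activity is
uniform per voxel except the lesion, whose specific activity is the
tumor-to-background ratio (TBR, 10:1 by default) times higher.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

__all__ = [
    "BreastPhantom",
    "LABELS",
    "build_breast_phantom",
    "breast_activity_from_dose",
    "total_emissions",
    "assign_activity",
    "point_source_slices",
    "BQ_PER_UCI",
]

#: Becquerel per microcurie.
BQ_PER_UCI = 3.7e4

#: Tissue label codes used in the ``labels`` grid.
LABELS = {
    "background": 0,
    "skin": 1,
    "adipose": 2,
    "glandular": 3,
    "duct": 4,
    "lesion": 5,
}

_BREAST_TISSUES = (LABELS["skin"], LABELS["adipose"], LABELS["glandular"],
                   LABELS["duct"])


@dataclass
class BreastPhantom:
    """Labeled voxel grid plus per-voxel activity.

    Arrays are indexed ``(t, y, x)`` where ``t`` is depth in voxels measured
    from the chest wall (t = 0) toward the apex.  ``semi_axes`` is
    ``(rx, ry, height)`` in mm.
    """

    labels: np.ndarray
    voxel_size: float                     # mm, isotropic
    semi_axes: tuple[float, float, float]
    lesion_diameter: float                # mm
    tbr: float = 1.0
    activity: np.ndarray | None = None    # Bq per voxel
    seed: int | None = None
    meta: dict = field(default_factory=dict)

    @property
    def voxel_volume(self) -> float:
        """Voxel volume in mm^3 (0.125 for the default 0.5 mm voxels)."""
        return self.voxel_size ** 3

    @property
    def interior_mask(self) -> np.ndarray:
        return self.labels != LABELS["background"]

    @property
    def lesion_mask(self) -> np.ndarray:
        return self.labels == LABELS["lesion"]

    @property
    def interior_volume_ml(self) -> float:
        return self.interior_mask.sum() * self.voxel_volume / 1000.0

    @property
    def total_activity(self) -> float:
        if self.activity is None:
            return 0.0
        return float(self.activity.sum())

    @property
    def height(self) -> float:
        """Breast depth (chest wall to apex) in mm."""
        return self.semi_axes[2]

    def lesion_center_depth(self) -> float:
        """Depth of the lesion centre from the chest wall, mm."""
        return self.height / 2.0

    def slice_images(self, geometry) -> dict[int, np.ndarray]:
        """Sum activity into 2-D per-slice images keyed by slice index.

        Slice ``z`` of the geometry covers depths
        ``[(z - z_min) * dz, (z - z_min + 1) * dz)`` from the chest wall, so
        the farthest slice (z_min, largest a) sits at the chest wall and the
        closest slice holds the apex.  Depths beyond the breast give empty
        images.  Pixel size of the returned images is ``voxel_size``.
        """
        if self.activity is None:
            raise ValueError("phantom has no activity assigned")
        dz = geometry.slice_thickness
        nt = self.labels.shape[0]
        out: dict[int, np.ndarray] = {}
        for z in geometry.z_range:
            t0 = (z - geometry.z_min) * dz
            i0 = int(round(t0 / self.voxel_size))
            i1 = int(round((t0 + dz) / self.voxel_size))
            if i0 >= nt:
                img = np.zeros(self.labels.shape[1:], dtype=np.float64)
            else:
                img = self.activity[i0:min(i1, nt)].sum(axis=0)
            out[z] = img
        return out

    def to_files(self, labels_path: str | Path,
                 activity_path: str | Path | None = None,
                 sidecar_path: str | Path | None = None) -> None:
        """Write labels (and activity) as NIfTI volumes plus a JSON sidecar."""
        import nibabel as nib

        affine = np.diag([self.voxel_size] * 3 + [1.0])
        nib.save(nib.Nifti1Image(self.labels.astype(np.int16), affine),
                 str(labels_path))
        if activity_path is not None and self.activity is not None:
            nib.save(nib.Nifti1Image(self.activity.astype(np.float32),
                                     affine), str(activity_path))
        if sidecar_path is not None:
            meta = {
                "voxel_size_mm": self.voxel_size,
                "semi_axes_mm": list(self.semi_axes),
                "lesion_diameter_mm": self.lesion_diameter,
                "tbr": self.tbr,
                "seed": self.seed,
                "total_activity_bq": self.total_activity,
            }
            Path(sidecar_path).write_text(json.dumps(meta, indent=2))


def breast_activity_from_dose(dose_mci: float, breast_volume_ml: float,
                              body_volume_l: float) -> float:
    """Breast activity in uCi from a systemic dose apportioned by volume.

    ``dose * breast_volume / body_volume`` with units handled:
    20 mCi x (134 mL / 80 L) = 33.5 uCi.
    """
    if dose_mci <= 0 or breast_volume_ml <= 0:
        raise ValueError("dose and breast volume must be positive")
    if body_volume_l <= 0:
        raise ValueError("body volume must be positive")
    dose_uci = dose_mci * 1000.0
    return dose_uci * breast_volume_ml / (body_volume_l * 1000.0)


def total_emissions(activity_uci: float, duration_s: float) -> float:
    """Total gamma emissions over an acquisition: activity x 3.7e4 x t."""
    if activity_uci < 0 or duration_s < 0:
        raise ValueError("activity and duration must be non-negative")
    return activity_uci * BQ_PER_UCI * duration_s


def _grow_duct_tree(labels: np.ndarray, interior: np.ndarray,
                    voxel_size: float, height_mm: float,
                    rng: np.random.Generator, depth: int = 4) -> None:
    """Mark a seeded recursive bifurcating duct tree (labels only).

    Branches start at the apex and bifurcate toward the chest wall with
    random lateral deflections -- a parametric stand-in for an
    anthropomorphic ductal network.
    """
    nt, ny, nx = labels.shape
    apex = np.array([height_mm / voxel_size - 2.0, ny / 2.0, nx / 2.0])

    def mark_segment(p0: np.ndarray, p1: np.ndarray) -> None:
        n = max(2, int(np.linalg.norm(p1 - p0) * 4))
        for s in np.linspace(0.0, 1.0, n):
            q = np.round(p0 + s * (p1 - p0)).astype(int)
            if (0 <= q[0] < nt and 0 <= q[1] < ny and 0 <= q[2] < nx
                    and interior[tuple(q)]
                    and labels[tuple(q)] != LABELS["skin"]):
                labels[tuple(q)] = LABELS["duct"]

    def grow(p: np.ndarray, direction: np.ndarray, length: float,
             level: int) -> None:
        if level > depth or length < 1.0:
            return
        end = p + direction * length
        mark_segment(p, end)
        for _ in range(2):
            deflect = rng.normal(scale=0.35, size=3)
            d = direction + deflect
            d[0] = -abs(d[0])  # keep growing toward the chest wall
            d /= np.linalg.norm(d)
            grow(end, d, length * 0.7, level + 1)

    trunk_len = 0.25 * height_mm / voxel_size
    grow(apex, np.array([-1.0, 0.0, 0.0]), trunk_len, 1)


def build_breast_phantom(semi_axes: tuple[float, float, float] = (40.0, 40.0, 40.0),
                         lesion_diameter: float = 8.0,
                         voxel_size: float = 0.5,
                         seed: int | None = 0,
                         glandular_fraction: float = 0.6,
                         duct_depth: int = 4) -> BreastPhantom:
    """Build the labeled half-ellipsoid phantom.

    Parameters
    ----------
    semi_axes : (rx, ry, height) in mm
        Half-ellipsoid semi-axes; the default (40, 40, 40) hemisphere has a
        volume of (2/3) pi 40^3 = 134.0 mL, matching the reference breast.
    lesion_diameter : float
        Spherical lesion diameter in mm, centred on the axis at half the
        breast depth.  ``0`` builds a lesion-free phantom.
    voxel_size : float
        Isotropic voxel edge in mm (0.5 mm -> 0.125 mm^3 voxels).
    seed : int or None
        Seed for the stochastic duct tree; same seed, same phantom.
    """
    if voxel_size <= 0:
        raise ValueError("voxel size must be positive")
    if lesion_diameter < 0:
        raise ValueError("lesion diameter must be non-negative")
    rx, ry, h = semi_axes
    if min(rx, ry, h) <= 0:
        raise ValueError("semi-axes must be positive")
    # lesion sits at half depth; require it to fit inside the ellipsoid
    if lesion_diameter > 0:
        cross = np.sqrt(max(0.0, 1.0 - 0.25)) * min(rx, ry)
        if lesion_diameter / 2.0 >= min(cross, h / 2.0):
            raise ValueError("lesion does not fit inside the breast")

    nt = int(np.ceil(h / voxel_size))
    ny = int(np.ceil(2 * ry / voxel_size))
    nx = int(np.ceil(2 * rx / voxel_size))
    t = (np.arange(nt) + 0.5) * voxel_size               # depth from chest
    y = (np.arange(ny) + 0.5) * voxel_size - ry
    x = (np.arange(nx) + 0.5) * voxel_size - rx
    T, Y, X = np.meshgrid(t, y, x, indexing="ij")

    r2 = (X / rx) ** 2 + (Y / ry) ** 2 + (T / h) ** 2
    interior = r2 <= 1.0

    labels = np.zeros((nt, ny, nx), dtype=np.uint8)
    labels[interior] = LABELS["adipose"]
    shell = interior & ~ndimage.binary_erosion(interior)
    labels[shell] = LABELS["skin"]

    g = glandular_fraction
    core = ((X / (g * rx)) ** 2 + (Y / (g * ry)) ** 2
            + (T / (g * h)) ** 2) <= 1.0
    labels[core & (labels == LABELS["adipose"])] = LABELS["glandular"]

    rng = np.random.default_rng(seed)
    if duct_depth > 0:
        _grow_duct_tree(labels, interior, voxel_size, h, rng, duct_depth)

    if lesion_diameter > 0:
        lesion = ((X ** 2 + Y ** 2 + (T - h / 2.0) ** 2)
                  <= (lesion_diameter / 2.0) ** 2)
        labels[lesion & interior] = LABELS["lesion"]

    phantom = BreastPhantom(labels=labels, voxel_size=voxel_size,
                            semi_axes=(rx, ry, h),
                            lesion_diameter=lesion_diameter, seed=seed)
    target = (2.0 / 3.0) * np.pi * rx * ry * h / 1000.0  # mL
    achieved = phantom.interior_volume_ml
    if abs(achieved - target) > 0.02 * target:
        raise RuntimeError(
            f"voxelized volume {achieved:.1f} mL deviates more than 2% from "
            f"the analytic half-ellipsoid volume {target:.1f} mL")
    phantom.meta["target_volume_ml"] = target
    return phantom


def assign_activity(phantom: BreastPhantom, total_activity: float,
                    tbr: float = 10.0) -> BreastPhantom:
    """Distribute ``total_activity`` (Bq) uniformly per voxel, TBR-weighted.

    Every breast-tissue voxel receives the same rate ``q`` and every lesion
    voxel ``tbr * q``, with ``q`` chosen so the grand total is exactly the
    requested activity.
    """
    if tbr < 1:
        raise ValueError("TBR must be >= 1")
    if total_activity < 0:
        raise ValueError("total activity must be non-negative")
    breast = np.isin(phantom.labels, _BREAST_TISSUES)
    lesion = phantom.lesion_mask
    n_breast = int(breast.sum())
    n_lesion = int(lesion.sum())
    if n_breast + n_lesion == 0:
        raise ValueError("phantom has no tissue voxels")
    q = total_activity / (n_breast + tbr * n_lesion)
    activity = np.zeros(phantom.labels.shape, dtype=np.float64)
    activity[breast] = q
    activity[lesion] = tbr * q
    phantom.activity = activity
    phantom.tbr = tbr
    phantom.meta["per_voxel_bq"] = q
    return phantom


def point_source_slices(geometry, z0: int, pixel_size: float = 0.5,
                        grid_side: int = 41, offset_mm: tuple[float, float] = (0.0, 0.0),
                        activity: float = 1.0) -> dict[int, np.ndarray]:
    """Point-source fixture: an impulse on slice ``z0``, zeros elsewhere.

    Returns per-slice activity images on a small ``grid_side`` square grid of
    ``pixel_size`` mm pixels, suitable as input to the projector.
    """
    out: dict[int, np.ndarray] = {}
    c = grid_side // 2
    for z in geometry.z_range:
        img = np.zeros((grid_side, grid_side), dtype=np.float64)
        if z == z0:
            iy = c + int(round(offset_mm[1] / pixel_size))
            ix = c + int(round(offset_mm[0] / pixel_size))
            img[iy, ix] = activity
        out[z] = img
    return out
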