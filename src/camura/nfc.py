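"""Near-field correction (NFC) of coded-aperture projections.

In near-field geometry the rays from a finite-distance source are oblique,
so the raw projection carries a smooth ``cos^n`` intensity envelope on top
of the mask shadow texture.  Decoding a modulated projection smears the
correlation peak and degrades contrast, so the envelope is divided out
before reconstruction.

Two variants are provided:

``analytic``
    Divide by the known ``cos^n(theta)`` map from the geometry.  Exact when
    the projection was formed by the analytic forward model; the default in
    simulation where the geometry is known.
``envelope``
    Estimate the envelope from the projection itself by heavy Gaussian
    smoothing (kernel much wider than one magnified mask element) and divide
    by it.  Geometry-free, intended for externally supplied projections.

Both modes renormalise so the corrected image keeps the original mean, and
neither can introduce negative values.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .geometry import SystemGeometry
from .projector import Projection, near_field_modulation

__all__ = ["near_field_correct"]

_MODES = ("analytic", "envelope")


def _envelope(img: np.ndarray, sigma_px: float) -> np.ndarray:
    # nearest-mode smoothing avoids edge roll-off biasing the envelope
    return ndimage.gaussian_filter(img, sigma=sigma_px, mode="nearest")


def near_field_correct(projection: Projection, mode: str = "analytic",
                       exponent: float = 3.0,
                       envelope_sigma_mm: float | None = None) -> Projection:
    """Divide the near-field intensity envelope out of a projection.

    Parameters
    ----------
    projection : Projection
        Raw (modulated) projection; counts must be non-negative.
    mode : {"analytic", "envelope"}
    exponent : float
        ``n`` of the ``cos^n`` model (analytic mode).
    envelope_sigma_mm : float, optional
        Smoothing scale of the envelope fit; defaults to 8 magnified mask
        elements, i.e. well above the shadow texture scale.
    """
    if mode not in _MODES:
        raise ValueError(f"mode must be one of {_MODES}")
    geometry: SystemGeometry = projection.geometry
    img = np.asarray(projection.counts, dtype=np.float64)
    if not img.any():
        raise ValueError("cannot near-field correct an all-zero projection")
    if mode == "analytic":
        flat = np.ones_like(img)
        gain = near_field_modulation(flat, geometry, exponent)
        corrected = img / gain
    else:
        m_center = geometry.magnification_at(0)
        sigma_mm = envelope_sigma_mm if envelope_sigma_mm is not None \
            else 8.0 * geometry.hole_size * m_center
        env = _envelope(img, sigma_mm / geometry.detector_pitch)
        pos = env > 0
        if not pos.any():
            raise ValueError("degenerate envelope fit")
        corrected = np.zeros_like(img)
        corrected[pos] = img[pos] / env[pos]
    corrected *= img.mean() / corrected.mean()
    out = Projection(counts=corrected, geometry=geometry,
                     exposure=projection.exposure, is_ideal=True,
                     meta=dict(projection.meta))
    out.meta["nfc"] = mode
    return out
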