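"""MURA coded-aperture masks: base patterns, mosaics, antimasks, decoders.

A Modified Uniformly Redundant Array (MURA) is a binary aperture pattern of
prime rank ``p`` built from quadratic residues modulo ``p``.  Its open
fraction is just under 50% and its periodic cross-correlation with the
balanced decoding array is exactly two-valued: a single central peak equal to
the number of open elements, and a perfectly flat (zero) sidelobe floor.
That delta-like system response is what makes the pattern usable as a
multiplexing collimator in emission imaging.

The mosaic mask is the ``2p x 2p`` periodic extension of the base pattern.
Every ``p x p`` window of the mosaic is a complete cyclic shift of the base,
so a source anywhere in the field of view casts a fully decodable pattern on
the detector.  The antimask used for background subtraction is the mask
rotated by 90 degrees.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.signal import correlate

__all__ = [
    "MaskPattern",
    "MosaicMask",
    "generate_mura",
    "mosaic_of",
    "antimask_of",
    "decoding_array",
    "response_function",
    "complement_overlap",
    "mura_open_count",
]


def _is_prime(n: int) -> bool:
    if n < 2:
        return False
    if n % 2 == 0:
        return n == 2
    f = 3
    while f * f <= n:
        if n % f == 0:
            return False
        f += 2
    return True


def mura_open_count(rank: int) -> int:
    """Closed-form number of open elements of a rank-``p`` MURA base."""
    return (rank - 1) + (rank - 1) ** 2 // 2


@dataclass(frozen=True)
class MaskPattern:
    """A square binary aperture pattern (1 = open/transparent, 0 = opaque)."""

    elements: np.ndarray
    rank: int
    hole_pitch: float = 1.0  # mm per element

    def __post_init__(self) -> None:
        e = np.asarray(self.elements)
        if e.ndim != 2 or e.shape[0] != e.shape[1]:
            raise ValueError("mask elements must be a square 2-D array")
        if not np.isin(e, (0, 1)).all():
            raise ValueError("mask elements must be binary (0/1)")
        object.__setattr__(self, "elements", e.astype(np.uint8))

    @property
    def side(self) -> int:
        return self.elements.shape[0]

    @property
    def open_count(self) -> int:
        return int(self.elements.sum())

    @property
    def open_fraction(self) -> float:
        return self.open_count / self.elements.size

    @property
    def physical_side(self) -> float:
        """Physical side length of the pattern in mm."""
        return self.side * self.hole_pitch

    @property
    def decoding(self) -> np.ndarray:
        """Balanced decoding array G aligned with ``elements``."""
        return decoding_array(self)


@dataclass(frozen=True)
class MosaicMask(MaskPattern):
    """``2p x 2p`` mosaic built by 2x2 cyclic tiling of a MURA base.

    ``rank`` remains the rank of the base pattern; ``side == 2 * rank``.
    """

    base: MaskPattern = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        super().__post_init__()
        if self.base is not None and self.side != 2 * self.base.rank:
            raise ValueError("mosaic side must be twice the base rank")


def generate_mura(rank: int, hole_pitch: float = 1.0) -> MaskPattern:
    """Generate the rank-``p`` MURA base pattern from quadratic residues.

    Convention (Gottesman-Fenimore): row 0 fully closed, column 0 open except
    the corner element, and an interior element (i, j) open exactly when the
    Legendre symbols of i and j modulo ``p`` agree.

    Parameters
    ----------
    rank : int
        An odd prime; the side length of the pattern in elements.
    hole_pitch : float
        Physical size of one element in mm.
    """
    if not _is_prime(rank) or rank == 2:
        raise ValueError(f"MURA rank must be an odd prime, got {rank}")
    residues = {(i * i) % rank for i in range(1, rank)}
    legendre = np.array([1 if i in residues else -1 for i in range(1, rank)])
    a = np.zeros((rank, rank), dtype=np.uint8)
    a[1:, 0] = 1
    a[1:, 1:] = np.equal.outer(legendre, legendre)
    return MaskPattern(elements=a, rank=rank, hole_pitch=hole_pitch)


def mosaic_of(base: MaskPattern) -> MosaicMask:
    """2x2 cyclic tiling of a MURA base into a ``2p x 2p`` mosaic.

    Because the tiling is periodic with period ``p`` along both axes, every
    ``p x p`` contiguous window (with cyclic completion) of the mosaic is a
    cyclic shift of the base pattern.
    """
    tiled = np.tile(base.elements, (2, 2))
    return MosaicMask(elements=tiled, rank=base.rank,
                      hole_pitch=base.hole_pitch, base=base)


def antimask_of(mask: MaskPattern) -> MaskPattern:
    """The antimask: the mask rotated by 90 degrees.

    Rotation preserves the open count, and applying it four times returns the
    original pattern exactly.  Note this is a rotation, not the logical
    complement; :func:`complement_overlap` quantifies how close the two are.
    """
    e = np.asarray(mask.elements)
    if e.ndim != 2 or e.shape[0] != e.shape[1]:
        raise ValueError("antimask is only defined for square masks")
    if isinstance(mask, MosaicMask) and mask.base is not None:
        # rotating a 2x2 tiling of identical tiles == tiling the rotated tile
        return replace(mask, elements=np.rot90(e), base=antimask_of(mask.base))
    return replace(mask, elements=np.rot90(e))


def decoding_array(mask: MaskPattern) -> np.ndarray:
    """Balanced decoder: +1 on open, -1 on closed elements.

    For a MURA base the corner element G(0,0) is set to +1 although A(0,0)
    is closed; with that convention the periodic cross-correlation of the
    pattern with its decoder is a perfect delta (flat zero sidelobes).  For a
    mosaic the base decoder is tiled with the same 2x2 periodicity.
    """
    if isinstance(mask, MosaicMask) and mask.base is not None:
        return np.tile(decoding_array(mask.base), (2, 2))
    g = np.where(mask.elements == 1, 1, -1).astype(np.int64)
    g[0, 0] = 1
    return g


def response_function(mask: MosaicMask) -> np.ndarray:
    """Full (non-periodic) cross-correlation of the mosaic with its decoder.

    The map shows one full-height central peak (the complete copy of a
    reconstructed object) and partial-height peaks at lags of one base period
    along the axes and at the corners -- the partial copies introduced by the
    mosaic periodicity.  The result is normalised by the number of base tiles
    (4) so the central peak height equals the open count of the base.
    """
    g = decoding_array(mask).astype(np.float64)
    r = correlate(mask.elements.astype(np.float64), g, mode="full")
    return r / 4.0


def complement_overlap(mask: MaskPattern) -> float:
    """Fraction of elements where the rotated mask equals the complement.

    For a true mask/antimask pair in the strict sense the 90-degree rotation
    would equal the logical complement element-wise; for MURA ranks with
    ``p = 3 (mod 4)`` the identity is not exact.  This diagnostic reports the
    agreement fraction so the discrepancy is visible rather than hidden.
    """
    rot = np.rot90(mask.elements)
    return float(np.mean(rot == 1 - mask.elements))
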