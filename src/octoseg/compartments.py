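"""Rasterization between boundary lines and four-compartment label masks.

The anatomical inclusion rules are: the vitreous lies strictly above the ILM;
the retina runs from the ILM row to and including the CC row (Bruch's membrane
is merged into this compartment because it is too thin to resolve); the
choroid lies strictly below the CC row down to and including the CSI row; the
sclera is everything below the CSI.

Fractional boundary coordinates are assigned to pixel rows by round-half-up,
so with ``R(t) = floor(t + 0.5)`` a column with row index ``r`` is::

    vitreous  : r <  R(ilm)
    retina    : R(ilm) <= r <= R(cc)
    choroid   : R(cc) <  r <= R(csi)
    sclera    : r >  R(csi)

which is a full partition for any ordered trace triple.  Note the retina is
never empty (it always owns at least the ILM row).
"""

from __future__ import annotations

import numpy as np

from .types import BoundarySet, Compartment, LabelMask, ValidationError

__all__ = ["lines_to_mask", "mask_to_lines", "round_half_up"]


def round_half_up(x: np.ndarray) -> np.ndarray:
    """Round to nearest integer with halves going up (toward larger rows)."""
    return np.floor(np.asarray(x, dtype=np.float64) + 0.5).astype(np.int64)


def lines_to_mask(
    boundaries: BoundarySet, height_px: int, width_px: int
) -> LabelMask:
    """Rasterize the three boundary traces into a label mask."""
    if boundaries.width_px != width_px:
        raise ValidationError(
            f"trace length {boundaries.width_px} does not match width_px {width_px}"
        )
    ilm = round_half_up(boundaries.ilm)
    cc = round_half_up(boundaries.cc)
    csi = round_half_up(boundaries.csi)
    rows = np.arange(height_px, dtype=np.int64)[:, None]
    # Sum of indicator steps gives the label directly because the class
    # encoding follows anatomical depth order.
    labels = (
        (rows >= ilm[None, :]).astype(np.uint8)
        + (rows > cc[None, :]).astype(np.uint8)
        + (rows > csi[None, :]).astype(np.uint8)
    )
    return LabelMask(labels=labels)


def mask_to_lines(mask: LabelMask) -> BoundarySet:
    """Recover boundary traces from a column-monotone label mask.

    Per column: ``ilm`` is the first retina row, ``cc`` the last retina row,
    ``csi`` the last choroid row (falling back to ``cc`` when the choroid is
    empty).  Degenerate columns use explicit fallbacks:

    - no retina but some non-vitreous label: all three lines collapse at the
      first non-vitreous row;
    - entirely vitreous: lines collapse at the last row (``height_px - 1``),
      the deepest representable position.

    For any mask produced by :func:`lines_to_mask`,
    ``lines_to_mask(mask_to_lines(m)) == m`` holds exactly.
    """
    if not mask.is_column_monotone():
        lab = mask.labels.astype(np.int16)
        bad = np.flatnonzero((np.diff(lab, axis=0) < 0).any(axis=0))
        raise ValidationError(
            f"mask is not column-monotone (first bad column: {int(bad[0])})"
        )
    lab = mask.labels
    h, w = lab.shape

    def first_row(cond: np.ndarray) -> np.ndarray:
        # first row where cond holds, else h
        return np.where(cond.any(axis=0), cond.argmax(axis=0), h).astype(np.int64)

    def last_row(cond: np.ndarray) -> np.ndarray:
        # last row where cond holds, else -1
        rev = cond[::-1]
        return np.where(cond.any(axis=0), h - 1 - rev.argmax(axis=0), -1).astype(
            np.int64
        )

    retina = lab == Compartment.RETINA
    choroid = lab == Compartment.CHOROID
    nonvit = lab != Compartment.VITREOUS

    ilm = first_row(retina).astype(np.float64)
    cc = last_row(retina).astype(np.float64)
    csi = last_row(choroid).astype(np.float64)

    has_retina = retina.any(axis=0)
    has_choroid = choroid.any(axis=0)

    # choroid absent -> csi collapses onto cc
    csi = np.where(has_choroid, csi, cc)
    # retina absent -> all three collapse at the first non-vitreous row;
    # an all-vitreous column collapses at the deepest representable row
    collapse = np.where(
        nonvit.any(axis=0), first_row(nonvit).astype(np.float64), float(h - 1)
    )
    ilm = np.where(has_retina, ilm, collapse)
    cc = np.where(has_retina, cc, collapse)
    csi = np.where(has_retina, csi, collapse)
    return BoundarySet(ilm=ilm, cc=cc, csi=csi, height_px=h, image_id="")
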