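"""Core domain types for OCT compartment segmentation.

An OCT B-scan is a cross-sectional grayscale image with the vitreous at the
top (row 0) and depth increasing with the row index.  Three boundary lines —
the internal limiting membrane (ILM), the inner border of the choriocapillaris
(CC) and the choroid–sclera interface (CSI) — partition every column into four
compartments: vitreous, retina, choroid and sclera.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DeviceKind",
    "Compartment",
    "COMPARTMENT_NAMES",
    "BScan",
    "BoundarySet",
    "LabelMask",
    "ScoreSet",
    "TestResult",
    "ValidationError",
]


class ValidationError(ValueError):
    """Raised when an input violates a domain-type invariant."""


class DeviceKind(str, enum.Enum):
    """OCT acquisition technology: spectral-domain or swept-source."""

    SD = "SD"
    SS = "SS"


class Compartment(enum.IntEnum):
    """Label encoding in anatomical depth order (top of image first)."""

    VITREOUS = 0
    RETINA = 1
    CHOROID = 2
    SCLERA = 3


COMPARTMENT_NAMES = tuple(c.name.lower() for c in Compartment)

#: Standard acquisition geometries (width_px, height_px).
SD_GEOMETRIES = ((384, 496), (768, 496), (1024, 496))
SS_GEOMETRY = (512, 992)


@dataclass
class BScan:
    """A single grayscale OCT cross-section with intensities in [0, 1]."""

    pixels: np.ndarray
    device_kind: DeviceKind = DeviceKind.SD
    scan_length_mm: float = 6.0
    id: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2:
            raise ValidationError(
                f"B-scan pixels must be 2-D, got shape {self.pixels.shape}"
            )
        if not np.isfinite(self.pixels).all():
            raise ValidationError("B-scan pixels must be finite")
        lo, hi = float(self.pixels.min(initial=0.0)), float(self.pixels.max(initial=0.0))
        if lo < 0.0 or hi > 1.0:
            raise ValidationError(
                f"B-scan intensities must lie in [0, 1]; got range [{lo}, {hi}]"
            )
        self.device_kind = DeviceKind(self.device_kind)
        if self.scan_length_mm <= 0:
            raise ValidationError("scan_length_mm must be positive")

    @property
    def height_px(self) -> int:
        return self.pixels.shape[0]

    @property
    def width_px(self) -> int:
        return self.pixels.shape[1]


@dataclass
class BoundarySet:
    """Per-column fractional row coordinates of the ILM, CC and CSI lines.

    Each trace has one value per image column.  At every column the anatomical
    ordering ``ilm <= cc <= csi`` must hold, and all traces must stay inside
    the image (``0 <= trace <= height_px - 1``).  ``height_px`` is carried so
    the upper bound can be validated.
    """

    ilm: np.ndarray
    cc: np.ndarray
    csi: np.ndarray
    height_px: int
    image_id: str = ""

    def __post_init__(self) -> None:
        self.ilm = np.asarray(self.ilm, dtype=np.float64)
        self.cc = np.asarray(self.cc, dtype=np.float64)
        self.csi = np.asarray(self.csi, dtype=np.float64)
        n = self.ilm.shape
        if self.cc.shape != n or self.csi.shape != n or self.ilm.ndim != 1:
            raise ValidationError("ilm/cc/csi must be 1-D arrays of equal length")
        for name, tr in (("ilm", self.ilm), ("cc", self.cc), ("csi", self.csi)):
            if not np.isfinite(tr).all():
                raise ValidationError(f"{name} trace contains non-finite values")
        bad = np.flatnonzero((self.ilm > self.cc) | (self.cc > self.csi))
        if bad.size:
            raise ValidationError(
                f"boundary ordering ilm <= cc <= csi violated at column {int(bad[0])}"
            )
        out = np.flatnonzero(
            (self.ilm < 0) | (self.csi > self.height_px - 1)
        )
        if out.size:
            raise ValidationError(
                f"boundary trace leaves the image at column {int(out[0])} "
                f"(height_px={self.height_px})"
            )

    @property
    def width_px(self) -> int:
        return self.ilm.shape[0]

    def traces(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return self.ilm, self.cc, self.csi


@dataclass
class LabelMask:
    """Per-pixel compartment labels (0=vitreous, 1=retina, 2=choroid, 3=sclera).

    Every pixel carries exactly one of the four labels.  Masks produced from
    boundary lines are additionally column-monotone (labels non-decreasing
    with depth); raw network predictions need not be, so monotonicity is a
    query (:meth:`is_column_monotone`) rather than a hard invariant.
    """

    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValidationError("labels must be an integer array")
        if self.labels.ndim != 2:
            raise ValidationError("labels must be 2-D")
        if self.labels.size and (self.labels.min() < 0 or self.labels.max() > 3):
            raise ValidationError("labels must take values in {0, 1, 2, 3}")
        self.labels = self.labels.astype(np.uint8)

    @property
    def height_px(self) -> int:
        return self.labels.shape[0]

    @property
    def width_px(self) -> int:
        return self.labels.shape[1]

    def is_column_monotone(self) -> bool:
        """True if labels are non-decreasing with row index in every column."""
        return bool((np.diff(self.labels.astype(np.int16), axis=0) >= 0).all())

    def class_counts(self) -> np.ndarray:
        return np.bincount(self.labels.ravel(), minlength=4)


class ComparisonDesign(str, enum.Enum):
    INTRA_GRADER = "intra_grader"
    INTER_GRADER = "inter_grader"
    CNN_VS_GROUP = "cnn_vs_group"
    CNN_VS_GT = "cnn_vs_gt"


@dataclass
class ScoreSet:
    """A labelled collection of per-image IOU scores for one comparison design.

    ``provenance`` records, per score, the image id and a label for the pair
    of segmentations compared (e.g. ``"run1-run2"`` or ``"cnn-graderA"``).
    """

    design: ComparisonDesign
    group_or_grader: str
    compartment: Compartment
    scores: np.ndarray
    provenance: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.design = ComparisonDesign(self.design)
        self.compartment = Compartment(self.compartment)
        self.scores = np.asarray(self.scores, dtype=np.float64)
        if self.scores.ndim != 1:
            raise ValidationError("scores must be a 1-D array")
        if self.scores.size and (self.scores.min() < 0 or self.scores.max() > 1):
            raise ValidationError("IOU scores must lie in [0, 1]")
        if self.provenance and len(self.provenance) != self.scores.size:
            raise ValidationError("provenance length must match scores length")

    def __len__(self) -> int:
        return int(self.scores.size)


@dataclass
class TestResult:
    """Outcome of one two-sample comparison in the benchmarking table."""

    test_used: str  # "welch_t_two_sided" or "mann_whitney_u"
    p_value: float
    significant_at_1pct: bool
    normality_verdicts: tuple[bool, bool]

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValidationError("p_value must lie in [0, 1]")
        if self.significant_at_1pct != (self.p_value < 0.01):
            raise ValidationError("significance flag inconsistent with p-value")
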