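"""Readers and writers for B-scan images, boundary annotations, label masks
and IOU score tables.

Formats
-------
Images
    8- or 16-bit grayscale PNG/TIFF; intensities are rescaled to [0, 1] on
    read by dividing by the bit-depth maximum.
Annotations
    JSON (primary): one object per image with three named vertex lists, e.g.
    ``{"image_id": "b001", "ilm": [[x, y], ...], "cc": ..., "csi": ...}``.
    CSV (secondary): columns ``line_name,x,y``.
    Polylines are resampled to one fractional row value per integer column.
Masks
    Indexed (palette) PNG with palette indices 0–3; round trips are lossless.
Score tables
    CSV with columns ``design,group,grader_pair,image_id,compartment,iou``.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
from PIL import Image

from .types import (
    COMPARTMENT_NAMES,
    BoundarySet,
    BScan,
    Compartment,
    ComparisonDesign,
    DeviceKind,
    LabelMask,
    ScoreSet,
    ValidationError,
)

__all__ = [
    "read_bscan",
    "write_bscan",
    "read_annotation",
    "write_annotation",
    "read_mask",
    "write_mask",
    "read_score_table",
    "write_score_table",
    "resample_polyline",
]

# Distinct gray levels for the four compartments so mask PNGs are viewable.
_MASK_PALETTE = [(0, 0, 0), (85, 85, 85), (170, 170, 170), (255, 255, 255)]


def read_bscan(
    path: str | Path,
    device_kind: DeviceKind | str = DeviceKind.SD,
    scan_length_mm: float = 6.0,
) -> BScan:
    """Read a grayscale PNG/TIFF into a [0, 1]-scaled :class:`BScan`."""
    path = Path(path)
    arr = iio.imread(path)
    if arr.ndim == 3:
        # Accept images whose channels are identical (gray stored as RGB).
        if arr.shape[2] in (3, 4) and (arr[..., :3] == arr[..., :1]).all():
            arr = arr[..., 0]
        else:
            raise ValidationError(
                f"{path.name}: multi-channel image is not trivially grayscale"
            )
    if arr.ndim != 2:
        raise ValidationError(f"{path.name}: expected a 2-D grayscale image")
    if arr.dtype == np.uint8:
        maxval = 255.0
    elif arr.dtype == np.uint16:
        maxval = 65535.0
    else:
        raise ValidationError(
            f"{path.name}: unsupported pixel dtype {arr.dtype}; need uint8/uint16"
        )
    return BScan(
        pixels=arr.astype(np.float64) / maxval,
        device_kind=DeviceKind(device_kind),
        scan_length_mm=scan_length_mm,
        id=path.stem,
    )


def write_bscan(bscan: BScan, path: str | Path, bit_depth: int = 8) -> None:
    """Write a B-scan as an 8- or 16-bit grayscale PNG/TIFF."""
    if bit_depth == 8:
        arr = np.rint(bscan.pixels * 255.0).astype(np.uint8)
    elif bit_depth == 16:
        arr = np.rint(bscan.pixels * 65535.0).astype(np.uint16)
    else:
        raise ValidationError("bit_depth must be 8 or 16")
    iio.imwrite(Path(path), arr)


def resample_polyline(
    vertices: np.ndarray, width_px: int
) -> np.ndarray:
    """Resample an x-monotone polyline to one y per integer column.

    Linear interpolation between vertices; columns outside the polyline's x
    span get the nearest endpoint's y (constant extension).
    """
    v = np.asarray(vertices, dtype=np.float64)
    if v.ndim != 2 or v.shape[1] != 2 or v.shape[0] < 1:
        raise ValidationError("polyline must be an (n, 2) array of (x, y) vertices")
    x, y = v[:, 0], v[:, 1]
    if np.any(np.diff(x) < 0):
        raise ValidationError("polyline x coordinates must be non-decreasing")
    cols = np.arange(width_px, dtype=np.float64)
    # np.interp extends constantly beyond the x range, which is the wanted
    # endpoint extension.  Strictly vertical segments (duplicate x) resolve to
    # the first vertex at that x.
    xi, idx = np.unique(x, return_index=True)
    return np.interp(cols, xi, y[idx])


def _boundaryset_from_polylines(
    lines: dict[str, np.ndarray], width_px: int, height_px: int, image_id: str
) -> BoundarySet:
    traces = {}
    for name in ("ilm", "cc", "csi"):
        if name not in lines:
            raise ValidationError(f"annotation is missing the {name} line")
        traces[name] = resample_polyline(np.asarray(lines[name]), width_px)
    return BoundarySet(
        ilm=traces["ilm"],
        cc=traces["cc"],
        csi=traces["csi"],
        height_px=height_px,
        image_id=image_id,
    )


def read_annotation(
    path: str | Path, width_px: int, height_px: int
) -> BoundarySet:
    """Read a three-polyline annotation (JSON or CSV) into a BoundarySet."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        with open(path) as fh:
            doc = json.load(fh)
        image_id = doc.get("image_id", path.stem)
        lines = {k: np.asarray(doc[k]) for k in ("ilm", "cc", "csi") if k in doc}
    elif path.suffix.lower() == ".csv":
        lines: dict[str, list[list[float]]] = {}
        with open(path, newline="") as fh:
            for row in csv.DictReader(fh):
                lines.setdefault(row["line_name"], []).append(
                    [float(row["x"]), float(row["y"])]
                )
        lines = {k: np.asarray(v) for k, v in lines.items()}
        image_id = path.stem
    else:
        raise ValidationError(f"unsupported annotation format: {path.suffix}")
    return _boundaryset_from_polylines(lines, width_px, height_px, image_id)


def write_annotation(boundaries: BoundarySet, path: str | Path) -> None:
    """Write a BoundarySet as the JSON annotation dialect (one vertex/column)."""
    path = Path(path)
    cols = np.arange(boundaries.width_px, dtype=float)
    doc = {
        "image_id": boundaries.image_id,
        "height_px": boundaries.height_px,
    }
    for name, tr in zip(("ilm", "cc", "csi"), boundaries.traces()):
        doc[name] = [[float(c), float(v)] for c, v in zip(cols, tr)]
    with open(path, "w") as fh:
        json.dump(doc, fh)


def write_mask(mask: LabelMask, path: str | Path) -> None:
    """Write a label mask as an indexed PNG (palette indices 0–3)."""
    img = Image.fromarray(mask.labels, mode="P")
    palette = [c for rgb in _MASK_PALETTE for c in rgb]
    img.putpalette(palette + [0] * (768 - len(palette)))
    img.save(Path(path), format="PNG")


def read_mask(path: str | Path) -> LabelMask:
    """Read an indexed PNG back into a LabelMask (lossless round trip)."""
    img = Image.open(Path(path))
    if img.mode != "P":
        raise ValidationError(f"{Path(path).name}: mask PNG must be palette-indexed")
    arr = np.asarray(img, dtype=np.uint8)
    if arr.size and arr.max() > 3:
        raise ValidationError(
            f"{Path(path).name}: palette index {int(arr.max())} outside 0–3"
        )
    return LabelMask(labels=arr)


def write_score_table(score_sets: list[ScoreSet], path: str | Path) -> None:
    """Write ScoreSets to the long-format CSV score table."""
    rows = []
    for ss in score_sets:
        prov = ss.provenance or [("", "")] * len(ss)
        for (image_id, pair), score in zip(prov, ss.scores):
            rows.append(
                {
                    "design": ss.design.value,
                    "group": ss.group_or_grader,
                    "grader_pair": pair,
                    "image_id": image_id,
                    "compartment": COMPARTMENT_NAMES[ss.compartment],
                    "iou": float(score),
                }
            )
    pd.DataFrame(
        rows,
        columns=["design", "group", "grader_pair", "image_id", "compartment", "iou"],
    ).to_csv(path, index=False)


def read_score_table(path: str | Path) -> list[ScoreSet]:
    """Read a score-table CSV back into one ScoreSet per (design, group, compartment)."""
    df = pd.read_csv(path, keep_default_na=False)
    out = []
    for (design, group, comp), sub in df.groupby(
        ["design", "group", "compartment"], sort=False
    ):
        out.append(
            ScoreSet(
                design=ComparisonDesign(design),
                group_or_grader=str(group),
                compartment=Compartment(COMPARTMENT_NAMES.index(comp)),
                scores=sub["iou"].to_numpy(),
                provenance=list(zip(sub["image_id"].astype(str), sub["grader_pair"].astype(str))),
            )
        )
    return out
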