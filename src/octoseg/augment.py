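"""Dataset augmentation, network resizing and train/validation splitting.

Augmentation triples the dataset: every labeled B-scan contributes itself, a
left–right mirror, and one copy rotated by an angle drawn uniformly from a
small range (default ±8°).  Images are rotated with bilinear interpolation and
masks with nearest neighbour so no new labels appear; rotation borders are
filled by edge replication.  Splitting is grouped: all augmented variants of
one source image land on the same side of the train/validation boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, replace as dc_replace

import numpy as np
from skimage.transform import resize, rotate

from .types import BScan, LabelMask, ValidationError

__all__ = ["SplitSpec", "augment_dataset", "resize_for_network", "split_dataset", "source_id"]

#: separator between a source image id and its augmentation tag
_AUG_SEP = "#"


def source_id(item_id: str) -> str:
    """Source image id of an (possibly augmented) item id."""
    return item_id.split(_AUG_SEP, 1)[0]


@dataclass
class SplitSpec:
    """Train/validation split parameters (train size = floor(fraction * n))."""

    train_fraction: float = 0.8
    seed: int = 0
    stratify_by_device: bool = False

    def __post_init__(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise ValidationError("train_fraction must lie in (0, 1)")


def _rotate_pair(
    scan: BScan, mask: LabelMask, angle_deg: float
) -> tuple[np.ndarray, np.ndarray]:
    img = rotate(
        scan.pixels, angle_deg, order=1, mode="edge", preserve_range=True
    )
    lab = rotate(
        mask.labels.astype(np.float64),
        angle_deg,
        order=0,
        mode="edge",
        preserve_range=True,
    )
    return np.clip(img, 0.0, 1.0), lab.astype(np.uint8)


def augment_dataset(
    pairs: list[tuple[BScan, LabelMask]],
    rotation_range_deg: tuple[float, float] = (-8.0, 8.0),
    seed: int = 0,
) -> list[tuple[BScan, LabelMask]]:
    """Original + mirror + one random rotation per image: exactly 3n pairs.

    Augmented ids are tagged ``<id>#mirror`` / ``<id>#rot`` so grouped
    splitting can keep siblings together.
    """
    rng = np.random.default_rng(seed)
    out: list[tuple[BScan, LabelMask]] = []
    lo, hi = rotation_range_deg
    for scan, mask in pairs:
        if scan.pixels.shape != mask.labels.shape:
            raise ValidationError(
                f"{scan.id}: image shape {scan.pixels.shape} does not match "
                f"mask shape {mask.labels.shape}"
            )
        out.append((scan, mask))
        mirrored = dc_replace(
            scan,
            pixels=scan.pixels[:, ::-1].copy(),
            id=f"{scan.id}{_AUG_SEP}mirror",
        )
        out.append((mirrored, LabelMask(labels=mask.labels[:, ::-1].copy())))
        angle = float(rng.uniform(lo, hi))
        img, lab = _rotate_pair(scan, mask, angle)
        rotated = dc_replace(scan, pixels=img, id=f"{scan.id}{_AUG_SEP}rot")
        out.append((rotated, LabelMask(labels=lab)))
    return out


def resize_for_network(
    scan: BScan,
    mask: LabelMask | None = None,
    size: tuple[int, int] = (512, 512),
) -> tuple[BScan, LabelMask | None]:
    """Plain (aspect-breaking) resize: bicubic for images, nearest for masks."""
    img = resize(
        scan.pixels, size, order=3, mode="edge", anti_aliasing=False,
        preserve_range=True,
    )
    scan_out = dc_replace(scan, pixels=np.clip(img, 0.0, 1.0))
    mask_out = None
    if mask is not None:
        lab = resize(
            mask.labels, size, order=0, mode="edge", anti_aliasing=False,
            preserve_range=True,
        )
        mask_out = LabelMask(labels=lab.astype(np.uint8))
    return scan_out, mask_out


def split_dataset(items: list, spec: SplitSpec, group_key=None) -> tuple[list, list]:
    """Seeded grouped split with |train| = floor(train_fraction * n).

    ``group_key(item)`` identifies the source image of each item (default: the
    untagged ``BScan.id`` when the item is or contains a BScan, else the item's
    position, i.e. ungrouped).  Groups are shuffled and assigned whole to the
    training side until the target size is reached, so augmented siblings never
    straddle the boundary.  When group sizes do not tile the target exactly the
    training side is the largest grouped subset not exceeding the target.
    """
    n = len(items)
    if n == 0:
        return [], []
    if group_key is None:
        def group_key(item):  # noqa: ANN001 - heterogeneous items
            obj = item[0] if isinstance(item, tuple) else item
            return source_id(obj.id) if isinstance(obj, BScan) else id(obj)

    groups: dict = {}
    for idx, item in enumerate(items):
        groups.setdefault(group_key(item), []).append(idx)
    order = list(groups.keys())
    rng = np.random.default_rng(spec.seed)
    rng.shuffle(order)

    target = int(np.floor(spec.train_fraction * n))
    train_idx: list[int] = []
    val_idx: list[int] = []
    taken = 0
    for key in order:
        members = groups[key]
        if taken + len(members) <= target:
            train_idx.extend(members)
            taken += len(members)
        else:
            val_idx.extend(members)
    train_idx.sort()
    val_idx.sort()
    return [items[i] for i in train_idx], [items[i] for i in val_idx]
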