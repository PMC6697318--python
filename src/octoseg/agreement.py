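"""Pixel-based IOU (Jaccard) agreement and the four comparison designs.

For one compartment the IOU of two segmentations is the ratio of the pixel
counts of the intersection and union of its supports; 1 means perfect
agreement.  When a compartment is absent from both masks the union is empty
and the score is defined as 1.0 (both raters agree it is absent).

Comparison designs over an n-image benchmark:

- intra-grader: one grader's three runs, all three unordered run pairs per
  image -> 3*n scores per compartment;
- inter-grader: the first runs of a group's three graders, all three
  unordered grader pairs per image -> 3*n scores per compartment;
- CNN vs group: the network prediction against each of the three graders'
  first runs per image -> 3*n scores per compartment;
- CNN vs ground truth: prediction against the reference annotation -> n.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd

from .compartments import lines_to_mask
from .types import (
    COMPARTMENT_NAMES,
    BoundarySet,
    Compartment,
    ComparisonDesign,
    LabelMask,
    ScoreSet,
    ValidationError,
)

__all__ = [
    "compartment_iou",
    "all_compartment_ious",
    "intra_grader_scores",
    "inter_grader_scores",
    "cnn_vs_group_scores",
    "cnn_vs_gt_scores",
    "summarize",
    "summary_table",
]


def compartment_iou(a: LabelMask, b: LabelMask, compartment: int) -> float:
    """IOU of one compartment's pixel supports in two masks of equal size."""
    if a.labels.shape != b.labels.shape:
        raise ValidationError(
            f"mask shapes differ: {a.labels.shape} vs {b.labels.shape}"
        )
    k = int(Compartment(compartment))
    sa, sb = a.labels == k, b.labels == k
    union = int(np.count_nonzero(sa | sb))
    if union == 0:
        return 1.0
    return int(np.count_nonzero(sa & sb)) / union


def all_compartment_ious(a: LabelMask, b: LabelMask) -> np.ndarray:
    """IOU for all four compartments in one pass (same convention)."""
    if a.labels.shape != b.labels.shape:
        raise ValidationError(
            f"mask shapes differ: {a.labels.shape} vs {b.labels.shape}"
        )
    out = np.empty(4)
    for k in range(4):
        sa, sb = a.labels == k, b.labels == k
        union = int(np.count_nonzero(sa | sb))
        out[k] = 1.0 if union == 0 else int(np.count_nonzero(sa & sb)) / union
    return out


def _rasterize(b: BoundarySet, width_px: int | None = None) -> LabelMask:
    return lines_to_mask(b, b.height_px, width_px or b.width_px)


def _check_coverage(
    image_ids: list[str], annotation_sets: dict[str, dict[str, BoundarySet]]
) -> None:
    for label, ann in annotation_sets.items():
        missing = [i for i in image_ids if i not in ann]
        if missing:
            raise ValidationError(f"{label}: missing annotations for images {missing}")


def _pairwise_scores(
    design: ComparisonDesign,
    who: str,
    image_ids: list[str],
    masks: dict[str, dict[str, LabelMask]],
    pairs: list[tuple[str, str]],
) -> list[ScoreSet]:
    """IOU per image, per pair, per compartment -> one ScoreSet per compartment."""
    scores = {k: [] for k in range(4)}
    provenance = []
    for image_id in image_ids:
        for left, right in pairs:
            ious = all_compartment_ious(masks[left][image_id], masks[right][image_id])
            for k in range(4):
                scores[k].append(ious[k])
            provenance.append((image_id, f"{left}-{right}"))
    return [
        ScoreSet(
            design=design,
            group_or_grader=who,
            compartment=Compartment(k),
            scores=np.asarray(scores[k]),
            provenance=list(provenance),
        )
        for k in range(4)
    ]


def _rasterize_all(
    image_ids: list[str], runs: dict[str, dict[str, BoundarySet]]
) -> dict[str, dict[str, LabelMask]]:
    return {
        label: {i: _rasterize(ann[i]) for i in image_ids}
        for label, ann in runs.items()
    }


def intra_grader_scores(
    runs: dict[int, dict[str, BoundarySet]], grader: str
) -> list[ScoreSet]:
    """Within-grader reproducibility: all run pairs (1,2), (1,3), (2,3).

    ``runs`` maps run index -> {image_id -> BoundarySet}.  With n images and
    three runs this yields 3*n scores per compartment.
    """
    run_ids = sorted(runs)
    named = {f"run{r}": runs[r] for r in run_ids}
    image_ids = sorted(named[f"run{run_ids[0]}"])
    _check_coverage(image_ids, named)
    masks = _rasterize_all(image_ids, named)
    pairs = list(combinations([f"run{r}" for r in run_ids], 2))
    return _pairwise_scores(
        ComparisonDesign.INTRA_GRADER, grader, image_ids, masks, pairs
    )


def inter_grader_scores(
    first_runs: dict[str, dict[str, BoundarySet]], group: str
) -> list[ScoreSet]:
    """Across-grader agreement on first runs: all unordered grader pairs."""
    graders = sorted(first_runs)
    image_ids = sorted(first_runs[graders[0]])
    _check_coverage(image_ids, first_runs)
    masks = _rasterize_all(image_ids, first_runs)
    pairs = list(combinations(graders, 2))
    return _pairwise_scores(
        ComparisonDesign.INTER_GRADER, group, image_ids, masks, pairs
    )


def cnn_vs_group_scores(
    predictions: dict[str, LabelMask],
    first_runs: dict[str, dict[str, BoundarySet]],
    group: str,
) -> list[ScoreSet]:
    """Network prediction vs each group member's first run: 3*n scores."""
    graders = sorted(first_runs)
    image_ids = sorted(first_runs[graders[0]])
    _check_coverage(image_ids, first_runs)
    missing = [i for i in image_ids if i not in predictions]
    if missing:
        raise ValidationError(f"predictions missing for images {missing}")
    masks = _rasterize_all(image_ids, first_runs)
    masks["cnn"] = {i: predictions[i] for i in image_ids}
    pairs = [("cnn", g) for g in graders]
    return _pairwise_scores(
        ComparisonDesign.CNN_VS_GROUP, group, image_ids, masks, pairs
    )


def cnn_vs_gt_scores(
    predictions: dict[str, LabelMask], ground_truth: dict[str, BoundarySet]
) -> list[ScoreSet]:
    """Network prediction vs the reference annotation: n scores/compartment."""
    image_ids = sorted(ground_truth)
    missing = [i for i in image_ids if i not in predictions]
    if missing:
        raise ValidationError(f"predictions missing for images {missing}")
    masks = {
        "gt": {i: _rasterize(ground_truth[i]) for i in image_ids},
        "cnn": {i: predictions[i] for i in image_ids},
    }
    return _pairwise_scores(
        ComparisonDesign.CNN_VS_GT, "gt", image_ids, masks, [("cnn", "gt")]
    )


def summarize(scores: ScoreSet) -> dict[str, float]:
    """Five-number summary plus mean (the data behind one box plot)."""
    if len(scores) == 0:
        raise ValidationError("cannot summarize an empty ScoreSet")
    x = scores.scores
    q1, med, q3 = np.percentile(x, [25, 50, 75])
    return {
        "design": scores.design.value,
        "group": scores.group_or_grader,
        "compartment": COMPARTMENT_NAMES[scores.compartment],
        "n": int(x.size),
        "mean": float(x.mean()),
        "min": float(x.min()),
        "q1": float(q1),
        "median": float(med),
        "q3": float(q3),
        "max": float(x.max()),
    }


def summary_table(score_sets: list[ScoreSet]) -> pd.DataFrame:
    """One summary row per ScoreSet (design x group x compartment)."""
    return pd.DataFrame([summarize(s) for s in score_sets])
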