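"""Mask-overlap scoring of registration quality.

Every frame's cervix mask is compared with the frame-1 (reference) mask by
the Dice coefficient 2|A∩B|/(|A|+|B|) and the IoU |A∩B|/|A∪B|; a sequence
report carries the per-frame curves (frames 2..T), their unweighted means at
full precision, and the relative-improvement statistic
100·(registered − unregistered)/unregistered between two conditions.

Note that while dice = 2·iou/(1+iou) holds for every individual mask pair,
it does not hold between *averaged* Dice and averaged IoU, so both means are
reported independently.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import List, Optional

import numpy as np

__all__ = ["dice", "iou", "EvalReport", "evaluate_sequence", "improvement"]


def _as_bool(mask, name):
    mask = np.asarray(mask)
    if mask.dtype != bool:
        uniq = np.unique(mask)
        if not np.all(np.isin(uniq, (0, 1))) and not np.all(
            np.isin(uniq, (0, 255))
        ):
            raise ValueError(f"{name} is not binary (values {uniq[:6]}...)")
        mask = mask > 0
    return mask


def _overlap(a, b):
    a = _as_bool(a, "mask a")
    b = _as_bool(b, "mask b")
    if a.shape != b.shape:
        raise ValueError(f"mask shapes differ: {a.shape} vs {b.shape}")
    na, nb = int(a.sum()), int(b.sum())
    if na == 0 and nb == 0:
        raise ValueError("both masks are empty; overlap is undefined")
    return int(np.logical_and(a, b).sum()), na, nb


def dice(a, b) -> float:
    """Dice coefficient 2|A∩B|/(|A|+|B|) of two binary masks."""
    inter, na, nb = _overlap(a, b)
    return 2.0 * inter / (na + nb)


def iou(a, b) -> float:
    """Intersection over union |A∩B|/|A∪B| of two binary masks."""
    inter, na, nb = _overlap(a, b)
    return inter / (na + nb - inter)


@dataclass
class EvalReport:
    """Per-frame overlap of frames 2..T against frame 1, with means."""

    per_frame_dice: List[float]
    per_frame_iou: List[float]
    mean_dice: float
    mean_iou: float
    improvement_percent: Optional[float] = None
    mask_source: str = "unspecified"

    def to_dict(self) -> dict:
        return {
            "per_frame_dice": self.per_frame_dice,
            "per_frame_iou": self.per_frame_iou,
            "mean_dice": self.mean_dice,
            "mean_iou": self.mean_iou,
            "improvement_percent": self.improvement_percent,
            "mask_source": self.mask_source,
        }

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def evaluate_sequence(masks, mask_source: str = "unspecified") -> EvalReport:
    """Score an index-aligned series of per-frame cervix masks.

    ``masks`` is a (T, H, W) binary array or list, T >= 2; frame 1 is the
    reference.  Means are unweighted averages over frames 2..T and are
    reported at full precision.
    """
    masks = [_as_bool(m, f"mask {i + 1}") for i, m in enumerate(masks)]
    if len(masks) < 2:
        raise ValueError("need at least 2 masks")
    shapes = {m.shape for m in masks}
    if len(shapes) != 1:
        raise ValueError(f"masks have mixed dimensions: {sorted(shapes)}")
    if masks[0].sum() == 0:
        raise ValueError("reference (frame 1) mask is empty")
    d = [dice(m, masks[0]) for m in masks[1:]]
    j = [iou(m, masks[0]) for m in masks[1:]]
    return EvalReport(
        per_frame_dice=d,
        per_frame_iou=j,
        mean_dice=float(np.mean(d)),
        mean_iou=float(np.mean(j)),
        mask_source=mask_source,
    )


def improvement(unregistered_mean: float, registered_mean: float) -> float:
    """Relative change (percent) of a mean overlap score after registration."""
    if unregistered_mean <= 0:
        raise ValueError("unregistered mean must be positive")
    return 100.0 * (registered_mean - unregistered_mean) / unregistered_mean
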