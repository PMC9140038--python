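"""Backward warping of images by dense displacement fields.

Convention
----------
A displacement field ``u`` is an ``(H, W, 2)`` array of ``(dy, dx)`` offsets
in absolute pixels defining a *backward* warp: ``output(p) = input(p + u(p))``.
Sampling locations outside the image are clamped to the border (no black
fill), which keeps the warped image free of empty corners.  Bilinear
interpolation is used for intensities; nearest-neighbour for binary masks.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .nn import bilinear_warp_forward

FIELD_CONVENTION = {
    "order": "dy_dx",
    "direction": "backward",
    "units": "pixels",
    "out_of_bounds": "clamp_to_edge",
}


def _check(image, field):
    field = np.asarray(field)
    image = np.asarray(image)
    if field.ndim != 3 or field.shape[2] != 2:
        raise ValueError(f"field must be (H, W, 2), got {field.shape}")
    if image.shape[:2] != field.shape[:2]:
        raise ValueError(
            f"image {image.shape[:2]} and field {field.shape[:2]} dimensions differ"
        )
    if not np.all(np.isfinite(field)):
        raise ValueError("field contains non-finite values")
    return image, field


def warp(image: np.ndarray, field: np.ndarray) -> np.ndarray:
    """Warp a single-channel (H, W) image by a (H, W, 2) displacement field.

    Each output pixel is the bilinear interpolation of the input at
    ``p + u(p)``; out-of-bounds samples clamp to the nearest border pixel.
    """
    image, field = _check(image, field)
    if image.ndim != 2:
        raise ValueError(f"image must be single-channel (H, W), got {image.shape}")
    warped, _ = bilinear_warp_forward(
        np.ascontiguousarray(image, dtype=np.float64),
        np.ascontiguousarray(field.transpose(2, 0, 1), dtype=np.float64),
    )
    return warped.astype(image.dtype, copy=False)


def warp_rgb(frame: np.ndarray, fields) -> np.ndarray:
    """Warp each channel of an (H, W, 3) frame by its own displacement field.

    ``fields`` is a sequence of three (H, W, 2) fields, one per channel;
    the channels are deliberately *not* forced to share a field.
    """
    frame = np.asarray(frame)
    if frame.ndim != 3 or frame.shape[2] != 3:
        raise ValueError(f"frame must be (H, W, 3), got {frame.shape}")
    fields = list(fields)
    if len(fields) != 3:
        raise ValueError(f"expected 3 fields, got {len(fields)}")
    return np.stack(
        [warp(frame[:, :, c], fields[c]) for c in range(3)], axis=-1
    )


def warp_mask_nearest(mask: np.ndarray, field: np.ndarray) -> np.ndarray:
    """Warp a binary mask with nearest-neighbour sampling; output stays binary."""
    mask, field = _check(mask, field)
    if mask.ndim != 2:
        raise ValueError(f"mask must be (H, W), got {mask.shape}")
    H, W = mask.shape
    rr, cc = np.meshgrid(np.arange(H), np.arange(W), indexing="ij")
    r = np.clip(np.rint(rr + field[:, :, 0]), 0, H - 1).astype(np.intp)
    c = np.clip(np.rint(cc + field[:, :, 1]), 0, W - 1).astype(np.intp)
    return mask[r, c]


def zero_field(height: int, width: int, dtype=np.float64) -> np.ndarray:
    return np.zeros((height, width, 2), dtype=dtype)


def save_field(path, field: np.ndarray) -> None:
    """Save a field as .npz with a JSON header recording the convention."""
    _, field = _check(np.zeros(field.shape[:2]), field)
    np.savez_compressed(
        path, field=field, convention=json.dumps(FIELD_CONVENTION)
    )


def load_field(path) -> np.ndarray:
    with np.load(path) as z:
        conv = json.loads(str(z["convention"]))
        if conv != FIELD_CONVENTION:
            raise ValueError(f"unsupported field convention in {Path(path)}: {conv}")
        return z["field"]
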