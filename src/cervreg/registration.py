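"""Inference: align every frame of a time sequence to its first frame.

Frame 1 is the reference and passes through untouched; each later frame is
pushed through the trained branch(es) against frame 1 to predict per-channel
displacement fields, then backward-warped channel by channel.  Binary masks
can be transported along a designated field with nearest-neighbour sampling
for ground-truth-based scoring.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import List

import numpy as np

from .network import BranchNetwork, CHANNELS, RGBRegistrar, predict_field
from .trainer import MODES, to_gray
from .transform import warp_mask_nearest, warp_rgb, zero_field

__all__ = ["RegisteredSequence", "register_sequence", "transport_mask"]


@dataclass
class RegisteredSequence:
    """Registered frames plus the fields that produced them.

    ``frames`` is (T, H, W, 3); frame 1 is bit-identical to the input
    reference.  ``fields[t]`` is a list of per-channel (H, W, 2) fields
    (three in rgb mode, one otherwise); frame 1's fields are identically
    zero.  ``mode`` records which channels were registered.
    """

    frames: np.ndarray
    fields: List[List[np.ndarray]]
    mode: str


def _model_branches(model, mode: str):
    if mode == "rgb":
        if not isinstance(model, RGBRegistrar):
            raise ValueError("rgb mode requires an RGBRegistrar")
        return [model.branches[c] for c in CHANNELS]
    if not isinstance(model, BranchNetwork):
        raise ValueError(f"{mode} mode requires a single BranchNetwork")
    return [model]


def _planes(frame, mode: str):
    if mode == "rgb":
        return [frame[:, :, c] for c in range(3)]
    if mode == "grayscale":
        return [to_gray(frame)]
    return [frame[:, :, CHANNELS.index(mode)]]


def register_sequence(model, sequence, mode: str = "rgb") -> RegisteredSequence:
    """Register frames 2..T of ``sequence`` to frame 1.

    In rgb mode each channel is warped by its own branch's field; in
    single-channel modes the one predicted field warps all three channels
    so the output remains a colour image.
    """
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}, got {mode!r}")
    sequence = np.asarray(sequence, dtype=np.float64)
    if sequence.ndim != 4 or sequence.shape[-1] != 3:
        raise ValueError(f"sequence must be (T, H, W, 3), got {sequence.shape}")
    T, H, W = sequence.shape[:3]
    if T < 2:
        raise ValueError("need at least 2 frames to register")
    branches = _model_branches(model, mode)
    if branches[0].height != H or branches[0].width != W:
        raise ValueError(
            f"model was built for {branches[0].height}x{branches[0].width}, "
            f"sequence is {H}x{W}"
        )
    head = branches[0].params["head_w"].data
    if float(np.abs(head).max()) < 1e-4:
        warnings.warn(
            "model head weights are near zero (untrained?); output will be "
            "close to the unregistered input",
            stacklevel=2,
        )

    ref = sequence[0]
    out_frames = np.empty_like(sequence)
    out_frames[0] = ref
    all_fields: List[List[np.ndarray]] = [
        [zero_field(H, W) for _ in branches]
    ]
    ref_planes = _planes(ref, mode)
    for t in range(1, T):
        moving = sequence[t]
        mov_planes = _planes(moving, mode)
        fields = [
            predict_field(br, np.stack([f_c, m_c]))
            for br, f_c, m_c in zip(branches, ref_planes, mov_planes)
        ]
        rgb_fields = fields if mode == "rgb" else [fields[0]] * 3
        out_frames[t] = np.clip(warp_rgb(moving, rgb_fields), 0.0, 1.0)
        all_fields.append(fields)
    return RegisteredSequence(frames=out_frames, fields=all_fields, mode=mode)


def transport_mask(mask, fields, channel_policy: str = "green") -> np.ndarray:
    """Warp a binary mask by one of a frame's predicted fields.

    ``fields`` is the per-channel field list of one frame; the designated
    field (default: the green channel's, or the only field in
    single-channel mode) transports the mask with nearest-neighbour
    sampling, so the output stays strictly binary.
    """
    mask = np.asarray(mask)
    if mask.dtype != bool:
        mask = mask > (mask.max() / 2 if mask.max() > 1 else 0.5)
    fields = list(fields)
    if len(fields) == 1:
        field = fields[0]
    elif channel_policy in CHANNELS:
        field = fields[CHANNELS.index(channel_policy)]
    else:
        raise ValueError(f"unknown channel_policy {channel_policy!r}")
    return warp_mask_nearest(mask, field)
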