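"""Photometric augmentation for per-sequence training.

Only appearance is perturbed — colour shift, contrast, unsharp-mask
sharpening, Gaussian noise.  No spatial transform of any kind is available
here, by construction: augmented frames keep their pixel coordinates, so a
frame's ground-truth mask (when one exists) remains valid, and the
registration target is never corrupted by synthetic motion.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np
from scipy.ndimage import gaussian_filter

KINDS = ("color_shift", "contrast", "sharpen", "gaussian_noise")

# documented magnitude ranges per kind
RANGES = {
    "color_shift": (-0.2, 0.2),  # additive per-channel shift
    "contrast": (0.7, 1.3),  # gain about the frame mean
    "sharpen": (0.0, 1.0),  # unsharp-mask amount
    "gaussian_noise": (0.0, 0.1),  # noise sigma
}

__all__ = ["KINDS", "RANGES", "augment_frame", "upsample_sequence", "Provenance"]


def augment_frame(frame, kind: str, magnitude: float, seed: int = 0) -> np.ndarray:
    """Apply one photometric augmentation to an (H, W, 3) frame in [0,1].

    Magnitude 0 (or contrast 1.0 — its identity point) returns the input
    unchanged.  Deterministic given ``seed``.
    """
    frame = np.asarray(frame, dtype=np.float64)
    if frame.ndim != 3 or frame.shape[2] != 3:
        raise ValueError(f"frame must be (H, W, 3), got {frame.shape}")
    if kind not in KINDS:
        raise ValueError(f"unknown augmentation kind {kind!r}; allowed: {KINDS}")
    lo, hi = RANGES[kind]
    if not lo <= magnitude <= hi:
        raise ValueError(f"{kind} magnitude {magnitude} outside [{lo}, {hi}]")
    rng = np.random.default_rng(seed)
    if kind == "color_shift":
        # shift one randomly chosen channel by the signed magnitude
        ch = int(rng.integers(3))
        out = frame.copy()
        out[:, :, ch] = out[:, :, ch] + magnitude
    elif kind == "contrast":
        mean = frame.mean()
        out = mean + magnitude * (frame - mean)
    elif kind == "sharpen":
        blurred = gaussian_filter(frame, sigma=(1.0, 1.0, 0.0))
        out = frame + magnitude * (frame - blurred)
    else:  # gaussian_noise
        out = frame + rng.normal(0.0, magnitude, size=frame.shape)
    return np.clip(out, 0.0, 1.0)


@dataclass(frozen=True)
class Provenance:
    """Where a pooled frame came from."""

    source_index: int  # 0-based frame index in the original sequence
    kind: Optional[str] = None  # None = unmodified original
    magnitude: float = 0.0


def upsample_sequence(
    sequence, per_frame_copies: int, seed: int = 0
) -> Tuple[np.ndarray, List[Provenance]]:
    """Expand a (T, H, W, 3) sequence into a training pool.

    Returns ``(pool, provenance)`` with ``T * (1 + per_frame_copies)``
    frames: every original, followed by augmented copies whose kinds are
    drawn uniformly from the four photometric kinds (magnitudes drawn
    within each kind's documented range, shrunk away from the extremes).
    """
    sequence = np.asarray(sequence, dtype=np.float64)
    if per_frame_copies < 0:
        raise ValueError("per_frame_copies must be >= 0")
    rng = np.random.default_rng(seed)
    pool = [sequence[i] for i in range(sequence.shape[0])]
    prov = [Provenance(i) for i in range(sequence.shape[0])]
    for i in range(sequence.shape[0]):
        for _ in range(per_frame_copies):
            kind = KINDS[int(rng.integers(len(KINDS)))]
            lo, hi = RANGES[kind]
            span = hi - lo
            mag = float(rng.uniform(lo + 0.1 * span, hi - 0.1 * span))
            sub = int(rng.integers(2 ** 31))
            pool.append(augment_frame(sequence[i], kind, mag, seed=sub))
            prov.append(Provenance(i, kind, mag))
    return np.stack(pool), prov
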