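"""Reading and writing time sequences, masks and ground-truth sidecars.

Sequences live on disk as directories of numbered 8-bit PNG (or TIFF/JPEG)
frames; masks as 0/255 single-channel PNGs; phantom ground truth as a JSON
sidecar of per-frame rigid transforms.  In memory everything is floating
point on [0,1].  Loading can resize so the longer edge matches a target
(aspect ratio preserved) and then symmetrically pad to dimensions divisible
by the network's downsampling factor; the padding is recorded in the
manifest so outputs can be cropped back.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass
from pathlib import Path
from typing import List, Optional, Tuple

import imageio.v3 as iio
import numpy as np
from scipy.ndimage import zoom as _ndzoom

from .network import N_DOWN
from .phantom import GroundTruth, RigidTransform

FRAME_EXTENSIONS = (".png", ".tif", ".tiff", ".jpg", ".jpeg")

__all__ = [
    "SequenceManifest",
    "load_sequence",
    "save_sequence",
    "load_masks",
    "save_masks",
    "save_ground_truth",
    "load_ground_truth",
]


@dataclass
class SequenceManifest:
    directory: str
    frame_files: List[str]
    height: int
    width: int
    n_frames: int
    mask_directory: Optional[str] = None
    provenance: str = "external"
    original_size: Optional[Tuple[int, int]] = None  # pre-resize (H, W)
    padding: Tuple[int, int, int, int] = (0, 0, 0, 0)  # top, bottom, left, right

    def to_dict(self) -> dict:
        return {
            "directory": self.directory,
            "frame_files": self.frame_files,
            "height": self.height,
            "width": self.width,
            "n_frames": self.n_frames,
            "mask_directory": self.mask_directory,
            "provenance": self.provenance,
            "original_size": list(self.original_size)
            if self.original_size
            else None,
            "padding": list(self.padding),
        }


def _natural_key(name: str):
    return [int(p) if p.isdigit() else p for p in re.split(r"(\d+)", name)]


def _resize(frame: np.ndarray, out_hw: Tuple[int, int]) -> np.ndarray:
    factors = (out_hw[0] / frame.shape[0], out_hw[1] / frame.shape[1])
    chans = [
        _ndzoom(frame[:, :, c], factors, order=1, grid_mode=True, mode="nearest")
        for c in range(frame.shape[2])
    ]
    out = np.stack(chans, axis=-1)
    if out.shape[:2] != out_hw:  # guard against rounding in zoom
        out = out[: out_hw[0], : out_hw[1]]
    return out


def load_sequence(path, long_edge: Optional[int] = None, pad_to_multiple: bool = True):
    """Load a directory of frames into a (T, H, W, 3) array in [0,1].

    Frames are ordered by natural filename sort.  If ``long_edge`` is given,
    frames are resized so their longer edge matches it (aspect preserved);
    dimensions are then symmetrically edge-padded up to the nearest multiple
    of the network's downsampling factor, with the padding recorded in the
    manifest.  Returns ``(frames, manifest)``.
    """
    path = Path(path)
    files = sorted(
        (f for f in path.iterdir() if f.suffix.lower() in FRAME_EXTENSIONS),
        key=lambda f: _natural_key(f.name),
    )
    if len(files) < 2:
        raise ValueError(f"{path} holds {len(files)} frames; need at least 2")
    frames = []
    for f in files:
        try:
            img = iio.imread(f)
        except Exception as exc:  # pragma: no cover - codec specific
            raise ValueError(f"cannot decode {f.name}: {exc}") from exc
        img = np.asarray(img)
        if img.ndim == 2:
            img = np.stack([img] * 3, axis=-1)
        if img.shape[2] == 4:
            img = img[:, :, :3]
        frames.append(img.astype(np.float64) / np.iinfo(img.dtype).max
                      if np.issubdtype(img.dtype, np.integer) else img)
    shapes = {f.shape for f in frames}
    if len(shapes) != 1:
        raise ValueError(f"mixed frame dimensions in {path}: {sorted(shapes)}")
    seq = np.stack(frames)
    original = seq.shape[1:3]

    if long_edge is not None:
        H, W = original
        scale = long_edge / max(H, W)
        out_hw = (int(round(H * scale)), int(round(W * scale)))
        seq = np.stack([_resize(f, out_hw) for f in seq])

    padding = (0, 0, 0, 0)
    if pad_to_multiple:
        div = 2 ** N_DOWN
        H, W = seq.shape[1:3]
        ph, pw = (-H) % div, (-W) % div
        if ph or pw:
            padding = (ph // 2, ph - ph // 2, pw // 2, pw - pw // 2)
            seq = np.pad(
                seq,
                ((0, 0), padding[:2], padding[2:], (0, 0)),
                mode="edge",
            )
    manifest = SequenceManifest(
        directory=str(path),
        frame_files=[f.name for f in files],
        height=seq.shape[1],
        width=seq.shape[2],
        n_frames=seq.shape[0],
        original_size=tuple(original),
        padding=padding,
    )
    return seq, manifest


def save_sequence(frames, path, prefix: str = "frame") -> List[Path]:
    """Write a (T, H, W, 3) [0,1] array as zero-padded 8-bit PNGs."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    frames = np.asarray(frames)
    digits = max(2, len(str(frames.shape[0])))
    written = []
    for t in range(frames.shape[0]):
        f = path / f"{prefix}_{t + 1:0{digits}d}.png"
        iio.imwrite(f, (np.clip(frames[t], 0, 1) * 255).round().astype(np.uint8))
        written.append(f)
    return written


def save_masks(masks, path) -> List[Path]:
    """Write (T, H, W) binary masks as 0/255 single-channel PNGs."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    masks = np.asarray(masks)
    digits = max(2, len(str(masks.shape[0])))
    written = []
    for t in range(masks.shape[0]):
        f = path / f"mask_{t + 1:0{digits}d}.png"
        iio.imwrite(f, (masks[t].astype(np.uint8) * 255))
        written.append(f)
    return written


def load_masks(path) -> np.ndarray:
    path = Path(path)
    files = sorted(
        (f for f in path.iterdir() if f.suffix.lower() == ".png"),
        key=lambda f: _natural_key(f.name),
    )
    if not files:
        raise ValueError(f"no mask PNGs in {path}")
    masks = [np.asarray(iio.imread(f)) for f in files]
    masks = [m[:, :, 0] if m.ndim == 3 else m for m in masks]
    return np.stack([m > 127 for m in masks])


def save_ground_truth(truth: GroundTruth, path) -> None:
    """Write per-frame rigid transforms as a JSON sidecar."""
    payload = {"transforms": [tf.to_dict() for tf in truth.transforms]}
    Path(path).write_text(json.dumps(payload, indent=2))


def load_ground_truth(path, masks=None) -> GroundTruth:
    payload = json.loads(Path(path).read_text())
    transforms = [RigidTransform.from_dict(d) for d in payload["transforms"]]
    if masks is None:
        masks = np.zeros((len(transforms), 1, 1), dtype=bool)
        masks[:, :, :] = True  # placeholder when only transforms are needed
    return GroundTruth(transforms=transforms, masks=np.asarray(masks))
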