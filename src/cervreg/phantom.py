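"""Synthetic acetowhitening phantom sequences with exact ground truth.

Each phantom emulates the structure of a colposcopy time sequence acquired on
a DYSIS-style digital colposcope: a roughly elliptical bright region (the
cervix) with a darker interior region (the os), whose epithelium brightens
over the sequence as the acetowhitening reaction develops.  Frames 2..T are
the frame-1 scene transported by per-frame rigid transforms (rotation about
the image centre plus translation), with photometric jitter and Gaussian
noise; the applied transforms and the rasterized per-frame cervix masks are
returned as ground truth.

The scene is defined analytically in continuous coordinates and evaluated at
the inverse-transformed pixel grid of every frame, so masks and transforms
are mutually consistent by construction (no resampling error enters the
ground truth).  Edges are smoothed over a configurable softness scale, which
mimics the soft tissue boundaries of real cervigrams and gives
intensity-driven registration a usable capture range.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np

__all__ = [
    "PhantomConfig",
    "RigidTransform",
    "GroundTruth",
    "whitening_profile",
    "generate_sequence",
    "rasterize_cervix_mask",
    "rigid_field",
]

# base colours (R, G, B) in [0,1]: dark vaginal background, pink cervix,
# darker os; green is suppressed relative to red as in real cervigrams
_BG = np.array([0.32, 0.10, 0.12])
_CERVIX = np.array([0.78, 0.46, 0.44])
_OS = np.array([0.42, 0.16, 0.17])


@dataclass(frozen=True)
class RigidTransform:
    """Rotation (degrees, about the image centre) then translation, mapping
    frame-1 geometry to a later frame."""

    rotation_deg: float = 0.0
    dy: float = 0.0
    dx: float = 0.0

    @property
    def is_identity(self) -> bool:
        return self.rotation_deg == 0.0 and self.dy == 0.0 and self.dx == 0.0

    def to_dict(self) -> dict:
        return {"rotation_deg": self.rotation_deg, "dy": self.dy, "dx": self.dx}

    @classmethod
    def from_dict(cls, d: dict) -> "RigidTransform":
        return cls(d["rotation_deg"], d["dy"], d["dx"])


@dataclass(frozen=True)
class PhantomConfig:
    height: int = 64
    width: int = 64
    n_frames: int = 17
    cervix_center: Optional[Tuple[float, float]] = None  # (row, col); None = centre
    cervix_axes: Tuple[float, float] = (22.0, 18.0)  # (a rows, b cols) semi-axes
    os_axes: Tuple[float, float] = (7.0, 5.0)
    whitening_rate: float = 0.5
    max_translation: float = 6.0
    max_rotation: float = 4.0
    illumination_jitter: float = 0.05
    noise_sigma: float = 0.01
    edge_softness: float = 2.0  # pixels over which region edges blend
    seed: int = 0

    @property
    def center(self) -> Tuple[float, float]:
        if self.cervix_center is not None:
            return self.cervix_center
        return ((self.height - 1) / 2.0, (self.width - 1) / 2.0)

    def validate(self) -> None:
        if self.n_frames < 2:
            raise ValueError(f"n_frames must be >= 2, got {self.n_frames}")
        if not (0.0 <= self.whitening_rate <= 1.0):
            raise ValueError("whitening_rate must lie in [0, 1]")
        if min(self.cervix_axes) <= 0 or min(self.os_axes) <= 0:
            raise ValueError("ellipse semi-axes must be positive")
        if not (
            self.os_axes[0] < self.cervix_axes[0]
            and self.os_axes[1] < self.cervix_axes[1]
        ):
            raise ValueError("os ellipse must be strictly contained in the cervix")
        cr, cc = self.center
        reach = max(self.cervix_axes) + self.max_translation
        if (
            cr - reach < 0
            or cc - reach < 0
            or cr + reach > self.height - 1
            or cc + reach > self.width - 1
        ):
            raise ValueError(
                "cervix ellipse (plus maximal translation) exceeds image bounds"
            )


@dataclass
class GroundTruth:
    """Exact per-frame transforms and rasterized cervix masks."""

    transforms: List[RigidTransform]
    masks: np.ndarray  # (T, H, W) bool

    def __post_init__(self):
        if not self.transforms[0].is_identity:
            raise ValueError("frame-1 transform must be the identity")


def whitening_profile(t: int, config: PhantomConfig) -> float:
    """Brightening multiplier for frame t (1-based).

    Saturating exponential: 1 at t=1, rising monotonically toward
    ``1 + whitening_rate``.  Applied in the generator as an exponent on the
    distance-to-white, ``I' = 1 - (1 - I)**w``, so intensities stay in [0,1]
    for any multiplier >= 1.
    """
    if not 1 <= t <= config.n_frames:
        raise ValueError(f"frame index {t} outside 1..{config.n_frames}")
    tau = max((config.n_frames - 1) / 3.0, 1e-9)
    return 1.0 + config.whitening_rate * (1.0 - float(np.exp(-(t - 1) / tau)))


def _inverse_transformed_grid(config: PhantomConfig, tf: RigidTransform):
    """Map every pixel of frame t back to frame-1 scene coordinates."""
    H, W = config.height, config.width
    cr, cc = config.center
    rr, cc_grid = np.meshgrid(
        np.arange(H, dtype=np.float64), np.arange(W, dtype=np.float64), indexing="ij"
    )
    th = np.deg2rad(tf.rotation_deg)
    cos, sin = np.cos(th), np.sin(th)
    y = rr - cr - tf.dy
    x = cc_grid - cc - tf.dx
    # inverse rotation
    y0 = cos * y + sin * x + cr
    x0 = -sin * y + cos * x + cc
    return y0, x0


def _ellipse_distance(y, x, center, axes):
    """Approximate signed distance (pixels) to an axis-aligned ellipse;
    negative inside."""
    a, b = axes
    cr, cc = center
    q = np.sqrt(((y - cr) / a) ** 2 + ((x - cc) / b) ** 2)
    return (q - 1.0) * min(a, b)


def _soft(d, softness):
    if softness <= 0:
        return (d < 0).astype(np.float64)
    return 1.0 / (1.0 + np.exp(np.clip(d / softness, -50, 50)))


def _render_frame(config: PhantomConfig, tf: RigidTransform, t: int) -> np.ndarray:
    """Evaluate the analytic scene, transported by tf, at frame t."""
    y0, x0 = _inverse_transformed_grid(config, tf)
    ctr = config.center
    d_cervix = _ellipse_distance(y0, x0, ctr, config.cervix_axes)
    d_os = _ellipse_distance(y0, x0, ctr, config.os_axes)
    s_cervix = _soft(d_cervix, config.edge_softness)
    s_os = _soft(d_os, config.edge_softness)
    frame = np.empty((config.height, config.width, 3), dtype=np.float64)
    w = whitening_profile(t, config)
    for ch in range(3):
        base = (
            _BG[ch]
            + s_cervix * (_CERVIX[ch] - _BG[ch])
            + s_os * (_OS[ch] - _CERVIX[ch])
        )
        # acetowhitening brightens the epithelium (cervix minus os)
        white = 1.0 - (1.0 - base) ** w
        epith = s_cervix * (1.0 - s_os)
        frame[:, :, ch] = base + epith * (white - base)
    return frame


def rasterize_cervix_mask(config: PhantomConfig, tf: RigidTransform) -> np.ndarray:
    """Hard cervix mask of the frame-1 ellipse transported by tf."""
    y0, x0 = _inverse_transformed_grid(config, tf)
    return _ellipse_distance(y0, x0, config.center, config.cervix_axes) < 0


def rigid_field(tf: RigidTransform, height: int, width: int) -> np.ndarray:
    """Backward displacement field (H, W, 2) that undoes tf.

    Warping frame t by this field recovers frame 1:
    ``frame1(p) = frame_t(T(p))``, so ``u(p) = T(p) - p`` where T maps
    frame-1 coordinates to frame-t coordinates (rotation about the image
    centre, then translation).
    """
    cr, cc = (height - 1) / 2.0, (width - 1) / 2.0
    rr, cc_grid = np.meshgrid(
        np.arange(height, dtype=np.float64),
        np.arange(width, dtype=np.float64),
        indexing="ij",
    )
    th = np.deg2rad(tf.rotation_deg)
    cos, sin = np.cos(th), np.sin(th)
    y = rr - cr
    x = cc_grid - cc
    ty = cos * y - sin * x + cr + tf.dy
    tx = sin * y + cos * x + cc + tf.dx
    return np.stack([ty - rr, tx - cc_grid], axis=-1)


def generate_sequence(config: PhantomConfig):
    """Generate one phantom time sequence.

    Returns ``(frames, truth)`` where ``frames`` is a ``(T, H, W, 3)`` float
    array in [0,1] and ``truth`` a :class:`GroundTruth`.  Frame 1 is the
    reference; each later frame is the same scene under a rigid transform
    drawn uniformly within ``(±max_rotation, ±max_translation)`` from the
    config seed, with per-frame illumination/colour jitter and Gaussian
    noise.  Identical configs produce bit-identical output.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    transforms = [RigidTransform()]
    for _ in range(config.n_frames - 1):
        rot = float(rng.uniform(-config.max_rotation, config.max_rotation))
        dy = float(rng.uniform(-config.max_translation, config.max_translation))
        dx = float(rng.uniform(-config.max_translation, config.max_translation))
        transforms.append(RigidTransform(rot, dy, dx))

    frames = np.empty(
        (config.n_frames, config.height, config.width, 3), dtype=np.float64
    )
    masks = np.empty((config.n_frames, config.height, config.width), dtype=bool)
    for t, tf in enumerate(transforms, start=1):
        frame = _render_frame(config, tf, t)
        jit = config.illumination_jitter
        if jit > 0:
            gain = rng.uniform(1.0 - jit, 1.0 + jit)
            color = rng.uniform(1.0 - jit / 2.0, 1.0 + jit / 2.0, size=3)
            frame = frame * (gain * color)[None, None, :]
        elif jit == 0:
            pass
        if config.noise_sigma > 0:
            frame = frame + rng.normal(0.0, config.noise_sigma, size=frame.shape)
        frames[t - 1] = np.clip(frame, 0.0, 1.0)
        masks[t - 1] = rasterize_cervix_mask(config, tf)
    return frames, GroundTruth(transforms=transforms, masks=masks)
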