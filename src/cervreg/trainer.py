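"""Per-sequence unsupervised training of the registration network.

Misalignment in an acetowhitening sequence is intra-sequence, so the network
is fitted to one time sequence at a time: at every step two distinct frames
are drawn from the sequence's photometrically augmented pool, one labelled
"fixed" and one "moving" (batch size one), the pair is split into colour
channels routed to the corresponding branches, and the aggregated
similarity + smoothness loss is backpropagated through the spatial
transform into all trained branches.

Training never sees ground-truth transforms or masks — its inputs are the
frames and the configuration only.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from typing import List

import numpy as np

from . import nn
from .augment import upsample_sequence
from .losses import LossConfig, similarity_term, smoothness_term
from .network import (
    CHANNELS,
    DEFAULT_WIDTHS,
    RGBRegistrar,
    build_branch,
    build_rgb_registrar,
)
from .nn import Adam, Tensor

MODES = ("rgb", "red", "green", "blue", "grayscale")

LUMA = (0.299, 0.587, 0.114)  # ITU-R BT.601 luminance weights

__all__ = ["TrainConfig", "MODES", "train_on_sequence", "desk_profile",
           "full_profile", "to_gray", "write_log"]


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 420
    steps_per_epoch: int = 1000
    learning_rate: float = 1e-4
    optimizer: str = "adam"
    loss: LossConfig = field(default_factory=LossConfig)
    per_frame_copies: int = 1  # photometric augmentation copies per frame
    widths: tuple = tuple(DEFAULT_WIDTHS)
    mode: str = "rgb"
    seed: int = 0

    def validate(self) -> None:
        if self.epochs < 1 or self.steps_per_epoch < 1:
            raise ValueError("epochs and steps_per_epoch must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.optimizer != "adam":
            raise ValueError(f"unsupported optimizer {self.optimizer!r}")
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}, got {self.mode!r}")
        self.loss.validate()


def desk_profile(mode: str = "rgb", seed: int = 0) -> TrainConfig:
    """Reduced schedule sized for a single CPU: 64x64 phantoms train in
    a couple of minutes.  The full-scale schedule is :func:`full_profile`."""
    return TrainConfig(
        epochs=15,
        steps_per_epoch=60,
        learning_rate=2e-3,
        per_frame_copies=1,
        mode=mode,
        seed=seed,
    )


def full_profile(mode: str = "rgb", seed: int = 0) -> TrainConfig:
    """Full-scale schedule (420 epochs x 1000 steps, learning rate 1e-4)
    intended for long-edge-1024 clinical sequences on accelerator hardware."""
    return TrainConfig(mode=mode, seed=seed)


def to_gray(frame: np.ndarray) -> np.ndarray:
    """Luminance conversion of an (..., 3) RGB array."""
    return (
        LUMA[0] * frame[..., 0] + LUMA[1] * frame[..., 1] + LUMA[2] * frame[..., 2]
    )


def _channel_planes(frame: np.ndarray, mode: str):
    """Planes routed to trained branches, in branch order."""
    if mode == "rgb":
        return [frame[:, :, c] for c in range(3)]
    if mode == "grayscale":
        return [to_gray(frame)]
    return [frame[:, :, CHANNELS.index(mode)]]


def _branch_list(model, mode: str):
    if mode == "rgb":
        return [model.branches[name] for name in CHANNELS], list(CHANNELS)
    return [model], [mode]


def train_on_sequence(sequence, config: TrainConfig):
    """Fit the registration network to one time sequence.

    ``sequence`` is a (T, H, W, 3) array in [0,1], T >= 2, all frames the
    same size.  Returns ``(model, log)`` where ``model`` is a trained
    :class:`~cervreg.network.RGBRegistrar` (rgb mode) or a single
    :class:`~cervreg.network.BranchNetwork`, and ``log`` is one dict per
    step with per-channel similarity/smoothness terms and the total loss.
    The whole run — augmentation, initialization, pair sampling, updates —
    is reproducible from ``config.seed``.
    """
    config.validate()
    sequence = np.asarray(sequence, dtype=np.float64)
    if sequence.ndim != 4 or sequence.shape[-1] != 3:
        raise ValueError(f"sequence must be (T, H, W, 3), got {sequence.shape}")
    T, H, W = sequence.shape[:3]
    if T < 2:
        raise ValueError("need at least 2 frames to register")

    seeds = np.random.SeedSequence(config.seed).generate_state(3)
    pool, _prov = upsample_sequence(
        sequence, config.per_frame_copies, seed=int(seeds[0]) % (2 ** 31)
    )
    pool = pool.astype(np.float32)
    init_seed = int(seeds[1]) % (2 ** 31)
    if config.mode == "rgb":
        model = build_rgb_registrar(H, W, list(config.widths), seed=init_seed)
    else:
        model = build_branch(H, W, list(config.widths), seed=init_seed)
    branches, names = _branch_list(model, config.mode)
    params = [p for br in branches for p in br.parameters()]
    opt = Adam(params, lr=config.learning_rate)
    rng = np.random.default_rng(int(seeds[2]) % (2 ** 31))

    n_pool = pool.shape[0]
    log: List[dict] = []
    order = np.empty(0, dtype=np.intp)
    cursor = 0
    for epoch in range(config.epochs):
        for step in range(config.steps_per_epoch):
            # walk a shuffled pool in disjoint pairs; reshuffle when spent,
            # so every pooled frame is visited as epochs accumulate
            if cursor + 2 > order.size:
                order = rng.permutation(n_pool)
                cursor = 0
            i, j = int(order[cursor]), int(order[cursor + 1])
            cursor += 2
            fixed, moving = pool[i], pool[j]

            opt.zero_grad()
            total = None
            row = {"epoch": epoch, "step": step}
            f_planes = _channel_planes(fixed, config.mode)
            m_planes = _channel_planes(moving, config.mode)
            for name, br, f_c, m_c in zip(names, branches, f_planes, m_planes):
                stack = np.stack([f_c, m_c]).astype(np.float32)
                u = br.forward(stack)
                warped = nn.warp(Tensor(np.ascontiguousarray(m_c)), u)
                sim = similarity_term(Tensor(np.ascontiguousarray(f_c)),
                                      warped, config.loss)
                smooth = smoothness_term(u)
                term = sim + config.loss.lambda_smooth * smooth
                total = term if total is None else total + term
                row[f"sim_{name}"] = float(sim.data)
                row[f"smooth_{name}"] = float(smooth.data)
            loss_val = float(total.data)
            if not np.isfinite(loss_val):
                raise RuntimeError(
                    f"non-finite loss {loss_val} at epoch {epoch} step {step}; "
                    "lower the learning rate or the augmentation magnitudes"
                )
            total.backward()
            opt.step()
            row["total"] = loss_val
            log.append(row)
    return model, log


def write_log(log, path) -> None:
    """Write the per-step training log to CSV."""
    if not log:
        raise ValueError("empty training log")
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=list(log[0].keys()))
        writer.writeheader()
        writer.writerows(log)
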