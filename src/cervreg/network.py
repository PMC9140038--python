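"""Encoder-decoder registration CNN: one branch per colour channel.

A branch maps a (fixed, moving) single-channel pair — stacked as a
2-channel input — to a dense (dy, dx) displacement field at full input
resolution.  The architecture is U-Net-like with the channel widths
[16, 32, 32, 32, 32, 32, 32, 16] split evenly into a 4-stage stride-2
encoder and a 4-stage nearest-upsampling decoder with skip connections,
3x3 kernels and leaky-ReLU activations throughout, and a linear 2-channel
output head.  The head is initialized near zero so a freshly built branch
predicts (almost) the identity warp.

An RGB registrar is three such branches with identical architecture and
independent parameters, one each for the red, green and blue channels.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List

import numpy as np

from . import nn
from .nn import Tensor

DEFAULT_WIDTHS = [16, 32, 32, 32, 32, 32, 32, 16]
N_DOWN = 4  # stride-2 encoder stages; input dims must divide 2**N_DOWN
CHANNELS = ("red", "green", "blue")

__all__ = [
    "BranchNetwork",
    "RGBRegistrar",
    "build_branch",
    "build_rgb_registrar",
    "predict_field",
    "save_checkpoint",
    "load_checkpoint",
    "DEFAULT_WIDTHS",
    "CHANNELS",
]


def _he_conv(rng, c_out, c_in, k, std=None, dtype=np.float32):
    if std is None:
        std = np.sqrt(2.0 / (c_in * k * k))
    w = Tensor(rng.normal(0.0, std, size=(c_out, c_in, k, k)).astype(dtype))
    b = Tensor(np.zeros(c_out, dtype=dtype))
    w.requires_grad = b.requires_grad = True
    return w, b


@dataclass
class BranchNetwork:
    """Parameter set and topology of one single-channel registration branch."""

    height: int
    width: int
    widths: List[int]
    kernel_size: int = 3
    activation_slope: float = 0.2
    params: Dict[str, Tensor] = field(default_factory=dict)

    @property
    def enc_widths(self):
        return self.widths[: len(self.widths) // 2]

    @property
    def dec_widths(self):
        return self.widths[len(self.widths) // 2 :]

    def parameters(self):
        return list(self.params.values())

    def forward(self, pair: np.ndarray) -> Tensor:
        """(2, H, W) fixed/moving stack -> (2, H, W) displacement Tensor."""
        if pair.shape != (2, self.height, self.width):
            raise ValueError(
                f"input shape {pair.shape} != (2, {self.height}, {self.width})"
            )
        p = self.params
        slope = self.activation_slope
        x = Tensor(np.ascontiguousarray(pair, dtype=p["head_w"].data.dtype))
        skips = [x]
        h = x
        for i in range(len(self.enc_widths)):
            h = nn.leaky_relu(
                nn.conv2d(h, p[f"enc{i}_w"], p[f"enc{i}_b"], stride=2), slope
            )
            skips.append(h)
        # decoder: upsample, concatenate the matching encoder activation
        for i in range(len(self.dec_widths)):
            h = nn.upsample2x(h)
            skip = skips[len(self.enc_widths) - 1 - i]
            h = nn.leaky_relu(
                nn.conv2d(nn.concat([h, skip]), p[f"dec{i}_w"], p[f"dec{i}_b"]), slope
            )
        return nn.conv2d(h, p["head_w"], p["head_b"])


def build_branch(
    height: int,
    width: int,
    widths=DEFAULT_WIDTHS,
    seed: int = 0,
    dtype=np.float32,
) -> BranchNetwork:
    """Build and initialize one branch.

    The output head is drawn with std 1e-5 and zero bias so the initial
    predicted field is near zero everywhere (training starts from the
    identity warp).
    """
    widths = list(widths)
    if len(widths) < 2 or len(widths) % 2:
        raise ValueError("widths must split evenly into encoder and decoder halves")
    div = 2 ** N_DOWN
    if height % div or width % div:
        raise ValueError(
            f"input dimensions {height}x{width} must be divisible by {div}"
        )
    rng = np.random.default_rng(seed)
    net = BranchNetwork(height=height, width=width, widths=widths)
    enc, dec = net.enc_widths, net.dec_widths
    k = net.kernel_size
    c_in = 2
    for i, c_out in enumerate(enc):
        net.params[f"enc{i}_w"], net.params[f"enc{i}_b"] = _he_conv(
            rng, c_out, c_in, k, dtype=dtype
        )
        c_in = c_out
    # decoder stage i consumes upsampled features + the mirrored skip
    skip_widths = [2] + list(enc)  # input itself is the outermost skip
    for i, c_out in enumerate(dec):
        c_cat = c_in + skip_widths[len(enc) - 1 - i]
        net.params[f"dec{i}_w"], net.params[f"dec{i}_b"] = _he_conv(
            rng, c_out, c_cat, k, dtype=dtype
        )
        c_in = c_out
    net.params["head_w"], net.params["head_b"] = _he_conv(
        rng, 2, c_in, k, std=1e-5, dtype=dtype
    )
    return net


@dataclass
class RGBRegistrar:
    """Three architecturally identical, independently parameterized branches."""

    branches: Dict[str, BranchNetwork]

    @property
    def height(self):
        return self.branches["red"].height

    @property
    def width(self):
        return self.branches["red"].width

    def parameters(self):
        out = []
        for name in CHANNELS:
            out.extend(self.branches[name].parameters())
        return out


def build_rgb_registrar(
    height: int, width: int, widths=DEFAULT_WIDTHS, seed: int = 0
) -> RGBRegistrar:
    seeds = np.random.SeedSequence(seed).generate_state(3)
    return RGBRegistrar(
        branches={
            name: build_branch(height, width, widths, seed=int(s) % (2 ** 31))
            for name, s in zip(CHANNELS, seeds)
        }
    )


def predict_field(branch: BranchNetwork, pair) -> np.ndarray:
    """Run one branch on a (fixed, moving) channel pair.

    ``pair`` is a tuple/sequence of two (H, W) arrays in [0,1] (or an
    already stacked (2, H, W) array).  Returns an (H, W, 2) float field.
    """
    arr = np.asarray(pair, dtype=np.float64)
    if arr.ndim == 3 and arr.shape[0] == 2:
        stack = arr
    elif arr.ndim == 3 and arr.shape[-1] == 2:
        raise ValueError("pass the pair as (fixed, moving), not channel-last")
    else:
        raise ValueError(f"expected a (2, H, W) fixed/moving stack, got {arr.shape}")
    out = branch.forward(stack)
    return np.ascontiguousarray(out.data.transpose(1, 2, 0), dtype=np.float64)


# -- checkpoints ---------------------------------------------------------


def save_checkpoint(model, path) -> None:
    """Save parameters as .npz plus a JSON architecture sidecar."""
    path = Path(path)
    arrays, meta = {}, {}
    if isinstance(model, RGBRegistrar):
        meta["kind"] = "rgb"
        branches = model.branches
    else:
        meta["kind"] = "single"
        branches = {"only": model}
    ref = next(iter(branches.values()))
    meta.update(
        height=ref.height,
        width=ref.width,
        widths=ref.widths,
        kernel_size=ref.kernel_size,
        activation_slope=ref.activation_slope,
        branches=sorted(branches),
    )
    for bname, br in branches.items():
        for pname, t in br.params.items():
            arrays[f"{bname}/{pname}"] = t.data
    np.savez_compressed(path, **arrays)
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2))


def load_checkpoint(path):
    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    with np.load(path) as z:
        arrays = {k: z[k] for k in z.files}

    def rebuild(bname):
        br = BranchNetwork(
            height=meta["height"],
            width=meta["width"],
            widths=list(meta["widths"]),
            kernel_size=meta["kernel_size"],
            activation_slope=meta["activation_slope"],
        )
        prefix = f"{bname}/"
        for key, arr in arrays.items():
            if key.startswith(prefix):
                t = Tensor(arr)
                t.requires_grad = True
                br.params[key[len(prefix) :]] = t
        return br

    if meta["kind"] == "rgb":
        return RGBRegistrar(branches={b: rebuild(b) for b in meta["branches"]})
    return rebuild("only")
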