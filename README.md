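# cervreg

Unsupervised, per-channel registration of colposcopy time sequences, with a
synthetic acetowhitening phantom benchmark and Dice/IoU mask-overlap
evaluation.

## The problem

During a colposcopic exam, a sequence of cervix images (typically T = 17 on
a DYSIS-style digital colposcope) is acquired before and after applying
dilute acetic acid. The transient whitening of the cervical epithelium —
the *acetowhitening* reaction — carries diagnostic signal, but patient and
device motion misalign the frames, corrupting any downstream longitudinal
analysis. No registration ground truth exists for such data, so the
alignment must be learned without supervision, and it must preserve the
colour information that encodes the whitening dynamics.

## The method

Each frame *t* = 2..T (the *moving* image, m) is aligned to frame 1 (the
*fixed* image, f). The registrar has three independent branches, one per
RGB channel. A branch is an encoder–decoder CNN g_θ with channel widths
[16, 32, 32, 32, 32, 32, 32, 16] (four stride-2 encoder stages, four
upsampling decoder stages with skip connections, 3×3 kernels, leaky-ReLU),
mapping the stacked pair (f_c, m_c) to a dense displacement field
u_c : Ω → ℝ², one (dy, dx) offset per pixel. A differentiable spatial
transform layer backward-warps the moving channel by bilinear
interpolation, m′_c(p) = m_c(p + u_c(p)), clamping out-of-bounds samples to
the border so no black fill appears.

Training is per sequence and unsupervised: each step draws two distinct
frames from the photometrically augmented pool of one sequence (batch size
one), and minimises, summed over channels c,

    L = Σ_c  sim(f_c, m′_c)  +  λ · ‖∇u_c‖²

where `sim` is MSE by default (local normalized cross-correlation is
selectable), ‖∇u‖² is the mean squared forward-difference gradient of the
field (the local spatial variation loss), and λ = 0.1. Augmentation is
strictly photometric — colour shift, contrast, sharpening, Gaussian noise —
never spatial.

Because clinical sequences are restricted-access, the package ships a
phantom generator: elliptical cervix + os scenes whose epithelium brightens
along a saturating whitening profile, transported frame to frame by known
rigid transforms, with known rasterized masks. Registration quality is
scored as Dice = 2|A∩B|/(|A|+|B|) and IoU = |A∩B|/|A∪B| of each frame's
mask against frame 1, before vs after registration, plus the relative
improvement 100·(D_reg − D_unreg)/D_unreg.

## Worked example

```python
import numpy as np
import cervreg as cr

cfg = cr.PhantomConfig(seed=1)          # 64x64, 17 frames, <=6 px, <=4 deg
frames, truth = cr.generate_sequence(cfg)

unreg = cr.evaluate_sequence(truth.masks)
print(f"unregistered mean Dice: {unreg.mean_dice:.4f}")

model, log = cr.train_on_sequence(frames, cr.desk_profile(seed=1))
reg = cr.register_sequence(model, frames)

masks = [truth.masks[0]] + [
    cr.transport_mask(truth.masks[t], reg.fields[t]) for t in range(1, 17)
]
after = cr.evaluate_sequence(np.stack(masks))
print(f"registered mean Dice:   {after.mean_dice:.4f}")
print(f"improvement:            {cr.improvement(unreg.mean_dice, after.mean_dice):+.1f}%")
```

prints (about a minute on one CPU):

```
unregistered mean Dice: 0.8691
registered mean Dice:   0.9271
improvement:            +6.7%
```

The misaligned phantom's masks overlap frame 1 at Dice 0.869 on average;
after desk-profile training and registration the transported masks overlap
at 0.927, a 6.7% relative improvement — the same direction and order of
magnitude as reported for clinical DYSIS sequences (0.792 → 0.892, +12.6%),
where the misalignments are larger.

The same pipeline is scriptable from the shell:

```bash
cervreg simulate --out seq/ --seed 1
cervreg train --sequence seq/ --mode rgb --out model.npz
cervreg register --sequence seq/ --model model.npz --mode rgb --out reg/
cervreg evaluate --masks-ref seq/masks --masks-test reg/masks --out report.json
cervreg run --config config.yaml --out run/     # all four stages
```

## Layout

- `cervreg.phantom` — synthetic acetowhitening sequences with exact ground truth
- `cervreg.network` / `cervreg.nn` — branch CNN and the autodiff engine
- `cervreg.transform` — differentiable bilinear warping, mask transport
- `cervreg.losses` — similarity (MSE/LNCC) and smoothness losses
- `cervreg.augment` — photometric-only augmentation
- `cervreg.trainer` — per-sequence unsupervised training loop
- `cervreg.registration` — sequence inference against frame 1
- `cervreg.evaluation` — Dice/IoU scoring and improvement statistic
- `cervreg.io` / `cervreg.pipeline` / `cervreg.cli` — I/O, config, CLI

See `docs/methods.md` for modelling assumptions, parameter defaults and
limitations.
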