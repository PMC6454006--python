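"""Deep residual aggregation networks for nucleus segmentation.

**DRAN** is an encoder-decoder with a pre-activated 50-layer residual
contracting path (7x7 valid stride-1 stem, no max pooling, stage strides
1/2/2/2) and a valid-convolution expanding path.  The expanding path opens
with a 2x2 stride-2 transpose convolution, then alternates addition merges
with center-cropped contracting-stage skips, grouped-convolution decoders
(5x5 -> grouped 3x3 -> 1x1, all valid, each spatial side shrinking by 6) and
nearest-neighbor x2 upsampling.  A 102x102 input yields a 54x54 two-class
map; because every decoder convolution is valid, outputs carry no border
artifacts from zero padding.

**MDRAN** runs three DRANs on x0.5 / x1 / x2 copies of the input, resizes
each branch's decoder1 output (128 channels) to the x1 grid, fuses them by
element-wise addition and finishes with a same-padded decoder (decoder4).

Channel plan at full width: stem 64; stage outputs 256/512/1024/2048;
decoder3 [5x5 -> 1024, grouped 3x3 C=256 -> 1024, 1x1 -> 512], decoder2
[512, C=128, 256], decoder1 [256, C=64, 128]; decoder4 [5x5 128 -> 256,
grouped 3x3 C=64 -> 256, 1x1 -> classes].  Every grouped convolution keeps
4 channels per group, which is what a ``width_divisor`` > 1 preserves when
building reduced desk-scale variants.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .nn import functional as F
from .nn.autodiff import Tensor

__all__ = [
    "ContractingPath",
    "DRAN",
    "MDRAN",
    "build_contracting_path",
    "build_dran",
    "build_mdran",
    "dran_output_side",
    "weighted_loss",
    "BORDER_WEIGHTS",
    "UNIFORM_WEIGHTS",
    "Phase",
    "TrainSchedule",
    "default_dran_schedule",
    "default_mdran_schedule",
    "train_dran",
    "train_mdran",
    "patches_to_arrays",
]

#: w[true, predicted]: border pixels weigh 5.0 (6.0 when missed as
#: background); background pixels weigh 1.0 (4.0 when missed as border).
BORDER_WEIGHTS = np.array([[1.0, 4.0], [6.0, 5.0]])
UNIFORM_WEIGHTS = np.ones((2, 2))


class _PreActBottleneck(nn.Module):
    """Pre-activation bottleneck: BN-ReLU-1x1, BN-ReLU-3x3(s), BN-ReLU-1x1."""

    def __init__(self, in_ch, mid_ch, out_ch, stride, rng):
        super().__init__()
        self.bn1 = nn.BatchNorm2d(in_ch)
        self.conv1 = nn.Conv2d(in_ch, mid_ch, 1, rng)
        self.bn2 = nn.BatchNorm2d(mid_ch)
        self.conv2 = nn.Conv2d(mid_ch, mid_ch, 3, rng, stride=stride,
                               padding="same")
        self.bn3 = nn.BatchNorm2d(mid_ch)
        self.conv3 = nn.Conv2d(mid_ch, out_ch, 1, rng)
        self.proj = None
        if in_ch != out_ch or stride != 1:
            self.proj = nn.Conv2d(in_ch, out_ch, 1, rng, stride=stride,
                                  is_projection=True)

    def forward(self, x: Tensor) -> Tensor:
        pre = F.relu(self.bn1(x))
        shortcut = self.proj(pre) if self.proj is not None else x
        h = self.conv1(pre)
        h = self.conv2(F.relu(self.bn2(h)))
        h = self.conv3(F.relu(self.bn3(h)))
        return F.add(h, shortcut)


class ContractingPath(nn.Module):
    """Modified pre-activated 50-layer residual encoder.

    The 7x7 stem convolves with stride 1 and no padding, and the usual max
    pooling after it is removed, so a 102x102 input maps through stage
    spatial sides 96 / 96 / 48 / 24 / 12.
    """

    def __init__(self, rng, width_divisor: int = 1, blocks=(3, 4, 6, 3)):
        super().__init__()
        d = width_divisor
        stem = 64 // d
        self.stem = nn.Conv2d(3, stem, 7, rng, stride=1, padding="valid")
        mids = [64 // d, 128 // d, 256 // d, 512 // d]
        outs = [m * 4 for m in mids]
        strides = [1, 2, 2, 2]
        in_ch = stem
        stages = []
        for mid, out, s, n in zip(mids, outs, strides, blocks):
            units = []
            for i in range(n):
                units.append(_PreActBottleneck(in_ch, mid, out,
                                               s if i == 0 else 1, rng))
                in_ch = out
            stages.append(nn.Sequential(*units))
        self.stage1, self.stage2, self.stage3, self.stage4 = stages
        self.bn_out = nn.BatchNorm2d(outs[3])
        self.stage_channels = outs

    def forward(self, x: Tensor):
        h = self.stem(x)
        s1 = self.stage1(h)
        s2 = self.stage2(s1)
        s3 = self.stage3(s2)
        s4 = self.stage4(s3)
        return s1, s2, s3, F.relu(self.bn_out(s4))


class _Decoder(nn.Module):
    """Valid decoder block: 5x5 -> grouped 3x3 (4 ch/group) -> 1x1."""

    def __init__(self, in_ch, out_ch, reduced_ch, rng, padding="valid"):
        super().__init__()
        groups = max(1, out_ch // 4)
        self.conv5 = nn.Conv2d(in_ch, out_ch, 5, rng, padding=padding)
        self.bn5 = nn.BatchNorm2d(out_ch)
        self.conv3 = nn.Conv2d(out_ch, out_ch, 3, rng, padding=padding,
                               groups=groups)
        self.bn3 = nn.BatchNorm2d(out_ch)
        self.conv1 = nn.Conv2d(out_ch, reduced_ch, 1, rng)
        self.bn1 = nn.BatchNorm2d(reduced_ch)
        self.groups = groups

    def forward(self, x: Tensor) -> Tensor:
        h = F.relu(self.bn5(self.conv5(x)))
        h = F.relu(self.bn3(self.conv3(h)))
        return F.relu(self.bn1(self.conv1(h)))


def _merge(a: Tensor, b: Tensor) -> Tensor:
    """Addition merge; the larger operand is center-cropped to the smaller."""
    ha, wa = a.shape[2], a.shape[3]
    hb, wb = b.shape[2], b.shape[3]
    h, w = min(ha, hb), min(wa, wb)
    if (ha, wa) != (h, w):
        a = F.center_crop(a, h, w)
    if (hb, wb) != (h, w):
        b = F.center_crop(b, h, w)
    return F.add(a, b)


class DRAN(nn.Module):
    """Single-scale deep residual aggregation network (two-class head)."""

    def __init__(self, n_classes: int = 2, seed: int = 0,
                 width_divisor: int = 1, blocks=(3, 4, 6, 3)):
        super().__init__()
        rng = np.random.default_rng(seed)
        d = width_divisor
        self.contracting = ContractingPath(rng, d, blocks)
        c1, c2, c3, c4 = self.contracting.stage_channels
        self.tconv = nn.ConvTranspose2x2(c4, c3, rng)
        self.decoder3 = _Decoder(c3, 1024 // d, 512 // d, rng)
        self.decoder2 = _Decoder(512 // d, 512 // d, 256 // d, rng)
        self.decoder1 = _Decoder(256 // d, 256 // d, 128 // d, rng)
        self.head = nn.Conv2d(128 // d, n_classes, 1, rng)
        self.n_classes = n_classes
        self.width_divisor = d

    # -- forward ---------------------------------------------------------
    def features(self, x: Tensor) -> Tensor:
        """decoder1 output (the tensor MDRAN aggregates)."""
        s1, s2, s3, s4 = self.contracting(x)
        h = self.tconv(s4)
        h = self.decoder3(_merge(h, s3))
        h = F.upsample_nearest(h, 2)
        h = self.decoder2(_merge(h, s2))
        h = F.upsample_nearest(h, 2)
        return self.decoder1(_merge(h, s1))

    def forward(self, x: Tensor) -> Tensor:
        return F.softmax(self.head(self.features(x)), axis=1)

    # -- training phases -------------------------------------------------
    def expanding_modules(self):
        return [self.tconv, self.decoder3, self.decoder2, self.decoder1,
                self.head]

    def freeze_contracting(self):
        self.contracting.freeze()
        return self

    def unfreeze_all(self):
        self.unfreeze()
        self.train(self.training)
        return self


class _Decoder4(nn.Module):
    """Same-padded aggregation decoder of MDRAN."""

    def __init__(self, in_ch, mid_ch, n_classes, rng):
        super().__init__()
        self.conv5 = nn.Conv2d(in_ch, mid_ch, 5, rng, padding="same")
        self.bn5 = nn.BatchNorm2d(mid_ch)
        self.conv3 = nn.Conv2d(mid_ch, mid_ch, 3, rng, padding="same",
                               groups=max(1, mid_ch // 4))
        self.bn3 = nn.BatchNorm2d(mid_ch)
        self.conv1 = nn.Conv2d(mid_ch, n_classes, 1, rng)

    def forward(self, x: Tensor) -> Tensor:
        h = F.relu(self.bn5(self.conv5(x)))
        h = F.relu(self.bn3(self.conv3(h)))
        return self.conv1(h)


class MDRAN(nn.Module):
    """Three-scale aggregation of DRAN branches through decoder4.

    Branch inputs are the x0.5 / x1 / x2 nearest-neighbor resizes of the
    tile; each branch's decoder1 output is resized to the x1 branch's output
    grid and the three 128-channel maps are summed before decoder4.
    """

    SCALES = (0.5, 1.0, 2.0)

    def __init__(self, n_classes: int = 2, seed: int = 0,
                 width_divisor: int = 1, blocks=(3, 4, 6, 3)):
        super().__init__()
        rng = np.random.default_rng(seed)
        d = width_divisor
        self.branch05 = DRAN(n_classes, seed + 1, d, blocks)
        self.branch10 = DRAN(n_classes, seed + 2, d, blocks)
        self.branch20 = DRAN(n_classes, seed + 3, d, blocks)
        self.decoder4 = _Decoder4(128 // d, 256 // d, n_classes, rng)
        self.n_classes = n_classes

    def branches(self):
        return {0.5: self.branch05, 1.0: self.branch10, 2.0: self.branch20}

    def load_branch_weights(self, weights: dict[float, dict]):
        missing = set(self.SCALES) - set(weights)
        if missing:
            raise ValueError(f"missing branch weights for scales {sorted(missing)}")
        for scale, dran in self.branches().items():
            dran.load_state_dict(weights[scale])

    def forward(self, x: Tensor) -> Tensor:
        h, w = x.shape[2], x.shape[3]
        x05 = F.resize_nearest(x, max(1, h // 2), max(1, w // 2))
        x20 = F.resize_nearest(x, 2 * h, 2 * w)
        f10 = self.branch10.features(x)
        oh, ow = f10.shape[2], f10.shape[3]
        f05 = F.resize_nearest(self.branch05.features(x05), oh, ow)
        f20 = F.resize_nearest(self.branch20.features(x20), oh, ow)
        fused = F.add(F.add(f05, f10), f20)
        return F.softmax(self.decoder4(fused), axis=1)


def build_contracting_path(seed: int = 0, width_divisor: int = 1,
                           blocks=(3, 4, 6, 3)) -> ContractingPath:
    return ContractingPath(np.random.default_rng(seed), width_divisor, blocks)


def build_dran(n_classes: int = 2, seed: int = 0, width_divisor: int = 1,
               blocks=(3, 4, 6, 3)) -> DRAN:
    return DRAN(n_classes, seed, width_divisor, blocks)


def build_mdran(branch_weights: dict[float, dict] | None = None,
                n_classes: int = 2, seed: int = 0, width_divisor: int = 1,
                blocks=(3, 4, 6, 3)) -> MDRAN:
    model = MDRAN(n_classes, seed, width_divisor, blocks)
    if branch_weights is not None:
        model.load_branch_weights(branch_weights)
    return model


def dran_output_side(input_side: int) -> int:
    """Symbolic spatial-shape propagation through DRAN (square inputs).

    Mirrors the architecture arithmetic: valid 7x7 stem (-6), stride-2
    same-padded stages (ceil halving), 2x2 transpose convolution (doubling),
    addition merges (min of operand sides), valid decoders (-6 each) and
    nearest x2 upsampling.  Raises when an intermediate side collapses.
    """
    s = input_side - 6              # stem
    s1 = s
    s2 = -(-s1 // 2)
    s3 = -(-s2 // 2)
    s4 = -(-s3 // 2)
    h = min(2 * s4, s3) - 6         # merge + decoder3
    h = min(2 * h, s2) - 6          # upsample, merge + decoder2
    h = min(2 * h, s1) - 6          # upsample, merge + decoder1
    if h < 1:
        raise ValueError(f"input side {input_side} too small for DRAN")
    return h


def weighted_loss(probs, target, weights=UNIFORM_WEIGHTS, eps: float = 1e-7):
    """Mean weighted cross-entropy over pixels.

    ``probs`` is (B, K, H, W) class probabilities (Tensor or ndarray);
    ``target`` is (B, H, W) integer labels.  ``weights[t, c]`` multiplies the
    negative log-likelihood of a pixel of true class ``t`` whose predicted
    argmax is ``c`` (ties resolve to the higher class index).  Zero true-class
    probabilities are clamped at ``eps``.
    """
    if not isinstance(probs, Tensor):
        probs = Tensor(probs)
    return F.weighted_cross_entropy(probs, np.asarray(target),
                                    np.asarray(weights, dtype=np.float64), eps)


# --------------------------------------------------------------------------
# training schedules

@dataclass(frozen=True)
class Phase:
    """One training phase: epoch count, what trains, LR breakpoints.

    ``lr_breakpoints`` maps epoch index (within the phase) to the learning
    rate that takes effect at that epoch.
    """

    name: str
    epochs: int
    trainable: str                      # expanding | all | decoder4 | branches
    lr_breakpoints: dict[int, float]

    def lr_at(self, epoch: int) -> float:
        best = None
        for e, lr in sorted(self.lr_breakpoints.items()):
            if e <= epoch:
                best = lr
        if best is None:
            raise ValueError(f"no learning rate defined at epoch {epoch}")
        return best


@dataclass(frozen=True)
class TrainSchedule:
    phases: tuple[Phase, ...]
    batch_size: int = 32
    l2_factor: float = 1.0e-5
    adam_betas: tuple[float, float] = (0.9, 0.999)
    adam_eps: float = 1e-8


def default_dran_schedule() -> TrainSchedule:
    """Two-phase schedule: 35 epochs expanding-path-only with the stepped
    rate 1e-4 / 5e-5 / 1e-5 / 7.5e-6 / 5e-6, then 40 all-trainable epochs
    (continuing at the final rate, which the first phase ends on)."""
    phase1 = Phase("expanding", 35, "expanding",
                   {0: 1.0e-4, 1: 5.0e-5, 15: 1.0e-5, 25: 7.5e-6})
    phase2 = Phase("finetune", 40, "all", {0: 5.0e-6})
    return TrainSchedule((phase1, phase2))


def default_mdran_schedule() -> TrainSchedule:
    """10 epochs decoder4-only at 1e-4, then 35 epochs that also train the
    branch expanding paths at 1e-4 / 1e-5 / 1e-6 (epochs 1 / 15 / 30)."""
    phase_a = Phase("decoder4", 10, "decoder4", {0: 1.0e-4})
    phase_b = Phase("branches", 35, "branches",
                    {0: 1.0e-4, 15: 1.0e-5, 30: 1.0e-6})
    return TrainSchedule((phase_a, phase_b))


# --------------------------------------------------------------------------
# training loops

def patches_to_arrays(patches, task: str = "blob", input_side: int = 102,
                      target_side: int = 54):
    """Center-crop patches into network inputs and aligned targets."""
    from .seg_data import center_crop as _cc
    xs, ys = [], []
    for p in patches:
        img = _cc(p.image, input_side).astype(np.float32) / 255.0
        tgt = p.blob_target if task == "blob" else p.border_target
        ys.append(_cc(tgt, target_side).astype(np.int64))
        xs.append(img.transpose(2, 0, 1))
    return np.stack(xs), np.stack(ys)


def _run_epochs(model, forward, x, y, phase, schedule, weights, rng, history,
                steps_per_epoch=None):
    params = model.trainable_parameters()
    opt = nn.Adam(params, betas=schedule.adam_betas, eps=schedule.adam_eps,
                  l2=schedule.l2_factor)
    n = x.shape[0]
    bs = min(schedule.batch_size, n)
    for epoch in range(phase.epochs):
        opt.lr = phase.lr_at(epoch)
        order = rng.permutation(n)
        losses = []
        steps = 0
        for start in range(0, n, bs):
            if steps_per_epoch is not None and steps >= steps_per_epoch:
                break
            idx = order[start:start + bs]
            model.zero_grad()
            probs = forward(Tensor(x[idx]))
            loss = F.weighted_cross_entropy(probs, y[idx], weights)
            loss.backward()
            opt.step()
            losses.append(loss.item() + opt.penalty())
            steps += 1
        history.append({"phase": phase.name, "epoch": epoch, "lr": opt.lr,
                        "loss": float(np.mean(losses))})


def train_dran(model: DRAN, patches, schedule: TrainSchedule | None = None,
               seed: int = 0, task: str = "blob", weights=None,
               steps_per_epoch=None, input_side: int = 102,
               target_side: int = 54):
    """Two-phase DRAN training.

    Phase semantics: ``expanding`` freezes the contracting path (He-initialized
    or externally injected weights stay fixed, batch-norm statistics pinned);
    ``all`` unfreezes everything.  Returns ``(state_dict, history)`` with the
    per-epoch loss and the learning rate actually used.
    """
    if not patches:
        raise ValueError("training dataset is empty")
    schedule = default_dran_schedule() if schedule is None else schedule
    if weights is None:
        weights = UNIFORM_WEIGHTS if task == "blob" else BORDER_WEIGHTS
    rng = np.random.default_rng(seed)
    x, y = patches_to_arrays(patches, task, input_side, target_side)
    history: list[dict] = []
    for phase in schedule.phases:
        if phase.trainable == "expanding":
            model.unfreeze()
            model.freeze_contracting()
        elif phase.trainable == "all":
            model.unfreeze_all()
        else:
            raise ValueError(f"unsupported DRAN phase {phase.trainable!r}")
        model.train()
        _run_epochs(model, model.forward, x, y, phase, schedule, weights, rng,
                    history, steps_per_epoch)
    model.eval()
    return model.state_dict(), history


def train_mdran(model: MDRAN, patches, schedule: TrainSchedule | None = None,
                seed: int = 0, task: str = "blob", weights=None,
                steps_per_epoch=None, input_side: int = 102):
    """Two-phase MDRAN training on top of pretrained branch weights.

    Phase ``decoder4`` trains only the aggregation decoder (all branches
    frozen); phase ``branches`` additionally trains the branch expanding
    paths while every contracting path stays frozen throughout.
    """
    if not patches:
        raise ValueError("training dataset is empty")
    schedule = default_mdran_schedule() if schedule is None else schedule
    if weights is None:
        weights = UNIFORM_WEIGHTS if task == "blob" else BORDER_WEIGHTS
    rng = np.random.default_rng(seed)
    out_side = dran_output_side(input_side)
    x, y = patches_to_arrays(patches, task, input_side, out_side)
    history: list[dict] = []
    for phase in schedule.phases:
        if phase.trainable == "decoder4":
            for dran in model.branches().values():
                dran.freeze()
            model.decoder4.unfreeze()
        elif phase.trainable == "branches":
            for dran in model.branches().values():
                dran.unfreeze()
                dran.freeze_contracting()
            model.decoder4.unfreeze()
        else:
            raise ValueError(f"unsupported MDRAN phase {phase.trainable!r}")
        model.train()
        _run_epochs(model, model.forward, x, y, phase, schedule, weights, rng,
                    history, steps_per_epoch)
    model.eval()
    return model.state_dict(), history
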