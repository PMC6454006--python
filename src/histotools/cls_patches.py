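"""Patch-level lung-tissue classification.

256x256 H&E patches at 20x magnification are stain-normalized (Reinhard
color transfer in the l-alpha-beta space), randomly cropped to 224x224 with
flip/rotation augmentation, and classified into non-diagnostic (ND), lung
adenocarcinoma (LUAD) or lung squamous cell carcinoma (LUSC) by a 32-layer
residual network: a ResNet50 variant whose stem uses a 3x3 kernel (small
receptive fields matter for histology texture) and whose bottleneck-unit
plan is reduced from (3, 4, 6, 3) to (2, 3, 3, 2), giving
1 stem + 10 units x 3 convolutions + 1 classifier = 32 weighted layers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .fixtures import CLASS_NAMES
from .nn import functional as F
from .nn.autodiff import Tensor

__all__ = [
    "StainTarget",
    "ClsTrainConfig",
    "reinhard_normalize",
    "rgb_to_lab",
    "lab_to_rgb",
    "ResNet32",
    "build_resnet32",
    "augment_cls",
    "train_patch_classifier",
    "predict_patch",
]

# Ruderman et al. RGB <-> LMS <-> l-alpha-beta constants used by the Reinhard
# color-transfer method.
_RGB2LMS = np.array([[0.3811, 0.5783, 0.0402],
                     [0.1967, 0.7244, 0.0782],
                     [0.0241, 0.1288, 0.8444]])
_LMS2RGB = np.linalg.inv(_RGB2LMS)
_LMS2LAB = np.diag([1 / np.sqrt(3), 1 / np.sqrt(6), 1 / np.sqrt(2)]) @ np.array(
    [[1, 1, 1], [1, 1, -2], [1, -1, 0]], dtype=float)
_LAB2LMS = np.linalg.inv(_LMS2LAB)
_LMS_FLOOR = 1e-6


def rgb_to_lab(image: np.ndarray) -> np.ndarray:
    """RGB (0..255 or 0..1) to Ruderman l-alpha-beta, float64."""
    rgb = np.asarray(image, dtype=np.float64)
    if rgb.max() > 1.5:
        rgb = rgb / 255.0
    lms = rgb @ _RGB2LMS.T
    lms = np.log10(np.maximum(lms, _LMS_FLOOR))
    return lms @ _LMS2LAB.T


def lab_to_rgb(lab: np.ndarray) -> np.ndarray:
    """Inverse of :func:`rgb_to_lab`, returning uint8 RGB."""
    lms = np.power(10.0, lab @ _LAB2LMS.T)
    rgb = lms @ _LMS2RGB.T
    return np.clip(np.rint(rgb * 255.0), 0, 255).astype(np.uint8)


@dataclass(frozen=True)
class StainTarget:
    """Per-channel mean/std of a designated target image in l-alpha-beta."""

    means: tuple[float, float, float]
    stds: tuple[float, float, float]

    def __post_init__(self):
        if any(s <= 0 for s in self.stds):
            raise ValueError("target standard deviations must be positive")

    @classmethod
    def from_image(cls, image: np.ndarray) -> "StainTarget":
        lab = rgb_to_lab(image).reshape(-1, 3)
        stds = lab.std(axis=0)
        stds = np.maximum(stds, 1e-8)
        return cls(tuple(lab.mean(axis=0)), tuple(stds))


def reinhard_normalize(image: np.ndarray, target: StainTarget,
                       eps: float = 1e-8) -> np.ndarray:
    """Map an image's l-alpha-beta channel statistics onto the target's.

    Each channel is standardized by the source image's own mean/std and
    rescaled to the target statistics; zero-variance source channels are
    epsilon-guarded (the channel then simply shifts to the target mean).
    """
    if np.asarray(image).size == 0:
        raise ValueError("cannot normalize an empty image")
    lab = rgb_to_lab(image)
    flat = lab.reshape(-1, 3)
    mu = flat.mean(axis=0)
    sd = flat.std(axis=0)
    sd = np.maximum(sd, eps)
    out = (lab - mu) / sd * np.asarray(target.stds) + np.asarray(target.means)
    return lab_to_rgb(out)


# --------------------------------------------------------------------------
# ResNet32

class _Bottleneck(nn.Module):
    """Post-activation bottleneck unit (conv-BN-ReLU layout)."""

    def __init__(self, in_ch, mid_ch, out_ch, stride, rng):
        super().__init__()
        self.conv1 = nn.Conv2d(in_ch, mid_ch, 1, rng)
        self.bn1 = nn.BatchNorm2d(mid_ch)
        self.conv2 = nn.Conv2d(mid_ch, mid_ch, 3, rng, stride=stride,
                               padding="same")
        self.bn2 = nn.BatchNorm2d(mid_ch)
        self.conv3 = nn.Conv2d(mid_ch, out_ch, 1, rng)
        self.bn3 = nn.BatchNorm2d(out_ch)
        self.proj = None
        self.proj_bn = None
        if in_ch != out_ch or stride != 1:
            self.proj = nn.Conv2d(in_ch, out_ch, 1, rng, stride=stride,
                                  is_projection=True)
            self.proj_bn = nn.BatchNorm2d(out_ch)

    def forward(self, x: Tensor) -> Tensor:
        h = F.relu(self.bn1(self.conv1(x)))
        h = F.relu(self.bn2(self.conv2(h)))
        h = self.bn3(self.conv3(h))
        shortcut = x if self.proj is None else self.proj_bn(self.proj(x))
        return F.relu(F.add(h, shortcut))


class ResNet32(nn.Module):
    """32-weighted-layer residual classifier for 224x224 RGB patches."""

    def __init__(self, n_classes: int = 3, seed: int = 0,
                 width_divisor: int = 1, stage_plan=(2, 3, 3, 2)):
        super().__init__()
        rng = np.random.default_rng(seed)
        d = width_divisor
        stem = 64 // d
        self.stem = nn.Conv2d(3, stem, 3, rng, stride=2, padding="same")
        self.stem_bn = nn.BatchNorm2d(stem)
        self.pool = nn.MaxPool2d(3, 2)
        mids = [64 // d, 128 // d, 256 // d, 512 // d]
        strides = [1, 2, 2, 2]
        in_ch = stem
        stages = []
        for mid, s, n in zip(mids, strides, stage_plan):
            units = []
            for i in range(n):
                units.append(_Bottleneck(in_ch, mid, mid * 4,
                                         s if i == 0 else 1, rng))
                in_ch = mid * 4
            stages.append(nn.Sequential(*units))
        self.stages = nn.ModuleList(stages)
        self.gap = nn.GlobalAvgPool()
        self.fc = nn.Linear(in_ch, n_classes, rng)
        self.n_classes = n_classes
        self.stage_plan = tuple(stage_plan)

    def forward(self, x: Tensor) -> Tensor:
        h = F.relu(self.stem_bn(self.stem(x)))
        h = self.pool(h)
        for stage in self.stages:
            h = stage(h)
        return F.softmax(self.fc(self.gap(h)), axis=1)


def build_resnet32(n_classes: int = 3, seed: int = 0, width_divisor: int = 1,
                   stage_plan=(2, 3, 3, 2)) -> ResNet32:
    return ResNet32(n_classes, seed, width_divisor, stage_plan)


# --------------------------------------------------------------------------
# augmentation / training

def augment_cls(patch: np.ndarray, rng: np.random.Generator,
                crop_side: int = 224) -> np.ndarray:
    """Random crop to 224x224 plus random axis flips and 90-degree rotation."""
    if patch.shape[:2] != (256, 256):
        raise ValueError(f"expected a 256x256 patch, got {patch.shape[:2]}")
    r = int(rng.integers(0, 256 - crop_side + 1))
    c = int(rng.integers(0, 256 - crop_side + 1))
    out = patch[r:r + crop_side, c:c + crop_side]
    if rng.random() < 0.5:
        out = out[::-1, :]
    if rng.random() < 0.5:
        out = out[:, ::-1]
    out = np.rot90(out, k=int(rng.integers(0, 4)))
    return np.ascontiguousarray(out)


def _center_crop_224(patch: np.ndarray, crop_side: int = 224) -> np.ndarray:
    o = (patch.shape[0] - crop_side) // 2
    return patch[o:o + crop_side, o:o + crop_side]


@dataclass(frozen=True)
class ClsTrainConfig:
    """Patch-classifier training configuration.

    The optimal epoch is the one with the greatest average validation
    accuracy; ties resolve to the earliest epoch.
    """

    patch_side: int = 256
    crop_side: int = 224
    classes: tuple[str, ...] = CLASS_NAMES
    epochs: int = 5
    batch_size: int = 32
    lr: float = 1.0e-4
    l2_factor: float = 1.0e-5
    val_fraction: float = 0.25
    width_divisor: int = 1
    stage_plan: tuple[int, ...] = (2, 3, 3, 2)
    augment: bool = True


def _to_batch(images, crop_side, rng=None):
    out = []
    for img in images:
        arr = augment_cls(img, rng, crop_side) if rng is not None else \
            _center_crop_224(img, crop_side)
        out.append(arr.astype(np.float32).transpose(2, 0, 1) / 255.0)
    return np.stack(out)


def train_patch_classifier(patches, labels, config: ClsTrainConfig,
                           seed: int = 0, model: ResNet32 | None = None):
    """Train the 32-layer patch classifier.

    ``patches`` is a sequence of 256x256 RGB arrays; ``labels`` the matching
    class names.  Returns ``(model, result)`` where ``result`` holds the
    per-epoch validation accuracies, the selected epoch (1-based) and the
    selected epoch's weights (also loaded into the returned model).
    """
    labels = list(labels)
    y = np.array([config.classes.index(l) for l in labels])
    for k, name in enumerate(config.classes):
        if not (y == k).any():
            raise ValueError(f"class {name!r} has no training patches")
    rng = np.random.default_rng(seed)
    n = len(patches)
    order = rng.permutation(n)
    n_val = max(len(config.classes), int(round(config.val_fraction * n)))
    val_idx, train_idx = order[:n_val], order[n_val:]
    if train_idx.size == 0:
        raise ValueError("no training patches left after the validation split")

    if model is None:
        model = build_resnet32(len(config.classes), seed=seed,
                               width_divisor=config.width_divisor,
                               stage_plan=config.stage_plan)
    opt = nn.Adam(model.trainable_parameters(), lr=config.lr,
                  l2=config.l2_factor)
    table = np.ones((len(config.classes),) * 2)
    history = []
    checkpoints = []
    bs = min(config.batch_size, train_idx.size)
    for epoch in range(config.epochs):
        model.train()
        perm = rng.permutation(train_idx)
        losses = []
        for start in range(0, perm.size, bs):
            idx = perm[start:start + bs]
            x = _to_batch([patches[i] for i in idx], config.crop_side,
                          rng if config.augment else None)
            model.zero_grad()
            probs = model(Tensor(x))
            loss = F.weighted_cross_entropy(probs, y[idx], table)
            loss.backward()
            opt.step()
            losses.append(loss.item() + opt.penalty())
        # refresh batch-norm running statistics on the training data so
        # eval-mode accuracy reflects the fitted network
        calib = (_to_batch([patches[i] for i in train_idx[s:s + bs]],
                           config.crop_side)
                 for s in range(0, train_idx.size, bs))
        nn.recalibrate_batchnorm(model, calib)
        correct = 0
        for start in range(0, val_idx.size, bs):
            idx = val_idx[start:start + bs]
            x = _to_batch([patches[i] for i in idx], config.crop_side)
            probs = model(Tensor(x)).data
            correct += int((probs.argmax(axis=1) == y[idx]).sum())
        acc = correct / val_idx.size
        history.append({"epoch": epoch + 1, "loss": float(np.mean(losses)),
                        "val_accuracy": acc})
        checkpoints.append(model.state_dict())
    accs = [h["val_accuracy"] for h in history]
    best = int(np.argmax(accs))  # argmax returns the earliest maximum
    model.load_state_dict(checkpoints[best])
    model.eval()
    result = {"history": history, "selected_epoch": best + 1,
              "state_dict": checkpoints[best]}
    return model, result


def predict_patch(model: ResNet32, patch: np.ndarray,
                  crop_side: int = 224) -> np.ndarray:
    """Class-probability 3-vector for one patch (deterministic center crop)."""
    model.eval()
    if patch.shape[0] > crop_side:
        patch = _center_crop_224(patch, crop_side)
    x = patch.astype(np.float32).transpose(2, 0, 1)[None] / 255.0
    return model(Tensor(x)).data[0]
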