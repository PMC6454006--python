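"""Layer modules over the autodiff core.

The :class:`Module` container mirrors the conventions of mainstream deep
learning toolkits (named parameters, state dicts, train/eval modes) at the
scale this package needs.  Freezing a subtree both stops gradient updates and
pins its batch-norm statistics, so frozen weights stay bit-identical through
a training phase.
"""

from __future__ import annotations

import numpy as np

from . import autodiff as F
from .autodiff import Parameter, Tensor

__all__ = [
    "Module",
    "ModuleList",
    "Sequential",
    "Conv2d",
    "ConvTranspose2x2",
    "BatchNorm2d",
    "ReLU",
    "MaxPool2d",
    "Linear",
    "GlobalAvgPool",
    "Softmax",
    "count_weighted_layers",
    "he_normal",
]


def he_normal(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape).astype(np.float32)


class Module:
    def __init__(self):
        self.training = True
        self._frozen = False

    # -- traversal -------------------------------------------------------
    def children(self):
        for name, value in vars(self).items():
            if isinstance(value, Module):
                yield name, value
            elif isinstance(value, ModuleList):
                for i, m in enumerate(value):
                    yield f"{name}.{i}", m

    def named_parameters(self, prefix: str = ""):
        for name, value in vars(self).items():
            if isinstance(value, Parameter):
                yield prefix + name, value
        for name, child in self.children():
            yield from child.named_parameters(prefix + name + ".")

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def named_buffers(self, prefix: str = ""):
        for name, value in vars(self).items():
            if isinstance(value, np.ndarray):
                yield prefix + name, value
        for name, child in self.children():
            yield from child.named_buffers(prefix + name + ".")

    # -- state -----------------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        out = {name: p.data.copy() for name, p in self.named_parameters()}
        out.update({name: b.copy() for name, b in self.named_buffers()})
        return out

    def load_state_dict(self, state: dict[str, np.ndarray]):
        params = dict(self.named_parameters())
        buffers = dict(self.named_buffers())
        for key, value in state.items():
            if key in params:
                params[key].data[...] = value
            elif key in buffers:
                buffers[key][...] = value
            else:
                raise KeyError(f"unexpected state key {key!r}")

    # -- modes -----------------------------------------------------------
    def train(self, mode: bool = True):
        self.training = mode and not self._frozen
        for _, child in self.children():
            child.train(self.training)
        return self

    def eval(self):
        return self.train(False)

    def freeze(self):
        """Stop gradients and batch-norm updates for this subtree."""
        self._frozen = True
        for p in self.parameters():
            p.requires_grad = False
        self.train(self.training)
        return self

    def unfreeze(self):
        self._frozen = False
        for _, child in self.children():
            child._frozen = False
        for p in self.parameters():
            p.requires_grad = True
        return self

    def trainable_parameters(self):
        return [p for p in self.parameters() if p.requires_grad]

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    def forward(self, *args, **kwargs):  # pragma: no cover - abstract
        raise NotImplementedError


class ModuleList(list):
    pass


class Sequential(Module):
    def __init__(self, *modules: Module):
        super().__init__()
        self.layers = ModuleList(modules)

    def forward(self, x: Tensor) -> Tensor:
        for layer in self.layers:
            x = layer(x)
        return x


class Conv2d(Module):
    def __init__(self, in_ch: int, out_ch: int, kernel: int, rng: np.random.Generator,
                 stride: int = 1, padding: str = "valid", groups: int = 1,
                 bias: bool = True, is_projection: bool = False):
        super().__init__()
        if in_ch % groups or out_ch % groups:
            raise ValueError("channels must divide groups")
        self.stride = stride
        self.padding = padding
        self.groups = groups
        self.is_projection = is_projection
        fan_in = (in_ch // groups) * kernel * kernel
        self.weight = Parameter(
            he_normal(rng, (out_ch, in_ch // groups, kernel, kernel), fan_in))
        self.bias = Parameter(np.zeros(out_ch, dtype=np.float32)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return F.conv2d(x, self.weight, self.bias, self.stride, self.padding,
                        self.groups)

    def named_parameters(self, prefix: str = ""):
        yield prefix + "weight", self.weight
        if self.bias is not None:
            yield prefix + "bias", self.bias


class ConvTranspose2x2(Module):
    """2x2 stride-2 transpose convolution (exact spatial doubling)."""

    def __init__(self, in_ch: int, out_ch: int, rng: np.random.Generator):
        super().__init__()
        self.weight = Parameter(he_normal(rng, (in_ch, out_ch, 2, 2), in_ch * 4))
        self.bias = Parameter(np.zeros(out_ch, dtype=np.float32))

    def forward(self, x: Tensor) -> Tensor:
        return F.conv_transpose2x2(x, self.weight, self.bias)


class BatchNorm2d(Module):
    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.momentum = momentum
        self.eps = eps
        self.gamma = Parameter(np.ones(channels, dtype=np.float32))
        self.beta = Parameter(np.zeros(channels, dtype=np.float32))
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)

    def forward(self, x: Tensor) -> Tensor:
        return F.batch_norm(x, self.gamma, self.beta, self.running_mean,
                            self.running_var, self.training, self.momentum,
                            self.eps)


class ReLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return F.relu(x)


class MaxPool2d(Module):
    def __init__(self, kernel: int = 3, stride: int = 2):
        super().__init__()
        self.kernel = kernel
        self.stride = stride

    def forward(self, x: Tensor) -> Tensor:
        return F.max_pool2d(x, self.kernel, self.stride)


class GlobalAvgPool(Module):
    def forward(self, x: Tensor) -> Tensor:
        return F.global_avg_pool(x)


class Softmax(Module):
    def __init__(self, axis: int = 1):
        super().__init__()
        self.axis = axis

    def forward(self, x: Tensor) -> Tensor:
        return F.softmax(x, self.axis)


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator):
        super().__init__()
        self.weight = Parameter(he_normal(rng, (out_features, in_features), in_features))
        self.bias = Parameter(np.zeros(out_features, dtype=np.float32))

    def forward(self, x: Tensor) -> Tensor:
        return F.linear(x, self.weight, self.bias)


def iter_batchnorms(module: Module):
    stack = [module]
    while stack:
        m = stack.pop()
        if isinstance(m, BatchNorm2d):
            yield m
        stack.extend(child for _, child in m.children())


def recalibrate_batchnorm(model: Module, batches, forward=None):
    """Re-estimate batch-norm running statistics from data.

    Deep networks trained with small batches can end up with running
    statistics that lag the co-adapted batch statistics, hurting eval-mode
    accuracy.  This resets every (non-frozen) batch-norm layer and replaces
    its running mean/variance with the cumulative average of the batch
    statistics over ``batches`` (momentum 1/t), then returns the model in
    eval mode.  Frozen subtrees keep their statistics untouched.
    """
    from .autodiff import Tensor

    bns = [bn for bn in iter_batchnorms(model) if not bn._frozen]
    model.train()
    bns = [bn for bn in bns if bn.training]
    for bn in bns:
        bn.running_mean[...] = 0.0
        bn.running_var[...] = 1.0
    fwd = forward if forward is not None else model.forward
    for i, x in enumerate(batches):
        for bn in bns:
            bn.momentum = 1.0 / (i + 1)
        fwd(x if isinstance(x, Tensor) else Tensor(x))
    for bn in bns:
        bn.momentum = 0.1
    model.eval()
    return model


def count_weighted_layers(module: Module) -> int:
    """Count weight-bearing layers (convolutions and affine heads).

    Projection shortcuts inside residual units carry weights but are excluded,
    matching the usual depth-naming convention of residual networks (a
    "50-layer" network counts its stem, unit convolutions and classifier).
    Batch-norm scale/shift parameters are not counted as layers.
    """
    n = 0
    stack = [module]
    while stack:
        m = stack.pop()
        if isinstance(m, Conv2d):
            if not m.is_projection:
                n += 1
        elif isinstance(m, (Linear, ConvTranspose2x2)):
            n += 1
        stack.extend(child for _, child in m.children())
    return n
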