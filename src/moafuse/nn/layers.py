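"""Neural-network building blocks over the autodiff engine.

Initialisation is He-normal (suited to ReLU nets) from a caller-supplied
`numpy.random.Generator`, so every model in the package is reproducible from
a single seed.
"""

from __future__ import annotations

import numpy as np

from .autograd import Tensor, conv2d, max_pool2d

__all__ = [
    "Parameter",
    "Module",
    "Linear",
    "Conv2d",
    "BatchNorm",
    "ReLU",
    "Sequential",
    "Adam",
    "ReduceLROnPlateau",
]


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(np.asarray(data), requires_grad=True)


class Module:
    """Base class: recursive parameter discovery and train/eval mode."""

    def __init__(self):
        self.training = True

    def forward(self, *args, **kwargs):  # pragma: no cover - abstract
        raise NotImplementedError

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    def modules(self):
        for value in self.__dict__.values():
            if isinstance(value, Module):
                yield value
                yield from value.modules()
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        yield item
                        yield from item.modules()

    def parameters(self):
        seen = set()
        for mod in (self, *self.modules()):
            for value in mod.__dict__.values():
                if isinstance(value, Parameter) and id(value) not in seen:
                    seen.add(id(value))
                    yield value

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def train(self):
        self.training = True
        for m in self.modules():
            m.training = True
        return self

    def eval(self):
        self.training = False
        for m in self.modules():
            m.training = False
        return self

    def state_arrays(self):
        """Flat list of parameter arrays (used by the lr=0 invariance test)."""
        return [p.data.copy() for p in self.parameters()]


class Linear(Module):
    def __init__(self, in_features, out_features, rng, bias=True, dtype=np.float32):
        super().__init__()
        std = np.sqrt(2.0 / in_features)
        self.weight = Parameter(
            rng.normal(0.0, std, size=(in_features, out_features)).astype(dtype)
        )
        self.bias = Parameter(np.zeros(out_features, dtype=dtype)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        out = x @ self.weight
        if self.bias is not None:
            out = out + self.bias
        return out


class Conv2d(Module):
    def __init__(
        self,
        in_channels,
        out_channels,
        kernel_size,
        rng,
        stride=1,
        padding=0,
        dilation=1,
        groups=1,
        bias=True,
        dtype=np.float32,
    ):
        super().__init__()
        k = kernel_size
        fan_in = (in_channels // groups) * k * k
        std = np.sqrt(2.0 / fan_in)
        self.weight = Parameter(
            rng.normal(0.0, std, size=(out_channels, in_channels // groups, k, k)).astype(dtype)
        )
        self.bias = Parameter(np.zeros(out_channels, dtype=dtype)) if bias else None
        self.stride, self.padding, self.dilation, self.groups = stride, padding, dilation, groups

    def forward(self, x: Tensor) -> Tensor:
        return conv2d(
            x,
            self.weight,
            self.bias,
            stride=self.stride,
            padding=self.padding,
            dilation=self.dilation,
            groups=self.groups,
        )


class BatchNorm(Module):
    """Batch normalisation over (N,C) or (N,C,H,W) inputs, per channel C."""

    def __init__(self, num_features, eps=1e-5, momentum=0.1, dtype=np.float32):
        super().__init__()
        self.gamma = Parameter(np.ones(num_features, dtype=dtype))
        self.beta = Parameter(np.zeros(num_features, dtype=dtype))
        self.running_mean = np.zeros(num_features, dtype=dtype)
        self.running_var = np.ones(num_features, dtype=dtype)
        self.eps = eps
        self.momentum = momentum

    def forward(self, x: Tensor) -> Tensor:
        from .autograd import batch_norm

        return batch_norm(
            x,
            self.gamma,
            self.beta,
            self.running_mean,
            self.running_var,
            self.training,
            self.momentum,
            self.eps,
        )


class ReLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.relu()


class Sequential(Module):
    def __init__(self, *layers):
        super().__init__()
        self.layers = list(layers)

    def forward(self, x: Tensor) -> Tensor:
        for layer in self.layers:
            x = layer(x)
        return x


class MaxPool2d(Module):
    def __init__(self, kernel_size=3, stride=2, padding=1):
        super().__init__()
        self.kernel_size, self.stride, self.padding = kernel_size, stride, padding

    def forward(self, x: Tensor) -> Tensor:
        return max_pool2d(x, self.kernel_size, self.stride, self.padding)


class Adam:
    """Adaptive-moment first-order optimizer (decoupled from any model class)."""

    def __init__(self, params, lr=1e-3, betas=(0.9, 0.999), eps=1e-8):
        self.params = list(params)
        self.lr = float(lr)
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        self.t += 1
        b1, b2 = self.b1, self.b2
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1**self.t)
            vhat = self.v[i] / (1 - b2**self.t)
            p.data -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(p.data.dtype)

    def zero_grad(self):
        for p in self.params:
            p.grad = None


class ReduceLROnPlateau:
    """Multiply the optimizer's lr by `factor` after `patience` epochs without
    improvement of the monitored value (lower is better)."""

    def __init__(self, optimizer, factor=0.1, patience=10, min_lr=1e-8, threshold=1e-4):
        self.optimizer = optimizer
        self.factor = factor
        self.patience = patience
        self.min_lr = min_lr
        self.threshold = threshold
        self.best = np.inf
        self.num_bad = 0
        self.events = []  # epoch indices at which the lr was reduced

    def step(self, metric, epoch=None):
        if metric < self.best - self.threshold:
            self.best = metric
            self.num_bad = 0
        else:
            self.num_bad += 1
            if self.num_bad > self.patience:
                new_lr = max(self.optimizer.lr * self.factor, self.min_lr)
                if new_lr < self.optimizer.lr:
                    self.optimizer.lr = new_lr
                    self.events.append(epoch if epoch is not None else len(self.events))
                self.num_bad = 0
        return self.optimizer.lr
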