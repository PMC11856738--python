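"""Network layers built on the autodiff tape.

Initialisation follows He-style fan-in scaling appropriate for the leaky
rectifier used throughout the backbone. Every layer takes an explicit
``numpy.random.Generator`` so that parameter initialisation is fully
reproducible and independent between submodules.
"""

from __future__ import annotations

import numpy as np

from .tensor import Tensor, conv2d, conv_transpose2d, instance_norm2d

LEAKY_SLOPE = 0.01


class Module:
    """Base class: recursive parameter collection over attributes."""

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        seen: set[int] = set()

        def walk(obj):
            if isinstance(obj, Tensor):
                if obj.requires_grad and id(obj) not in seen:
                    seen.add(id(obj))
                    params.append(obj)
            elif isinstance(obj, Module):
                for v in vars(obj).values():
                    walk(v)
            elif isinstance(obj, (list, tuple)):
                for v in obj:
                    walk(v)

        walk(self)
        return params

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()

    def state_dict(self) -> dict[str, np.ndarray]:
        out: dict[str, np.ndarray] = {}

        def walk(obj, prefix):
            if isinstance(obj, Tensor):
                if obj.requires_grad:
                    out[prefix] = obj.data
            elif isinstance(obj, Module):
                for k, v in vars(obj).items():
                    walk(v, f"{prefix}.{k}" if prefix else k)
            elif isinstance(obj, (list, tuple)):
                for i, v in enumerate(obj):
                    walk(v, f"{prefix}.{i}")

        walk(self, "")
        return out

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        own = self.state_dict()
        missing = set(own) - set(state)
        if missing:
            raise KeyError(f"missing parameters in state dict: {sorted(missing)}")

        def walk(obj, prefix):
            if isinstance(obj, Tensor):
                if obj.requires_grad:
                    obj.data = np.asarray(state[prefix], dtype=obj.data.dtype)
            elif isinstance(obj, Module):
                for k, v in vars(obj).items():
                    walk(v, f"{prefix}.{k}" if prefix else k)
            elif isinstance(obj, (list, tuple)):
                for i, v in enumerate(obj):
                    walk(v, f"{prefix}.{i}")

        walk(self, "")


def _he_init(rng: np.random.Generator, shape, fan_in: int, dtype) -> np.ndarray:
    gain = np.sqrt(2.0 / (1.0 + LEAKY_SLOPE**2))
    std = gain / np.sqrt(fan_in)
    return (rng.standard_normal(shape) * std).astype(dtype)


class Conv2d(Module):
    def __init__(self, cin: int, cout: int, k: int, rng: np.random.Generator,
                 stride: int = 1, padding: int = 0, bias: bool = True,
                 dtype=np.float32):
        self.stride = stride
        self.padding = padding
        self.w = Tensor(_he_init(rng, (cout, cin, k, k), cin * k * k, dtype),
                        requires_grad=True)
        self.b = Tensor(np.zeros(cout, dtype=dtype), requires_grad=True) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        return conv2d(x, self.w, self.b, stride=self.stride, padding=self.padding)


class ConvTranspose2d(Module):
    """Upsampling by a transposed convolution with kernel == stride."""

    def __init__(self, cin: int, cout: int, stride: int, rng: np.random.Generator,
                 dtype=np.float32):
        self.stride = stride
        self.w = Tensor(_he_init(rng, (cin, cout, stride, stride), cin, dtype),
                        requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return conv_transpose2d(x, self.w, stride=self.stride)


class InstanceNorm2d(Module):
    def __init__(self, c: int, eps: float = 1e-5, dtype=np.float32):
        self.eps = eps
        self.gamma = Tensor(np.ones(c, dtype=dtype), requires_grad=True)
        self.beta = Tensor(np.zeros(c, dtype=dtype), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        c = self.gamma.data.shape[0]
        xhat = instance_norm2d(x, eps=self.eps)
        return xhat * self.gamma.reshape(1, c, 1, 1) + self.beta.reshape(1, c, 1, 1)


class ConvNormAct(Module):
    """conv 3x3 -> instance norm -> leaky rectifier (backbone unit block)."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator,
                 stride: int = 1, dtype=np.float32):
        self.conv = Conv2d(cin, cout, 3, rng, stride=stride, padding=1, dtype=dtype)
        self.norm = InstanceNorm2d(cout, dtype=dtype)

    def __call__(self, x: Tensor) -> Tensor:
        return self.norm(self.conv(x)).leaky_relu(LEAKY_SLOPE)
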