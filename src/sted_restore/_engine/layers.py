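"""Layer/module abstractions over the autodiff core.

Modules hold named parameters (``Tensor`` with ``requires_grad=True``) and
compose; ``parameters()`` walks the tree in construction order, which makes
seeded He-uniform initialization reproducible.
"""

from __future__ import annotations

import numpy as np

from .autograd import Tensor, conv_nd, conv_transpose2


class Module:
    """Base class: parameter registration and state (de)serialization."""

    def __init__(self):
        self._params: dict[str, Tensor] = {}
        self._children: dict[str, "Module"] = {}

    def __setattr__(self, name, value):
        if isinstance(value, Module):
            self.__dict__.setdefault("_children", {})[name] = value
        elif isinstance(value, Tensor) and value.requires_grad:
            self.__dict__.setdefault("_params", {})[name] = value
        object.__setattr__(self, name, value)

    def register_children(self, name: str, modules) -> list:
        """Register a homogeneous list of sub-modules (e.g. CAB stacks)."""
        for i, m in enumerate(modules):
            self._children[f"{name}.{i}"] = m
        return list(modules)

    def parameters(self) -> list[Tensor]:
        out = list(self._params.values())
        for child in self._children.values():
            out.extend(child.parameters())
        return out

    def named_parameters(self, prefix: str = "") -> list[tuple[str, Tensor]]:
        out = [(prefix + name, p) for name, p in self._params.items()]
        for cname, child in self._children.items():
            out.extend(child.named_parameters(prefix + cname + "."))
        return out

    def num_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    def state_dict(self) -> dict[str, np.ndarray]:
        return {name: p.data.copy() for name, p in self.named_parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        mine = dict(self.named_parameters())
        missing = set(mine) ^ set(state)
        if missing:
            raise KeyError(f"state mismatch on parameters: {sorted(missing)}")
        for name, p in mine.items():
            arr = np.asarray(state[name], dtype=p.data.dtype)
            if arr.shape != p.data.shape:
                raise ValueError(f"shape mismatch for {name}: "
                                 f"{arr.shape} vs {p.data.shape}")
            p.data = arr.copy()

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


def he_uniform(rng: np.random.Generator, shape: tuple, fan_in: int,
               dtype=np.float32) -> Tensor:
    limit = np.sqrt(6.0 / fan_in)
    return Tensor(rng.uniform(-limit, limit, size=shape).astype(dtype),
                  requires_grad=True)


class Conv(Module):
    """Stride-1 same-padding convolution, 2D or 3D, odd kernel."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int, dims: int,
                 rng: np.random.Generator, bias: bool = True):
        super().__init__()
        shape = (out_ch, in_ch) + (kernel,) * dims
        fan_in = in_ch * kernel ** dims
        self.weight = he_uniform(rng, shape, fan_in)
        self.bias = Tensor(np.zeros(out_ch, dtype=np.float32),
                           requires_grad=True) if bias else None

    def forward(self, x):
        return conv_nd(x, self.weight, self.bias)


class ConvTranspose(Module):
    """Kernel-2 stride-2 transposed convolution (2x upsampling)."""

    def __init__(self, in_ch: int, out_ch: int, dims: int,
                 rng: np.random.Generator):
        super().__init__()
        shape = (in_ch, out_ch) + (2,) * dims
        self.weight = he_uniform(rng, shape, in_ch * 2 ** dims)
        self.bias = Tensor(np.zeros(out_ch, dtype=np.float32), requires_grad=True)

    def forward(self, x):
        return conv_transpose2(x, self.weight, self.bias)
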