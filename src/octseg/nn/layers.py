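"""Layer objects (parameter containers) on top of the autodiff core."""

from __future__ import annotations

import numpy as np

from . import core
from .core import Tensor


class Module:
    """Tiny module tree: named parameters, train/eval flag, state dicts."""

    def __init__(self):
        self._params: dict[str, Tensor] = {}
        self._modules: dict[str, Module] = {}
        self.training = False

    def __setattr__(self, name, value):
        if isinstance(value, Module):
            self.__dict__.setdefault("_modules", {})[name] = value
        super().__setattr__(name, value)

    def register(self, name: str, array: np.ndarray) -> Tensor:
        t = Tensor(array, requires_grad=True)
        self._params[name] = t
        setattr(self, name, t)
        return t

    def modules(self):
        yield self
        for m in self._modules.values():
            yield from m.modules()

    def parameters(self) -> list[Tensor]:
        out = []
        for m in self.modules():
            out.extend(m._params.values())
        return out

    def named_state(self, prefix: str = "") -> dict[str, np.ndarray]:
        state: dict[str, np.ndarray] = {}
        for name, p in self._params.items():
            state[prefix + name] = p.data
        for extra, arr in getattr(self, "_buffers", {}).items():
            state[prefix + extra] = arr
        for mname, m in self._modules.items():
            state.update(m.named_state(prefix + mname + "."))
        return state

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.named_state().items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        own = self.named_state()
        missing = set(own) - set(state)
        if missing:
            raise KeyError(f"missing parameters in state dict: {sorted(missing)[:5]}")
        for name, p in self._params.items():
            p.data = np.array(state[name])
        for extra in getattr(self, "_buffers", {}):
            self._buffers[extra][...] = state[extra]
        for mname, m in self._modules.items():
            sub = {k[len(mname) + 1:]: v for k, v in state.items()
                   if k.startswith(mname + ".")}
            m.load_state_dict(sub)

    def train(self, mode: bool = True):
        for m in self.modules():
            m.training = mode
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def n_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))


class Conv2d(Module):
    def __init__(self, cin: int, cout: int, k: int, rng: np.random.Generator,
                 pad: int | None = None, dtype=np.float32):
        super().__init__()
        self.k = k
        self.pad = k // 2 if pad is None else pad
        std = np.sqrt(2.0 / (cin * k * k))
        self.register("weight", rng.normal(0.0, std, (cout, cin, k, k)).astype(dtype))
        self.register("bias", np.zeros(cout, dtype=dtype))

    def __call__(self, x: Tensor) -> Tensor:
        return core.conv2d(x, self.weight, self.bias, stride=1, pad=self.pad)


class ConvTranspose2x2(Module):
    def __init__(self, cin: int, cout: int, rng: np.random.Generator, dtype=np.float32):
        super().__init__()
        std = np.sqrt(2.0 / (cin * 4))
        self.register("weight", rng.normal(0.0, std, (cin, cout, 2, 2)).astype(dtype))
        self.register("bias", np.zeros(cout, dtype=dtype))

    def __call__(self, x: Tensor) -> Tensor:
        return core.conv_transpose2x2(x, self.weight, self.bias)


class BatchNorm2d(Module):
    def __init__(self, c: int, momentum: float = 0.1, eps: float = 1e-5, dtype=np.float32):
        super().__init__()
        self.eps = eps
        self.momentum = momentum
        self.register("gamma", np.ones(c, dtype=dtype))
        self.register("beta", np.zeros(c, dtype=dtype))
        self._buffers = {
            "running_mean": np.zeros(c, dtype=dtype),
            "running_var": np.ones(c, dtype=dtype),
        }

    def __call__(self, x: Tensor) -> Tensor:
        if self.training:
            out, mu, var = core.batchnorm2d_train(x, self.gamma, self.beta, self.eps)
            m = self.momentum
            self._buffers["running_mean"] *= 1 - m
            self._buffers["running_mean"] += m * np.atleast_1d(mu).astype(
                self._buffers["running_mean"].dtype)
            self._buffers["running_var"] *= 1 - m
            self._buffers["running_var"] += m * np.atleast_1d(var).astype(
                self._buffers["running_var"].dtype)
            return out
        rm = self._buffers["running_mean"].reshape(1, -1, 1, 1)
        rv = self._buffers["running_var"].reshape(1, -1, 1, 1)
        scale = self.gamma.data.reshape(1, -1, 1, 1) / np.sqrt(rv + self.eps)
        shift = self.beta.data.reshape(1, -1, 1, 1) - rm * scale
        t = core.mul(x, Tensor(scale.astype(x.dtype)))
        return core.add(t, Tensor(shift.astype(x.dtype)))


class DoubleConv(Module):
    """conv(3x3)-BN-ReLU twice — the per-stage block of the U-Net."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator, dtype=np.float32):
        super().__init__()
        self.conv1 = Conv2d(cin, cout, 3, rng, dtype=dtype)
        self.bn1 = BatchNorm2d(cout, dtype=dtype)
        self.conv2 = Conv2d(cout, cout, 3, rng, dtype=dtype)
        self.bn2 = BatchNorm2d(cout, dtype=dtype)

    def __call__(self, x: Tensor) -> Tensor:
        x = core.relu(self.bn1(self.conv1(x)))
        return core.relu(self.bn2(self.conv2(x)))
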