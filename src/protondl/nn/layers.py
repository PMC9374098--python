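"""Network layers and the dense blocks used by the HD U-Net."""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, parameter
from . import ops

__all__ = ["Module", "Conv3d", "BatchNorm3d", "ConvBNReLU", "DenseConvolve"]


class Module:
    """Base class: named parameters/buffers with state-dict (de)serialization."""

    def __init__(self):
        self._params: dict[str, Tensor] = {}
        self._buffers: dict[str, np.ndarray] = {}
        self._children: dict[str, "Module"] = {}
        self.training = True

    def register_parameter(self, name: str, value: np.ndarray) -> Tensor:
        t = parameter(value)
        self._params[name] = t
        return t

    def register_buffer(self, name: str, value: np.ndarray) -> np.ndarray:
        arr = np.asarray(value, dtype=np.float32)
        self._buffers[name] = arr
        return arr

    def register_child(self, name: str, module: "Module") -> "Module":
        self._children[name] = module
        return module

    def parameters(self) -> list[Tensor]:
        out = list(self._params.values())
        for child in self._children.values():
            out.extend(child.parameters())
        return out

    def named_state(self, prefix: str = "") -> dict[str, np.ndarray]:
        state = {}
        for name, t in self._params.items():
            state[prefix + name] = t.data
        for name, b in self._buffers.items():
            state[prefix + name] = b
        for name, child in self._children.items():
            state.update(child.named_state(prefix + name + "."))
        return state

    def load_state(self, state: dict[str, np.ndarray], prefix: str = "") -> None:
        for name, t in self._params.items():
            src = np.asarray(state[prefix + name], dtype=np.float32)
            if src.shape != t.data.shape:
                raise ValueError(
                    f"shape mismatch for {prefix + name}: "
                    f"{src.shape} vs {t.data.shape}"
                )
            t.data = src.copy()
        for name, b in self._buffers.items():
            src = np.asarray(state[prefix + name], dtype=np.float32)
            if src.shape != b.shape:
                raise ValueError(f"shape mismatch for buffer {prefix + name}")
            b[...] = src
        for name, child in self._children.items():
            child.load_state(state, prefix + name + ".")

    def set_training(self, training: bool) -> None:
        self.training = training
        for child in self._children.values():
            child.set_training(training)


class Conv3d(Module):
    """'Same'-padded 3D convolution with bias and He-normal initialization."""

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel: tuple[int, int, int],
        rng: np.random.Generator,
        stride: tuple[int, int, int] = (1, 1, 1),
    ):
        super().__init__()
        self.stride = tuple(stride)
        fan_in = int(np.prod(kernel)) * in_channels
        std = np.sqrt(2.0 / fan_in)
        self.weight = self.register_parameter(
            "weight",
            rng.normal(0.0, std, size=(*kernel, in_channels, out_channels)).astype(
                np.float32
            ),
        )
        self.bias = self.register_parameter(
            "bias", np.zeros(out_channels, dtype=np.float32)
        )

    def __call__(self, x: Tensor) -> Tensor:
        return ops.add_bias(ops.conv3d(x, self.weight, stride=self.stride), self.bias)


class BatchNorm3d(Module):
    def __init__(self, channels: int):
        super().__init__()
        self.gamma = self.register_parameter("gamma", np.ones(channels, dtype=np.float32))
        self.beta = self.register_parameter("beta", np.zeros(channels, dtype=np.float32))
        self.running_mean = self.register_buffer(
            "running_mean", np.zeros(channels, dtype=np.float32)
        )
        self.running_var = self.register_buffer(
            "running_var", np.ones(channels, dtype=np.float32)
        )

    def __call__(self, x: Tensor) -> Tensor:
        return ops.batchnorm(
            x,
            self.gamma,
            self.beta,
            self.running_mean,
            self.running_var,
            training=self.training,
        )


class ConvBNReLU(Module):
    """conv -> batch norm -> ReLU, the unit everything else is built from."""

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel: tuple[int, int, int],
        rng: np.random.Generator,
        stride: tuple[int, int, int] = (1, 1, 1),
    ):
        super().__init__()
        self.conv = self.register_child(
            "conv", Conv3d(in_channels, out_channels, kernel, rng, stride=stride)
        )
        self.bn = self.register_child("bn", BatchNorm3d(out_channels))

    def __call__(self, x: Tensor) -> Tensor:
        return ops.relu(self.bn(self.conv(x)))


class DenseConvolve(Module):
    """Densely connected convolutions: each unit's output is concatenated onto
    its input, so channels grow by the growth rate per convolution."""

    def __init__(
        self,
        in_channels: int,
        growth_rate: int,
        n_convs: int,
        kernel: tuple[int, int, int],
        rng: np.random.Generator,
    ):
        super().__init__()
        self.out_channels = in_channels
        for i in range(n_convs):
            self.register_child(
                f"unit{i}", ConvBNReLU(self.out_channels, growth_rate, kernel, rng)
            )
            self.out_channels += growth_rate

    def __call__(self, x: Tensor) -> Tensor:
        for unit in self._children.values():
            x = ops.concat([x, unit(x)])
        return x
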