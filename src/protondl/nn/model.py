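"""The HD U-Net dose-conversion model.

A U-Net whose encoder uses densely connected convolutions and dense
downsampling: at each resolution drop, max-pooled features are carried
alongside newly strided-convolved ones, so earlier features propagate to every
level. Decoding uses plain U-Net upsampling (nearest-neighbour + convolution,
then concatenation with the skip connection) to keep memory bounded.

Inputs are two channels (normalized pencil-beam dose, normalized CT) in the
default field orientation; the output is one channel of normalized
MC-equivalent dose (final ReLU keeps it non-negative).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ..grid import ScalarVolume, VolumeKind
from ..preprocess import dose_bounding_box, patch_grid_corners, sample_patch
from .autodiff import Tensor, constant
from . import ops
from .layers import ConvBNReLU, DenseConvolve, Module

__all__ = [
    "ModelConfig",
    "HDUNet",
    "predict_volume",
    "save_checkpoint",
    "load_checkpoint",
    "FULL_SCALE_CONFIG",
    "DESK_SCALE_CONFIG",
]


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyperparameters.

    ``pool_schedule`` gives the per-axis pooling factors of each resolution
    drop; its length sets the number of drops (levels = drops + 1). The default
    schedule takes a 128 x 128 x 16 patch to an 8 x 8 x 1 bottleneck, pooling
    the slice axis less aggressively at first because it starts much coarser.
    """

    in_channels: int = 2
    out_channels: int = 1
    growth_rate: int = 16
    convs_per_block: int = 2
    kernel: tuple[int, int, int] = (3, 3, 3)
    pool_schedule: tuple[tuple[int, int, int], ...] = (
        (2, 2, 1),
        (2, 2, 2),
        (2, 2, 2),
        (2, 2, 2),
        (1, 1, 2),
    )
    up_channels: int = 32
    patch_shape: tuple[int, int, int] = (128, 128, 16)
    dropout: float = 0.0
    #: predict the dose as input PB plus a learned correction. The function
    #: class is unchanged (the head could learn the same map directly), but
    #: the identity component comes for free, which conditions short training
    #: runs far better.
    residual: bool = True

    def __post_init__(self):
        object.__setattr__(
            self, "pool_schedule", tuple(tuple(int(f) for f in p) for p in self.pool_schedule)
        )
        object.__setattr__(self, "kernel", tuple(int(k) for k in self.kernel))
        object.__setattr__(self, "patch_shape", tuple(int(s) for s in self.patch_shape))
        if self.dropout != 0.0:
            raise ValueError("only dropout = 0 is supported")
        shape = list(self.patch_shape)
        for pool in self.pool_schedule:
            for ax in range(3):
                if shape[ax] % pool[ax]:
                    raise ValueError(
                        f"patch shape {self.patch_shape} is not divisible by "
                        f"pool schedule {self.pool_schedule}"
                    )
                shape[ax] //= pool[ax]

    @property
    def bottleneck_shape(self) -> tuple[int, int, int]:
        shape = list(self.patch_shape)
        for pool in self.pool_schedule:
            shape = [s // p for s, p in zip(shape, pool)]
        return tuple(shape)

    def to_dict(self) -> dict:
        return {
            "in_channels": self.in_channels,
            "out_channels": self.out_channels,
            "growth_rate": self.growth_rate,
            "convs_per_block": self.convs_per_block,
            "kernel": list(self.kernel),
            "pool_schedule": [list(p) for p in self.pool_schedule],
            "up_channels": self.up_channels,
            "patch_shape": list(self.patch_shape),
            "dropout": self.dropout,
            "residual": self.residual,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        return cls(
            in_channels=d["in_channels"],
            out_channels=d["out_channels"],
            growth_rate=d["growth_rate"],
            convs_per_block=d["convs_per_block"],
            kernel=tuple(d["kernel"]),
            pool_schedule=tuple(tuple(p) for p in d["pool_schedule"]),
            up_channels=d["up_channels"],
            patch_shape=tuple(d["patch_shape"]),
            dropout=d["dropout"],
            residual=d.get("residual", True),
        )


#: full-size configuration (128 x 128 x 16 patches, 8 x 8 x 1 bottleneck)
FULL_SCALE_CONFIG = ModelConfig()

#: reduced configuration sized for quick desk runs on a single CPU
DESK_SCALE_CONFIG = ModelConfig(
    growth_rate=8,
    pool_schedule=((2, 2, 1), (2, 2, 2), (2, 2, 2)),
    up_channels=16,
    patch_shape=(32, 32, 8),
)


class HDUNet(Module):
    def __init__(self, config: ModelConfig, rng: np.random.Generator):
        super().__init__()
        self.config = config
        self.last_bottleneck_shape: tuple | None = None
        g = config.growth_rate
        k = config.kernel
        n = config.convs_per_block

        enc_channels: list[int] = []
        ch = config.in_channels
        block = self.register_child("enc0", DenseConvolve(ch, g, n, k, rng))
        ch = block.out_channels
        enc_channels.append(ch)
        for i, pool in enumerate(config.pool_schedule):
            # dense downsample: strided-conv features alongside pooled ones
            self.register_child(
                f"down{i}", ConvBNReLU(ch, g, k, rng, stride=pool)
            )
            ch = ch + g
            block = self.register_child(f"enc{i + 1}", DenseConvolve(ch, g, n, k, rng))
            ch = block.out_channels
            enc_channels.append(ch)

        for i in reversed(range(len(config.pool_schedule))):
            self.register_child(f"up{i}", ConvBNReLU(ch, config.up_channels, k, rng))
            ch = config.up_channels + enc_channels[i]
            block = self.register_child(f"dec{i}", DenseConvolve(ch, g, n, k, rng))
            ch = block.out_channels

        self.register_child(
            "head",
            _FinalConv(ch, config.out_channels, rng, zero_init=config.residual),
        )

    def __call__(self, x: Tensor) -> Tensor:
        cfg = self.config
        inp = x
        skips = []
        x = self._children["enc0"](x)
        for i, pool in enumerate(cfg.pool_schedule):
            skips.append(x)
            new = self._children[f"down{i}"](x)
            pooled = ops.maxpool3d(x, pool)
            x = ops.concat([pooled, new])
            x = self._children[f"enc{i + 1}"](x)
        # spatial size and channels at the deepest level, for inspection
        self.last_bottleneck_shape = tuple(x.shape[1:])
        for i in reversed(range(len(cfg.pool_schedule))):
            x = ops.upsample_nearest(x, cfg.pool_schedule[i])
            x = self._children[f"up{i}"](x)
            x = ops.concat([x, skips[i]])
            x = self._children[f"dec{i}"](x)
        x = self._children["head"](x)
        if cfg.residual:
            # correction head: add back the pencil-beam input channel
            x = ops.add(x, ops.channel_slice(inp, 0, cfg.out_channels))
        return ops.relu(x)

    def n_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))


class _FinalConv(Module):
    """1x1x1 convolution to the output channel(s).

    With ``zero_init`` the weights start at zero so a residual model's initial
    output is exactly its pencil-beam input.
    """

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        rng: np.random.Generator,
        zero_init: bool = False,
    ):
        super().__init__()
        from .layers import Conv3d

        self.conv = self.register_child(
            "conv", Conv3d(in_channels, out_channels, (1, 1, 1), rng)
        )
        if zero_init:
            self.conv.weight.data[...] = 0.0

    def __call__(self, x: Tensor) -> Tensor:
        return self.conv(x)


def predict_volume(
    model: HDUNet,
    pb_norm: ScalarVolume,
    ct_norm: ScalarVolume,
    overlap_fraction: float = 0.5,
    restrict_to_treated: bool = True,
) -> ScalarVolume:
    """Run the model over a whole volume by sliding-window patch inference.

    Patches follow the model's patch shape with the given overlap; overlapping
    predictions are averaged uniformly. Inputs must be normalized volumes in
    the default field orientation.

    With ``restrict_to_treated`` (the default) the sliding window only covers
    the PB dose's bounding box expanded by half a patch on every side; outside
    that region the PB values are returned unchanged. The conversion is a
    correction of the PB dose, so where the PB engine deposits no dose there
    is nothing to correct, and skipping the empty canvas makes whole-volume
    inference several times faster.
    """
    pb_norm.require_same_grid(ct_norm)
    if pb_norm.kind is not VolumeKind.NORMALIZED or ct_norm.kind is not VolumeKind.NORMALIZED:
        raise ValueError("predict_volume expects normalized input volumes")
    model.set_training(False)
    shape = pb_norm.grid.shape
    patch = model.config.patch_shape
    if restrict_to_treated and float(pb_norm.values.max()) > 0.0:
        lo, hi = dose_bounding_box(pb_norm)
        lo = tuple(max(0, l - p // 2) for l, p in zip(lo, patch))
        hi = tuple(min(s - 1, h + p // 2) for h, p, s in zip(hi, patch, shape))
        span = tuple(h - l + 1 for l, h in zip(lo, hi))
        corners = [
            tuple(c + l for c, l in zip(corner, lo))
            for corner in patch_grid_corners(span, patch, overlap_fraction)
        ]
        out = pb_norm.values.astype(np.float64).copy()
    else:
        corners = patch_grid_corners(shape, patch, overlap_fraction)
        out = np.zeros(shape, dtype=np.float64)
    total = np.zeros(shape, dtype=np.float64)
    weight = np.zeros(shape, dtype=np.float64)
    for corner in corners:
        pb_p, ct_p = sample_patch([pb_norm, ct_norm], corner, patch)
        x = constant(np.stack([pb_p, ct_p], axis=-1)[None])
        pred = model(x).data[0, ..., 0]
        sl_dst = []
        sl_src = []
        for ax in range(3):
            lo_ax = max(corner[ax], 0)
            hi_ax = min(corner[ax] + patch[ax], shape[ax])
            sl_dst.append(slice(lo_ax, hi_ax))
            sl_src.append(slice(lo_ax - corner[ax], hi_ax - corner[ax]))
        total[tuple(sl_dst)] += pred[tuple(sl_src)]
        weight[tuple(sl_dst)] += 1.0
    if not restrict_to_treated and np.any(weight == 0):
        raise RuntimeError("sliding window failed to cover the volume")
    covered = weight > 0
    out[covered] = total[covered] / weight[covered]
    return ScalarVolume(pb_norm.grid, out, VolumeKind.NORMALIZED)


def save_checkpoint(model: HDUNet, path) -> None:
    """Write model weights (.npz) plus a JSON config sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savez(path, **model.named_state())
    path.with_suffix(".json").write_text(
        json.dumps({"config": model.config.to_dict()}, indent=2)
    )


def load_checkpoint(path) -> HDUNet:
    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    config = ModelConfig.from_dict(meta["config"])
    model = HDUNet(config, np.random.default_rng(0))
    with np.load(path) as data:
        model.load_state({k: data[k] for k in data.files})
    model.set_training(False)
    return model
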