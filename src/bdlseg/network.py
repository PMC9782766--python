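"""Network configuration, construction and checkpointing.

``build_model`` turns a :class:`NetworkConfig` into a seeded
:class:`~bdlseg.nn.UNet3D`; checkpoints carry the config alongside the
weights so a transfer-learning run can validate architecture compatibility
before loading.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from .nn import UNet3D

__all__ = [
    "NetworkConfig",
    "build_model",
    "predict_case",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass(frozen=True)
class NetworkConfig:
    """Architecture hyperparameters of the 3D U-Net.

    ``input_size`` is the cubic edge length of the input grid and must be
    divisible by ``2**(depth - 1)`` so every downsampling halving lands on an
    integer grid. The 4 input channels are the T1 / contrast-enhanced T1 /
    T2 / FLAIR modalities.
    """

    input_channels: int = 4
    base_filters: int = 8
    depth: int = 3
    leaky_slope: float = 0.01
    input_size: int = 32
    seed: int = 0

    def __post_init__(self) -> None:
        if self.depth < 3:
            raise ValueError(f"depth must be >= 3, got {self.depth}")
        if self.base_filters < 4:
            raise ValueError(f"base_filters must be >= 4, got {self.base_filters}")
        if self.input_size % 2 ** (self.depth - 1) != 0:
            raise ValueError(
                f"input_size {self.input_size} not divisible by "
                f"2^(depth-1) = {2 ** (self.depth - 1)}"
            )


def build_model(cfg: NetworkConfig) -> UNet3D:
    """Construct the seeded U-Net described by ``cfg``."""
    return UNet3D(
        in_channels=cfg.input_channels,
        base_filters=cfg.base_filters,
        depth=cfg.depth,
        leaky_slope=cfg.leaky_slope,
        seed=cfg.seed,
    )


def predict_case(model: UNet3D, volume: np.ndarray) -> np.ndarray:
    """Run inference on one 4-channel volume, returning the probability map.

    Deterministic for fixed weights: the network has no stochastic layers
    and instance normalization makes the output independent of batching.
    """
    volume = np.asarray(volume)
    if volume.ndim != 4 or volume.shape[0] != model.in_channels:
        raise ValueError(
            f"expected ({model.in_channels}, S, S, S) volume, got {volume.shape}"
        )
    return model.forward(volume)


def save_checkpoint(model: UNet3D, cfg: NetworkConfig, path: str | Path) -> None:
    """Save weights plus the architecture config in one ``.npz`` container."""
    state = model.state_dict()
    np.savez(path, __config__=json.dumps(asdict(cfg)), **state)


def load_checkpoint(
    path: str | Path, expect_cfg: NetworkConfig | None = None
) -> tuple[UNet3D, NetworkConfig]:
    """Load a checkpoint; optionally validate it against an expected config.

    Transfer learning across differing architectures is refused: the stored
    config's shape-determining fields must match ``expect_cfg``.
    """
    with np.load(path) as data:
        cfg = NetworkConfig(**json.loads(str(data["__config__"])))
        state = {k: data[k] for k in data.files if k != "__config__"}
    if expect_cfg is not None:
        shape_fields = ("input_channels", "base_filters", "depth")
        for f in shape_fields:
            if getattr(cfg, f) != getattr(expect_cfg, f):
                raise ValueError(
                    f"checkpoint architecture mismatch on {f}: "
                    f"{getattr(cfg, f)} vs {getattr(expect_cfg, f)}"
                )
    model = build_model(cfg)
    model.load_state_dict(state)
    return model, cfg
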