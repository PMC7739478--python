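"""Architecture and training hyperparameter containers.

``NetworkConfig`` pins every structural choice of the segmentation network
so that parameter counts are bit-reproducible from a saved JSON/YAML
sidecar.  ``layers_per_block`` lists the layer counts of the down-sampling
dense blocks followed by the bottleneck; the up-sampling path mirrors the
down-sampling blocks in reverse.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml


@dataclass
class NetworkConfig:
    growth_rate: int = 12
    layers_per_block: tuple[int, ...] = (4, 5, 7, 10, 12, 15)
    initial_channels: int = 48
    in_channels: int = 3
    multiscale: bool = True
    ms_kernels: tuple[int, ...] = (3, 5, 7)
    ms_filters_per_branch: int | None = None  # default: initial_channels // len(ms_kernels)
    scse: bool = True
    scse_reduction: int = 2
    scse_placement: str = "per_block"  # or "per_layer"
    dropout: float = 0.2
    num_classes: int = 2

    def __post_init__(self):
        if self.growth_rate < 1:
            raise ValueError("growth_rate must be >= 1")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")
        if self.num_classes < 2:
            raise ValueError("num_classes must be >= 2")
        if any(k % 2 == 0 or k < 3 for k in self.ms_kernels):
            raise ValueError("multi-scale kernels must be odd and >= 3")
        if len(self.layers_per_block) < 2:
            raise ValueError("layers_per_block needs at least one down block and a bottleneck")
        if self.scse_placement not in ("per_block", "per_layer"):
            raise ValueError(f"unknown scse_placement {self.scse_placement!r}")
        self.layers_per_block = tuple(int(v) for v in self.layers_per_block)
        self.ms_kernels = tuple(int(v) for v in self.ms_kernels)

    @property
    def down_blocks(self) -> tuple[int, ...]:
        return self.layers_per_block[:-1]

    @property
    def bottleneck_layers(self) -> int:
        return self.layers_per_block[-1]

    @property
    def branch_filters(self) -> int:
        if self.ms_filters_per_branch is not None:
            return self.ms_filters_per_branch
        return self.initial_channels // len(self.ms_kernels)

    @property
    def pool_factor(self) -> int:
        """Total spatial down-sampling factor of the encoder."""
        return 2 ** len(self.down_blocks)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "NetworkConfig":
        known = {f for f in cls.__dataclass_fields__}
        return cls(**{k: v for k, v in d.items() if k in known})

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict()))

    @classmethod
    def load(cls, path: str | Path) -> "NetworkConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


#: Configuration reproducing the published backbone (no multi-scale stem,
#: no scSE recalibration): 5,415,278 trainable parameters.
BASELINE_CONFIG = NetworkConfig(multiscale=False, scse=False)

#: Full multi-scale scSE configuration with the same pinned layout.
FULL_CONFIG = NetworkConfig(multiscale=True, scse=True)


@dataclass
class TrainingConfig:
    learning_rate: float = 1e-4
    beta1: float = 0.9
    beta2: float = 0.999
    weight_decay: float = 1e-4
    max_epochs: int = 200
    patience: int = 20
    batch_size: int = 4
    flip_prob: float = 0.5
    loss: str = "swcel"  # cel | wcel | swcel
    boundary_iterations: int = 2
    seed: int | None = None

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ValueError("learning rate must be positive")
        if self.patience > self.max_epochs:
            raise ValueError("patience must not exceed max_epochs")
        if self.loss not in ("cel", "wcel", "swcel"):
            raise ValueError(f"unknown loss mode {self.loss!r}")
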