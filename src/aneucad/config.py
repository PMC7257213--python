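"""Pipeline configuration: every tunable of the CAD system in one place.

Defaults are the study protocol values: sigmoid alpha=400 / beta=600,
30 %-of-max skull growing band, radius-10 VOI dilation, 0.5 likelihood
threshold, strict >30 % overlap matching, 128^3 blocks, batch size 1,
Adam at 5e-4.  Configs load from YAML; unknown keys are rejected before
any stage runs.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields

import yaml

from .unet3d import NetworkConfig, TrainConfig

__all__ = ["PipelineConfig", "load_config", "save_config"]


@dataclass
class PipelineConfig:
    # preprocessing
    bias_correction: bool = True
    histogram_normalize: bool = False  # needs a reference volume
    sigmoid_alpha: float = 400.0
    sigmoid_beta: float = 600.0
    # step one: segmentation
    skull_lower_fraction: float = 0.30
    skull_closing_radius: int = 2
    background_value: float | None = None  # None -> Otsu
    seed_top_k: int = 5
    voi_radius: float = 10.0
    # step two: detection
    block_size: int = 128
    likelihood_threshold: float = 0.5
    min_component_size: int = 5
    overlap_threshold: float = 0.30
    # augmentation: "full" = the 8-fold factorial, "flip" = geometric
    # flip only (desk-scale), "off" = none
    augment: str = "full"
    gaussian_variance: float = 4.0
    gaussian_max_kernel_width: int = 32
    # network / training
    network: NetworkConfig = field(default_factory=NetworkConfig)
    training: TrainConfig = field(default_factory=TrainConfig)
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.voi_radius < 0:
            raise ValueError("voi_radius must be >= 0")
        if not 0.0 <= self.likelihood_threshold <= 1.0:
            raise ValueError("likelihood_threshold must be in [0, 1]")
        if not 0.0 < self.skull_lower_fraction < 1.0:
            raise ValueError("skull_lower_fraction must be in (0, 1)")
        if self.block_size % (2**self.network.depth) != 0:
            raise ValueError("block_size must be divisible by 2^network.depth")
        if self.augment not in ("off", "flip", "full"):
            raise ValueError("augment must be 'off', 'flip' or 'full'")

    @classmethod
    def test_scale(cls, **overrides) -> "PipelineConfig":
        """CPU-sized configuration: 32^3 blocks, 4-filter network."""
        base = dict(
            block_size=32,
            network=NetworkConfig.test_scale(),
            # one Adam step per block per epoch at this scale: a slightly
            # higher rate stands in for the full-scale 5e-4 protocol
            training=TrainConfig(
                learning_rate=1e-3,
                max_epochs=200,
                early_stop_patience=15,
                validation_fraction=0.0,
            ),
            augment="off",
        )
        base.update(overrides)
        return cls(**base)

    def to_dict(self) -> dict:
        return asdict(self)


def load_config(path) -> PipelineConfig:
    """Load and validate a YAML config file; unknown keys are an error."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return config_from_dict(raw)


def config_from_dict(raw: dict) -> PipelineConfig:
    known = {f.name for f in fields(PipelineConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    kwargs = dict(raw)
    if "network" in kwargs and isinstance(kwargs["network"], dict):
        bad = set(kwargs["network"]) - {f.name for f in fields(NetworkConfig)}
        if bad:
            raise ValueError(f"unknown network config keys: {sorted(bad)}")
        kwargs["network"] = NetworkConfig(**kwargs["network"])
    if "training" in kwargs and isinstance(kwargs["training"], dict):
        bad = set(kwargs["training"]) - {f.name for f in fields(TrainConfig)}
        if bad:
            raise ValueError(f"unknown training config keys: {sorted(bad)}")
        kwargs["training"] = TrainConfig(**kwargs["training"])
    return PipelineConfig(**kwargs)


def save_config(config: PipelineConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)
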