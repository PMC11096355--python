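"""Configuration objects for cohort generation, encoders and training.

Two named profiles are provided:

* ``full`` — the full-scale configuration: 0.5 mm isotropic resampling,
  64x96x96 patches, full-width residual encoder emitting 512-d features.
* ``desk`` — a reduced configuration for laptop/CI-scale experiments:
  1.0 mm resampling, 32x48x48 patches, quarter-width encoder emitting
  64-d features.  Same code paths, smaller tensors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of the synthetic longitudinal lesion cohort.

    Defaults emulate a stereotactic-radiosurgery brain-metastasis cohort:
    four timepoints per lesion (one pre-treatment, three follow-ups at
    roughly 2.6/2.8/2.9-month intervals), pre-treatment enhancing-nodule
    diameters 5-58 mm (mean 14.1, SD 9), ~24% progressive-disease (PD)
    prevalence, rim-enhancing lesions (bright rim, darker core) on a
    uniform tissue background with a designated grey-matter reference
    point of known intensity.
    """

    n_cases: int = 120
    pd_fraction: float = 0.24
    diameter_mean_mm: float = 14.1
    diameter_sd_mm: float = 9.0
    diameter_range_mm: tuple[float, float] = (5.0, 58.0)
    noise_sd: float = 4.0
    grid_shape: tuple[int, int, int] = (56, 64, 64)  # (z, y, x) voxels
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    rim_intensity: float = 240.0
    core_intensity: float = 150.0
    background_intensity: float = 80.0
    gm_intensity: float = 100.0
    #: first follow-up (1-based timepoint index) at which PD and non-PD
    #: diameter trajectories are drawn from different distributions.
    #: 2 (default): PD lesions already shrink less at the first follow-up.
    #: 3: trajectories are class-indistinguishable until timepoint 3
    #: (used to study how accuracy grows with follow-up length).
    signal_onset: int = 2
    seed: int = 0

    def validate(self) -> None:
        if self.n_cases < 2:
            raise ValueError("n_cases must be >= 2")
        if not (0.0 <= self.pd_fraction <= 1.0):
            raise ValueError("pd_fraction must lie in [0, 1]")
        if self.pd_fraction in (0.0, 1.0):
            warnings.warn(
                "pd_fraction of 0 or 1 produces a single-class cohort; "
                "downstream classifiers will refuse to fit it",
                stacklevel=2,
            )
        lo, hi = self.diameter_range_mm
        if not (0 < lo <= hi):
            raise ValueError("diameter_range_mm must be positive and ordered")
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError("spacing_mm must be strictly positive")
        if any(n < 8 for n in self.grid_shape):
            raise ValueError("grid_shape axes must be >= 8 voxels")
        extent = [n * s for n, s in zip(self.grid_shape, self.spacing_mm)]
        # an in-plane diameter hi must fit inside the (y, x) extent
        if hi > min(extent[1], extent[2]) - 4 * max(self.spacing_mm):
            raise ValueError(
                f"diameter_range_mm upper bound {hi} mm does not fit the "
                f"grid extent {extent} mm"
            )
        if self.signal_onset not in (2, 3):
            raise ValueError("signal_onset must be 2 or 3")
        if not (
            self.rim_intensity
            > self.core_intensity
            > self.background_intensity
            > 0
        ):
            raise ValueError("expected rim > core > background > 0 intensities")


@dataclass(frozen=True)
class EncoderConfig:
    """Residual CNN encoder configuration.

    ``dims`` selects the 2D (tri-planar, 3-channel) or 3D (single-channel
    volume) variant.  ``width`` scales the channel counts of the standard
    34-layer residual layout (stem 64 channels, stages x1/x2/x4/x8,
    blocks 3/4/6/3); ``width=1.0`` with ``feature_dim=512`` is the
    full-scale encoder.
    """

    dims: str = "2d"  # "2d" | "3d"
    width: float = 1.0
    feature_dim: int = 512
    blocks: tuple[int, int, int, int] = (3, 4, 6, 3)
    input_shape: tuple[int, ...] = (96, 96)  # spatial, without channels

    def __post_init__(self):
        if self.dims not in ("2d", "3d"):
            raise ValueError("dims must be '2d' or '3d'")
        if self.feature_dim <= 0:
            raise ValueError("feature_dim must be positive")
        expected_rank = 2 if self.dims == "2d" else 3
        if len(self.input_shape) != expected_rank:
            raise ValueError(
                f"input_shape must have {expected_rank} spatial axes for {self.dims}"
            )

    @property
    def in_channels(self) -> int:
        return 3 if self.dims == "2d" else 1

    @property
    def stage_channels(self) -> tuple[int, int, int, int]:
        base = max(4, int(round(64 * self.width)))
        return (base, base * 2, base * 4, base * 8)


@dataclass(frozen=True)
class TrainConfig:
    """Optimisation and augmentation settings for the neural arm.

    Defaults: Adam, 20 epochs, batch size 8,
    learning rate 1e-4 dropping to 1e-5 for epochs 10-15 and 1e-6 beyond
    epoch 15; focal loss; augmentation with rotation +/-30 deg, scaling
    0.85-1.15x, horizontal flip p=0.5 and per-axis translation +/-10 px.
    """

    epochs: int = 20
    batch_size: int = 8
    base_lr: float = 1e-4
    mid_lr: float = 1e-5      # epochs 10..15 (1-based, inclusive)
    late_lr: float = 1e-6     # epochs > 15
    focal_gamma: float = 2.0
    #: weight of the positive (PD) class; None = complement of the
    #: training-set positive fraction.
    focal_alpha: float | None = None
    gamma_grid: tuple[float, ...] = (0.0, 1.0, 2.0, 5.0)
    augment: bool = True
    rotation_deg: float = 30.0
    scale_range: tuple[float, float] = (0.85, 1.15)
    flip_prob: float = 0.5
    translate_px: float = 10.0
    seed: int = 0

    def lr_at_epoch(self, epoch: int) -> float:
        """Learning rate for a 1-based epoch index under the step schedule."""
        if epoch < 1:
            raise ValueError("epoch is 1-based")
        if epoch < 10:
            return self.base_lr
        if epoch <= 15:
            return self.mid_lr
        return self.late_lr


@dataclass(frozen=True)
class Profile:
    """A coherent bundle of preprocessing + model scale settings."""

    name: str
    target_spacing_mm: float
    patch_shape: tuple[int, int, int]
    encoder_2d: EncoderConfig
    encoder_3d: EncoderConfig
    train: TrainConfig = field(default_factory=TrainConfig)

    @property
    def canvas_side(self) -> int:
        return max(self.patch_shape)


def full_profile() -> Profile:
    return Profile(
        name="full",
        target_spacing_mm=0.5,
        patch_shape=(64, 96, 96),
        encoder_2d=EncoderConfig(dims="2d", width=1.0, feature_dim=512,
                                 blocks=(3, 4, 6, 3), input_shape=(96, 96)),
        encoder_3d=EncoderConfig(dims="3d", width=1.0, feature_dim=512,
                                 blocks=(3, 4, 6, 3), input_shape=(64, 96, 96)),
        train=TrainConfig(),
    )


def desk_profile() -> Profile:
    return Profile(
        name="desk",
        target_spacing_mm=1.0,
        patch_shape=(32, 48, 48),
        encoder_2d=EncoderConfig(dims="2d", width=0.25, feature_dim=64,
                                 blocks=(1, 1, 1, 1), input_shape=(48, 48)),
        encoder_3d=EncoderConfig(dims="3d", width=0.25, feature_dim=64,
                                 blocks=(1, 1, 1, 1), input_shape=(32, 48, 48)),
        train=TrainConfig(translate_px=5.0),
    )


def get_profile(name: str) -> Profile:
    if name == "full":
        return full_profile()
    if name == "desk":
        return desk_profile()
    raise KeyError(f"unknown profile {name!r}; expected 'full' or 'desk'")


def scaled(profile: Profile, **train_overrides) -> Profile:
    """Return a copy of *profile* with TrainConfig fields overridden."""
    return replace(profile, train=replace(profile.train, **train_overrides))
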