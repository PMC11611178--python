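"""Shared training hyperparameters for both networks."""

from __future__ import annotations

from dataclasses import dataclass

from .errors import ConfigError


@dataclass(frozen=True)
class TrainConfig:
    """Optimization settings used by both network trainers.

    ``frames_per_epoch`` bounds the number of frames drawn (without
    replacement) from the training pool each epoch, which keeps desk-scale
    runs fast while every epoch still sees a fresh random subset.
    ``aug_shift`` is the half-range of the depth-translation augmentation
    (ROI detector); ``jitter`` the half-range of the window-centering
    jitter (tracker). The jitter must cover the tail of the ROI detector's
    localization-error distribution, not just its mean — held-out subjects
    whose lumen depth sits at the edge of the training distribution see
    center errors of ~2-3x the across-subject MAE, and a tracker trained
    with narrower jitter degrades sharply on exactly those frames.
    """

    lr: float = 1e-3
    weight_decay: float = 1e-4
    batch_size: int = 64
    roi_epochs: int = 10
    tracker_epochs: int = 20
    frames_per_epoch_roi: int = 1024
    frames_per_epoch_tracker: int = 2048
    aug_shift: int = 150
    jitter: int = 25
    val_fraction: float = 0.1
    seed: int = 0

    def validate(self) -> None:
        if self.lr <= 0 or self.batch_size < 1:
            raise ConfigError("lr must be positive and batch_size >= 1")
        if not 0.0 <= self.val_fraction < 0.5:
            raise ConfigError("val_fraction must be in [0, 0.5)")
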