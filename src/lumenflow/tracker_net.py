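"""Stage 2: diameter-regression network.

Maps a fixed-width ROI window of the envelope to a single diameter
estimate in depth samples. Five same-width, zero-padded 1-D convolutions
with batch normalization (channels rise 8→16→32 then fall 32→16→8 — no
pooling anywhere, so the relative position information of the two wall
echoes is preserved), a flatten, and three fully connected layers with
dropout. The final sigmoid output in (0, 1) is scaled by the window width
so estimates are in samples and bounded by the window.

Trained with the Huber loss — robust against the abrupt amplitude changes
the envelope shows as the pulse enters and exits the lumen. Each frame is
estimated separately and independently of all other frames (stateless,
stream-ready); smoothing is deferred to post-processing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _nn
from .errors import ConfigError, DataError, TrainingError
from .preprocess import envelope_stack
from .roi_net import ROIDetector, _lr_scale, clip_roi
from .training import TrainConfig

__all__ = ["TrackerConfig", "DiameterTrace", "DiameterTracker", "huber_loss",
           "train_tracker", "predict_trace", "extract_windows"]


@dataclass(frozen=True)
class TrackerConfig:
    input_width: int = 401
    conv_channels: tuple[int, ...] = (8, 16, 32, 16, 8)
    conv_kernel: int = 9
    fc_widths: tuple[int, ...] = (300, 64, 1)
    dropout: float = 0.2
    huber_delta: float = 1.0

    def __post_init__(self) -> None:
        if len(self.conv_channels) != 5 or len(self.fc_widths) != 3:
            raise ConfigError("architecture contract: 5 conv layers and 3 FC layers")
        c = self.conv_channels
        if not (c[0] < c[1] < c[2] and c[2] > c[3] > c[4]):
            raise ConfigError("conv channels must rise then fall (e.g. 8,16,32,16,8)")
        if self.huber_delta <= 0:
            raise ConfigError("huber_delta must be positive")


@dataclass
class DiameterTrace:
    """Per-frame arterial diameter estimates, in depth samples."""

    values: np.ndarray
    frame_rate_hz: float = 500.0
    smoothed: bool = False

    def __len__(self) -> int:
        return len(self.values)


class DiameterTracker:
    """Five-conv / three-FC regression network for arterial diameter."""

    def __init__(self, config: TrackerConfig | None = None, seed: int = 0):
        self.config = config or TrackerConfig()
        c = self.config
        rng = np.random.default_rng(seed)
        layers: list[_nn.Layer] = []
        cin = 1
        for cout in c.conv_channels:
            layers += [_nn.Conv1d(cin, cout, c.conv_kernel, rng),
                       _nn.BatchNorm1d(cout), _nn.ReLU()]
            cin = cout
        layers.append(_nn.Flatten())
        n_in = c.conv_channels[-1] * c.input_width
        for i, width in enumerate(c.fc_widths):
            layers.append(_nn.Linear(n_in, width, rng))
            if i < len(c.fc_widths) - 1:
                layers += [_nn.ReLU(), _nn.Dropout(c.dropout, rng)]
            n_in = width
        layers.append(_nn.Sigmoid())
        # zero-init the regression head: training starts from the window
        # midpoint instead of a random (possibly saturated) estimate
        head = layers[-2]
        head.W[...] = 0.0
        head.b[...] = 0.0
        self._net = _nn.Sequential(*layers)

    def n_params(self) -> int:
        return self._net.n_params()

    def params(self) -> list[np.ndarray]:
        return self._net.params()

    def grads(self) -> list[np.ndarray]:
        return self._net.grads()

    def buffers(self) -> list[np.ndarray]:
        return self._net.buffers()

    def forward(self, windows: np.ndarray, training: bool = False) -> np.ndarray:
        """Diameter estimates (samples) for windows of shape (B, input_width)."""
        single = windows.ndim == 1
        x = np.atleast_2d(np.asarray(windows, dtype=_nn.DTYPE))
        if x.shape[1] != self.config.input_width:
            raise DataError(
                f"window width {x.shape[1]} does not match configured input width "
                f"{self.config.input_width}"
            )
        unit = self._net.forward(x[:, None, :], training)[:, 0]
        out = unit * self.config.input_width
        return float(out[0]) if single else out

    def backward(self, dunit: np.ndarray) -> None:
        self._net.backward(dunit[:, None])

    def predict(self, windows: np.ndarray, chunk: int = 256) -> np.ndarray:
        windows = np.atleast_2d(windows)
        out = np.empty(windows.shape[0])
        for i in range(0, windows.shape[0], chunk):
            out[i:i + chunk] = self.forward(windows[i:i + chunk], training=False)
        return out


def huber_loss(pred: np.ndarray, target: np.ndarray, delta: float = 1.0) -> float:
    """Batch-averaged Huber loss: quadratic for |error| <= delta, linear beyond."""
    if delta <= 0:
        raise ConfigError("huber delta must be positive")
    err = np.asarray(pred, dtype=np.float64) - np.asarray(target, dtype=np.float64)
    return float(np.mean(_nn.huber(err, delta)))


def extract_windows(envelopes: np.ndarray, centers: np.ndarray,
                    width: int) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized fixed-width window extraction with inward edge clamping.

    Returns (windows (n, width), starts (n,)).
    """
    envelopes = np.atleast_2d(envelopes)
    n, length = envelopes.shape
    if width > length:
        raise DataError(f"window width {width} exceeds frame length {length}")
    starts = np.rint(np.asarray(centers)).astype(np.int64) - width // 2
    starts = np.clip(starts, 0, length - width)
    idx = starts[:, None] + np.arange(width)[None, :]
    return envelopes[np.arange(n)[:, None], idx], starts


def train_tracker(envelopes: np.ndarray, walls: np.ndarray,
                  config: TrackerConfig | None = None,
                  train_cfg: TrainConfig | None = None
                  ) -> tuple[DiameterTracker, dict[str, list[float]]]:
    """Train the diameter tracker on ground-truth-centered, jittered windows.

    Windows are clipped around the true lumen center plus uniform integer
    jitter (±train_cfg.jitter samples) so inference tolerates the ROI
    detector's localization error; the target is the true diameter in
    samples, scaled internally to the unit interval by the window width.
    """
    config = config or TrackerConfig()
    train_cfg = train_cfg or TrainConfig()
    train_cfg.validate()
    envelopes = np.asarray(envelopes, dtype=_nn.DTYPE)
    walls = np.asarray(walls, dtype=np.float64)
    n = envelopes.shape[0]
    if n == 0:
        raise DataError("empty training set")

    rng = np.random.default_rng(train_cfg.seed + 1)
    tracker = DiameterTracker(config, seed=int(rng.integers(2 ** 31)))
    opt = _nn.Adam(tracker.params(), lr=train_cfg.lr,
                   weight_decay=train_cfg.weight_decay)

    centers = walls.mean(axis=1)
    diameters = walls[:, 1] - walls[:, 0]
    n_val = int(n * train_cfg.val_fraction)
    perm = rng.permutation(n)
    val_idx, pool = perm[:n_val], perm[n_val:]

    history: dict[str, list[float]] = {"train_loss": [], "val_loss": []}
    per_epoch = min(train_cfg.frames_per_epoch_tracker, len(pool))
    delta = config.huber_delta
    steps_per_epoch = -(-per_epoch // train_cfg.batch_size)
    total_steps = train_cfg.tracker_epochs * steps_per_epoch
    step = 0
    for _epoch in range(train_cfg.tracker_epochs):
        idx = rng.choice(pool, size=per_epoch, replace=False)
        jit = rng.integers(-train_cfg.jitter, train_cfg.jitter + 1, size=per_epoch)
        windows, _ = extract_windows(envelopes[idx], centers[idx] + jit,
                                     config.input_width)
        targets = diameters[idx]
        losses = []
        for b in range(0, per_epoch, train_cfg.batch_size):
            opt.lr = train_cfg.lr * _lr_scale(step, total_steps)
            step += 1
            xb = windows[b:b + train_cfg.batch_size]
            yb = targets[b:b + train_cfg.batch_size]
            pred = tracker.forward(xb, training=True)
            err = pred - yb
            loss = float(np.mean(_nn.huber(err, delta)))
            if not np.isfinite(loss):
                raise TrainingError("tracker training loss is not finite")
            dunit = (_nn.huber_grad(err, delta) / err.size
                     * config.input_width).astype(_nn.DTYPE)
            tracker.backward(dunit)
            opt.step(tracker._net.grads())
            losses.append(loss)
        history["train_loss"].append(float(np.mean(losses)))
        if n_val:
            vwin, _ = extract_windows(envelopes[val_idx], centers[val_idx],
                                      config.input_width)
            vpred = tracker.predict(vwin)
            history["val_loss"].append(huber_loss(vpred, diameters[val_idx], delta))
    return tracker, history


def predict_trace(record, detector: ROIDetector, tracker: DiameterTracker,
                  envelopes: np.ndarray | None = None) -> DiameterTrace:
    """Per-frame streaming diameter estimation: envelope → ROI → tracker.

    Every frame is processed on its own (no temporal state or look-ahead).
    ``envelopes`` may carry precomputed normalized envelope frames
    (n_frames, length) to skip the Hilbert stage.
    """
    if envelopes is None:
        env = envelope_stack(record.samples, detector.config.decimation).T
    else:
        env = np.atleast_2d(envelopes)
    centers = detector.predict_centers(env)
    windows, _ = extract_windows(env, centers, tracker.config.input_width)
    values = tracker.predict(windows.astype(_nn.DTYPE))
    rate = record.spec.frame_rate_hz if record is not None else 500.0
    return DiameterTrace(values=values, frame_rate_hz=rate, smoothed=False)
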