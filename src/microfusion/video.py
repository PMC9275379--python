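"""ROI preprocessing and the spatiotemporal video classifier.

Each ROI frame window is cropped to the detected face, converted to
grayscale if needed, min-max normalized to [0, 1] per frame and resized
to 64x64 (bilinear), yielding a ``window x 64 x 64`` tensor.  A small 3D
convolutional network classifies the tensor for binary arousal or
valence; one network is trained per target.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from skimage.transform import resize as _sk_resize

from ._net.conv3d import Conv3dNet
from .classifiers import ClassWeights, ProbabilityPair
from .spotting import Box, clip_box

logger = logging.getLogger(__name__)

ROI_SIZE = 64


@dataclass(frozen=True)
class RoiTensor:
    """Normalized grayscale ROI stack, (window, 64, 64) in [0, 1]."""

    data: np.ndarray
    target: Optional[str] = None  # {"arousal", "valence"}

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=np.float32)
        object.__setattr__(self, "data", data)
        if data.ndim != 3 or data.shape[1:] != (ROI_SIZE, ROI_SIZE):
            raise ValueError(f"ROI tensor must be (window, {ROI_SIZE}, {ROI_SIZE})")


@dataclass(frozen=True)
class VideoNetConfig:
    """Hyper-parameters of the 3D convolutional video model."""

    window: int = 60
    conv_filters: tuple[int, int] = (8, 16)
    dense_units: int = 64
    dropout: float = 0.5
    spatial_prepool: int = 2
    epochs: int = 50
    batch_size: int = 8
    lr: float = 1e-3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.window < 4:
            raise ValueError("ROI window too short for the network")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")


def _to_gray(frame: np.ndarray) -> np.ndarray:
    if frame.ndim == 3:  # (H, W, 3) color
        return frame @ np.array([0.299, 0.587, 0.114])
    return frame


def _minmax(frame: np.ndarray) -> np.ndarray:
    lo, hi = float(frame.min()), float(frame.max())
    if hi <= lo:
        # constant frame: keep its level (clipped), e.g. all-white stays 1
        return np.clip(frame, 0.0, 1.0)
    return (frame - lo) / (hi - lo)


def preprocess_roi(
    frames: np.ndarray,
    face_box: Box | Sequence[Optional[Box]],
    target: Optional[str] = None,
    out_size: int = ROI_SIZE,
) -> RoiTensor:
    """Crop, grayscale, min-max normalize and resize each ROI frame.

    `face_box` is either one box used for every frame or a per-frame
    sequence; a ``None`` entry (face lost mid-window) reuses the last
    valid box, keeping the tensor shape fixed.
    """
    frames = np.asarray(frames)
    if frames.shape[0] == 0:
        raise ValueError("empty ROI window")
    if isinstance(face_box, tuple) and len(face_box) == 4 and np.isscalar(face_box[0]):
        boxes: list[Optional[Box]] = [face_box] * frames.shape[0]
    else:
        boxes = list(face_box)
        if len(boxes) != frames.shape[0]:
            raise ValueError("need one face box per frame")
    out = np.empty((frames.shape[0], out_size, out_size), dtype=np.float32)
    last_box: Optional[Box] = None
    for f, (frame, box) in enumerate(zip(frames, boxes)):
        if box is None:
            if last_box is None:
                raise ValueError("face box missing for the first ROI frame")
            logger.warning("face lost at ROI frame %d; reusing previous box", f)
            box = last_box
        box = clip_box(box, frame.shape[0], frame.shape[1])
        last_box = box
        top, left, h, w = box
        crop = _minmax(_to_gray(np.asarray(frame, dtype=np.float64))[top : top + h, left : left + w])
        out[f] = _sk_resize(crop, (out_size, out_size), order=1, mode="edge",
                            anti_aliasing=False, preserve_range=True)
    return RoiTensor(data=out, target=target)


class VideoModel:
    """Trained 3D CNN for one binary target.

    Inputs are centred on the training-set mean tensor and scaled by the
    global residual SD before entering the network: the neutral face is a
    large constant component shared by every trial, and removing it is
    what lets the optimizer see the small transient movements.
    """

    def __init__(self, net: Conv3dNet, config: VideoNetConfig,
                 mu: np.ndarray, sd: float) -> None:
        self.net = net
        self.config = config
        self.mu = mu
        self.sd = sd

    def _scale(self, x: np.ndarray) -> np.ndarray:
        return (x - self.mu) / self.sd

    def predict_proba(self, rois: Sequence[RoiTensor] | np.ndarray) -> np.ndarray:
        return self.net.predict_proba(self._scale(_stack(rois)))

    @property
    def history(self):
        return self.net.history

    def save(self, path) -> None:
        self.net.save(path)
        np.savez(str(path) + ".scaler.npz", mu=self.mu, sd=np.array([self.sd]))

    @classmethod
    def load(cls, path, config: Optional[VideoNetConfig] = None) -> "VideoModel":
        net = Conv3dNet.load(path)
        scaler = np.load(str(path) + ".scaler.npz")
        return cls(net, config or VideoNetConfig(window=net.in_shape[0], seed=net.seed),
                   mu=scaler["mu"], sd=float(scaler["sd"][0]))


def _stack(rois) -> np.ndarray:
    if isinstance(rois, np.ndarray):
        return rois
    return np.stack([r.data if isinstance(r, RoiTensor) else np.asarray(r) for r in rois])


def train_video_model(
    rois: Sequence[RoiTensor],
    labels: Sequence[int],
    class_weights: ClassWeights,
    config: VideoNetConfig,
) -> VideoModel:
    """Train the 3D CNN with cost-sensitive (class-weighted) loss."""
    x = _stack(rois)
    y = np.asarray(labels, dtype=int)
    counts = np.bincount(y, minlength=2)
    if counts.min() < 2:
        raise ValueError("need at least 2 training trials per class")
    if x.shape[1] != config.window:
        raise ValueError(f"ROI window {x.shape[1]} != configured {config.window}")
    net = Conv3dNet(
        in_shape=x.shape[1:],
        filters=config.conv_filters,
        dense_units=config.dense_units,
        dropout=config.dropout,
        spatial_prepool=config.spatial_prepool,
        seed=config.seed,
    )
    mu = x.mean(axis=0)
    sd = float(max((x - mu).std(), 1e-6))
    model = VideoModel(net, config, mu=mu, sd=sd)
    sample_w = np.where(y == 1, class_weights.weight_high, class_weights.weight_low)
    net.fit(model._scale(x), y, sample_w, epochs=config.epochs,
            batch_size=config.batch_size, lr=config.lr)
    return model


def predict_video(model: VideoModel, roi: RoiTensor,
                  trial_id: str = "") -> ProbabilityPair:
    """Class probabilities {low, high} for one ROI tensor."""
    p = model.predict_proba([roi])[0]
    return ProbabilityPair(p_low=float(p[0]), p_high=float(p[1]),
                           modality="video", trial_id=trial_id)
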