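"""Micro-expression apex spotting.

A trial recorded under poker-face instructions is neutral in almost every
frame; the genuine emotion leaks as a brief, low-intensity facial movement.
The first frame of the trial stands in for the onset frame and the last
frame for the offset frame (both show the face at rest).  For every frame
we average the absolute pixel differences against both reference frames
over ten regions placed around the facial components where muscle
movements concentrate (eyebrows, eyes, nose, mouth corners, chin).  The
frame with the largest mean difference is taken as the apex frame, and a
fixed-length window of frames around it becomes the video region of
interest (ROI) passed on to the spatiotemporal classifier.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np

logger = logging.getLogger(__name__)

Box = tuple[int, int, int, int]  # (top, left, height, width)


class FaceNotFoundError(RuntimeError):
    """Raised when the plugged-in face detector finds no face in a frame."""


#: Default layout of the ten facial regions, as (name, top, left, height,
#: width) fractions of the face crop.  Regions sit on the eyebrows, eyes,
#: nose root, nose wings, mouth corners and chin.
REGION_FRACTIONS: tuple[tuple[str, float, float, float, float], ...] = (
    ("left_eyebrow", 0.18, 0.12, 0.10, 0.25),
    ("right_eyebrow", 0.18, 0.63, 0.10, 0.25),
    ("left_eye", 0.32, 0.15, 0.12, 0.20),
    ("right_eye", 0.32, 0.65, 0.12, 0.20),
    ("nose_root", 0.35, 0.42, 0.14, 0.16),
    ("left_nose_wing", 0.52, 0.30, 0.10, 0.14),
    ("right_nose_wing", 0.52, 0.56, 0.10, 0.14),
    ("left_mouth_corner", 0.68, 0.22, 0.12, 0.16),
    ("right_mouth_corner", 0.68, 0.62, 0.12, 0.16),
    ("chin", 0.84, 0.38, 0.12, 0.24),
)


@dataclass(frozen=True)
class FacialRegionSet:
    """Exactly ten pixel boxes (top, left, height, width) over a face crop."""

    regions: tuple[Box, ...]
    names: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if len(self.regions) != 10:
            raise ValueError(
                f"a FacialRegionSet holds exactly 10 regions, got {len(self.regions)}"
            )
        for top, left, h, w in self.regions:
            if h <= 0 or w <= 0 or top < 0 or left < 0:
                raise ValueError(f"invalid region box {(top, left, h, w)}")

    @classmethod
    def default(cls, face_height: int, face_width: int) -> "FacialRegionSet":
        """Scale the default fractional layout to a face crop size."""
        boxes = []
        names = []
        for name, ft, fl, fh, fw in REGION_FRACTIONS:
            top = int(round(ft * face_height))
            left = int(round(fl * face_width))
            h = max(1, int(round(fh * face_height)))
            w = max(1, int(round(fw * face_width)))
            h = min(h, face_height - top)
            w = min(w, face_width - left)
            boxes.append((top, left, h, w))
            names.append(name)
        return cls(regions=tuple(boxes), names=tuple(names))

    def shifted(self, dtop: int, dleft: int) -> "FacialRegionSet":
        """Translate all boxes, e.g. from face-crop to frame coordinates."""
        return FacialRegionSet(
            regions=tuple((t + dtop, l + dleft, h, w) for t, l, h, w in self.regions),
            names=self.names,
        )

    def validate_inside(self, height: int, width: int) -> None:
        for top, left, h, w in self.regions:
            if top + h > height or left + w > width:
                raise ValueError(
                    f"region {(top, left, h, w)} exceeds bounds {(height, width)}"
                )


@dataclass(frozen=True)
class DifferenceCurve:
    """Per-frame mean absolute difference against the first and last frame."""

    values: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.ndim != 1 or values.size == 0:
            raise ValueError("difference curve must be a non-empty vector")

    def __len__(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class ApexResult:
    """Chosen apex frame plus the ROI bounds (half-open) that contain it."""

    apex_frame: int
    roi_start: int
    roi_end: int
    curve: Optional[DifferenceCurve] = None

    def __post_init__(self) -> None:
        if not (self.roi_start <= self.apex_frame < self.roi_end):
            raise ValueError("apex frame must lie inside the ROI window")


FaceDetector = Callable[[np.ndarray], Optional[Box]]


def clip_box(box: Box, height: int, width: int) -> Box:
    """Clip a (top, left, h, w) box to image bounds."""
    top, left, h, w = box
    top2 = min(max(top, 0), height - 1)
    left2 = min(max(left, 0), width - 1)
    bottom = min(max(top + h, top2 + 1), height)
    right = min(max(left + w, left2 + 1), width)
    return (top2, left2, bottom - top2, right - left2)


def threshold_face_detector(threshold: float = 0.35, min_pixels: int = 64) -> FaceDetector:
    """A strict luminance detector: bounding box of pixels above `threshold`.

    Returns ``None`` (no face) when fewer than `min_pixels` pixels pass,
    e.g. for an all-black frame.
    """

    def detect(frame: np.ndarray) -> Optional[Box]:
        mask = np.asarray(frame) > threshold
        if mask.sum() < min_pixels:
            return None
        rows = np.flatnonzero(mask.any(axis=1))
        cols = np.flatnonzero(mask.any(axis=0))
        return (int(rows[0]), int(cols[0]), int(rows[-1] - rows[0] + 1), int(cols[-1] - cols[0] + 1))

    return detect


def detect_face(frame: np.ndarray, detector: FaceDetector) -> Box:
    """Run a pluggable face detector on one frame and clip the box to bounds.

    Raises
    ------
    FaceNotFoundError
        When the detector reports no face; callers exclude the trial (with a
        logged warning) rather than guessing a crop.
    """
    frame = np.asarray(frame)
    if frame.size == 0:
        raise ValueError("empty frame")
    box = detector(frame)
    if box is None:
        raise FaceNotFoundError("no face detected in frame")
    return clip_box(box, frame.shape[0], frame.shape[1])


def difference_curve(frames: np.ndarray, regions: FacialRegionSet) -> DifferenceCurve:
    """Score each frame by its mean absolute difference to the trial ends.

    ``score(f) = mean over all pixels in the ten regions of
    (|f - first frame| + |f - last frame|) / 2``.

    The first and last frames score half their mutual difference, so a
    neutral start/end keeps both ends of the curve near zero.
    """
    frames = np.asarray(frames)
    if frames.ndim != 3 or frames.shape[0] < 3:
        raise ValueError("need a (n_frames, H, W) stack with at least 3 frames")
    if len(regions.regions) == 0:  # pragma: no cover - type guarantees 10
        raise ValueError("empty region set")
    regions.validate_inside(frames.shape[1], frames.shape[2])
    n = frames.shape[0]
    pix = np.concatenate(
        [
            frames[:, t : t + h, l : l + w].reshape(n, -1)
            for t, l, h, w in regions.regions
        ],
        axis=1,
    ).astype(np.float32, copy=False)
    vals = 0.5 * (np.abs(pix - pix[0]) + np.abs(pix - pix[-1])).mean(axis=1)
    return DifferenceCurve(values=vals.astype(float))


def find_apex(curve: DifferenceCurve | np.ndarray) -> int:
    """Return the index of the curve maximum (earliest index on ties)."""
    values = curve.values if isinstance(curve, DifferenceCurve) else np.asarray(curve, float)
    if values.size == 0:
        raise ValueError("empty curve")
    return int(np.argmax(values))


def roi_bounds(n_frames: int, apex_frame: int, window: int) -> tuple[int, int]:
    """Half-open [start, end) of a `window`-frame ROI centred on the apex.

    ``window // 2`` frames precede the apex; if the centred window overruns
    either end of the trial it is shifted (never shrunk) to fit.
    """
    if window > n_frames:
        raise ValueError(f"ROI window {window} exceeds trial length {n_frames}")
    if not 0 <= apex_frame < n_frames:
        raise ValueError("apex frame outside trial")
    start = apex_frame - window // 2
    start = min(max(start, 0), n_frames - window)
    return start, start + window


def extract_video_roi(
    frames: np.ndarray,
    apex_frame: int,
    window: int,
    curve: Optional[DifferenceCurve] = None,
) -> tuple[ApexResult, np.ndarray]:
    """Cut the `window`-frame ROI around the apex; returns (result, frames)."""
    frames = np.asarray(frames)
    start, end = roi_bounds(frames.shape[0], apex_frame, window)
    result = ApexResult(apex_frame=apex_frame, roi_start=start, roi_end=end, curve=curve)
    return result, frames[start:end]


def spot_trial(
    frames: np.ndarray,
    detector: FaceDetector,
    window: int,
    regions: Optional[FacialRegionSet] = None,
) -> tuple[ApexResult, Box, np.ndarray]:
    """Full spotting pass for one trial.

    Detects the face on the first frame, lays the ten default regions over
    the face crop, computes the difference curve, picks the apex, and cuts
    the video ROI.  Returns ``(apex_result, face_box, roi_frames)`` where
    `roi_frames` are uncropped original frames.
    """
    frames = np.asarray(frames)
    face_box = detect_face(frames[0], detector)
    top, left, h, w = face_box
    if regions is None:
        regions = FacialRegionSet.default(h, w)
    curve = difference_curve(frames, regions.shifted(top, left))
    apex = find_apex(curve)
    result, roi_frames = extract_video_roi(frames, apex, window, curve=curve)
    return result, face_box, roi_frames
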