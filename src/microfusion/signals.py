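"""EEG/GSR/PPG cleaning and apex-aligned signal ROI extraction.

Cleaning defaults: EEG band-passed 1-45 Hz (brain-wave range) with a
common average reference; PPG band-passed 0.7-2.5 Hz (pulse band); GSR
band-passed 0.1-15 Hz with a median filter against rapid transient
artifacts.  All filters are 4th-order Butterworth applied
forward-backward (zero phase).  Signals are z-scored per channel over the
whole trial.  The apex frame found in the video maps into each stream by
rescaling with the stream's sampling rate; a fixed number of seconds
around that sample becomes the signal ROI.

Sample indices are 0-based and windows half-open ``[start, end)``.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Union

import numpy as np
from scipy import ndimage, signal as sps

#: Default band-pass edges (Hz) per modality.
EEG_BAND = (1.0, 45.0)
PPG_BAND = (0.7, 2.5)
GSR_BAND = (0.1, 15.0)


@dataclass(frozen=True)
class FilterSpec:
    """Either a Butterworth band-pass or a sliding median filter."""

    kind: str  # {"bandpass", "median"}
    low_hz: float = 0.0
    high_hz: float = 0.0
    kernel_samples: int = 0
    order: int = 4

    def __post_init__(self) -> None:
        if self.kind not in ("bandpass", "median"):
            raise ValueError(f"unknown filter kind {self.kind!r}")
        if self.kind == "bandpass" and not 0 < self.low_hz < self.high_hz:
            raise ValueError("bandpass needs 0 < low_hz < high_hz")
        if self.kind == "median" and self.kernel_samples % 2 == 0:
            raise ValueError("median kernel must be odd")


@dataclass(frozen=True)
class SignalRoi:
    """Half-open sample window of the signal region of interest."""

    start_sample: int
    end_sample: int
    rate: float
    seconds: Union[float, str]

    @property
    def n_samples(self) -> int:
        return self.end_sample - self.start_sample


def bandpass(x: np.ndarray, rate: float, low_hz: float, high_hz: float,
             order: int = 4) -> np.ndarray:
    """Zero-phase Butterworth band-pass along the last axis."""
    if not 0 < low_hz < high_hz:
        raise ValueError("need 0 < low_hz < high_hz")
    if high_hz >= rate / 2:
        raise ValueError(f"high cut {high_hz} Hz at or above Nyquist ({rate / 2} Hz)")
    x = np.asarray(x, dtype=float)
    sos = sps.butter(order, [low_hz, high_hz], btype="bandpass", fs=rate, output="sos")
    return sps.sosfiltfilt(sos, x, axis=-1)


def apply_filter(x: np.ndarray, rate: float, spec: FilterSpec) -> np.ndarray:
    """Apply a FilterSpec (band-pass or median) to a signal."""
    if spec.kind == "bandpass":
        return bandpass(x, rate, spec.low_hz, spec.high_hz, spec.order)
    return median_filter_gsr(x, spec.kernel_samples)


def common_average_reference(eeg: np.ndarray) -> np.ndarray:
    """Subtract the cross-channel mean from every sample (CAR)."""
    eeg = np.asarray(eeg, dtype=float)
    if eeg.ndim != 2 or eeg.shape[0] < 2:
        raise ValueError("CAR needs a (channels, samples) matrix with >= 2 channels")
    return eeg - eeg.mean(axis=0, keepdims=True)


def median_filter_gsr(gsr: np.ndarray, kernel_samples: int) -> np.ndarray:
    """Sliding median with reflected edges; removes narrow spikes."""
    gsr = np.asarray(gsr, dtype=float)
    if kernel_samples % 2 == 0:
        raise ValueError("median kernel must be odd")
    if kernel_samples > gsr.shape[-1]:
        raise ValueError("median kernel longer than signal")
    return ndimage.median_filter(gsr, size=kernel_samples, mode="reflect")


def default_median_kernel(rate: float, seconds: float = 0.5) -> int:
    """Kernel spanning `seconds` of samples, rounded up to an odd count."""
    k = max(3, int(round(seconds * rate)))
    return k + 1 if k % 2 == 0 else k


def normalize(x: np.ndarray) -> np.ndarray:
    """Per-channel z-score over the whole trial; constant channels -> zeros."""
    x = np.asarray(x, dtype=float)
    mean = x.mean(axis=-1, keepdims=True)
    sd = x.std(axis=-1, keepdims=True)
    flat = sd <= 0
    if np.any(flat):
        warnings.warn("constant channel(s) normalized to zeros", stacklevel=2)
    return np.where(flat, 0.0, (x - mean) / np.where(flat, 1.0, sd))


def trim_lead(x: np.ndarray, rate: float, trim_seconds: float = 8.0) -> np.ndarray:
    """Drop the leading `trim_seconds` (baseline + engagement time)."""
    x = np.asarray(x)
    n_trim = int(round(trim_seconds * rate))
    if n_trim >= x.shape[-1]:
        raise ValueError(
            f"cannot trim {trim_seconds} s from a {x.shape[-1] / rate:.1f} s trial"
        )
    return x[..., n_trim:]


def frame_to_sample(apex_frame: int, fps: float, rate: float) -> int:
    """Map a video frame index to the sample index of a signal stream."""
    if fps <= 0 or rate <= 0:
        raise ValueError("rates must be positive")
    return int(round(apex_frame / fps * rate))


def extract_signal_roi(
    x: np.ndarray,
    rate: float,
    apex_sample: int,
    seconds: Union[float, str],
) -> tuple[SignalRoi, np.ndarray]:
    """Cut ``round(seconds * rate)`` samples centred on the apex sample.

    A window overrunning either end of the trial is shifted, not shrunk,
    so the extracted length is always exact.  ``seconds="all"`` returns
    the full trial.
    """
    x = np.asarray(x)
    n = x.shape[-1]
    if seconds == "all":
        roi = SignalRoi(0, n, rate, "all")
        return roi, x
    length = int(round(float(seconds) * rate))
    if length < 1:
        raise ValueError("ROI must span at least one sample")
    if length > n:
        raise ValueError(f"requested ROI of {length} samples exceeds trial length {n}")
    start = apex_sample - length // 2
    start = min(max(start, 0), n - length)
    roi = SignalRoi(start, start + length, rate, float(seconds))
    return roi, x[..., start : start + length]


def clean_eeg(eeg: np.ndarray, rate: float) -> np.ndarray:
    """Band-pass 1-45 Hz, CAR, then z-score."""
    return normalize(common_average_reference(bandpass(eeg, rate, *EEG_BAND)))


def clean_gsr(gsr: np.ndarray, rate: float) -> np.ndarray:
    """Band-pass 0.1-15 Hz, median filter, then z-score."""
    out = bandpass(gsr, rate, *GSR_BAND)
    out = median_filter_gsr(out, default_median_kernel(rate))
    return normalize(out)


def clean_ppg(ppg: np.ndarray, rate: float) -> np.ndarray:
    """Band-pass 0.7-2.5 Hz (pulse band), then z-score."""
    return normalize(bandpass(ppg, rate, *PPG_BAND))
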