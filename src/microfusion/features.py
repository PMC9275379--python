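"""Per-window feature extraction from cleaned signal ROIs.

Each signal ROI is partitioned into non-overlapping windows (default
1 s).  EEG windows yield the five canonical band powers -- delta (1-4 Hz),
theta (4-8), alpha (8-12), beta (12-30), gamma (30-45) -- computed from a
plain periodogram, averaged over the in-band frequency bins and then over
channels, so each window contributes a 5-vector regardless of channel
count.  GSR windows yield [mean, SD, mean |first difference|, mean
|second difference|]; PPG windows yield [mean, SD].  GSR and PPG features
concatenate into a six-feature "physiological" vector.  All standard
deviations are population SDs (divide by n).
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import signal as sps


@dataclass(frozen=True)
class BandDefinition:
    name: str
    low_hz: float
    high_hz: float

    def __post_init__(self) -> None:
        if not 0 <= self.low_hz < self.high_hz:
            raise ValueError(f"invalid band {self.name}: {self.low_hz}-{self.high_hz}")


DEFAULT_BANDS: tuple[BandDefinition, ...] = (
    BandDefinition("delta", 1.0, 4.0),
    BandDefinition("theta", 4.0, 8.0),
    BandDefinition("alpha", 8.0, 12.0),
    BandDefinition("beta", 12.0, 30.0),
    BandDefinition("gamma", 30.0, 45.0),
)

GSR_FEATURE_NAMES = ("gsr_mean", "gsr_sd", "gsr_abs_diff1", "gsr_abs_diff2")
PPG_FEATURE_NAMES = ("ppg_mean", "ppg_sd")


@dataclass(frozen=True)
class WindowedFeatureSequence:
    """Ordered per-window feature vectors for one trial's ROI."""

    windows: np.ndarray  # (n_windows, n_features)
    window_seconds: float
    modality: str  # {"eeg", "gsr", "ppg", "physio"}
    feature_names: tuple[str, ...]

    def __post_init__(self) -> None:
        windows = np.asarray(self.windows, dtype=float)
        object.__setattr__(self, "windows", windows)
        if windows.ndim != 2:
            raise ValueError("windows must be (n_windows, n_features)")
        if windows.shape[1] != len(self.feature_names):
            raise ValueError("feature_names must match the feature width")

    @property
    def n_windows(self) -> int:
        return self.windows.shape[0]


def window_trial(x: np.ndarray, rate: float, window_seconds: float = 1.0) -> np.ndarray:
    """Split along the last axis into non-overlapping windows.

    A trailing partial window is dropped.  Returns ``(n_windows, ...,
    window_len)`` with the window axis first.
    """
    x = np.asarray(x)
    wlen = int(round(window_seconds * rate))
    if wlen < 1:
        raise ValueError("window must span at least one sample")
    n_win = x.shape[-1] // wlen
    if n_win == 0:
        raise ValueError("signal shorter than one window")
    trimmed = x[..., : n_win * wlen]
    shaped = trimmed.reshape(*x.shape[:-1], n_win, wlen)
    return np.moveaxis(shaped, -2, 0)


def eeg_band_powers(
    window: np.ndarray,
    rate: float,
    bands: Sequence[BandDefinition] = DEFAULT_BANDS,
) -> np.ndarray:
    """Channel-averaged spectral power in each band for one window.

    A plain (boxcar) periodogram is computed per channel; power is
    averaged over bins with ``low <= f < high`` and then across channels,
    giving one scalar per band ordered as `bands`.
    """
    window = np.atleast_2d(np.asarray(window, dtype=float))
    nyquist = rate / 2
    for band in bands:
        if band.high_hz > nyquist:
            raise ValueError(f"band {band.name} exceeds Nyquist ({nyquist} Hz)")
    freqs, pxx = sps.periodogram(window, fs=rate, window="boxcar", axis=-1)
    out = np.empty(len(bands))
    for i, band in enumerate(bands):
        mask = (freqs >= band.low_hz) & (freqs < band.high_hz)
        out[i] = pxx[:, mask].mean() if mask.any() else 0.0
    return out


def gsr_feature_vector(window: np.ndarray, rate: float | None = None) -> np.ndarray:
    """[mean, SD, mean |first diff|, mean |second diff|] of one GSR window."""
    window = np.asarray(window, dtype=float).ravel()
    if window.size < 3:
        raise ValueError("GSR feature window needs at least 3 samples")
    d1 = np.diff(window)
    d2 = np.diff(window, n=2)
    return np.array([window.mean(), window.std(),
                     np.abs(d1).mean(), np.abs(d2).mean()])


def ppg_feature_vector(window: np.ndarray) -> np.ndarray:
    """[mean, SD] of one PPG window."""
    window = np.asarray(window, dtype=float).ravel()
    if window.size < 2:
        raise ValueError("PPG feature window needs at least 2 samples")
    return np.array([window.mean(), window.std()])


def eeg_feature_sequence(roi: np.ndarray, rate: float,
                         window_seconds: float = 1.0,
                         bands: Sequence[BandDefinition] = DEFAULT_BANDS,
                         ) -> WindowedFeatureSequence:
    windows = window_trial(roi, rate, window_seconds)
    feats = np.stack([eeg_band_powers(w, rate, bands) for w in windows])
    return WindowedFeatureSequence(
        windows=feats, window_seconds=window_seconds, modality="eeg",
        feature_names=tuple(b.name for b in bands),
    )


def gsr_feature_sequence(roi: np.ndarray, rate: float,
                         window_seconds: float = 1.0) -> WindowedFeatureSequence:
    windows = window_trial(roi, rate, window_seconds)
    feats = np.stack([gsr_feature_vector(w, rate) for w in windows])
    return WindowedFeatureSequence(
        windows=feats, window_seconds=window_seconds, modality="gsr",
        feature_names=GSR_FEATURE_NAMES,
    )


def ppg_feature_sequence(roi: np.ndarray, rate: float,
                         window_seconds: float = 1.0) -> WindowedFeatureSequence:
    windows = window_trial(roi, rate, window_seconds)
    feats = np.stack([ppg_feature_vector(w) for w in windows])
    return WindowedFeatureSequence(
        windows=feats, window_seconds=window_seconds, modality="ppg",
        feature_names=PPG_FEATURE_NAMES,
    )


def concat_physio(gsr_seq: WindowedFeatureSequence,
                  ppg_seq: WindowedFeatureSequence) -> WindowedFeatureSequence:
    """Feature-level fusion of GSR and PPG (GSR features first)."""
    if gsr_seq.n_windows != ppg_seq.n_windows:
        raise ValueError(
            f"window count mismatch: GSR {gsr_seq.n_windows} vs PPG {ppg_seq.n_windows}"
        )
    return WindowedFeatureSequence(
        windows=np.hstack([gsr_seq.windows, ppg_seq.windows]),
        window_seconds=gsr_seq.window_seconds,
        modality="physio",
        feature_names=gsr_seq.feature_names + ppg_seq.feature_names,
    )
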