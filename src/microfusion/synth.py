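"""Synthetic multimodal trial generator with known ground truth.

Real affective datasets of this kind (synchronized facial video, EEG, GSR
and PPG with SAM self-reports) are access-restricted, so this module
produces trials whose latent emotional state, apex time and effect sizes
are known exactly.  Each trial emulates a participant watching an emotion
eliciting clip with a poker face:

* **frames** - a neutral synthetic face (an intensity field with fixed
  landmark-like geometry, not a photorealistic render) plus per-frame
  Gaussian noise.  One micro-expression is planted per trial: an additive
  intensity bump in one facial region with a triangular temporal profile
  peaking exactly at the apex frame.  The region encodes the latent state
  (eyebrows vs. mouth corners for high/low arousal, left vs. right side
  for high/low valence), so the video modality carries class information.
* **eeg** - per-channel pink (1/f) noise; near the apex an oscillatory
  component is added whose band depends on the latent state: high arousal
  boosts beta/gamma (low arousal theta), and high valence boosts alpha
  with a left-weighted channel asymmetry.
* **gsr** - slow tonic drift plus phasic skin-conductance bumps
  (exponential rise/decay); bump count and amplitude near the apex grow
  with high arousal.
* **ppg** - a pulsatile waveform whose rate rises with arousal and whose
  amplitude envelope swells near the apex for high valence.
* **ratings** - SAM-style 1-9 integers drawn to agree with the latent
  binary state (rating > 5 for "high") with configurable fidelity.

Latent (arousal, valence) combinations cycle deterministically over the
global trial index, so the dataset is balanced up to rounding.  All
randomness derives from a single seed through ``numpy.random.SeedSequence``
spawning, so a given configuration reproduces bit-identical trials.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterator, Optional

import numpy as np

from .spotting import Box, FacialRegionSet

LOW, HIGH = 0, 1

#: Half-span (seconds) of the window around the apex time in which the
#: emotion-dependent EEG oscillation is injected -- half the default 15 s
#: signal ROI, so the planted contrast lies inside the analysed window.
EFFECT_HALFSPAN_SECONDS = 7.5


class ParameterError(ValueError):
    """Invalid generator configuration."""


@dataclass(frozen=True)
class GeneratorConfig:
    """Study-condition parameters of the synthetic recordings.

    Defaults mirror the emulated acquisition: 80 s trials, a 30 Hz webcam,
    32-channel EEG at 128 Hz and 128 Hz GSR/PPG, 23 subjects with 10
    trials each.
    """

    n_subjects: int = 23
    trials_per_subject: int = 10
    trial_seconds: float = 80.0
    fps: float = 30.0
    frame_size: tuple[int, int] = (96, 96)
    eeg_rate: float = 128.0
    eeg_channels: int = 32
    physio_rate: float = 128.0
    apex_effect_amplitude: float = 0.10
    band_shift_strength: float = 1.0
    physio_effect_strength: float = 1.0
    noise_sd: float = 0.02
    rating_fidelity: float = 0.95
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1 or self.trials_per_subject < 1:
            raise ParameterError("subject and trial counts must be >= 1")
        if min(self.fps, self.eeg_rate, self.physio_rate) <= 0:
            raise ParameterError("all sampling rates must be > 0")
        if self.trial_seconds * self.fps < 60:
            raise ParameterError("trial must span at least 60 frames for a 60-frame ROI")
        if self.eeg_channels < 1:
            raise ParameterError("need at least one EEG channel")
        if len(self.frame_size) != 2 or min(self.frame_size) < 48:
            raise ParameterError("frame_size must be (H, W) with both >= 48")
        if min(self.apex_effect_amplitude, self.band_shift_strength,
               self.physio_effect_strength, self.noise_sd) < 0:
            raise ParameterError("effect strengths and noise_sd must be >= 0")
        if not 0.0 <= self.rating_fidelity <= 1.0:
            raise ParameterError("rating_fidelity must lie in [0, 1]")

    @property
    def n_frames(self) -> int:
        return int(round(self.trial_seconds * self.fps))

    @property
    def n_eeg_samples(self) -> int:
        return int(round(self.trial_seconds * self.eeg_rate))

    @property
    def n_physio_samples(self) -> int:
        return int(round(self.trial_seconds * self.physio_rate))

    @property
    def n_trials(self) -> int:
        return self.n_subjects * self.trials_per_subject


@dataclass(frozen=True)
class GroundTruth:
    """Latent state of one synthetic trial (0 = low, 1 = high)."""

    latent_arousal: int
    latent_valence: int
    apex_frame: int
    me_duration_frames: int


@dataclass
class MultimodalTrial:
    """One synchronized trial across all four modalities plus ratings."""

    subject_id: str
    trial_id: str
    frames: np.ndarray  # (n_frames, H, W) in [0, 1]
    eeg: np.ndarray  # (channels, samples)
    gsr: np.ndarray  # (samples,)
    ppg: np.ndarray  # (samples,)
    rating_arousal: int
    rating_valence: int
    fps: float
    eeg_rate: float
    physio_rate: float
    truth: Optional[GroundTruth] = None


# ---------------------------------------------------------------------------
# face geometry

def default_face_box(frame_shape: tuple[int, ...]) -> Box:
    """The generator's face bounding box for a given frame shape.

    The synthetic face always occupies the same fractional area of the
    frame, so this doubles as the oracle face detector.
    """
    h, w = int(frame_shape[0]), int(frame_shape[1])
    top = int(round(0.08 * h))
    left = int(round(0.15 * w))
    return (top, left, int(round(0.84 * h)), int(round(0.70 * w)))


def synthetic_face_detector():
    """A detector callable returning the generator's known face box."""

    def detect(frame: np.ndarray) -> Box:
        return default_face_box(np.asarray(frame).shape)

    return detect


def base_face(frame_shape: tuple[int, int]) -> np.ndarray:
    """Deterministic neutral-face intensity field for a frame size.

    A bright elliptical head on a dark background with darker patches at
    the eyebrow, eye and mouth landmarks (taken from the spotting module's
    region layout, so planted movements land on plausible geometry).
    """
    h, w = frame_shape
    img = np.full((h, w), 0.15, dtype=np.float32)
    top, left, fh, fw = default_face_box((h, w))
    cy, cx = top + fh / 2.0, left + fw / 2.0
    ry, rx = fh / 2.0, fw / 2.0
    yy, xx = np.mgrid[0:h, 0:w]
    inside = ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2 <= 1.0
    img[inside] = 0.65
    regions = FacialRegionSet.default(fh, fw).shifted(top, left)
    shade = {
        "left_eyebrow": 0.30, "right_eyebrow": 0.30,
        "left_eye": 0.25, "right_eye": 0.25,
        "nose_root": 0.55, "left_nose_wing": 0.50, "right_nose_wing": 0.50,
        "left_mouth_corner": 0.35, "right_mouth_corner": 0.35, "chin": 0.55,
    }
    for name, (t, l, bh, bw) in zip(regions.names, regions.regions):
        img[t : t + bh, l : l + bw] = shade[name]
    return img


def me_region_for(truth: GroundTruth, frame_shape: tuple[int, int]) -> Box:
    """Facial region (frame coordinates) where the micro-expression lands.

    High arousal moves the eyebrows, low arousal the mouth corners; high
    valence uses the left side of the face, low valence the right.
    """
    top, left, fh, fw = default_face_box(frame_shape)
    regions = FacialRegionSet.default(fh, fw).shifted(top, left)
    name = {
        (HIGH, HIGH): "left_eyebrow",
        (HIGH, LOW): "right_eyebrow",
        (LOW, HIGH): "left_mouth_corner",
        (LOW, LOW): "right_mouth_corner",
    }[(truth.latent_arousal, truth.latent_valence)]
    return regions.regions[regions.names.index(name)]


# ---------------------------------------------------------------------------
# per-modality generators

def plant_micro_expression(
    frames: np.ndarray,
    apex_frame: int,
    duration_frames: int,
    amplitude: float,
    region: Box,
) -> np.ndarray:
    """Add a triangular intensity bump to `region`, peaking at `apex_frame`.

    The bump ramps linearly from zero over ``duration_frames`` (onset to
    offset) with its maximum exactly at the apex; frames outside the
    sequence are clipped away.  All pixels outside the region are left
    untouched, and ``amplitude=0`` returns an unchanged copy.
    """
    frames = np.asarray(frames)
    n, h, w = frames.shape
    top, left, bh, bw = region
    if top < 0 or left < 0 or top + bh > h or left + bw > w:
        raise ValueError(f"region {region} outside frame bounds {(h, w)}")
    if not 0 <= apex_frame < n:
        raise ValueError("apex frame outside sequence")
    out = frames.copy()
    if amplitude == 0 or duration_frames <= 0:
        return out
    half = duration_frames / 2.0
    lo = max(0, int(math.ceil(apex_frame - half)))
    hi = min(n - 1, int(math.floor(apex_frame + half)))
    for f in range(lo, hi + 1):
        weight = 1.0 - abs(f - apex_frame) / (half + 0.5)
        if weight > 0:
            out[f, top : top + bh, left : left + bw] += amplitude * weight
    return out


def generate_frames(truth: GroundTruth, config: GeneratorConfig,
                    rng: np.random.Generator) -> np.ndarray:
    """Neutral face + noise + one planted micro-expression, in [0, 1]."""
    n = config.n_frames
    face = base_face(config.frame_size)
    frames = rng.standard_normal((n, *config.frame_size), dtype=np.float32)
    frames *= config.noise_sd
    frames += face[None, :, :]
    if config.apex_effect_amplitude > 0:
        region = me_region_for(truth, config.frame_size)
        frames = plant_micro_expression(
            frames, truth.apex_frame, truth.me_duration_frames,
            config.apex_effect_amplitude, region,
        )
    return np.clip(frames, 0.0, 1.0, out=frames)


def _pink_noise(n: int, rng: np.random.Generator) -> np.ndarray:
    """Unit-variance 1/f (power) noise via spectral shaping."""
    freqs = np.fft.rfftfreq(n)
    amp = 1.0 / np.sqrt(np.maximum(freqs, freqs[1]))
    coeff = amp * (rng.standard_normal(freqs.size) + 1j * rng.standard_normal(freqs.size))
    coeff[0] = 0.0
    x = np.fft.irfft(coeff, n=n)
    return x / x.std()


def _effect_window(n_samples: int, rate: float, apex_time: float) -> tuple[int, int]:
    lo = max(0, int(round((apex_time - EFFECT_HALFSPAN_SECONDS) * rate)))
    hi = min(n_samples, int(round((apex_time + EFFECT_HALFSPAN_SECONDS) * rate)))
    return lo, hi


def generate_eeg(truth: GroundTruth, config: GeneratorConfig,
                 rng: Optional[np.random.Generator] = None) -> np.ndarray:
    """Pink-noise EEG with latent-state band-power shifts near the apex.

    High arousal injects beta (20 Hz) plus gamma (35 Hz) oscillations on
    all channels; low arousal injects theta (6 Hz).  Valence modulates a
    10 Hz alpha component with a left-weighted asymmetry: high valence
    drives the left-half channels at full strength, low valence leaves
    only a weak symmetric alpha.  The oscillation is Hann-tapered inside
    ``apex time +/- EFFECT_HALFSPAN_SECONDS`` and absent elsewhere.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    n = config.n_eeg_samples
    c = config.eeg_channels
    eeg = np.stack([_pink_noise(n, rng) for _ in range(c)])
    strength = config.band_shift_strength
    if strength > 0:
        apex_time = truth.apex_frame / config.fps
        lo, hi = _effect_window(n, config.eeg_rate, apex_time)
        if hi - lo > 1:
            t = np.arange(lo, hi) / config.eeg_rate
            taper = np.hanning(hi - lo)
            phases = rng.uniform(0, 2 * np.pi, size=(c, 4))
            if truth.latent_arousal == HIGH:
                osc = (np.sin(2 * np.pi * 20.0 * t + phases[:, 0:1])
                       + 0.7 * np.sin(2 * np.pi * 35.0 * t + phases[:, 1:2]))
            else:
                osc = np.sin(2 * np.pi * 6.0 * t + phases[:, 2:3])
            left = (np.arange(c) < c // 2).astype(float)[:, None]
            if truth.latent_valence == HIGH:
                alpha_amp = 1.0 * left + 0.25 * (1 - left)
            else:
                alpha_amp = 0.25
            osc = osc + alpha_amp * np.sin(2 * np.pi * 10.0 * t + phases[:, 3:4])
            eeg[:, lo:hi] += strength * taper * osc
    return eeg * 10.0  # arbitrary microvolt-like scale


def _scr_kernel(t: np.ndarray, rise: float = 0.7, decay: float = 2.5) -> np.ndarray:
    """Skin-conductance-response shape: exponential rise then decay."""
    y = (1.0 - np.exp(-t / rise)) * np.exp(-t / decay)
    return y / y.max()


def generate_gsr(truth: GroundTruth, config: GeneratorConfig,
                 rng: Optional[np.random.Generator] = None) -> np.ndarray:
    """Tonic drift plus phasic bumps; bumps cluster at the apex with arousal."""
    if rng is None:
        rng = np.random.default_rng(0)
    n = config.n_physio_samples
    rate = config.physio_rate
    t = np.arange(n) / rate
    phase = rng.uniform(0, 2 * np.pi)
    gsr = 2.0 + 0.3 * np.sin(2 * np.pi * 0.02 * t + phase) + 0.05 * (t / max(t[-1], 1.0))
    apex_time = truth.apex_frame / config.fps

    def add_scr(onset: float, amp: float) -> None:
        i0 = int(round(onset * rate))
        if i0 >= n - 2:
            return
        tk = np.arange(n - i0) / rate
        gsr[i0:] += amp * _scr_kernel(tk)

    # spontaneous background responses, ~2 per minute
    for _ in range(rng.poisson(config.trial_seconds / 30.0)):
        add_scr(rng.uniform(0, config.trial_seconds), rng.uniform(0.05, 0.15))
    strength = config.physio_effect_strength
    if strength > 0:
        mean_bumps = strength * (3.0 if truth.latent_arousal == HIGH else 0.5)
        for _ in range(rng.poisson(mean_bumps)):
            onset = apex_time + rng.uniform(-4.0, 4.0)
            if onset >= 0:
                add_scr(onset, rng.uniform(0.25, 0.6))
    return gsr + rng.normal(0.0, config.noise_sd, size=n)


def generate_ppg(truth: GroundTruth, config: GeneratorConfig,
                 rng: Optional[np.random.Generator] = None) -> np.ndarray:
    """Pulsatile waveform with arousal-modulated rate and valence-modulated
    amplitude envelope near the apex."""
    if rng is None:
        rng = np.random.default_rng(0)
    n = config.n_physio_samples
    rate = config.physio_rate
    t = np.arange(n) / rate
    strength = config.physio_effect_strength
    base_hz = 1.1 + 0.3 * truth.latent_arousal * min(strength, 1.0)
    hrv_phase = rng.uniform(0, 2 * np.pi)
    inst_hz = base_hz * (1.0 + 0.05 * np.sin(2 * np.pi * 0.1 * t + hrv_phase))
    phase = 2 * np.pi * np.cumsum(inst_hz) / rate
    wave = np.sin(phase) + 0.3 * np.sin(2 * phase - 1.0)
    apex_time = truth.apex_frame / config.fps
    boost = 0.8 if truth.latent_valence == HIGH else 0.1
    envelope = 1.0 + strength * boost * np.exp(-((t - apex_time) ** 2) / (2 * 3.0**2))
    return envelope * wave + rng.normal(0.0, config.noise_sd, size=n)


def _draw_rating(latent: int, fidelity: float, rng: np.random.Generator) -> int:
    level = latent if rng.random() < fidelity else 1 - latent
    return int(rng.integers(6, 10)) if level == HIGH else int(rng.integers(1, 6))


# ---------------------------------------------------------------------------
# dataset assembly

def _latents_for(global_index: int) -> tuple[int, int]:
    combo = global_index % 4
    return combo & 1, (combo >> 1) & 1


def generate_truth(config: GeneratorConfig, global_index: int,
                   rng: np.random.Generator) -> GroundTruth:
    arousal, valence = _latents_for(global_index)
    n = config.n_frames
    apex = int(rng.integers(int(round(0.15 * n)), int(round(0.85 * n))))
    dur_lo = max(2, int(math.ceil(0.065 * config.fps)))
    dur_hi = max(dur_lo, int(math.floor(0.5 * config.fps)))
    duration = int(rng.integers(dur_lo, dur_hi + 1))
    return GroundTruth(latent_arousal=arousal, latent_valence=valence,
                       apex_frame=apex, me_duration_frames=duration)


def generate_trial(config: GeneratorConfig, subject_index: int, trial_index: int,
                   rng: np.random.Generator) -> MultimodalTrial:
    """Generate one trial from an already-seeded per-trial generator."""
    g = subject_index * config.trials_per_subject + trial_index
    truth = generate_truth(config, g, rng)
    frames = generate_frames(truth, config, rng)
    eeg = generate_eeg(truth, config, rng)
    gsr = generate_gsr(truth, config, rng)
    ppg = generate_ppg(truth, config, rng)
    return MultimodalTrial(
        subject_id=f"s{subject_index + 1:02d}",
        trial_id=f"s{subject_index + 1:02d}_t{trial_index + 1:02d}",
        frames=frames,
        eeg=eeg,
        gsr=gsr,
        ppg=ppg,
        rating_arousal=_draw_rating(truth.latent_arousal, config.rating_fidelity, rng),
        rating_valence=_draw_rating(truth.latent_valence, config.rating_fidelity, rng),
        fps=config.fps,
        eeg_rate=config.eeg_rate,
        physio_rate=config.physio_rate,
        truth=truth,
    )


def iter_trials(config: GeneratorConfig) -> Iterator[MultimodalTrial]:
    """Stream trials one by one (frames are large; avoid holding them all)."""
    children = np.random.SeedSequence(config.seed).spawn(config.n_trials)
    for s in range(config.n_subjects):
        for k in range(config.trials_per_subject):
            g = s * config.trials_per_subject + k
            yield generate_trial(config, s, k, np.random.default_rng(children[g]))


def generate_dataset(config: GeneratorConfig) -> list[MultimodalTrial]:
    """Materialize the full dataset (``n_subjects * trials_per_subject``)."""
    return list(iter_trials(config))
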