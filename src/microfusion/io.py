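"""Dataset writer/loader: one directory per trial.

Layout (written by :func:`save_dataset`)::

    dataset/
      s01_t01/
        frames.npy            # float32 (n_frames, H, W)  -- or frames/*.png
        eeg.csv               # first column "sample", then one column per channel
        gsr.csv, ppg.csv      # first column "sample", then "gsr"/"ppg"
        meta.json             # subject, ratings, rates, ground truth (if any)

Frames default to a lossless ``.npy`` stack; ``frame_format="png"`` writes
a 16-bit PNG stack instead (interoperable but quantized to 1/65535).
Signal CSVs use ``%.17g`` so float64 values round-trip exactly.
"""
from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence, Union

import numpy as np

from .synth import GroundTruth, MultimodalTrial

_PNG_MAX = 65535


def _write_csv(path: Path, data: np.ndarray, names: Sequence[str]) -> None:
    data = np.atleast_2d(data)
    n = data.shape[1]
    table = np.column_stack([np.arange(n), data.T])
    header = ",".join(["sample", *names])
    np.savetxt(path, table, delimiter=",", header=header, comments="", fmt="%.17g")


def _read_csv(path: Path) -> np.ndarray:
    table = np.loadtxt(path, delimiter=",", skiprows=1, ndmin=2)
    return table[:, 1:].T  # drop the sample-index column


def save_dataset(
    trials: Sequence[MultimodalTrial],
    out_dir: Union[str, Path],
    frame_format: str = "npy",
) -> Path:
    """Write trials to `out_dir`, one subdirectory per trial."""
    if frame_format not in ("npy", "png"):
        raise ValueError("frame_format must be 'npy' or 'png'")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for trial in trials:
        tdir = out_dir / trial.trial_id
        tdir.mkdir(exist_ok=True)
        if frame_format == "npy":
            np.save(tdir / "frames.npy", trial.frames.astype(np.float32))
        else:
            import imageio.v3 as iio

            fdir = tdir / "frames"
            fdir.mkdir(exist_ok=True)
            for i, frame in enumerate(trial.frames):
                quant = np.round(np.clip(frame, 0, 1) * _PNG_MAX).astype(np.uint16)
                iio.imwrite(fdir / f"frame_{i:05d}.png", quant)
        _write_csv(tdir / "eeg.csv", trial.eeg,
                   [f"ch{c + 1:02d}" for c in range(trial.eeg.shape[0])])
        _write_csv(tdir / "gsr.csv", trial.gsr, ["gsr"])
        _write_csv(tdir / "ppg.csv", trial.ppg, ["ppg"])
        meta = {
            "subject_id": trial.subject_id,
            "trial_id": trial.trial_id,
            "rating_arousal": trial.rating_arousal,
            "rating_valence": trial.rating_valence,
            "fps": trial.fps,
            "eeg_rate": trial.eeg_rate,
            "physio_rate": trial.physio_rate,
        }
        if trial.truth is not None:
            meta["truth"] = {
                "latent_arousal": "high" if trial.truth.latent_arousal else "low",
                "latent_valence": "high" if trial.truth.latent_valence else "low",
                "apex_frame": trial.truth.apex_frame,
                "me_duration_frames": trial.truth.me_duration_frames,
            }
        (tdir / "meta.json").write_text(json.dumps(meta, indent=1))
    return out_dir


def _load_frames(tdir: Path) -> np.ndarray:
    npy = tdir / "frames.npy"
    if npy.exists():
        return np.load(npy)
    fdir = tdir / "frames"
    if fdir.is_dir():
        import imageio.v3 as iio

        files = sorted(fdir.glob("frame_*.png"))
        if not files:
            raise FileNotFoundError(f"{fdir} contains no frame_*.png files")
        return np.stack([iio.imread(f).astype(np.float32) / _PNG_MAX for f in files])
    raise FileNotFoundError(f"trial {tdir.name}: neither frames.npy nor frames/ found")


def read_eeg_edf(path: Union[str, Path]) -> tuple[np.ndarray, float]:
    """Read an EDF/BDF EEG recording; returns (channels x samples, rate).

    Requires the optional ``mne`` dependency (``pip install microfusion[edf]``).
    """
    try:
        import mne
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError("reading EDF/BDF files requires the 'mne' package") from exc
    path = Path(path)
    reader = mne.io.read_raw_bdf if path.suffix.lower() == ".bdf" else mne.io.read_raw_edf
    raw = reader(path, preload=True, verbose="error")
    return raw.get_data(), float(raw.info["sfreq"])


def load_dataset(data_dir: Union[str, Path]) -> list[MultimodalTrial]:
    """Load a dataset directory written by :func:`save_dataset`.

    Raises a descriptive error naming the trial and the missing piece;
    mixed sampling rates across trials are rejected.
    """
    data_dir = Path(data_dir)
    tdirs = sorted(d for d in data_dir.iterdir() if d.is_dir())
    if not tdirs:
        raise FileNotFoundError(f"{data_dir} contains no trial directories")
    trials: list[MultimodalTrial] = []
    rates: set[tuple[float, float, float]] = set()
    for tdir in tdirs:
        meta_path = tdir / "meta.json"
        if not meta_path.exists():
            raise FileNotFoundError(f"trial {tdir.name}: missing meta.json")
        meta = json.loads(meta_path.read_text())
        for key in ("rating_arousal", "rating_valence", "fps", "eeg_rate", "physio_rate"):
            if key not in meta:
                raise KeyError(f"trial {tdir.name}: meta.json lacks {key!r}")
        truth = None
        if "truth" in meta:
            t = meta["truth"]
            truth = GroundTruth(
                latent_arousal=1 if t["latent_arousal"] == "high" else 0,
                latent_valence=1 if t["latent_valence"] == "high" else 0,
                apex_frame=int(t["apex_frame"]),
                me_duration_frames=int(t["me_duration_frames"]),
            )
        for name in ("eeg.csv", "gsr.csv", "ppg.csv"):
            if not (tdir / name).exists():
                raise FileNotFoundError(f"trial {tdir.name}: missing {name}")
        trial = MultimodalTrial(
            subject_id=meta.get("subject_id", tdir.name.split("_")[0]),
            trial_id=meta.get("trial_id", tdir.name),
            frames=_load_frames(tdir),
            eeg=_read_csv(tdir / "eeg.csv"),
            gsr=_read_csv(tdir / "gsr.csv")[0],
            ppg=_read_csv(tdir / "ppg.csv")[0],
            rating_arousal=int(meta["rating_arousal"]),
            rating_valence=int(meta["rating_valence"]),
            fps=float(meta["fps"]),
            eeg_rate=float(meta["eeg_rate"]),
            physio_rate=float(meta["physio_rate"]),
            truth=truth,
        )
        rates.add((trial.fps, trial.eeg_rate, trial.physio_rate))
        if len(rates) > 1:
            raise ValueError(
                f"mixed sampling rates across trials (at {tdir.name}): {sorted(rates)}"
            )
        trials.append(trial)
    return trials
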