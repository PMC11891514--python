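"""Readers and writers: audio, EEG recordings, metadata and result objects.

EEG is accepted either as EDF/BDF (read through MNE) or as the package's
own ``.npz`` array container (matrix + channel names + rate), which the
synthetic generator writes.  Results round-trip through CSV (tabular) or
JSON (structured) without loss beyond floating formatting.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .channels import match_channels

AUDIO_SUFFIXES = {".wav"}
EEG_SUFFIXES = {".edf", ".bdf", ".npz"}


@dataclass
class EEGRecording:
    """Raw multichannel recording, channels x samples, in file order."""

    data: np.ndarray
    channel_names: list[str]
    rate: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("EEG data must be channels x samples")
        if self.data.shape[0] != len(self.channel_names):
            raise ValueError("row count must equal the number of channel names")
        lowered = [c.lower() for c in self.channel_names]
        if len(set(lowered)) != len(lowered):
            dupes = sorted({c for c in lowered if lowered.count(c) > 1})
            raise ValueError(f"duplicated channel name(s): {dupes}")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def pick(self, channel_subset: list[str]) -> "EEGRecording":
        idx = match_channels(self.channel_names, list(channel_subset))
        return EEGRecording(self.data[idx], [self.channel_names[i] for i in idx], self.rate)

    def align(self, offset_s: float) -> "EEGRecording":
        """Drop the pre-stimulus lead-in so that stimulus onset becomes
        sample 0 (the package's time-alignment convention)."""
        if offset_s < 0:
            raise ValueError("alignment offset must be >= 0")
        start = int(round(offset_s * self.rate))
        if start >= self.n_samples:
            raise ValueError("alignment offset beyond the recording")
        return EEGRecording(self.data[:, start:], list(self.channel_names), self.rate)


@dataclass
class SubjectRecord:
    """Per-subject metadata tying a recording to the cohort table."""

    subject_id: str
    group: str
    age: float
    eeg: EEGRecording | str | None = None
    alignment_offset: float = 0.0
    seed: int | None = None
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.group not in ("control", "aphasia"):
            raise ValueError(f"group must be 'control' or 'aphasia', got {self.group!r}")
        if not self.age > 0:
            raise ValueError("age must be positive")
        if self.alignment_offset < 0:
            raise ValueError("alignment_offset must be >= 0")


# ---------------------------------------------------------------------------
# audio
# ---------------------------------------------------------------------------

def read_audio(path: str | Path, mixdown: bool = False) -> tuple[np.ndarray, float]:
    """Read a WAV file into float samples in [-1, 1].

    Multichannel audio is rejected unless ``mixdown=True``, in which case
    channels are averaged.
    """
    from scipy.io import wavfile

    path = Path(path)
    if path.suffix.lower() not in AUDIO_SUFFIXES:
        raise ValueError(f"unknown audio format: {path.suffix!r}")
    rate, data = wavfile.read(path)
    data = np.asarray(data)
    if np.issubdtype(data.dtype, np.integer):
        scale = float(max(abs(np.iinfo(data.dtype).min), np.iinfo(data.dtype).max))
        data = data.astype(float) / scale
    else:
        data = data.astype(float)
    if data.ndim == 2:
        if data.shape[1] == 1:
            data = data[:, 0]
        elif mixdown:
            data = data.mean(axis=1)
        else:
            raise ValueError(
                f"audio has {data.shape[1]} channels; pass mixdown=True to average"
            )
    return data, float(rate)


def write_audio(path: str | Path, samples: np.ndarray, rate: float) -> None:
    from scipy.io import wavfile

    wavfile.write(Path(path), int(rate), np.asarray(samples, dtype=np.float32))


# ---------------------------------------------------------------------------
# EEG
# ---------------------------------------------------------------------------

def read_eeg(path: str | Path, channel_subset: list[str] | None = None) -> EEGRecording:
    """Read an EDF/BDF file or the package's ``.npz`` container."""
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix == ".npz":
        with np.load(path, allow_pickle=False) as npz:
            rec = EEGRecording(
                data=np.asarray(npz["data"], dtype=float),
                channel_names=[str(c) for c in npz["channel_names"]],
                rate=float(npz["rate"]),
            )
    elif suffix in (".edf", ".bdf"):
        import mne

        reader = mne.io.read_raw_bdf if suffix == ".bdf" else mne.io.read_raw_edf
        raw = reader(path, preload=True, verbose="error")
        rec = EEGRecording(
            data=raw.get_data(),
            channel_names=list(raw.ch_names),
            rate=float(raw.info["sfreq"]),
        )
    else:
        raise ValueError(f"unknown EEG format: {suffix!r}")
    if channel_subset is not None:
        rec = rec.pick(channel_subset)
    return rec


def write_eeg(path: str | Path, rec: EEGRecording) -> None:
    """Write the array container (compressed .npz)."""
    path = Path(path)
    if path.suffix.lower() != ".npz":
        raise ValueError("the array container uses the .npz suffix")
    np.savez_compressed(
        path,
        data=rec.data,
        channel_names=np.array(rec.channel_names, dtype="U16"),
        rate=np.array(rec.rate),
    )


# ---------------------------------------------------------------------------
# cohort metadata
# ---------------------------------------------------------------------------

def write_cohort_table(path: str | Path, subjects: list[SubjectRecord]) -> None:
    rows = [
        {
            "subject_id": s.subject_id,
            "group": s.group,
            "age": s.age,
            "seed": s.seed if s.seed is not None else "",
            "eeg": s.eeg if isinstance(s.eeg, str) else "",
            "alignment_offset": s.alignment_offset,
        }
        for s in subjects
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_cohort_table(path: str | Path) -> list[SubjectRecord]:
    df = pd.read_csv(path, keep_default_na=False)
    out = []
    for _, row in df.iterrows():
        out.append(
            SubjectRecord(
                subject_id=str(row["subject_id"]),
                group=str(row["group"]),
                age=float(row["age"]),
                eeg=str(row["eeg"]) or None,
                alignment_offset=float(row.get("alignment_offset", 0.0) or 0.0),
                seed=int(row["seed"]) if str(row.get("seed", "")) != "" else None,
            )
        )
    return out


# ---------------------------------------------------------------------------
# results
# ---------------------------------------------------------------------------

def write_results(obj, path: str | Path) -> None:
    """Serialize a result object; CSV for tabular, JSON for structured.

    Dispatches on a ``to_frame`` (tabular) or ``to_json_dict`` (structured)
    method so each result type owns its own layout.
    """
    path = Path(path)
    if hasattr(obj, "to_frame") and path.suffix.lower() == ".csv":
        obj.to_frame().to_csv(path, index=False)
    elif hasattr(obj, "to_json_dict"):
        with open(path, "w") as fh:
            json.dump(obj.to_json_dict(), fh, indent=1, default=_json_default)
    else:
        raise TypeError(
            f"cannot write object of type {type(obj).__name__} to {path.suffix!r}"
        )


def _json_default(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, np.ndarray):
        return x.tolist()
    raise TypeError(f"not JSON serializable: {type(x)}")


def read_json(path: str | Path) -> dict:
    with open(path) as fh:
        return json.load(fh)
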