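"""In-memory container and plain-text I/O for one participant x condition recording.

A :class:`Recording` holds the [oxy-Hb] concentration-change matrix (time x
channel), the sampling rate, trial-onset sample indices, the participant's age
and the task condition ("own" or "other" race).  Recordings are interchanged
as a long-format CSV (time, channel, value) plus a JSON sidecar carrying the
metadata, so a cohort is a directory of small text files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import PreconditionError

CONDITIONS = ("own", "other")


@dataclass
class Recording:
    participant_id: str
    age: float
    condition: str
    fs: float
    data: np.ndarray  # (n_samples, n_channels)
    trial_onsets: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))
    preprocessed: bool = False
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise PreconditionError("data must be a (time, channel) matrix")
        if self.fs <= 0:
            raise PreconditionError("sampling rate must be positive")
        self.trial_onsets = np.asarray(self.trial_onsets, dtype=int)
        if np.isnan(self.data).any() and self.preprocessed:
            raise PreconditionError("preprocessed data must not contain NaN")
        if self.condition not in CONDITIONS:
            raise PreconditionError(f"condition must be one of {CONDITIONS}")

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def with_data(self, data: np.ndarray, step: str | None = None) -> "Recording":
        """Copy of the recording with replaced signal and appended provenance."""
        new = replace(self, data=np.asarray(data, dtype=float),
                      provenance=list(self.provenance))
        if step is not None:
            new.provenance.append(step)
        return new

    def copy(self) -> "Recording":
        return replace(self, data=self.data.copy(), provenance=list(self.provenance))


def recording_stem(rec: Recording) -> str:
    return f"{rec.participant_id}_{rec.condition}"


def write_recording(rec: Recording, directory: str | Path, stem: str | None = None) -> Path:
    """Write ``<stem>.csv`` (long format: time, channel, value) and ``<stem>.json``.

    Returns the path of the CSV file.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    stem = stem or recording_stem(rec)
    t_idx, ch_idx = np.meshgrid(
        np.arange(rec.n_samples), np.arange(1, rec.n_channels + 1), indexing="ij"
    )
    df = pd.DataFrame(
        {
            "time": t_idx.ravel() / rec.fs,
            "channel": ch_idx.ravel(),
            "value": rec.data.ravel(),
        }
    )
    csv_path = directory / f"{stem}.csv"
    df.to_csv(csv_path, index=False, float_format="%.10g")
    sidecar = {
        "participant_id": rec.participant_id,
        "age": rec.age,
        "condition": rec.condition,
        "fs": rec.fs,
        "n_samples": rec.n_samples,
        "n_channels": rec.n_channels,
        "trial_onsets": rec.trial_onsets.tolist(),
        "preprocessed": rec.preprocessed,
        "provenance": rec.provenance,
    }
    (directory / f"{stem}.json").write_text(json.dumps(sidecar, indent=1))
    return csv_path


def read_recording(csv_path: str | Path) -> Recording:
    """Inverse of :func:`write_recording`."""
    csv_path = Path(csv_path)
    sidecar = json.loads(csv_path.with_suffix(".json").read_text())
    df = pd.read_csv(csv_path)
    n_t, n_c = sidecar["n_samples"], sidecar["n_channels"]
    data = (
        df.sort_values(["time", "channel"])["value"].to_numpy().reshape(n_t, n_c)
    )
    return Recording(
        participant_id=sidecar["participant_id"],
        age=float(sidecar["age"]),
        condition=sidecar["condition"],
        fs=float(sidecar["fs"]),
        data=data,
        trial_onsets=np.asarray(sidecar["trial_onsets"], dtype=int),
        preprocessed=bool(sidecar["preprocessed"]),
        provenance=list(sidecar["provenance"]),
    )
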