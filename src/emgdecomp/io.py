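"""Signal and result file I/O.

Signals travel as delimited text with a ``# fs=<Hz>`` header line and one
sample (µV) per line, or as PCM WAV. Ground truth and decomposition results
are JSON: self-describing arrays of template waveforms and firing times.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.io import wavfile


@dataclass
class EMGRecord:
    """A uniformly sampled single-channel voltage trace.

    Parameters
    ----------
    samples : ndarray
        Voltage samples in µV.
    fs : float
        Sampling rate in Hz.
    """

    samples: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1:
            raise ValueError("EMGRecord requires a single-channel 1-D signal")
        if not self.fs > 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("EMGRecord samples must be finite")

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.fs

    def __len__(self) -> int:
        return len(self.samples)


def read_signal(path: str | Path) -> EMGRecord:
    """Read a signal file (``# fs=`` headed text, or PCM WAV)."""
    path = Path(path)
    if path.suffix.lower() == ".wav":
        fs, data = wavfile.read(path)
        if data.ndim > 1:
            data = data[:, 0]
        return EMGRecord(np.asarray(data, dtype=np.float64), float(fs))
    fs = None
    with open(path) as fh:
        first = fh.readline().strip()
        if first.startswith("#") and "fs=" in first:
            fs = float(first.split("fs=")[1].split()[0])
            samples = np.loadtxt(fh, dtype=np.float64, ndmin=1)
        else:
            raise ValueError(
                f"{path}: missing '# fs=<Hz>' header line in signal file"
            )
    return EMGRecord(samples, fs)


def write_signal(record: EMGRecord, path: str | Path) -> None:
    """Write a signal as text (or PCM WAV when the suffix is .wav)."""
    path = Path(path)
    if path.suffix.lower() == ".wav":
        wavfile.write(path, int(round(record.fs)), record.samples)
        return
    with open(path, "w") as fh:
        fh.write(f"# fs={record.fs:g}\n")
        np.savetxt(fh, record.samples, fmt="%.6f")


def dump_json(obj, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, sort_keys=True)
        fh.write("\n")


def load_json(path: str | Path):
    with open(path) as fh:
        return json.load(fh)
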