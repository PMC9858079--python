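"""Single-lead ECG record container and plain-text I/O.

An :class:`EcgRecord` holds a single-lead voltage trace in millivolts
together with its sampling rate and an optional rhythm label
(``"normal"``, ``"bradycardia"`` or ``"tachycardia"``).  Records are
written to / read from CSV with a ``# fs=<Hz>`` header comment so a file
is self-describing.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

RHYTHM_CLASSES = ("normal", "bradycardia", "tachycardia")


@dataclass
class EcgRecord:
    """A raw or preprocessed single-lead ECG signal.

    Parameters
    ----------
    samples
        Voltage samples in mV.
    fs
        Sampling rate in Hz, strictly positive.
    record_id
        Free-form identifier carried through delineation and imaging.
    label
        Optional rhythm class, one of :data:`RHYTHM_CLASSES`.
    """

    samples: np.ndarray
    fs: float
    record_id: str = "record"
    label: str | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if self.samples.ndim != 1 or self.samples.size < 2:
            raise ValueError("samples must be a 1-D sequence of length >= 2")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must be finite")
        if self.label is not None and self.label not in RHYTHM_CLASSES:
            raise ValueError(f"unknown rhythm label {self.label!r}")

    def __len__(self) -> int:
        return self.samples.size

    @property
    def duration_s(self) -> float:
        """Record duration in seconds."""
        return self.samples.size / self.fs

    @property
    def time(self) -> np.ndarray:
        """Sample times in seconds, starting at 0."""
        return np.arange(self.samples.size) / self.fs

    def with_samples(self, samples: np.ndarray) -> "EcgRecord":
        """Copy of this record with new samples (fs and metadata kept)."""
        return replace(self, samples=np.asarray(samples, dtype=float))

    # ------------------------------------------------------------------
    # plain-text I/O
    # ------------------------------------------------------------------
    def to_csv(self, path: str | Path) -> Path:
        """Write ``sample_index, mV`` columns with an ``# fs=`` header."""
        path = Path(path)
        header = f"# fs={self.fs}\n# record_id={self.record_id}\n"
        if self.label is not None:
            header += f"# label={self.label}\n"
        frame = pd.DataFrame(
            {"sample_index": np.arange(self.samples.size), "mV": self.samples}
        )
        with open(path, "w") as fh:
            fh.write(header)
            frame.to_csv(fh, index=False)
        return path

    @classmethod
    def from_csv(cls, path: str | Path, fs: float | None = None) -> "EcgRecord":
        """Read a record written by :meth:`to_csv` (or any ``mV`` CSV).

        ``fs`` overrides the header value; one of the two must be present.
        """
        path = Path(path)
        meta: dict[str, str] = {}
        with open(path) as fh:
            for line in fh:
                m = re.match(r"#\s*(\w+)\s*=\s*(.+)", line)
                if m:
                    meta[m.group(1)] = m.group(2).strip()
                else:
                    break
        frame = pd.read_csv(path, comment="#")
        if fs is None:
            if "fs" not in meta:
                raise ValueError(f"{path}: no fs header and none supplied")
            fs = float(meta["fs"])
        col = "mV" if "mV" in frame.columns else frame.columns[-1]
        return cls(
            samples=frame[col].to_numpy(dtype=float),
            fs=fs,
            record_id=meta.get("record_id", path.stem),
            label=meta.get("label"),
        )
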