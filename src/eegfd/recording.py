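"""In-memory container for one multichannel EEG session, plus CSV/EDF I/O.

The canonical on-disk format is a plain matrix CSV: one row per sample,
one column per channel, header row of electrode names.  EDF files are read
through MNE when available.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .montage import STANDARD_1020_NAMES


@dataclass
class Recording:
    """One EEG recording: a channel x sample matrix with its metadata.

    Parameters
    ----------
    data
        Array of shape (n_channels, n_samples), microvolts.
    rate_hz
        Sampling rate in Hz.
    montage
        Ordered electrode names, one per data row.
    eye_state
        ``"closed"`` or ``"open"``.
    reference
        ``"linked-ears"`` (acquisition reference) or ``"common-average"``.
    """

    data: np.ndarray
    rate_hz: float = 250.0
    montage: tuple[str, ...] = STANDARD_1020_NAMES
    eye_state: str = "closed"
    reference: str = "linked-ears"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be a 2-D channel x sample array")
        if self.data.shape[0] != len(self.montage):
            raise ValueError(
                f"data has {self.data.shape[0]} rows but montage lists "
                f"{len(self.montage)} electrodes"
            )
        if self.rate_hz <= 0:
            raise ValueError("rate_hz must be positive")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.rate_hz

    def copy_with(self, **changes) -> "Recording":
        """Return a copy with ``data`` copied and the given fields replaced."""
        new = replace(self, **changes)
        if "data" not in changes:
            new.data = self.data.copy()
        return new


@dataclass
class SubjectRecord:
    """All recordings of one subject plus the ground truth that generated them.

    ``truth`` carries the per-channel Hurst exponents a synthetic subject was
    drawn with (``None`` for real data), so parameter-recovery tests can
    compare estimated fractal dimension against 2 - H.
    """

    subject_id: str
    group: str
    recordings: list[Recording] = field(default_factory=list)
    truth: np.ndarray | None = None


def write_csv(rec: Recording, path: str | Path) -> None:
    """Write a recording as matrix CSV (rows = samples, columns = channels)."""
    df = pd.DataFrame(rec.data.T, columns=list(rec.montage))
    df.to_csv(path, index=False, float_format="%.6f")


def read_csv(path: str | Path, rate_hz: float = 250.0, eye_state: str = "closed") -> Recording:
    """Read a matrix CSV written by :func:`write_csv` (or compatible)."""
    df = pd.read_csv(path)
    return Recording(
        data=df.to_numpy().T,
        rate_hz=rate_hz,
        montage=tuple(df.columns),
        eye_state=eye_state,
    )


def read_edf(path: str | Path) -> Recording:
    """Read an EDF file through MNE, keeping only the montage channels found."""
    import mne  # heavy import; only needed for EDF input

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    names = tuple(raw.ch_names)
    return Recording(
        data=raw.get_data() * 1e6,  # MNE loads volts; store microvolts
        rate_hz=float(raw.info["sfreq"]),
        montage=names,
    )


def load_recording(path: str | Path, rate_hz: float = 250.0) -> Recording:
    """Dispatch on file suffix: ``.edf`` via MNE, anything else as matrix CSV."""
    path = Path(path)
    if path.suffix.lower() == ".edf":
        return read_edf(path)
    return read_csv(path, rate_hz=rate_hz)
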