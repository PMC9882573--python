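"""ECG record container and plain-text I/O.

An :class:`EcgRecord` is the universal signal container of the package: a
``(leads, N)`` sample matrix in millivolts together with the sampling
frequency.  Records are interchanged as CSV with a fixed dialect (comma
separator, dot decimal, a header row carrying the sampling frequency and
lead names) so that write → read round-trips are bit-exact for tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["EcgRecord", "read_record", "write_record", "read_rpeaks", "write_rpeaks"]


@dataclass
class EcgRecord:
    """Multi-lead ECG sample matrix with sampling frequency.

    Parameters
    ----------
    samples : ndarray, shape (leads, N)
        Signal amplitudes in millivolts. A 1-D array is promoted to one lead.
    fs : float
        Sampling frequency in Hz, strictly positive.
    lead_names : list of str, optional
        One label per lead; defaults to ``lead1, lead2, ...``.
    """

    samples: np.ndarray
    fs: float
    lead_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=float))
        if self.fs <= 0:
            raise ValueError(f"sampling frequency must be positive, got {self.fs}")
        if self.samples.shape[1] < 1:
            raise ValueError("record must contain at least one sample")
        bad = ~np.isfinite(self.samples)
        if bad.any():
            lead, idx = np.argwhere(bad)[0]
            raise ValueError(f"non-finite sample at lead {lead}, index {idx}")
        if not self.lead_names:
            self.lead_names = [f"lead{i + 1}" for i in range(self.n_leads)]
        if len(self.lead_names) != self.n_leads:
            raise ValueError("lead_names length does not match number of leads")

    @property
    def n_leads(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        """Record length in seconds."""
        return self.n_samples / self.fs

    def lead(self, which: int | str = 0) -> np.ndarray:
        """Return one lead as a 1-D array (by index or by name)."""
        if isinstance(which, str):
            which = self.lead_names.index(which)
        return self.samples[which]

    def copy_with(self, samples: np.ndarray) -> "EcgRecord":
        """New record sharing fs/lead names, with replaced samples."""
        return EcgRecord(np.asarray(samples, dtype=float), self.fs, list(self.lead_names))


def write_record(record: EcgRecord, path: str | Path) -> None:
    """Write a record as CSV: ``time_s`` column plus one column per lead.

    The sampling frequency is embedded in the time-column header as
    ``time_s[fs=<value>]`` so the file is self-describing.
    """
    t = np.arange(record.n_samples) / record.fs
    cols = {f"time_s[fs={record.fs!r}]": t}
    for name, x in zip(record.lead_names, record.samples):
        cols[name] = x
    pd.DataFrame(cols).to_csv(path, index=False, float_format="%.17g")


def read_record(path: str | Path) -> EcgRecord:
    """Read a CSV record written by :func:`write_record`.

    Raises
    ------
    ValueError
        If the sampling-frequency metadata is missing or a sample is NaN.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    time_cols = [c for c in df.columns if c.startswith("time_s[fs=")]
    if not time_cols:
        raise ValueError(f"{path}: missing sampling-frequency header 'time_s[fs=...]'")
    fs = float(time_cols[0][len("time_s[fs=") : -1])
    lead_names = [c for c in df.columns if c not in time_cols]
    samples = df[lead_names].to_numpy(dtype=float).T
    return EcgRecord(samples, fs, lead_names)


def write_rpeaks(r_peaks: np.ndarray, path: str | Path) -> None:
    """Write R-peak sample indices as a single-column CSV."""
    pd.DataFrame({"r_peak": np.asarray(r_peaks, dtype=int)}).to_csv(path, index=False)


def read_rpeaks(path: str | Path) -> np.ndarray:
    """Read R-peak sample indices from a single-column CSV."""
    return pd.read_csv(path)["r_peak"].to_numpy(dtype=int)
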