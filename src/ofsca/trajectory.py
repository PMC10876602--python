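"""Planar trajectory container.

A :class:`Trajectory2D` is the unit of analysis everywhere in this package:
two uniformly sampled channels (by convention ``c1`` = mediolateral / x,
``c2`` = anteroposterior / y) plus the sampling rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class Trajectory2D:
    """A uniformly sampled planar trajectory.

    Parameters
    ----------
    c1, c2 : array-like
        First (ML/x) and second (AP/y) channel, equal lengths.
    fs : float
        Sampling rate in Hz; time stamps are ``arange(n) / fs``.
    """

    c1: np.ndarray
    c2: np.ndarray
    fs: float = 100.0
    t: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.c1 = np.asarray(self.c1, dtype=float)
        self.c2 = np.asarray(self.c2, dtype=float)
        if self.c1.ndim != 1 or self.c2.ndim != 1:
            raise ValueError("channels must be 1-D")
        if self.c1.size != self.c2.size:
            raise ValueError(
                f"channel length mismatch: {self.c1.size} != {self.c2.size}"
            )
        if not (self.fs > 0):
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if not (np.all(np.isfinite(self.c1)) and np.all(np.isfinite(self.c2))):
            raise ValueError("channels contain non-finite values")
        if self.t is None:
            self.t = np.arange(self.c1.size) / self.fs
        else:
            self.t = np.asarray(self.t, dtype=float)
            if self.t.size != self.c1.size:
                raise ValueError("time vector length mismatch")

    def __len__(self) -> int:
        return self.c1.size

    @property
    def n(self) -> int:
        return self.c1.size

    @property
    def duration(self) -> float:
        """Trial duration in seconds."""
        return self.n / self.fs

    def as_matrix(self) -> np.ndarray:
        """Return the trajectory as an ``(n, 2)`` array ``[c1, c2]``."""
        return np.column_stack([self.c1, self.c2])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({"time": self.t, "c1": self.c1, "c2": self.c2})

    def to_csv(self, path) -> None:
        """Write ``time,c1,c2`` CSV (the package's interchange format)."""
        self.to_dataframe().to_csv(path, index=False, float_format="%.12g")

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, fs: float | None = None) -> "Trajectory2D":
        if fs is None:
            dt = np.diff(df["time"].to_numpy())
            if dt.size == 0 or np.ptp(dt) > 1e-6 * np.median(dt):
                raise ValueError("cannot infer fs from non-uniform time stamps")
            fs = 1.0 / float(np.median(dt))
        return cls(df["c1"].to_numpy(), df["c2"].to_numpy(), fs=fs)
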