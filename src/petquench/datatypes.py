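"""Shared data containers: photon streams, sampled state sequences, correlation curves.

Unit conventions
----------------
Correlation lags are seconds internally.  Sampled sequences carry their frame
spacing in nanoseconds (the natural unit of MD frame output); photon
timestamps are integer ticks at a stated picosecond resolution, mirroring
TCSPC hardware output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "StateSequence",
    "PhotonStream",
    "CorrelationCurve",
    "BRIGHT",
    "DARK",
    "CLOSE",
    "INTERMEDIATE",
    "OPEN",
]

# binary quenching states
DARK = 0
BRIGHT = 1

# ternary end-to-end regimes
CLOSE = 0
INTERMEDIATE = 1
OPEN = 2


@dataclass
class StateSequence:
    """Uniformly sampled discrete-state series.

    ``values`` holds small integer codes: for binary quenching series
    ``BRIGHT``/``DARK`` (1 = fully fluorescent), for ternary end-to-end
    series ``CLOSE``/``INTERMEDIATE``/``OPEN``.
    """

    values: np.ndarray
    dt_ns: float
    kind: str = "binary"  # "binary" | "ternary"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 1:
            raise ValueError("state sequence must be one-dimensional")
        if self.dt_ns <= 0:
            raise ValueError("frame spacing dt_ns must be positive")

    @property
    def n(self) -> int:
        return self.values.size

    @property
    def duration_ns(self) -> float:
        return self.n * self.dt_ns

    @property
    def duration_us(self) -> float:
        return self.duration_ns * 1e-3

    def window(self, start_ns: float = 0.0, stop_ns: float | None = None) -> "StateSequence":
        """Sub-series on the half-open time window [start_ns, stop_ns)."""
        i0 = int(np.ceil(start_ns / self.dt_ns))
        i1 = self.n if stop_ns is None else int(np.floor(stop_ns / self.dt_ns))
        if i1 - i0 < 2:
            raise ValueError("analysis window contains fewer than two frames")
        return StateSequence(self.values[i0:i1], self.dt_ns, self.kind)

    def to_text(self, path) -> None:
        t = np.arange(self.n) * self.dt_ns
        header = f"kind={self.kind} dt_ns={self.dt_ns!r}\ntime_ns\tstate"
        np.savetxt(path, np.column_stack([t, self.values]), fmt=["%.6f", "%d"],
                   delimiter="\t", header=header)

    @classmethod
    def from_text(cls, path) -> "StateSequence":
        with open(path) as fh:
            first = fh.readline().lstrip("# ").strip()
        meta = dict(kv.split("=") for kv in first.split())
        arr = np.loadtxt(path)
        return cls(arr[:, 1].astype(np.int8), float(meta["dt_ns"]), meta.get("kind", "binary"))


@dataclass
class PhotonStream:
    """Ordered photon arrival timestamps, one integer-tick array per channel."""

    channels: tuple
    tick_ps: float
    duration_s: float

    def __post_init__(self) -> None:
        self.channels = tuple(np.asarray(c, dtype=np.int64) for c in self.channels)
        if self.tick_ps <= 0 or self.duration_s <= 0:
            raise ValueError("tick_ps and duration_s must be positive")
        for c in self.channels:
            if c.size > 1 and np.any(np.diff(c) <= 0):
                raise ValueError("timestamps must be strictly increasing within a channel")

    @property
    def n_channels(self) -> int:
        return len(self.channels)

    @property
    def n_photons(self) -> int:
        return int(sum(c.size for c in self.channels))

    @property
    def duration_ticks(self) -> int:
        return int(round(self.duration_s / (self.tick_ps * 1e-12)))

    def merged(self) -> np.ndarray:
        """All timestamps pooled across channels, sorted (ticks)."""
        return np.sort(np.concatenate(self.channels)) if self.channels else np.empty(0, np.int64)

    def segment(self, i: int, n_segments: int) -> "PhotonStream":
        """The i-th of n equal-duration sub-streams, timestamps re-zeroed."""
        seg_ticks = self.duration_ticks // n_segments
        lo, hi = i * seg_ticks, (i + 1) * seg_ticks
        chans = []
        for c in self.channels:
            sel = c[(c >= lo) & (c < hi)] - lo
            chans.append(sel)
        return PhotonStream(tuple(chans), self.tick_ps, seg_ticks * self.tick_ps * 1e-12)

    def to_text(self, path) -> None:
        rows = []
        for ch, c in enumerate(self.channels):
            rows.append(np.column_stack([np.full(c.size, ch, np.int64), c]))
        table = np.concatenate(rows) if rows else np.empty((0, 2), np.int64)
        header = (f"tick_ps={self.tick_ps!r} duration_s={self.duration_s!r} "
                  f"n_channels={self.n_channels}\nchannel\ttick")
        np.savetxt(path, table, fmt="%d", delimiter="\t", header=header)

    @classmethod
    def from_text(cls, path) -> "PhotonStream":
        with open(path) as fh:
            meta = dict(kv.split("=") for kv in fh.readline().lstrip("# ").split())
        table = np.loadtxt(path, dtype=np.int64, ndmin=2)
        n_ch = int(meta["n_channels"])
        chans = tuple(np.sort(table[table[:, 0] == ch, 1]) for ch in range(n_ch))
        return cls(chans, float(meta["tick_ps"]), float(meta["duration_s"]))


@dataclass
class CorrelationCurve:
    """Normalized intensity correlation on a strictly increasing lag grid.

    ``convention`` is ``"raw"`` (G -> 1 at large lag) or ``"excess"``
    (G -> 0); conversion between the two is subtraction/addition of exactly 1.
    ``npairs`` optionally records the number of contributing time-average
    windows per lag, used to restrict fits to well-converged lags.
    """

    lags_s: np.ndarray
    values: np.ndarray
    sigma: np.ndarray | None = None
    convention: str = "raw"
    npairs: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.lags_s = np.asarray(self.lags_s, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.sigma is not None:
            self.sigma = np.asarray(self.sigma, dtype=float)
            if np.any(self.sigma < 0):
                raise ValueError("sigma must be non-negative")
        if self.lags_s.size != self.values.size:
            raise ValueError("lag and value arrays differ in length")
        if np.any(self.lags_s <= 0) or np.any(np.diff(self.lags_s) <= 0):
            raise ValueError("lags must be positive and strictly increasing")
        if self.convention not in ("raw", "excess"):
            raise ValueError(f"unknown convention {self.convention!r}")

    def __len__(self) -> int:
        return self.lags_s.size

    def to_excess(self) -> "CorrelationCurve":
        if self.convention == "excess":
            return self
        return CorrelationCurve(self.lags_s, self.values - 1.0, self.sigma, "excess", self.npairs)

    def to_raw(self) -> "CorrelationCurve":
        if self.convention == "raw":
            return self
        return CorrelationCurve(self.lags_s, self.values + 1.0, self.sigma, "raw", self.npairs)

    def select(self, mask: np.ndarray) -> "CorrelationCurve":
        return CorrelationCurve(
            self.lags_s[mask], self.values[mask],
            None if self.sigma is None else self.sigma[mask],
            self.convention,
            None if self.npairs is None else self.npairs[mask])

    def to_text(self, path, comment: str = "") -> None:
        sig = self.sigma if self.sigma is not None else np.full(len(self), np.nan)
        header = f"convention={self.convention}"
        if comment:
            header += f" {comment}"
        header += "\nlag_s\tG\tsigma"
        np.savetxt(path, np.column_stack([self.lags_s, self.values, sig]),
                   delimiter="\t", header=header)

    @classmethod
    def from_text(cls, path) -> "CorrelationCurve":
        with open(path) as fh:
            meta = dict(kv.split("=") for kv in fh.readline().lstrip("# ").split()
                        if "=" in kv)
        arr = np.loadtxt(path, ndmin=2)
        sigma = arr[:, 2] if arr.shape[1] > 2 and not np.all(np.isnan(arr[:, 2])) else None
        return cls(arr[:, 0], arr[:, 1], sigma, meta.get("convention", "raw"))
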