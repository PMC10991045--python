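"""Time-series container and CSV I/O shared by all analysis modules.

A :class:`Trace` is a strictly increasing time grid (seconds) paired with one
signal channel.  Three channels are distinguished because their admissible
ranges differ: raw bacteriochlorophyll fluorescence ``raw_fluorescence``
(arbitrary units), normalized variable fluorescence ``phi`` and fractional
oxidized dimer ``p_plus`` (both dimensionless, nominally in [0, 1] with small
noise excursions tolerated).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

CHANNELS = ("raw_fluorescence", "phi", "p_plus")

#: Channels whose values are fractions of a normalized quantity.
BOUNDED_CHANNELS = ("phi", "p_plus")

_MIN_SAMPLES = 8
_BOUND_SLACK = 0.05


class TraceError(ValueError):
    """Raised when a trace violates its structural invariants."""


@dataclass(frozen=True)
class Trace:
    """A single-channel time series.

    Parameters
    ----------
    times:
        Sample times in seconds, strictly increasing, at least 8 points.
    values:
        Signal samples, same length as ``times``.
    channel:
        One of ``raw_fluorescence``, ``phi``, ``p_plus``.
    """

    times: np.ndarray
    values: np.ndarray
    channel: str = "raw_fluorescence"
    meta: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "values", values)
        if self.channel not in CHANNELS:
            raise TraceError(
                f"unknown channel {self.channel!r}; expected one of {CHANNELS}"
            )
        if times.ndim != 1 or values.ndim != 1 or times.size != values.size:
            raise TraceError("times and values must be 1-D arrays of equal length")
        if times.size < _MIN_SAMPLES:
            raise TraceError(
                f"trace needs at least {_MIN_SAMPLES} samples, got {times.size}"
            )
        if not np.all(np.diff(times) > 0):
            raise TraceError("times must be strictly increasing")
        if not np.all(np.isfinite(values)):
            raise TraceError("values contain non-finite entries")
        if self.channel in BOUNDED_CHANNELS:
            lo, hi = values.min(), values.max()
            if lo < -_BOUND_SLACK or hi > 1 + _BOUND_SLACK:
                raise TraceError(
                    f"{self.channel} values outside [-{_BOUND_SLACK}, "
                    f"{1 + _BOUND_SLACK}]: range [{lo:.4g}, {hi:.4g}]"
                )

    def __len__(self) -> int:
        return int(self.times.size)

    def with_values(self, values: np.ndarray, channel: str | None = None) -> "Trace":
        return Trace(self.times, values, channel or self.channel, dict(self.meta))

    def interp_to(self, times: np.ndarray) -> "Trace":
        """Linear interpolation onto a new grid inside the original span."""
        times = np.asarray(times, dtype=float)
        if times.min() < self.times[0] - 1e-15 or times.max() > self.times[-1] + 1e-15:
            raise TraceError("interpolation grid extends beyond the trace span")
        return Trace(times, np.interp(times, self.times, self.values), self.channel)


def read_trace(path, channel: str) -> Trace:
    """Read a two-column CSV (``time_s,value``, one header line)."""
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise TraceError(f"{path}: expected two columns time_s,value")
    try:
        times = df.iloc[:, 0].to_numpy(dtype=float)
        values = df.iloc[:, 1].to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise TraceError(f"{path}: non-numeric data ({exc})") from exc
    return Trace(times, values, channel)


def write_trace(trace: Trace, path) -> None:
    """Write a trace as ``time_s,value`` CSV with '.' decimal separator."""
    df = pd.DataFrame({"time_s": trace.times, "value": trace.values})
    df.to_csv(path, index=False, float_format="%.12g")


def average_traces(traces: list[Trace]) -> Trace:
    """Mean-by-timepoint average after aligning all traces to the first grid.

    Replicate traces are linearly interpolated onto the first trace's grid
    restricted to the overlapping time window.
    """
    if not traces:
        raise TraceError("no traces to average")
    first = traces[0]
    if len(traces) == 1:
        return first
    lo = max(t.times[0] for t in traces)
    hi = min(t.times[-1] for t in traces)
    if hi <= lo:
        raise TraceError("traces do not overlap in time")
    mask = (first.times >= lo) & (first.times <= hi)
    grid = first.times[mask]
    if grid.size < _MIN_SAMPLES:
        raise TraceError("overlap window too short to average")
    stacked = np.vstack([np.interp(grid, t.times, t.values) for t in traces])
    return Trace(grid, stacked.mean(axis=0), first.channel)
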