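"""Labeled half-open time intervals.

An :class:`IntervalSet` holds sorted, non-overlapping ``[start, stop)``
intervals with a state label per interval (UP/DOWN/NREM/SWR/...).  It is the
common currency between the simulated-state detectors, the LFP event
detectors and the duration-matching step.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["IntervalSet", "intervals_from_mask", "intersect_intervals",
           "filter_by_duration"]


@dataclass
class IntervalSet:
    starts: np.ndarray
    stops: np.ndarray
    labels: np.ndarray
    units: str = "s"

    def __post_init__(self) -> None:
        self.starts = np.asarray(self.starts, dtype=float)
        self.stops = np.asarray(self.stops, dtype=float)
        self.labels = np.asarray(self.labels, dtype=object)
        if not (len(self.starts) == len(self.stops) == len(self.labels)):
            raise ValueError("starts, stops and labels must have equal length")
        if np.any(self.stops <= self.starts):
            raise ValueError("every interval must satisfy stop > start")
        if np.any(np.diff(self.starts) < 0):
            raise ValueError("intervals must be sorted by start time")
        if len(self.starts) > 1 and np.any(self.starts[1:] < self.stops[:-1] - 1e-12):
            raise ValueError("intervals must be non-overlapping")

    def __len__(self) -> int:
        return len(self.starts)

    def __iter__(self):
        return iter(zip(self.starts, self.stops, self.labels))

    @classmethod
    def empty(cls, units: str = "s") -> "IntervalSet":
        return cls(np.empty(0), np.empty(0), np.empty(0, dtype=object), units)

    def durations(self, label: str | None = None) -> np.ndarray:
        d = self.stops - self.starts
        if label is None:
            return d
        return d[self.labels == label]

    def select(self, label: str) -> "IntervalSet":
        m = self.labels == label
        return IntervalSet(self.starts[m], self.stops[m], self.labels[m], self.units)

    def total_duration(self, label: str | None = None) -> float:
        return float(self.durations(label).sum())

    def contains(self, times: np.ndarray) -> np.ndarray:
        """Boolean mask: which of ``times`` fall inside any interval."""
        times = np.asarray(times, dtype=float)
        idx = np.searchsorted(self.starts, times, side="right") - 1
        ok = idx >= 0
        out = np.zeros(times.shape, dtype=bool)
        out[ok] = times[ok] < self.stops[idx[ok]]
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"start": self.starts, "stop": self.stops, "label": self.labels})

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# units: {self.units}\n")
            self.to_frame().to_csv(fh, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "IntervalSet":
        units = "s"
        with open(path) as fh:
            first = fh.readline()
            if first.startswith("# units:"):
                units = first.split(":", 1)[1].strip()
                df = pd.read_csv(fh, sep="\t")
            else:
                fh.seek(0)
                df = pd.read_csv(fh, sep="\t")
        return cls(df["start"].to_numpy(), df["stop"].to_numpy(),
                   df["label"].to_numpy(dtype=object), units)


def intervals_from_mask(mask: np.ndarray, dt: float, label: str,
                        t0: float = 0.0, units: str = "s") -> IntervalSet:
    """Runs of True in a uniformly sampled boolean mask -> intervals."""
    mask = np.asarray(mask, dtype=bool)
    if mask.size == 0 or not mask.any():
        return IntervalSet.empty(units)
    d = np.diff(mask.astype(np.int8))
    starts = np.flatnonzero(d == 1) + 1
    stops = np.flatnonzero(d == -1) + 1
    if mask[0]:
        starts = np.r_[0, starts]
    if mask[-1]:
        stops = np.r_[stops, mask.size]
    return IntervalSet(t0 + starts * dt, t0 + stops * dt,
                       np.full(len(starts), label, dtype=object), units)


def filter_by_duration(events: IntervalSet, min_dur: float = 0.0,
                       max_dur: float = np.inf) -> IntervalSet:
    """Keep intervals with min_dur <= duration <= max_dur."""
    d = events.durations()
    keep = (d >= min_dur - 1e-12) & (d <= max_dur + 1e-12)
    return IntervalSet(events.starts[keep], events.stops[keep],
                       events.labels[keep], events.units)


def intersect_intervals(a: IntervalSet, b: IntervalSet, label: str | None = None) -> IntervalSet:
    """Pairwise overlaps of two interval sets (labels taken from ``label`` or from ``a``)."""
    starts, stops, labels = [], [], []
    j = 0
    for sa, ea, la in a:
        while j < len(b) and b.stops[j] <= sa:
            j += 1
        k = j
        while k < len(b) and b.starts[k] < ea:
            s, e = max(sa, b.starts[k]), min(ea, b.stops[k])
            if e > s:
                starts.append(s)
                stops.append(e)
                labels.append(label if label is not None else la)
            k += 1
    if not starts:
        return IntervalSet.empty(a.units)
    return IntervalSet(np.array(starts), np.array(stops), np.array(labels, dtype=object), a.units)
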