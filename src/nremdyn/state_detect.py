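"""UP/DOWN state detection on simulated rate traces.

A trace is declared to alternate only if the distribution of r(t) is
bimodal (Hartigan dip test).  Transition detection then uses a "sticky"
(hysteresis) threshold pair derived from the rate distribution: the system
switches to UP only when the rate rises above the midpoint of the
high-rate peak and the inter-peak trough, and to DOWN only when it falls
below the midpoint of the low-rate peak and the trough, which suppresses
spurious transitions from noise excursions that cross only the trough.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from numba import njit
from scipy.signal import find_peaks

from ._dip import dip_pvalue, dip_statistic
from .intervals import IntervalSet
from .params import RatePopParams

__all__ = [
    "BimodalityResult",
    "DurationStats",
    "bimodality_gate",
    "sticky_thresholds",
    "detect_updown",
    "duration_stats",
    "duration_map",
]


@dataclass(frozen=True)
class BimodalityResult:
    dip: float
    pvalue: float
    bimodal: bool
    n: int


@dataclass(frozen=True)
class DurationStats:
    mean_up: float
    mean_down: float
    cv_up: float
    cv_down: float
    ratio: float
    n_up: int
    n_down: int


def bimodality_gate(trace_or_sample, alpha: float = 0.05, n_boot: int = 500,
                    seed: int = 12345) -> BimodalityResult:
    """Dip test of the rate sample against a unimodal null.

    Accepts a SimTrace or a bare 1D sample.  Degenerate (constant) traces
    are reported unimodal with a warning.
    """
    r = np.asarray(getattr(trace_or_sample, "r", trace_or_sample), float).ravel()
    if r.size < 1000:
        raise ValueError("bimodality gate needs at least 1000 samples")
    if np.ptp(r) == 0.0:
        warnings.warn("constant trace: dip test degenerate, reporting unimodal")
        return BimodalityResult(dip=0.0, pvalue=1.0, bimodal=False, n=r.size)
    dip = dip_statistic(r)
    p = dip_pvalue(dip, r.size, n_boot=n_boot)
    return BimodalityResult(dip=dip, pvalue=p, bimodal=p < alpha, n=r.size)


def _smoothed_histogram(x: np.ndarray):
    edges = np.histogram_bin_edges(x, bins="fd")
    if len(edges) > 1001:  # cap resolution for very long traces
        edges = np.linspace(edges[0], edges[-1], 1001)
    counts, edges = np.histogram(x, bins=edges)
    smooth = np.convolve(counts.astype(float), np.ones(3) / 3.0, mode="same")
    centers = edges[:-1] + np.diff(edges) / 2.0
    return centers, smooth


def sticky_thresholds(rate_sample) -> tuple[float, float]:
    """(down_to_up, up_to_down) hysteresis thresholds from the rate distribution.

    The rate histogram (Freedman-Diaconis bins, 3-bin moving average) must
    show a low-rate peak and a high-rate peak separated by a trough; the
    DOWN->UP threshold is the midpoint of the high peak and the trough, the
    UP->DOWN threshold the midpoint of the low peak and the trough.
    """
    x = np.asarray(getattr(rate_sample, "r", rate_sample), float).ravel()
    centers, smooth = _smoothed_histogram(x)
    floor = max(5.0, 2e-5 * x.size)
    # zero-pad so modes in the first/last bin count as peaks
    peaks, _ = find_peaks(np.r_[0.0, smooth, 0.0], height=floor)
    peaks = peaks - 1
    if len(peaks) < 2:
        raise ValueError(
            "rate distribution has fewer than two peaks; run bimodality_gate first")
    best = None
    for ii in range(len(peaks)):
        for jj in range(ii + 1, len(peaks)):
            a, b = peaks[ii], peaks[jj]
            if smooth[a:b + 1].min() >= 0.5 * min(smooth[a], smooth[b]):
                continue
            # place the trough on a coarsely smoothed density so narrow
            # low-occupancy notches beside a mode cannot capture it
            w2 = max(3, (b - a) // 10)
            coarse = np.convolve(smooth[a:b + 1], np.ones(w2) / w2, mode="same")
            v = coarse.min()
            near = np.flatnonzero(coarse <= v + max(1e-9, 0.02 * (coarse.max() - v)))
            t = a + int(near[len(near) // 2])   # middle of the trough plateau
            sep = centers[b] - centers[a]
            if best is None or sep > best[0]:
                best = (sep, a, b, t)
    if best is None:
        raise ValueError(
            "no trough separating two modes; run bimodality_gate first")
    _, a, b, t = best
    low_peak, high_peak, trough = centers[a], centers[b], centers[t]
    down_to_up = (high_peak + trough) / 2.0
    up_to_down = (low_peak + trough) / 2.0
    return float(down_to_up), float(up_to_down)


@njit(cache=False)
def _hysteresis_scan(r, up_thresh, down_thresh):
    """Transition sample indices and states via sticky-threshold scan."""
    n = len(r)
    trans_idx = np.empty(n, dtype=np.int64)
    trans_state = np.empty(n, dtype=np.int8)  # 1 = enters UP, 0 = enters DOWN
    k = 0
    state = -1
    for i in range(1, n):
        if state != 1 and r[i - 1] <= up_thresh < r[i]:
            trans_idx[k] = i
            trans_state[k] = 1
            k += 1
            state = 1
        elif state != 0 and r[i - 1] >= down_thresh > r[i]:
            trans_idx[k] = i
            trans_state[k] = 0
            k += 1
            state = 0
    return trans_idx[:k], trans_state[:k]


def detect_updown(trace, thresholds: tuple[float, float] | None = None,
                  gate: BimodalityResult | None = None,
                  alpha: float = 0.05) -> IntervalSet:
    """Detect UP/DOWN intervals on a simulated trace.

    Runs the bimodality gate (unless a result is supplied), derives sticky
    thresholds, and scans with hysteresis.  Partial first/last states are
    discarded; the result strictly alternates UP and DOWN.  A trace failing
    the gate yields an empty interval set (with a warning).
    """
    r = np.asarray(trace.r, float)
    dt = float(trace.dt)
    if gate is None:
        gate = bimodality_gate(trace, alpha=alpha)
    if not gate.bimodal:
        warnings.warn("trace failed the bimodality gate; no UP/DOWN states detected")
        return IntervalSet.empty(units="model")
    if thresholds is None:
        thresholds = sticky_thresholds(r)
    up_th, down_th = thresholds
    if not up_th > down_th:
        raise ValueError("down_to_up threshold must exceed up_to_down threshold")
    idx, states = _hysteresis_scan(r, up_th, down_th)
    if len(idx) < 3:
        return IntervalSet.empty(units="model")
    # interval k spans transitions k -> k+1; drop the leading partial state
    starts = idx[:-1] * dt
    stops = idx[1:] * dt
    labels = np.where(states[:-1] == 1, "UP", "DOWN").astype(object)
    return IntervalSet(starts, stops, labels, units="model")


def duration_stats(states: IntervalSet) -> DurationStats:
    """Per-label mean, CV (population std / mean), UP/DOWN mean ratio, counts."""
    out = {}
    for label in ("UP", "DOWN"):
        d = states.durations(label)
        if len(d) == 0:
            out[label] = (np.nan, np.nan, 0)
        elif len(d) == 1:
            out[label] = (float(d[0]), np.nan, 1)
        else:
            out[label] = (float(d.mean()), float(d.std() / d.mean()), len(d))
    ratio = out["UP"][0] / out["DOWN"][0] if out["DOWN"][2] else np.nan
    return DurationStats(mean_up=out["UP"][0], mean_down=out["DOWN"][0],
                         cv_up=out["UP"][1], cv_down=out["DOWN"][1],
                         ratio=ratio, n_up=out["UP"][2], n_down=out["DOWN"][2])


@dataclass
class DurationMapCell:
    stats: DurationStats | None
    durations_up: np.ndarray
    durations_down: np.ndarray
    alternating: bool


@dataclass
class DurationMap:
    axis1: tuple[str, np.ndarray]
    axis2: tuple[str, np.ndarray]
    cells: np.ndarray          # object array of DurationMapCell
    log_bins: np.ndarray

    def histogram(self, i: int, j: int, label: str = "UP") -> np.ndarray:
        cell = self.cells[i, j]
        d = cell.durations_up if label == "UP" else cell.durations_down
        counts, _ = np.histogram(d, bins=self.log_bins)
        return counts


def duration_map(base: RatePopParams, axis1, axis2, noise, duration: float = 10_000.0,
                 seed: int = 0, alpha: float = 0.05) -> DurationMap:
    """Simulate/gate/detect/summarize over a 2D parameter grid.

    Cells whose trace fails the bimodality gate are marked non-alternating
    and carry empty duration samples; per-cell failures never abort the map.
    """
    from .simulate import simulate_rate

    (name1, grid1), (name2, grid2) = axis1, axis2
    grid1, grid2 = np.asarray(grid1, float), np.asarray(grid2, float)
    if grid1.size == 0 or grid2.size == 0:
        raise ValueError("duration map grids must be non-empty")
    cells = np.empty((grid1.size, grid2.size), dtype=object)
    rng = np.random.default_rng(seed)
    for i, v1 in enumerate(grid1):
        for j, v2 in enumerate(grid2):
            params = base.replace(**{name1: float(v1), name2: float(v2)})
            cell_seed = int(rng.integers(2**31 - 1))
            try:
                trace = simulate_rate(params, noise, duration, seed=cell_seed)
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    states = detect_updown(trace, alpha=alpha)
            except (ValueError, FloatingPointError):
                states = IntervalSet.empty(units="model")
            if len(states) == 0:
                cells[i, j] = DurationMapCell(None, np.empty(0), np.empty(0), False)
            else:
                cells[i, j] = DurationMapCell(duration_stats(states),
                                              states.durations("UP"),
                                              states.durations("DOWN"), True)
    log_bins = np.logspace(-1, np.log10(duration), 40)
    return DurationMap((name1, grid1), (name2, grid2), cells, log_bins)
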