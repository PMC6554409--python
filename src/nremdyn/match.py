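"""Non-parametric matching of UP/DOWN duration distributions.

Simulated and observed dwell-time distributions are compared with the
Kolmogorov-Smirnov statistic per state and combined multiplicatively::

    s = (1 - KS_UP) * (1 - KS_DOWN)

so s = 1 means both distributions are identical and s = 0 means at least
one pair of distributions has non-overlapping support.  The single free
parameter is the time-scale factor tau (ms per model time unit), scanned
over [1, 25] ms in 0.1 ms steps; scaling durations preserves distribution
shapes and the relative UP/DOWN durations.  For hippocampal data the SWR
state maps to UP and the inter-SWR period to DOWN.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .state_detect import DurationStats

__all__ = [
    "DurationSample",
    "SimilarityResult",
    "SimilarityMap",
    "ks_stat",
    "similarity",
    "best_tau",
    "similarity_map",
    "TAU_GRID_MS",
]

#: time-scale factors scanned when matching model durations to seconds
TAU_GRID_MS = np.round(np.arange(10, 251) * 0.1, 10)  # 1.0 .. 25.0 ms, step 0.1

#: label mapping used for hippocampal recordings: SWR ~ UP, inter-SWR ~ DOWN
HIPPOCAMPAL_LABEL_MAP = {"SWR": "UP", "interSWR": "DOWN"}


@dataclass
class DurationSample:
    """Unordered multisets of UP and DOWN dwell times."""

    up: np.ndarray
    down: np.ndarray
    units: str = "s"

    def __post_init__(self) -> None:
        self.up = np.asarray(self.up, dtype=float).ravel()
        self.down = np.asarray(self.down, dtype=float).ravel()
        if (len(self.up) and self.up.min() <= 0) or (len(self.down) and self.down.min() <= 0):
            raise ValueError("durations must be strictly positive")

    def scaled(self, factor: float) -> "DurationSample":
        return DurationSample(self.up * factor, self.down * factor, units=self.units)

    @classmethod
    def from_intervals(cls, states, units: str | None = None,
                       label_map: dict | None = None) -> "DurationSample":
        labels = np.array([
            (label_map or {}).get(str(lab), str(lab)) for lab in states.labels
        ], dtype=object)
        d = states.stops - states.starts
        return cls(d[labels == "UP"], d[labels == "DOWN"],
                   units=units if units is not None else states.units)

    def to_tsv(self, path) -> None:
        import pandas as pd

        df = pd.DataFrame({
            "duration": np.r_[self.up, self.down],
            "label": ["UP"] * len(self.up) + ["DOWN"] * len(self.down),
        })
        with open(path, "w") as fh:
            fh.write(f"# units: {self.units}\n")
            df.to_csv(fh, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "DurationSample":
        import pandas as pd

        units = "s"
        with open(path) as fh:
            first = fh.readline()
            if first.startswith("# units:"):
                units = first.split(":", 1)[1].strip()
            else:
                fh.seek(0)
            df = pd.read_csv(fh, sep="\t")
        return cls(df.loc[df["label"] == "UP", "duration"].to_numpy(),
                   df.loc[df["label"] == "DOWN", "duration"].to_numpy(), units)


@dataclass(frozen=True)
class SimilarityResult:
    ks_up: float
    ks_down: float
    s: float
    best_tau: float | None = None   # ms, present when produced by a tau scan


def ks_stat(sample_a, sample_b) -> float:
    """Exact two-sample KS statistic sup_x |F_a(x) - F_b(x)|.

    Evaluated at every step point of the pooled sample (both one-sided
    limits), so the supremum is attained exactly.
    """
    a = np.sort(np.asarray(sample_a, dtype=float).ravel())
    b = np.sort(np.asarray(sample_b, dtype=float).ravel())
    if a.size == 0 or b.size == 0:
        raise ValueError("ks_stat requires non-empty samples")
    pooled = np.concatenate([a, b])
    cdf_a = np.searchsorted(a, pooled, side="right") / a.size
    cdf_b = np.searchsorted(b, pooled, side="right") / b.size
    cdf_a_left = np.searchsorted(a, pooled, side="left") / a.size
    cdf_b_left = np.searchsorted(b, pooled, side="left") / b.size
    return float(max(np.abs(cdf_a - cdf_b).max(),
                     np.abs(cdf_a_left - cdf_b_left).max()))


def similarity(sim: DurationSample, obs: DurationSample, tau: float = 1.0) -> SimilarityResult:
    """KS-product similarity after scaling simulated durations by tau."""
    if tau <= 0:
        raise ValueError("time-scale factor must be positive")
    if min(len(sim.up), len(sim.down), len(obs.up), len(obs.down)) == 0:
        raise ValueError("similarity requires non-empty UP and DOWN duration samples")
    ks_up = ks_stat(sim.up * tau, obs.up)
    ks_down = ks_stat(sim.down * tau, obs.down)
    return SimilarityResult(ks_up=ks_up, ks_down=ks_down,
                            s=(1.0 - ks_up) * (1.0 - ks_down))


def _ks_sorted(a: np.ndarray, b: np.ndarray) -> float:
    """Exact two-sample KS for already-sorted inputs."""
    pooled = np.concatenate([a, b])
    d_right = np.abs(np.searchsorted(a, pooled, side="right") / a.size
                     - np.searchsorted(b, pooled, side="right") / b.size)
    d_left = np.abs(np.searchsorted(a, pooled, side="left") / a.size
                    - np.searchsorted(b, pooled, side="left") / b.size)
    return float(max(d_right.max(), d_left.max()))


def best_tau(sim: DurationSample, obs: DurationSample,
             tau_grid=TAU_GRID_MS, to_seconds: bool = False) -> SimilarityResult:
    """Scan the time-scale factor (1-25 ms by default) and keep the argmax of s.

    With ``to_seconds`` the scale is applied as tau/1000 (model units ->
    seconds) while still being reported in ms.  Ties break toward the
    smallest tau.
    """
    if min(len(sim.up), len(sim.down), len(obs.up), len(obs.down)) == 0:
        raise ValueError("best_tau requires non-empty UP and DOWN duration samples")
    sim_up, sim_down = np.sort(sim.up), np.sort(sim.down)
    obs_up, obs_down = np.sort(obs.up), np.sort(obs.down)
    best = None
    for tau in np.asarray(tau_grid, float):
        factor = tau / 1000.0 if to_seconds else tau
        if factor <= 0:
            raise ValueError("time-scale factor must be positive")
        ks_up = _ks_sorted(sim_up * factor, obs_up)     # scaling preserves order
        ks_down = _ks_sorted(sim_down * factor, obs_down)
        s = (1.0 - ks_up) * (1.0 - ks_down)
        if best is None or s > best.s:
            best = SimilarityResult(ks_up, ks_down, s, best_tau=float(tau))
    return best


@dataclass
class SimilarityMap:
    axis1: tuple[str, np.ndarray]
    axis2: tuple[str, np.ndarray]
    mean_s: np.ndarray                  # (n1, n2) mean similarity over recordings
    per_recording_s: np.ndarray         # (n_rec, n1, n2)
    per_recording_tau: np.ndarray       # (n_rec, n1, n2) ms
    best_cells: list                    # per recording: (i, j) argmax cell
    constraint_mask: np.ndarray | None  # cells within 2 SD of experimental stats
    no_alternation: np.ndarray          # cells without UP/DOWN alternations


def _within_2sd(stats: DurationStats, experimental: dict) -> bool:
    for key, attr in (("cv_up", "cv_up"), ("cv_down", "cv_down"), ("ratio", "ratio")):
        if key in experimental:
            mean, sd = experimental[key]
            v = getattr(stats, attr)
            if not np.isfinite(v) or abs(v - mean) > 2.0 * sd:
                return False
    return True


def similarity_map(grid_samples: np.ndarray, recordings: list,
                   axis1, axis2, experimental_stats: dict | None = None,
                   grid_stats: np.ndarray | None = None,
                   to_seconds: bool = True) -> SimilarityMap:
    """Per-cell best-tau similarity against each recording, plus the mean map.

    ``grid_samples`` is an object array of DurationSample (or None for cells
    without alternations, which contribute s = 0 by convention).  The
    constraint mask marks cells whose simulated CV_UP, CV_DOWN and mean
    ratio all fall within 2 SD of the experimental values
    (``experimental_stats = {"cv_up": (mean, sd), ...}``; needs ``grid_stats``).
    """
    if len(recordings) == 0:
        raise ValueError("need at least one recording")
    n1, n2 = grid_samples.shape
    n_rec = len(recordings)
    s_maps = np.zeros((n_rec, n1, n2))
    tau_maps = np.full((n_rec, n1, n2), np.nan)
    no_alt = np.zeros((n1, n2), dtype=bool)
    for i in range(n1):
        for j in range(n2):
            cell = grid_samples[i, j]
            if cell is None or min(len(cell.up), len(cell.down)) == 0:
                no_alt[i, j] = True
                continue
            for k, rec in enumerate(recordings):
                res = best_tau(cell, rec, to_seconds=to_seconds)
                s_maps[k, i, j] = res.s
                tau_maps[k, i, j] = res.best_tau
    best_cells = []
    for k in range(n_rec):
        flat = int(np.argmax(s_maps[k]))
        best_cells.append((flat // n2, flat % n2))
    mask = None
    if experimental_stats is not None and grid_stats is not None:
        mask = np.zeros((n1, n2), dtype=bool)
        for i in range(n1):
            for j in range(n2):
                st = grid_stats[i, j]
                mask[i, j] = st is not None and _within_2sd(st, experimental_stats)
    return SimilarityMap(axis1=axis1, axis2=axis2, mean_s=s_maps.mean(axis=0),
                         per_recording_s=s_maps, per_recording_tau=tau_maps,
                         best_cells=best_cells, constraint_mask=mask,
                         no_alternation=no_alt)
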