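"""LFP and spike-train event detection.

Implements the in-vivo side of the pipeline on 1250 Hz extracellular
recordings: NREM scoring from a spectrogram slow-wave-power metric,
slow-wave (DOWN state) detection from the coincidence of a delta-band
(0.5-8 Hz) peak and a high-gamma (100-400 Hz) power drop with
spiking-calibrated dual thresholds, sharp wave-ripple detection from the
coincidence of a deep-layer sharp wave (2-50 Hz) and a pyramidal-layer
ripple (80-250 Hz) burst, and delta-power (1-4 Hz) stratified duration
statistics.

All thresholds operate on normalized (z-scored) signals, so detection is
invariant to a global gain on the LFP.  All band-pass filters are
4th-order zero-phase (forward-backward) Butterworth filters.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal as sps

from .intervals import (IntervalSet, filter_by_duration, intersect_intervals,
                        intervals_from_mask)
from .state_detect import DurationStats, duration_stats

__all__ = [
    "LFPRecord",
    "SpikeRaster",
    "DetectionConfig",
    "score_nrem",
    "select_channels",
    "calibrate_sw_thresholds",
    "detect_slow_waves",
    "detect_swr",
    "delta_conditioned_stats",
]


@dataclass
class LFPRecord:
    data: np.ndarray            # (n_channels, n_samples)
    rate: float = 1250.0
    channel_ids: list | None = None
    start: float = 0.0

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data))
        if self.channel_ids is None:
            self.channel_ids = list(range(self.data.shape[0]))
        if self.rate <= 800.0:
            raise ValueError("sampling rate must exceed twice the 400 Hz analysis band")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.rate

    @property
    def t(self) -> np.ndarray:
        return self.start + np.arange(self.n_samples) / self.rate

    def to_hdf5(self, path) -> None:
        import h5py

        with h5py.File(path, "w") as f:
            f.create_dataset("lfp", data=self.data)
            f.attrs["rate"] = self.rate
            f.attrs["start"] = self.start
            f.attrs["channel_ids"] = [str(c) for c in self.channel_ids]

    @classmethod
    def from_hdf5(cls, path) -> "LFPRecord":
        import h5py

        with h5py.File(path, "r") as f:
            return cls(data=f["lfp"][:], rate=float(f.attrs["rate"]),
                       channel_ids=list(f.attrs["channel_ids"]),
                       start=float(f.attrs.get("start", 0.0)))

    def to_binary(self, path) -> None:
        """Flat little-endian int16 binary (channel-interleaved) + JSON sidecar."""
        path = Path(path)
        scale = np.max(np.abs(self.data)) or 1.0
        scaled = np.clip(self.data / scale * 32000.0, -32768, 32767)
        scaled.T.astype("<i2").tofile(path)
        sidecar = {"n_channels": self.n_channels, "rate": self.rate,
                   "scale": float(scale) / 32000.0, "start": self.start}
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar))

    @classmethod
    def from_binary(cls, path) -> "LFPRecord":
        path = Path(path)
        meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
        raw = np.fromfile(path, dtype="<i2").reshape(-1, meta["n_channels"]).T
        return cls(data=raw.astype(float) * meta.get("scale", 1.0),
                   rate=float(meta["rate"]), start=float(meta.get("start", 0.0)))


@dataclass
class SpikeRaster:
    units: list                     # list of sorted spike-time arrays (s)
    classes: list | None = None     # per-unit tag: pE | pI | unknown

    def __post_init__(self) -> None:
        self.units = [np.asarray(u, dtype=float) for u in self.units]
        for u in self.units:
            if len(u) and (np.any(np.diff(u) < 0) or u[0] < 0):
                raise ValueError("spike times must be sorted and non-negative")
        if self.classes is None:
            self.classes = ["unknown"] * len(self.units)

    @property
    def n_units(self) -> int:
        return len(self.units)

    def all_spikes(self) -> np.ndarray:
        if not self.units:
            return np.empty(0)
        return np.sort(np.concatenate(self.units))

    def population_rate(self, bin_s: float, t_max: float) -> tuple[np.ndarray, np.ndarray]:
        """(bin centers, summed rate in Hz) on a uniform grid."""
        edges = np.arange(0.0, t_max + bin_s, bin_s)
        counts, _ = np.histogram(self.all_spikes(), bins=edges)
        return edges[:-1] + bin_s / 2.0, counts / bin_s

    def to_tsv(self, path) -> None:
        rows = []
        for k, (u, c) in enumerate(zip(self.units, self.classes)):
            for t in u:
                rows.append((k, t, c))
        pd.DataFrame(rows, columns=["unit", "time", "class"]).to_csv(
            path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "SpikeRaster":
        df = pd.read_csv(path, sep="\t")
        units, classes = [], []
        for uid, grp in df.groupby("unit"):
            units.append(np.sort(grp["time"].to_numpy()))
            classes.append(str(grp["class"].iloc[0]))
        return cls(units=units, classes=classes)


@dataclass(frozen=True)
class DetectionConfig:
    # analysis bands (Hz)
    band_slow_delta: tuple = (0.5, 8.0)
    band_gamma: tuple = (100.0, 400.0)
    band_delta_power: tuple = (1.0, 4.0)
    band_sharp_wave: tuple = (2.0, 50.0)
    band_ripple: tuple = (80.0, 250.0)
    # thresholds
    swr_threshold_std: float = 2.5
    candidate_peak_floor_std: float = 0.25
    sensitivity: float = 0.5
    # windows (s)
    gamma_smooth: float = 0.08
    ripple_smooth: float = 0.01
    local_norm_window: float = 20.0
    delta_context_window: float = 8.0
    spectrogram_window: float = 10.0
    spectrogram_step: float = 1.0
    # PETH calibration
    peth_halfwidth: float = 1.0
    peth_bin: float = 0.02
    magnitude_bin_std: float = 0.1
    # duration limits (s)
    min_slow_wave: float = 0.040
    sharp_wave_limits: tuple = (0.020, 0.500)
    min_ripple: float = 0.025

    def __post_init__(self) -> None:
        if not (0.0 < self.sensitivity < 1.0):
            raise ValueError("sensitivity must lie in (0, 1)")


# ---------------------------------------------------------------------------
# signal helpers

def bandpass(x: np.ndarray, band: tuple, fs: float, order: int = 4) -> np.ndarray:
    """Zero-phase 4th-order Butterworth band-pass."""
    sos = sps.butter(order, band, btype="bandpass", fs=fs, output="sos")
    return sps.sosfiltfilt(sos, x)


def _smooth(x: np.ndarray, window_s: float, fs: float) -> np.ndarray:
    n = max(1, int(round(window_s * fs)))
    kernel = np.ones(n) / n
    return sps.fftconvolve(x, kernel, mode="same")


def _local_modified_zscore(x: np.ndarray, fs: float, window_s: float,
                           hop_s: float = 2.0) -> np.ndarray:
    """(x - median) / (1.4826 * MAD) over a sliding window.

    Medians and MADs are computed on overlapping windows at a coarse hop
    and linearly interpolated back to the full grid.
    """
    n = len(x)
    half = int(window_s * fs / 2)
    hop = max(1, int(hop_s * fs))
    centers = np.arange(0, n, hop)
    med = np.empty(len(centers))
    mad = np.empty(len(centers))
    for k, c in enumerate(centers):
        seg = x[max(0, c - half):min(n, c + half)]
        med[k] = np.median(seg)
        mad[k] = np.median(np.abs(seg - med[k]))
    med_full = np.interp(np.arange(n), centers, med)
    mad_full = np.interp(np.arange(n), centers, mad)
    mad_full = np.where(mad_full > 0, mad_full, np.nan)
    fallback = 1.4826 * np.nanmedian(mad_full) if np.any(np.isfinite(mad_full)) else 1.0
    scale = np.where(np.isfinite(mad_full), 1.4826 * mad_full, fallback)
    return (x - med_full) / scale


def _zscore_in(x: np.ndarray, mask: np.ndarray | None) -> np.ndarray:
    ref = x if mask is None else x[mask]
    sd = ref.std()
    if sd == 0:
        raise ValueError("flat signal: cannot z-score")
    return (x - ref.mean()) / sd


# ---------------------------------------------------------------------------
# NREM scoring

#: default spectral weights for the slow-wave-power metric: positive weight
#: on delta frequencies, negative on beta/gamma, echoing the first principal
#: component of NREM-dominated spectrograms.
def default_nrem_weights(freqs: np.ndarray) -> np.ndarray:
    w = np.where(freqs <= 6.0, 1.0, np.where(freqs >= 20.0, -1.0, 0.0))
    return w / np.sum(np.abs(w))


def score_nrem(lfp: LFPRecord, channel: int = 0, config: DetectionConfig | None = None,
               weights=None) -> IntervalSet:
    """Score NREM epochs from the spectrogram slow-wave-power metric.

    Log-power on log-spaced 1-100 Hz frequencies in overlapping 10 s
    windows at 1 s steps is z-scored per frequency and projected onto a
    spectral weight vector; the metric's distribution is bimodal when NREM
    is present and the trough between its modes is the NREM threshold.
    """
    config = config or DetectionConfig()
    x = lfp.data[channel].astype(float)
    fs = lfp.rate
    if lfp.duration < 60.0:
        raise ValueError("NREM scoring needs at least 60 s of data")
    nperseg = int(config.spectrogram_window * fs)
    step = int(config.spectrogram_step * fs)
    freqs, times, spec = sps.spectrogram(x, fs=fs, nperseg=nperseg,
                                         noverlap=nperseg - step)
    log_freqs = np.logspace(0.0, 2.0, 100)
    interp = np.empty((len(log_freqs), spec.shape[1]))
    for k in range(spec.shape[1]):
        interp[:, k] = np.interp(log_freqs, freqs, spec[:, k])
    logp = np.log10(interp + 1e-20)
    z = (logp - logp.mean(axis=1, keepdims=True)) / (logp.std(axis=1, keepdims=True) + 1e-12)
    w = default_nrem_weights(log_freqs) if weights is None else np.asarray(weights, float)
    metric = w @ z

    from ._dip import dip_pvalue, dip_statistic

    if dip_pvalue(dip_statistic(metric), len(metric)) >= 0.05:
        warnings.warn("slow-wave-power metric unimodal: no NREM epochs found")
        return IntervalSet.empty()
    counts, edges = np.histogram(metric, bins=40)
    smooth = np.convolve(counts.astype(float), np.ones(3) / 3.0, "same")
    peaks, _ = sps.find_peaks(smooth, height=max(2.0, 0.02 * smooth.max()))
    best = None
    for ii in range(len(peaks)):
        for jj in range(ii + 1, len(peaks)):
            a, b = peaks[ii], peaks[jj]
            t = a + int(np.argmin(smooth[a:b + 1]))
            if smooth[t] < 0.5 * min(smooth[a], smooth[b]):
                sep = b - a
                if best is None or sep > best[0]:
                    best = (sep, a, b, t)
    if best is None:
        warnings.warn("slow-wave-power metric unimodal: no NREM epochs found")
        return IntervalSet.empty()
    _, a, b, trough = best
    threshold = edges[trough] + (edges[1] - edges[0]) / 2.0
    mask = metric > threshold
    if len(mask) >= 3:  # suppress single-window flickers
        mask = sps.medfilt(mask.astype(float), 3).astype(bool)
    nrem = intervals_from_mask(mask, config.spectrogram_step, "NREM",
                               t0=float(times[0]) - config.spectrogram_step / 2.0)
    # clip to the recording span
    keep = (nrem.stops > 0) & (nrem.starts < lfp.duration)
    return IntervalSet(np.clip(nrem.starts[keep], 0, lfp.duration),
                       np.clip(nrem.stops[keep], 0, lfp.duration),
                       nrem.labels[keep])


# ---------------------------------------------------------------------------
# channel selection

def select_channels(lfp: LFPRecord, spikes: SpikeRaster,
                    nrem: IntervalSet | None = None,
                    config: DetectionConfig | None = None) -> tuple[int, int]:
    """(delta channel, gamma channel) by correlation with population spiking.

    The delta channel minimizes the correlation of the delta-filtered LFP
    with binned population rate (delta peaks during silence); the gamma
    channel maximizes the correlation of smoothed high-gamma power with
    population rate.
    """
    config = config or DetectionConfig()
    if spikes.n_units == 0 or len(spikes.all_spikes()) == 0:
        raise ValueError("channel selection requires spikes")
    fs = lfp.rate
    # integer number of LFP samples per bin so rate and LFP bins stay aligned
    bin_len = int(round(0.05 * fs))
    bin_s = bin_len / fs
    centers, rate = spikes.population_rate(bin_s, lfp.duration)
    if nrem is not None and len(nrem):
        sel = nrem.contains(centers)
    else:
        sel = np.ones(len(centers), dtype=bool)
    n_bins = min(len(centers), lfp.n_samples // bin_len)
    centers, rate, sel = centers[:n_bins], rate[:n_bins], sel[:n_bins]

    def binned(sig):
        usable = sig[: n_bins * bin_len]
        return usable.reshape(n_bins, bin_len).mean(axis=1)

    corr_delta = np.empty(lfp.n_channels)
    corr_gamma = np.empty(lfp.n_channels)
    for c in range(lfp.n_channels):
        x = lfp.data[c].astype(float)
        delta = binned(bandpass(x, config.band_slow_delta, fs))
        gpow = binned(_smooth(bandpass(x, config.band_gamma, fs) ** 2,
                              config.gamma_smooth, fs))
        corr_delta[c] = np.corrcoef(delta[sel], rate[sel])[0, 1]
        corr_gamma[c] = np.corrcoef(gpow[sel], rate[sel])[0, 1]
    return int(np.argmin(corr_delta)), int(np.argmax(corr_gamma))


# ---------------------------------------------------------------------------
# slow-wave detection

def _detection_signals(lfp: LFPRecord, config: DetectionConfig,
                       delta_channel: int, gamma_channel: int,
                       nrem: IntervalSet | None):
    """(deltaZ, gamma_dropZ): positive deflections mean 'more DOWN-like'."""
    fs = lfp.rate
    mask = nrem.contains(lfp.t) if nrem is not None and len(nrem) else None
    delta = bandpass(lfp.data[delta_channel].astype(float), config.band_slow_delta, fs)
    delta_z = _zscore_in(delta, mask)
    gamma = bandpass(lfp.data[gamma_channel].astype(float), config.band_gamma, fs)
    gpow = _smooth(gamma**2, config.gamma_smooth, fs)
    gz = _local_modified_zscore(gpow, fs, config.local_norm_window)
    return delta_z, -gz


def _peth_calibration(sig: np.ndarray, fs: float, spikes: SpikeRaster,
                      sensitivity: float, config: DetectionConfig,
                      nrem: IntervalSet | None):
    """Dual-threshold calibration of one detection signal against spiking.

    Candidate deflection peaks above the 0.25-std floor are binned by
    magnitude (0.1-std bins); each bin's spike PETH (+-1 s, 20 ms bins) is
    normalized by the grand mean rate.  The peak threshold is the smallest
    magnitude bin whose PETH at lag 0 drops below the sensitivity; the
    window threshold averages, over qualifying bins, the signal value at
    the lags where the PETH crosses the sensitivity level.
    """
    peaks, props = sps.find_peaks(sig, height=config.candidate_peak_floor_std)
    if len(peaks) == 0:
        raise ValueError("no candidate peaks above the 0.25-std floor")
    if nrem is not None and len(nrem):
        keep = nrem.contains(peaks / fs)
        peaks = peaks[keep]
        if len(peaks) == 0:
            raise ValueError("no candidate peaks inside NREM epochs")
    heights = sig[peaks]
    all_sp = spikes.all_spikes()
    half = config.peth_halfwidth
    nbins = int(round(2 * half / config.peth_bin))
    lags = (np.arange(nbins) + 0.5) * config.peth_bin - half

    bin_w = config.magnitude_bin_std
    mag_edges = np.arange(config.candidate_peak_floor_std,
                          heights.max() + bin_w, bin_w)
    peth = np.zeros((len(mag_edges) - 1, nbins))
    counts = np.zeros(len(mag_edges) - 1, dtype=int)
    wave = np.zeros((len(mag_edges) - 1, nbins))
    for m in range(len(mag_edges) - 1):
        sel = (heights >= mag_edges[m]) & (heights < mag_edges[m + 1])
        counts[m] = sel.sum()
        if counts[m] == 0:
            continue
        for pk in peaks[sel]:
            t0 = pk / fs
            lo = np.searchsorted(all_sp, t0 - half)
            hi = np.searchsorted(all_sp, t0 + half)
            rel = all_sp[lo:hi] - t0
            h, _ = np.histogram(rel, bins=nbins, range=(-half, half))
            peth[m] += h
            k0 = int(pk - half * fs)
            idx = np.clip(np.round(k0 + (np.arange(nbins) + 0.5) * config.peth_bin * fs).astype(int),
                          0, len(sig) - 1)
            wave[m] += sig[idx]
        peth[m] /= counts[m]
        wave[m] /= counts[m]
    grand = peth[counts > 0].mean()
    if grand == 0:
        raise ValueError("no spikes around candidate peaks; cannot calibrate")
    norm = peth / grand
    centre = nbins // 2
    valid = np.flatnonzero(counts > 0)
    qual = [m for m in valid if norm[m, centre] < sensitivity]
    if not qual:
        raise ValueError("spiking never drops below the sensitivity level; "
                         "no peak threshold found")
    m0 = min(qual)
    peak_threshold = float(mag_edges[m0])
    vals = []
    for m in valid:
        if m < m0:
            continue
        prof = norm[m]
        below = prof < sensitivity
        if not below[:centre].any() or not below.any():
            continue
        # last crossing into silence before lag 0 and first recovery after
        pre = np.flatnonzero(~below[:centre + 1])
        k_in = pre[-1] + 1 if len(pre) and pre[-1] + 1 <= centre else 0
        post = np.flatnonzero(~below[centre:])
        k_out = centre + post[0] - 1 if len(post) else nbins - 1
        vals.extend([wave[m, k_in], wave[m, k_out]])
    window_threshold = float(np.mean(vals)) if vals else peak_threshold / 2.0
    # the window threshold must nest below the peak threshold for the
    # two-stage extension to be meaningful; clip in degenerate cases
    return peak_threshold, min(window_threshold, peak_threshold)


def calibrate_sw_thresholds(lfp: LFPRecord, spikes: SpikeRaster,
                            sensitivity: float | None = None,
                            config: DetectionConfig | None = None,
                            nrem: IntervalSet | None = None,
                            channels: tuple[int, int] | None = None) -> dict:
    """PETH-calibrated peak/window thresholds for the delta and gamma signals."""
    config = config or DetectionConfig()
    if sensitivity is None:
        sensitivity = config.sensitivity
    if not (0.0 < sensitivity < 1.0):
        raise ValueError("sensitivity must lie in (0, 1)")
    if channels is None:
        channels = select_channels(lfp, spikes, nrem, config)
    delta_z, gamma_drop = _detection_signals(lfp, config, channels[0], channels[1], nrem)
    d_peak, d_window = _peth_calibration(delta_z, lfp.rate, spikes, sensitivity,
                                         config, nrem)
    g_peak, g_window = _peth_calibration(gamma_drop, lfp.rate, spikes, sensitivity,
                                         config, nrem)
    return {"delta": (d_peak, d_window), "gamma": (g_peak, g_window),
            "channels": channels, "sensitivity": sensitivity}


def _dual_threshold_events(sig: np.ndarray, fs: float, peak_thr: float,
                           window_thr: float, min_dur: float,
                           label: str) -> IntervalSet:
    """Suprathreshold epochs of the window threshold that contain a peak-threshold sample."""
    above_w = sig > window_thr
    events = intervals_from_mask(above_w, 1.0 / fs, label)
    if len(events) == 0:
        return events
    keep = []
    for k, (s, e, _) in enumerate(events):
        seg = sig[int(s * fs):int(e * fs)]
        if seg.size and seg.max() > peak_thr and (e - s) >= min_dur:
            keep.append(k)
    return IntervalSet(events.starts[keep], events.stops[keep],
                       events.labels[keep])


def detect_slow_waves(lfp: LFPRecord, spikes: SpikeRaster,
                      config: DetectionConfig | None = None,
                      nrem: IntervalSet | None = None,
                      thresholds: dict | None = None) -> IntervalSet:
    """Detect DOWN states (slow waves) and complementary UP states within NREM.

    DOWN candidates are overlapping delta-peak and gamma-drop events (each
    dual-thresholded and at least 40 ms long); candidates with within-event
    spiking above the sensitivity level are discarded.  The gaps between
    DOWN states inside NREM become UP states.
    """
    config = config or DetectionConfig()
    if thresholds is None:
        thresholds = calibrate_sw_thresholds(lfp, spikes, config=config, nrem=nrem)
    ch_delta, ch_gamma = thresholds["channels"]
    delta_z, gamma_drop = _detection_signals(lfp, config, ch_delta, ch_gamma, nrem)
    fs = lfp.rate
    d_events = _dual_threshold_events(delta_z, fs, *thresholds["delta"],
                                      config.min_slow_wave, "DOWN")
    g_events = _dual_threshold_events(gamma_drop, fs, *thresholds["gamma"],
                                      config.min_slow_wave, "DOWN")
    down = intersect_intervals(d_events, g_events, label="DOWN")
    down = filter_by_duration(down, config.min_slow_wave)
    if nrem is not None and len(nrem):
        down = intersect_intervals(down, nrem, label="DOWN")
        down = filter_by_duration(down, config.min_slow_wave)

    # reject candidates whose within-event spiking exceeds the sensitivity level
    all_sp = spikes.all_spikes()
    span = nrem.total_duration() if nrem is not None and len(nrem) else lfp.duration
    mean_rate = len(all_sp) / span if span > 0 else 0.0
    keep = []
    for k, (s, e, _) in enumerate(down):
        n_in = np.searchsorted(all_sp, e) - np.searchsorted(all_sp, s)
        rate_in = n_in / (e - s)
        if mean_rate == 0 or rate_in < thresholds["sensitivity"] * mean_rate:
            keep.append(k)
    down = IntervalSet(down.starts[keep], down.stops[keep], down.labels[keep])

    # complementary UP states inside NREM
    epochs = nrem if nrem is not None and len(nrem) else IntervalSet(
        np.array([0.0]), np.array([lfp.duration]), np.array(["NREM"], dtype=object))
    starts, stops, labels = [], [], []
    for es, ee, _ in epochs:
        inside = [(s, e) for s, e, _ in down if s >= es and e <= ee]
        cursor = es
        for s, e in inside:
            if s > cursor:
                starts.append(cursor); stops.append(s); labels.append("UP")
            starts.append(s); stops.append(e); labels.append("DOWN")
            cursor = e
        if cursor < ee:
            starts.append(cursor); stops.append(ee); labels.append("UP")
    if not starts:
        return IntervalSet.empty()
    return IntervalSet(np.array(starts), np.array(stops),
                       np.array(labels, dtype=object))


# ---------------------------------------------------------------------------
# SWR detection

def detect_swr(lfp: LFPRecord, deep_channel: int, superficial_channel: int,
               config: DetectionConfig | None = None) -> IntervalSet:
    """Sharp wave-ripple events: coincidence of a deep sharp wave and a ripple.

    Sharp waves are 2.5-std negative deflections of the 2-50 Hz deep
    signal kept if 20-500 ms; ripples are 2.5-std excursions of smoothed
    80-250 Hz band power on the superficial channel kept if >= 25 ms;
    overlapping pairs are merged into SWR intervals.
    """
    config = config or DetectionConfig()
    if deep_channel >= lfp.n_channels or superficial_channel >= lfp.n_channels:
        raise ValueError("deep/superficial channel index out of range")
    fs = lfp.rate
    sw = -bandpass(lfp.data[deep_channel].astype(float), config.band_sharp_wave, fs)
    sw_z = _zscore_in(sw, None)
    sw_events = intervals_from_mask(sw_z > config.swr_threshold_std, 1.0 / fs, "SW")
    sw_events = filter_by_duration(sw_events, *config.sharp_wave_limits)

    rip = bandpass(lfp.data[superficial_channel].astype(float), config.band_ripple, fs)
    rip_pow = _smooth(rip**2, config.ripple_smooth, fs)
    rip_z = _zscore_in(rip_pow, None)
    rip_events = intervals_from_mask(rip_z > config.swr_threshold_std, 1.0 / fs, "RIP")
    rip_events = filter_by_duration(rip_events, config.min_ripple)

    # merge coincident sharp-wave / ripple pairs into single SWR events
    starts, stops = [], []
    for s, e, _ in sw_events:
        j = np.flatnonzero((rip_events.starts < e) & (rip_events.stops > s))
        if len(j):
            starts.append(min(s, rip_events.starts[j].min()))
            stops.append(max(e, rip_events.stops[j].max()))
    if not starts:
        return IntervalSet.empty()
    # merge overlaps after union
    starts, stops = np.array(starts), np.array(stops)
    order = np.argsort(starts)
    m_starts, m_stops = [starts[order[0]]], [stops[order[0]]]
    for k in order[1:]:
        if starts[k] <= m_stops[-1]:
            m_stops[-1] = max(m_stops[-1], stops[k])
        else:
            m_starts.append(starts[k]); m_stops.append(stops[k])
    return IntervalSet(np.array(m_starts), np.array(m_stops),
                       np.full(len(m_starts), "SWR", dtype=object))


# ---------------------------------------------------------------------------
# delta-power stratification

def delta_conditioned_stats(states: IntervalSet, lfp: LFPRecord,
                            delta_channel: int, nrem: IntervalSet,
                            n_groups: int = 6,
                            config: DetectionConfig | None = None) -> list[dict]:
    """UP/DOWN duration statistics stratified by surrounding delta (1-4 Hz) power.

    Delta-band power is averaged over the 8 s window centered on each
    state and normalized to the median power during NREM; states are split
    into ``n_groups`` quantile groups of that value.
    """
    config = config or DetectionConfig()
    fs = lfp.rate
    delta = bandpass(lfp.data[delta_channel].astype(float), config.band_delta_power, fs)
    power = _smooth(delta**2, config.delta_context_window, fs)
    nrem_mask = nrem.contains(lfp.t)
    med = np.median(power[nrem_mask]) if nrem_mask.any() else np.median(power)
    if med <= 0:
        raise ValueError("median NREM delta power is zero")
    norm_power = power / med

    mids = (states.starts + states.stops) / 2.0
    idx = np.clip((mids * fs).astype(int), 0, lfp.n_samples - 1)
    state_power = norm_power[idx]
    qs = np.quantile(state_power, np.linspace(0, 1, n_groups + 1))
    qs[-1] += 1e-9
    groups = []
    for g in range(n_groups):
        sel = (state_power >= qs[g]) & (state_power < qs[g + 1])
        if not sel.any():
            continue
        sub = IntervalSet(states.starts[sel], states.stops[sel],
                          states.labels[sel])
        d_up = sub.durations("UP")
        d_down = sub.durations("DOWN")
        groups.append({
            "delta_range": (float(qs[g]), float(qs[g + 1])),
            "mean_delta": float(state_power[sel].mean()),
            "durations_up": d_up,
            "durations_down": d_down,
            "stats": _safe_stats(d_up, d_down),
        })
    return groups


def _safe_stats(d_up: np.ndarray, d_down: np.ndarray) -> DurationStats:
    def mcv(d):
        if len(d) == 0:
            return np.nan, np.nan
        if len(d) == 1:
            return float(d[0]), np.nan
        return float(d.mean()), float(d.std() / d.mean())
    mu_u, cv_u = mcv(d_up)
    mu_d, cv_d = mcv(d_down)
    return DurationStats(mean_up=mu_u, mean_down=mu_d, cv_up=cv_u, cv_down=cv_d,
                         ratio=mu_u / mu_d if np.isfinite(mu_u) and np.isfinite(mu_d) else np.nan,
                         n_up=len(d_up), n_down=len(d_down))
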