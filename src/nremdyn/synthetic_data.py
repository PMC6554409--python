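"""Ground-truthed synthetic recordings.

Generates LFP + spike-raster recordings with the statistical structure the
detectors rely on, so every pipeline stage is testable without any real
data: 1250 Hz field signals with delta-band deflections during silent DOWN
states, broadband high-gamma during active UP states, ripple-band
transients riding deep sharp waves for SWRs, and inhomogeneous-Poisson
spike rasters whose rates collapse during DOWN states.  No biophysical
forward model is attempted -- the point is controllable ground truth.

Stable (long) states default to lognormal durations and transient (brief)
states to gamma durations, echoing the asymmetric in-vivo distributions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .intervals import IntervalSet
from .match import DurationSample

__all__ = ["SynthConfig", "SynthRecording", "synth_durations",
           "synth_updown_recording", "synth_swr_recording"]

_SUPPORTED = ("fixed", "exponential", "gamma", "lognormal")


def _draw(spec: tuple, n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw n positive durations from (name, mean, cv)."""
    name, mean, cv = spec
    if name not in _SUPPORTED:
        raise ValueError(f"unsupported distribution {name!r}; supported: {_SUPPORTED}")
    if mean <= 0:
        raise ValueError("duration mean must be positive")
    if name == "fixed":
        return np.full(n, float(mean))
    if name == "exponential":
        return rng.exponential(mean, n)
    if name == "gamma":
        shape = 1.0 / cv**2
        return rng.gamma(shape, mean / shape, n)
    sig2 = np.log(1.0 + cv**2)
    mu = np.log(mean) - sig2 / 2.0
    return rng.lognormal(mu, np.sqrt(sig2), n)


def synth_durations(up_spec: tuple = ("lognormal", 1.7, 1.1),
                    down_spec: tuple = ("gamma", 0.21, 0.38),
                    n: int = 1000, seed: int = 0, units: str = "s") -> DurationSample:
    """Reproducible parametric UP/DOWN duration sample."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    return DurationSample(_draw(up_spec, n, rng), _draw(down_spec, n, rng), units=units)


@dataclass(frozen=True)
class SynthConfig:
    duration_s: float = 120.0
    lfp_rate: float = 1250.0
    n_channels: int = 1
    n_units: int = 20
    up_rate_hz: float = 5.0         # per-unit rate during UP / outside NREM
    down_rate_hz: float = 0.0       # per-unit rate during DOWN
    up_duration: tuple = ("lognormal", 1.7, 1.1)
    down_duration: tuple = ("gamma", 0.21, 0.38)
    delta_amp: float = 4.0          # DOWN-state delta deflection, noise-floor std units
    gamma_amp: float = 1.5          # UP-state high-gamma amplitude
    noise_floor: float = 1.0
    # SWR generation
    swr_rate_hz: float = 0.5
    swr_duration: tuple = ("gamma", 0.06, 0.33)
    inter_swr: tuple | None = None   # default: exponential with mean 1/rate
    ripple_freq_hz: float = 150.0
    ripple_amp: float = 4.0
    sharp_amp: float = 4.0
    swr_unit_rate_hz: float = 25.0   # per-unit rate inside an SWR
    baseline_rate_hz: float = 1.0    # per-unit rate between SWRs
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration_s <= 1.0:
            raise ValueError("recording too short")
        if self.up_rate_hz < 0 or self.down_rate_hz < 0:
            raise ValueError("rates must be non-negative")
        if not (80.0 <= self.ripple_freq_hz <= 250.0):
            raise ValueError("ripple frequency must lie in the 80-250 Hz band")


@dataclass
class SynthRecording:
    lfp: "object"
    spikes: "object"
    states: IntervalSet
    nrem: IntervalSet


def _alternating_tiling(cfg: SynthConfig, rng: np.random.Generator,
                        t0: float, t1: float) -> IntervalSet:
    starts, stops, labels = [], [], []
    t = t0
    state = "UP"
    while t < t1:
        spec = cfg.up_duration if state == "UP" else cfg.down_duration
        d = float(_draw(spec, 1, rng)[0])
        end = min(t + d, t1)
        starts.append(t); stops.append(end); labels.append(state)
        t = end
        state = "DOWN" if state == "UP" else "UP"
    return IntervalSet(np.array(starts), np.array(stops),
                       np.array(labels, dtype=object))


def _poisson_spikes(rate_fn, t1: float, rng: np.random.Generator,
                    lam_max: float | None = None) -> np.ndarray:
    """Inhomogeneous Poisson by exact thinning of a homogeneous process."""
    if lam_max is None:
        probe = rate_fn(np.linspace(0.0, t1, 10_000))
        lam_max = float(probe.max())
    if lam_max <= 0:
        return np.empty(0)
    n = rng.poisson(lam_max * t1)
    cand = np.sort(rng.random(n) * t1)
    keep = rng.random(n) < rate_fn(cand) / lam_max
    return cand[keep]


def _hann_deflection(n: int) -> np.ndarray:
    return np.hanning(max(n, 3))


def synth_updown_recording(cfg: SynthConfig,
                           nrem_epochs: IntervalSet | None = None) -> SynthRecording:
    """Neocortex-like recording: UP/DOWN tiling, delta peaks + spike silence in DOWN.

    Channel 0 carries the DOWN-locked delta deflections and UP-locked
    gamma; additional channels are noise only.  If ``nrem_epochs`` is given,
    UP/DOWN structure exists only inside those epochs and the rest of the
    recording is desynchronized (tonic spiking, broadband noise, no delta).
    """
    from .event_detect import LFPRecord, SpikeRaster

    rng = np.random.default_rng(cfg.seed)
    fs = cfg.lfp_rate
    n = int(cfg.duration_s * fs)
    if n < fs:
        raise ValueError("configuration yields an empty recording")
    if nrem_epochs is None:
        nrem_epochs = IntervalSet(np.array([0.0]), np.array([cfg.duration_s]),
                                  np.array(["NREM"], dtype=object))
    pieces = [_alternating_tiling(cfg, rng, s, e) for s, e, _ in nrem_epochs]
    states = IntervalSet(np.concatenate([p.starts for p in pieces]),
                         np.concatenate([p.stops for p in pieces]),
                         np.concatenate([p.labels for p in pieces]))

    lfp = rng.standard_normal((cfg.n_channels, n)) * cfg.noise_floor
    # UP-state gamma on channel 0: band-filtered noise gated by UP mask
    gamma_carrier = sps.sosfiltfilt(
        sps.butter(4, (100.0, 400.0), btype="bandpass", fs=fs, output="sos"),
        rng.standard_normal(n))
    gamma_carrier /= gamma_carrier.std() + 1e-12
    t_grid = np.arange(n) / fs
    up_mask = np.zeros(n, dtype=bool)
    down_sel = states.labels == "DOWN"
    for s, e, lab in states:
        k0, k1 = int(s * fs), int(e * fs)
        if lab == "UP":
            up_mask[k0:k1] = True
    outside = ~nrem_epochs.contains(t_grid)
    up_mask |= outside          # desynchronized epochs look UP-like (gamma on)
    lfp[0] += cfg.gamma_amp * cfg.noise_floor * gamma_carrier * up_mask

    # DOWN-state delta deflections on channel 0, variable amplitude
    for s, e in zip(states.starts[down_sel], states.stops[down_sel]):
        k0, k1 = int(s * fs), int(e * fs)
        if k1 <= k0 + 2:
            continue
        amp = cfg.delta_amp * cfg.noise_floor * rng.lognormal(0.0, 0.25)
        lfp[0, k0:k1] += amp * _hann_deflection(k1 - k0)[: k1 - k0]

    # spikes: per-state rates inside NREM, tonic UP rate outside
    down_starts = states.starts[down_sel]
    down_stops = states.stops[down_sel]

    def rate_fn(t):
        lam = np.full(t.shape, cfg.up_rate_hz)
        idx = np.searchsorted(down_starts, t, side="right") - 1
        ok = idx >= 0
        in_down = np.zeros(t.shape, dtype=bool)
        in_down[ok] = t[ok] < down_stops[idx[ok]]
        lam[in_down] = cfg.down_rate_hz
        return lam

    units = [_poisson_spikes(rate_fn, cfg.duration_s, rng) for _ in range(cfg.n_units)]
    classes = ["pE"] * int(0.8 * cfg.n_units) + ["pI"] * (cfg.n_units - int(0.8 * cfg.n_units))
    return SynthRecording(lfp=LFPRecord(lfp, rate=fs),
                          spikes=SpikeRaster(units, classes),
                          states=states, nrem=nrem_epochs)


def synth_swr_recording(cfg: SynthConfig) -> SynthRecording:
    """Hippocampus-like recording: deep sharp waves + superficial ripples + bursts.

    Channel 0 is the deep (below-pyramidal) channel carrying negative
    sharp-wave deflections; channel 1 is the superficial channel carrying
    the ripple oscillation.  Truth intervals are labeled SWR.
    """
    from .event_detect import LFPRecord, SpikeRaster

    rng = np.random.default_rng(cfg.seed)
    fs = cfg.lfp_rate
    n = int(cfg.duration_s * fs)
    # event times
    starts, stops = [], []
    if cfg.swr_rate_hz > 0:
        inter_spec = cfg.inter_swr or ("exponential", 1.0 / cfg.swr_rate_hz, 1.0)
        t = float(_draw(inter_spec, 1, rng)[0]) + 1.0
        while t < cfg.duration_s - 1.0:
            d = float(_draw(cfg.swr_duration, 1, rng)[0])
            d = max(d, 0.03)
            if t + d > cfg.duration_s - 0.5:
                break
            starts.append(t); stops.append(t + d)
            t = t + d + float(_draw(inter_spec, 1, rng)[0])
    lfp = rng.standard_normal((2, n)) * cfg.noise_floor
    for s, e in zip(starts, stops):
        k0, k1 = int(s * fs), int(e * fs)
        m = k1 - k0
        if m < 3:
            continue
        # near-flat envelope: the nominal duration is the detectable span
        env = sps.windows.tukey(m, alpha=0.25)
        lfp[0, k0:k1] -= cfg.sharp_amp * cfg.noise_floor * env
        tt = np.arange(m) / fs
        lfp[1, k0:k1] += cfg.ripple_amp * cfg.noise_floor * env * np.sin(
            2.0 * np.pi * cfg.ripple_freq_hz * tt)

    starts_a, stops_a = np.array(starts), np.array(stops)

    def rate_fn(t):
        lam = np.full(t.shape, cfg.baseline_rate_hz)
        idx = np.searchsorted(starts_a, t, side="right") - 1
        ok = idx >= 0
        in_ev = np.zeros(t.shape, dtype=bool)
        if len(starts_a):
            in_ev[ok] = t[ok] < stops_a[idx[ok]]
        lam[in_ev] = cfg.swr_unit_rate_hz
        return lam

    units = [_poisson_spikes(rate_fn, cfg.duration_s, rng) for _ in range(cfg.n_units)]
    truth = (IntervalSet(starts_a, stops_a, np.full(len(starts_a), "SWR", dtype=object))
             if len(starts_a) else IntervalSet.empty())
    nrem = IntervalSet(np.array([0.0]), np.array([cfg.duration_s]),
                       np.array(["NREM"], dtype=object))
    return SynthRecording(lfp=LFPRecord(lfp, rate=fs),
                          spikes=SpikeRaster(units), states=truth, nrem=nrem)
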