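"""Stochastic simulation of the rate models.

Input noise is an Ornstein-Uhlenbeck process realized by forward Euler on
its own grid (``dxi = -theta xi dt + sigma sqrt(2 theta dt) W``), held
piecewise-constant over each solver step.  The state equations are
integrated with a fixed-step Heun (explicit trapezoid) scheme at the noise
step; halving the solver step is supported for accuracy checks by
piecewise-constant resampling of the same noise realization.

Each trace is fully determined by (parameters, noise settings, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .params import EIParams, OUParams, RatePopParams, Sigmoid, ThresholdPowerLaw

__all__ = [
    "SimTrace",
    "PulseSpec",
    "ou_noise",
    "simulate_rate",
    "evoked_response",
    "evoked_probability",
]


@dataclass
class SimTrace:
    dt: float
    r: np.ndarray
    a: np.ndarray
    r_i: np.ndarray | None
    seed: int | None
    params: object

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.r)):
            raise FloatingPointError("non-finite rate samples in trace")

    @property
    def n(self) -> int:
        return len(self.r)

    @property
    def duration(self) -> float:
        return self.n * self.dt

    @property
    def t(self) -> np.ndarray:
        return np.arange(self.n) * self.dt

    def to_hdf5(self, path) -> None:
        import h5py

        with h5py.File(path, "w") as f:
            f.create_dataset("r", data=self.r)
            f.create_dataset("a", data=self.a)
            if self.r_i is not None:
                f.create_dataset("r_i", data=self.r_i)
            f.attrs["dt"] = self.dt
            if self.seed is not None:
                f.attrs["seed"] = self.seed
            f.attrs["params"] = repr(self.params)

    @classmethod
    def from_hdf5(cls, path) -> "SimTrace":
        import h5py

        with h5py.File(path, "r") as f:
            return cls(dt=float(f.attrs["dt"]), r=f["r"][:], a=f["a"][:],
                       r_i=f["r_i"][:] if "r_i" in f else None,
                       seed=int(f.attrs["seed"]) if "seed" in f.attrs else None,
                       params=None)

    def to_tsv(self, path) -> None:
        import pandas as pd

        cols = {"time": self.t, "r": self.r, "a": self.a}
        if self.r_i is not None:
            cols["r_i"] = self.r_i
        pd.DataFrame(cols).to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class PulseSpec:
    """A brief square drive perturbation."""

    amplitude: float
    onset: float
    width: float
    target: str = "r"       # r (2-var) | r_e | r_i

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError("pulse width must be positive")


def ou_noise(params: OUParams, n_steps: int, seed: int | np.random.Generator) -> np.ndarray:
    """Forward-Euler OU realization ``xi[k+1] = xi[k](1 - theta dt) + sigma sqrt(2 theta dt) N_k``."""
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if params.sigma == 0.0:
        return np.zeros(n_steps)
    from scipy.signal import lfilter

    incr = params.sigma * np.sqrt(2.0 * params.theta * params.dt) * rng.standard_normal(n_steps)
    # xi[k] = (1 - theta*dt) * xi[k-1] + incr[k], xi[-1] = 0
    return lfilter([1.0], [1.0, -(1.0 - params.theta * params.dt)], incr)


@njit(cache=False)
def _integrate_ra(n, dt, tau_r, tau_a, w, b, I, gr, hr, sr, ga, ha, sa,
                  xi, drive, r0, a0):
    r = np.empty(n + 1)
    a = np.empty(n + 1)
    r[0], a[0] = r0, a0
    for k in range(n):
        x = w * r[k] - b * a[k] + I + xi[k] + drive[k]
        fr = (-r[k] + sr / (1.0 + np.exp(-gr * (x - hr)))) / tau_r
        fa = (-a[k] + sa / (1.0 + np.exp(-ga * (r[k] - ha)))) / tau_a
        rp = r[k] + dt * fr
        ap = a[k] + dt * fa
        x2 = w * rp - b * ap + I + xi[k] + drive[k]
        fr2 = (-rp + sr / (1.0 + np.exp(-gr * (x2 - hr)))) / tau_r
        fa2 = (-ap + sa / (1.0 + np.exp(-ga * (rp - ha)))) / tau_a
        r[k + 1] = r[k] + 0.5 * dt * (fr + fr2)
        a[k + 1] = a[k] + 0.5 * dt * (fa + fa2)
    return r, a


@njit(cache=False)
def _integrate_ei(n, dt, tau_e, tau_i, tau_a, wee, wei, wie, wii, Ie, Ii, b,
                  ke, the, pe, ki, thi, pi, ga, ha, sa,
                  xie, xii, drive_e, drive_i, re0, ri0, a0):
    re = np.empty(n + 1)
    ri = np.empty(n + 1)
    a = np.empty(n + 1)
    re[0], ri[0], a[0] = re0, ri0, a0
    for k in range(n):
        xe = wee * re[k] - wei * ri[k] - b * a[k] + Ie + xie[k] + drive_e[k]
        xi_ = wie * re[k] - wii * ri[k] + Ii + xii[k] + drive_i[k]
        ze = xe - the
        zi = xi_ - thi
        fe = (-re[k] + (ke * ze**pe if ze > 0.0 else 0.0)) / tau_e
        fi = (-ri[k] + (ki * zi**pi if zi > 0.0 else 0.0)) / tau_i
        fa = (-a[k] + sa / (1.0 + np.exp(-ga * (re[k] - ha)))) / tau_a
        rep = re[k] + dt * fe
        rip = ri[k] + dt * fi
        ap = a[k] + dt * fa
        xe2 = wee * rep - wei * rip - b * ap + Ie + xie[k] + drive_e[k]
        xi2 = wie * rep - wii * rip + Ii + xii[k] + drive_i[k]
        ze2 = xe2 - the
        zi2 = xi2 - thi
        fe2 = (-rep + (ke * ze2**pe if ze2 > 0.0 else 0.0)) / tau_e
        fi2 = (-rip + (ki * zi2**pi if zi2 > 0.0 else 0.0)) / tau_i
        fa2 = (-ap + sa / (1.0 + np.exp(-ga * (rep - ha)))) / tau_a
        re[k + 1] = re[k] + 0.5 * dt * (fe + fe2)
        ri[k + 1] = ri[k] + 0.5 * dt * (fi + fi2)
        a[k + 1] = a[k] + 0.5 * dt * (fa + fa2)
    return re, ri, a


def _resample_pc(x: np.ndarray, dt_from: float, dt_to: float, n_to: int) -> np.ndarray:
    """Piecewise-constant resampling of a grid signal onto solver steps."""
    idx = np.minimum((np.arange(n_to) * dt_to / dt_from).astype(np.int64), len(x) - 1)
    return x[idx]


def simulate_rate(params: RatePopParams | EIParams, noise: OUParams | None,
                  duration: float, seed: int | None = 0, dt: float | None = None,
                  r0: float | None = None, a0: float | None = None,
                  drive: dict | None = None) -> SimTrace:
    """Integrate the 2-variable or E-I model with precomputed OU input noise.

    ``drive`` may map population names ("r"/"r_e"/"r_i") to extra-drive
    arrays on the solver grid (used for evoked-event protocols).
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    dt_noise = noise.dt if noise is not None else 0.1
    if dt is None:
        dt = dt_noise
    n = int(round(duration / dt))
    n_noise = int(round(duration / dt_noise)) + 1
    drive = drive or {}

    def _drive(name):
        arr = drive.get(name)
        if arr is None:
            return np.zeros(n)
        arr = np.asarray(arr, float)
        if len(arr) < n:
            arr = np.r_[arr, np.zeros(n - len(arr))]
        return arr[:n]

    if isinstance(params, RatePopParams):
        if noise is not None:
            xi = _resample_pc(ou_noise(noise, n_noise, seed if seed is not None else 0),
                              dt_noise, dt, n)
        else:
            xi = np.zeros(n)
        r_init = params.rate_max / 2 if r0 is None else r0
        a_init = float(params.a_inf(r_init)) if a0 is None else a0
        r, a = _integrate_ra(
            n, dt, params.tau_r, params.tau_a, params.w, params.b, params.I,
            params.r_inf.gain, params.r_inf.half, params.r_inf.sat,
            params.a_inf.gain, params.a_inf.half, params.a_inf.sat,
            xi, _drive("r"), r_init, a_init)
        if not (np.all(np.isfinite(r)) and np.all(np.isfinite(a))):
            raise FloatingPointError("numerical blow-up in rate-adaptation integration")
        return SimTrace(dt=dt, r=r, a=a, r_i=None, seed=seed, params=params)

    if isinstance(params, EIParams):
        if noise is not None:
            rng = np.random.default_rng(seed if seed is not None else 0)
            xie = _resample_pc(ou_noise(noise, n_noise, rng), dt_noise, dt, n)
            xii = _resample_pc(ou_noise(noise, n_noise, rng), dt_noise, dt, n)
        else:
            xie = np.zeros(n)
            xii = np.zeros(n)
        re0 = 0.0 if r0 is None else r0
        a_init = float(params.a_inf(re0)) if a0 is None else a0
        re, ri, a = _integrate_ei(
            n, dt, params.tau_e, params.tau_i, params.tau_a,
            params.w_ee, params.w_ei, params.w_ie, params.w_ii,
            params.I_e, params.I_i, params.b,
            params.io_e.gain, params.io_e.threshold, params.io_e.power,
            params.io_i.gain, params.io_i.threshold, params.io_i.power,
            params.a_inf.gain, params.a_inf.half, params.a_inf.sat,
            xie, xii, _drive("r_e"), _drive("r_i"), re0, 0.0, a_init)
        if not np.all(np.isfinite(re)):
            raise FloatingPointError("numerical blow-up in E-I integration")
        return SimTrace(dt=dt, r=re, a=a, r_i=ri, seed=seed, params=params)

    raise TypeError(f"unsupported parameter type {type(params)!r}")


def _transition_threshold(params) -> tuple[float, float, float]:
    """(resting rate, threshold rate, far-branch direction) for event flags."""
    if isinstance(params, RatePopParams):
        from .model_core import nullcline_folds, steady_states

        stable = [f for f in steady_states(params) if f.stable]
        if not stable:
            raise ValueError("evoked protocols need a model with a stable fixed point")
        fp = stable[0].r_star
        folds = nullcline_folds(params)
        if folds is None:
            raise ValueError("evoked protocols need a folded (excitable) model")
        lo, hi = folds
        return (fp, hi, +1.0) if fp < lo else (fp, lo, -1.0)
    # frozen-a portrait at the resting adaptation level provides the saddle
    from .ei_model import ei_fixed_points, ei_steady_states

    stable = [f for f in ei_steady_states(params) if f[3]]
    if not stable:
        raise ValueError("evoked protocols need a stable fixed point")
    re_fp, _, a_fp = stable[0][:3]
    portrait = ei_fixed_points(params, a_frozen=a_fp)
    saddles = [p for p in portrait.fixed_points if p.stability == "saddle"]
    if not saddles:
        raise ValueError("no saddle in the frozen-a phase plane; not excitable/bistable")
    thr = saddles[0].r_e
    return (re_fp, thr, +1.0 if re_fp < thr else -1.0)


def evoked_response(params, pulse: PulseSpec, noise: OUParams | None = None,
                    seed: int | None = 0, settle: float | None = None,
                    window_factor: float = 5.0):
    """Apply a brief drive pulse from rest; flag whether a state transition follows.

    The event flag is True iff the (excitatory) rate crosses to the far
    side of the middle branch / saddle within ``window_factor * tau_a`` of
    pulse onset.  Returns ``(trace, event_flag)``.
    """
    tau_a = params.tau_a
    settle = 10.0 * tau_a if settle is None else settle
    dt = noise.dt if noise is not None else 0.1
    duration = settle + pulse.onset + pulse.width + window_factor * tau_a + 5.0 * tau_a
    n = int(round(duration / dt))
    onset = settle + pulse.onset
    drive_arr = np.zeros(n)
    k0, k1 = int(onset / dt), int((onset + pulse.width) / dt)
    drive_arr[k0:k1] = pulse.amplitude
    rest, thr, direction = _transition_threshold(params)
    trace = simulate_rate(params, noise, duration, seed=seed,
                          r0=rest, drive={pulse.target: drive_arr})
    rate = trace.r
    w0 = k0
    w1 = min(n, int((onset + window_factor * tau_a) / dt))
    seg = rate[w0:w1 + 1]
    event = bool(np.any(seg > thr) if direction > 0 else np.any(seg < thr))
    return trace, event


def evoked_probability(params, noise: OUParams | None, pulse: PulseSpec,
                       amplitudes, n_trials: int = 100, seed: int = 0) -> np.ndarray:
    """Fraction of trials with an evoked transition, per pulse amplitude."""
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    amplitudes = np.asarray(amplitudes, float)
    out = np.zeros(len(amplitudes))
    rng = np.random.default_rng(seed)
    for i, amp in enumerate(amplitudes):
        p = PulseSpec(amplitude=float(amp), onset=pulse.onset, width=pulse.width,
                      target=pulse.target)
        hits = 0
        for _ in range(n_trials):
            _, ev = evoked_response(params, p, noise,
                                    seed=int(rng.integers(2**31 - 1)))
            hits += ev
        out[i] = hits / n_trials
    return out
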