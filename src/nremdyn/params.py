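"""Parameter containers for the adapting-population models.

The core model is a Wilson-Cowan-like rate equation for a recurrently
connected population ``r`` with slow spike-frequency adaptation ``a``::

    tau_r dr/dt = -r + R_inf(w*r - b*a + I + xi(t))
    tau_a da/dt = -a + A_inf(r)

``R_inf`` maps net input to steady-state population rate and ``A_inf`` maps
rate to steady-state adaptation; both are bounded, monotone sigmoids.  The
E-I extension (the adapting inhibition-stabilized network, aISN) replaces
``R_inf`` by threshold-power-law transfer functions for separate excitatory
and inhibitory populations, with adaptation acting on the excitatory one.

Default sigmoid shapes were calibrated so that the published operating
points land in their described dynamical regimes (see docs/methods.md).
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

__all__ = [
    "Sigmoid",
    "ThresholdPowerLaw",
    "RatePopParams",
    "EIParams",
    "OUParams",
    "load_config",
    "save_config",
]


@dataclass(frozen=True)
class Sigmoid:
    """Logistic transfer function ``sat / (1 + exp(-gain*(x - half)))``."""

    gain: float = 1.0
    half: float = 0.0
    sat: float = 1.0

    def __post_init__(self) -> None:
        if not (math.isfinite(self.gain) and math.isfinite(self.half) and math.isfinite(self.sat)):
            raise ValueError("sigmoid parameters must be finite")
        if self.gain <= 0 or self.sat <= 0:
            raise ValueError("sigmoid gain and saturation must be positive")

    def __call__(self, x):
        return self.sat / (1.0 + np.exp(-self.gain * (np.asarray(x, dtype=float) - self.half)))

    def deriv(self, x):
        y = self.__call__(x) / self.sat
        return self.sat * self.gain * y * (1.0 - y)

    def inverse(self, y):
        """Inverse on the open interval (0, sat)."""
        y = np.asarray(y, dtype=float)
        return self.half - np.log(self.sat / y - 1.0) / self.gain


@dataclass(frozen=True)
class ThresholdPowerLaw:
    """Transfer function ``gain * max(x - threshold, 0)**power``.

    Zero below threshold, supralinear above it -- the fluctuation-driven
    operating regime of cortical populations.
    """

    gain: float = 1.0
    threshold: float = 0.0
    power: float = 2.0

    def __post_init__(self) -> None:
        if self.gain <= 0 or self.power <= 0:
            raise ValueError("power-law gain and exponent must be positive")

    def __call__(self, x):
        z = np.maximum(np.asarray(x, dtype=float) - self.threshold, 0.0)
        return self.gain * z**self.power

    def deriv(self, x):
        z = np.maximum(np.asarray(x, dtype=float) - self.threshold, 0.0)
        return self.gain * self.power * z ** (self.power - 1.0)


#: Calibrated defaults: with these shapes the published operating points
#: (w=6.3, b=1, I=2.35) -> bistable, (w=6, b=1, I=2.4) -> excitable_down,
#: (w=6.28, b=1, I=2.64) -> excitable_up and (w=6, b=1, I=1.9) -> excitable_down.
DEFAULT_R_INF = Sigmoid(gain=1.0, half=4.9, sat=1.0)
DEFAULT_A_INF = Sigmoid(gain=8.0, half=0.4, sat=1.0)


@dataclass(frozen=True)
class RatePopParams:
    """Parameters of the two-variable rate + adaptation model.

    Times are in dimensionless model units; matching to seconds happens
    later through the time-scale factor of the duration-matching step.
    """

    w: float = 6.0          # recurrent excitation
    b: float = 1.0          # adaptation gain
    I: float = 2.4          # tonic drive
    tau_r: float = 1.0      # rate time constant
    tau_a: float = 20.0     # adaptation time constant (slow)
    r_inf: Sigmoid = DEFAULT_R_INF
    a_inf: Sigmoid = DEFAULT_A_INF

    def __post_init__(self) -> None:
        for name in ("w", "b", "I", "tau_r", "tau_a"):
            v = getattr(self, name)
            if not (isinstance(v, (int, float)) and math.isfinite(v)):
                raise ValueError(f"parameter {name!r} must be a finite number, got {v!r}")
        if self.w < 0 or self.b < 0:
            raise ValueError("w and b must be non-negative")
        if self.tau_r <= 0 or self.tau_a <= 0:
            raise ValueError("time constants must be strictly positive")
        if self.tau_a <= self.tau_r:
            raise ValueError("slow-adaptation assumption requires tau_a > tau_r")

    def replace(self, **kw) -> "RatePopParams":
        return dataclasses.replace(self, **kw)

    @property
    def rate_max(self) -> float:
        return self.r_inf.sat


#: Calibrated aISN defaults: excitatory weight w_e=4 (onto both populations),
#: inhibitory weight w_i=3 (onto E), weak I->I coupling, threshold power laws
#: with exponent 2.  At the default drive the network is Excitable_UP with a
#: spiral UP fixed point whose frozen-a phase plane is bistable (saddle +
#: separatrix).  See docs/methods.md for the calibration.
DEFAULT_IO_E = ThresholdPowerLaw(gain=0.1, threshold=1.0, power=2.0)
DEFAULT_IO_I = ThresholdPowerLaw(gain=0.1, threshold=1.0, power=2.0)
DEFAULT_A_INF_EI = Sigmoid(gain=8.0, half=0.4, sat=1.0)


@dataclass(frozen=True)
class EIParams:
    """Parameters of the adapting inhibition-stabilized network (aISN).

    Time constants are in milliseconds (tau_e = tau_i = 5 ms, tau_a = 200 ms
    at the published operating point).
    """

    w_ee: float = 4.0
    w_ei: float = 3.0
    w_ie: float = 4.0
    w_ii: float = 1.0
    I_e: float = 2.4
    I_i: float = 0.0
    b: float = 1.0
    tau_e: float = 5.0
    tau_i: float = 5.0
    tau_a: float = 200.0
    io_e: ThresholdPowerLaw = DEFAULT_IO_E
    io_i: ThresholdPowerLaw = DEFAULT_IO_I
    a_inf: Sigmoid = DEFAULT_A_INF_EI
    rate_max: float = 10.0   # admissible search range for fixed points

    def __post_init__(self) -> None:
        for name in ("w_ee", "w_ei", "w_ie", "w_ii"):
            if getattr(self, name) < 0:
                raise ValueError(f"synaptic weight {name!r} must be non-negative")
        if self.tau_e <= 0 or self.tau_i <= 0 or self.tau_a <= 0:
            raise ValueError("time constants must be strictly positive")
        if self.tau_a <= max(self.tau_e, self.tau_i):
            raise ValueError("slow-adaptation assumption requires tau_a >> tau_e, tau_i")

    def replace(self, **kw) -> "EIParams":
        return dataclasses.replace(self, **kw)


@dataclass(frozen=True)
class OUParams:
    """Ornstein-Uhlenbeck input noise ``dxi = -theta*xi*dt + sigma*sqrt(2*theta*dt)*W_t``."""

    theta: float = 0.05     # inverse correlation time
    sigma: float = 0.25     # stationary standard deviation
    dt: float = 0.1         # noise grid step

    def __post_init__(self) -> None:
        if not (self.theta > 0):
            raise ValueError("ou theta must be positive")
        if self.sigma < 0:
            raise ValueError("ou sigma must be non-negative")
        if not (self.dt > 0):
            raise ValueError("noise grid step must be positive")


# ---------------------------------------------------------------------------
# config file round trip (flat YAML; keys mirror the dataclass fields)

_SHAPE_TYPES = {"sigmoid": Sigmoid, "threshold_power_law": ThresholdPowerLaw}


def _encode(obj):
    if isinstance(obj, Sigmoid):
        return {"kind": "sigmoid", **dataclasses.asdict(obj)}
    if isinstance(obj, ThresholdPowerLaw):
        return {"kind": "threshold_power_law", **dataclasses.asdict(obj)}
    return obj


def _decode(value):
    if isinstance(value, dict) and "kind" in value:
        kind = value.pop("kind")
        return _SHAPE_TYPES[kind](**value)
    return value


_PARAM_TYPES = {"rate_pop": RatePopParams, "ei": EIParams, "ou": OUParams}


def save_config(path: str | Path, **sections) -> None:
    """Write parameter sets to a YAML config, e.g. ``save_config(p, rate_pop=params, ou=noise)``."""
    doc = {}
    for name, params in sections.items():
        if name not in _PARAM_TYPES:
            raise KeyError(f"unknown config section {name!r}; expected one of {sorted(_PARAM_TYPES)}")
        doc[name] = {k: _encode(v) for k, v in dataclasses.asdict(params).items()}
        # asdict flattens nested dataclasses to dicts; re-encode shape fields
        for k, v in list(doc[name].items()):
            if isinstance(v, dict) and "kind" not in v:
                if "power" in v:
                    doc[name][k] = {"kind": "threshold_power_law", **v}
                else:
                    doc[name][k] = {"kind": "sigmoid", **v}
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=True))


def load_config(path: str | Path) -> dict:
    """Read a YAML config written by :func:`save_config` (or hand-authored)."""
    doc = yaml.safe_load(Path(path).read_text())
    out = {}
    for name, fields_ in doc.items():
        if name not in _PARAM_TYPES:
            raise KeyError(f"unknown config section {name!r}; expected one of {sorted(_PARAM_TYPES)}")
        kwargs = {k: _decode(v) for k, v in fields_.items()}
        out[name] = _PARAM_TYPES[name](**kwargs)
    return out
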