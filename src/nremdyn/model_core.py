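"""Deterministic analysis of the rate-adaptation model.

Fixed points of::

    r = R_inf(w*r - b*A_inf(r) + I),    a = A_inf(r)

their linear stability, the effective input/output curve r_ss(I), and the
classification of the four UP/DOWN regimes (oscillatory, bistable,
Excitable_UP, Excitable_DOWN).  Alternation dynamics require a folded
(S-shaped) r-nullcline; the two fold rates split it into a DOWN branch, a
middle (unstable) branch and an UP branch.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.optimize import brentq

from .params import RatePopParams

__all__ = [
    "FixedPoint",
    "IOCurve",
    "REGIMES",
    "steady_states",
    "classify_regime",
    "nullcline_folds",
    "io_curve",
    "regime_map",
    "write_regime_map",
]

REGIMES = ("oscillatory", "bistable", "excitable_up", "excitable_down",
           "monostable_no_alternations")

_GRID_N = 2000
_ROOT_XTOL = 1e-10


@dataclass(frozen=True)
class FixedPoint:
    r_star: float
    a_star: float
    branch: str                 # DOWN | middle | UP | unlabeled
    stability: str              # stable_node | stable_spiral | saddle | unstable_node | unstable_spiral
    eigenvalues: tuple

    @property
    def stable(self) -> bool:
        return self.stability.startswith("stable")


@dataclass
class IOCurve:
    drive: np.ndarray                  # drive grid
    branches: list                     # per drive: list of (r_ss, stable: bool)
    saddle_nodes: list                 # drive values where the fixed-point count changes
    hopf_points: list                  # drive values where stability flips along a branch
    shape: str                         # monotonic_stable | oscillatory_centered | bistable_centered


def _g(params: RatePopParams, r):
    return r - params.r_inf(params.w * r - params.b * params.a_inf(r) + params.I)


def _jacobian(params: RatePopParams, r: float) -> np.ndarray:
    x = params.w * r - params.b * params.a_inf(r) + params.I
    rp = float(params.r_inf.deriv(x))
    ap = float(params.a_inf.deriv(r))
    return np.array([
        [(-1.0 + rp * params.w) / params.tau_r, -params.b * rp / params.tau_r],
        [ap / params.tau_a, -1.0 / params.tau_a],
    ])


def _stability_label(eig: np.ndarray) -> str:
    re = eig.real
    if np.iscomplexobj(eig) and abs(eig[0].imag) > 1e-12:
        return "stable_spiral" if re.max() < 0 else "unstable_spiral"
    if re[0] * re[1] < 0:
        return "saddle"
    return "stable_node" if re.max() < 0 else "unstable_node"


def nullcline_folds(params: RatePopParams) -> tuple[float, float] | None:
    """Fold rates of the r-nullcline, or None when it is unfolded.

    Along the r-nullcline a(r) = (w*r + I - R_inf^{-1}(r)) / b; folds occur
    where w = d R_inf^{-1}/dr, i.e. for a logistic R_inf where
    r (sat - r) = sat / (gain * w).
    """
    g, sat = params.r_inf.gain, params.r_inf.sat
    if params.b == 0 or g * params.w * sat <= 4.0:
        return None
    d = np.sqrt(1.0 - 4.0 / (g * params.w * sat))
    return (sat * (1.0 - d) / 2.0, sat * (1.0 + d) / 2.0)


def _branch_of(r: float, folds) -> str:
    if folds is None:
        return "unlabeled"
    lo, hi = folds
    if r < lo:
        return "DOWN"
    if r > hi:
        return "UP"
    return "middle"


def steady_states(params: RatePopParams) -> list[FixedPoint]:
    """All fixed points in the admissible rate range, sorted by rate.

    Roots of ``g(r) = r - R_inf(w r - b A_inf(r) + I)`` are bracketed by a
    dense sign-change scan over [0, sat(R_inf)] and refined by Brent's
    method; stability comes from the eigenvalues of the full 2D Jacobian.
    """
    rmax = params.rate_max
    rs = np.linspace(0.0, rmax, _GRID_N + 1)
    gv = _g(params, rs)
    roots: list[float] = []
    for i in range(len(rs) - 1):
        if gv[i] == 0.0:
            roots.append(float(rs[i]))
        elif gv[i] * gv[i + 1] < 0:
            roots.append(float(brentq(lambda r: float(_g(params, r)),
                                      rs[i], rs[i + 1], xtol=_ROOT_XTOL)))
    if gv[-1] == 0.0:
        roots.append(float(rs[-1]))
    folds = nullcline_folds(params)
    out = []
    for r in sorted(roots):
        eig = np.linalg.eigvals(_jacobian(params, r))
        out.append(FixedPoint(
            r_star=r,
            a_star=float(params.a_inf(r)),
            branch=_branch_of(r, folds),
            stability=_stability_label(eig),
            eigenvalues=(complex(eig[0]), complex(eig[1])),
        ))
    return out


def limit_cycle_probe(params: RatePopParams, n_periods_required: int = 5,
                      rel_tol: float = 0.05) -> bool:
    """Detect a stable limit cycle by noise-free simulation.

    Integrates for 50*tau_a from a perturbed start and declares a cycle if
    at least ``n_periods_required`` consecutive inter-peak intervals of r(t)
    agree within ``rel_tol``.
    """
    from .simulate import simulate_rate  # deferred: simulate imports params only

    fps = steady_states(params)
    if fps:
        start = (min(fps, key=lambda f: f.r_star).r_star + 0.2 * params.rate_max,
                 None)
        r0 = min(start[0], params.rate_max)
    else:  # pragma: no cover - g always has a root for bounded sigmoids
        r0 = params.rate_max / 2
    trace = simulate_rate(params, noise=None, duration=50.0 * params.tau_a,
                          seed=0, r0=r0, a0=0.0)
    r = trace.r
    # discard the first 10*tau_a transient
    skip = int(10.0 * params.tau_a / trace.dt)
    r = r[skip:]
    span = r.max() - r.min()
    if span < 0.05 * params.rate_max:
        return False
    mid = (r.max() + r.min()) / 2.0
    above = r > mid
    up_cross = np.flatnonzero(~above[:-1] & above[1:])
    if len(up_cross) < n_periods_required + 1:
        return False
    periods = np.diff(up_cross[-(n_periods_required + 1):]).astype(float)
    return bool(np.all(np.abs(periods - periods.mean()) <= rel_tol * periods.mean()))


def classify_regime(params: RatePopParams) -> str:
    """Label the UP/DOWN regime from the fixed-point structure.

    oscillatory: no stable fixed point (stable limit cycle, confirmed by a
    deterministic probe); bistable: one stable point on each outer branch;
    excitable_up/down: a single stable point on the UP/DOWN branch of a
    folded r-nullcline; otherwise monostable_no_alternations.
    """
    fps = steady_states(params)
    stable = [f for f in fps if f.stable]
    folds = nullcline_folds(params)
    if len(stable) == 0:
        if limit_cycle_probe(params):
            return "oscillatory"
        return "oscillatory"  # bounded planar flow with no stable FP must cycle
    if len(stable) >= 2:
        return "bistable"
    fp = stable[0]
    if folds is not None:
        if fp.branch == "UP":
            return "excitable_up"
        if fp.branch == "DOWN":
            return "excitable_down"
    return "monostable_no_alternations"


def io_curve(params: RatePopParams, drive_range: tuple[float, float],
             n_points: int = 201) -> IOCurve:
    """Fixed-point branches of r_ss versus tonic drive I.

    Saddle-node bifurcations are located where the fixed-point count
    changes between neighbouring grid drives; Hopf points where the
    stability of a tracked non-saddle branch flips.  The shape label
    follows the regime at the curve's centre (where r_ss crosses half
    saturation): bistable there -> bistable_centered, oscillatory there ->
    oscillatory_centered, a single stable branch everywhere ->
    monotonic_stable.
    """
    if n_points < 2:
        raise ValueError("n_points must be >= 2")
    drives = np.linspace(drive_range[0], drive_range[1], n_points)
    branches = []
    counts = []
    for I in drives:
        fps = steady_states(params.replace(I=float(I)))
        branches.append([(f.r_star, f.stable) for f in fps])
        counts.append(len(fps))
    if not any(counts):
        raise ValueError("no fixed points found anywhere in the drive range")

    saddle_nodes = [float((drives[i] + drives[i + 1]) / 2)
                    for i in range(n_points - 1) if counts[i] != counts[i + 1]]

    hopf_points = []
    for i in range(n_points - 1):
        if counts[i] == 1 and counts[i + 1] == 1:
            if branches[i][0][1] != branches[i + 1][0][1]:
                hopf_points.append(float((drives[i] + drives[i + 1]) / 2))
        elif counts[i] == counts[i + 1] and counts[i] > 1:
            # compare stability of lowest and highest branches
            for sel in (0, -1):
                if branches[i][sel][1] != branches[i + 1][sel][1]:
                    hopf_points.append(float((drives[i] + drives[i + 1]) / 2))

    shape = _io_shape(params, drives, branches)
    return IOCurve(drives, branches, saddle_nodes, sorted(set(hopf_points)), shape)


def _io_shape(params: RatePopParams, drives, branches) -> str:
    half = params.rate_max / 2.0
    multi = any(len(br) > 1 for br in branches)
    unstable_single = any(len(br) == 1 and not br[0][1] for br in branches)
    if not multi and not unstable_single:
        return "monotonic_stable"
    # centre cell: the drive whose fixed-point set straddles half activation
    centre = None
    for I, br in zip(drives, branches):
        rs = [r for r, _ in br]
        if min(rs) <= half <= max(rs) or any(abs(r - half) < 0.1 * params.rate_max for r in rs):
            centre = (I, br)
            break
    if centre is None:
        return "bistable_centered" if multi else "oscillatory_centered"
    _, br = centre
    n_stable = sum(1 for _, s in br if s)
    if n_stable >= 2:
        return "bistable_centered"
    if n_stable == 0:
        return "oscillatory_centered"
    # single stable point at centre but folds/instability elsewhere
    return "bistable_centered" if multi else "oscillatory_centered"


_AXES = ("I", "w", "b")


def regime_map(base: RatePopParams, axis1: tuple[str, np.ndarray],
               axis2: tuple[str, np.ndarray]) -> np.ndarray:
    """Grid of regime labels over two parameter axes chosen from (I, w, b).

    Returns an object array of shape (len(grid1), len(grid2)).
    """
    (name1, grid1), (name2, grid2) = axis1, axis2
    for name in (name1, name2):
        if name not in _AXES:
            raise ValueError(f"axis {name!r} not supported; choose from {_AXES}")
    grid1, grid2 = np.asarray(grid1, float), np.asarray(grid2, float)
    if grid1.size == 0 or grid2.size == 0:
        raise ValueError("regime map grids must be non-empty")
    out = np.empty((grid1.size, grid2.size), dtype=object)
    for i, v1 in enumerate(grid1):
        for j, v2 in enumerate(grid2):
            out[i, j] = classify_regime(base.replace(**{name1: float(v1), name2: float(v2)}))
    return out


def write_regime_map(path_tsv: str | Path, path_json: str | Path,
                     axis1, axis2, labels: np.ndarray,
                     bifurcations: dict | None = None) -> None:
    """Write a regime map as TSV (axis1, axis2, regime) plus a JSON summary."""
    (name1, grid1), (name2, grid2) = axis1, axis2
    with open(path_tsv, "w") as fh:
        fh.write(f"{name1}\t{name2}\tregime\n")
        for i, v1 in enumerate(np.asarray(grid1)):
            for j, v2 in enumerate(np.asarray(grid2)):
                fh.write(f"{v1:g}\t{v2:g}\t{labels[i, j]}\n")
    summary = {
        "axes": {name1: list(map(float, grid1)), name2: list(map(float, grid2))},
        "regime_counts": {lab: int((labels == lab).sum()) for lab in REGIMES},
        "bifurcations": bifurcations or {},
    }
    Path(path_json).write_text(json.dumps(summary, indent=2))
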