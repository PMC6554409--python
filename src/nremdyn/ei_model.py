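"""The adapting inhibition-stabilized network (aISN).

With adaptation frozen (it is slow relative to the population time
constants), the E-I subsystem::

    tau_e dr_e/dt = -r_e + R_e(w_ee r_e - w_ei r_i - b a + I_e)
    tau_i dr_i/dt = -r_i + R_i(w_ie r_e - w_ii r_i + I_i)

is analyzed in the r_e-r_i phase plane: fixed points, stability, the
effective I/O curve of the excitatory rate versus drive, and, when UP and
DOWN states coexist, the separatrix between their basins of attraction
(grown by reverse-time integration from the saddle).  The full
three-variable system (a dynamic, tau_a da/dt = -a + A_inf(r_e)) is
classified into the same UP/DOWN regimes as the two-variable model by
intersecting the effective I/O curve with the adaptation nullcline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

from .params import EIParams

__all__ = [
    "EIFixedPoint",
    "EIPhasePortrait",
    "ei_fixed_points",
    "ei_effective_io",
    "ei_separatrix",
    "separatrix_side",
    "ei_regime",
    "ei_steady_states",
]

_GRID_N = 1200


@dataclass(frozen=True)
class EIFixedPoint:
    r_e: float
    r_i: float
    stability: str           # as in model_core
    eigenvalues: tuple

    @property
    def stable(self) -> bool:
        return self.stability.startswith("stable")

    @property
    def spiral(self) -> bool:
        return self.stability.endswith("spiral")


@dataclass
class EIPhasePortrait:
    a_frozen: float
    fixed_points: list
    separatrix: np.ndarray | None = None    # (k, 2) polyline in (r_e, r_i)


def _ri_star_vec(params: EIParams, r_e: np.ndarray) -> np.ndarray:
    """Unique inhibitory fixed rate(s) given r_e (negative self-feedback).

    ``f(ri) = ri - R_i(w_ie r_e - w_ii ri + I_i)`` is strictly increasing in
    ri, so the root is unique; solved by vectorized bisection.
    """
    r_e = np.atleast_1d(np.asarray(r_e, dtype=float))
    drive = params.w_ie * r_e + params.I_i
    lo = np.zeros_like(r_e)
    hi = np.maximum(np.asarray(params.io_i(drive), dtype=float), 1e-9)
    # io_i(drive - w_ii*ri) <= io_i(drive), so ri* <= io_i(drive): hi brackets
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        fmid = mid - params.io_i(drive - params.w_ii * mid)
        lo = np.where(fmid < 0, mid, lo)
        hi = np.where(fmid < 0, hi, mid)
    return 0.5 * (lo + hi)


def _ri_star(params: EIParams, r_e: float) -> float:
    return float(_ri_star_vec(params, np.array([r_e]))[0])


def _jac_frozen(params: EIParams, r_e: float, r_i: float, a: float) -> np.ndarray:
    xe = params.w_ee * r_e - params.w_ei * r_i - params.b * a + params.I_e
    xi = params.w_ie * r_e - params.w_ii * r_i + params.I_i
    rep = float(params.io_e.deriv(xe))
    rip = float(params.io_i.deriv(xi))
    return np.array([
        [(-1.0 + rep * params.w_ee) / params.tau_e, -rep * params.w_ei / params.tau_e],
        [rip * params.w_ie / params.tau_i, (-1.0 - rip * params.w_ii) / params.tau_i],
    ])


def _stability_label(eig: np.ndarray) -> str:
    re = eig.real
    if abs(eig[0].imag) > 1e-12:
        return "stable_spiral" if re.max() < 0 else "unstable_spiral"
    if re[0] * re[1] < 0:
        return "saddle"
    return "stable_node" if re.max() < 0 else "unstable_node"


def ei_fixed_points(params: EIParams, a_frozen: float) -> EIPhasePortrait:
    """All fixed points of the frozen-adaptation E-I system with stability."""
    if a_frozen < 0:
        raise ValueError("a_frozen must be non-negative")
    res = np.linspace(0.0, params.rate_max, _GRID_N + 1)

    def g(r_e: float) -> float:
        ri = _ri_star(params, r_e)
        xe = params.w_ee * r_e - params.w_ei * ri - params.b * a_frozen + params.I_e
        return r_e - float(params.io_e(xe))

    ri_grid = _ri_star_vec(params, res)
    gv = res - params.io_e(params.w_ee * res - params.w_ei * ri_grid
                           - params.b * a_frozen + params.I_e)
    roots = []
    for i in range(len(res) - 1):
        if gv[i] == 0.0:
            roots.append(float(res[i]))
        elif gv[i] * gv[i + 1] < 0:
            roots.append(float(brentq(g, res[i], res[i + 1], xtol=1e-12)))
    fps = []
    for re_ in sorted(roots):
        ri = _ri_star(params, re_)
        eig = np.linalg.eigvals(_jac_frozen(params, re_, ri, a_frozen))
        fps.append(EIFixedPoint(re_, ri, _stability_label(eig),
                                (complex(eig[0]), complex(eig[1]))))
    return EIPhasePortrait(a_frozen=a_frozen, fixed_points=fps)


def ei_effective_io(params: EIParams, drive_range: tuple[float, float],
                    n_points: int = 161, a_frozen: float = 0.0):
    """Effective I/O curve r_ss(I_e) of the frozen-a system (IOCurve container)."""
    from .model_core import IOCurve

    if n_points < 2:
        raise ValueError("n_points must be >= 2")
    drives = np.linspace(drive_range[0], drive_range[1], n_points)
    branches = []
    counts = []
    for Ie in drives:
        p = params.replace(I_e=float(Ie))
        pp = ei_fixed_points(p, a_frozen)
        branches.append([(f.r_e, f.stable) for f in pp.fixed_points])
        counts.append(len(pp.fixed_points))
    saddle_nodes = [float((drives[i] + drives[i + 1]) / 2)
                    for i in range(n_points - 1) if counts[i] != counts[i + 1]]
    hopf = []
    for i in range(n_points - 1):
        if counts[i] == 1 and counts[i + 1] == 1 and branches[i][0][1] != branches[i + 1][0][1]:
            hopf.append(float((drives[i] + drives[i + 1]) / 2))
    multi = any(c > 1 for c in counts)
    unstable_single = any(c == 1 and not br[0][1] for c, br in zip(counts, branches))
    if multi:
        shape = "bistable_centered"
    elif unstable_single:
        shape = "oscillatory_centered"
    else:
        shape = "monotonic_stable"
    return IOCurve(drives, branches, saddle_nodes, hopf, shape)


def _flow(params: EIParams, a: float):
    def f(t, y):
        re_, ri = y
        xe = params.w_ee * re_ - params.w_ei * ri - params.b * a + params.I_e
        xi = params.w_ie * re_ - params.w_ii * ri + params.I_i
        return [(-re_ + float(params.io_e(xe))) / params.tau_e,
                (-ri + float(params.io_i(xi))) / params.tau_i]
    return f


def ei_separatrix(params: EIParams, a_frozen: float,
                  box: float | None = None, max_time: float = 2000.0) -> EIPhasePortrait:
    """Basin boundary of the bistable frozen-a system.

    Reverse-time trajectories are launched from +/- 1e-6 along the saddle's
    stable eigenvector and integrated until they leave the phase-plane
    bounding box; the concatenated polyline is the separatrix.
    """
    portrait = ei_fixed_points(params, a_frozen)
    saddles = [f for f in portrait.fixed_points if f.stability == "saddle"]
    if not saddles:
        labels = [f.stability for f in portrait.fixed_points]
        raise ValueError(f"no saddle in frozen-a phase plane (fixed points: {labels}); "
                         "the system is not bistable at this adaptation level")
    saddle = saddles[0]
    J = _jac_frozen(params, saddle.r_e, saddle.r_i, a_frozen)
    eigval, eigvec = np.linalg.eig(J)
    stable_dir = eigvec[:, int(np.argmin(eigval.real))].real
    stable_dir /= np.linalg.norm(stable_dir)
    if box is None:
        box = max(2.0 * max(abs(f.r_e) for f in portrait.fixed_points) + 1.0, 5.0)
    f = _flow(params, a_frozen)
    rev = lambda t, y: [-v for v in f(t, y)]

    def leave_box(t, y):
        return box - max(abs(y[0]), abs(y[1]))
    leave_box.terminal = True

    pieces = []
    for sgn in (+1.0, -1.0):
        y0 = np.array([saddle.r_e, saddle.r_i]) + sgn * 1e-6 * stable_dir
        sol = solve_ivp(rev, (0.0, max_time), y0, events=leave_box,
                        max_step=1.0, rtol=1e-8, atol=1e-10, dense_output=False)
        pieces.append(sol.y.T)
    poly = np.vstack([pieces[0][::-1], pieces[1]])
    portrait.separatrix = poly
    return portrait


def separatrix_side(portrait: EIPhasePortrait, point) -> str:
    """Classify a phase-plane point as 'UP' or 'DOWN' side of the separatrix.

    Uses the sign of the cross product with the nearest separatrix segment,
    oriented so the UP fixed point lies on the 'UP' side.
    """
    if portrait.separatrix is None:
        raise ValueError("portrait has no separatrix; call ei_separatrix")
    stable = sorted((f for f in portrait.fixed_points if f.stable), key=lambda f: f.r_e)
    if len(stable) < 2:
        raise ValueError("need both UP and DOWN fixed points to orient the separatrix")
    up_fp = np.array([stable[-1].r_e, stable[-1].r_i])

    def signed(p):
        poly = portrait.separatrix
        p = np.asarray(p, float)
        d2 = np.sum((poly - p) ** 2, axis=1)
        k = int(np.argmin(d2))
        k0 = max(0, min(k, len(poly) - 2))
        tang = poly[k0 + 1] - poly[k0]
        rel = p - poly[k0]
        return float(tang[0] * rel[1] - tang[1] * rel[0])

    ref = signed(up_fp)
    s = signed(point)
    return "UP" if s * ref > 0 else "DOWN"


def simulate_basin(params: EIParams, a_frozen: float, point,
                   t_max: float = 5000.0) -> str:
    """Forward-integrate the frozen-a system and report which attractor wins."""
    portrait = ei_fixed_points(params, a_frozen)
    stable = sorted((f for f in portrait.fixed_points if f.stable), key=lambda f: f.r_e)
    if len(stable) < 2:
        raise ValueError("frozen-a system is not bistable")
    f = _flow(params, a_frozen)
    sol = solve_ivp(f, (0.0, t_max), np.asarray(point, float), rtol=1e-8, atol=1e-10)
    end = sol.y[:, -1]
    d = [np.hypot(end[0] - fp.r_e, end[1] - fp.r_i) for fp in stable]
    return "UP" if int(np.argmin(d)) == len(stable) - 1 else "DOWN"


def ei_steady_states(params: EIParams):
    """Fixed points of the full 3-variable system as (r_e, r_i, a, stable, eigenvalues)."""
    res = np.linspace(0.0, params.rate_max, _GRID_N + 1)

    def g(r_e: float) -> float:
        ri = _ri_star(params, r_e)
        a = float(params.a_inf(r_e))
        xe = params.w_ee * r_e - params.w_ei * ri - params.b * a + params.I_e
        return r_e - float(params.io_e(xe))

    ri_grid = _ri_star_vec(params, res)
    gv = res - params.io_e(params.w_ee * res - params.w_ei * ri_grid
                           - params.b * params.a_inf(res) + params.I_e)
    roots = []
    for i in range(len(res) - 1):
        if gv[i] == 0.0:
            roots.append(float(res[i]))
        elif gv[i] * gv[i + 1] < 0:
            roots.append(float(brentq(g, res[i], res[i + 1], xtol=1e-12)))
    out = []
    for re_ in sorted(roots):
        ri = _ri_star(params, re_)
        a = float(params.a_inf(re_))
        J2 = _jac_frozen(params, re_, ri, a)
        xe = params.w_ee * re_ - params.w_ei * ri - params.b * a + params.I_e
        rep = float(params.io_e.deriv(xe))
        ap = float(params.a_inf.deriv(re_))
        J = np.zeros((3, 3))
        J[:2, :2] = J2
        J[0, 2] = -params.b * rep / params.tau_e
        J[2, 0] = ap / params.tau_a
        J[2, 2] = -1.0 / params.tau_a
        eig = np.linalg.eigvals(J)
        out.append((re_, ri, a, bool(np.all(eig.real < 0)), tuple(eig)))
    return out


def ei_regime(params: EIParams) -> str:
    """Classify the full aISN into the UP/DOWN regimes of the 2-variable model.

    The effective I/O curve r_ss(I_e) of the frozen-a system plays the role
    of the r-nullcline: its fold interval (in drive) defines DOWN/middle/UP
    branches, and the full-system fixed points (intersections with the
    adaptation curve) determine the regime.
    """
    fps = ei_steady_states(params)
    stable = [f for f in fps if f[3]]
    # fold structure of the effective I/O curve at a = 0 (drive offsets shift
    # with b*a but the fold rates in r_e do not)
    io = ei_effective_io(params, _auto_drive_range(params), n_points=121, a_frozen=0.0)
    folded = len(io.saddle_nodes) >= 2
    if len(stable) == 0:
        return "oscillatory"
    if len(stable) >= 2:
        return "bistable"
    if folded:
        lo_knee, hi_knee = _fold_rates(io)
        re_ = stable[0][0]
        if re_ > hi_knee:
            return "excitable_up"
        if re_ < lo_knee:
            return "excitable_down"
    return "monostable_no_alternations"


def _auto_drive_range(params: EIParams) -> tuple[float, float]:
    lo = params.io_e.threshold - 2.0
    return (lo, params.I_e + 4.0)


def _fold_rates(io) -> tuple[float, float]:
    """(upper rate of DOWN branch, lower rate of UP branch) across the fold."""
    lows, highs = [], []
    for br in io.branches:
        if len(br) >= 3:
            rs = sorted(r for r, _ in br)
            lows.append(rs[0])
            highs.append(rs[-1])
    if not lows:
        return (0.0, 0.0)
    return (max(lows), min(highs))
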