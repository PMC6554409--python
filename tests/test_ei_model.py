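"""Frozen-adaptation E-I analysis and the full aISN classification."""

import numpy as np
import pytest

from nremdyn.ei_model import (ei_effective_io, ei_fixed_points, ei_regime,
                              ei_separatrix, ei_steady_states, separatrix_side,
                              simulate_basin)
from nremdyn.model_core import steady_states
from nremdyn.params import EIParams, RatePopParams, Sigmoid, ThresholdPowerLaw

BISTABLE_FROZEN = EIParams(I_e=1.55)   # inside the frozen-a bistable drive window


def grid_oracle_fixed_points(params, a_frozen, n=25, box=3.0):
    """Independent 2D oracle: multistart root finding on the raw system."""
    from scipy.optimize import fsolve

    def resid(y):
        re_, ri = y
        ge = re_ - float(params.io_e(params.w_ee * re_ - params.w_ei * ri
                                     - params.b * a_frozen + params.I_e))
        gi = ri - float(params.io_i(params.w_ie * re_ - params.w_ii * ri + params.I_i))
        return [ge, gi]

    import warnings as _warnings

    roots = []
    for re0 in np.linspace(0, box, n):
        for ri0 in np.linspace(0, box, n):
            with _warnings.catch_warnings():
                _warnings.simplefilter("ignore")
                sol, info, ok, _ = fsolve(resid, [re0, ri0], full_output=True)
            if ok != 1 or np.max(np.abs(info["fvec"])) > 1e-9:
                continue
            if sol[0] < -1e-9 or sol[1] < -1e-9 or sol[0] > box:
                continue
            if all(abs(sol[0] - a) + abs(sol[1] - b) > 1e-4 for a, b in roots):
                roots.append((max(sol[0], 0.0), max(sol[1], 0.0)))
    return roots


class TestEIFixedPoints:
    def test_zero_weights_unique_forced_fixed_point(self):
        p = EIParams(w_ee=0, w_ei=0, w_ie=0, w_ii=0, I_e=2.0, I_i=1.5)
        pp = ei_fixed_points(p, a_frozen=0.5)
        assert len(pp.fixed_points) == 1
        f = pp.fixed_points[0]
        assert f.r_e == pytest.approx(float(p.io_e(2.0 - 0.5 * p.b)), abs=1e-8)
        assert f.r_i == pytest.approx(float(p.io_i(1.5)), abs=1e-8)
        assert f.stable

    def test_bistable_window_has_up_down_and_saddle(self):
        pp = ei_fixed_points(BISTABLE_FROZEN, a_frozen=0.0)
        stabs = [f.stability for f in pp.fixed_points]
        assert sum(f.stable for f in pp.fixed_points) == 2
        assert stabs.count("saddle") == 1
        # the UP state is inhibition-stabilized: an attracting spiral
        assert pp.fixed_points[-1].spiral

    def test_matches_dense_grid_oracle(self):
        rng = np.random.default_rng(17)
        for _ in range(20):
            p = EIParams(I_e=float(rng.uniform(0.5, 2.5)),
                         I_i=float(rng.uniform(-0.5, 0.5)),
                         w_ee=float(rng.uniform(2, 5)))
            a = float(rng.uniform(0, 1))
            found = [(f.r_e, f.r_i) for f in ei_fixed_points(p, a).fixed_points
                     if f.r_e < 3.0]
            oracle = grid_oracle_fixed_points(p, a)
            # two-way coverage: every solver root has a nearby oracle cell
            # and every oracle cell a nearby solver root
            for fe, fi in found:
                assert min(abs(fe - oe) + abs(fi - oi) for oe, oi in oracle) < 2e-2
            for oe, oi in oracle:
                assert min(abs(fe - oe) + abs(fi - oi) for fe, fi in found) < 2e-2


class TestEffectiveIO:
    def test_weak_recurrence_monotonic(self):
        p = EIParams(w_ee=0.5)
        io = ei_effective_io(p, (-1.0, 4.0), 51)
        assert io.shape == "monotonic_stable"

    def test_strong_recurrence_bistable_at_low_drive(self):
        io = ei_effective_io(EIParams(), (0.5, 2.5), 81)
        assert io.shape == "bistable_centered"
        assert len(io.saddle_nodes) >= 2
        # the fold interval brackets the frozen-a bistable window
        lo, hi = min(io.saddle_nodes), max(io.saddle_nodes)
        assert lo < 1.55 < hi

    def test_fold_drives_match_fixed_point_scan(self):
        io = ei_effective_io(EIParams(), (1.0, 2.0), 101)
        lo, hi = min(io.saddle_nodes), max(io.saddle_nodes)
        inside = EIParams(I_e=(lo + hi) / 2)
        below = EIParams(I_e=lo - 0.3)
        assert sum(f.stable for f in ei_fixed_points(inside, 0.0).fixed_points) == 2
        # below the lower fold only the DOWN state remains
        pp = ei_fixed_points(below, 0.0)
        assert sum(f.stable for f in pp.fixed_points) == 1
        assert pp.fixed_points[0].r_e < 0.3


class TestSeparatrix:
    def test_sides_and_forward_simulation_agree(self):
        p = BISTABLE_FROZEN
        portrait = ei_separatrix(p, a_frozen=0.0)
        stable = sorted([f for f in portrait.fixed_points if f.stable],
                        key=lambda f: f.r_e)
        up, down = stable[-1], stable[0]
        assert separatrix_side(portrait, (up.r_e, up.r_i)) == "UP"
        assert separatrix_side(portrait, (down.r_e, down.r_i)) == "DOWN"
        rng = np.random.default_rng(23)
        agree = 0
        n_pts = 60
        for _ in range(n_pts):
            pt = (float(rng.uniform(0, 1.2)), float(rng.uniform(0, 0.6)))
            if separatrix_side(portrait, pt) == simulate_basin(p, 0.0, pt):
                agree += 1
        assert agree / n_pts >= 0.95

    def test_rate_kick_across_separatrix_switches_basin(self):
        p = BISTABLE_FROZEN
        portrait = ei_separatrix(p, a_frozen=0.0)
        up = sorted([f for f in portrait.fixed_points if f.stable],
                    key=lambda f: f.r_e)[-1]
        assert simulate_basin(p, 0.0, (up.r_e, up.r_i)) == "UP"
        # a large enough increase of r_i from the UP state drives it DOWN
        assert simulate_basin(p, 0.0, (up.r_e, up.r_i + 1.5)) == "DOWN"

    def test_no_saddle_is_an_error_naming_the_structure(self):
        with pytest.raises(ValueError, match="saddle"):
            ei_separatrix(EIParams(I_e=3.5), a_frozen=0.0)


class TestEIRegime:
    def test_default_operating_point_is_excitable_up_with_spiral(self):
        p = EIParams()
        assert ei_regime(p) == "excitable_up"
        fps = [f for f in ei_steady_states(p) if f[3]]
        assert len(fps) == 1
        eig = np.array(fps[0][4])
        assert np.any(np.abs(eig.imag) > 0)           # attracting spiral:
        assert np.all(eig.real < 0)                   # damped E-I oscillation

    def test_zero_recurrence_monostable(self):
        assert ei_regime(EIParams(w_ee=0.0, w_ie=0.0)) == "monostable_no_alternations"

    def test_classification_matches_stochastic_branch_visits(self):
        """Regimes with alternations visit the DOWN branch under noise;
        monostable operating points never leave the UP branch."""
        from nremdyn.params import OUParams
        from nremdyn.simulate import simulate_rate

        cases = [(EIParams(I_e=2.4), True),
                 (EIParams(w_ee=0.5, w_ie=0.5, I_e=2.4), False)]
        for p, expect_alt in cases:
            trace = simulate_rate(p, OUParams(sigma=0.25), 60_000.0, seed=31)
            # alternating regimes occupy both the DOWN (<0.15) and the UP
            # (>0.4) branch; monostable dynamics stay in one band
            both = (trace.r < 0.15).mean() > 0.01 and (trace.r > 0.4).mean() > 0.05
            regime = ei_regime(p)
            if expect_alt:
                assert regime in ("excitable_up", "excitable_down",
                                  "bistable", "oscillatory")
                assert both
            else:
                assert regime == "monostable_no_alternations"
                assert not both


def test_removing_inhibition_reduces_to_two_variable_structure():
    """With w_ei = w_ie = 0 the E population decouples; its fixed points
    match a matched excitation-only model."""
    p = EIParams(w_ei=0.0, w_ie=0.0, I_e=1.4)
    ei_fps = sorted(f[0] for f in ei_steady_states(p))

    # matched 1-population system: r = io_e(w_ee r - b a + I_e), a = a_inf(r)
    from scipy.optimize import brentq

    def g(r):
        return r - float(p.io_e(p.w_ee * r - p.b * p.a_inf(r) + p.I_e))

    rs = np.linspace(0, 10, 4001)
    gv = np.array([g(r) for r in rs])
    roots = [brentq(g, rs[i], rs[i + 1]) for i in
             np.flatnonzero(np.sign(gv[:-1]) * np.sign(gv[1:]) < 0)]
    assert len(ei_fps) == len(roots)
    assert np.allclose(ei_fps, sorted(roots), atol=1e-6)
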