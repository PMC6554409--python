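"""Bimodality gate, sticky thresholds, hysteresis detection, duration stats."""

import warnings

import numpy as np
import pytest

from nremdyn.intervals import IntervalSet
from nremdyn.params import OUParams, RatePopParams
from nremdyn.simulate import SimTrace, simulate_rate
from nremdyn.state_detect import (bimodality_gate, detect_updown, duration_map,
                                  duration_stats, sticky_thresholds)


def _trace(r, dt=0.1):
    return SimTrace(dt=dt, r=np.asarray(r, float), a=np.zeros(len(r)),
                    r_i=None, seed=None, params=None)


class TestBimodalityGate:
    def test_single_gaussian_not_bimodal(self):
        rng = np.random.default_rng(0)
        res = bimodality_gate(rng.normal(size=2000))
        assert not res.bimodal and res.pvalue >= 0.05

    def test_separated_modes_bimodal(self):
        rng = np.random.default_rng(1)
        x = np.r_[rng.normal(0, 1, 1000), rng.normal(6, 1, 1000)]
        res = bimodality_gate(x)
        assert res.bimodal and res.dip > 0.01

    def test_constant_trace_degenerate(self):
        with pytest.warns(UserWarning, match="constant"):
            res = bimodality_gate(np.ones(2000))
        assert not res.bimodal and res.dip == 0.0

    def test_short_sample_rejected(self):
        with pytest.raises(ValueError):
            bimodality_gate(np.random.default_rng(0).normal(size=100))


class TestStickyThresholds:
    def test_midpoint_rule_on_two_modes(self):
        rng = np.random.default_rng(2)
        x = np.r_[rng.normal(0.0, 0.02, 5000), rng.normal(1.0, 0.02, 5000)]
        up, down = sticky_thresholds(x)
        # peaks at 0 and 1, trough near 0.5 -> thresholds (0.75, 0.25)
        assert up == pytest.approx(0.75, abs=0.05)
        assert down == pytest.approx(0.25, abs=0.05)

    def test_symmetric_sample_gives_symmetric_thresholds(self):
        rng = np.random.default_rng(3)
        x = np.r_[rng.normal(-1, 0.1, 4000), rng.normal(1, 0.1, 4000)]
        up, down = sticky_thresholds(x)
        assert up == pytest.approx(-down, abs=0.08)

    def test_unimodal_sample_raises(self):
        rng = np.random.default_rng(4)
        with pytest.raises(ValueError, match="bimodality_gate"):
            sticky_thresholds(rng.normal(size=5000))


class TestDetectUpdown:
    def _square_wave(self, period=100.0, n_cycles=30, dt=0.1, noise=0.0, rng=None):
        half = int(period / dt)
        cyc = np.r_[np.zeros(half), np.ones(half)]
        r = np.tile(cyc, n_cycles)
        if noise:
            r = r + rng.normal(0, noise, r.size)
        return _trace(r, dt)

    def test_square_wave_durations_exact(self):
        rng = np.random.default_rng(5)
        trace = self._square_wave(noise=0.05, rng=rng)
        states = detect_updown(trace)
        for lab in ("UP", "DOWN"):
            d = states.durations(lab)
            assert len(d) > 20
            assert np.allclose(d, 100.0, atol=1.0)

    def test_hysteresis_rejects_subthreshold_excursion(self):
        rng = np.random.default_rng(6)
        trace = self._square_wave(noise=0.05, rng=rng)
        r = trace.r.copy()
        n_before = len(detect_updown(_trace(r)))
        # a brief excursion from DOWN that crosses the trough (0.5) but not
        # the far threshold (~0.75) must not create a transition
        k = np.flatnonzero(r < 0.2)[len(r) // 4]
        r2 = r.copy()
        r2[k:k + 30] = 0.6
        states2 = detect_updown(_trace(r2))
        assert len(states2) == n_before

    def test_alternation_and_tiling_invariant(self, nc_states):
        labels = list(nc_states.labels)
        assert all(a != b for a, b in zip(labels, labels[1:]))
        # detected intervals tile the analyzed span: stops == next starts
        assert np.allclose(nc_states.stops[:-1], nc_states.starts[1:])

    def test_affine_rescaling_invariance(self, nc_trace):
        scaled = _trace(5.0 + 3.0 * nc_trace.r, dt=nc_trace.dt)
        a = detect_updown(nc_trace)
        b = detect_updown(scaled)
        assert len(a) == len(b)
        assert np.allclose(a.starts, b.starts, atol=nc_trace.dt)

    def test_gate_failure_yields_empty_set(self):
        rng = np.random.default_rng(7)
        trace = _trace(rng.normal(size=5000))
        with pytest.warns(UserWarning, match="gate"):
            states = detect_updown(trace)
        assert len(states) == 0

    def test_excitable_down_trace_brief_stereotyped_up(self, hc_states):
        """Long variable DOWN states punctuated by brief stereotyped UPs."""
        st = duration_stats(hc_states)
        assert st.mean_down > 10 * st.mean_up
        assert st.cv_down > st.cv_up


class TestDurationStats:
    def test_exact_small_case(self):
        states = IntervalSet(np.array([0., 1., 2., 3.]), np.array([1., 2., 3., 4.]),
                             np.array(["UP", "DOWN", "UP", "DOWN"], dtype=object))
        st = duration_stats(states)
        assert st.mean_up == 1.0 and st.cv_up == 0.0
        assert st.ratio == 1.0 and st.n_up == 2

    def test_exponential_durations_have_unit_cv(self):
        rng = np.random.default_rng(8)
        d = rng.exponential(2.0, 10_000)
        starts = np.r_[0.0, np.cumsum(d)[:-1]]
        labels = np.array(["UP", "DOWN"] * 5000, dtype=object)
        st = duration_stats(IntervalSet(starts, starts + d, labels))
        assert st.cv_up == pytest.approx(1.0, abs=0.05)
        assert st.cv_down == pytest.approx(1.0, abs=0.05)

    def test_missing_label_flagged(self):
        states = IntervalSet(np.array([0.0]), np.array([1.0]),
                             np.array(["UP"], dtype=object))
        st = duration_stats(states)
        assert st.n_down == 0 and np.isnan(st.mean_down)


class TestDurationMap:
    def test_drive_sweep_up_grows_down_stays(self, noise):
        """Across the Excitable_UP band, UP durations grow with drive while
        DOWN durations remain on the adaptation timescale."""
        base = RatePopParams(w=6.28, b=1.0)
        drives = np.linspace(2.55, 2.75, 4)
        dm = duration_map(base, ("I", drives), ("w", np.array([6.28])), noise,
                          duration=30_000.0, seed=40)
        ups = [dm.cells[i, 0].stats.mean_up for i in range(4)]
        downs = [dm.cells[i, 0].stats.mean_down for i in range(4)]
        assert ups[-1] > 2.0 * ups[0]
        assert all(1.0 < d / base.tau_a < 5.0 for d in downs)

    def test_zero_recurrence_row_marked_no_alternation(self, noise):
        dm = duration_map(RatePopParams(b=1.0), ("w", np.array([0.0])),
                          ("I", np.array([2.0, 3.0])), noise,
                          duration=5000.0, seed=41)
        assert not any(c.alternating for c in dm.cells.ravel())

    def test_noise_free_oscillation_cv_below_005(self):
        p = RatePopParams(w=4.75, b=1.0, I=3.3)
        trace = simulate_rate(p, noise=None, duration=20_000.0, seed=0,
                              r0=0.9, a0=0.0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            st = duration_stats(detect_updown(trace))
        assert st.cv_up < 0.05 and st.cv_down < 0.05
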