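import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from isostim import controller as ctl
from isostim.errors import DegenerateWindowError
from isostim.isostable import Grid2D
from isostim.response import AugmentedResponseField


def make_gamma(gamma, grid=None, dt=1e-3):
    gamma = np.asarray(gamma, dtype=float)
    if grid is None:
        grid = Grid2D(0.0, gamma.shape[0], 0.0, gamma.shape[1], 1.0, 1.0)
    return AugmentedResponseField(grid=grid, gamma=gamma, dt=dt)


class TestPhaseTracker:
    def _track(self, signal, bootstrap):
        tr = ctl.PhaseTracker(bootstrap_steps=bootstrap)
        phases = np.empty(len(signal))
        for k, s in enumerate(signal):
            ctl.update_phase(tr, s, k)
            phases[k] = tr.phase
        return tr, phases

    def test_tone_phase_tracking(self):
        fs, f = 1000.0, 5.0
        t = np.arange(int(2 * fs)) / fs
        sig = np.sin(2 * np.pi * f * t)
        tr, phases = self._track(sig, bootstrap=int(fs / f))
        truth = (2 * np.pi * f * t) % (2 * np.pi)
        # after the first full period tracking locks to the tone
        err = np.abs(phases[400:] - truth[400:])
        err = np.minimum(err, 2 * np.pi - err)
        assert np.max(err) < 0.05

    def test_constant_positive_no_crossings(self):
        tr, phases = self._track(np.ones(500), bootstrap=200)
        assert tr.n_crossings == 0
        # phase still wraps on the bootstrap period
        assert phases.max() < 2 * np.pi
        assert phases[250] == pytest.approx(
            (250 * 2 * np.pi / 200) % (2 * np.pi), abs=1e-9
        )

    def test_period_doubling_adapts_after_one_cycle(self):
        fs = 1000.0
        t1 = np.arange(int(1 * fs)) / fs
        t2 = np.arange(int(2 * fs)) / fs
        sig = np.concatenate([np.sin(2 * np.pi * 5 * t1), np.sin(2 * np.pi * 2.5 * t2)])
        tr = ctl.PhaseTracker(bootstrap_steps=200)
        n1_at_crossing = []
        for k, s in enumerate(sig):
            old = tr.n_crossings
            ctl.update_phase(tr, s, k)
            if tr.n_crossings > old:
                n1_at_crossing.append((k, tr.n1))
        # the first crossing in the slow regime still predicts with the stale
        # 5 Hz period; the one after that uses the measured 2.5 Hz period
        slow = [(k, n1) for k, n1 in n1_at_crossing if k > 900]
        assert slow[0][1] - slow[0][0] == pytest.approx(200, abs=20)
        assert slow[1][1] - slow[1][0] == pytest.approx(400, abs=20)


class TestDiscountFactor:
    def test_k1_is_one(self):
        assert ctl.discount_factor(50, 1, 0, 100, -5.0, 1e-3) == 1.0

    def test_period_end_is_zero(self):
        assert ctl.discount_factor(50, 51, 0, 100, -5.0, 1e-3) == 0.0

    def test_hand_values(self):
        # t_n0 = 0, t_n1 = 1 s, t_i = 0.25 s, t_{i+k-1} = 0.5 s at dt = 1 ms
        a_neg = ctl.discount_factor(250, 251, 0, 1000, -5.0, 1e-3)
        a_pos = ctl.discount_factor(250, 251, 0, 1000, 5.0, 1e-3)
        assert a_neg == pytest.approx(0.96970, abs=1e-4)
        assert a_pos == pytest.approx(0.03030, abs=1e-4)

    def test_degenerate_window(self):
        with pytest.raises(DegenerateWindowError):
            ctl.discount_factor(5, 2, 5, 5, 1.0, 1e-3)

    def test_b_zero_log_limit(self):
        # t_i = 0.25 s, t_{i+k-1} = 0.5 s, t_n1 = 1 s
        a = ctl.discount_factor(250, 251, 0, 1000, 0.0, 1e-3)
        assert a == pytest.approx(math.log(2.0) / math.log(4.0))

    def test_b_positive_at_period_start(self):
        # t_i = t_n0 with b > 0: continuous limit is 0
        assert ctl.discount_factor(0, 2, 0, 100, 5.0, 1e-3) == 0.0

    @given(
        i=st.integers(1, 98), k=st.integers(2, 50),
        b=st.floats(-6, 6),
    )
    @settings(max_examples=200)
    def test_bounded_in_unit_interval(self, i, k, b):
        if i + k - 1 > 100:
            return
        a = ctl.discount_factor(i, k, 0, 100, b, 1e-3)
        assert -1e-12 <= a <= 1.0 + 1e-12


class TestDecide:
    def _tracker(self, n0=0, n1=200, step_now=100):
        tr = ctl.PhaseTracker(bootstrap_steps=200)
        tr.n0, tr.n1 = n0, n1
        tr.last_stim_step = -(10**9)
        tr.stimulated_this_period = False
        return tr

    def test_zero_gamma_never_fires(self):
        cfg = ctl.ControllerConfig(b=-5.0, dE=0.1, gamma=make_gamma(np.zeros((3, 3, 5))))
        tr = self._tracker()
        assert not ctl.decide(tr, cfg, np.array([1.5, 1.5]), 100)

    def test_all_future_zero_fires(self):
        g = np.zeros((1, 1, 5))
        g[0, 0, 0] = -1.0
        cfg = ctl.ControllerConfig(b=-5.0, dE=0.1, gamma=make_gamma(g))
        tr = self._tracker()
        assert ctl.decide(tr, cfg, np.array([0.5, 0.5]), 100)

    def test_discounted_future_rule(self):
        # gamma(p,q,:) = (-1, -2, 0): fire iff alpha_{i,2} < 0.5
        g = np.zeros((1, 1, 3))
        g[0, 0, 0], g[0, 0, 1] = -1.0, -2.0
        x = np.array([0.5, 0.5])
        tr = self._tracker(n0=0, n1=1000)

        cfg_wait = ctl.ControllerConfig(b=0.0, dE=0.1, gamma=make_gamma(g))
        alpha = ctl.discount_factor(10, 2, 0, 1000, 0.0, 1e-3)
        assert alpha > 0.5  # -1 >= alpha * -2: better to wait
        assert not ctl.decide(tr, cfg_wait, x, 10)

        cfg_go = ctl.ControllerConfig(b=10.0, dE=0.1, gamma=make_gamma(g))
        alpha = ctl.discount_factor(10, 2, 0, 1000, 10.0, 1e-3)
        assert alpha < 0.5  # -1 < alpha * -2: future too uncertain, fire now
        assert ctl.decide(tr, cfg_go, x, 10)

    def test_period_end_reached_fires(self):
        g = np.zeros((1, 1, 3))
        g[0, 0, 0] = -0.1
        g[0, 0, 1] = -10.0  # future would be much better, but period is over
        cfg = ctl.ControllerConfig(b=-5.0, dE=0.1, gamma=make_gamma(g))
        tr = self._tracker(n0=0, n1=50)
        assert ctl.decide(tr, cfg, np.array([0.5, 0.5]), 60)

    def test_rate_cap_blocks(self):
        g = np.full((1, 1, 3), -1.0)
        cfg = ctl.ControllerConfig(b=5.0, dE=0.1, gamma=make_gamma(g))
        tr = self._tracker()
        tr.last_stim_step = 95
        assert not ctl.decide(tr, cfg, np.array([0.5, 0.5]), 100)

    def test_once_per_period_blocks(self):
        g = np.full((1, 1, 3), -1.0)
        cfg = ctl.ControllerConfig(b=5.0, dE=0.1, gamma=make_gamma(g))
        tr = self._tracker()
        tr.stimulated_this_period = True
        assert not ctl.decide(tr, cfg, np.array([0.5, 0.5]), 100)

    def test_outside_grid_waits(self):
        g = np.full((2, 2, 3), -1.0)
        cfg = ctl.ControllerConfig(b=5.0, dE=0.1, gamma=make_gamma(g))
        tr = self._tracker()
        assert not ctl.decide(tr, cfg, np.array([5.0, 0.5]), 100)


class TestClosedLoop:
    def test_engines_agree(self, field_store):
        p, fa, _ = field_store.model("patientA")
        cfg = ctl.ControllerConfig(b=-5.0, dE=p.dE0, gamma=field_store.gamma("patientA"))
        r_nb = ctl.run_closed_loop(p, cfg, 20.0, seed=11, fa=fa, engine="numba")
        r_py = ctl.run_closed_loop(p, cfg, 20.0, seed=11, fa=fa, engine="python")
        assert np.array_equal(r_nb.stim_times, r_py.stim_times)
        assert np.allclose(r_nb.states, r_py.states, atol=1e-12)

    def test_zero_magnitude_matches_no_stim_power(self, field_store):
        from isostim.evaluation import psd_power
        from isostim.wc_model import integrate_sde

        p, fa, _ = field_store.model("patientA")
        gamma = field_store.gamma("patientA")
        cfg = ctl.ControllerConfig(b=-5.0, dE=0.0, gamma=gamma)
        rec = ctl.run_closed_loop(p, cfg, 60.0, seed=21, fa=fa)
        base = integrate_sde(fa.x_star, p, 60.0, seed=21)
        assert psd_power(rec.E, 1000.0) == pytest.approx(
            psd_power(base.E, 1000.0), rel=1e-9
        )

    def test_determinism(self, field_store):
        p, fa, _ = field_store.model("patientA")
        cfg = ctl.ControllerConfig(b=-5.0, dE=p.dE0, gamma=field_store.gamma("patientA"))
        a = ctl.run_closed_loop(p, cfg, 30.0, seed=5, fa=fa)
        b = ctl.run_closed_loop(p, cfg, 30.0, seed=5, fa=fa)
        assert np.array_equal(a.stim_times, b.stim_times)
        assert np.array_equal(a.states, b.states)

    def test_rate_cap_enforced(self, field_store):
        p, fa, _ = field_store.model("patientA")
        cfg = ctl.ControllerConfig(b=50.0, dE=p.dE0, gamma=field_store.gamma("patientA"))
        rec = ctl.run_closed_loop(p, cfg, 60.0, seed=13, fa=fa)
        steps = np.round(rec.stim_times / rec.dt).astype(int)
        assert len(steps) > 10
        assert np.diff(steps).min() >= cfg.n_lim

    def test_heavy_discounting_fires_earlier(self, field_store):
        """Large positive b fully discounts futures -> pulses come earlier in
        the period, and waits occur at b = -5."""
        p, fa, _ = field_store.model("patientA")
        gamma = field_store.gamma("patientA")

        waits = {"n": 0}
        logs = {}
        for b in (50.0, -5.0):
            cfg = ctl.ControllerConfig(b=b, dE=p.dE0, gamma=gamma)
            hook = ctl.ClosedLoopController(cfg, fa, gamma.dt)

            fired_at = []
            wait_then_fire = []
            pending_wait = {"flag": False}

            def wrapped(x, k, hook=hook, fired_at=fired_at,
                        wait_then_fire=wait_then_fire, pending=pending_wait):
                tr = hook.tracker
                eligible = (
                    not tr.stimulated_this_period
                    and k - tr.last_stim_step >= cfg.n_lim
                )
                grid = gamma.grid
                pe = math.floor((x[0] - grid.e_min) / grid.de)
                qi = math.floor((x[1] - grid.i_min) / grid.di)
                beneficial = (
                    0 <= pe < grid.n_E and 0 <= qi < grid.n_I
                    and gamma.gamma[pe, qi, 0] < 0
                )
                pulse = hook(x, k)
                if pulse:
                    fired_at.append(k - tr.n0)
                    if pending["flag"]:
                        wait_then_fire.append(k)
                    pending["flag"] = False
                elif eligible and beneficial:
                    pending["flag"] = True
                return pulse

            from isostim.wc_model import integrate_sde

            rec = integrate_sde(fa.x_star, p, 60.0, dt=gamma.dt, seed=31,
                                controller=wrapped)
            logs[b] = (np.mean(fired_at), len(rec.stim_times), len(wait_then_fire))

        assert logs[50.0][0] <= logs[-5.0][0]  # earlier in the period on average
        assert logs[-5.0][2] > 0  # waits followed by a later pulse occur
        waits["n"] = logs[-5.0][2]


class TestControllerConfig:
    def test_n_lim(self, field_store):
        gamma = field_store.gamma("patientA")
        cfg = ctl.ControllerConfig(b=0.0, dE=0.01, gamma=gamma, max_rate_hz=10.0)
        assert cfg.n_lim == 100
        with pytest.raises(ValueError):
            ctl.ControllerConfig(b=0.0, dE=0.01, gamma=gamma, max_rate_hz=0.0)
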