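import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from isostim import wc_model as wc
from isostim.errors import NotAFocusError

from conftest import decoupled_params


class TestSigmoid:
    def test_midpoint(self):
        for beta in (0.5, 1.0, 4.0, 20.0):
            assert wc.sigmoid(1.0, beta) == pytest.approx(0.5)

    def test_saturation(self):
        assert wc.sigmoid(1e6, 3.0) == pytest.approx(1.0)
        assert wc.sigmoid(-1e6, 3.0) == pytest.approx(0.0)
        # no overflow either way
        assert np.isfinite(wc.sigmoid(np.array([-1e300, 1e300]), 50.0)).all()

    def test_hand_value(self):
        # x = 2, beta = ln 3: 1/(1 + 1/3) = 0.75
        assert wc.sigmoid(2.0, math.log(3.0)) == pytest.approx(0.75, rel=1e-12)

    @given(
        x1=st.floats(-50, 50), x2=st.floats(-50, 50),
        beta=st.floats(0.01, 50),
    )
    def test_monotone_and_bounded(self, x1, x2, beta):
        y1, y2 = wc.sigmoid(x1, beta), wc.sigmoid(x2, beta)
        assert 0.0 <= y1 <= 1.0
        if x1 < x2:
            assert y1 <= y2


class TestDrift:
    def test_decoupled_hand_value(self):
        p = decoupled_params()
        # f(1) = 0.5 so (0.5, 0.5) is the fixed point
        assert wc.drift(np.array([0.5, 0.5]), p) == pytest.approx([0.0, 0.0])

    def test_zero_at_fixed_point(self, patients):
        for p, fa, _ in patients:
            assert np.linalg.norm(wc.drift(fa.x_star, p)) < 1e-10

    def test_jacobian_matches_finite_differences(self, patients):
        p, fa, _ = patients[0]
        rng = np.random.default_rng(0)
        h = 1e-6
        for _ in range(10):
            x = rng.uniform(0.1, 0.9, 2)
            J = wc.jacobian(x, p)
            J_fd = np.empty((2, 2))
            for j in range(2):
                dx = np.zeros(2)
                dx[j] = h
                J_fd[:, j] = (wc.drift(x + dx, p) - wc.drift(x - dx, p)) / (2 * h)
            assert np.allclose(J, J_fd, rtol=1e-6, atol=1e-6)


class TestJacobian:
    def test_decoupled_diagonal(self):
        p = decoupled_params()
        J = wc.jacobian(np.array([0.5, 0.5]), p)
        assert np.allclose(J, np.diag([-1 / p.nu, -1 / p.nu]))

    def test_trace_det_identities(self, patients):
        for p, fa, _ in patients:
            J = fa.jacobian
            assert np.trace(J) == pytest.approx(2 * fa.sigma, rel=1e-9)
            assert np.linalg.det(J) == pytest.approx(
                fa.sigma**2 + fa.omega**2, rel=1e-9
            )


class TestFixedPoint:
    def test_decoupled_exact(self):
        p = decoupled_params()
        x = wc.find_fixed_point(p)
        assert x == pytest.approx([0.5, 0.5], abs=1e-12)

    def test_residual_postcondition(self, patients):
        for p, _, _ in patients:
            x = wc.find_fixed_point(p)
            assert np.linalg.norm(wc.drift(x, p)) < 1e-10

    def test_eta_monotonicity_decoupled(self):
        es = []
        for eta in (0.8, 1.0, 1.2):
            x = wc.find_fixed_point(decoupled_params(eta_E=eta))
            es.append(x[0])
        assert es[0] < es[1] < es[2]


class TestAnalyzeFocus:
    def test_decoupled_not_a_focus(self):
        with pytest.raises(NotAFocusError):
            wc.analyze_focus(decoupled_params())

    def test_fixture_frequency(self, patients):
        for p, fa, meta in patients:
            assert fa.omega / (2 * math.pi) == pytest.approx(5.0, abs=0.5)
            assert fa.sigma < 0 and fa.omega > 0

    def test_eigen_residual(self, patients):
        for _, fa, _ in patients:
            lam = fa.sigma + 1j * fa.omega
            assert np.linalg.norm(fa.jacobian @ fa.v1 - lam * fa.v1) < 1e-8

    def test_sign_convention_and_nondegeneracy(self, patients):
        for _, fa, _ in patients:
            assert fa.a[0] > 0 or (fa.a[0] == 0 and fa.b[0] > 0)
            assert fa.eigenbasis_norm > 0
            assert np.linalg.norm(fa.v1) == pytest.approx(1.0)


class TestDeterministicIntegration:
    def test_constant_at_fixed_point(self, patient_a):
        p, fa, _ = patient_a
        rec = wc.integrate_deterministic(fa.x_star, p, 1.0)
        assert np.allclose(rec.states, fa.x_star, atol=1e-7)

    def test_spectral_decay_envelope(self, patient_a):
        p, fa, meta = patient_a
        x0 = fa.x_star + np.array([meta["orbit_radius"], 0.0])
        t_end = 6 * fa.period_T
        rec = wc.integrate_deterministic(x0, p, t_end, dt=1e-3)
        # sampled at period multiples the distance decays like exp(sigma*t)
        idx = [int(round(k * fa.period_T / 1e-3)) for k in range(6)]
        d = np.linalg.norm(rec.states[idx] - fa.x_star, axis=1)
        rates = np.diff(np.log(d)) / fa.period_T
        assert np.mean(rates) == pytest.approx(fa.sigma, rel=0.05)

    def test_rk45_euler_agreement(self, patient_a):
        p, fa, meta = patient_a
        x0 = fa.x_star + np.array([meta["orbit_radius"], 0.0])
        r1 = wc.integrate_deterministic(x0, p, 2.0, method="rk45", dt=1e-3)
        r2 = wc.integrate_deterministic(x0, p, 2.0, method="euler", dt=1e-5)
        end2 = r2.states[-1]
        assert np.linalg.norm(r1.states[-1] - end2) < 1e-5

    def test_linearized_decay_rate(self, patient_a):
        p, fa, meta = patient_a
        x0 = fa.x_star + 1e-4 * meta["orbit_radius"] * np.array([1.0, 0.3])
        rec = wc.integrate_deterministic(x0, p, 4 * fa.period_T, dt=1e-3)
        idx = [int(round(k * fa.period_T / 1e-3)) for k in range(4)]
        d = np.linalg.norm(rec.states[idx] - fa.x_star, axis=1)
        rate = (np.log(d[-1]) - np.log(d[0])) / (3 * fa.period_T)
        assert rate == pytest.approx(fa.sigma, rel=0.05)


class TestStochasticIntegration:
    def test_zero_noise_equals_euler(self, patient_a):
        p, fa, meta = patient_a
        p0 = wc.ModelParams(
            **{**p.__dict__, "zeta": 0.0}
        )
        x0 = fa.x_star + np.array([meta["orbit_radius"], 0.0])
        r_sde = wc.integrate_sde(x0, p0, 0.5, dt=1e-3, seed=5)
        r_det = wc.integrate_deterministic(x0, p0, 0.5, method="euler", dt=1e-3)
        assert np.array_equal(r_sde.states, r_det.states)

    def test_seed_reproducibility(self, patient_a):
        p, fa, _ = patient_a
        r1 = wc.integrate_sde(fa.x_star, p, 2.0, seed=42)
        r2 = wc.integrate_sde(fa.x_star, p, 2.0, seed=42)
        assert np.array_equal(r1.states, r2.states)

    def test_seed_decorrelation(self, patient_a):
        import isostim._kernels as K

        p, fa, _ = patient_a
        traces = []
        for seed in (1, 2):
            noise = np.random.default_rng(seed).standard_normal((200_000, 2))
            s = K.sde_plain(
                fa.x_star, p.nu, p.beta, p.eta_E, p.eta_I, p.w_EE, p.w_IE,
                p.w_EI, p.zeta * math.sqrt(1e-3), 1e-3, noise,
            )
            traces.append(s[:, 0])
        corr = np.corrcoef(traces[0], traces[1])[0, 1]
        assert abs(corr) < 0.2

    def test_variance_grows_with_zeta(self, patient_a):
        p, fa, _ = patient_a
        variances = []
        for scale in (0.5, 1.0, 2.0):
            rec = wc.integrate_sde(fa.x_star, p, 100.0, seed=3, zeta_scale=scale)
            variances.append(np.var(rec.E[10_000:]))
        assert variances[0] < variances[1] < variances[2]

    def test_controller_hook_pulses_logged(self, patient_a):
        p, fa, _ = patient_a
        hook = lambda x, k: 0.01 if k in (100, 300) else 0.0  # noqa: E731
        rec = wc.integrate_sde(fa.x_star, p, 0.5, seed=0, controller=hook)
        assert np.array_equal(rec.stim_times, [0.1, 0.3])
        assert np.array_equal(rec.stim_magnitudes, [0.01, 0.01])


class TestApplyPulse:
    def test_identity_and_definition(self):
        assert wc.apply_pulse([0.4, 0.3], 0.0) == pytest.approx([0.4, 0.3])
        assert wc.apply_pulse([0.4, 0.3], 0.05) == pytest.approx([0.45, 0.3])

    @given(
        e=st.floats(-1, 2), i=st.floats(-1, 2),
        de=st.floats(-0.2, 0.2),
    )
    @settings(max_examples=50)
    def test_composition(self, e, i, de):
        one = wc.apply_pulse([e, i], de)
        two = wc.apply_pulse(wc.apply_pulse([e, i], de / 2), de / 2)
        assert np.allclose(one, two, atol=1e-15)


class TestSerialization:
    def test_params_roundtrip(self, tmp_path, patient_a):
        p, _, _ = patient_a
        path = tmp_path / "p.json"
        p.to_json(path)
        assert wc.ModelParams.from_json(path) == p

    def test_record_roundtrip(self, tmp_path, patient_a):
        p, fa, _ = patient_a
        rec = wc.integrate_sde(fa.x_star, p, 0.5, seed=9)
        path = tmp_path / "rec.npz"
        rec.save(path)
        back = wc.SimulationRecord.load(path)
        assert np.array_equal(back.states, rec.states)
        assert back.seed == rec.seed
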