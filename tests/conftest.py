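"""Shared fixtures.

Heavy artifacts (amplitude fields, augmented fields) are computed lazily
once per session and shared between unit and acceptance tests through the
``field_store`` cache.
"""

from __future__ import annotations

import math

import numpy as np
import pytest

from isostim import (
    ControllerConfig,
    HilbertConfig,
    IsostableConfig,
    ModelParams,
    analyze_focus,
    compute_isostable_field,
    estimate_hilbert_field,
    instantaneous_response,
    load_frozen_patients,
    run_closed_loop,
    toy_cases,
)
from isostim.fixtures import grid_from_occupancy
from isostim.isostable import Grid2D
from isostim.response import augment

FULL_N = 40  # flow periods for the "full" isostable preset at test scale
HILBERT_FULL = dict(n_traj=500, n_periods=200)  # reduced full-quality preset
HILBERT_QUICK = dict(n_traj=200, n_periods=100)


@pytest.fixture(scope="session")
def patients():
    """The frozen patient library with focus analyses and manifest entries."""
    out = []
    for p, meta in load_frozen_patients():
        out.append((p, analyze_focus(p), meta))
    return out


@pytest.fixture(scope="session")
def patient_a(patients):
    return patients[0]


@pytest.fixture(scope="session")
def toys():
    return toy_cases()


class FieldStore:
    """Session-level memoization of expensive field computations."""

    def __init__(self, patients):
        self._patients = {meta["label"]: (p, fa, meta) for p, fa, meta in patients}
        self._cache = {}

    def model(self, label):
        return self._patients[label]

    @property
    def labels(self):
        return list(self._patients)

    def grid(self, label) -> Grid2D:
        p, fa, meta = self._patients[label]
        return Grid2D(**meta["grid"])

    def _memo(self, key, fn):
        if key not in self._cache:
            self._cache[key] = fn()
        return self._cache[key]

    def iso_field(self, label, quality="full"):
        p, fa, meta = self._patients[label]
        cfg = (
            IsostableConfig.full(n=FULL_N)
            if quality == "full"
            else IsostableConfig.quick(full_n=FULL_N)
        )
        return self._memo(
            ("iso", label, quality),
            lambda: compute_isostable_field(p, self.grid(label), cfg, fa=fa),
        )

    def hilbert_field(self, label, quality="full", centering="mean"):
        p, fa, meta = self._patients[label]
        sizes = HILBERT_FULL if quality == "full" else HILBERT_QUICK
        cfg = HilbertConfig(
            centering=centering, seed=1000 + meta["seed"], quality=quality, **sizes
        )
        return self._memo(
            ("hil", label, quality, centering),
            lambda: estimate_hilbert_field(p, self.grid(label), cfg, fa=fa),
        )

    def gamma(self, label, quality="full"):
        """Augmented response field from the isostable field at dE = dE0."""
        p, fa, meta = self._patients[label]

        def build():
            g0 = instantaneous_response(self.iso_field(label, quality), p.dE0)
            return augment(g0.zero_fill(), p, fa)

        return self._memo(("gamma", label, quality), build)

    def closed_loop_report(self, label, b=-5.0, n_trials=6, duration=300.0,
                           seed_base=7000):
        """Paired closed-loop vs no-stim powers (same noise realizations)."""
        import isostim._kernels as K
        from isostim.evaluation import psd_power

        p, fa, meta = self._patients[label]
        cfg = ControllerConfig(b=b, dE=p.dE0, gamma=self.gamma(label))

        def build():
            stim_p, base_p, recs = [], [], []
            dt = cfg.gamma.dt
            for t in range(n_trials):
                seed = seed_base + t
                rec = run_closed_loop(p, cfg, duration, seed, fa=fa)
                n = int(round(duration / dt))
                noise = np.random.default_rng(seed).standard_normal((n, 2))
                states = K.sde_plain(
                    fa.x_star, p.nu, p.beta, p.eta_E, p.eta_I,
                    p.w_EE, p.w_IE, p.w_EI, p.zeta * math.sqrt(dt), dt, noise,
                )
                stim_p.append(psd_power(rec.E, 1.0 / dt))
                base_p.append(psd_power(states[:, 0], 1.0 / dt))
                recs.append(rec)
            return np.array(stim_p), np.array(base_p), recs

        return self._memo(("cl", label, b, n_trials, duration, seed_base), build)


@pytest.fixture(scope="session")
def field_store(patients):
    return FieldStore(patients)


def decoupled_params(**overrides) -> ModelParams:
    """All weights zero: E and I relax independently to f(eta)."""
    base = dict(
        nu=0.02, beta=4.0, eta_E=1.0, eta_I=1.0,
        w_EE=0.0, w_IE=0.0, w_EI=0.0, zeta=0.01, dE0=0.01,
        label="decoupled",
    )
    base.update(overrides)
    return ModelParams(**base)


@pytest.fixture()
def decoupled():
    return decoupled_params()
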