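"""Closed-loop phase-space stimulation: per-step decision against an
augmented response field, with zero-crossing phase tracking and temporal
discounting of future benefits.

A pulse is delivered at step ``i`` only when all of the following hold:

* no pulse for ``N_lim`` steps and none yet in the current period;
* the nearest bin to the current state has an immediate benefit
  ``gamma(p, q, 1) < 0``;
* the predicted period end has already been passed, or the immediate
  benefit beats every discounted future benefit
  ``min_k alpha_{i,k} * gamma(p, q, k)`` over the remainder of the period.

The discount factor ``alpha`` is 1 at the present step and 0 at the
predicted period end; larger ``b`` discounts future values more heavily.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .errors import DegenerateWindowError
from .response import AugmentedResponseField
from .wc_model import (
    FocusAnalysis,
    ModelParams,
    SimulationRecord,
    analyze_focus,
    integrate_sde,
)

__all__ = [
    "ControllerConfig",
    "PhaseTracker",
    "update_phase",
    "discount_factor",
    "decide",
    "ClosedLoopController",
    "run_closed_loop",
    "CENTERING_WINDOW_S",
]

#: causal running-mean window (s) used to center E for zero-crossing detection
CENTERING_WINDOW_S = 2.0


@dataclass
class ControllerConfig:
    b: float
    dE: float
    gamma: AugmentedResponseField
    max_rate_hz: float = 10.0

    def __post_init__(self):
        if self.max_rate_hz <= 0:
            raise ValueError("max_rate_hz must be > 0")

    @property
    def n_lim(self) -> int:
        return int(math.ceil(1.0 / (self.max_rate_hz * self.gamma.dt)))


@dataclass
class PhaseTracker:
    """Online zero-crossing phase estimate.

    Phase resets to 0 at positive zero-crossings of the centered signal and
    advances linearly at the inverse of the previous period's duration.
    Until the second crossing the bootstrap period (the linearized
    ``round(T/dt)``) is used.
    """

    bootstrap_steps: int
    phase: float = 0.0
    n0: int = 0
    prev_period_steps: int = 0
    n1: int = 0
    last_stim_step: int = -(10**9)
    stimulated_this_period: bool = False
    n_crossings: int = 0
    _prev_centered: float = 0.0
    _started: bool = False

    def __post_init__(self):
        if self.prev_period_steps == 0:
            self.prev_period_steps = self.bootstrap_steps
        if self.n1 == 0:
            self.n1 = self.n0 + self.prev_period_steps


def update_phase(tracker: PhaseTracker, e_centered: float, step: int) -> PhaseTracker:
    """Advance the tracker by one sample; mutates and returns ``tracker``."""
    crossed = tracker._started and tracker._prev_centered < 0.0 and e_centered >= 0.0
    if crossed:
        if tracker.n_crossings >= 1:
            tracker.prev_period_steps = step - tracker.n0
        tracker.n0 = step
        tracker.n1 = step + tracker.prev_period_steps
        tracker.phase = 0.0
        tracker.stimulated_this_period = False
        tracker.n_crossings += 1
    elif tracker._started:
        tracker.phase = (tracker.phase + 2.0 * math.pi / tracker.prev_period_steps) % (
            2.0 * math.pi
        )
    tracker._prev_centered = e_centered
    tracker._started = True
    return tracker


def discount_factor(i: int, k: int, n0: int, n1: int, b: float, dt: float) -> float:
    """The ``k - 1`` step ahead discount factor at step ``i``.

    Equals 1 at ``k = 1`` and 0 when ``i + k - 1`` reaches the predicted
    period end ``n1``.  ``b = 0`` is the logarithmic limit; when
    ``t_i = t_{n0}`` and ``b > 0`` the (continuous-limit) value is 0.
    """
    if n1 == n0:
        raise DegenerateWindowError("n1 == n0")
    return float(_kernels.discount_alpha(i, k, n0, n1, float(b), dt))


def decide(tracker: PhaseTracker, cfg: ControllerConfig, x, i: int) -> bool:
    """Stimulate-or-wait decision at step ``i`` with (pre-pulse) state ``x``."""
    if tracker.stimulated_this_period:
        return False
    if i - tracker.last_stim_step < cfg.n_lim:
        return False
    g = cfg.gamma
    grid = g.grid
    pe = math.floor((x[0] - grid.e_min) / grid.de)
    qi = math.floor((x[1] - grid.i_min) / grid.di)
    if not (0 <= pe < grid.n_E and 0 <= qi < grid.n_I):
        return False
    g1v = g.gamma[pe, qi, 0]
    if not g1v < 0.0:
        return False
    if i >= tracker.n1:
        return True
    kmax = min(tracker.n1 - i + 1, g.u)
    if kmax < 2:
        return False
    best_future = math.inf
    for k in range(2, kmax + 1):
        a = discount_factor(i, k, tracker.n0, tracker.n1, cfg.b, g.dt)
        best_future = min(best_future, a * g.gamma[pe, qi, k - 1])
    return g1v < best_future


class ClosedLoopController:
    """Stateful per-step hook for :func:`isostim.wc_model.integrate_sde`.

    Mirrors the compiled kernel exactly (shared discounting code, same
    running-mean centering and update order), so both engines produce
    identical event logs on the same noise.
    """

    def __init__(self, cfg: ControllerConfig, fa: FocusAnalysis, dt: float):
        self.cfg = cfg
        self.dt = dt
        self.e_star = float(fa.x_star[0])
        self.tracker = PhaseTracker(bootstrap_steps=int(round(fa.period_T / dt)))
        self.win = max(1, int(round(CENTERING_WINDOW_S / dt)))
        self._buf = np.zeros(self.win)
        self._rsum = 0.0
        self._seen = 0

    def __call__(self, x, step: int) -> float:
        E = float(x[0])
        if self._seen >= self.win:
            centered = E - self._rsum / self.win
        else:
            centered = E - self.e_star
        update_phase(self.tracker, centered, step)
        pulse = 0.0
        if decide(self.tracker, self.cfg, x, step):
            pulse = self.cfg.dE
            self.tracker.last_stim_step = step
            self.tracker.stimulated_this_period = True
        j = self._seen % self.win
        self._rsum += E - self._buf[j]
        self._buf[j] = E
        self._seen += 1
        return pulse


def run_closed_loop(
    p: ModelParams,
    cfg: ControllerConfig,
    duration: float,
    seed: int,
    zeta_scale: float = 1.0,
    fa: FocusAnalysis | None = None,
    x0=None,
    engine: str = "numba",
) -> SimulationRecord:
    """Closed-loop stochastic run with the augmented-field controller."""
    if fa is None:
        fa = analyze_focus(p)
    dt = cfg.gamma.dt
    if x0 is None:
        x0 = fa.x_star
    x0 = np.asarray(x0, dtype=float)
    n = int(round(duration / dt))
    noise = np.random.default_rng(seed).standard_normal((n, 2))
    snapshot = {
        "strategy": "closed-loop",
        "b": cfg.b,
        "dE": cfg.dE,
        "max_rate_hz": cfg.max_rate_hz,
        "duration": duration,
        "zeta_scale": zeta_scale,
        "dt": dt,
        "source_kind": cfg.gamma.meta.get("source_kind", ""),
        "source_quality": cfg.gamma.meta.get("source_quality", ""),
    }
    if engine == "python":
        hook = ClosedLoopController(cfg, fa, dt)
        rec = integrate_sde(
            x0, p, duration, dt=dt, seed=seed, controller=hook,
            zeta_scale=zeta_scale, noise=noise,
        )
        rec.config.update(snapshot)
        return rec
    grid = cfg.gamma.grid
    states, stim_steps = _kernels.sde_closed_loop(
        x0, p.nu, p.beta, p.eta_E, p.eta_I, p.w_EE, p.w_IE, p.w_EI,
        p.zeta * zeta_scale * math.sqrt(dt), dt, noise,
        cfg.gamma.gamma, grid.e_min, grid.de, grid.n_E,
        grid.i_min, grid.di, grid.n_I,
        cfg.dE, float(cfg.b), cfg.n_lim,
        int(round(fa.period_T / dt)),
        max(1, int(round(CENTERING_WINDOW_S / dt))),
        float(fa.x_star[0]),
    )
    return SimulationRecord(
        times=np.arange(n + 1) * dt,
        states=states,
        stim_times=stim_steps.astype(float) * dt,
        stim_magnitudes=np.full(len(stim_steps), cfg.dE),
        seed=seed,
        config=snapshot,
    )
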