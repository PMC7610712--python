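"""Reference stimulation strategies: phase-locked pulses at a calibrated
target phase, and open-loop high-frequency (130 Hz) stimulation with
efficacy-matched magnitude."""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import _kernels
from .controller import CENTERING_WINDOW_S
from .errors import NoMatchError
from .evaluation import psd_power, run_trials
from .wc_model import (
    FocusAnalysis,
    ModelParams,
    SimulationRecord,
    analyze_focus,
)

__all__ = [
    "PhaseLockedConfig",
    "HFConfig",
    "run_phase_locked",
    "calibrate_target_phase",
    "run_hf",
    "match_hf_magnitude",
]


@dataclass(frozen=True)
class PhaseLockedConfig:
    target_phase: float
    dE: float
    n_bins: int = 12
    calib_duration: float = 5000.0
    dt: float = 1e-3

    def __post_init__(self):
        if not (0.0 <= self.target_phase < 2.0 * math.pi):
            raise ValueError("target_phase must be in [0, 2*pi)")


@dataclass(frozen=True)
class HFConfig:
    magnitude: float
    freq_hz: float = 130.0
    dt: float = 1e-3

    def __post_init__(self):
        if self.freq_hz * self.dt > 1.0:
            raise ValueError("freq_hz*dt must be <= 1 (at most one pulse per step)")

    @property
    def interval_steps(self) -> int:
        """Pulse spacing in integration steps (grid-quantized rate)."""
        return max(1, int(round(1.0 / (self.freq_hz * self.dt))))


def run_phase_locked(
    p: ModelParams,
    cfg: PhaseLockedConfig,
    duration: float,
    seed: int,
    zeta_scale: float = 1.0,
    fa: FocusAnalysis | None = None,
    x0=None,
) -> SimulationRecord:
    """One pulse per tracked period at the first step reaching the target
    phase; a crossing arriving first triggers the pulse right then."""
    if fa is None:
        fa = analyze_focus(p)
    dt = cfg.dt
    if x0 is None:
        x0 = fa.x_star
    n = int(round(duration / dt))
    noise = np.random.default_rng(seed).standard_normal((n, 2))
    states, stim_steps = _kernels.sde_phase_locked(
        np.asarray(x0, dtype=float),
        p.nu, p.beta, p.eta_E, p.eta_I, p.w_EE, p.w_IE, p.w_EI,
        p.zeta * zeta_scale * math.sqrt(dt), dt, noise,
        float(cfg.target_phase), cfg.dE,
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
        config={
            "strategy": "phase-locked",
            "target_phase": cfg.target_phase,
            "dE": cfg.dE,
            "duration": duration,
            "zeta_scale": zeta_scale,
            "dt": dt,
        },
    )


def calibrate_target_phase(
    p: ModelParams,
    dE: float,
    seed: int,
    zeta_scale: float = 1.0,
    n_bins: int = 12,
    calib_duration: float = 5000.0,
    dt: float = 1e-3,
    fa: FocusAnalysis | None = None,
    full_report: bool = False,
):
    """Pick the target phase minimizing oscillatory power.

    One calibration run per bin-center phase; the phase with the lowest
    integrated PSD wins (lowest index among exact ties).
    """
    if fa is None:
        fa = analyze_focus(p)
    phases = (np.arange(n_bins) + 0.5) * 2.0 * math.pi / n_bins
    powers = np.empty(n_bins)
    for j, ph in enumerate(phases):
        cfg = PhaseLockedConfig(target_phase=float(ph), dE=dE, dt=dt)
        rec = run_phase_locked(p, cfg, calib_duration, seed, zeta_scale, fa=fa)
        powers[j] = psd_power(rec.E, 1.0 / dt)
    best = int(np.argmin(powers))
    if full_report:
        return float(phases[best]), {
            "phases": phases.tolist(),
            "powers": powers.tolist(),
            "best_bin": best,
        }
    return float(phases[best])


def run_hf(
    p: ModelParams,
    cfg: HFConfig,
    duration: float,
    seed: int,
    zeta_scale: float = 1.0,
    fa: FocusAnalysis | None = None,
    x0=None,
) -> SimulationRecord:
    """Open-loop pulses at fixed step intervals, independent of state."""
    if fa is None:
        fa = analyze_focus(p)
    dt = cfg.dt
    if x0 is None:
        x0 = fa.x_star
    n = int(round(duration / dt))
    noise = np.random.default_rng(seed).standard_normal((n, 2))
    states, stim_steps = _kernels.sde_scheduled(
        np.asarray(x0, dtype=float),
        p.nu, p.beta, p.eta_E, p.eta_I, p.w_EE, p.w_IE, p.w_EI,
        p.zeta * zeta_scale * math.sqrt(dt), dt, noise,
        cfg.interval_steps, cfg.magnitude,
    )
    return SimulationRecord(
        times=np.arange(n + 1) * dt,
        states=states,
        stim_times=stim_steps.astype(float) * dt,
        stim_magnitudes=np.full(len(stim_steps), cfg.magnitude),
        seed=seed,
        config={
            "strategy": "hf",
            "freq_hz": cfg.freq_hz,
            "dE": cfg.magnitude,
            "duration": duration,
            "zeta_scale": zeta_scale,
            "dt": dt,
        },
    )


def match_hf_magnitude(
    p: ModelParams,
    target_power: float,
    seed_base: int,
    tol_frac: float = 0.01,
    n_trials: int = 6,
    trial_duration: float = 5000.0,
    freq_hz: float = 130.0,
    dt: float = 1e-3,
    zeta_scale: float = 1.0,
    fa: FocusAnalysis | None = None,
    initial: float | None = None,
    initial_step: float | None = None,
    max_evals: int = 40,
) -> float:
    """Derivative-free 1-D pattern search for the HF pulse magnitude whose
    mean power matches ``target_power`` within ``tol_frac``.

    Polls magnitude +/- step around the incumbent; the step contracts by 1/2
    on failure and expands by 2 on success.  Returns 0 when the target is
    not below the no-stimulation power.
    """
    if fa is None:
        fa = analyze_focus(p)
    cache: dict[float, float] = {}
    evals = 0

    def mean_power(mag: float) -> float:
        nonlocal evals
        mag = max(0.0, round(mag, 12))
        if mag not in cache:
            rep = run_trials(
                lambda seed, dur: run_hf(
                    p, HFConfig(magnitude=mag, freq_hz=freq_hz, dt=dt),
                    dur, seed, zeta_scale, fa=fa,
                ),
                n_trials,
                trial_duration,
                seed_base,
            )
            cache[mag] = rep.mean_power
            evals += 1
        return cache[mag]

    no_stim = mean_power(0.0)
    if target_power >= no_stim:
        return 0.0

    def err(mag):
        return abs(mean_power(mag) - target_power) / target_power

    if initial is None:
        # the dose-response of the shifted-fixed-point mechanism is not
        # monotone: scan a coarse geometric grid, then bisect a bracket in
        # which the (deterministic, fixed-seed) power crosses the target
        scan = [0.0] + list(np.geomspace(p.dE0 / 2.0, 100.0 * p.dE0, 10))
        powers = [mean_power(m) for m in scan]
        brackets = [
            (scan[j], scan[j + 1])
            for j in range(len(scan) - 1)
            if (powers[j] - target_power) * (powers[j + 1] - target_power) <= 0
        ]
        if brackets:
            lo, hi = min(
                brackets,
                key=lambda br: min(
                    abs(mean_power(br[0]) - target_power),
                    abs(mean_power(br[1]) - target_power),
                ),
            )
            sign_lo = mean_power(lo) - target_power
            while evals < max_evals:
                for cand in (lo, hi):
                    if err(cand) <= tol_frac:
                        return cand
                mid = 0.5 * (lo + hi)
                if hi - lo < 1e-12:
                    break
                e_mid = err(mid)
                if e_mid <= tol_frac:
                    return mid
                if (mean_power(mid) - target_power) * sign_lo <= 0:
                    hi = mid
                else:
                    lo = mid
                    sign_lo = mean_power(lo) - target_power
        # fall through to pattern search from the best point seen so far
        initial = min(cache, key=lambda m: abs(cache[m] - target_power))
        if initial_step is None:
            initial_step = max(initial / 2.0, p.dE0 / 4.0)
    if initial_step is None:
        initial_step = max(initial / 2.0, p.dE0 / 4.0)

    m, s = float(initial), float(initial_step)
    best_m, best_err = m, err(m)
    while evals < max_evals:
        if best_err <= tol_frac:
            return best_m
        moved = False
        for cand in (m + s, max(0.0, m - s)):
            if evals >= max_evals:
                break
            e = err(cand)
            if e < best_err:
                best_m, best_err = cand, e
            if e < err(m):
                m = cand
                moved = True
                break
        if moved:
            s *= 2.0
        else:
            s *= 0.5
        if s < 1e-12:
            break
    if best_err <= tol_frac:
        return best_m
    raise NoMatchError(
        f"no magnitude within {tol_frac:.1%} of target after {evals} evaluations "
        f"(best {best_m:.4g} at {best_err:.2%})",
        best_magnitude=best_m,
        best_power=mean_power(best_m),
    )
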