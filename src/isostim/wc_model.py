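"""Stochastic and deterministic Wilson-Cowan dynamics for a two-population
excitatory/inhibitory neural mass, fixed-point and focus analysis, and pulse
stimulation.

The model is

    dE = (1/nu) * (-E + f(eta_E + w_EE*E - w_IE*I)) dt + zeta dW_E
    dI = (1/nu) * (-I + f(eta_I + w_EI*E)) dt + zeta dW_I

with the logistic sigmoid ``f(x) = 1 / (1 + exp(-beta*(x - 1)))``.  The
excitatory activity ``E`` stands for the tremor-generating population and is
the component that receives stimulation pulses (an instantaneous increment
``dE`` on ``E``).

Noise enters additively with coefficient ``zeta`` exactly as written above;
the alternative convention with ``zeta/nu`` is available behind the
``noise_inside_nu`` switch.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import root

from .errors import (
    IntegrationError,
    MultipleFixedPointsWarning,
    NoFixedPointError,
    NotAFocusError,
)

__all__ = [
    "ModelParams",
    "FocusAnalysis",
    "SimulationRecord",
    "sigmoid",
    "drift",
    "jacobian",
    "find_fixed_point",
    "analyze_focus",
    "focus_from_jacobian",
    "integrate_deterministic",
    "integrate_sde",
    "apply_pulse",
]

#: default RK45 tolerances; field convergence needs trajectory accuracy over
#: tens of periods.
RK45_RTOL = 1e-8
RK45_ATOL = 1e-10


@dataclass(frozen=True)
class ModelParams:
    """All constants of one synthetic "patient" model.

    ``dE0`` is the reference stimulation magnitude (the per-pulse increment
    applied to ``E`` at unit stimulation ratio).
    """

    nu: float
    beta: float
    eta_E: float
    eta_I: float
    w_EE: float
    w_IE: float
    w_EI: float
    zeta: float
    dE0: float
    label: str = ""

    def __post_init__(self):
        if not (self.nu > 0):
            raise ValueError("nu must be > 0")
        if not (self.beta > 0):
            raise ValueError("beta must be > 0")
        if not (self.zeta >= 0):
            raise ValueError("zeta must be >= 0")
        if not (self.dE0 > 0):
            raise ValueError("dE0 must be > 0")
        for name in ("w_EE", "w_IE", "w_EI", "eta_E", "eta_I"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")

    def to_json(self, path):
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2)

    @classmethod
    def from_json(cls, path):
        with open(path) as fh:
            return cls(**json.load(fh))


@dataclass(frozen=True)
class FocusAnalysis:
    """Linearization of the model at its stable focus.

    ``v1 = a - i*b`` is the unit right eigenvector of ``lambda+ = sigma +
    i*omega``; the sign ambiguity is fixed by requiring ``a[0] > 0``
    (fallback ``b[0] > 0``).
    """

    x_star: np.ndarray
    jacobian: np.ndarray
    sigma: float
    omega: float
    a: np.ndarray
    b: np.ndarray
    v2: np.ndarray
    period_T: float

    @property
    def v1(self) -> np.ndarray:
        return self.a - 1j * self.b

    @property
    def eigenbasis_norm(self) -> float:
        """|b2*a1 - b1*a2|, the denominator of the isostable formula."""
        return abs(self.b[1] * self.a[0] - self.b[0] * self.a[1])


@dataclass
class SimulationRecord:
    """Uniformly sampled trajectory plus the stimulation event log."""

    times: np.ndarray
    states: np.ndarray  # shape (n, 2), columns E, I
    stim_times: np.ndarray
    stim_magnitudes: np.ndarray
    seed: int | None
    config: dict = field(default_factory=dict)

    @property
    def E(self) -> np.ndarray:
        return self.states[:, 0]

    @property
    def I(self) -> np.ndarray:
        return self.states[:, 1]

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0])

    def save(self, path):
        """Columnar binary container plus embedded JSON sidecar."""
        np.savez_compressed(
            path,
            times=self.times,
            E=self.E,
            I=self.I,
            stim_times=self.stim_times,
            stim_magnitudes=self.stim_magnitudes,
            meta=np.array(json.dumps({"seed": self.seed, "config": self.config})),
        )

    @classmethod
    def load(cls, path):
        with np.load(path) as z:
            meta = json.loads(str(z["meta"]))
            return cls(
                times=z["times"],
                states=np.column_stack([z["E"], z["I"]]),
                stim_times=z["stim_times"],
                stim_magnitudes=z["stim_magnitudes"],
                seed=meta["seed"],
                config=meta["config"],
            )


def sigmoid(x, beta):
    """Logistic sigmoid ``1/(1 + exp(-beta*(x-1)))``, saturating safely."""
    return 0.5 * (1.0 + np.tanh(0.5 * beta * (np.asarray(x, dtype=float) - 1.0)))


def sigmoid_deriv(x, beta):
    s = sigmoid(x, beta)
    return beta * s * (1.0 - s)


def drift(x, p: ModelParams):
    """Deterministic vector field of the model at state ``x = (E, I)``."""
    E, I = x[0], x[1]
    dE = (-E + sigmoid(p.eta_E + p.w_EE * E - p.w_IE * I, p.beta)) / p.nu
    dI = (-I + sigmoid(p.eta_I + p.w_EI * E, p.beta)) / p.nu
    return np.array([dE, dI])


def drift_ensemble(states, p: ModelParams):
    """Vectorized drift for an (n, 2) array of states."""
    E = states[..., 0]
    I = states[..., 1]
    out = np.empty_like(states)
    out[..., 0] = (-E + sigmoid(p.eta_E + p.w_EE * E - p.w_IE * I, p.beta)) / p.nu
    out[..., 1] = (-I + sigmoid(p.eta_I + p.w_EI * E, p.beta)) / p.nu
    return out


def jacobian(x, p: ModelParams):
    """Analytic Jacobian of :func:`drift` at ``x``."""
    E, I = x[0], x[1]
    fpE = sigmoid_deriv(p.eta_E + p.w_EE * E - p.w_IE * I, p.beta)
    fpI = sigmoid_deriv(p.eta_I + p.w_EI * E, p.beta)
    return np.array(
        [
            [(-1.0 + p.w_EE * fpE) / p.nu, -p.w_IE * fpE / p.nu],
            [p.w_EI * fpI / p.nu, -1.0 / p.nu],
        ]
    )


def find_fixed_point(p: ModelParams, guess=(0.5, 0.5), tol=1e-10):
    """Locate a fixed point of the drift.

    Falls back on a 5x5 multi-start lattice over (0,1)^2 when the first root
    search fails.  If several distinct roots are found a
    :class:`MultipleFixedPointsWarning` is issued and the root whose
    linearization is a stable focus is returned (first root otherwise).
    """
    starts = [np.asarray(guess, dtype=float)]
    lattice = np.linspace(0.1, 0.9, 5)
    starts.extend(np.array([e, i]) for e in lattice for i in lattice)

    roots = []
    for s in starts:
        sol = root(lambda x: drift(x, p), s, jac=lambda x: jacobian(x, p), tol=1e-13)
        if not sol.success:
            continue
        x = sol.x
        if np.linalg.norm(drift(x, p)) >= tol:
            continue
        if not any(np.linalg.norm(x - r) < 1e-6 for r in roots):
            roots.append(x)
        if len(roots) == 1 and s is starts[0]:
            break
    if not roots:
        raise NoFixedPointError(f"no fixed point found for model {p.label!r}")
    if len(roots) > 1:
        warnings.warn(
            f"model {p.label!r} has {len(roots)} distinct fixed points: {roots}",
            MultipleFixedPointsWarning,
        )
        for x in roots:
            ev = np.linalg.eigvals(jacobian(x, p))
            if abs(ev[0].imag) > 0 and ev[0].real < 0:
                return x
    return roots[0]


def focus_from_jacobian(J, x_star) -> FocusAnalysis:
    """Build a :class:`FocusAnalysis` from an explicit Jacobian.

    Used both by :func:`analyze_focus` and by linear toy systems with a
    closed-form isostable amplitude.
    """
    J = np.asarray(J, dtype=float)
    x_star = np.asarray(x_star, dtype=float)
    eigvals, eigvecs = np.linalg.eig(J)
    if np.all(np.isreal(eigvals)):
        raise NotAFocusError(f"eigenvalues {eigvals} are real")
    k = int(np.argmax(eigvals.imag))
    lam = eigvals[k]
    sigma, omega = float(lam.real), float(lam.imag)
    if sigma >= 0:
        raise NotAFocusError(f"leading eigenvalue {lam} has non-negative real part")
    v1 = eigvecs[:, k]
    v1 = v1 / np.linalg.norm(v1)
    a, b = v1.real.copy(), -v1.imag.copy()
    # sign convention: a1 > 0, fallback b1 > 0
    if a[0] < 0 or (a[0] == 0 and b[0] < 0):
        a, b = -a, -b
    return FocusAnalysis(
        x_star=x_star,
        jacobian=J,
        sigma=sigma,
        omega=omega,
        a=a,
        b=b,
        v2=np.conj(a - 1j * b),
        period_T=2.0 * np.pi / omega,
    )


def analyze_focus(p: ModelParams, guess=(0.5, 0.5)) -> FocusAnalysis:
    """Fixed point, Jacobian and eigen-decomposition of a stable focus."""
    x_star = find_fixed_point(p, guess=guess)
    return focus_from_jacobian(jacobian(x_star, p), x_star)


def apply_pulse(x, dE):
    """One stimulation pulse: increment E by ``dE`` (stimulation vector (dE, 0))."""
    x = np.asarray(x, dtype=float)
    return np.array([x[0] + dE, x[1]])


def _check_finite(states):
    if not np.all(np.isfinite(states)):
        raise IntegrationError("trajectory became non-finite")


def integrate_deterministic(
    x0,
    p: ModelParams,
    duration,
    method="rk45",
    dt=1e-3,
    rtol=RK45_RTOL,
    atol=RK45_ATOL,
) -> SimulationRecord:
    """Noiseless trajectory from ``x0`` over ``duration`` seconds.

    ``rk45`` uses adaptive internal stepping with the output resampled onto
    the ``dt`` grid; ``euler`` takes fixed explicit steps of size ``dt``.
    """
    if duration <= 0:
        raise ValueError("duration must be > 0")
    x0 = np.asarray(x0, dtype=float)
    n = int(round(duration / dt))
    times = np.arange(n + 1) * dt
    if method == "rk45":
        sol = solve_ivp(
            lambda t, x: drift(x, p),
            (0.0, times[-1]),
            x0,
            method="RK45",
            t_eval=times,
            rtol=rtol,
            atol=atol,
        )
        if not sol.success:
            raise IntegrationError(sol.message)
        states = sol.y.T.copy()
    elif method == "euler":
        states = np.empty((n + 1, 2))
        states[0] = x0
        x = x0.copy()
        for k in range(n):
            x = x + dt * drift(x, p)
            states[k + 1] = x
    else:
        raise ValueError(f"unknown method {method!r}")
    _check_finite(states)
    return SimulationRecord(
        times=times,
        states=states,
        stim_times=np.empty(0),
        stim_magnitudes=np.empty(0),
        seed=None,
        config={"method": method, "dt": dt, "duration": duration, "zeta": 0.0},
    )


def integrate_sde(
    x0,
    p: ModelParams,
    duration,
    dt=1e-3,
    seed=0,
    controller=None,
    zeta_scale=1.0,
    noise_inside_nu=False,
    noise=None,
) -> SimulationRecord:
    """Euler-Maruyama integration with optional per-step stimulation hook.

    ``controller(x, step) -> float`` is called before every step with the
    current state and step index; a non-zero return is applied as an
    instantaneous pulse on E and logged.  ``noise`` may supply a
    pre-generated ``(n, 2)`` array of standard normal increments (the same
    array a seeded generator would produce), enabling paired comparisons.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    x0 = np.asarray(x0, dtype=float)
    n = int(round(duration / dt))
    if noise is None:
        noise = np.random.default_rng(seed).standard_normal((n, 2))
    zeta_eff = p.zeta * zeta_scale
    if noise_inside_nu:
        zeta_eff = zeta_eff / p.nu
    sq = zeta_eff * np.sqrt(dt)

    times = np.arange(n + 1) * dt
    states = np.empty((n + 1, 2))
    x = x0.copy()
    states[0] = x
    stim_steps: list[int] = []
    stim_mags: list[float] = []
    for k in range(n):
        if controller is not None:
            pulse = controller(x, k)
            if pulse:
                x = apply_pulse(x, pulse)
                stim_steps.append(k)
                stim_mags.append(float(pulse))
        x = x + dt * drift(x, p) + sq * noise[k]
        if not np.isfinite(x).all():
            raise IntegrationError(f"non-finite state at step {k + 1}")
        states[k + 1] = x
    return SimulationRecord(
        times=times,
        states=states,
        stim_times=np.asarray(stim_steps, dtype=float) * dt,
        stim_magnitudes=np.asarray(stim_mags, dtype=float),
        seed=seed,
        config={
            "dt": dt,
            "duration": duration,
            "zeta_scale": zeta_scale,
            "noise_inside_nu": noise_inside_nu,
        },
    )
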