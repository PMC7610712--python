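"""Isostable amplitude of a stable focus over a 2-D phase-space grid.

For a stable focus with eigenvalues ``sigma +/- i*omega`` the isostable
amplitude ``r(X)`` labels the sets of points that converge to the fixed
point synchronously.  It is computed by flowing the deterministic system for
``n`` linear periods ``T = 2*pi/omega`` and reading off two linear
observables of the endpoint:

    r(X) ~= exp(-sigma*n*T) * sqrt(g1(y)^2 + g2(y)^2) / |b2*a1 - b1*a2|

with ``y`` the endpoint of the flow, ``g1 = <X - X*, (b2, -b1)>`` and
``g2 = <X - X*, (a2, -a1)>`` where ``v1 = a - i*b`` is the unit eigenvector
of ``sigma + i*omega``.  Along deterministic trajectories ``r`` decays
exactly as ``exp(sigma*t)``.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp

from .errors import DegenerateEigenbasisError, DivergenceError
from .wc_model import (
    RK45_ATOL,
    RK45_RTOL,
    FocusAnalysis,
    ModelParams,
    analyze_focus,
    drift,
    drift_ensemble,
)

__all__ = [
    "Grid2D",
    "IsostableConfig",
    "AmplitudeField",
    "observables",
    "isostable_amplitude",
    "linear_isostable_amplitude",
    "compute_isostable_field",
]

#: trajectories leaving the grid bounds inflated by this factor are treated
#: as outside the basin of attraction
BASIN_INFLATION = 3.0


@dataclass(frozen=True)
class Grid2D:
    """Uniform half-open binning of an (E, I) rectangle.

    Bins are ``[lo + j*width, lo + (j+1)*width)`` with centers at
    ``lo + (j + 0.5)*width``.  Bounds are snapped outward so that an integer
    number of bins spans each range exactly.
    """

    e_min: float
    e_max: float
    i_min: float
    i_max: float
    de: float = 0.001
    di: float = 0.001

    @property
    def n_E(self) -> int:
        return int(round((self.e_max - self.e_min) / self.de))

    @property
    def n_I(self) -> int:
        return int(round((self.i_max - self.i_min) / self.di))

    @classmethod
    def from_bounds(cls, e_lo, e_hi, i_lo, i_hi, de=0.001, di=0.001):
        """Snap arbitrary bounds outward to bin-width multiples."""
        e_min = np.floor(e_lo / de) * de
        e_max = np.ceil(e_hi / de) * de
        i_min = np.floor(i_lo / di) * di
        i_max = np.ceil(i_hi / di) * di
        if e_max <= e_min:
            e_max = e_min + de
        if i_max <= i_min:
            i_max = i_min + di
        return cls(float(e_min), float(e_max), float(i_min), float(i_max), de, di)

    def e_centers(self) -> np.ndarray:
        return self.e_min + (np.arange(self.n_E) + 0.5) * self.de

    def i_centers(self) -> np.ndarray:
        return self.i_min + (np.arange(self.n_I) + 0.5) * self.di

    def centers(self) -> np.ndarray:
        """All bin centers as an (n_E*n_I, 2) array, E-major order."""
        ee, ii = np.meshgrid(self.e_centers(), self.i_centers(), indexing="ij")
        return np.column_stack([ee.ravel(), ii.ravel()])

    def bin_index(self, e, i):
        """Containing-bin indices (vectorized); -1 where out of range."""
        je = np.floor((np.asarray(e) - self.e_min) / self.de).astype(np.int64)
        ji = np.floor((np.asarray(i) - self.i_min) / self.di).astype(np.int64)
        bad = (je < 0) | (je >= self.n_E) | (ji < 0) | (ji >= self.n_I)
        je = np.where(bad, -1, je)
        ji = np.where(bad, -1, ji)
        return je, ji

    def __eq__(self, other):
        if not isinstance(other, Grid2D):
            return NotImplemented
        return all(
            np.isclose(getattr(self, f), getattr(other, f), rtol=0, atol=1e-12)
            for f in ("e_min", "e_max", "i_min", "i_max", "de", "di")
        )

    def to_dict(self):
        return {
            "e_min": self.e_min,
            "e_max": self.e_max,
            "i_min": self.i_min,
            "i_max": self.i_max,
            "de": self.de,
            "di": self.di,
        }


@dataclass(frozen=True)
class IsostableConfig:
    """Settings of the flow-based isostable computation."""

    n: int = 80
    integrator: str = "rk45"  # {"rk45", "euler"}
    dt: float = 1e-3
    quality: str = "full"  # {"full", "quick"}

    def __post_init__(self):
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.integrator not in ("rk45", "euler"):
            raise ValueError("integrator must be rk45 or euler")

    @classmethod
    def full(cls, n=80):
        return cls(n=n, integrator="rk45", quality="full")

    @classmethod
    def quick(cls, full_n=80, dt=1e-3):
        """Relaxed-convergence preset: Euler integration, smaller n."""
        return cls(n=max(10, full_n // 6), integrator="euler", dt=dt, quality="quick")


@dataclass
class AmplitudeField:
    """Scalar amplitude field on a :class:`Grid2D` with a missing-value mask."""

    grid: Grid2D
    values: np.ndarray  # (n_E, n_I)
    mask: np.ndarray  # True = missing
    kind: str  # {"isostable", "hilbert-mean", "hilbert-fp"}
    quality: str  # {"full", "quick"}
    meta: dict = field(default_factory=dict)

    def save(self, path):
        np.savez_compressed(
            path,
            values=self.values,
            mask=self.mask,
            meta=np.array(
                json.dumps(
                    {
                        "grid": self.grid.to_dict(),
                        "kind": self.kind,
                        "quality": self.quality,
                        "meta": self.meta,
                    }
                )
            ),
        )

    @classmethod
    def load(cls, path):
        with np.load(path) as z:
            meta = json.loads(str(z["meta"]))
            return cls(
                grid=Grid2D(**meta["grid"]),
                values=z["values"],
                mask=z["mask"].astype(bool),
                kind=meta["kind"],
                quality=meta["quality"],
                meta=meta["meta"],
            )



def _endpoint_atol(w0, sigma, t_end):
    """Per-component absolute tolerance tied to the expected endpoint scale.

    Pure relative control stalls when a component transits zero; an atol at
    1e-8 of the exponentially decayed endpoint magnitude keeps ~1e-8
    relative endpoint accuracy without letting steps collapse.
    """
    w0 = np.atleast_2d(w0)
    scale = np.linalg.norm(w0, axis=1)
    decay = np.exp(max(sigma * t_end, -650.0))
    atol = np.repeat(np.maximum(scale * decay * 1e-8, 1e-290), 2)
    return atol


def observables(x, fa: FocusAnalysis):
    """Linear observables (g1, g2) used by the isostable formula."""
    d = np.asarray(x, dtype=float) - fa.x_star
    g1 = d[0] * fa.b[1] - d[1] * fa.b[0]
    g2 = d[0] * fa.a[1] - d[1] * fa.a[0]
    return g1, g2


#: deviations below this magnitude are deep in the linear regime; flowing
#: further only grinds against the round-off noise floor of the drift
LINEAR_FLOOR = 1e-9


def _flow_horizon(w0, fa: FocusAnalysis, cfg: IsostableConfig) -> float:
    """Effective flow time: the configured n*T, shortened once every
    deviation is guaranteed below LINEAR_FLOOR.

    The read-off value is invariant along the flow (r scales exactly by
    exp(sigma*t)), so stopping deep in the linear regime yields the same
    amplitude while avoiding cancellation-noise step collapse.
    """
    t_end = cfg.n * fa.period_T
    scale = float(np.max(np.linalg.norm(np.atleast_2d(w0), axis=1)))
    if scale <= LINEAR_FLOOR:
        return min(t_end, fa.period_T)
    t_lin = math.log(LINEAR_FLOOR / scale) / fa.sigma  # sigma < 0
    return min(t_end, t_lin)


def _endpoint_amplitude(endpoints, fa: FocusAnalysis, t_used: float):
    """Apply the isostable read-off formula to flow endpoints (vectorized)."""
    denom = fa.eigenbasis_norm
    if denom < 1e-12:
        raise DegenerateEigenbasisError(f"|b2*a1 - b1*a2| = {denom:.3e}")
    d = endpoints - fa.x_star
    g1 = d[..., 0] * fa.b[1] - d[..., 1] * fa.b[0]
    g2 = d[..., 0] * fa.a[1] - d[..., 1] * fa.a[0]
    return np.exp(-fa.sigma * t_used) * np.hypot(g1, g2) / denom


def isostable_amplitude(
    x,
    fa: FocusAnalysis,
    cfg: IsostableConfig,
    p: ModelParams | None = None,
    drift_fn=None,
    bounds=None,
) -> float:
    """Isostable amplitude of a single point.

    The flow may come from a :class:`ModelParams` model or from an explicit
    ``drift_fn(x) -> 2-vector`` (used by linear toy systems).  ``bounds``
    is an optional ``(e_lo, e_hi, i_lo, i_hi)`` box; leaving it raises
    :class:`DivergenceError`.
    """
    if drift_fn is None:
        if p is None:
            raise ValueError("either p or drift_fn is required")
        drift_fn = lambda y: drift(y, p)  # noqa: E731
    x = np.asarray(x, dtype=float)
    x_star = fa.x_star
    if not np.any(x - x_star):
        return 0.0  # the fixed point is its own isostable, r = 0
    t_end = _flow_horizon(x - x_star, fa, cfg)
    # integrate the deviation from the fixed point under (near-)pure relative
    # error control: the endpoint decays by exp(sigma*n*T), far below any
    # sensible absolute tolerance on the state itself
    if cfg.integrator == "rk45":
        sol = solve_ivp(
            lambda t, w: drift_fn(x_star + w),
            (0.0, t_end),
            x - x_star,
            method="RK45",
            rtol=RK45_RTOL,
            atol=_endpoint_atol(x - x_star, fa.sigma, t_end),
            dense_output=False,
        )
        if not sol.success or not np.isfinite(sol.y[:, -1]).all():
            raise DivergenceError("flow did not stay finite")
        if bounds is not None:
            e_lo, e_hi, i_lo, i_hi = bounds
            if (
                sol.y[0].min() + x_star[0] < e_lo
                or sol.y[0].max() + x_star[0] > e_hi
                or sol.y[1].min() + x_star[1] < i_lo
                or sol.y[1].max() + x_star[1] > i_hi
            ):
                raise DivergenceError("trajectory left the bounding box")
        w_end = sol.y[:, -1]
    else:
        n_steps = int(round(t_end / cfg.dt))
        w = x - x_star
        for _ in range(n_steps):
            w = w + cfg.dt * drift_fn(x_star + w)
            if not np.isfinite(w).all():
                raise DivergenceError("flow did not stay finite")
            if bounds is not None:
                e_lo, e_hi, i_lo, i_hi = bounds
                if not (
                    e_lo <= w[0] + x_star[0] <= e_hi
                    and i_lo <= w[1] + x_star[1] <= i_hi
                ):
                    raise DivergenceError("trajectory left the bounding box")
        w_end = w
    return float(_endpoint_amplitude(w_end[None, :] + x_star, fa, t_end)[0])


def _rk45_amplitudes_bucketed(w0, fa: FocusAnalysis, cfg: IsostableConfig,
                              p: ModelParams):
    """Adaptive ensemble amplitudes with per-magnitude-bucket horizons.

    Members starting at very different distances from the focus cannot share
    one flow horizon: the closest ones sink into the round-off noise floor
    long before the farthest reach the linear regime, collapsing the step
    size.  Members are grouped by decade of initial deviation and each
    group gets its own horizon and tolerance.  Returns NaN for members whose
    flow failed to stay finite.
    """
    x_star = fa.x_star
    out = np.full(len(w0), np.nan)
    norms = np.linalg.norm(w0, axis=1)
    zero = norms == 0
    out[zero] = 0.0
    decades = np.full(len(w0), -9999)
    decades[~zero] = np.floor(np.log10(norms[~zero])).astype(int)
    for dec in np.unique(decades[~zero]):
        sel = np.nonzero(decades == dec)[0]
        sub = w0[sel]
        t_end = _flow_horizon(sub, fa, cfg)
        sol = solve_ivp(
            lambda t, w: drift_ensemble(w.reshape(-1, 2) + x_star, p).ravel(),
            (0.0, t_end),
            sub.ravel(),
            method="RK45",
            rtol=RK45_RTOL,
            atol=_endpoint_atol(sub, fa.sigma, t_end),
            t_eval=[t_end],
        )
        ends = sol.y[:, -1].reshape(-1, 2) + x_star
        vals = _endpoint_amplitude(ends, fa, t_end)
        vals[~np.isfinite(ends).all(axis=1)] = np.nan
        out[sel] = vals
    return out


def isostable_amplitudes(points, fa: FocusAnalysis, cfg: IsostableConfig, p: ModelParams):
    """Vectorized :func:`isostable_amplitude` for an (N, 2) array of points.

    Shared ensemble integrations (bucketed by deviation magnitude); no basin
    bounds check (intended for probe points inside the region of interest).
    """
    pts = np.asarray(points, dtype=float)
    x_star = fa.x_star
    if cfg.integrator == "rk45":
        out = _rk45_amplitudes_bucketed(pts - x_star, fa, cfg, p)
        if not np.isfinite(out).all():
            raise DivergenceError("flow did not stay finite")
        return out
    t_end = _flow_horizon(pts - x_star, fa, cfg)
    n_steps = int(round(t_end / cfg.dt))
    w = pts - x_star
    for _ in range(n_steps):
        w = w + cfg.dt * drift_ensemble(w + x_star, p)
    ends = w + x_star
    if not np.isfinite(ends).all():
        raise DivergenceError("flow did not stay finite")
    return _endpoint_amplitude(ends, fa, t_end)


def linear_isostable_amplitude(x, fa: FocusAnalysis):
    """Closed-form amplitude of the linearized system.

    Writing ``X - X* = 2*Re[c1*v1]`` in the eigenbasis, the amplitude is
    ``2*|c1|``.  Used as an independent oracle near the fixed point.
    """
    d = np.asarray(x, dtype=float) - fa.x_star
    # 2*Re[c1*v1] = 2*alpha*a + 2*beta*b for c1 = alpha + i*beta
    M = np.column_stack([2.0 * fa.a, 2.0 * fa.b])
    alpha, beta = np.linalg.solve(M, d)
    return 2.0 * float(np.hypot(alpha, beta))


def compute_isostable_field(
    p: ModelParams,
    grid: Grid2D,
    cfg: IsostableConfig,
    fa: FocusAnalysis | None = None,
) -> AmplitudeField:
    """Evaluate the isostable amplitude at every bin center of ``grid``.

    The flow is the deterministic model (``zeta`` plays no role).  The whole
    ensemble of bin centers is integrated at once; bins whose trajectory
    leaves the inflated grid box or becomes non-finite are masked.
    """
    if fa is None:
        fa = analyze_focus(p)
    pts = grid.centers()

    e_span = grid.e_max - grid.e_min
    i_span = grid.i_max - grid.i_min
    e_lo = grid.e_min - (BASIN_INFLATION - 1.0) * e_span
    e_hi = grid.e_max + (BASIN_INFLATION - 1.0) * e_span
    i_lo = grid.i_min - (BASIN_INFLATION - 1.0) * i_span
    i_hi = grid.i_max + (BASIN_INFLATION - 1.0) * i_span

    x_star = fa.x_star
    w0 = pts - x_star
    # a bin center coinciding with X* exactly would stall the relative-only
    # error control; nudge it by a negligible fraction of a bin
    exact = ~np.any(w0 != 0, axis=1)
    w0[exact] = 1e-9 * np.array([grid.de, grid.di])
    escaped = np.zeros(len(pts), dtype=bool)
    if cfg.integrator == "rk45":
        vals = _rk45_amplitudes_bucketed(w0, fa, cfg, p)
        bad = ~np.isfinite(vals)
        vals[bad] = 0.0
        values = vals.reshape(grid.n_E, grid.n_I)
        mask = bad.reshape(grid.n_E, grid.n_I)
        return AmplitudeField(
            grid=grid,
            values=values,
            mask=mask,
            kind="isostable",
            quality=cfg.quality,
            meta={"model": p.label, "n": cfg.n, "integrator": cfg.integrator,
                  "dt": cfg.dt},
        )
    else:
        t_end = _flow_horizon(w0, fa, cfg)
        n_steps = int(round(t_end / cfg.dt))
        w = w0
        check_every = max(1, n_steps // 50)
        for k in range(n_steps):
            w = w + cfg.dt * drift_ensemble(w + x_star, p)
            if k % check_every == 0:
                with np.errstate(invalid="ignore"):
                    escaped |= (
                        ~np.isfinite(w).all(axis=1)
                        | (w[:, 0] + x_star[0] < e_lo)
                        | (w[:, 0] + x_star[0] > e_hi)
                        | (w[:, 1] + x_star[1] < i_lo)
                        | (w[:, 1] + x_star[1] > i_hi)
                    )
                w[escaped] = 0.0  # freeze escaped points at the fixed point
        ends = w + x_star
    bad = escaped | ~np.isfinite(ends).all(axis=1)
    ends[bad] = x_star
    vals = _endpoint_amplitude(ends, fa, t_end)
    values = vals.reshape(grid.n_E, grid.n_I)
    mask = bad.reshape(grid.n_E, grid.n_I)
    return AmplitudeField(
        grid=grid,
        values=values,
        mask=mask,
        kind="isostable",
        quality=cfg.quality,
        meta={"model": p.label, "n": cfg.n, "integrator": cfg.integrator, "dt": cfg.dt},
    )
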