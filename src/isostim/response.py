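"""Instantaneous and augmented amplitude response fields.

The instantaneous response field is the amplitude change caused by one
pulse, ``gamma0(X) = Omega(X + (dE, 0)) - Omega(X)`` with nearest-bin
lookup; negative values mark states where stimulating is beneficial.  The
augmented field samples ``gamma0`` along the deterministic trajectory from
every bin over one linear period, keeping only values that are negative and
at least as beneficial as stimulating immediately.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import EmptyFieldError, GridMismatchError
from .isostable import AmplitudeField, Grid2D
from .wc_model import FocusAnalysis, ModelParams, drift_ensemble

__all__ = [
    "ResponseField",
    "AugmentedResponseField",
    "instantaneous_response",
    "harmonize_support",
    "augment",
]


@dataclass
class ResponseField:
    """gamma0 on a grid, with the bins where it is undefined."""

    grid: Grid2D
    gamma0: np.ndarray  # (n_E, n_I); 0 where missing once zero_filled
    missing: np.ndarray  # True = undefined (non-actionable)
    stim_dE: float
    source_kind: str = ""
    source_quality: str = ""
    zero_filled: bool = False

    def zero_fill(self) -> "ResponseField":
        """Missing bins set to exactly 0 so the controller never acts there."""
        g = self.gamma0.copy()
        g[self.missing] = 0.0
        return replace(self, gamma0=g, zero_filled=True)


@dataclass
class AugmentedResponseField:
    """gamma(i, j, k): benefit of stimulating k-1 steps ahead of bin (i, j)."""

    grid: Grid2D
    gamma: np.ndarray  # (n_E, n_I, u), all entries <= 0
    dt: float
    meta: dict = field(default_factory=dict)

    @property
    def u(self) -> int:
        return self.gamma.shape[2]


def instantaneous_response(fld: AmplitudeField, dE: float) -> ResponseField:
    """gamma0 = Omega(X + dX) - Omega(X) with dX = (dE, 0), nearest-bin lookup.

    Bins that are masked, or whose shifted lookup lands on a masked or
    out-of-range bin, are marked missing.
    """
    if dE <= 0:
        raise ValueError("dE must be > 0")
    if fld.mask.all():
        raise EmptyFieldError("field has no unmasked bins")
    grid = fld.grid
    shift = int(round(dE / grid.de))
    # nearest bin to (center_j + dE): offset by dE in units of de, rounded
    if not np.isclose(shift * grid.de, dE, rtol=0, atol=1e-12):
        offs = (np.arange(grid.n_E) + 0.5) * grid.de + dE
        je_shift = np.floor(offs / grid.de).astype(np.int64)
    else:
        je_shift = np.arange(grid.n_E) + shift
    gamma0 = np.zeros((grid.n_E, grid.n_I))
    missing = np.ones((grid.n_E, grid.n_I), dtype=bool)
    ok_row = (je_shift >= 0) & (je_shift < grid.n_E)
    rows = np.nonzero(ok_row)[0]
    tgt = je_shift[rows]
    valid = ~fld.mask[rows] & ~fld.mask[tgt]
    gamma0[rows] = np.where(valid, fld.values[tgt] - fld.values[rows], 0.0)
    missing[rows] = ~valid
    return ResponseField(
        grid=grid,
        gamma0=gamma0,
        missing=missing | fld.mask,
        stim_dE=dE,
        source_kind=fld.kind,
        source_quality=fld.quality,
        zero_filled=True,
    )


def harmonize_support(iso: ResponseField, hil: ResponseField) -> ResponseField:
    """Empty in ``iso`` every bin that is missing in ``hil`` (set to 0)."""
    if iso.grid != hil.grid:
        raise GridMismatchError("fields are on different grids")
    g = iso.gamma0.copy()
    g[hil.missing] = 0.0
    return replace(iso, gamma0=g, missing=iso.missing | hil.missing)


def _default_trajectories(g0: ResponseField, p: ModelParams, dt: float, u: int):
    """Deterministic Euler trajectories from every bin center, (N, u, 2)."""
    pts = g0.grid.centers()
    traj = np.empty((len(pts), u, 2))
    traj[:, 0] = pts
    x = pts.copy()
    for k in range(1, u):
        x = x + dt * drift_ensemble(x, p)
        traj[:, k] = x
    return traj


def augment(
    g0: ResponseField,
    p: ModelParams | None,
    fa: FocusAnalysis | None,
    dt: float = 1e-3,
    trajectory_fn=None,
    u: int | None = None,
) -> AugmentedResponseField:
    """Build the augmented field over one period ``T`` (inclusive endpoints).

    ``u = round(T/dt) + 1`` time samples with ``t_1 = 0`` and ``t_u = T``.
    At each step the trajectory position is mapped to its nearest bin
    ``(p, q)`` and ``gamma(i, j, k) = gamma0(p, q)`` if that value is
    negative and at least as beneficial as ``gamma0(i, j)``, else 0.
    Positions outside the grid contribute 0.  ``trajectory_fn(g0, p, dt, u)
    -> (N, u, 2)`` may replace the built-in deterministic integrator (used
    for hand-traced tests).
    """
    if not g0.zero_filled:
        raise ValueError("g0 must be zero_filled before augmentation")
    grid = g0.grid
    if u is None:
        u = int(round(fa.period_T / dt)) + 1
    if trajectory_fn is None:
        traj = _default_trajectories(g0, p, dt, u)
    else:
        traj = trajectory_fn(g0, p, dt, u)
    je, ji = grid.bin_index(traj[..., 0].ravel(), traj[..., 1].ravel())
    in_grid = je >= 0
    g0_at = np.zeros(len(je))
    g0_at[in_grid] = g0.gamma0[je[in_grid], ji[in_grid]]
    g0_at = g0_at.reshape(-1, u)  # (N, u)
    g0_own = g0.gamma0.reshape(-1, 1)  # (N, 1)
    keep = (g0_at < 0) & (g0_at <= g0_own) & in_grid.reshape(-1, u)
    gamma = np.where(keep, g0_at, 0.0).reshape(grid.n_E, grid.n_I, u)
    return AugmentedResponseField(
        grid=grid,
        gamma=gamma,
        dt=dt,
        meta={
            "source_kind": g0.source_kind,
            "source_quality": g0.source_quality,
            "stim_dE": g0.stim_dE,
            "model": p.label if p is not None else "",
        },
    )
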