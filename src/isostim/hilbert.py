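"""Hilbert amplitude fields by ensemble averaging of stochastic trajectories.

Many stochastic trajectories are launched from random initial positions in
the region of interest; each yields a Hilbert (analytic-signal) amplitude
series of the centered E component.  Samples are assigned to space bins and
averaged; bins never visited stay masked.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import hilbert as _analytic

from .errors import SeriesTooShortError
from .isostable import AmplitudeField, Grid2D
from .wc_model import ModelParams, analyze_focus, drift_ensemble

__all__ = ["HilbertConfig", "analytic_amplitude", "estimate_hilbert_field"]

_CHUNK = 128  # trajectories simulated at once (fixed: part of the RNG layout)


@dataclass(frozen=True)
class HilbertConfig:
    """Ensemble settings for the field estimate."""

    n_traj: int = 2000
    n_periods: int = 1000
    clip_frac: float = 0.005
    smooth_window: int = 4
    centering: str = "mean"  # {"mean", "fixed_point"}
    seed: int = 0
    quality: str = "full"
    dt: float = 1e-3

    def __post_init__(self):
        if not (0 <= self.clip_frac < 0.5):
            raise ValueError("clip_frac must be in [0, 0.5)")
        if self.smooth_window < 1:
            raise ValueError("smooth_window must be >= 1")
        if self.centering not in ("mean", "fixed_point"):
            raise ValueError("centering must be 'mean' or 'fixed_point'")

    @classmethod
    def full(cls, **kw):
        return cls(quality="full", **kw)

    @classmethod
    def quick(cls, n_traj=200, n_periods=100, **kw):
        """Budget-reduced preset: fewer, shorter simulations."""
        return cls(n_traj=n_traj, n_periods=n_periods, quality="quick", **kw)


def analytic_amplitude(e_series, centering="mean", e_star=None):
    """Modulus of the analytic signal of the centered series.

    Mean centering subtracts the series mean; fixed-point centering
    subtracts ``e_star``.
    """
    e = np.asarray(e_series, dtype=float)
    if e.ndim == 1:
        e = e[None, :]
    if e.shape[-1] < 16:
        raise SeriesTooShortError(f"need >= 16 samples, got {e.shape[-1]}")
    if centering == "mean":
        centered = e - e.mean(axis=-1, keepdims=True)
    elif centering == "fixed_point":
        if e_star is None:
            raise ValueError("fixed_point centering requires e_star")
        centered = e - e_star
    else:
        raise ValueError(f"unknown centering {centering!r}")
    amp = np.abs(_analytic(centered, axis=-1))
    return amp[0] if np.asarray(e_series).ndim == 1 else amp


def moving_average(x, window, axis=-1):
    """Centered moving average with truncated (shrinking) edge windows."""
    if window <= 1:
        return np.asarray(x, dtype=float)
    x = np.moveaxis(np.asarray(x, dtype=float), axis, -1)
    n = x.shape[-1]
    left = (window - 1) // 2  # samples taken before t for even windows
    right = window - 1 - left
    c = np.cumsum(x, axis=-1)
    c = np.concatenate([np.zeros(x.shape[:-1] + (1,)), c], axis=-1)
    idx_hi = np.minimum(np.arange(n) + right + 1, n)
    idx_lo = np.maximum(np.arange(n) - left, 0)
    out = (c[..., idx_hi] - c[..., idx_lo]) / (idx_hi - idx_lo)
    return np.moveaxis(out, -1, axis)


def estimate_hilbert_field(
    p: ModelParams, grid: Grid2D, cfg: HilbertConfig, fa=None
) -> AmplitudeField:
    """Monte-Carlo Hilbert amplitude field on ``grid``.

    Initial positions are drawn uniformly over the grid rectangle.  Each
    trajectory runs for ``n_periods`` linear periods at the baseline noise
    level (times any ``zeta_scale`` baked into ``p``); the first and last
    ``clip_frac`` of both the trajectory and its amplitude series are
    discarded, and both are lightly smoothed with a centered
    ``smooth_window``-sample moving average before binning.
    """
    if fa is None:
        fa = analyze_focus(p)
    n_steps = int(round(cfg.n_periods * fa.period_T / cfg.dt))
    rng = np.random.default_rng(cfg.seed)
    sq = p.zeta * np.sqrt(cfg.dt)

    nb = grid.n_E * grid.n_I
    sums = np.zeros(nb)
    counts = np.zeros(nb, dtype=np.int64)
    n_clip = int(round(cfg.clip_frac * (n_steps + 1)))

    done = 0
    while done < cfg.n_traj:
        m = min(_CHUNK, cfg.n_traj - done)
        x0 = np.column_stack(
            [
                rng.uniform(grid.e_min, grid.e_max, size=m),
                rng.uniform(grid.i_min, grid.i_max, size=m),
            ]
        )
        traj = np.empty((m, n_steps + 1, 2))
        traj[:, 0] = x0
        x = x0.copy()
        for k in range(n_steps):
            dw = rng.standard_normal((m, 2))
            x = x + cfg.dt * drift_ensemble(x, p) + sq * dw
            traj[:, k + 1] = x
        e_star = fa.x_star[0]
        amp = analytic_amplitude(
            traj[:, :, 0],
            centering="mean" if cfg.centering == "mean" else "fixed_point",
            e_star=e_star,
        )
        if n_clip > 0:
            traj = traj[:, n_clip:-n_clip]
            amp = amp[:, n_clip:-n_clip]
        traj = moving_average(traj, cfg.smooth_window, axis=1)
        amp = moving_average(amp, cfg.smooth_window, axis=1)

        je, ji = grid.bin_index(traj[:, :, 0].ravel(), traj[:, :, 1].ravel())
        ok = je >= 0
        flat = je[ok] * grid.n_I + ji[ok]
        sums += np.bincount(flat, weights=amp.ravel()[ok], minlength=nb)
        counts += np.bincount(flat, minlength=nb)
        done += m

    mask = counts == 0
    values = np.zeros(nb)
    values[~mask] = sums[~mask] / counts[~mask]
    kind = "hilbert-mean" if cfg.centering == "mean" else "hilbert-fp"
    return AmplitudeField(
        grid=grid,
        values=values.reshape(grid.n_E, grid.n_I),
        mask=mask.reshape(grid.n_E, grid.n_I),
        kind=kind,
        quality=cfg.quality,
        meta={
            "model": p.label,
            "n_traj": cfg.n_traj,
            "n_periods": cfg.n_periods,
            "seed": cfg.seed,
        },
    )
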