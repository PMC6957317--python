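"""Two-state (bound/free) kinetic fit of the jump-length distribution.

The Spot-On-style analysis: frame-to-frame (and multi-lag) displacement
magnitudes pooled per cell are fit with a two-component mixture of 2D
diffusion jump distributions. For a molecule diffusing with coefficient D
observed at lag ``t`` with per-coordinate localization error ``sigma`` at
both endpoints, the squared jump length is exponential and the CDF is

    P(r' <= r) = 1 - exp(-r^2 / (4 (D t + sigma^2)))

The mixture ``F_b * CDF(r | D_bound) + (1 - F_b) * CDF(r | D_free)`` is fit
to the empirical CDF on a quantile-spaced grid, jointly over lags, yielding
the per-cell bound fraction and free diffusion coefficient.

Because tracks are formed with a displacement gate ``r_max``, observed
lag-1 jumps are exactly the mixture conditioned on ``r <= r_max``, and
higher-lag jumps are sums of gated steps. The fit is gate-aware by default:
lag-1 model CDFs are renormalized at the gate and lags >= 2 use the
truncated-step effective D, which removes the downward D_free bias the gate
would otherwise cause for fast molecules.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .tracking import TrackSet

__all__ = [
    "JumpData",
    "TwoStateFit",
    "collect_jumps",
    "model_jump_cdf",
    "fit_two_state",
    "summarize_condition",
    "D_BOUND_MAX",
    "D_FREE_MIN",
]

D_BOUND_MAX = 0.08
D_FREE_MIN = 0.15
D_FREE_MAX = 25.0


@dataclass
class JumpData:
    """Pooled jump lengths of one cell, keyed by lag index (1..max_lag)."""

    jumps: dict[int, np.ndarray]
    frame_interval_s: float
    sigma_um: float
    cell_id: str = ""
    r_max_um: float | None = None  # linking gate, if tracks were gated

    @property
    def n_jumps(self) -> int:
        return int(sum(len(v) for v in self.jumps.values()))


def collect_jumps(tracks: TrackSet, max_lag: int = 4, sigma_um: float | None = None,
                  cap_per_track: int | None = None,
                  cell_id: str = "") -> JumpData:
    """Pool per-lag displacement magnitudes over all tracks of one cell.

    For lag ``n`` every in-track displacement between frames i and i+n is
    collected. ``cap_per_track`` optionally limits each track to its first
    so-many jumps per lag; it is off by default because when the linking
    gate fragments fast tracks, a per-track quota over-weights the mobile
    population (each fragment gets its own quota) and biases the bound
    fraction low. Warns when no track has >= 2 frames.
    """
    cfg = tracks.config
    out: dict[int, list[np.ndarray]] = {n: [] for n in range(1, max_lag + 1)}
    any_track = False
    for _, g in tracks.iter_tracks():
        xy = g[["x_um", "y_um"]].to_numpy(float)
        if len(xy) < 2:
            continue
        any_track = True
        for n in range(1, min(max_lag, len(xy) - 1) + 1):
            d = xy[n:] - xy[:-n]
            r = np.hypot(d[:, 0], d[:, 1])
            out[n].append(r[:cap_per_track] if cap_per_track else r)
    if not any_track:
        import warnings

        warnings.warn("no tracks with >= 2 frames; empty JumpData")
    jumps = {n: (np.concatenate(v) if v else np.array([])) for n, v in out.items()}
    jumps = {n: r for n, r in jumps.items() if len(r)}
    return JumpData(
        jumps=jumps,
        frame_interval_s=cfg.frame_interval_s,
        sigma_um=sigma_um if sigma_um is not None else cfg.localization_sigma_um,
        cell_id=cell_id,
        r_max_um=cfg.r_max_um,
    )


def model_jump_cdf(r, D: float, lag_time_s: float, sigma_um: float):
    """CDF of 2D jump lengths under diffusion D with endpoint localization error."""
    if D < 0:
        raise ValueError("D must be >= 0")
    r = np.asarray(r, dtype=float)
    scale = 4.0 * (D * lag_time_s + sigma_um**2)
    return 1.0 - np.exp(-(r**2) / scale)


def _truncated_step_ratio(D: float, dt: float, sigma: float, gate: float) -> float:
    """Variance retention of a gated diffusive step.

    The squared observed step is ~Exp(mean m = 4 D dt + 4 sigma^2); gating at
    ``gate`` retains the fraction ``1 - x e^-x / (1 - e^-x)`` of its mean,
    with ``x = gate^2 / m``.
    """
    m = 4.0 * D * dt + 4.0 * sigma**2
    x = gate**2 / m
    if x > 50.0:
        return 1.0
    emx = np.exp(-x)
    return float(1.0 - x * emx / (1.0 - emx))


@dataclass
class TwoStateFit:
    """Per-cell result of the two-state mixture fit."""

    F_bound_hat: float
    D_free_hat: float
    D_bound_hat: float
    sigma_um: float
    residual: float
    n_jumps: int
    cell_id: str = ""
    flags: list[str] = field(default_factory=list)


_GRID_POINTS = 200


def _prepare_grids(data: JumpData):
    """Quantile-spaced r grid and empirical CDF per lag."""
    grids = {}
    qs = (np.arange(_GRID_POINTS) + 0.5) / _GRID_POINTS
    for n, r in data.jumps.items():
        r_sorted = np.sort(r)
        grid = np.quantile(r_sorted, qs)
        ecdf = np.searchsorted(r_sorted, grid, side="right") / len(r_sorted)
        grids[n] = (grid, ecdf)
    return grids


def fit_two_state(
    data: JumpData,
    d_bound_max: float = D_BOUND_MAX,
    d_free_min: float = D_FREE_MIN,
    d_free_max: float = D_FREE_MAX,
    sigma_um: float | None = None,
    fit_sigma: bool = False,
    gate_aware: bool = True,
    min_jumps: int = 200,
) -> TwoStateFit:
    """Fit the bound/free mixture to the pooled jump-length CDFs of one cell.

    Minimizes the summed squared difference between empirical and model CDFs
    on a 200-point quantile-spaced grid per lag, jointly over all lags, with
    D_bound <= ``d_bound_max`` and D_free in [``d_free_min``, ``d_free_max``].
    Deterministic multi-start (6 starts spanning the bound box); the best
    residual wins. ``sigma`` is fixed by default (the near-degeneracy between
    sigma and D_bound makes joint fitting fragile); set ``fit_sigma=True``
    to free it within [0.01, 0.1] um.

    Fewer than ``min_jumps`` jumps flags the fit low-confidence; an empty
    JumpData raises.
    """
    if not data.jumps:
        raise ValueError("empty JumpData")
    sigma0 = data.sigma_um if sigma_um is None else sigma_um
    dt = data.frame_interval_s
    gate = data.r_max_um if gate_aware else None
    grids = _prepare_grids(data)
    weights = {n: len(data.jumps[n]) / data.n_jumps for n in grids}

    def objective(x):
        fb, db, dfree = x[0], x[1], x[2]
        sig = x[3] if fit_sigma else sigma0
        total = 0.0
        for n, (grid, ecdf) in grids.items():
            t = n * dt
            if gate is not None and n >= 2:
                db_n = db * _truncated_step_ratio(db, dt, sig, gate)
                df_n = dfree * _truncated_step_ratio(dfree, dt, sig, gate)
            else:
                db_n, df_n = db, dfree
            model = (fb * model_jump_cdf(grid, db_n, t, sig)
                     + (1.0 - fb) * model_jump_cdf(grid, df_n, t, sig))
            if gate is not None and n == 1:
                norm = (fb * model_jump_cdf(gate, db_n, t, sig)
                        + (1.0 - fb) * model_jump_cdf(gate, df_n, t, sig))
                model = model / max(norm, 1e-12)
            total += weights[n] * float(np.sum((ecdf - model) ** 2))
        return total

    bounds = [(0.0, 1.0), (0.0, d_bound_max), (d_free_min, d_free_max)]
    starts = [
        (0.2, 0.005, 0.5),
        (0.5, 0.005, 1.0),
        (0.8, 0.005, 1.0),
        (0.3, 0.02, 3.0),
        (0.6, 0.01, 2.0),
        (0.9, 0.04, max(d_free_min, 0.3)),
    ]
    if fit_sigma:
        bounds.append((0.01, 0.1))
        starts = [s + (sigma0,) for s in starts]

    best = None
    for s0 in starts:
        res = minimize(objective, np.array(s0, dtype=float), method="L-BFGS-B",
                       bounds=bounds)
        if best is None or res.fun < best.fun:
            best = res
    fb, db, dfree = best.x[0], best.x[1], best.x[2]
    sig = best.x[3] if fit_sigma else sigma0

    flags = []
    if data.n_jumps < min_jumps:
        flags.append("low_confidence")
    if dfree >= d_free_max * (1.0 - 1e-6):
        flags.append("D_free_at_upper_bound")
    return TwoStateFit(float(fb), float(dfree), float(db), float(sig),
                       float(best.fun), data.n_jumps, data.cell_id, flags)


def summarize_condition(fits: list[TwoStateFit]) -> dict:
    """Unweighted per-cell mean and SD of F_bound and D_free for one condition."""
    if len(fits) < 2:
        raise ValueError("need >= 2 cells to summarize a condition")
    fb = np.array([f.F_bound_hat for f in fits])
    df = np.array([f.D_free_hat for f in fits])
    return {
        "n_cells": len(fits),
        "F_bound_mean": float(fb.mean()),
        "F_bound_sd": float(fb.std(ddof=1)),
        "D_free_mean": float(df.mean()),
        "D_free_sd": float(df.std(ddof=1)),
        "cells": [f.cell_id for f in fits],
    }
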