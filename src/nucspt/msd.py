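"""Per-molecule apparent diffusion coefficients from MSD curves.

For each track the time-averaged mean squared displacement is computed over
all overlapping pairs, a line ``MSD(tau) = 4 D' tau + b`` is fit over the
first few lags (the intercept absorbs the static localization-error offset
``4 sigma^2``), and molecules are filtered by track length and fit quality
before entering distribution-level comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .tracking import TrackSet

__all__ = [
    "MSDResult",
    "DiffusionDistribution",
    "compute_msd",
    "estimate_D",
    "analyze_tracks",
    "filter_results",
    "D_PRIME_FLOOR",
]

#: floor for non-positive MSD slopes so log10(D') stays defined
D_PRIME_FLOOR = 1e-4

#: default number of MSD lags entering the linear fit
DEFAULT_FIT_LAGS = 4

MIN_FRAMES = 5
MAX_FRAMES = 150
MIN_R2 = 0.8


@dataclass
class MSDResult:
    track_id: object
    n_frames: int
    msd_curve: np.ndarray | None  # MSD at lags 1..n-1 (um^2)
    D_prime: float = np.nan
    r_squared: float = np.nan
    slope: float = np.nan
    intercept: float = np.nan
    flag: str = ""  # "", "nonpositive_slope", or an exclusion reason


def compute_msd(xy: np.ndarray, frames: np.ndarray | None = None) -> np.ndarray:
    """Time-averaged MSD of one gap-free track at lags 1..len-1.

    ``MSD(n dt) = mean_i |pos(i+n) - pos(i)|^2`` over all overlapping pairs.
    Rejects gapped tracks when ``frames`` is provided.
    """
    xy = np.asarray(xy, dtype=float)
    if len(xy) < 2:
        raise ValueError("track must have at least 2 points")
    if frames is not None:
        frames = np.asarray(frames)
        if np.any(np.diff(frames) != 1):
            raise ValueError("gapped track: frames must be consecutive")
    n = len(xy)
    out = np.empty(n - 1)
    for lag in range(1, n):
        d = xy[lag:] - xy[:-lag]
        out[lag - 1] = np.mean(d[:, 0] ** 2 + d[:, 1] ** 2)
    return out


def estimate_D(
    xy: np.ndarray,
    frame_interval_s: float,
    track_id: object = None,
    fit_lags: int = DEFAULT_FIT_LAGS,
    fit_intercept: bool = True,
    min_frames: int = MIN_FRAMES,
    max_frames: int = MAX_FRAMES,
) -> MSDResult:
    """Apparent diffusion coefficient D' of one track.

    Ordinary least squares of MSD(tau) over lags ``1..min(fit_lags, len-1)``;
    D' = slope / 4, with R^2 computed on the fitted window only. Tracks
    outside the length bounds are returned excluded (with a reason flag),
    not raised. Non-positive slopes are floored at ``D_PRIME_FLOOR`` and
    flagged.
    """
    n = len(xy)
    if n < min_frames:
        return MSDResult(track_id, n, None, flag="too_short")
    if n > max_frames:
        return MSDResult(track_id, n, None, flag="too_long")
    msd = compute_msd(xy)
    k = min(fit_lags, n - 1)
    tau = np.arange(1, k + 1) * frame_interval_s
    y = msd[:k]
    if fit_intercept:
        a = np.vstack([tau, np.ones_like(tau)]).T
        (slope, intercept), *_ = np.linalg.lstsq(a, y, rcond=None)
    else:
        slope = float(np.dot(tau, y) / np.dot(tau, tau))
        intercept = 0.0
    pred = slope * tau + intercept
    ss_res = float(np.sum((y - pred) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else (1.0 if ss_res == 0 else 0.0)
    if slope > 0:
        d_prime = slope / 4.0
        flag = ""
    else:
        d_prime = D_PRIME_FLOOR
        flag = "nonpositive_slope"
    return MSDResult(track_id, n, msd, d_prime, r2, float(slope), float(intercept), flag)


def analyze_tracks(tracks: TrackSet, fit_lags: int = DEFAULT_FIT_LAGS,
                   fit_intercept: bool = True,
                   min_frames: int = MIN_FRAMES, max_frames: int = MAX_FRAMES) -> pd.DataFrame:
    """Per-track MSD fits for a whole TrackSet.

    Returns a DataFrame: track_id, cell_id, n_frames, D_prime, r_squared,
    slope, intercept, flag.
    """
    dt = tracks.config.frame_interval_s
    rows = []
    for tid, g in tracks.iter_tracks():
        xy = g[["x_um", "y_um"]].to_numpy(float)
        res = estimate_D(xy, dt, track_id=tid, fit_lags=fit_lags,
                         fit_intercept=fit_intercept,
                         min_frames=min_frames, max_frames=max_frames)
        rows.append((tid, g["cell_id"].iloc[0], res.n_frames, res.D_prime,
                     res.r_squared, res.slope, res.intercept, res.flag))
    return pd.DataFrame(rows, columns=["track_id", "cell_id", "n_frames", "D_prime",
                                       "r_squared", "slope", "intercept", "flag"])


@dataclass
class DiffusionDistribution:
    """Filtered per-molecule D' values for one condition."""

    label: str
    results: pd.DataFrame  # filtered rows of analyze_tracks output
    counts: dict = field(default_factory=dict)  # in/out tallies per gate

    @property
    def log10_D(self) -> np.ndarray:
        """log10 D' of retained molecules, excluding floored slopes."""
        ok = self.results["flag"] == ""
        return np.log10(self.results.loc[ok, "D_prime"].to_numpy(float))

    @property
    def n_molecules(self) -> int:
        return len(self.results)


def filter_results(results: pd.DataFrame, label: str = "",
                   min_r2: float = MIN_R2, min_frames: int = MIN_FRAMES,
                   max_frames: int = MAX_FRAMES) -> DiffusionDistribution:
    """Apply the track-length and fit-quality gates (all boundaries inclusive).

    Retains rows with ``min_frames <= n_frames <= max_frames`` and
    ``r_squared >= min_r2``; records in/out counts per gate.
    """
    n_total = len(results)
    len_ok = (results["n_frames"] >= min_frames) & (results["n_frames"] <= max_frames)
    r2_ok = results["r_squared"] >= min_r2
    keep = len_ok & r2_ok
    counts = {
        "total": n_total,
        "fail_length": int((~len_ok).sum()),
        "fail_r2": int((len_ok & ~r2_ok).sum()),
        "retained": int(keep.sum()),
    }
    return DiffusionDistribution(label, results.loc[keep].reset_index(drop=True), counts)
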