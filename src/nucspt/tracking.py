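"""Trajectory linking from per-frame localizations.

Replicates the contract of MTT-style trackers: a maximum expected diffusion
coefficient ``D_max`` sets the largest admissible frame-to-frame displacement
``r_max``, and localizations are linked frame pair by frame pair with an
optimal bipartite assignment (minimum total squared displacement among
pairings within the gate). Unmatched localizations seed new tracks.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .simulate import CellRecording, GroundTruth

__all__ = [
    "LinkingConfig",
    "TrackSet",
    "compute_r_max",
    "link",
    "link_recording",
    "link_accuracy",
    "detect_spots",
]


def compute_r_max(D_max: float, frame_interval_s: float, sigma_um: float = 0.0) -> float:
    """Maximum admissible frame-to-frame displacement.

    ``sqrt(4 * D_max * dt)`` — the RMS displacement of the fastest expected
    molecule — plus a ``3 * sigma`` localization-noise allowance so legitimate
    jumps of fast molecules are not truncated by measurement error. Pass
    ``sigma_um=0`` for the bare formula.
    """
    if D_max <= 0 or frame_interval_s <= 0 or sigma_um < 0:
        raise ValueError("D_max and frame_interval_s must be positive, sigma_um >= 0")
    return math.sqrt(4.0 * D_max * frame_interval_s) + 3.0 * sigma_um


@dataclass(frozen=True)
class LinkingConfig:
    """Gating and gap parameters for the linker."""

    D_max: float
    frame_interval_s: float
    localization_sigma_um: float = 0.0
    gap_frames: int = 0

    @property
    def r_max_um(self) -> float:
        return compute_r_max(self.D_max, self.frame_interval_s, self.localization_sigma_um)


@dataclass
class TrackSet:
    """Linked trajectories plus provenance.

    ``tracks`` columns: track_id, cell_id, frame, t_s, x_um, y_um, loc_index
    (row position in the input localization table, for ground-truth audits).
    """

    tracks: pd.DataFrame
    config: LinkingConfig
    source_id: str = ""

    def __len__(self) -> int:
        return int(self.tracks["track_id"].nunique()) if len(self.tracks) else 0

    def track_lengths(self) -> pd.Series:
        return self.tracks.groupby("track_id").size()

    def iter_tracks(self):
        for tid, g in self.tracks.groupby("track_id", sort=True):
            yield tid, g


_BIG = 1e12  # cost for gated-out pairings; dominates any feasible total


def link(localizations: pd.DataFrame, config: LinkingConfig, source_id: str = "") -> TrackSet:
    """Link a localization table into tracks.

    Frame-to-frame assignment minimizes total squared displacement among
    pairings within ``r_max`` (optimal bipartite assignment, maximizing the
    number of feasible links first). Localizations are ordered canonically
    within each frame, so the result is invariant to input row order.

    Empty input yields an empty TrackSet. Duplicate (frame, x, y) rows are
    rejected.
    """
    cols = ["frame", "x_um", "y_um"]
    for c in cols:
        if c not in localizations.columns:
            raise ValueError(f"localizations missing required column {c!r}")
    if localizations.duplicated(subset=cols).any():
        raise ValueError("duplicate (frame, x_um, y_um) localization rows")

    out_cols = ["track_id", "cell_id", "frame", "t_s", "x_um", "y_um", "loc_index"]
    if len(localizations) == 0:
        return TrackSet(pd.DataFrame(columns=out_cols), config, source_id)

    df = localizations.reset_index(drop=True).copy()
    df["loc_index"] = np.arange(len(df))
    # canonical intra-frame order for permutation invariance
    df = df.sort_values(["frame", "x_um", "y_um"], kind="mergesort").reset_index(drop=True)
    has_cell = "cell_id" in df.columns
    has_t = "t_s" in df.columns
    r2_max = config.r_max_um**2
    gate = config.gap_frames + 1

    frames = df["frame"].to_numpy()
    xy = df[["x_um", "y_um"]].to_numpy(float)
    frame_values = np.unique(frames)

    next_track = 0
    assigned = np.full(len(df), -1, dtype=int)  # per-row track id
    # open tracks: id -> (last xy, last frame, last row)
    open_xy: list[np.ndarray] = []
    open_frame: list[int] = []
    open_tid: list[int] = []

    for fv in frame_values:
        rows = np.nonzero(frames == fv)[0]
        pts = xy[rows]
        # prune tracks that can no longer be extended
        keep = [i for i, lf in enumerate(open_frame) if fv - lf <= gate]
        open_xy = [open_xy[i] for i in keep]
        open_frame = [open_frame[i] for i in keep]
        open_tid = [open_tid[i] for i in keep]

        matched_rows = np.zeros(len(rows), dtype=bool)
        if open_xy:
            prev = np.vstack(open_xy)
            d2 = ((prev[:, None, :] - pts[None, :, :]) ** 2).sum(axis=2)
            cost = np.where(d2 <= r2_max, d2, _BIG)
            ri, ci = linear_sum_assignment(cost)
            used_tracks = []
            for i, j in zip(ri, ci):
                if cost[i, j] >= _BIG:
                    continue
                tid = open_tid[i]
                assigned[rows[j]] = tid
                open_xy[i] = pts[j]
                open_frame[i] = int(fv)
                matched_rows[j] = True
                used_tracks.append(i)
        # new tracks for unmatched localizations, in canonical order
        for j in np.nonzero(~matched_rows)[0]:
            tid = next_track
            next_track += 1
            assigned[rows[j]] = tid
            open_xy.append(pts[j])
            open_frame.append(int(fv))
            open_tid.append(tid)

    out = pd.DataFrame({
        "track_id": assigned,
        "cell_id": df["cell_id"].to_numpy() if has_cell else source_id,
        "frame": frames,
        "t_s": df["t_s"].to_numpy() if has_t else frames * config.frame_interval_s,
        "x_um": xy[:, 0],
        "y_um": xy[:, 1],
        "loc_index": df["loc_index"].to_numpy(),
    })
    out = out.sort_values(["track_id", "frame"], kind="mergesort").reset_index(drop=True)
    return TrackSet(out, config, source_id)


def link_recording(recording: CellRecording, D_max: float = 5.0,
                   gap_frames: int = 0, noise_allowance: bool = True) -> TrackSet:
    """Convenience: link a simulated recording with its own acquisition settings."""
    cfg = LinkingConfig(
        D_max=D_max,
        frame_interval_s=recording.acquisition.frame_interval_s,
        localization_sigma_um=(recording.acquisition.localization_sigma_um
                               if noise_allowance else 0.0),
        gap_frames=gap_frames,
    )
    return link(recording.localizations, cfg, source_id=recording.cell_id)


def link_accuracy(tracks: TrackSet, recording: CellRecording) -> float:
    """Fraction of reconstructed frame-to-frame links joining the same true molecule.

    Requires the recording's localization table (simulated, with molecule_id).
    """
    if "molecule_id" not in recording.localizations.columns:
        raise ValueError("recording has no ground-truth molecule identities")
    mol = recording.localizations.reset_index(drop=True)["molecule_id"].to_numpy()
    df = tracks.tracks
    n_links = 0
    n_correct = 0
    for _, g in df.groupby("track_id", sort=False):
        ids = mol[g["loc_index"].to_numpy()]
        n_links += len(ids) - 1
        n_correct += int((ids[:-1] == ids[1:]).sum())
    if n_links == 0:
        return float("nan")
    return n_correct / n_links


def detect_spots(image_stack: np.ndarray, threshold_sd: float = 5.0,
                 roi: tuple[slice, slice] | None = None,
                 min_distance: int = 3) -> pd.DataFrame:
    """Minimal local-maxima + Gaussian-weighted-centroid spot detector.

    Intended for synthetic rendered frames only; returns sub-pixel centroids
    (row, col) of maxima exceeding ``background + threshold_sd * robust SD``.
    """
    from skimage.feature import peak_local_max

    stack = np.asarray(image_stack, dtype=float)
    if stack.ndim == 2:
        stack = stack[None]
    rows = []
    for f, frame in enumerate(stack):
        img = frame[roi] if roi is not None else frame
        bg = np.median(img)
        mad = np.median(np.abs(img - bg))
        sd = 1.4826 * mad
        if sd == 0:
            warnings.warn(f"frame {f}: zero intensity spread, no detections")
            continue
        peaks = peak_local_max(img, min_distance=min_distance,
                               threshold_abs=bg + threshold_sd * sd)
        for r0, c0 in peaks:
            # 5x5 intensity-weighted centroid above background
            r_lo, r_hi = max(r0 - 2, 0), min(r0 + 3, img.shape[0])
            c_lo, c_hi = max(c0 - 2, 0), min(c0 + 3, img.shape[1])
            win = np.clip(img[r_lo:r_hi, c_lo:c_hi] - bg, 0, None)
            tot = win.sum()
            if tot <= 0:
                continue
            rr, cc = np.mgrid[r_lo:r_hi, c_lo:c_hi]
            rows.append((f, (rr * win).sum() / tot, (cc * win).sum() / tot,
                         float(img[r0, c0] - bg)))
    return pd.DataFrame(rows, columns=["frame", "row_px", "col_px", "intensity"])
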