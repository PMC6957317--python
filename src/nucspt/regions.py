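"""Euchromatin/heterochromatin masks and region-stratified track analysis.

A binary region mask is built from an intensity snapshot (or taken directly
from a simulated chromatin map), tracks are classified by the region that
holds the majority of their localizations, and the diffusion / kinetic /
dwell analyses are re-run on each region's subset for within-cell
comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import warnings

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .dwell import (
    extract_immobile_tracks,
    fit_double_exponential,
    survival_curve,
)
from .kinetics import fit_two_state, JumpData
from .msd import analyze_tracks, filter_results
from .simulate import CellRecording, ChromatinMap
from .tracking import TrackSet, link_recording

__all__ = [
    "RegionMask",
    "RegionAssignment",
    "mask_from_image",
    "mask_from_chromatin_map",
    "assign_tracks",
    "region_jumps",
    "region_stratified_analysis",
]

HET = "heterochromatin"
EU = "euchromatin"
AMBIGUOUS = "ambiguous"


@dataclass(frozen=True)
class RegionMask:
    """Binary heterochromatin mask; geometry conventions as ChromatinMap."""

    grid: np.ndarray  # bool, True = heterochromatin
    pixel_size_um: float
    origin_x_um: float
    origin_y_um: float
    method: dict = field(default_factory=dict)

    def het_at(self, x_um, y_um) -> np.ndarray:
        cm = ChromatinMap(self.grid.astype(np.uint8), self.pixel_size_um,
                          self.origin_x_um, self.origin_y_um)
        return cm.het_at(x_um, y_um)

    def in_extent(self, x_um, y_um) -> np.ndarray:
        nr, nc = self.grid.shape
        x = np.atleast_1d(x_um)
        y = np.atleast_1d(y_um)
        col = np.floor((x - self.origin_x_um) / self.pixel_size_um)
        row = np.floor((self.origin_y_um - y) / self.pixel_size_um)
        return (row >= 0) & (row < nr) & (col >= 0) & (col < nc)


def mask_from_image(intensity_image: np.ndarray, pixel_size_um: float,
                    origin_x_um: float, origin_y_um: float,
                    smoothing_um: float = 0.3,
                    method: str = "otsu", q: float | None = None,
                    min_size_px: int = 3) -> RegionMask:
    """Threshold an intensity snapshot into a heterochromatin mask.

    The image is Gaussian-smoothed at ``smoothing_um``, thresholded (Otsu by
    default, or at quantile ``q`` with ``method='quantile'``), and connected
    components smaller than ``min_size_px`` pixels are removed. The method
    parameters are recorded in the mask metadata.
    """
    from skimage.filters import threshold_otsu

    img = np.asarray(intensity_image, dtype=float)
    if img.ndim != 2:
        raise ValueError("intensity image must be 2D single-channel")
    if np.ptp(img) == 0:
        raise ValueError("constant image: cannot threshold")
    smoothed = gaussian_filter(img, smoothing_um / pixel_size_um)
    if method == "otsu":
        thr = float(threshold_otsu(smoothed))
    elif method == "quantile":
        if q is None:
            raise ValueError("quantile method requires q")
        thr = float(np.quantile(smoothed, q))
    else:
        raise ValueError(f"unknown method {method!r}")
    grid = smoothed >= thr
    if min_size_px > 1:
        from scipy.ndimage import label as cc_label

        lab, _ = cc_label(grid)
        sizes = np.bincount(lab.ravel())
        keep = sizes >= min_size_px
        keep[0] = False
        grid = keep[lab]
    return RegionMask(grid=grid, pixel_size_um=pixel_size_um,
                      origin_x_um=origin_x_um, origin_y_um=origin_y_um,
                      method={"type": method, "q": q, "threshold": thr,
                              "smoothing_um": smoothing_um, "min_size_px": min_size_px})


def mask_from_chromatin_map(cmap: ChromatinMap) -> RegionMask:
    """Use a simulated chromatin map directly as the region mask (no imaging)."""
    return RegionMask(grid=cmap.grid.astype(bool), pixel_size_um=cmap.pixel_size_um,
                      origin_x_um=cmap.origin_x_um, origin_y_um=cmap.origin_y_um,
                      method={"type": "ground_truth_map"})


@dataclass
class RegionAssignment:
    """Per-track region labels with the majority fraction that produced them."""

    table: pd.DataFrame  # track_id, label, majority_fraction
    majority_threshold: float

    def label_of(self) -> pd.Series:
        return self.table.set_index("track_id")["label"]

    def counts(self) -> dict:
        return self.table["label"].value_counts().to_dict()


def assign_tracks(tracks: TrackSet, mask: RegionMask,
                  majority_threshold: float = 0.8) -> RegionAssignment:
    """Label each track by the region holding the majority of its localizations.

    A track is labeled heterochromatin or euchromatin when the majority
    fraction reaches ``majority_threshold``, else ambiguous. Localizations
    outside the mask extent (e.g. localization noise past the grid edge) are
    ignored in the majority vote; a track entirely outside is ambiguous,
    with one warning per call.
    """
    rows = []
    warned = False
    for tid, g in tracks.iter_tracks():
        x = g["x_um"].to_numpy(float)
        y = g["y_um"].to_numpy(float)
        inside = mask.in_extent(x, y)
        if not inside.any():
            if not warned:
                warnings.warn("track(s) entirely outside mask extent -> ambiguous")
                warned = True
            rows.append((tid, AMBIGUOUS, np.nan))
            continue
        het = mask.het_at(x[inside], y[inside])
        frac_het = float(het.mean())
        frac = max(frac_het, 1.0 - frac_het)
        if frac < majority_threshold:
            rows.append((tid, AMBIGUOUS, frac))
            continue
        rows.append((tid, HET if frac_het >= 0.5 else EU, frac))
    return RegionAssignment(
        pd.DataFrame(rows, columns=["track_id", "label", "majority_fraction"]),
        majority_threshold,
    )


def _subset_tracks(tracks: TrackSet, track_ids) -> TrackSet:
    sub = tracks.tracks[tracks.tracks["track_id"].isin(set(track_ids))].reset_index(drop=True)
    return TrackSet(sub, tracks.config, tracks.source_id)


def region_jumps(tracks: TrackSet, mask: RegionMask, region: str,
                 max_lag: int = 4, **kwargs) -> JumpData:
    """Jump data restricted to displacements with both endpoints in ``region``.

    Requiring both endpoints in-region avoids contaminating a region's jump
    statistics with boundary-crossing displacements.
    """
    want_het = region == HET
    rows = []
    cfg = tracks.config
    out: dict[int, list[np.ndarray]] = {}
    cap = kwargs.get("cap_per_track", None)
    for _, g in tracks.iter_tracks():
        xy = g[["x_um", "y_um"]].to_numpy(float)
        if len(xy) < 2:
            continue
        het = mask.het_at(xy[:, 0], xy[:, 1])
        ok = het == want_het
        for n in range(1, min(max_lag, len(xy) - 1) + 1):
            both = ok[n:] & ok[:-n]
            if not both.any():
                continue
            d = xy[n:][both] - xy[:-n][both]
            r = np.hypot(d[:, 0], d[:, 1])
            out.setdefault(n, []).append(r[:cap] if cap else r)
    jumps = {n: np.concatenate(v) for n, v in out.items() if v}
    return JumpData(jumps=jumps, frame_interval_s=cfg.frame_interval_s,
                    sigma_um=cfg.localization_sigma_um, r_max_um=cfg.r_max_um)


def region_stratified_analysis(
    fast_recordings: list[CellRecording] | None = None,
    slow_recordings: list[CellRecording] | None = None,
    masks: dict[str, RegionMask] | None = None,
    D_max_fast: float = 5.0,
    D_max_dwell: float = 0.05,
    majority_threshold: float = 0.8,
    min_jumps: int = 50,
) -> dict:
    """Run the diffusion, kinetic, and dwell analyses per chromatin region.

    ``masks`` maps cell_id to its RegionMask; cells whose recording carries a
    simulated chromatin map fall back to that map when absent from ``masks``.
    Returns per-region per-cell two-state fits and diffusion tables (fast
    recordings), per-region pooled dwell fits (slow recordings), and a paired
    per-cell table for within-cell comparisons. Regions with fewer than
    ``min_jumps`` jumps in a cell are flagged and excluded from summaries.
    """
    masks = masks or {}

    def mask_for(rec: CellRecording) -> RegionMask | None:
        if rec.cell_id in masks:
            return masks[rec.cell_id]
        if rec.chromatin_map is not None:
            return mask_from_chromatin_map(rec.chromatin_map)
        return None

    result: dict = {"per_cell": [], "diffusion": {}, "dwell": {}}

    if fast_recordings:
        diff_tables = {HET: [], EU: []}
        for rec in fast_recordings:
            mask = mask_for(rec)
            if mask is None:
                raise ValueError(f"no mask available for cell {rec.cell_id}")
            ts = link_recording(rec, D_max=D_max_fast)
            assignment = assign_tracks(ts, mask, majority_threshold)
            row = {"cell_id": rec.cell_id}
            for region in (HET, EU):
                ids = assignment.table.loc[assignment.table["label"] == region, "track_id"]
                sub = _subset_tracks(ts, ids)
                res = analyze_tracks(sub)
                dist = filter_results(res, label=f"{rec.cell_id}:{region}")
                diff_tables[region].append(dist.results)
                jd = region_jumps(ts, mask, region)
                jd.cell_id = rec.cell_id
                if jd.n_jumps >= min_jumps:
                    fit = fit_two_state(jd)
                    row[f"F_bound_{region}"] = fit.F_bound_hat
                    row[f"D_free_{region}"] = fit.D_free_hat
                    row[f"n_jumps_{region}"] = jd.n_jumps
                else:
                    row[f"F_bound_{region}"] = np.nan
                    row[f"D_free_{region}"] = np.nan
                    row[f"n_jumps_{region}"] = jd.n_jumps
                    row.setdefault("flags", []).append(f"few_jumps_{region}")
                med = (np.median(dist.log10_D) if dist.n_molecules else np.nan)
                row[f"log10D_median_{region}"] = med
            result["per_cell"].append(row)
        for region in (HET, EU):
            tabs = [t for t in diff_tables[region] if len(t)]
            result["diffusion"][region] = (pd.concat(tabs, ignore_index=True)
                                           if tabs else pd.DataFrame())

    if slow_recordings:
        durations = {HET: [], EU: []}
        for rec in slow_recordings:
            mask = mask_for(rec)
            if mask is None:
                raise ValueError(f"no mask available for cell {rec.cell_id}")
            ts = extract_immobile_tracks(rec, D_max=D_max_dwell)
            assignment = assign_tracks(ts, mask, majority_threshold)
            labels = assignment.label_of()
            dt = ts.config.frame_interval_s
            sizes = ts.tracks.groupby("track_id").size()
            for region in (HET, EU):
                ids = labels[labels == region].index
                durations[region].append((sizes.loc[sizes.index.isin(ids)] - 1) * dt)
        for region in (HET, EU):
            if durations[region]:
                d = np.concatenate([np.asarray(x, float) for x in durations[region]])
            else:
                d = np.array([])
            if len(d) >= 5:
                curve = survival_curve(d)
                result["dwell"][region] = fit_double_exponential(curve)
            else:
                result["dwell"][region] = None

    result["per_cell"] = pd.DataFrame(result["per_cell"]) if result["per_cell"] else pd.DataFrame()
    return result
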