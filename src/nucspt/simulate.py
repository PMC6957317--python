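"""Forward model: sparse single-molecule recordings of a nuclear protein.

Simulates molecules switching between free and bound states (see
:mod:`nucspt.presets`) while diffusing inside a reflecting circular nucleus,
observed through a camera with Gaussian localization error, photobleaching,
and — in slow-dwell mode — motion-blur-based loss of mobile molecules.

Two acquisition modes mirror the two experimental protocols:

* ``fast`` (10 ms frames, 100 Hz): all emitting molecules are detected; the
  data feed trajectory linking, MSD, and jump-length kinetic analysis.
* ``slow`` (500 ms frames, 2 Hz): a molecule is detected only if its true
  displacement during the exposure stays below ``blur_threshold_um`` — mobile
  molecules blur into the background and only stably bound ones are recorded,
  which is what makes track durations read out residence times.

Sparse labeling is emulated by giving each molecule a random activation frame
(uniform over the movie) and a geometric photobleaching lifetime, so only a
small number of emitters is visible at any instant.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .presets import (
    STATE_BOUND_LONG,
    STATE_BOUND_SHORT,
    STATE_FREE,
    KineticPreset,
    derive_rates,
)

__all__ = [
    "AcquisitionConfig",
    "NucleusGeometry",
    "ChromatinMap",
    "GroundTruth",
    "CellRecording",
    "simulate_cell",
    "simulate_condition",
    "simulate_chromatin_map",
    "render_chromatin_image",
    "render_spot_frames",
]


@dataclass(frozen=True)
class AcquisitionConfig:
    """Camera and photophysics settings for one recording.

    frame_interval_s >= exposure_s > 0; in the replication configs the fast
    mode runs at 100 Hz (0.01 s frames) and the slow mode at 2 Hz (0.5 s).
    """

    frame_interval_s: float
    exposure_s: float
    n_frames: int
    localization_sigma_um: float = 0.035
    mode: str = "fast"  # "fast" | "slow"
    bleach_prob_per_frame: float = 0.01
    blur_threshold_um: float = 0.2
    density_per_um2: float | None = None
    #: "staggered": molecules become fluorescent at uniform-random frames
    #: (activation/label-exchange regime, keeps instantaneous density low for
    #: fast tracking); "from_start": all molecules emit from frame 0 until
    #: bleached (pre-labeled regime, lets dwell analysis identify and drop
    #: left-censored binding events as tracks touching frame 0)
    activation: str = "staggered"

    def __post_init__(self) -> None:
        if not (self.frame_interval_s >= self.exposure_s > 0.0):
            raise ValueError("require frame_interval_s >= exposure_s > 0")
        if not (0.0 <= self.bleach_prob_per_frame <= 1.0):
            raise ValueError("bleach_prob_per_frame must be in [0, 1]")
        if self.mode not in ("fast", "slow"):
            raise ValueError(f"mode must be 'fast' or 'slow', got {self.mode!r}")
        if self.activation not in ("staggered", "from_start"):
            raise ValueError("activation must be 'staggered' or 'from_start'")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")

    @classmethod
    def fast_tracking(cls, n_frames: int = 5000, **kwargs) -> "AcquisitionConfig":
        """100 Hz configuration for jump/diffusion analysis."""
        kwargs.setdefault("bleach_prob_per_frame", 0.01)
        return cls(frame_interval_s=0.01, exposure_s=0.01, n_frames=n_frames,
                   mode="fast", **kwargs)

    @classmethod
    def slow_dwell(cls, n_frames: int = 1200, **kwargs) -> "AcquisitionConfig":
        """2 Hz configuration for residence-time analysis.

        The default movie length (600 s) keeps observation windows dominated
        by the mild exponential bleaching rather than by movie-end
        truncation; short windows preferentially censor long dwells and
        distort the fitted survival mixture.
        """
        kwargs.setdefault("bleach_prob_per_frame", 0.005)
        kwargs.setdefault("activation", "from_start")
        return cls(frame_interval_s=0.5, exposure_s=0.5, n_frames=n_frames,
                   mode="slow", **kwargs)


@dataclass(frozen=True)
class NucleusGeometry:
    """2D circular nucleus with a reflecting boundary."""

    radius_um: float = 3.0
    boundary: str = "reflecting"

    def __post_init__(self) -> None:
        if self.radius_um <= 0:
            raise ValueError("radius_um must be positive")

    @property
    def area_um2(self) -> float:
        return math.pi * self.radius_um**2


#: default nucleus sizes for the two cerebellar cell types
GRANULE_GEOMETRY = NucleusGeometry(radius_um=3.0)
PURKINJE_GEOMETRY = NucleusGeometry(radius_um=6.0)


@dataclass(frozen=True)
class ChromatinMap:
    """Binary heterochromatin map on a pixel grid covering the nucleus box.

    Pixel (0, 0) has its upper-left corner at (origin_x_um, origin_y_um);
    rows advance toward negative y (row-major, half-open pixels).
    """

    grid: np.ndarray  # 2D uint8/bool, 1 = heterochromatin
    pixel_size_um: float
    origin_x_um: float
    origin_y_um: float

    def pixel_of(self, x_um: np.ndarray, y_um: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        col = np.floor((np.asarray(x_um) - self.origin_x_um) / self.pixel_size_um).astype(int)
        row = np.floor((self.origin_y_um - np.asarray(y_um)) / self.pixel_size_um).astype(int)
        return row, col

    def het_at(self, x_um, y_um) -> np.ndarray:
        """Vectorized lookup: True where (x, y) falls in a heterochromatin pixel.

        Positions outside the grid extent are classified euchromatin.
        """
        row, col = self.pixel_of(np.atleast_1d(x_um), np.atleast_1d(y_um))
        nr, nc = self.grid.shape
        inside = (row >= 0) & (row < nr) & (col >= 0) & (col < nc)
        out = np.zeros(row.shape, dtype=bool)
        out[inside] = self.grid[row[inside], col[inside]].astype(bool)
        return out

    def het_fraction(self, geometry: NucleusGeometry) -> float:
        """Heterochromatin fraction among pixels whose center lies in the nucleus."""
        nr, nc = self.grid.shape
        ys = self.origin_y_um - (np.arange(nr) + 0.5) * self.pixel_size_um
        xs = self.origin_x_um + (np.arange(nc) + 0.5) * self.pixel_size_um
        xx, yy = np.meshgrid(xs, ys)
        inside = xx**2 + yy**2 <= geometry.radius_um**2
        return float(self.grid.astype(bool)[inside].mean())


@dataclass
class GroundTruth:
    """Exact per-frame states/positions and event-level dwell log.

    frames: molecule_id, frame, state, true_x_um, true_y_um (all emitting
    molecule-frames, including ones blurred out of the localization table).
    events: molecule_id, state, t_start_s, t_end_s for every contiguous state
    dwell; events truncated by activation, bleaching, or movie end keep their
    observed span.
    """

    frames: pd.DataFrame
    events: pd.DataFrame
    bleach_frame: pd.Series  # molecule_id -> first frame no longer emitting


@dataclass
class CellRecording:
    """One cell's localization stream plus acquisition settings and truth."""

    localizations: pd.DataFrame  # cell_id, molecule_id, frame, t_s, x_um, y_um
    acquisition: AcquisitionConfig
    geometry: NucleusGeometry
    preset_name: str
    cell_id: str
    seed: int | None = None
    ground_truth: GroundTruth | None = None
    chromatin_map: ChromatinMap | None = None


def _reflect_into_disk(pos: np.ndarray, radius: float) -> np.ndarray:
    """Mirror positions outside the circle back inside (iteratively)."""
    pos = np.array(pos, dtype=float, copy=True)
    for _ in range(32):
        r = np.hypot(pos[:, 0], pos[:, 1])
        out = r > radius
        if not out.any():
            break
        scale = (2.0 * radius - r[out]) / r[out]
        # a reflected point that overshoots the far side is handled on the
        # next iteration; pathological overshoot past the center is clipped
        scale = np.maximum(scale, -1.0)
        pos[out] *= scale[:, None]
    else:  # pragma: no cover - steps are tiny relative to the radius
        r = np.hypot(pos[:, 0], pos[:, 1])
        out = r > radius
        pos[out] *= (radius / r[out])[:, None]
    return pos


def _uniform_disk(rng: np.random.Generator, n: int, radius: float) -> np.ndarray:
    r = radius * np.sqrt(rng.uniform(size=n))
    theta = rng.uniform(0.0, 2.0 * math.pi, size=n)
    return np.column_stack([r * np.cos(theta), r * np.sin(theta)])


def _sample_initial_states(rng: np.random.Generator, n: int, preset: KineticPreset) -> np.ndarray:
    """Draw states from the stationary distribution of the chain."""
    rates = derive_rates(preset)
    pi_free, pi_short, pi_long = rates.stationary_distribution()
    return rng.choice(
        [STATE_FREE, STATE_BOUND_SHORT, STATE_BOUND_LONG],
        size=n,
        p=[pi_free, pi_short, pi_long],
    )


def _simulate_state_paths(
    rng: np.random.Generator,
    preset: KineticPreset,
    appear: np.ndarray,
    death: np.ndarray,
    dt: float,
    n_frames: int,
):
    """Exact continuous-time state paths for every molecule (homogeneous case).

    Returns per-frame effective diffusion coefficients (time-weighted over
    within-frame state switches), the state at each frame start, and the
    event log.
    """
    n_mol = len(appear)
    rates = derive_rates(preset)
    d_of_state = {STATE_FREE: preset.D_free,
                  STATE_BOUND_SHORT: preset.D_bound,
                  STATE_BOUND_LONG: preset.D_bound}
    mean_dwell = {STATE_FREE: 1.0 / rates.k_on,
                  STATE_BOUND_SHORT: preset.tau_short_s,
                  STATE_BOUND_LONG: preset.tau_long_s}

    eff_d = np.zeros((n_mol, n_frames), dtype=np.float32)
    state_at = np.full((n_mol, n_frames), -1, dtype=np.int8)
    init_states = _sample_initial_states(rng, n_mol, preset)
    ev_mol, ev_state, ev_t0, ev_t1 = [], [], [], []

    for m in range(n_mol):
        t = appear[m] * dt
        t_stop = death[m] * dt
        state = int(init_states[m])
        while t < t_stop:
            dwell = rng.exponential(mean_dwell[state])
            t_end = min(t + dwell, t_stop)
            ev_mol.append(m)
            ev_state.append(state)
            ev_t0.append(t)
            ev_t1.append(t_end)
            # time-weighted D contribution for every frame the segment overlaps
            f_lo = int(math.floor(t / dt + 1e-12))
            f_hi = min(int(math.ceil(t_end / dt - 1e-12)), n_frames)
            if f_hi > f_lo:
                idx = np.arange(f_lo, f_hi)
                overlap = np.minimum((idx + 1) * dt, t_end) - np.maximum(idx * dt, t)
                eff_d[m, idx] += (overlap * d_of_state[state]).astype(np.float32)
                # state at frame start: frames whose start time falls in the segment
                s_lo = int(math.ceil(t / dt - 1e-12))
                s_hi = min(int(math.ceil(t_end / dt - 1e-12)), n_frames)
                if s_hi > s_lo:
                    state_at[m, s_lo:s_hi] = state
            if state == STATE_FREE:
                state = (STATE_BOUND_LONG if rng.uniform() < rates.p_long
                         else STATE_BOUND_SHORT)
            else:
                state = STATE_FREE
            t = t_end
    eff_d /= np.float32(dt)
    events = pd.DataFrame({
        "molecule_id": np.array(ev_mol, dtype=int),
        "state": np.array(ev_state, dtype=np.int8),
        "t_start_s": np.array(ev_t0, dtype=float),
        "t_end_s": np.array(ev_t1, dtype=float),
    })
    return eff_d, state_at, events


def _regional_rate_table(preset: KineticPreset):
    """Per-region (euchromatin/heterochromatin) kinetic parameters."""
    out = {}
    for region in ("euchromatin", "heterochromatin"):
        p = preset.for_region(region)
        r = derive_rates(p)
        out[region] = (p, r)
    return out


def simulate_cell(
    preset: KineticPreset,
    geometry: NucleusGeometry,
    acq: AcquisitionConfig,
    n_molecules: int,
    seed: int,
    chromatin_map: ChromatinMap | None = None,
    cell_id: str = "cell0",
    keep_ground_truth: bool = True,
) -> CellRecording:
    """Simulate one cell's recording with exact ground truth.

    Molecules activate at uniform-random frames, bleach with a per-frame
    Bernoulli probability, start from the stationary state distribution and
    a uniform position in the nucleus, and take Gaussian frame displacements
    with per-axis variance ``2 * D_eff * dt`` (``D_eff`` time-weighted over
    within-frame state switches). Reported positions are the true frame-start
    positions plus Gaussian localization noise. In slow mode a molecule is
    reported only when its true displacement over the exposure does not
    exceed ``blur_threshold_um``.

    When ``chromatin_map`` is given and the preset carries region modifiers,
    kinetics become position-dependent: states are then updated per frame
    with region-local rates (transitions at frame boundaries).

    Identical arguments (including ``seed``) give bit-identical output.
    """
    if n_molecules <= 0:
        raise ValueError("n_molecules must be positive")
    rng = np.random.default_rng(seed)
    dt = acq.frame_interval_s
    n_frames = acq.n_frames
    radius = geometry.radius_um
    sigma = acq.localization_sigma_um

    if acq.activation == "staggered":
        appear = rng.integers(0, n_frames, size=n_molecules)
    else:
        appear = np.zeros(n_molecules, dtype=int)
    if acq.bleach_prob_per_frame > 0:
        lifetime = rng.geometric(acq.bleach_prob_per_frame, size=n_molecules)
    else:
        lifetime = np.full(n_molecules, n_frames, dtype=int)
    death = np.minimum(appear + lifetime, n_frames)

    regional = chromatin_map is not None and bool(preset.region_modifiers)
    if not regional:
        eff_d, state_at, events = _simulate_state_paths(rng, preset, appear, death, dt, n_frames)
    else:
        rate_table = _regional_rate_table(preset)
        state_now = np.full(n_molecules, -1, dtype=np.int8)
        t_unbind = np.full(n_molecules, np.inf)  # absolute unbinding time (s)
        state_hist = np.full((n_molecules, n_frames), -1, dtype=np.int8)
        tau_of = {STATE_BOUND_SHORT: preset.tau_short_s,
                  STATE_BOUND_LONG: preset.tau_long_s}

    pos = _uniform_disk(rng, n_molecules, radius)
    mol_ids = np.arange(n_molecules)

    loc_chunks: list[dict] = []
    gt_chunks: list[dict] = []
    slow = acq.mode == "slow"

    for f in range(n_frames):
        active = (appear <= f) & (f < death)
        if not active.any():
            continue
        idx = np.nonzero(active)[0]
        p = pos[idx]

        t_f = f * dt
        t_f1 = (f + 1) * dt
        if regional:
            het = chromatin_map.het_at(p[:, 0], p[:, 1])
            p_eu, r_eu = rate_table["euchromatin"]
            p_he, r_he = rate_table["heterochromatin"]
            newly = state_now[idx] < 0
            if newly.any():
                u = rng.uniform(size=int(newly.sum()))
                v = rng.uniform(size=int(newly.sum()))
                sub = idx[newly]
                het_n = het[newly]
                fb = np.where(het_n, p_he.F_bound, p_eu.F_bound)
                # split bound occupancy between short/long by occupancy share
                share_he = (r_he.p_long / r_he.k_off_long) / r_he.mean_bound_dwell_s
                share_eu = (r_eu.p_long / r_eu.k_off_long) / r_eu.mean_bound_dwell_s
                share = np.where(het_n, share_he, share_eu)
                st0 = np.where(u < fb,
                               np.where(v < share, STATE_BOUND_LONG, STATE_BOUND_SHORT),
                               STATE_FREE)
                state_now[sub] = st0
                # residual dwell of an in-progress event is exponential with
                # the same mean (memorylessness)
                bound0 = st0 != STATE_FREE
                taus = np.where(st0 == STATE_BOUND_LONG,
                                preset.tau_long_s, preset.tau_short_s)
                resid = rng.exponential(taus)
                t_unbind[sub] = np.where(bound0, t_f + resid, np.inf)
            st = state_now[idx]
            free = st == STATE_FREE
            d_free = np.where(het, p_he.D_free, p_eu.D_free)
            d_bound = np.where(het, p_he.D_bound, p_eu.D_bound)
            # frames containing the (exact, sub-frame) unbinding moment get a
            # time-weighted D; fully bound frames stay at D_bound
            tu = t_unbind[idx]
            w_bound = np.clip((tu - t_f) / dt, 0.0, 1.0)
            d_eff = np.where(free, d_free,
                             w_bound * d_bound + (1.0 - w_bound) * d_free)
            state_hist[idx, f] = st
            states_f = st
        else:
            d_eff = eff_d[idx, f].astype(float)
            states_f = state_at[idx, f]

        if keep_ground_truth:
            gt_chunks.append({
                "molecule_id": mol_ids[idx], "frame": np.full(len(idx), f),
                "state": states_f.copy(), "true_x_um": p[:, 0].copy(),
                "true_y_um": p[:, 1].copy(),
            })

        step = rng.normal(size=(len(idx), 2)) * np.sqrt(2.0 * d_eff * dt)[:, None]
        new_p = _reflect_into_disk(p + step, radius)
        noise = rng.normal(scale=sigma, size=(len(idx), 2)) if sigma > 0 else np.zeros((len(idx), 2))
        d_vis = d_eff

        if regional:
            # unbinding this frame -> free afterwards
            done = (~free) & (t_unbind[idx] < t_f1)
            state_now[idx[done]] = STATE_FREE
            t_unbind[idx[done]] = np.inf
            # binding is decided at the landing position (the region a free
            # molecule ends up in sets k_on and f_long; free steps are large
            # relative to chromatin blobs) and starts at an exact sub-frame
            # time, so the binding frame carries mixed mobility and blurs
            # like a partial frame in the homogeneous path
            het_new = chromatin_map.het_at(new_p[:, 0], new_p[:, 1])
            u = rng.uniform(size=len(idx))
            v = rng.uniform(size=len(idx))
            phase = rng.uniform(size=len(idx))
            k_on = np.where(het_new, r_he.k_on, r_eu.k_on)
            p_long = np.where(het_new, r_he.p_long, r_eu.p_long)
            bind = free & (u < 1.0 - np.exp(-k_on * dt))
            if bind.any():
                comp = np.where(v[bind] < p_long[bind],
                                STATE_BOUND_LONG, STATE_BOUND_SHORT)
                taus = np.where(comp == STATE_BOUND_LONG,
                                preset.tau_long_s, preset.tau_short_s)
                t_bind = t_f + phase[bind] * dt
                state_now[idx[bind]] = comp
                t_unbind[idx[bind]] = t_bind + rng.exponential(taus)
                # visibility of the binding frame reflects its free portion
                d_vis = d_eff.copy()
                d_vis[bind] = (phase[bind] * d_free[bind]
                               + (1.0 - phase[bind]) * d_bound[bind])

        if slow:
            # detection requires the within-exposure diffusion length to stay
            # under the blur threshold: motion blur depends on how far the
            # molecule roams during the exposure, not on its net step (which
            # can be small by chance for a mobile molecule)
            blur_len = np.sqrt(4.0 * d_vis * acq.exposure_s)
            visible = blur_len <= acq.blur_threshold_um
        else:
            visible = np.ones(len(idx), dtype=bool)
        if visible.any():
            obs = p[visible] + noise[visible]
            loc_chunks.append({
                "molecule_id": mol_ids[idx][visible],
                "frame": np.full(int(visible.sum()), f),
                "x_um": obs[:, 0], "y_um": obs[:, 1],
            })
        pos[idx] = new_p

    def _concat(chunks, columns):
        if not chunks:
            return pd.DataFrame({c: np.array([]) for c in columns})
        return pd.DataFrame({c: np.concatenate([ch[c] for ch in chunks]) for c in columns})

    locs = _concat(loc_chunks, ["molecule_id", "frame", "x_um", "y_um"])
    locs["frame"] = locs["frame"].astype(int)
    locs["molecule_id"] = locs["molecule_id"].astype(int)
    locs.insert(0, "cell_id", cell_id)
    locs.insert(2, "t_s", locs["frame"] * dt)
    locs = locs[["cell_id", "molecule_id", "frame", "t_s", "x_um", "y_um"]]

    ground_truth = None
    if keep_ground_truth:
        gt = _concat(gt_chunks, ["molecule_id", "frame", "state", "true_x_um", "true_y_um"])
        gt["molecule_id"] = gt["molecule_id"].astype(int)
        gt["frame"] = gt["frame"].astype(int)
        gt["state"] = gt["state"].astype(int)
        if regional:
            events = _events_from_state_history(state_hist, appear, death, dt)
        ground_truth = GroundTruth(
            frames=gt,
            events=events,
            bleach_frame=pd.Series(death, index=mol_ids, name="bleach_frame"),
        )

    return CellRecording(
        localizations=locs, acquisition=acq, geometry=geometry,
        preset_name=preset.name, cell_id=cell_id, seed=seed,
        ground_truth=ground_truth, chromatin_map=chromatin_map,
    )


def _events_from_state_history(state_hist: np.ndarray, appear, death, dt: float) -> pd.DataFrame:
    """Event log from per-frame states (regional simulation path)."""
    rows = []
    for m in range(state_hist.shape[0]):
        sl = state_hist[m, appear[m]:death[m]]
        if sl.size == 0:
            continue
        change = np.nonzero(np.diff(sl))[0] + 1
        starts = np.concatenate([[0], change])
        ends = np.concatenate([change, [sl.size]])
        for s, e in zip(starts, ends):
            rows.append((m, int(sl[s]), (appear[m] + s) * dt, (appear[m] + e) * dt))
    return pd.DataFrame(rows, columns=["molecule_id", "state", "t_start_s", "t_end_s"])


def simulate_condition(
    preset: KineticPreset,
    n_cells: int,
    geometry: NucleusGeometry,
    acq: AcquisitionConfig,
    base_seed: int,
    n_molecules: int,
    chromatin_map: ChromatinMap | None = None,
    keep_ground_truth: bool = True,
) -> list[CellRecording]:
    """Simulate ``n_cells`` independent replicate cells; cell i uses seed base_seed + i."""
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    return [
        simulate_cell(
            preset, geometry, acq, n_molecules, seed=base_seed + i,
            chromatin_map=chromatin_map, cell_id=f"{preset.name}_cell{i:03d}",
            keep_ground_truth=keep_ground_truth,
        )
        for i in range(n_cells)
    ]


def simulate_chromatin_map(
    geometry: NucleusGeometry,
    het_fraction: float,
    blob_scale_um: float = 0.5,
    pixel_size_um: float = 0.05,
    seed: int = 0,
) -> ChromatinMap:
    """Random smooth heterochromatin map with a prescribed in-nucleus fraction.

    A Gaussian random field (white noise smoothed so the thresholded mask's
    1/e autocorrelation length equals ``blob_scale_um``) is thresholded at
    the quantile that makes ``het_fraction`` of in-nucleus pixels
    heterochromatic.
    """
    if not (0.0 < het_fraction < 1.0):
        raise ValueError("het_fraction must be in (0, 1)")
    if pixel_size_um >= 2.0 * geometry.radius_um:
        raise ValueError("pixel_size_um must be smaller than the nucleus diameter")
    rng = np.random.default_rng(seed)
    radius = geometry.radius_um
    n_px = int(math.ceil(2.0 * radius / pixel_size_um))
    # a Gaussian kernel of std s gives the field an ACF exp(-l^2/(4 s^2));
    # after median thresholding (arcsine law) the binary ACF hits 1/e at
    # ~1.56 s, so s = blob/1.56 makes blob_scale the mask correlation length
    sigma_px = blob_scale_um / 1.56 / pixel_size_um
    field_ = gaussian_filter(rng.normal(size=(n_px, n_px)), sigma_px)
    ys = radius - (np.arange(n_px) + 0.5) * pixel_size_um
    xs = -radius + (np.arange(n_px) + 0.5) * pixel_size_um
    xx, yy = np.meshgrid(xs, ys)
    inside = xx**2 + yy**2 <= radius**2
    thresh = np.quantile(field_[inside], 1.0 - het_fraction)
    grid = (field_ >= thresh).astype(np.uint8)
    grid[~inside] = 0
    return ChromatinMap(grid=grid, pixel_size_um=pixel_size_um,
                        origin_x_um=-radius, origin_y_um=radius)


def render_chromatin_image(
    cmap: ChromatinMap,
    hi: float = 1000.0,
    lo: float = 200.0,
    psf_sigma_um: float = 0.1,
    noise_sd: float = 20.0,
    seed: int = 0,
) -> np.ndarray:
    """Render a synthetic fluorescence snapshot from a chromatin map.

    Heterochromatin pixels emit at ``hi`` and euchromatin at ``lo``, blurred
    by a Gaussian PSF and corrupted with Gaussian noise — a stand-in for the
    intensity snapshot that region masks are derived from.
    """
    rng = np.random.default_rng(seed)
    img = np.where(cmap.grid.astype(bool), hi, lo).astype(float)
    img = gaussian_filter(img, psf_sigma_um / cmap.pixel_size_um)
    if noise_sd > 0:
        img = img + rng.normal(scale=noise_sd, size=img.shape)
    return img


def render_spot_frames(
    positions_per_frame: Sequence[np.ndarray],
    shape: tuple[int, int],
    psf_sigma_px: float = 1.2,
    amplitude: float = 500.0,
    background: float = 100.0,
    noise_sd: float = 10.0,
    seed: int = 0,
) -> np.ndarray:
    """Render a minimal synthetic image stack of Gaussian spots.

    ``positions_per_frame[f]`` holds (row, col) sub-pixel centers for frame f.
    Used to exercise the optional spot detector; not a camera model.
    """
    rng = np.random.default_rng(seed)
    n_frames = len(positions_per_frame)
    stack = np.full((n_frames, *shape), background, dtype=float)
    rr, cc = np.mgrid[0:shape[0], 0:shape[1]]
    for f, centers in enumerate(positions_per_frame):
        for r0, c0 in np.atleast_2d(centers) if len(centers) else []:
            stack[f] += amplitude * np.exp(
                -((rr - r0) ** 2 + (cc - c0) ** 2) / (2.0 * psf_sigma_px**2)
            )
    if noise_sd > 0:
        stack += rng.normal(scale=noise_sd, size=stack.shape)
    return stack
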