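"""Simulator physics: displacement law, occupancy, dwell mixture, photophysics."""

import numpy as np
import pandas as pd
import pytest

from nucspt import (
    AcquisitionConfig,
    NucleusGeometry,
    simulate_cell,
    simulate_chromatin_map,
    simulate_condition,
)
from nucspt.presets import STATE_FREE, KineticPreset

from conftest import pure_free_preset


def frame_displacements(recording):
    """Squared frame-to-frame displacements from the localization table."""
    out = []
    df = recording.localizations.sort_values(["molecule_id", "frame"])
    for _, g in df.groupby("molecule_id"):
        if (np.diff(g["frame"]) != 1).any():
            continue
        xy = g[["x_um", "y_um"]].to_numpy(float)
        d = np.diff(xy, axis=0)
        out.append((d**2).sum(axis=1))
    return np.concatenate(out)


def test_pure_free_mean_squared_displacement():
    """For pure free diffusion without noise, E[r^2] = 4 D dt within 2%."""
    acq = AcquisitionConfig(frame_interval_s=0.01, exposure_s=0.01, n_frames=400,
                            localization_sigma_um=0.0, mode="fast",
                            bleach_prob_per_frame=0.0, activation="from_start")
    rec = simulate_cell(pure_free_preset(D_free=1.0), NucleusGeometry(50.0), acq,
                        n_molecules=300, seed=3, keep_ground_truth=False)
    r2 = frame_displacements(rec)
    assert len(r2) >= 1e5
    assert np.mean(r2) == pytest.approx(4 * 1.0 * 0.01, rel=0.02)


def test_no_bleach_all_frames():
    """With bleaching off and all molecules lit from frame 0, every molecule
    appears in every frame of a fast-mode movie."""
    acq = AcquisitionConfig(frame_interval_s=0.01, exposure_s=0.01, n_frames=100,
                            mode="fast", bleach_prob_per_frame=0.0,
                            activation="from_start")
    rec = simulate_cell(pure_free_preset(), NucleusGeometry(3.0), acq,
                        n_molecules=20, seed=0)
    counts = rec.localizations.groupby("molecule_id")["frame"].size()
    assert (counts == 100).all()


def test_wt_ground_truth_occupancy(catalog, granule):
    """Fraction of molecule-frames in bound states matches F_bound=0.55."""
    acq = AcquisitionConfig(frame_interval_s=0.01, exposure_s=0.01, n_frames=150,
                            mode="fast", bleach_prob_per_frame=0.0,
                            activation="from_start")
    rec = simulate_cell(catalog["MeCP2_GC_WT"], granule, acq,
                        n_molecules=1000, seed=17)
    occ = (rec.ground_truth.frames["state"] != STATE_FREE).mean()
    assert occ == pytest.approx(0.55, abs=0.03)


def test_dwell_event_mixture_moments(catalog, granule):
    """Completed bound-event durations match the two-exponential mixture
    (f_long=0.25, tau=2/7) in mean and long-event fraction."""
    acq = AcquisitionConfig.slow_dwell(n_frames=1200)
    durs, states = [], []
    for rec in simulate_condition(catalog["MeCP2_GC_WT"], 10, granule, acq,
                                  base_seed=21, n_molecules=30):
        gt = rec.ground_truth
        b = gt.events[gt.events["state"] != STATE_FREE]
        # exclude events censored by bleach or the movie edges
        end_t = gt.bleach_frame.loc[b["molecule_id"]].to_numpy() * 0.5
        completed = b[(b["t_end_s"].to_numpy() < end_t - 1e-9)
                      & (b["t_start_s"].to_numpy() > 0)]
        durs.append((completed["t_end_s"] - completed["t_start_s"]).to_numpy())
        states.append(completed["state"].to_numpy())
    dur = np.concatenate(durs)
    assert len(dur) > 1000
    expected_mean = 0.25 * 7.0 + 0.75 * 2.0
    assert np.mean(dur) == pytest.approx(expected_mean, rel=0.05)
    long_frac = (np.concatenate(states) == 2).mean()
    assert long_frac == pytest.approx(0.25, abs=0.03)


def test_determinism_and_cell_independence(catalog, granule):
    """Identical seeds give bit-identical recordings; condition replicates
    use distinct derived seeds."""
    acq = AcquisitionConfig.fast_tracking(n_frames=300)
    a = simulate_condition(catalog["MeCP2_GC_WT"], 3, granule, acq,
                           base_seed=9, n_molecules=50)
    b = simulate_condition(catalog["MeCP2_GC_WT"], 3, granule, acq,
                           base_seed=9, n_molecules=50)
    for ra, rb in zip(a, b):
        pd.testing.assert_frame_equal(ra.localizations, rb.localizations)
    assert not a[0].localizations[["x_um", "y_um"]].equals(
        a[1].localizations[["x_um", "y_um"]])


def test_per_cell_occupancy_spread(catalog, granule):
    """Per-cell ground-truth occupancies concentrate near the preset value."""
    acq = AcquisitionConfig(frame_interval_s=0.01, exposure_s=0.01, n_frames=100,
                            mode="fast", bleach_prob_per_frame=0.0,
                            activation="from_start")
    occs = []
    for rec in simulate_condition(catalog["MeCP2_GC_WT"], 10, granule, acq,
                                  base_seed=33, n_molecules=500):
        occs.append((rec.ground_truth.frames["state"] != STATE_FREE).mean())
    assert np.std(occs) < 0.05
    # presets differing only in occupancy separate cleanly cell by cell
    lo = [float((r.ground_truth.frames["state"] != STATE_FREE).mean())
          for r in simulate_condition(catalog["MeCP2_Dnmt3a_cKO"], 5, granule,
                                      acq, base_seed=61, n_molecules=500)]
    hi = [float((r.ground_truth.frames["state"] != STATE_FREE).mean())
          for r in simulate_condition(catalog["MeCP2_Tets_cKO"], 5, granule,
                                      acq, base_seed=71, n_molecules=500)]
    assert max(lo) < min(hi)


def test_reported_positions_near_nucleus(wt_fast_recording):
    """Localizations never stray beyond the nucleus plus noise allowance."""
    r = np.hypot(wt_fast_recording.localizations["x_um"],
                 wt_fast_recording.localizations["y_um"])
    radius = wt_fast_recording.geometry.radius_um
    sigma = wt_fast_recording.acquisition.localization_sigma_um
    assert (r <= radius + 3 * sigma).all()


def test_slow_mode_blur_hides_mobile_molecules(wt_slow_recording):
    """In slow-dwell mode only bound-state molecule-frames are reported."""
    rec = wt_slow_recording
    gt = rec.ground_truth.frames.set_index(["molecule_id", "frame"])["state"]
    key = list(zip(rec.localizations["molecule_id"], rec.localizations["frame"]))
    states = gt.loc[key].to_numpy()
    assert (states != STATE_FREE).mean() >= 0.95


def test_invalid_inputs_rejected(catalog, granule):
    acq = AcquisitionConfig.fast_tracking(n_frames=10)
    with pytest.raises(ValueError):
        simulate_cell(catalog["MeCP2_GC_WT"], granule, acq, n_molecules=0, seed=1)
    with pytest.raises(ValueError):
        AcquisitionConfig(frame_interval_s=0.01, exposure_s=0.02, n_frames=10)
    with pytest.raises(ValueError):
        AcquisitionConfig(frame_interval_s=0.01, exposure_s=0.01, n_frames=10,
                          bleach_prob_per_frame=1.5)


class TestChromatinMap:
    def test_fraction_by_construction(self, granule):
        cmap = simulate_chromatin_map(granule, het_fraction=0.5, seed=2)
        assert 0.48 <= cmap.het_fraction(granule) <= 0.52

    def test_seed_reproducibility(self, granule):
        a = simulate_chromatin_map(granule, het_fraction=0.3, seed=7)
        b = simulate_chromatin_map(granule, het_fraction=0.3, seed=7)
        assert np.array_equal(a.grid, b.grid)

    def test_blob_scale_sets_correlation_length(self, granule):
        """The mask's 1/e autocorrelation length tracks blob_scale_um."""
        blob = 0.6
        lags = []
        for seed in range(5):
            cmap = simulate_chromatin_map(granule, het_fraction=0.5,
                                          blob_scale_um=blob,
                                          pixel_size_um=0.05, seed=seed)
            n = cmap.grid.shape[0]
            c, w = n // 2, 40  # central 4 um crop, fully inside the nucleus
            g = cmap.grid[c - w:c + w, c - w:c + w].astype(float)
            g -= g.mean()
            ac = np.array([(g[:, :g.shape[1] - k] * g[:, k:]).mean()
                           for k in range(w)])
            ac /= ac[0]
            lags.append(np.argmax(ac < np.exp(-1)) * cmap.pixel_size_um)
        assert abs(np.mean(lags) - blob) / blob < 0.3

    def test_degenerate_pixel_size_rejected(self, granule):
        with pytest.raises(ValueError):
            simulate_chromatin_map(granule, het_fraction=0.5, pixel_size_um=10.0)
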