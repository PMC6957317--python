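"""Dwell-time analysis: immobile extraction, survival curves, double-exp fit."""

import numpy as np
import pytest

from nucspt import AcquisitionConfig, NucleusGeometry, simulate_cell
from nucspt.dwell import (
    bleach_correct,
    extract_immobile_tracks,
    fit_double_exponential,
    survival_curve,
    track_durations,
)
from nucspt.presets import KineticPreset, STATE_FREE

from conftest import pure_bound_preset, pure_free_preset


def test_fast_mode_rejected(wt_fast_recording):
    with pytest.raises(ValueError):
        extract_immobile_tracks(wt_fast_recording)


def test_persistent_bound_molecule_single_track(granule):
    """A permanently bound, non-bleaching molecule gives one track spanning
    the interior frames of the movie (edge-touching tracks are censored)."""
    acq = AcquisitionConfig.slow_dwell(n_frames=16, bleach_prob_per_frame=0.0)
    rec = simulate_cell(pure_bound_preset(), granule, acq, n_molecules=1, seed=4)
    ts = extract_immobile_tracks(rec, drop_censored=False)
    assert len(ts) == 1
    assert ts.track_lengths().iloc[0] == 16
    # the same track is recognized as censored (it touches both movie edges)
    assert len(extract_immobile_tracks(rec, drop_censored=True)) == 0


def test_free_molecules_yield_no_multiframe_tracks(granule):
    """Free molecules (D=1) blur away in slow mode; nothing to link."""
    acq = AcquisitionConfig.slow_dwell(n_frames=200, bleach_prob_per_frame=0.0)
    rec = simulate_cell(pure_free_preset(D_free=1.0), granule, acq,
                        n_molecules=50, seed=5)
    assert len(rec.localizations) == 0


def test_immobile_set_purity(wt_slow_recording):
    """Ground-truth bound-state purity of extracted immobile tracks >= 95%."""
    rec = wt_slow_recording
    ts = extract_immobile_tracks(rec)
    mol = rec.localizations.reset_index(drop=True)
    gt = rec.ground_truth.frames.set_index(["molecule_id", "frame"])["state"]
    states = []
    for _, g in ts.tracks.groupby("track_id"):
        rows = mol.iloc[g["loc_index"].to_numpy()]
        states.append(gt.loc[list(zip(rows["molecule_id"], rows["frame"]))].to_numpy())
    states = np.concatenate(states)
    assert (states != STATE_FREE).mean() >= 0.95


class TestSurvivalCurve:
    def test_counting_closed_form(self):
        c = survival_curve(np.array([0.5, 1.0, 1.5]))
        assert c.grid == pytest.approx([0.5, 1.0, 1.5])
        assert c.S == pytest.approx([1.0, 2 / 3, 1 / 3])
        assert "low_n" in c.flags

    def test_exponential_slope(self):
        """log S of exponential durations decays at rate 1/tau."""
        rng = np.random.default_rng(1)
        tau = 5.0
        c = survival_curve(rng.exponential(tau, size=10_000))
        sel = (c.S > 0.05) & (c.grid < 3 * tau)
        slope = np.polyfit(c.grid[sel], np.log(c.S[sel]), 1)[0]
        assert -slope == pytest.approx(1 / tau, rel=0.05)

    def test_equal_durations_step_function(self):
        c = survival_curve(np.full(100, 2.0))
        assert c.grid == pytest.approx([2.0])
        assert c.S == pytest.approx([1.0])

    def test_monotone_on_pipeline_output(self, wt_slow_recording):
        d = track_durations(extract_immobile_tracks(wt_slow_recording))
        c = survival_curve(d)
        assert np.all(np.diff(c.S) <= 1e-12)
        assert c.S[0] == pytest.approx(1.0)


class TestDoubleExponentialFit:
    def _sampled_mixture(self, f_long, tau_s, tau_l, n, seed, dt=0.5):
        """Durations as the camera reports them: an event starting at phase
        u covers floor((u+T)/dt) - 1 full frames (partial edge frames blur
        away), and a track of k frames has duration (k-1) dt."""
        rng = np.random.default_rng(seed)
        comp = rng.uniform(size=n) < f_long
        t = np.where(comp, rng.exponential(tau_l, n), rng.exponential(tau_s, n))
        u = rng.uniform(0, dt, n)
        frames = np.floor((t + u) / dt).astype(int) - 1
        return (frames[frames >= 2] - 1) * dt

    def test_single_exponential_flagged(self):
        d = self._sampled_mixture(1.0, 5.0, 5.0, 8000, seed=2)
        fit = fit_double_exponential(survival_curve(d))
        assert "effectively_single_exponential" in fit.flags
        assert fit.tau_long_s == pytest.approx(5.0, rel=0.15)

    def test_mixture_recovery_at_reference_size(self):
        """f=0.25, tau=2/7 at 5x10^3 events recovers within the bands."""
        d = self._sampled_mixture(0.25, 2.0, 7.0, 7000, seed=3)
        fit = fit_double_exponential(survival_curve(d))
        assert 0.20 <= fit.f_long <= 0.30
        assert 5.6 <= fit.tau_long_s <= 8.4
        assert 1.6 <= fit.tau_short_s <= 2.4

    def test_f_long_one_is_single_exponential_at_tau_long(self):
        d = self._sampled_mixture(1.0, 2.0, 7.0, 8000, seed=4)
        fit = fit_double_exponential(survival_curve(d))
        assert fit.tau_long_s == pytest.approx(7.0, rel=0.15)

    def test_non_monotone_curve_rejected(self):
        c = survival_curve(np.array([0.5, 1.0, 1.5, 2.0, 2.5]))
        c.S = c.S[::-1].copy()
        with pytest.raises(ValueError):
            fit_double_exponential(c)

    def test_too_few_distinct_durations_rejected(self):
        c = survival_curve(np.array([0.5, 1.0, 1.5, 2.0] * 20))
        with pytest.raises(ValueError):
            fit_double_exponential(c)


def test_longer_lived_factor_presets_recovered(granule):
    """tau_long of a 10 s preset is recovered within 20% at ~5x10^3 events."""
    preset = KineticPreset("slowoff", F_bound=0.5, D_free=2.0,
                           tau_short_s=2.0, tau_long_s=10.0, f_long_event=0.25)
    acq = AcquisitionConfig.slow_dwell(n_frames=1600,
                                       bleach_prob_per_frame=0.002)
    durs = []
    for seed in range(30):
        rec = simulate_cell(preset, granule, acq, n_molecules=20,
                            seed=500 + seed, keep_ground_truth=False)
        durs.append(track_durations(extract_immobile_tracks(rec)))
    d = np.concatenate(durs)
    assert len(d) >= 4000
    fit = fit_double_exponential(survival_curve(d))
    assert fit.tau_long_s == pytest.approx(10.0, rel=0.2)


class TestBleachCorrect:
    def test_identity_control(self):
        c = survival_curve(np.array([0.5, 1.0, 1.5, 2.0, 3.0] * 20))
        ctrl = survival_curve(np.array([10.0] * 50))
        out = bleach_correct(c, ctrl)
        assert out.S == pytest.approx(c.S)

    def test_identical_sample_and_control_flat(self):
        d = np.array([0.5, 1.0, 1.5, 2.0, 3.0] * 20)
        c = survival_curve(d)
        out = bleach_correct(c, survival_curve(d))
        assert out.S == pytest.approx(np.ones_like(out.S))

    def test_known_bleach_rate_recovered(self):
        """Dividing by the control survival undoes exponential bleaching."""
        rng = np.random.default_rng(6)
        tau, k_b, n = 7.0, 0.05, 40_000
        t_true = rng.exponential(tau, n)
        bleach = rng.exponential(1 / k_b, n)
        obs = survival_curve(np.round(np.minimum(t_true, bleach), 1) + 0.1)
        ctrl = survival_curve(np.round(rng.exponential(1 / k_b, n), 1) + 0.1)
        corrected = bleach_correct(obs, ctrl)
        sel = (corrected.S > 0.05) & (corrected.grid < 15)
        slope = np.polyfit(corrected.grid[sel], np.log(corrected.S[sel]), 1)[0]
        assert -1 / slope == pytest.approx(tau, rel=0.15)

    def test_short_control_support_rejected(self):
        c = survival_curve(np.array([1.0, 2.0, 30.0]))
        ctrl = survival_curve(np.array([1.0, 2.0, 3.0]))
        with pytest.raises(ValueError):
            bleach_correct(c, ctrl)
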