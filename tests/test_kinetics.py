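"""Two-state jump-length fit: counting, model CDF, and parameter recovery."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from nucspt import (
    AcquisitionConfig,
    LinkingConfig,
    NucleusGeometry,
    link_recording,
    simulate_cell,
)
from nucspt.kinetics import (
    JumpData,
    collect_jumps,
    fit_two_state,
    model_jump_cdf,
    summarize_condition,
)
from nucspt.presets import KineticPreset
from nucspt.tracking import TrackSet

from conftest import pure_free_preset


def _trackset(list_of_xy, dt=0.01, sigma=0.035):
    rows = []
    for tid, xy in enumerate(list_of_xy):
        for f, (x, y) in enumerate(xy):
            rows.append((tid, "c", f, f * dt, x, y, 0))
    df = pd.DataFrame(rows, columns=["track_id", "cell_id", "frame", "t_s",
                                     "x_um", "y_um", "loc_index"])
    cfg = LinkingConfig(D_max=5.0, frame_interval_s=dt, localization_sigma_um=sigma)
    return TrackSet(df, cfg)


def test_jump_counting_per_lag():
    """A 5-frame track yields 4/3/2/1 jumps at lags 1..4."""
    xy = np.column_stack([np.arange(5) * 0.01, np.zeros(5)])
    jd = collect_jumps(_trackset([xy]))
    assert {n: len(r) for n, r in jd.jumps.items()} == {1: 4, 2: 3, 3: 2, 4: 1}


def test_optional_cap_limits_long_tracks():
    xy = np.column_stack([np.arange(200) * 1e-3, np.zeros(200)])
    jd = collect_jumps(_trackset([xy]), cap_per_track=30)
    assert len(jd.jumps[1]) == 30
    jd_uncapped = collect_jumps(_trackset([xy]))
    assert len(jd_uncapped.jumps[1]) == 199


def test_stationary_emitter_jumps_rayleigh():
    """Lag-1 jumps of a noisy stationary emitter are Rayleigh(sigma*sqrt(2)):
    squared lengths exponential with mean 4 sigma^2."""
    rng = np.random.default_rng(2)
    sigma = 0.035
    xy = rng.normal(scale=sigma, size=(20000, 2))
    jd = collect_jumps(_trackset([xy], sigma=sigma))
    r = jd.jumps[1]
    assert np.mean(r**2) == pytest.approx(4 * sigma**2, rel=0.05)
    # Rayleigh CDF comparison through the model with D=0
    grid = np.quantile(r, np.linspace(0.05, 0.95, 19))
    ecdf = np.searchsorted(np.sort(r), grid, side="right") / len(r)
    model = model_jump_cdf(grid, D=0.0, lag_time_s=0.01, sigma_um=sigma)
    assert np.abs(ecdf - model).max() < 0.02


def test_model_cdf_limits_and_closed_form():
    assert model_jump_cdf(0.0, 1.0, 0.01, 0.0) == 0.0
    assert model_jump_cdf(np.inf, 1.0, 0.01, 0.0) == 1.0
    assert model_jump_cdf(0.2, 1.0, 0.01, 0.0) == pytest.approx(1 - np.exp(-1))


def test_model_cdf_matches_monte_carlo():
    """10^6 sampled jumps vs the analytic CDF: sup deviation < 0.002."""
    rng = np.random.default_rng(3)
    D, dt, sigma, n = 1.0, 0.01, 0.035, 1_000_000
    start = rng.normal(scale=sigma, size=(n, 2))
    end = (rng.normal(scale=np.sqrt(2 * D * dt), size=(n, 2))
           + rng.normal(scale=sigma, size=(n, 2)))
    r = np.hypot(*(end - start).T)
    grid = np.linspace(0, r.max(), 400)
    ecdf = np.searchsorted(np.sort(r), grid, side="right") / n
    model = model_jump_cdf(grid, D, dt, sigma)
    assert np.abs(ecdf - model).max() < 0.002


@given(st.floats(0.05, 5.0), st.floats(0.0, 0.1))
@settings(max_examples=30, deadline=None)
def test_mixture_cdf_is_valid_cdf(D_free, sigma):
    """The fitted mixture is nondecreasing, 0 at 0, and tends to 1."""
    r = np.linspace(0, 5, 500)
    fb = 0.4
    mix = (fb * model_jump_cdf(r, 0.005, 0.01, sigma)
           + (1 - fb) * model_jump_cdf(r, D_free, 0.01, sigma))
    assert mix[0] == 0.0
    assert np.all(np.diff(mix) >= -1e-12)
    assert mix[-1] <= 1.0 + 1e-12
    wide = (fb * model_jump_cdf(50.0, 0.005, 0.01, sigma)
            + (1 - fb) * model_jump_cdf(50.0, D_free, 0.01, sigma))
    assert wide == pytest.approx(1.0, abs=1e-6)


def test_two_state_recovery_single_cell(catalog, granule):
    """F_b=0.55, D_f=1.0 simulation recovers both within the stated bands."""
    acq = AcquisitionConfig.fast_tracking(n_frames=5000)
    rec = simulate_cell(catalog["MeCP2_GC_WT"], granule, acq, n_molecules=300,
                        seed=101, keep_ground_truth=False)
    fit = fit_two_state(collect_jumps(link_recording(rec, D_max=5.0)))
    assert fit.n_jumps >= 10_000
    assert 0.50 <= fit.F_bound_hat <= 0.60
    assert 0.9 <= fit.D_free_hat <= 1.1


def test_pure_free_population_boundary_case(granule):
    acq = AcquisitionConfig.fast_tracking(n_frames=4000)
    rec = simulate_cell(pure_free_preset(D_free=4.0), NucleusGeometry(5.0), acq,
                        n_molecules=200, seed=5, keep_ground_truth=False)
    fit = fit_two_state(collect_jumps(link_recording(rec, D_max=5.0)))
    assert fit.F_bound_hat <= 0.05


def test_all_bound_degenerate_mixture():
    """Jumps at pure noise scale fit as an essentially fully bound cell."""
    rng = np.random.default_rng(6)
    sigma = 0.035
    tracks = [rng.normal(scale=sigma, size=(40, 2)) + rng.uniform(-2, 2, 2)
              for _ in range(200)]
    fit = fit_two_state(collect_jumps(_trackset(tracks, sigma=sigma)))
    assert fit.F_bound_hat >= 0.95


def test_identifiability_error_shrinks_with_jumps(catalog, granule):
    """Recovery error of F_bound decreases from 10^3 to 10^5 jumps."""
    acq = AcquisitionConfig.fast_tracking(n_frames=5000)
    errs = {}
    for n_mol, label in [(8, "small"), (600, "large")]:
        errors = []
        for seed in (201, 202, 203):
            rec = simulate_cell(catalog["MeCP2_GC_WT"], granule, acq,
                                n_molecules=n_mol, seed=seed,
                                keep_ground_truth=False)
            jd = collect_jumps(link_recording(rec, D_max=5.0))
            fit = fit_two_state(jd)
            errors.append(abs(fit.F_bound_hat - 0.55))
        errs[label] = np.mean(errors)
    assert errs["large"] < errs["small"]


def test_lag1_only_agrees_with_multilag(catalog, granule):
    acq = AcquisitionConfig.fast_tracking(n_frames=5000)
    rec = simulate_cell(catalog["MeCP2_GC_WT"], granule, acq, n_molecules=300,
                        seed=301, keep_ground_truth=False)
    ts = link_recording(rec, D_max=5.0)
    full = fit_two_state(collect_jumps(ts, max_lag=4))
    lag1 = fit_two_state(collect_jumps(ts, max_lag=1))
    assert abs(full.F_bound_hat - lag1.F_bound_hat) <= 0.05
    assert abs(full.D_free_hat - lag1.D_free_hat) / full.D_free_hat <= 0.1


def test_within_frame_switching_bias_small(granule):
    """Mid-frame state switches at tau >= 2 s barely move the fit: a cell
    simulated with fast exchange truncated to frame boundaries and one with
    exact within-frame switching agree within 2 pp."""
    acq = AcquisitionConfig.fast_tracking(n_frames=5000)
    # exact switching (default path)
    p = KineticPreset("x", F_bound=0.55, D_free=1.0)
    rec = simulate_cell(p, granule, acq, n_molecules=400, seed=401,
                        keep_ground_truth=False)
    fit = fit_two_state(collect_jumps(link_recording(rec, D_max=5.0)))
    # switching much slower than the frame: within-frame effects vanish
    slow_exchange = KineticPreset("y", F_bound=0.55, D_free=1.0,
                                  tau_short_s=200.0, tau_long_s=700.0)
    rec2 = simulate_cell(slow_exchange, granule, acq, n_molecules=400,
                         seed=401, keep_ground_truth=False)
    fit2 = fit_two_state(collect_jumps(link_recording(rec2, D_max=5.0)))
    assert abs(fit.F_bound_hat - fit2.F_bound_hat) <= 0.02


def test_summarize_condition(catalog, granule):
    from nucspt.kinetics import TwoStateFit

    same = [TwoStateFit(0.5, 1.0, 0.005, 0.035, 0.0, 1000, f"c{i}")
            for i in range(3)]
    s = summarize_condition(same)
    assert s["F_bound_sd"] == 0.0
    with pytest.raises(ValueError):
        summarize_condition(same[:1])


def test_empty_jump_data_raises():
    with pytest.raises(ValueError):
        fit_two_state(JumpData({}, 0.01, 0.035))


def test_low_jump_count_flagged():
    rng = np.random.default_rng(9)
    jd = JumpData({1: rng.rayleigh(0.05, size=50)}, 0.01, 0.035)
    fit = fit_two_state(jd)
    assert "low_confidence" in fit.flags
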