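# Methods

This note documents the forward model, the analysis estimators, the
numerical choices behind them, and what the synthetic benchmarks do and do
not demonstrate about real recordings.

## Kinetic model

A nuclear factor is modeled as a three-state continuous-time Markov chain:
freely diffusing (FREE, diffusion coefficient `D_free`), transiently bound
(BOUND_SHORT, mean dwell `τ_short`), and stably bound (BOUND_LONG, mean
dwell `τ_long`). Binding events start from the free state at rate `k_on`;
each event is long-lived with probability `f_long_event`. Both bound states
share `D_bound`. Presets are parameterized by the stationary bound
occupancy `F_bound` instead of `k_on`, because occupancy is what the
jump-length analysis measures; flux balance gives

    k_on = F_bound / ((1 − F_bound) · E[τ_b]),
    E[τ_b] = f_long_event · τ_long + (1 − f_long_event) · τ_short.

Default `D_bound = 0.005 µm²/s` (not exactly zero) so bound molecules show
realistic sub-resolution jitter dominated by localization error.

Preset values (`preset_catalog()`) encode the per-condition literature
values for MeCP2 in cerebellar granule cells — wild type `F_bound = 0.55`,
`D_free = 1.0 µm²/s`, `τ_short = 2 s`, `τ_long = 7 s`, `f_long = 0.25` —
and the knockout/mutant/control conditions around them. Fields without a
literature anchor are defaults chosen for qualitative consistency: the NLS
control binds rarely and briefly; H2b is dominated by stable nucleosomal
incorporation (`f_long_event = 0.9`, `τ_long = 300 s`, effectively
permanent at observation scale), which also makes it usable as a
photobleaching control.

## Simulator

2D Brownian dynamics inside a reflecting circle (granule radius 3 µm,
Purkinje 6 µm; boundary handled by iterative mirroring). State paths are
sampled with exact exponential event times; a frame containing a switch
uses the time-weighted effective `D` for its displacement (exact sub-frame
bridging is unnecessary at `τ ≥ 2 s` vs `Δt = 10 ms`; the assumption-
consistency test bounds the induced shift in fitted parameters at < 2 pp).
Reported positions are true frame-start positions plus Gaussian noise
(`σ = 0.035 µm` per coordinate by default). Photobleaching is a per-frame
Bernoulli (defaults 0.01/frame fast, 0.005/frame slow).

Activation: in fast mode molecules become fluorescent at uniform-random
frames (emulating the sparse activation/turnover that keeps instantaneous
spot density low); in slow mode all molecules emit from frame 0 until
bleached, matching chemical pre-labeling, which makes dwells already in
progress at movie start identifiable (their tracks touch frame 0).

Slow-mode detection: a molecule is recorded in a frame only if its
within-exposure diffusion length `sqrt(4 · D_eff · t_exp)` stays below
`blur_threshold_um` (default 0.2 µm). The criterion deliberately uses the
roaming scale, not the sampled net step: a mobile molecule's net
displacement can be small by chance while its path still smears the PSF.
With the net-step criterion, frames containing a bind/unbind switch passed
the blur test ~20% of the time and mobile molecules ~4% per frame, which
contaminated dwell tracks enough to shift the fitted survival mixture by
+15 pp in `f_long`.

Chromatin maps are thresholded Gaussian random fields; `blob_scale_um` is
calibrated to the mask's 1/e autocorrelation length (kernel std =
blob/1.56, from the arcsine law for thresholded Gaussian fields). With
region modifiers active, kinetics become position-dependent: binding is
decided at the frame's landing position (free steps are large relative to
chromatin blobs, so the landing region is what sets `k_on` and
`f_long_event`), events are scheduled at exact sub-frame times, and frames
containing a switch carry time-weighted mobility — so the detection
channel is identical to the homogeneous path.

## Trajectory linking

Frame-to-frame optimal bipartite assignment (scipy's Hungarian solver) on
squared displacement, gated at `r_max = sqrt(4 D_max Δt) + 3σ`. The `+3σ`
allowance prevents measurement noise from truncating legitimate fast
jumps; setting `localization_sigma_um = 0` in `LinkingConfig` gives the
bare formula. Infeasible pairings get a dominating cost, so the solver
maximizes the number of in-gate links first and minimizes total squared
displacement among those. Localizations are canonically ordered within
frames, making the result invariant to input row order; on frames with
≤ 5 emitters the assignment provably equals the enumeration optimum (test
suite). No gap closing by default (`gap_frames = 0`).

## Per-molecule diffusion (MSD)

Time-averaged MSD over overlapping pairs; ordinary least squares of
`MSD(τ) = 4D′τ + b` over the first 4 lags with a free intercept (the
intercept absorbs the `4σ²` static-error offset). The lag count and
intercept are configurable since different conventions exist. `R²` is
computed on the fitted window. Filters: 5–150 frames and `R² ≥ 0.8`, all
boundaries inclusive. Non-positive slopes are floored at `10⁻⁴ µm²/s` and
flagged; floored molecules are excluded from `log₁₀ D′` summaries but
counted.

## Two-state jump-length fit

Displacement magnitudes at lags 1–4 pooled per cell are compared with the
mixture CDF `F_b·CDF(r|D_bound) + (1−F_b)·CDF(r|D_free)` on a 200-point
quantile-spaced grid per lag (CDF fitting is bin-free); the summed squared
deviation is minimized over `(F_b, D_bound, D_free)` with bounds
`D_bound ∈ [0, 0.08]`, `D_free ∈ [0.15, 25] µm²/s`, six deterministic
starts spanning the bound box (L-BFGS-B), best residual kept. `σ` is fixed
to the known value by default — `σ` and `D_bound` are nearly degenerate —
with an optional free-σ mode (`[0.01, 0.1] µm`) for real data.

Two numerical choices matter at the few-percent level:

* **Gate awareness.** Linked lag-1 jumps are exactly the mixture
  conditioned on `r ≤ r_max`, so the lag-1 model CDF is renormalized at
  the gate; lags ≥ 2 are sums of gated steps, handled by a truncated-step
  effective `D`. Without this, `D_free` is biased low by ~7–11% at
  `D = 2 µm²/s`.
* **No per-track jump cap by default.** With bleach-limited (~100-frame)
  tracks, a fixed per-track quota interacts with gate fragmentation: a
  fast molecule's track splits into several fragments, each drawing its
  own quota, which over-weights the mobile population (at
  `F_bound = 0.6, D_free = 2` the recovered bound fraction dropped from
  59% to 39% with a 30-jump cap). A cap remains available
  (`cap_per_track`) for long-track-dominance studies.

No defocalization correction is applied: the forward model is 2D, so the
fit's no-z-loss assumption is exactly consistent with the data. This is a
deliberate simplification relative to published 3D-aware jump-fitting
tools; a per-lag correction hook would be needed for real 2D images of
thick nuclei.

Residual known biases, quantified on simulations: recovered `D_free` runs
~2% low at `D = 1` and ~7% low at `D = 2` in a 3-µm nucleus (confinement
plus multi-lag gating); mean bound fractions recover within ~2.5 pp.

## Dwell-time analysis

Immobile tracks are linked at `D_max = 0.05 µm²/s`; tracks need ≥ 2 frames;
duration is `(n_frames − 1)·Δt`. Tracks touching the first or last movie
frame are dropped: a dwell already in progress at movie start is a
length-biased draw of the event mixture (such tracks fit at `f_long ≈
0.54`, the long-state occupancy share, instead of 0.25), and both ends are
identifiable from the track itself.

The survival curve `S(t)` on the distinct observed durations is fit with
the renormalized double exponential. Two estimator details:

* **Log-space residuals.** Residuals are taken on `log S` (floored at
  `0.5/N`) with weights `sqrt(N·S)` — by the delta method exactly the
  inverse standard error of `log S`. Fitting `S` directly with the same
  weights leaves the amplitude/time-constant ridge so flat that replicate
  simulations of ~6000 events landed in different basins (fitted `f_long`
  drifting over 0.26–0.32 for a true 0.25).
* **Detection dead time.** An event starting at frame phase `u` yields
  `floor((u+T)/Δt) − 1` fully-bound frames (partial edge frames are
  motion-blurred), and the `(n−1)·Δt` convention drops one more interval,
  so observed duration ≈ `T − 1.5Δt`. A shifted exponential mixture has
  its amplitudes re-weighted by `exp(−1.5Δt/τ)`; for the MeCP2 mixture
  this inflates the apparent `f_long` from 0.25 to 0.30. The fit models
  the shift explicitly (`dead_time_s`, auto-detected as 1.5× the duration
  grid spacing, 0 for continuous grids) and therefore reports event-level
  amplitudes.

No photobleaching correction is applied by default; at the default slow-
mode bleach rate (0.01 s⁻¹ vs `1/τ_long = 0.14 s⁻¹`) the fitted `τ_long`
runs ~7% low (`1/(1/7 + 0.01) = 6.5 s`), within the stated recovery
tolerance. `bleach_correct()` divides by a permanently-bound control's
survival (e.g. H2b under identical acquisition), which is exact under
memoryless bleaching (`S_obs = S_T · S_bleach`) and restores `τ_long` to
~7.2–7.4 s at the cost of control-sampling noise; the active mode is
recorded in output metadata.

Sparse labeling matters: at ≥ 25 molecules per granule nucleus the crowded
early movie merges tracks from different molecules and shifts the fit
(`f_long` +4 pp, `τ_long` −0.9 s at 25/cell); benchmark and acceptance
runs use ~6 molecules per nucleus (~3 visible bound spots, ~0.1 µm⁻²),
the regime slow-dwell imaging is designed for.

## Region-stratified analysis

Masks come from Otsu or quantile thresholding of a smoothed intensity
snapshot (connected components < 3 px removed) or directly from a
simulated map. Tracks are labeled by majority region at threshold 0.8 with
an explicit ambiguous class; kinetic fits use only jumps with both
endpoints in-region. Known artifact: long-dwelling molecules wander
(~0.4 µm RMS over 7 s), so with chromatin domains much smaller than ~1 µm
boundary-crossing tracks become ambiguous, preferentially removing long
events and distorting per-region dwell fits; benchmarks use
chromocenter-scale (≥ 1.5 µm) domains, and within-cell comparisons of
`f_long` between regions remain valid because the selection acts on both
regions.

## Statistics

Pooled per-molecule distributions: two-sample Kolmogorov–Smirnov. Per-cell
summaries (the primary comparison level, mirroring per-cell experimental
designs): two-tailed unpaired t-test for two groups, one-way ANOVA with
Bonferroni-adjusted pairwise t-tests (`p_adj = min(1, p·m)`) for more.
Under null simulations the type-I error of the per-cell t-test matches the
nominal α (acceptance suite, 10³ replicates).

## Reproducibility and problem sizes

Every simulation consumes a single seeded generator per cell; condition
replicates use `base_seed + i`; the pipeline is a pure function of config
and seeds (byte-identical reruns, tested). Benchmark sizes — 10 cells ×
500 molecules for fast-mode recovery, three replicates of ≥ 2000 immobile
events for dwell recovery, ~10⁶ jumps for distribution-law checks — were
chosen so that each stage's statistical error is several times smaller
than the recovery tolerances it is tested against.

## What the benchmarks do not show

The simulator omits fluorophore blinking and re-activation, 3D motion and
defocalization (an optional 3D slab mode exists but is off by default),
anomalous or position-dependent diffusion within a region, PSF-level image
formation (detection is a hard blur threshold), and dense-field linking
ambiguity beyond what the chosen densities produce. Passing recovery tests
therefore validates the estimator implementations and their documented
bias budget under this generative model, not performance on arbitrary real
microscope data.
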