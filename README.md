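# nucspt

Single-molecule tracking (SMT) analysis of nuclear protein dynamics, built
around the kinetic behavior of MeCP2 in live neurons, together with a
ground-truth simulator that makes every stage of the analysis testable by
parameter recovery.

Nuclear factors such as MeCP2, transcription factors, and linker histones
exchange between chromatin-bound and freely diffusing states. Sparse
fluorescent labeling lets a camera follow individual molecules; two
acquisition regimes read out complementary quantities:

* **Fast tracking** (100 Hz, 10 ms frames): trajectories of all molecules.
  The distribution of frame-to-frame jump lengths pooled per cell is fit
  with a two-state mixture — for a molecule with diffusion coefficient `D`
  observed at lag `t` with localization error `σ` per coordinate, the jump
  length CDF is `P(r' ≤ r) = 1 − exp(−r² / (4(Dt + σ²)))` — yielding the
  bound fraction `F_bound` and the free-population coefficient `D_free`
  (Spot-On-style analysis, `D_bound ≤ 0.08`, `D_free ≥ 0.15` µm²/s).
  Per-molecule apparent coefficients `D′` come from linear MSD fits
  (`MSD(τ) ≈ 4D′τ + b`), filtered at 5–150 frames and `R² ≥ 0.8`.
* **Slow dwell imaging** (2 Hz, 500 ms exposures): mobile molecules blur
  into the background and only stably bound molecules are recorded, so
  track durations are residence times. The survival curve of durations is
  fit with a constrained double exponential
  `S(t) = (1−f_long) e^(−t/τ_short) + f_long e^(−t/τ_long)`.

Trajectories are linked with an MTT-style maximum-displacement gate
`r_max = sqrt(4 · D_max · Δt) + 3σ` (`D_max` = 5 µm²/s fast, 0.05 µm²/s for
dwell imaging) using optimal bipartite assignment per frame pair. Tracks
can further be stratified into heterochromatin and euchromatin by masks
derived from an intensity snapshot.

The simulator (`nucspt.simulate`) generates recordings of molecules
switching between free, short-bound, and long-bound states inside a
reflecting circular nucleus, with exact exponential state switching,
Gaussian localization error, photobleaching, motion-blur detection loss in
slow mode, and optional heterochromatin subdomains with region-dependent
kinetics. Preset parameter sets (`nucspt.presets.preset_catalog()`) encode
the reported per-condition values (wild type, DNA-modification knockouts,
Rett-syndrome mutants, minimal constructs, control factors, Purkinje
cells), so every analysis stage can be validated by recovering known
ground truth.

## Worked example

```python
import numpy as np
from nucspt import (AcquisitionConfig, NucleusGeometry, preset_catalog,
                    simulate_condition, link_recording, collect_jumps,
                    fit_two_state, summarize_condition)

catalog = preset_catalog()
acq = AcquisitionConfig.fast_tracking(n_frames=5000)
cells = simulate_condition(catalog["MeCP2_GC_WT"], n_cells=5,
                           geometry=NucleusGeometry(radius_um=3.0),
                           acq=acq, base_seed=100, n_molecules=300)
fits = [fit_two_state(collect_jumps(link_recording(rec, D_max=5.0),
                                    cell_id=rec.cell_id))
        for rec in cells]
s = summarize_condition(fits)
print(f"bound fraction {s['F_bound_mean']:.3f} +/- {s['F_bound_sd']:.3f}")
print(f"D_free {s['D_free_mean']:.2f} +/- {s['D_free_sd']:.2f} um^2/s")
```

Output:

```
bound fraction 0.558 +/- 0.046
D_free 0.94 +/- 0.02 um^2/s
```

Five simulated wild-type granule cells recover the preset ground truth
(55% bound, `D_free` 1.0 µm²/s) to within the per-cell scatter; the small
downward shift of `D_free` reflects nuclear confinement and the linking
gate, both quantified in `docs/methods.md`.

The same stages are available from a shell:

```bash
nucspt simulate --preset MeCP2_GC_WT --mode fast --cells 5 --molecules 300 --seed 1 --out sim/
nucspt track --in sim/MeCP2_GC_WT_cell000_loc.csv --dmax 5 --dt 0.01 --out tracks.csv
nucspt kinetics --in tracks.csv --dt 0.01 --out fits.csv
nucspt run --config study.yaml     # full multi-condition study
```

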