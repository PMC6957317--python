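# Study configuration schema (informal; validated by nucspt.pipeline.load_config)
#
# output_dir: str            # where per-stage artifacts are written
# geometry:                  # optional, defaults to a 3 um granule nucleus
#   radius_um: float > 0
# fast_acquisition:          # optional overrides of AcquisitionConfig.fast_tracking
#   n_frames: int
#   localization_sigma_um: float
#   bleach_prob_per_frame: float in [0, 1]
# slow_acquisition:          # optional overrides of AcquisitionConfig.slow_dwell
#   n_frames: int
#   blur_threshold_um: float
# analysis:                  # optional analysis-parameter overrides
#   D_max_fast: float        # linking gate for fast mode (um^2/s), default 5.0
#   D_max_dwell: float       # linking gate for dwell mode, default 0.05
#   D_bound_max: float       # two-state fit upper bound, default 0.08
#   D_free_min: float        # two-state fit lower bound, default 0.15
#   max_lag: int             # jump lags, default 4
#   min_r2: float            # MSD filter, default 0.8
# conditions:                # one entry per experimental condition
#   - label: str             # unique
#     preset: str            # a name from nucspt.presets.preset_catalog()
#     n_cells: int >= 1
#     n_molecules: int >= 1
#     seed: int              # cell i uses seed + i
#     modes: [fast] | [slow] | [fast, slow]
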