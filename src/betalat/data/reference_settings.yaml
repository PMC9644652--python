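# Frozen canonical analysis settings; PipelineConfig defaults must match.
active_window:
- 0.3
- 1.0
alpha: 0.05
baseline_window:
- -0.7
- 0.0
center_freq: 24.0
fmri_connectivity: 18
fmri_cutoff: 0.2
fmri_min_extent: 10
fmri_t_crit: 3.13
grid_spacing: 10.0
halfbandwidth: 11.0
lambda_frac: 0.1
meg_cutoff: 0.1
n_perm: 10000
seed: 0
source_connectivity: 6
t_crit: 1.65
t_fallback: 1.97
tfr_fmax: 45.0
tfr_fmin: 1.0
tfr_n_cycles: 5.0
top_fraction: 0.1
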