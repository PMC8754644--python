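# Example pipeline configuration: simulate a small field and analyze it
# end to end.  Run:  burstcall pipeline --config examples/config.yaml \
#                       --seed 7 --out runs/demo
frame_interval: 16.8
channel_histone: 0
channel_ms2: 1
segmentation_method: 1
nucleus_radius: 9.0
fit_window: 11
min_len: 5
end_frac: 0.55
shift: 2
smooth_window: 5
activity_fraction: 0.10
half_life: 7.0
decay_model: exponential
seed: 7
simulation:
  field:
    image_shape: [250, 250]
    n_nuclei: 30
    noise_sd: 50.0
    drift_sd: 0.3
  telegraph:
    k_on: 0.4
    k_off: 0.8
    r_load: 40.0
    dwell: 1.2
    unit_intensity: 100.0
    n_frames: 30
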