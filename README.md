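# ms2burst

Quantification of transcriptional bursting from MS2/MCP live-imaging movies
of early embryos.

In the MS2/MCP system, stem-loops inserted into a reporter transcript are
bound by fluorescent coat protein, so nascent transcription at one locus
appears as a diffraction-limited dot inside the nucleus. Filming such
embryos through nuclear cycle 14 yields, per nucleus, a fluorescence
trajectory whose episodic rises and falls are transcriptional bursts.
`ms2burst` turns raw two-channel movies (histone marker + MS2) into burst
statistics:

1. **Segmentation** of nuclei on the max-projected histone channel — a
   classical filter/Otsu/watershed method and a threshold-adaptive method
   with MS2-dot-aware boundary refinement and Voronoi clipping;
2. **Tracking** by greedy minimal centroid displacement, forward/backward
   reconciled, with a displacement gate and short-gap bridging;
3. **Spot quantification**: the brightest MS2 voxel per nucleus is fitted
   with a 2-D Gaussian `I(x,y) = α + I₀·exp(−((x−x₀)²/2σₓ² + (y−y₀)²/2σᵧ²))`
   in an 11×11 window; the spot intensity is the background-subtracted
   integral `2π·σₓ·σᵧ·I₀`, and each trajectory is baselined to zero;
4. **Burst calling**: on 5-frame-smoothed traces, a burst opens above the
   group threshold (10% of the group's maximum signal), closes when the
   signal drops below 55% of its running local peak, shifts 2 frames, and
   must last ≥ 5 frames. Per nucleus it reports burst count, amplitude,
   duration, total output (area under the raw trace), first-burst time and
   induction rate (bursts per minute after the first);
5. **Population metrics**: instantaneous/cumulative active fractions, mean
   intensity of active nuclei, exponential fits with KS tests for ON/OFF
   durations, and periodicity via the autocorrelation of the derivative of
   the smoothed signal against a time-shuffled null;
6. **Reconstitution**: predicted intact mRNA per nucleus under first-order
   decay (7-minute half-life by default), rendered as a false-colored
   spatial pattern.

A fully ground-truthed **synthetic-data generator** (two-state telegraph
promoters with Poisson Pol II loading, rendered as drifting textured nuclei
with Gaussian MS2 dots) makes every stage testable without microscope data.
See `docs/methods.md` for the models, conventions and validation design.

## Worked example

```python
import numpy as np
from ms2burst import (FieldParams, TelegraphParams, render_movie,
                      max_project, segment_movie, link,
                      extract_trajectories, group_threshold, smooth,
                      call_bursts, burst_stats)

# simulate a 30-nucleus field, 8 minutes at 16.8 s/frame
field = FieldParams(image_shape=(250, 250), n_nuclei=30, noise_sd=50.0)
kinetics = TelegraphParams(k_on=0.4, k_off=0.8, r_load=40.0, dwell=1.2,
                           unit_intensity=100.0, n_frames=30)
movie, truth = render_movie(field, kinetics, seed=7)

masks = segment_movie(max_project(movie, 0), method=1)
tracks = link(masks, max_disp=field.nucleus_radius)
trajs, fits = extract_trajectories(movie[:, :, 1], masks, tracks,
                                   frame_interval=16.8)
thr = group_threshold(trajs)
stats = [burst_stats(call_bursts(smooth(t.intensity), thr,
                                 nucleus_id=t.nucleus_id), t) for t in trajs]
active = [s for s in stats if s.n_bursts > 0]
print(f"nuclei: {len(trajs)}, active: {len(active)}, "
      f"threshold: {thr:.0f} AU")
print(f"mean amplitude: {np.mean([s.amplitude for s in active]):.0f} AU, "
      f"mean duration: {np.mean([s.duration for s in active]):.0f} s")
```

prints

```
nuclei: 30, active: 25, threshold: 527 AU
mean amplitude: 3626 AU, mean duration: 186 s
```

i.e. 25 of 30 nuclei burst within the 8-minute window; a typical burst
peaks around 3,600 fluorescence units (about 36 nascent transcripts at
`unit_intensity=100`) and lasts ~3 minutes — consistent with the simulated
mean ON time (1/`k_off` = 75 s) plus the 72-second signal dwell and the
widening contributed by the 5-frame smoothing.

The same pipeline runs from the shell:

```bash
burstcall pipeline --config examples/config.yaml --seed 7 --out runs/demo
```

which writes masks, tracks, trajectories, burst tables, population
statistics, the autocorrelation table, per-nucleus remaining-mRNA amounts
and a manifest with the config hash into `runs/demo/`.

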