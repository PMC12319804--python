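# fuslink

Analysis chain for functional ultrasound (fUS) neuroimaging experiments
that probe the link between evoked cerebral hemodynamics and myelin
content — for example block-design whisker-stimulation studies in mouse
models of demyelination.

fUS measures cerebral blood volume (CBV) at high frame rates: a linear
probe acquires beamformed complex ultrafast frames (e.g. 500 Hz from
11-angle plane-wave compounding at a 5,500 Hz pulse-repetition frequency),
tissue clutter is removed by truncating the singular value decomposition
of the space–time (Casorati) matrix, and the mean squared magnitude of the
filtered signal — power Doppler — is proportional to blood volume in each
pixel. `fuslink` implements everything downstream of beamforming:

- **`fuslink.doppler`** — SVD clutter filtering (`svd_clutter_filter`,
  default: remove the 60 leading singular components) and power-Doppler
  integration (`power_doppler`, default 200-frame blocks → 2.5 Hz).
- **`fuslink.activation`** — per-pixel GLM on a stimulus boxcar after
  polynomial detrending; a pixel is active when the one-sided p-value of
  its stimulus coefficient passes the Bonferroni threshold
  `alpha / n_pixels`; statistics are reported as z-scores.
- **`fuslink.descriptors`** — the three per-acquisition descriptors of the
  evoked response: number of active pixels, steady-state ΔCBV (mean %
  change over the 7–20 s window of a 20 s stimulation block), and the
  10–90 % rise time of the trial-averaged evoked trace.
- **`fuslink.histology`** — myelin (MBP) immunofluorescence quantification
  on 8-bit grayscale sections: background-subtracted mean gray intensity
  and thresholded area fraction (threshold 64), with left/right and
  section averaging per animal.
- **`fuslink.linking`** — cohort statistics joining descriptors to regional
  myelin: Spearman correlation matrix with Benjamini–Hochberg adjustment,
  and per-region stepwise multiple linear regression (entry/removal
  p-thresholds 0.05/0.10) with per-coefficient t-tests and an F-test
  against the constant model.
- **`fuslink.synthetic`** — generators for every input with known ground
  truth: ultrafast stacks (low-rank tissue + variance-modulated blood +
  noise, exponential-rise CBV response), stained sections, and cohorts
  with a known linear descriptor→myelin link.

## Worked example

```python
import numpy as np
import fuslink as fl

protocol = fl.make_stimulus_protocol(20, 20, 20, 10)   # 420 s block design
zz, xx = np.ogrid[:16, :16]
active = (zz - 8) ** 2 + (xx - 8) ** 2 <= 32           # ~100-pixel patch
cfg = fl.SimulationConfig(nz=16, nx=16, ultrafast_rate_hz=250,
                          duration_s=protocol.total_duration_s,
                          active_mask=active, seed=0, pd_block_size=100)
stack, truth = fl.simulate_ultrafast_stack(cfg, protocol)

filtered = fl.svd_clutter_filter(stack, n_remove=15)
movie = fl.detrend(fl.power_doppler(filtered, block_size=100), order=1)
design = fl.build_design_matrix(protocol, movie.frame_rate_hz,
                                n_frames=movie.n_frames)
amap = fl.glm_activation(movie, design, alpha_family=0.05)
ds = fl.compute_descriptors(movie, amap, None, protocol)
print(f"active pixels: {ds.n_active_pixels} (ground truth {int(truth.active_mask.sum())})")
print(f"steady-state dCBV: {ds.delta_cbv_pct:.2f} % "
      f"(ground truth {truth.response_amplitude_pct:.1f} %)")
print(f"rise time: {ds.rise_time_s:.2f} s "
      f"(ground truth {truth.theoretical_rise_time_s:.2f} s)")
```

prints

```
active pixels: 101 (ground truth 101)
steady-state dCBV: 14.29 % (ground truth 15.0 %)
rise time: 4.14 s (ground truth 4.39 s)
```

The simulated acquisition has a 101-pixel responding patch with a 15 %
plateau CBV increase and a 2 s exponential rise constant; the pipeline
recovers the patch exactly (Bonferroni suppresses false positives), the
plateau within ~1 percentage point (the small negative bias comes from
additive-noise power dilution), and the 10–90 % rise time
`τ·ln 9 ≈ 4.39 s` within the power-Doppler frame spacing.

A command-line front end mirrors the library:

```sh
fuslink simulate stack --seed 1 --out stack.h5
fuslink process doppler --n-remove 60 --block 200 stack.h5 movie.h5
fuslink process activation movie.h5 amap.h5
fuslink link --response mbp_s1bf cohort.csv --out models/
```

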