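# ippg — light- and displacement-compensated heart-rate measurement from RGB video

Imaging photoplethysmography (iPPG/rPPG) recovers the cardiac pulse from
the sub-percent color modulation that blood volume imposes on skin in
ordinary video. It works well when the subject sits still under steady
light — and degrades quickly when the ambient light drifts or the subject
moves. `ippg` is a Python library (plus a thin `ippg` command) for
researchers and engineers who need a transparent, testable implementation
of a compensated iPPG pipeline and a controlled synthetic test bench with
exact ground truth.

## The method

Four stages, applied to ≥30 fps, ≥20 s RGB video of exposed skin:

1. **Spatial processing.** Frames are smoothed with a 5×5 Gaussian
   (σ = 1 px); skin pixels are gated by hue and chroma
   (1 ≤ H ≤ 23 half-degrees, 77 ≤ Cb ≤ 127, 133 ≤ Cr ≤ 173, full-range
   BT.601) and reduced to R/G/B time series over the skin region.
2. **Light compensation.** With g_n(i,j) the 32×32 windowed mean of
   frame n, each pixel is corrected by the drift of its windowed mean
   against the first frame, independently per channel:
   I\*_n = I′_n − (g_n − g_1).
3. **Displacement compensation.** Skin points are tracked with
   Lucas–Kanade optical flow — (u, v) solves
   [ΣI_x², ΣI_xI_y; ΣI_xI_y, ΣI_y²](u, v)ᵀ = (−ΣI_xI_t, −ΣI_yI_t)ᵀ over
   an m×m window — and traces are sampled along trajectories instead of
   fixed pixels.
4. **Measurement (CHROME).** Mean-normalized channels combine into
   X_s = 3R − 2G and Y_s = 1.5R + G − 1.5B; both are band-pass filtered
   (257-tap FIR, 0.8–1.9 Hz) and recombined as S = X_f − α·Y_f with
   α = std(X_f)/std(Y_f), cancelling components shared by all channels
   (specular reflection, residual drift). Beats are the peaks of S;
   with k peaks spanning T seconds, bpm = 60·(k−1)/T — e.g. 19 peaks
   spanning 18.82 s → 57.4 bpm.

A seeded synthetic-video generator renders the underlying reflection
model (elliptical skin patch, tunable pulse depth, drift, sway, specular
flicker, sensor noise) so every estimate can be checked against ground
truth.

## Worked example

```bash
python examples/01_measure_synthetic.py
```

```
true rate        : 72.0 bpm
estimated rate   : 72.0 bpm
heartbeat cycles : 12
mean cycle       : 0.833 s
first peaks (s)  : [5.2, 6.03, 6.87, 7.7, 8.53]
```

A clean 20 s synthetic recording at 72 bpm is generated and measured: the
12 transient-free heartbeat cycles average 0.833 s, i.e. 60/0.833 =
72.0 bpm. The other examples exercise one capability each — skin gating
(`02`), drift removal (`03`, RMS trace deviation 4.37 → 0.17 under a
+1 intensity/s ramp), point tracking (`04`, ≤0.4 px RMS against ground
truth under 1.5 px sway), and the chrominance filter (`05`, a shared
artifact 5× stronger than the pulse is cancelled and 66.2 bpm is read
against a true 66.0).

From the shell:

```bash
ippg simulate --hr 72 --out frames/ --truth truth.json
ippg measure --input frames/ --fps 30 --out result.json
ippg ablate --axis drift --levels 0.2,0.5,1.0 --seeds 10 --out table.csv
```

`measure` prints a JSON record `{bpm, n_cycles, mean_cycle_s,
peak_times_s, config_echo}` and exits 0/2/3/4 for success / validation
failure / signal-quality failure / I/O failure.

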