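# Methods

`ippg` estimates a resting heart rate from RGB video of exposed skin. The
cardiac pulse modulates the blood volume in skin capillaries, which
modulates the diffusely reflected light by a fraction of a percent; the
package recovers that modulation from the frame-to-frame color statistics
of a skin region and reads the rate from the intervals between beats.

## Signal model

The value of channel C ∈ {R, G, B} of a skin pixel at time t is modeled
as

    C(t) = I_C · (ρ_Cdc + ρ_C · p(t) + S(t))

where I_C is the illumination reaching the sensor in that channel,
ρ_Cdc the static skin reflectance (ρ_Rdc > ρ_Gdc > ρ_Bdc for skin),
ρ_C the pulsatile modulation depth, p(t) the pulse waveform, and S(t) a
specular component that is *equal in all three channels*. On top of the
model sit two disturbances the pipeline explicitly compensates: an
ambient-light drift that moves all intensities slowly, and small subject
motion that decouples pixel coordinates from skin locations.

## Pipeline stages

**1. Spatial processing.** Every frame is denoised with a 5×5 Gaussian
kernel (σ = 1 px, sampled and renormalized to sum 1 — the raw sampled
weights sum to ≈0.982, so renormalization is what keeps constant images
constant). Skin pixels are gated by a joint color box: hue 1–23 on the
half-degree scale (H ∈ [0,180)), Cb 77–127 and Cr 133–173 on the
full-range BT.601 8-bit scale, all bounds inclusive. The raw gate is
cleaned by a 3×3 morphological open/close and restricted to the largest
connected component; the reference mask is computed on the first frame.

**2. Light compensation.** The compensator assumes the windowed mean
intensity around any pixel is constant over time: with g_n(i,j) the
2a×2b box mean of frame n (default a = b = 16, i.e. 32×32), every pixel
is corrected by

    I*_n(i,j) = I'_n(i,j) − (g_n(i,j) − g_1(i,j))

independently per channel. Subtraction cancels the drift; the additive
variant (`sign="add"`) is kept for comparison but doubles the drift
instead. Note the window definition: exactly 2a×2b pixels
([i−a, i+a−1]×[j−b, j+b−1], edge-replicated), so the divisor equals the
number of summed terms and a constant image is a fixed point.

*Pulse attenuation trade-off.* Wherever the window lies entirely on
uniformly pulsing skin, g_n carries the pulse and the subtraction
attenuates it. A spatially uniform pulse over a patch much larger than
the window is therefore attenuated by roughly the mean skin fraction of
the window around ROI pixels; near the patch boundary the window sees
background and the pulse survives. The 32×32 default keeps enough of the
pulse (the end-to-end recovery tests run with compensation on) while
still tracking spatially non-uniform illumination. Larger windows retain
more pulse but localize drift less.

**3. Displacement compensation.** Apparent motion of chosen skin points
is estimated with Lucas–Kanade optical flow: under brightness constancy
and locally constant flow over an m×m window (default m = 15), the flow
(u, v) solves the 2×2 normal equations built from spatial gradients
(central differences) and the temporal difference. A window whose normal
matrix has smallest eigenvalue below 1e-4·m² (0–255 gradient scale) is
rejected as degenerate (aperture problem). The single-step solution is
valid only for sub-pixel steps, so each solve is refined iteratively
(≤5 warp-and-resolve rounds, stop at 0.01 px).

Tracking integrates these estimates frame to frame, then re-anchors each
position against the *first frame's* window using the integrated estimate
as initialization. Without re-anchoring the integration error random-walks
(≈0.6 px RMS over 600 frames on the synthetic sway scenario); with it the
error stays bounded (≈0.3 px RMS). Tracking runs on the smoothed green
channel *before* light compensation, so the compensation arithmetic
cannot violate brightness constancy. Three seed points (deterministically
the strongest well-separated corners inside the eroded mask) are tracked;
the ROI is re-centered by their per-frame median displacement. A
per-point sampling mode (`flow.sampling="points"`) instead averages
traces sampled along the trajectories themselves, which is the natural
object for point-level analysis.

**4. Measurement.** The R/G/B traces are divided by their temporal means,
combined into two chrominance signals

    X_s = 3R − 2G,    Y_s = 1.5R + G − 1.5B

band-pass filtered to X_f, Y_f, and recombined as S = X_f − α·Y_f with
α = std(X_f)/std(Y_f). A component shared equally by the normalized
channels enters X_s and Y_s identically and cancels in S; the pulsatile
term survives because its per-channel weights differ. α is undefined in
the original formulation; the standard deviation ratio is the
conventional choice because it equalizes the artifact amplitude between
the two chrominance signals before differencing.

The band-pass is a 257-tap Hamming-windowed linear-phase FIR with −6 dB
edges at 0.8 and 1.9 Hz (48–114 bpm). A recursive "256th-order
Butterworth" is numerically unrealizable; the FIR design reproduces the
intended behavior (measured at fs = 30: 0 dB at 1.35 Hz, −56 dB at
0.2 Hz, −87 dB at 5 Hz) and its symmetric taps make the group delay an
exact order/2 samples, which centered convolution compensates, keeping
peak times on video time. The temporal mean is removed before filtering
so the implicit zero-padding does not inject a step transient; the first
and last order/2 samples are warm-up and excluded from peak search.

S is standardized — centered on its median and scaled into the
[−0.5, 0.5] span — which moves no peak. Beats are local maxima separated
by at least 1/1.9 s with prominence ≥ 0.1 of the signal span. With peaks
at t_1 < … < t_k, each adjacent interval is one heartbeat cycle, the mean
cycle is (t_k − t_1)/(k − 1) (equal to the mean of adjacent intervals by
telescoping), and bpm = 60/mean cycle, reported to 0.1 bpm. The printed
convention: 19 peaks spanning 18.82 s are 18 cycles and 57.4 bpm.

## Synthetic data

The generator renders the signal model directly: an elliptical skin patch
(default ≈45×32 px semi-axes in a 160×120 frame) whose base color
(200, 140, 110) passes the skin gate, over a neutral gray textured
background that fails it. Defaults are the study conditions: 30 fps, 20 s,
pulsatile depths (ρ_R, ρ_G, ρ_B) = (0.002, 0.004, 0.002) — invisible to
the eye, recoverable from 20 s of video — sensor noise σ = 2 on the 8-bit
scale, and a multiplicative pixel-scale skin texture (2% contrast,
smoothed at 1.2 px) that moves rigidly with the patch and gives the flow
tracker its gradients. Drift profiles (linear/step/sinusoidal), motion
profiles (translation/sway, ≤2 px per frame), a shared specular flicker,
and an optional fast-systole asymmetric waveform are available per
scenario; one seed determines every random quantity bit-exactly.
Experimental axes map onto scenarios: subject distance scales the patch
area as 1/d², light level scales brightness linearly and noise as
1/sqrt(lux).

What the generator does *not* emulate: photorealistic faces and
physiological waveform detail, camera gain/exposure dynamics, spatially
non-uniform illumination fields, non-rigid motion, and disturbances with
broadband in-band structure. Passing tests therefore demonstrate the
pipeline's mechanics and its behavior under controlled, model-faithful
disturbances — not performance on real recordings.

## What the controlled ablations can and cannot show

A finding worth stating explicitly: a spatially uniform *linear* additive
drift lies almost entirely below the 0.8 Hz passband edge, and every
stage between the traces and the peak detector is linear up to
normalization and standardization, so the CHROME + band-pass core removes
such drift on its own. Likewise a 0.3 Hz sinusoidal sway of 1–2 px
produces an ROI disturbance concentrated at the sway fundamental, below
the passband, and the albedo-like (channel-proportional) texture artifact
cancels in the chrominance difference by construction. Under these
idealized conditions the bpm-level benefit of the compensation stages is
small — the compensators' effect is instead locked in at the trace level:
the compensated ROI trace's RMS deviation from its initial value drops
under drift, and tracked-point traces vary ≥5× less than fixed-pixel
traces under motion. On real recordings drift and motion have in-band,
non-proportional structure, which is where the compensation stages earn
their keep; reproducing that requires real data, which is out of scope
here.

## Numerical choices and degenerate inputs

- Intensities stay 8-bit through I/O and are promoted to float at the
  first arithmetic stage. The orchestration processes frames one at a
  time (smooth → box-mean correct → sample), never materializing a
  full-precision frame stack; the stack-level APIs remain and the two
  paths are asserted equivalent in tests.
- Sub-pixel sampling: cubic B-spline interpolation inside the flow
  solver (pre-filtered crops), bilinear for trace sampling, where its
  exactness on linear ramps and integer shifts is what tests rely on.
- Empty-mask frames are gap-filled by linear interpolation up to 10% of
  frames, then a hard error; all-constant signals, zero-mean channels,
  zero-std chrominance, and <2 detected peaks raise typed errors rather
  than returning numbers.
- Estimates outside the passband-implied 48–114 bpm range attach a
  warning (they indicate missed or spurious peaks).
- Problem sizes in the test suite are the study conditions: 160×120
  frames, 30 fps, 20 s, 20 seeds for clean recovery, 10 seeds per
  ablation level; module-level tests use smaller frames and durations
  chosen to exercise the same code paths.

## Known limitations

- Motion beyond ~2 px/frame breaks the small-motion linearization (no
  image pyramid by default); large or non-rigid motion is out of scope.
- The skin gate is color-only: it cannot separate two skin regions or
  reject skin-colored background, and very low light pushes chroma out
  of the gate box.
- A single rate is reported per recording; rate variability and beat
  morphology are not measured. A sliding-window mode would localize rate
  changes but is not the default.
- The compensator attenuates a spatially uniform pulse (see above); on
  faces, pulse amplitude varies spatially, which softens but does not
  remove the effect.
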