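# Methods

`ipgbp` implements a complete cuffless blood-pressure (BP) estimation
pipeline for single-channel impedance plethysmography (IPG): a physics-based
simulator of carotid IPG acquisitions, signal preprocessing, wavelet
scalogram features, a compact stagewise-regression CNN trained with a
quartile-penalty loss, and an AAMI-style accuracy evaluation. This note
documents the models, the defaults and why they were chosen, and what the
synthetic experiments do and do not demonstrate.

## Forward model: from arterial pressure to measured impedance

The simulator builds each subject's signal in three layers.

**Pressure pulse.** One beat is a two-Gaussian template — a systolic peak
and a dicrotic (reflected) wave — sampled over one heart period and rescaled
so the beat maximum is exactly the beat's systolic pressure (SBP) and the
minimum its diastolic pressure (DBP), both in mmHg. The template's shape
parameters are smooth functions of pressure: higher SBP delays and narrows
the systolic peak, higher DBP strengthens and delays the dicrotic wave.
This coupling matters because the preprocessing min-max-normalizes every
beat, which removes all amplitude information; in this simulator, pressure
must therefore be legible in beat *morphology*, which is also the premise of
the shape-based estimation approach itself. Real carotid pulse shapes do
co-vary with pressure (arterial stiffening, wave reflection timing), but the
specific parameterization here is a modelling choice, not a fitted
physiological law.

**Bramwell–Hill area coupling.** Pressure changes map to cross-sectional
area changes through dP = ρ (D/PTT)² dA/A, with blood density ρ, electrode
separation D, and pulse transit time PTT treated as subject constants.
Integrating exactly gives

    A(P) = A0 · exp[(P − P0) · PTT² / (ρ D²)]      (pressures in Pa),

and the implementation uses this closed form (tested against brute-force
Euler integration of the differential relation to within 1%). User-facing
pressures remain in mmHg; the conversion (×133.322 Pa/mmHg) happens inside
the physics.

**Ohm's law.** The measured segment impedance is Z = L/(σA) for segment
length L and blood conductivity σ, so impedance falls when pressure rises.
Defaults (ρ = 1060 kg/m³, D = 0.2 m, PTT = 35 ms, L = 2 cm, σ = 0.6 S/m,
A0 = 3×10⁻⁵ m², P0 = 70 mmHg) give a pulse-wave velocity of ≈5.7 m/s, a
baseline impedance of ≈1111 Ω and an area excursion of ≈20% over a typical
pulse pressure — plausible orders of magnitude, but the absolute ohm scale
of real carotid IPG is hardware-dependent and is deliberately not asserted;
downstream normalization removes it anyway.

**Measurement noise.** White Gaussian noise is added at a configurable SNR
(default 20 dB) defined against the *pulsatile* (AC) signal power, since
the large DC impedance carries no pulse information, plus a baseline-wander
sinusoid below 0.3 Hz (default 0.15 Hz, amplitude equal to the AC standard
deviation) that the band-pass removes. An infinite SNR selects the fully
noise-free path, used by the parameter-recovery tests.

**Acquisition protocol.** A subject is measured in 30 trials. Each trial
draws latent true (SBP, DBP) around the subject baseline with SD
`trial_sd` (default 5 mmHg, matching a per-subject spread of roughly
110–130 / 56–79 mmHg over 30 trials), renders 9 beats (5 wanted + 4 margin)
at 500 Hz, and attaches one cuff reference equal to the true values plus
Gaussian cuff noise (default SD 1.5 mmHg, a plausible oscillometric-device
repeatability). The cuff operating time sits at the middle of the segment.
Subject baselines are drawn uniformly from 110–130 mmHg (SBP) and
56–79 mmHg (DBP); heart rate from 0.9–1.5 Hz within the 0.67–3.33 Hz band.

## Preprocessing

The analog front end is emulated by a 4th-order Butterworth band-pass,
0.3–5 Hz, applied forward–backward (zero phase). The analog original is
causal; zero-phase application is a deliberate deviation that preserves
beat morphology for feature extraction, and the filter's amplitude response
is verified against the analytic band-pass magnitude (the double pass
squares it). Because impedance anticorrelates with pressure, the filtered
waveform is inverted before peak detection so systole is a peak.

Beats are segmented by systolic-peak detection (minimum inter-peak distance
fs/3.33 Hz, prominence ≥ 0.3 of the signal range) and cut trough-to-trough.
Per trial, the 5 beats whose peaks lie nearest the cuff operating time are
selected (ties resolve to the earlier beat) — one concrete reading of
"beats around the cuff operation"; strictly-before or strictly-after
readings would be equally defensible. Each beat is linearly resampled to
128 samples and min-max scaled to [0, 1]; a constant beat maps to zeros.

## Scalogram features

Each normalized beat becomes the magnitude of a continuous wavelet
transform using the Daubechies-8 wavelet. db8 is an orthogonal discrete
wavelet with no closed-form mother function, so the transform
cross-correlates the beat with rescaled db8 wavelet functions from the
cascade-algorithm approximation, L2-normalized per scale — the construction
some wavelet toolboxes use in this situation; a Morlet alternative is
available by configuration. Default: 64 log-spaced scales spanning
pseudo-frequencies ≈1–20 Hz at the beat's effective sampling rate (128
samples per beat period), covering the pulse fundamental and its relevant
harmonics. The 64×128 scalogram is bilinearly resized (align-corners) to a
32×32 image and min-max normalized; both the scale set and the image
resolution are configuration defaults, not physiological facts.

## The regression network

A two-stream stagewise soft-regression CNN maps a 32×32 scalogram to one
BP value. Each stream has three 3×3-conv blocks of 16 channels; stream A
uses ReLU + average pooling, stream B tanh + max pooling (complementary
nonlinearity and pooling). Stage s (3 stages, coarse→fine) taps the streams
at decreasing depth, reduces each tap with a 1×1 conv (4 channels), pools
to 2×2, and projects to a 4-d vector; the two streams fuse by elementwise
multiplication. Three small heads per stage emit bin probabilities p_s
(softmax over K_s = 3 bins), bin shifts η_s (tanh), and a stage-width
refinement Δ_s (tanh scaled to ±0.25). The prediction is

    y = y_min + (y_max − y_min) · clip( Σ_s m_s / Π_{j≤s} K_j (1 + Δ_j), 0, 1 ),
    m_s = Σ_k p_{s,k} (k + η_{s,k}),

bounded by construction. Regression spans default to 80–180 mmHg (SBP) and
40–120 mmHg (DBP). Biases initialize to zero, so a zero image yields
uniform bin probabilities and the analytic centre prediction (13/27 of the
span for 3×3×3 bins) — a hand-checkable anchor for the stagewise formula.
The default network has 10,521 trainable parameters, well under the 0.04 M
budget it is sized against.

The network, its backward pass and the Adam optimizer are implemented
directly in NumPy (float32 by default; float64 available and used by the
finite-difference gradient tests, which the analytic gradients match to
1e-4 relative).

## Loss and training

Training minimizes a quartile-penalty mean absolute error. With Q1 and Q3
the linear-interpolation quartiles of the *training* cuff references,

    loss = α · |ŷ − y_cuff|   if y_cuff < Q1 or y_cuff > Q3,
    loss =     |ŷ − y_cuff|   otherwise (boundaries included),

with α = 3 by default. The boundary tie-break (references exactly at
Q1/Q3 use the unweighted branch) is a documented convention. Optimizer:
Adam, learning rate 10⁻³, batch 16, at most 300 epochs with early stopping
when the running-best epoch loss improves by less than 0.5% for 15
consecutive epochs — in practice runs stop near 60–120 epochs. Separate
models are trained for SBP and DBP; quartiles come from the training
references of the respective target only. Training is deterministic for a
fixed seed.

`convergence_epoch` declares convergence at the first epoch after which the
running-best loss improves by less than 2% (relative) for 10 consecutive
epochs; the criterion is this package's own operationalization (with its
brute-force oracle in the tests), used to compare convergence speed across
α values at a reduced 25-epoch budget.

## Evaluation

The 150 (scalogram, reference) pairs per subject split 120/30. The split is
stratified by trial: all five beats of a trial share one cuff label, so
they are assigned to the same partition (6 whole trials form the test set),
which is stricter than an unconstrained random split and avoids label
leakage. Statistics on the 30 test pairs: mean error ME = mean(ŷ − x) and
MAE with sample (n−1) SDs; Bland–Altman bias (identical to ME) with
1.96·SD limits of agreement; the AAMI verdict |ME| ≤ 5 mmHg and SD ≤ 8 mmHg;
and five-number box summaries reusing the same quartile convention. All
statistics are verified against brute-force loop oracles to 1e-12.

## What the synthetic experiments show — and what they do not

On the default synthetic subject (20 dB SNR, 1.5 mmHg cuff noise) the full
pipeline reaches |ME| ≲ 3 mmHg with error SD ≲ 5 mmHg on the held-out 30
pairs for both targets across seeds, passing the AAMI bound with margin —
and the error SD falls well below the 5.2 mmHg that a reference-mean
predictor would score, so the network demonstrably reads pressure from beat
morphology rather than regressing to the mean. This validates the
*pipeline mechanics* (segmentation, feature extraction, optimization,
evaluation) under a generator whose shape–pressure coupling is smooth,
stationary and noise-controlled. It does not validate clinical accuracy:
real carotid IPG has motion artifacts, electrode-contact drift,
inter-subject morphology differences, and shape–pressure relationships far
less tidy than the template's, none of which the generator emulates.

## Numerical and scope notes

- Problem sizes: default experiments use one subject, 30 trials × 5 beats,
  128-sample beats, 64-scale scalograms, 32×32 inputs; the multi-subject
  pipeline (`run_full`) defaults to 6 subjects.
- Degenerate inputs are defined, not rejected: constant beats/scalograms
  normalize to zeros; an all-zero signal segments to an empty beat list;
  fewer than k segmentable beats in a trial raises a trial-identifying
  error.
- The hardware chain (electrodes, 50 kHz carrier, demodulation, ADC) is
  out of scope and represented only by the band-pass + noise model; there
  are no baseline model comparisons, no model-size/inference-time claims,
  and no regulatory-grade AAMI protocol (subject counts, cuff strata).
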