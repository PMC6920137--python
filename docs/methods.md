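# Methods

This note documents the models, numerical choices and limitations behind
`epievents`: a pipeline for automated detection and classification of
interictal epileptiform events — spikes, ripples, ripples-on-spikes (RonS)
and baseline activity — in intracranial EEG (iEEG).

## Signal model and preprocessing

Input is a multichannel voltage time series sampled at ≥ 500 Hz (the
analysis bands extend to 236 Hz, so the Nyquist frequency must exceed that).
Preprocessing repairs missing samples (linear interpolation over interior
gaps, nearest-value extension at the edges; gaps longer than 1 s are logged
and flagged for exclusion, preserving segment timing for spectrogram
binning), applies a 300-order FIR highpass at 0.5 Hz forward-backward
(zero-phase), and optionally a second-order IIR notch (default 60 Hz,
Q = 35) when line interference is present.

*Highpass convention.* A 301-tap Hamming windowed-sinc design at 500 Hz has
a transition width of ≈ 3.3·fs/taps ≈ 5.5 Hz. If the −6 dB point is placed
*at* 0.5 Hz, frequencies below the cutoff are barely attenuated
(|H(0)| ≈ 0.68): the filter cannot do its job. `design_highpass` therefore
treats the cutoff as the **stopband edge** — the transition band is placed
above it — so everything at or below 0.5 Hz sits in the ~53 dB stopband,
and channel means are subtracted before filtering so DC is nulled exactly.
The cost is partial attenuation up to ≈ 6 Hz; this is immaterial downstream
because detection operates on per-band power *ratios*, which are invariant
to any fixed per-band gain.

## Band spectrogram

Power is computed by short-time FFT with a 0.25 s Hann window, giving a
4 Hz frequency grid, and averaged into eight bands: theta (4–8), alpha
(8–13), beta (13–30), gamma1 (30–56), gamma2 (64–116), rip1 (124–176),
rip2 (184–196) and rip3 (204–236 Hz). Band membership is half-open
[low, high) on the grid, so a printed shared edge (8 Hz) is counted once,
in the upper band. The gaps around 60, 120, 180 and 200 Hz keep line
interference and its harmonics out of every band. Power is the one-sided
squared spectrum scaled so that its frequency sum equals the tapered-window
energy (Parseval); the absolute scale is a convention since only ratios are
used.

*Window stride.* Successive windows advance by **half a window** (62
samples at 500 Hz) rather than a full window. A Hann taper is nearly zero
at its edges, so with non-overlapping windows a 20–70 ms event straddling a
window boundary is strongly attenuated in *both* adjacent windows: in our
simulations, events centred within 0.1 window-length of a boundary were
never detected and overall recovery fell to ~53%. With the half-window hop
every instant lies near the centre of some window and recovery of injected
events at the default amplitudes is ≥ 90% (measured ≈ 99%), while window
length, frequency resolution and taper are unchanged. Non-overlapping
windows remain available (`hop_s = window_s`).

## Baseline power from the mode of the log-power distribution

For each channel and band, baseline power is estimated from the empirical
distribution of log power over the analysis segment. Log spectral power of
background activity is approximately normal; rare high-power events (the
spikes and ripples the detector is looking for) skew the distribution's
upper tail but barely affect its peak. The estimate is
`exp(mean of the most probable log values making up 20% of the distribution)`:
a histogram window is grown around the density peak, one bin at a time
toward the denser neighbour, until it holds ≥ 20% of the mass, and the mean
of the log values inside is taken.

Numerical refinements: binning noise displaces the empirical peak, so the
procedure uses an **averaged shifted histogram** (four bin origins, bin
width by Freedman–Diaconis, overridable) with 3-bin moving-average
smoothing of the counts for peak finding, and averages the four window
means. On 10⁴ log-normal samples (σ = 0.5) this recovers exp(µ) with ≈ 3%
error, and 5% contamination at 50× power moves the estimate by < 1% while
more than doubling the plain mean — the property that makes the estimator
usable without first excising events. A Kolmogorov–Smirnov log-normality
check is provided as a diagnostic only and never gates the pipeline.

Degenerate inputs: zeros are excluded with a logged count; an all-zero
series is an error; fewer than 100 positive values produces a warning but
still an estimate; a constant series returns itself.

## Threshold detection

Each bin of the relative (baseline-normalised) spectrogram is labelled:

* **spike** — beta ≥ 4 and max(gamma1, gamma2) ≥ 4, ripple criterion not met;
* **ripple** — any of rip1/rip2/rip3 ≥ 7, spike criterion not met;
* **RonS** — both criteria met;
* **baseline** — neither.

The ripple threshold is higher than the spike threshold because relative
power excursions during genuine ripples are larger. "Not in the other
band" is read as *the other criterion not met*, which makes the four labels
an exhaustive partition. A strict mode requiring both gamma sub-bands is
available (`strict_gamma`); the default accepts one, since narrow spikes
may not reach gamma2. Classification is per bin; adjacent supra-threshold
bins are not merged (the 3-bin feature context absorbs events split across
bin edges), though a post-hoc merge utility exists.

This spectrogram route is what distinguishes true ripples from "false
ripples": highpass-filtering a sharp spike produces an oscillatory
time-domain burst above 100 Hz, but a genuine smooth spike has negligible
ripple-band *spectral* power, so the 7× criterion is not met and the bin
stays spike, not RonS.

## Feature extraction, ground truth and splits

An event's feature matrix is 8 bands × 3 time bins (previous, current,
next); edge bins replicate the missing neighbour. Balanced per-subject
ground-truth sets (default 1000 events per class; the desk-scale benchmark
uses 200) are drawn uniformly without replacement, stratified by
(subject, class), across all channels; a class absent for a subject is an
empty cell, not an error. Train/test splits are disjoint per
(subject, class) within each randomization and reproducible from a seed.
For synthetic data the visual-verification step is replaced by the
generator's injection log: candidates are kept only if their detector label
matches an injection (non-baseline) or if no injection is nearby
(baseline).

## The sequence classifier

Sequences of 3 time steps with 8 features feed one (default) bidirectional
LSTM layer of `HU` hidden units (20–200; default 200), then a fully
connected layer and a softmax over the four classes; variants with one or
two unidirectional layers and dropout (0.2) after each LSTM layer are
supported. The forward pass, backpropagation through time and the Adam
optimizer (lr 10⁻³, batch 128, gradient clipping at global norm 1,
Glorot-uniform initialization, unit forget-gate bias) are implemented
directly in NumPy: the network is small enough that this is fast on one
CPU and bit-for-bit reproducible from a seed. "Iterations" counts
optimizer steps. Relative powers pass through log(1+x) before training
(raw mode selectable), compressing the 1–50× dynamic range.

Exact probability ties break toward the first class in the fixed order
(spike, rons, ripple, baseline). Training on a single-class set is
rejected. `NI = 0` leaves the model at its initialization.

## Evaluation

From the 4×4 confusion matrix (rows true, columns predicted), with P(i)
positives, N(i) negatives, TP(i) hits and FP(i) false alarms per class:

    Acc     = 100 · Σ TP(i) / Σ P(i)
    Sens(i) = 100 · TP(i) / P(i)
    Spec(i) = 100 · (1 − FP(i)/N(i))

Acc is identically the P(i)-weighted mean of the sensitivities. Metrics
aggregate over randomizations as mean and sample SD (n−1). A class with
P(i) = 0 reports sensitivity as undefined (NaN) and propagates it.

Validation scenarios: within-subject; between-subjects (train on one
subject, test on each other — the off-diagonal grid); global (pool all
training subjects, evaluate per subject); cross-site (global training
evaluated additionally on every subject of a held-out dataset).

## Synthetic iEEG generator

The generator emulates the statistics the pipeline operates on, not
biophysics:

* background: Gaussian 1/f^α noise (α = 1 by default, RMS 20 µV), built by
  spectral shaping;
* spikes: smooth biphasic transients, 20–70 ms, peak 8–12× background SD.
  The fast lobe is a Gaussian of width max(0.10·duration, 2.5 ms): wide
  enough that spectral energy decays fast above ~120 Hz (a real spike has
  no genuine ripple-band power), sharp enough to drive beta–gamma;
* ripples: Hann-enveloped bursts of ≥ 4 cycles (more than 3 oscillations),
  4–6× SD, centre frequency inside one of the three ripple passbands
  (frequencies jittered into a gap are snapped back with a 3 Hz margin);
* RonS: a ripple burst centred on the spike peak;
* optional 60 Hz line interference;
* per-subject morphology jitter: log-normal multiplicative offsets
  (σ = 0.2 by default) on amplitude, duration and ripple frequency — the
  mechanism behind limited between-subject generalisation;
* scheduling: a merged Poisson process thinned to classes, with ≥ 1 s
  separation enforced so every bin has a unique true label; everything is
  reproducible from (seed, subject index).

Calibration contract: with the default amplitudes the threshold detector
recovers ≥ 90% of injections at the correct bin ± 1 with the correct class
(measured ≈ 99% over 10 seeds), so the injection log is a faithful stand-in
for visually verified ground truth. Line noise at 60 Hz leaves detection
output identical (a steady tone inflates a band's baseline exactly as it
inflates every bin), though raw gamma2 band power does shift because Hann
leakage from the on-grid 60 Hz reaches the 64 Hz edge bin.

What the generator does **not** emulate: real electrode artifacts,
state-dependent background (sleep/wake), spike-wave complexes, overlapping
events, non-stationary line noise, or realistic inter-channel correlation.
Passing benchmarks on this data demonstrates the internal consistency of
detector, ground-truth assembly and classifier under the stated morphology
ranges — not clinical-grade performance on hospital recordings.

## Benchmark problem sizes

The desk-scale global benchmark uses 7 training-site + 2 held-out-site
subjects, 200 events per class per subject (segment length is sized from
the injection rate, ~23 min per subject at 6 events/min/class), training on
100 events/class/subject with a biLSTM (HU = 50, NI = 500), testing on 100
held-out events/class/subject, over 3 randomizations; the small-network
variant uses HU = 20, NI = 1200. These sizes keep a full run in minutes on
one CPU while leaving every pipeline stage at its default configuration.

## Known limitations

* EDF support: reading via MNE; writing via a minimal internal 16-bit EDF
  writer (one-second records) used for fixtures.
* Fast ripples (> 250 Hz) are out of scope, as is any visual-review GUI,
  automatic bad-channel detection, re-referencing or resampling.
* The half-window hop doubles the number of bins; adjacent bins overlap by
  50% and may both fire for one event. Downstream consumers that need
  disjoint events should use the merge utility or the injection-log
  verification.
* The between-subject degradation reproduced here is driven entirely by
  multiplicative morphology jitter; real inter-patient variability is
  richer.
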