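# Methods

This note documents the modeling choices, their defaults, and what the
synthetic benchmark does and does not establish.

## Preprocessing

Recordings are polyphase-resampled to 200 Hz (anti-alias FIR inside
`scipy.signal.resample_poly`) and then band-passed to 8–45 Hz. The band
keeps the alpha (8–13 Hz), beta (13–30 Hz) and gamma (30–45 Hz) rhythms
that carry affective state and rejects slow drift, eye-movement
artifacts below 8 Hz and line interference above 45 Hz. Theta and delta
are deliberately outside the analysis band.

Filter: order-4 Butterworth, applied forward–backward (zero phase).
Zero phase matters because the latency metric Δt measures *when* a
transition is recognized; a causal filter's group delay would bias
every measured latency. The effective stop-band attenuation at 2 Hz
and 60 Hz exceeds 20 dB (verified in the test suite). Downsampling
precedes filtering, matching the listed order of the processing stages.
The first and last second of any filtered recording are treated as
filter-transient padding and excluded from benchmark material.
Label tracks are categorical, so downsampling maps them by
nearest-neighbor index rather than interpolation.

## Windowing

Windows longer than 3 s average over too much signal for real-time
use; the configuration refuses them unless explicitly overridden (the
override exists because latency *comparisons* need long windows as a
baseline). Steps outside 50–80% of the window emit an advisory only.
Window and step are rounded half-up to whole samples before cutting so
segmentation is bit-exact at any sampling rate; trailing partial
windows are dropped, never zero-padded, because padding would dilute
the spectral features. The streaming segmenter is provably equivalent
to batch segmentation for every chunking (property-tested) and retains
only the samples future windows still need.

Ground-truth labels for mixed windows use majority vote. The tie rule
is configurable: `newest_tiebreak_majority` (default during
segmentation) resolves an exact tie toward the label appearing latest
in the window, consistent with the real-time emphasis on the newest
data; plain `majority` resolves ties toward the earliest-appearing
label so both policies are deterministic.

## Spectral features

Within each 1 s window the STFT uses 0.25 s Hann sub-windows with 50%
sub-window overlap, giving 7 frames — a genuine sequence for the
recurrent layer. (Using the full window length as the transform length
would collapse each window to a single frame and leave the LSTM
nothing to recur over, so the window/step numbers are interpreted as
segmentation parameters and the intra-window transform scale is a
separate, shorter sub-window.) A 0.25 s sub-window at 200 Hz yields a
4 Hz bin grid; the retained bins are 8, 12, …, 44 Hz — ten per
channel. Channels are transformed independently and occupy disjoint
blocks of the feature vector; they are never concatenated into one
spectrum or mixed.

Magnitudes are log-scaled by default (`log(|F| + 1e-8)`) because band
powers span orders of magnitude. Whether to feed magnitude, power or
complex values is an open choice; log magnitude is the standard
spectrogram convention and is what the classifier consumes. No
normalization happens at the feature level; instead the *training
routine* z-scores each feature using training-split statistics only
(stored in the checkpoint and re-applied at inference), which prevents
leakage by construction and keeps the large negative log-floor values
of silent bins from saturating the LSTM gates at initialization.

## Classifier

"128 nodes" is interpreted as the LSTM hidden dimension (the only
layer with a node count). Fusion of the attention context Z with the
LSTM output hₙ is underdetermined by the architecture description;
both readings are implemented: `concat` (default — softmax over
[Z; hₙ], the safer choice) and `gated_sum` (softmax over
λZ + (1−λ)hₙ with λ = σ(ρ) learned). Dropout (rate 0.5) applies to the
fused representation only, during training only. Loss is categorical
cross-entropy; the optimizer is Adam at lr 0.001 with batch size 64.
Parameters initialize uniform(−k, k), k = 1/√d, from the run's seed.

Early stopping runs two monitors side by side — validation accuracy
failing to improve by ≥ 1e-4, and validation loss failing to decrease —
and either ends training after 50 stalled epochs (≤ 500 total). The
returned parameters are those of the best validation-accuracy epoch.
The validation split is stratified 80/20 within the training pool,
seed-controlled; identical seeds give bit-identical histories.

Gradients are analytic backpropagation through time, verified against
central finite differences to 1e-5 relative on small random models
(with an absolute floor where the gradient sits at finite-difference
noise level).

## Synthetic generator

Each emotion is a profile of mean tone amplitudes over the rhythm
bands plus a broadband white-noise level. A scripted scenario renders
one sinusoid per band per channel (frequency uniform inside the band,
random phase), summed and crossfaded over 50 ms at block transitions —
sharp relative to the 0.5 s update period but without impulsive
spectral splatter. The native rate is 1000 Hz so the downsampling path
is always exercised. Defaults: dominant-band amplitude 1.0, minor
bands 0.1, noise sd 0.3 — a strong but not noiseless contrast, chosen
so the three default classes (alpha-, beta-, gamma-dominant) are
linearly separable in mean band power, which a nearest-centroid
band-power oracle verifies independently of the neural model.

Benchmark recordings are built from consecutive 2 s same-emotion
blocks so tone frequencies are redrawn every couple of seconds: a
class is its band *profile*, not one incidental frequency draw. With a
single draw per class, even spectrally identical profiles would be
separable by their accidental tone positions. The 80/20 split is
stratified at the segment level; because 50%-overlapping neighbors can
straddle the split, residual within-recording correlation exists at
very small sample counts — the indistinguishability check therefore
runs at 100 segments per class, where it sits at chance.

What passing these tests shows: the pipeline recovers band-power class
structure end to end and its latency behaves as the windowing theory
predicts. What it does not show: performance on physiological EEG —
the generator has no 1/f background, no artifacts, no inter-subject
variability, and its class structure is far cleaner than evoked
emotion.

## Latency metric

A prediction exists at its window's *end* time — the earliest causally
available moment. For a transition to label y at time T, the detection
time is the first prediction time ≥ T (and before the next transition)
whose predicted label equals y for k consecutive emissions (k = 1 by
default; the persistence option suppresses single-window flicker).
Δt = detection − T, hence Δt ≥ 0 always, and for a perfect classifier
Δt ≤ window + step. Undetected transitions are reported as such rather
than folded into the mean as infinities. The test suite verifies, on a
noiseless scripted scenario, that mean Δt shrinks strictly as the
window shortens from 10 s to 5 s to 1 s at fixed 50% overlap.

## Problem sizes

The class-recovery benchmark uses 300 segments per class (720 train /
180 held-out, 4 channels) with the full default hyperparameters; the
latency sweep trains smaller models (hidden 32, ≤ 60 epochs, 40
segments per class, 2 channels) per window length, which is ample for
noiseless profiles. The quickstart config uses 60 segments per class
and hidden size 32. These sizes are the package's own benchmark
definitions; all complete in seconds to a couple of minutes on a
single CPU core.

## Known limitations

- Single-layer unidirectional LSTM only; no GPU path.
- EDF support: reading is full-featured (via mne); the bundled writer
  is minimal (16-bit, integer sampling rates, 1 s records) and meant
  for fixtures and synthetic exports.
- The synthetic benchmark's train/test split is segment-level, not
  subject- or session-level; it measures pipeline correctness, not
  generalization across recording conditions.
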