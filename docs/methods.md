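# Methods

This note documents the models and procedures the package implements, the
parameters that matter, what the synthetic population does and does not
emulate, and the numerical choices made where the design was open.

## Calibration and timebase

Sound level is defined operationally: `level(x) = 94 + 20·log10(RMS(x)/0.04)`
dB SPL, with no frequency weighting. All timing is locked to the canonical
audio rate of 24,414.0625 samples/s; one spike-count bin is exactly 32 audio
samples (1/762.9395 s ≈ 1.31 ms), so model output frames and count bins never
drift apart. An analysis window [a, b) seconds includes every bin whose span
overlaps it: bins `floor(a·rate)` through `ceil(b·rate)−1`. At the canonical
bin width a 7.9-ms window start therefore excludes exactly the first 6 bins.

## Stimulus generators

Every generator is a pure function of its arguments and a seed. Octave-
stepped grids are `f_lo·2^(k·step)` for k = 0, 1, … while f ≤ f_hi; a printed
endpoint that misses the lattice by a relative gap in (10⁻⁴, 5·10⁻³) is
appended so grids reproduce their stated extremes (e.g. the characteristic-
frequency battery 294 → 16,384 Hz at 0.2 octaves has 31 frequencies). Cosine
ramps are raised-cosine half-windows inside the stated duration. Noise bursts
are fresh Gaussian noise per burst, band-limited where required with
4th-order Butterworth filters.

The high-probability-region (HPR) sequences treat a "12-dB range" as 13
integer-dB levels inclusive; over 21–96 dB SPL with each HPR level drawn 20
times and every other level once this gives 323 bursts of 50 ms = 16.15 s,
concatenated without silence. Burst boundaries are accumulated from nominal
times so the total stays within one sample of 16.15 s.

Moving ripples sum carriers at 0.02-octave spacing with uniform random
phases; the instantaneous amplitude-modulation rate (0–10 Hz) and ripple
density (0–4 cycles/octave) are piecewise-linear random trajectories
resampled every 0.25 s (the distribution within the stated ranges is an open
choice; uniform was assumed), and the modulation depth is 50 dB.

The level offsets that compensate higher thresholds at the edges of the
hearing range interpolate the additive table [15, 0, 0, 0, 20, 20] dB at
anchors 0.5, 1, 2, 4, 8 and 16 kHz on a log-frequency axis (the final anchor
closes the table; values outside are held flat).

Speed changes in processed speech are plain polyphase resampling without
pitch correction; multiband amplification applies log-frequency-interpolated
gains in the frequency domain; speech–noise mixing rescales the noise to the
requested SNR and trims (rather than loops) it to the speech length.

## MUA preprocessing

Raw 20-kHz traces are band-passed 700–5,000 Hz with a zero-phase
(forward–backward) 4th-order Butterworth — zero-phase so that binning incurs
no filter latency. The background-noise SD is the median absolute deviation
divided by 0.6745 (robust to the spikes themselves); positive-going
crossings of 3.5 SD are counted per bin and clipped at 4, with the pre-clip
fraction above 4 reported.

The characteristic frequency (CF) is the frequency with a significant
response at the lowest level: a (frequency, level) cell is significant when
its total count over all repeats exceeds the exact Poisson upper tail at
α = 10⁻⁴ with rate `max(silence rate, 1/8)` per repeat (at μ = 1 the
smallest significant count is 7). The count is summed over repeats; the rate
floor of 1/8 per repeat matches that reading. Ties at the lowest significant
level go to the largest count, then the lowest frequency. Unit inclusion
uses the signal correlation across two repeated broadband-noise trials with
an inclusive threshold (r ≥ 0.2); zero-variance units are excluded.

## Model architecture

The encoder applies (1) a bank of parametric band-pass filters — windowed-
sinc kernels whose low cut-off and bandwidth are the learnable parameters,
initialized mel-spaced over 50 Hz–12 kHz and clamped to (0, Nyquist) after
every optimizer step (the constraint scheme is unstated upstream; clamping
keeps the filters valid without reordering them) — followed by the symmetric
log; (2) five causal strided conv layers with per-channel parametric
rectifiers (slopes initialized at 0.25); (3) a stride-1 bottleneck conv.
Causality is implemented as left zero-padding of kernel−1 samples, and the
left context (2,048 samples = 64 bottleneck bins) is cropped after the
bottleneck so no convolutional edge effects reach the output.

The printed form of the categorical loss multiplies log-probabilities by the
count value, which degenerates for zero counts; the standard one-hot
cross-entropy (the log-probability of the observed count) is used instead.

Time conditioning: the audio-rate module projects τ/36,000 through a 1×1
conv (no bias) and symmetric log and concatenates it with the front-end
output (doubling the channel count into the first encoder layer — the
post-concatenation width is inferred, not stated upstream); the bottleneck
module projects it through a per-branch 1×1 conv with bias and a rectifier
and multiplies the result into the bottleneck. The "complex" variant uses a
cascade of four 128-channel 1×1 layers; because the printed 128-channel
output cannot multiply a 64-channel bottleneck elementwise, a final 1×1
projection to the bottleneck width closes the cascade here. Both
multiplicative modules are initialized near-identity (small weights, unit
bias) and the audio-rate projection with small weights: an auxiliary gating
path that starts neutral trains stably, whereas a randomly initialized gate
injects large constant per-frame biases that stall optimization at desk
scale.

The LNP baseline maps a Mel spectrogram (512-sample windows, 32-sample hop,
96 bands over 50 Hz–12 kHz, log-power offset by 7 so values are positive,
sigmoid squashing) through one causal conv per unit (64 taps, no bias) and
an exponential nonlinearity, fitted by Poisson maximum likelihood with L2
penalty 10⁻⁵ on the kernels. Spectrogram windows are left-aligned with
reflect padding of window−hop samples so the frame count equals
input/hop and frames stay locked to count bins.

## Training protocol

Adam with batch 50 and initial learning rate 4·10⁻⁴ (desk-scale runs use
3·10⁻³, appropriate for the much smaller models); the learning rate is
halved after two consecutive validation epochs without improvement and
training stops after four. Frames are non-overlapping 8,192-sample windows
with 2,048 samples of left context (zero-padded at session start); 10% of
frames form the validation split, drawn by a seeded permutation (sound-level
splitting is available as an option). Sounds enter the model on the
calibration scale (RMS 0.04 at 94 dB SPL) and time in seconds/36,000; both
are asserted at the model boundary.

## Evaluation metrics

RMSE and log-likelihood compare sampled responses and the predicted
distribution against recorded counts, averaged per unit-bin. The
noise-corrected metrics use two successive identical-stimulus trials:
the fraction of explainable correlation explained,
100/2·(ρ(R₁,R̂₁)+ρ(R₂,R̂₂))/ρ(R₁,R₂) on flattened responses, and the
fraction of explainable variance explained, with σ²_noise = ½Var[R₁−R₂] and
the prediction entering through the distribution expectation E_c[R̂].
Sampled responses (fixed seed) enter RMSE, correlation and coherence; the
expectation enters the variance numerator. Per-unit variants compute over
time only; undefined cells (non-positive explainable signal, zero spectral
power, zero-mean Fano bins) are masked and excluded from averages, and a
flattened metric whose denominator is not positive is an error. When only
one trial pairing exists the coherence falls back to it with a warning.
The non-stationarity index is the absolute difference between the mean
sample covariance of flattened counts on successive trial pairs and on
pairs separated by hours. Bottleneck PCA subtracts each channel's mean
response to silence and divides by −500 (matching the scale and sign of MUA)
before the decomposition. Bootstrap CIs resample units with replacement
(1,000 draws by default; the desk-scale evaluation uses 200).

## Synthetic population

The simulator exists to make every module testable, emulating four response
statistics: tonotopy, underdispersion, adaptation and slow drift. Per unit:
CF log-uniform over 300 Hz–12 kHz; tuning width 0.3–0.7 octaves applied as a
super-Gaussian (quartic) weight on the log-frequency axis — plain Gaussian
skirts are too shallow on a dB scale to give realistic frequency
selectivity; threshold 15–45 dB SPL; dynamic range 25–40 dB; maximum rate
2–4 counts/bin; spontaneous rate 0.05 counts/bin.

The band level at CF (in dB SPL, from a short-time spectrum with an
~8-bin lookback) is reduced by 0.3 times its exponentially averaged recent
value (τ = 100 ms) before the sigmoidal rate–intensity function. This
subtractive-in-dB (divisive-in-energy) adaptation shifts rate–intensity
functions toward the prevailing intensity (the HPR phenomenon) and
suppresses probes after a masker, with larger shifts for louder maskers.
An output-divisive gain was tried first and rejected: it only rescales the
rate–intensity curve and cannot shift its midpoint.

Counts are Binomial(4, rate/4): bounded at the clip value 4 and analytically
underdispersed with Fano = 1 − rate/4 (0.75 at one count/bin); mixing with a
clipped Poisson raises the Fano target toward 1. Drift multiplies rates by a
linear, exponential or sinusoidal gain profile over a 12-h session.

What the simulator does not emulate: cochlear mechanics, realistic
spectro-temporal receptive fields, spike timing within bins, across-unit
noise correlations beyond an optional shared slow gain, and single-unit
dynamics (build-up, pauser). Tests passing on it therefore certify the
pipeline's correctness and the statistical claims, not performance on
physiological recordings.

## Desk-scale experiment sizes

The comparative experiments (`iccode.experiments`) use a reduced rate of
4,882.8125 Hz (canonical/5; count bins of 8 samples keep the power-of-two
lock), 20–24 units with CFs 300–2,000 Hz, and a model with 8 sinc filters
(17 taps), three stride-2 layers of 16 filters and a 16-channel bottleneck
(512-sample frames, 128 context). Training sounds are soundscapes of band
noise and multi-carrier complexes at 30–90 dB SPL: 40 s for the
likelihood-head and transfer experiments, and 8 presentations of 12 s spread
across the session for the drift experiment (the time-variant model needs
enough distinct (sound, time) pairs to separate drift from stimulus
variation). These sizes were chosen so each experiment trains in minutes on
one CPU while leaving the qualitative contrasts (categorical vs Poisson,
time-variant vs invariant, transfer) clearly resolved; they are not intended
to reach the accuracy of full-scale models trained on hours of recordings.
Fano factors in the likelihood-head comparison are computed over driven bins
(across-trial mean ≥ 0.5 counts), where the population's underdispersion is
expressed — the conventional tone-driven-window analysis.

The CF-recovery check runs at the same reduced rate with the tone battery
truncated to 294–2,000 Hz; the "within one grid step" criterion is
independent of the band.

## Known limitations

- The numpy training loop is single-threaded and unsuited to full-scale
  (10-h, 512-unit) datasets; the architecture code itself builds the
  full-scale model and runs its forward pass.
- The moving-ripple envelope realizes the stated modulation ranges with an
  assumed uniform distribution; other trajectory statistics are possible.
- `estimate_cf` assumes the tone battery's repeats are summed, per the rate
  floor of 1/8 per repeat.
- Transfer fits a whole new branch (time module + decoder); per-unit warm
  starts are not implemented.
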