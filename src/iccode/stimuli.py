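"""Parametric synthesis and level calibration of auditory stimuli.

All generators are pure functions of their arguments and a seed, producing
bit-identical sample arrays on repeated calls.  Sound level (dB SPL) is defined
operationally through an RMS calibration convention: a waveform with RMS 0.04
is at 94 dB SPL, and level(x) = level_ref + 20*log10(RMS(x)/rms_ref).  No
frequency weighting is applied.

The canonical audio rate is 24,414.0625 Hz; spike-count bins are locked to it
at 32 samples per bin (762.9395 Hz).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal

from .errors import CalibrationError, StimulusError

AUDIO_RATE = 24414.0625
SAMPLES_PER_BIN = 32
BIN_RATE = AUDIO_RATE / SAMPLES_PER_BIN  # 762.9395... Hz


@dataclass(frozen=True)
class CalibrationConvention:
    """RMS-to-dB-SPL mapping. The default ties RMS 0.04 to 94 dB SPL."""

    rms_ref: float = 0.04
    level_ref: float = 94.0

    def __post_init__(self):
        if not self.rms_ref > 0:
            raise CalibrationError("rms_ref must be positive")

    def level_of_rms(self, rms: float) -> float:
        if rms <= 0:
            raise CalibrationError("cannot assign a level to zero RMS")
        return self.level_ref + 20.0 * np.log10(rms / self.rms_ref)

    def rms_of_level(self, level_db_spl: float) -> float:
        return self.rms_ref * 10.0 ** ((level_db_spl - self.level_ref) / 20.0)


DEFAULT_CONVENTION = CalibrationConvention()


@dataclass(frozen=True)
class Annotation:
    """A labelled stimulus event: onset/duration in seconds plus a parameter map."""

    onset: float
    duration: float
    label: str
    params: dict = field(default_factory=dict)


@dataclass
class SoundStimulus:
    """A calibrated sound waveform (pressure-proportional amplitudes)."""

    samples: np.ndarray
    rate: float = AUDIO_RATE
    level_db_spl: float | None = None
    annotations: list[Annotation] = field(default_factory=list)

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1:
            raise StimulusError("samples must be a 1-D array")
        if not self.rate > 0:
            raise StimulusError("rate must be positive")
        if not np.all(np.isfinite(self.samples)):
            raise StimulusError("samples must be finite")

    @property
    def duration(self) -> float:
        return self.samples.size / self.rate

    def rms(self) -> float:
        return float(np.sqrt(np.mean(self.samples**2)))

    def measured_level(self, convention: CalibrationConvention = DEFAULT_CONVENTION) -> float:
        """dB SPL of the waveform as-is, from the calibration convention."""
        return convention.level_of_rms(self.rms())


def calibrate_level(
    waveform: np.ndarray | SoundStimulus,
    target_db_spl: float,
    convention: CalibrationConvention = DEFAULT_CONVENTION,
) -> SoundStimulus:
    """Rescale a waveform so its RMS corresponds to ``target_db_spl``."""
    if isinstance(waveform, SoundStimulus):
        stim = waveform
        samples = stim.samples
    else:
        stim = None
        samples = np.asarray(waveform, dtype=np.float64)
    if not np.isfinite(target_db_spl):
        raise CalibrationError("target level must be finite")
    rms = float(np.sqrt(np.mean(samples**2)))
    if rms == 0.0:
        raise CalibrationError("cannot calibrate an all-zero waveform")
    scaled = samples * (convention.rms_of_level(target_db_spl) / rms)
    if stim is not None:
        return replace(stim, samples=scaled, level_db_spl=target_db_spl)
    return SoundStimulus(scaled, level_db_spl=target_db_spl)


# ---------------------------------------------------------------------------
# grids and envelopes


def octave_grid(f_lo: float, f_hi: float, step_oct: float) -> np.ndarray:
    """Frequencies f_lo * 2**(k*step) for k=0,1,... while f <= f_hi.

    A printed endpoint that misses the lattice by a small relative gap
    (between 1e-4 and 5e-3) is appended, honouring grids whose stated
    extremes are not exact lattice points.
    """
    if not (0 < f_lo < f_hi):
        raise StimulusError("need 0 < f_lo < f_hi")
    if not step_oct > 0:
        raise StimulusError("step must be positive")
    n = int(np.floor(np.log2(f_hi / f_lo) / step_oct + 1e-9)) + 1
    freqs = f_lo * 2.0 ** (step_oct * np.arange(n))
    gap = f_hi / freqs[-1] - 1.0
    if 1e-4 < gap < 5e-3:
        freqs = np.append(freqs, f_hi)
    return freqs


def level_grid(lo: float, hi: float, step: float) -> np.ndarray:
    """Endpoint-inclusive dB grid lo, lo+step, ... <= hi."""
    n = int(np.floor((hi - lo) / step + 1e-9)) + 1
    return lo + step * np.arange(n)


def cosine_ramps(n_samples: int, ramp_s: float, rate: float) -> np.ndarray:
    """Raised-cosine on/off ramps applied on top of the steady-state amplitude.

    Ramp time counts inside the stated duration."""
    n_ramp = int(round(ramp_s * rate))
    if 2 * n_ramp > n_samples:
        raise StimulusError("ramp longer than half the duration")
    env = np.ones(n_samples)
    if n_ramp > 0:
        ramp = 0.5 * (1.0 - np.cos(np.pi * np.arange(n_ramp) / n_ramp))
        env[:n_ramp] = ramp
        env[-n_ramp:] = ramp[::-1]
    return env


def _tone(freq: float, duration: float, ramp: float, rate: float, phase: float = 0.0) -> np.ndarray:
    n = int(round(duration * rate))
    t = np.arange(n) / rate
    return np.sin(2 * np.pi * freq * t + phase) * cosine_ramps(n, ramp, rate)


def intensity_offset_db(freq_hz: float | np.ndarray) -> np.ndarray:
    """Additive level offset used to compensate higher thresholds at band edges.

    Linear interpolation on a log-frequency axis of the additive table
    [15, 0, 0, 0, 20, 20] dB anchored at 0.5, 1, 2, 4, 8 and 16 kHz, with
    flat extrapolation outside.
    """
    anchors = np.log2([500.0, 1000.0, 2000.0, 4000.0, 8000.0, 16000.0])
    offsets = np.array([15.0, 0.0, 0.0, 0.0, 20.0, 20.0])
    return np.interp(np.log2(np.asarray(freq_hz, dtype=float)), anchors, offsets)


# ---------------------------------------------------------------------------
# tone batteries


@dataclass(frozen=True)
class StimulusGrid:
    """A tone battery: frequency x level grid with presentation parameters."""

    frequencies: np.ndarray
    levels: np.ndarray
    duration: float = 0.05
    ramp: float = 0.01
    gap: float = 0.075
    repeats: int = 1
    order_seed: int = 0

    def __post_init__(self):
        f = np.asarray(self.frequencies, dtype=float)
        if f.size == 0 or np.any(np.diff(f) <= 0):
            raise StimulusError("frequencies must be strictly increasing")
        if self.repeats < 1:
            raise StimulusError("repeats must be >= 1")
        object.__setattr__(self, "frequencies", f)
        object.__setattr__(self, "levels", np.asarray(self.levels, dtype=float))


def fra_grid(**kw) -> StimulusGrid:
    """Frequency-response-area battery: 256-16,384 Hz at 1/5 octave, 4-103 dB at 9 dB."""
    return StimulusGrid(octave_grid(256.0, 16384.0, 0.2), level_grid(4.0, 103.0, 9.0), **kw)


def cf_grid(**kw) -> StimulusGrid:
    """Characteristic-frequency battery: 294-16,384 Hz at 0.2 octave, 4-85 dB at 9 dB,
    eight repeats by default."""
    kw.setdefault("repeats", 8)
    return StimulusGrid(octave_grid(294.0, 16384.0, 0.2), level_grid(4.0, 85.0, 9.0), **kw)


def synth_tone_battery(
    grid: StimulusGrid,
    seed: int,
    rate: float = AUDIO_RATE,
    convention: CalibrationConvention = DEFAULT_CONVENTION,
) -> SoundStimulus:
    """Tones at every (frequency, level) of the grid, each presented ``repeats``
    times in seed-randomized order with cosine ramps and inter-tone silence."""
    if 2 * grid.ramp > grid.duration:
        raise StimulusError("ramp exceeds half the tone duration")
    cells = [
        (f, lv) for f in grid.frequencies for lv in grid.levels for _ in range(grid.repeats)
    ]
    rng = np.random.default_rng(seed if seed is not None else grid.order_seed)
    order = rng.permutation(len(cells))
    n_tone = int(round(grid.duration * rate))
    n_gap = int(round(grid.gap * rate))
    out = np.zeros(len(cells) * (n_tone + n_gap))
    annotations = []
    for slot, idx in enumerate(order):
        f, lv = cells[idx]
        tone = _tone(f, grid.duration, grid.ramp, rate)
        tone = tone * (convention.rms_of_level(lv) / np.sqrt(np.mean(tone**2)))
        start = slot * (n_tone + n_gap)
        out[start : start + n_tone] = tone
        annotations.append(
            Annotation(start / rate, grid.duration, "tone", {"frequency": f, "level": lv})
        )
    return SoundStimulus(out, rate=rate, annotations=annotations)


# ---------------------------------------------------------------------------
# moving ripples


def _random_trajectory(rng, lo, hi, duration, rate, knot_s=0.25):
    """Piecewise-linear trajectory with uniform knots every knot_s seconds."""
    n = int(round(duration * rate))
    n_knots = max(int(np.ceil(duration / knot_s)) + 1, 2)
    knots = rng.uniform(lo, hi, n_knots)
    t_knots = np.linspace(0, duration, n_knots)
    return np.interp(np.arange(n) / rate, t_knots, knots)


def synth_moving_ripple(
    f_lo: float,
    f_hi: float,
    carrier_step: float = 0.02,
    am_range: float = 10.0,
    fm_range: float = 4.0,
    depth: float = 50.0,
    duration: float = 1.0,
    seed: int = 0,
    rate: float = AUDIO_RATE,
    level_db_spl: float | None = None,
) -> SoundStimulus:
    """Dynamic moving ripple: a sum of log-spaced sinusoids with random phases
    whose joint spectro-temporal envelope realizes instantaneous amplitude
    modulations in [0, am_range] Hz and frequency modulations in
    [0, fm_range] cycles/octave at the given modulation depth (dB)."""
    if not f_lo < f_hi:
        raise StimulusError("need f_lo < f_hi")
    if f_hi > rate / 2:
        raise StimulusError("carrier band extends above Nyquist")
    rng = np.random.default_rng(seed)
    carriers = octave_grid(f_lo, f_hi, carrier_step)
    phases = rng.uniform(0, 2 * np.pi, carriers.size)
    n = int(round(duration * rate))
    t = np.arange(n) / rate
    out = np.zeros(n)
    if depth == 0:
        for f, ph in zip(carriers, phases):
            out += np.sin(2 * np.pi * f * t + ph)
    else:
        am = _random_trajectory(rng, 0.0, am_range, duration, rate)  # Hz
        fm = _random_trajectory(rng, 0.0, fm_range, duration, rate)  # cyc/oct
        ripple_phase = rng.uniform(0, 2 * np.pi)
        theta = 2 * np.pi * np.cumsum(am) / rate + ripple_phase
        x_oct = np.log2(carriers / f_lo)
        for f, ph, x in zip(carriers, phases, x_oct):
            a_db = 0.5 * depth * (np.sin(theta + 2 * np.pi * fm * x) - 1.0)
            out += 10.0 ** (a_db / 20.0) * np.sin(2 * np.pi * f * t + ph)
    stim = SoundStimulus(
        out,
        rate=rate,
        annotations=[
            Annotation(0.0, duration, "ripple", {"f_lo": f_lo, "f_hi": f_hi, "n_carriers": carriers.size})
        ],
    )
    if level_db_spl is not None:
        stim = calibrate_level(stim, level_db_spl)
    return stim


# ---------------------------------------------------------------------------
# dynamic range adaptation (HPR sequences)


def synth_hpr_sequence(
    level_min: float = 21.0,
    level_max: float = 96.0,
    step: float = 1.0,
    hpr_center: float | None = 39.0,
    hpr_range: float = 12.0,
    hpr_draws: int = 20,
    other_draws: int = 1,
    burst_dur: float = 0.05,
    seed: int = 0,
    rate: float = AUDIO_RATE,
    convention: CalibrationConvention = DEFAULT_CONVENTION,
) -> SoundStimulus:
    """Concatenated broadband noise bursts whose levels over-represent a
    high-probability region (HPR).

    Every grid level inside [hpr_center - hpr_range/2, hpr_center + hpr_range/2]
    appears ``hpr_draws`` times and every other level ``other_draws`` times, in
    seed-randomized order with no inter-burst silence.  ``hpr_center=None``
    gives the uniform baseline (all levels ``other_draws`` times).
    """
    levels = level_grid(level_min, level_max, step)
    if hpr_center is not None:
        lo, hi = hpr_center - hpr_range / 2, hpr_center + hpr_range / 2
        if lo < level_min - 1e-9 or hi > level_max + 1e-9:
            raise StimulusError("HPR extends outside the level range")
        in_hpr = (levels >= lo - 1e-9) & (levels <= hi + 1e-9)
    else:
        in_hpr = np.zeros(levels.size, dtype=bool)
    draws = np.where(in_hpr, hpr_draws, other_draws)
    burst_levels = np.repeat(levels, draws)
    rng = np.random.default_rng(seed)
    burst_levels = burst_levels[rng.permutation(burst_levels.size)]
    # cumulative boundaries keep the total at n_bursts * burst_dur within 1 sample
    edges = np.round(np.arange(burst_levels.size + 1) * burst_dur * rate).astype(int)
    out = np.empty(edges[-1])
    annotations = []
    for i, lv in enumerate(burst_levels):
        noise = rng.standard_normal(edges[i + 1] - edges[i])
        noise *= convention.rms_of_level(lv) / np.sqrt(np.mean(noise**2))
        out[edges[i] : edges[i + 1]] = noise
        annotations.append(Annotation(edges[i] / rate, burst_dur, "burst", {"level": lv}))
    return SoundStimulus(out, rate=rate, annotations=annotations)


# ---------------------------------------------------------------------------
# amplitude-modulated narrowband noise


def _band_noise(rng, center, bandwidth_oct, n, rate):
    lo = center * 2.0 ** (-bandwidth_oct / 2)
    hi = center * 2.0 ** (bandwidth_oct / 2)
    if hi >= rate / 2:
        raise StimulusError("noise band extends above Nyquist")
    sos = signal.butter(4, [lo, hi], btype="bandpass", fs=rate, output="sos")
    return signal.sosfiltfilt(sos, rng.standard_normal(n))


def synth_am_noise(
    center: float,
    bandwidth: float = 1.0,
    mod_freq: float | None = 8.0,
    envelope: str = "sinusoid",
    depth: float = 1.0,
    duration: float = 1.0,
    level: float = 65.0,
    seed: int = 0,
    rate: float = AUDIO_RATE,
    ramp: float = 0.004,
) -> SoundStimulus:
    """One-octave band-limited noise with a sinusoidal or raised-sine-N
    envelope (``envelope='raised-sine-32'`` etc.) at the given modulation depth."""
    if mod_freq is not None and mod_freq >= rate / 2:
        raise StimulusError("modulation frequency at or above Nyquist")
    rng = np.random.default_rng(seed)
    n = int(round(duration * rate))
    noise = _band_noise(rng, center, bandwidth, n, rate)
    if mod_freq is not None and depth > 0:
        t = np.arange(n) / rate
        m = 0.5 * (1.0 - np.cos(2 * np.pi * mod_freq * t))  # in [0, 1], starts at 0
        if envelope.startswith("raised-sine"):
            power = int(envelope.rsplit("-", 1)[1])
            if power < 1:
                raise StimulusError("raised-sine power must be >= 1")
            m = m**power
        elif envelope != "sinusoid":
            raise StimulusError(f"unknown envelope {envelope!r}")
        noise = noise * ((1.0 - depth) + depth * m)
    noise = noise * cosine_ramps(n, ramp, rate)
    stim = SoundStimulus(
        noise,
        rate=rate,
        annotations=[
            Annotation(0.0, duration, "am_noise",
                       {"center": center, "mod_freq": mod_freq, "envelope": envelope, "depth": depth})
        ],
    )
    return calibrate_level(stim, level)


def am_mod_freqs() -> np.ndarray:
    """Modulation frequencies 2-512 Hz at 1-octave spacing (9 values)."""
    return octave_grid(2.0, 512.0, 1.0)


def am_center_freqs() -> np.ndarray:
    """Carrier centre frequencies 500-8,000 Hz at 1/2-octave spacing (9 values)."""
    return octave_grid(500.0, 8000.0, 0.5)


# ---------------------------------------------------------------------------
# forward masking


def masking_probe_freqs() -> np.ndarray:
    """Probe frequencies 500-11,313.71 Hz at 1/2-octave spacing (10 values)."""
    return octave_grid(500.0, 11313.71, 0.5)


def synth_forward_masking(
    probe_freq: float,
    probe_levels,
    masker_level: float | None = None,
    masker_dur: float = 0.2,
    probe_dur: float = 0.02,
    gap: float = 0.01,
    ramp: float = 0.01,
    inter_trial: float = 0.48,
    rate: float = AUDIO_RATE,
    convention: CalibrationConvention = DEFAULT_CONVENTION,
) -> SoundStimulus:
    """Masker-gap-probe trials, one per probe level.

    The masker is a tone at the probe frequency (200 ms, 10-ms ramps) followed
    by a 10-ms silent pause and a 20-ms probe tone.  ``masker_level=None``
    keeps the masker interval silent (unmasked condition, identical timing).
    Probe onsets are annotated for the 7.9-20 ms analysis window.
    """
    if gap < 0:
        raise StimulusError("gap must be non-negative")
    probe_levels = np.atleast_1d(np.asarray(probe_levels, dtype=float))
    n_mask = int(round(masker_dur * rate))
    n_gap = int(round(gap * rate))
    n_probe = int(round(probe_dur * rate))
    n_iti = int(round(inter_trial * rate))
    n_trial = n_mask + n_gap + n_probe + n_iti
    out = np.zeros(probe_levels.size * n_trial)
    annotations = []
    masker = None
    if masker_level is not None:
        masker = _tone(probe_freq, masker_dur, ramp, rate)
        masker *= convention.rms_of_level(masker_level) / np.sqrt(np.mean(masker**2))
    for i, lv in enumerate(probe_levels):
        start = i * n_trial
        if masker is not None:
            out[start : start + n_mask] = masker
            annotations.append(
                Annotation(start / rate, masker_dur, "masker",
                           {"frequency": probe_freq, "level": masker_level})
            )
        probe = _tone(probe_freq, probe_dur, ramp, rate)
        probe *= convention.rms_of_level(lv) / np.sqrt(np.mean(probe**2))
        p0 = start + n_mask + n_gap
        out[p0 : p0 + n_probe] = probe
        annotations.append(
            Annotation(p0 / rate, probe_dur, "probe", {"frequency": probe_freq, "level": lv})
        )
    return SoundStimulus(out, rate=rate, annotations=annotations)


# ---------------------------------------------------------------------------
# context enhancement


def synth_context_enhancement(
    notch_center: float,
    notch_width: float = 1.0,
    conditioner_dur: float = 0.5,
    test_dur: float = 0.1,
    level: float = 60.0,
    with_conditioner: bool = True,
    seed: int = 0,
    ramp: float = 0.01,
    rate: float = AUDIO_RATE,
) -> SoundStimulus:
    """Multitone complex (200 Hz-16 kHz at 1/10 octave, random phases) with a
    spectral notch; the test adds a tone at the notch centre.  When
    ``with_conditioner`` the 500-ms conditioner immediately precedes the
    100-ms test."""
    components = octave_grid(200.0, 16000.0, 0.1)
    if not (components[0] <= notch_center <= components[-1]):
        raise StimulusError("notch centre outside the component band")
    keep = np.abs(np.log2(components / notch_center)) > notch_width / 2
    rng = np.random.default_rng(seed)
    phases = rng.uniform(0, 2 * np.pi, components.size)

    def complex_tone(duration, add_center):
        n = int(round(duration * rate))
        t = np.arange(n) / rate
        x = np.zeros(n)
        for f, ph, k in zip(components, phases, keep):
            if k:
                x += np.sin(2 * np.pi * f * t + ph)
        if add_center:
            x += np.sin(2 * np.pi * notch_center * t)
        return x * cosine_ramps(n, ramp, rate)

    annotations = []
    if with_conditioner:
        cond = complex_tone(conditioner_dur, add_center=False)
        test = complex_tone(test_dur, add_center=True)
        out = np.concatenate([cond, test])
        annotations.append(Annotation(0.0, conditioner_dur, "conditioner",
                                      {"notch_center": notch_center, "notch_width": notch_width}))
        annotations.append(Annotation(conditioner_dur, test_dur, "test",
                                      {"notch_center": notch_center, "notch_width": notch_width}))
    else:
        out = complex_tone(test_dur, add_center=True)
        annotations.append(Annotation(0.0, test_dur, "test",
                                      {"notch_center": notch_center, "notch_width": notch_width}))
    stim = SoundStimulus(out, rate=rate, annotations=annotations)
    return calibrate_level(stim, level)


# ---------------------------------------------------------------------------
# speech processing and mixing


def process_speech(
    x: SoundStimulus,
    speed_factor: int = 1,
    multiband_gains: list[tuple[float, float]] | None = None,
    highpass_hz: float | None = None,
) -> SoundStimulus:
    """Speed change by plain resampling (no pitch correction), linear
    multichannel amplification, and/or high-pass filtering.

    The default amplification table is channels at 0.5, 1, 2, 4 and 8 kHz with
    gains of 3, 10, 17, 22 and 25 dB; gains are interpolated on a
    log-frequency axis and applied in the frequency domain.
    """
    if speed_factor not in (1, 2, 3):
        raise StimulusError("speed_factor must be 1, 2 or 3")
    samples = x.samples
    if speed_factor != 1:
        samples = signal.resample_poly(samples, 1, speed_factor)
    if multiband_gains is not None:
        freqs, gains = map(np.asarray, zip(*multiband_gains))
        spec = np.fft.rfft(samples)
        f = np.fft.rfftfreq(samples.size, d=1.0 / x.rate)
        logf = np.log2(np.maximum(f, 1.0))
        g_db = np.interp(logf, np.log2(freqs), gains)
        samples = np.fft.irfft(spec * 10.0 ** (g_db / 20.0), n=samples.size)
    if highpass_hz is not None:
        sos = signal.butter(4, highpass_hz, btype="highpass", fs=x.rate, output="sos")
        samples = signal.sosfiltfilt(sos, samples)
    return SoundStimulus(samples, rate=x.rate, level_db_spl=None, annotations=list(x.annotations))


HEARING_AID_GAINS = [(500.0, 3.0), (1000.0, 10.0), (2000.0, 17.0), (4000.0, 22.0), (8000.0, 25.0)]


def mix_at_snr(speech: SoundStimulus, noise: SoundStimulus, snr_db: float) -> SoundStimulus:
    """Add noise rescaled so speech-RMS / noise-RMS = 10^(snr/20); the speech
    level is preserved and the noise is trimmed to the speech length."""
    if speech.rate != noise.rate:
        raise StimulusError("speech and noise rates differ")
    if noise.samples.size < speech.samples.size:
        raise StimulusError("noise shorter than speech")
    n = noise.samples[: speech.samples.size]
    n_rms = np.sqrt(np.mean(n**2))
    if n_rms == 0:
        raise StimulusError("silent noise cannot be mixed")
    target_noise_rms = speech.rms() * 10.0 ** (-snr_db / 20.0)
    mixed = speech.samples + n * (target_noise_rms / n_rms)
    return SoundStimulus(mixed, rate=speech.rate, level_db_spl=speech.level_db_spl,
                         annotations=list(speech.annotations))


def silence(duration: float, rate: float = AUDIO_RATE) -> SoundStimulus:
    return SoundStimulus(np.zeros(int(round(duration * rate))), rate=rate)
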