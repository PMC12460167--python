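"""Synthetic inferior-colliculus-like population simulator.

A controllable ground-truth fixture: a tonotopic population (log-spaced CFs)
that converts a calibrated sound waveform into bounded, underdispersed spike
counts with optional slow gain drift, so that stimulus synthesis,
preprocessing, models and metrics are all testable without neural recordings.

The response pipeline per unit is: band energy at CF (Gaussian weighting on a
log-frequency axis, expressed in dB SPL) -> divisive adaptation with
exponential memory, applied subtractively in the dB domain (the effective
input level is reduced by a fraction of the recent average band level, which
shifts rate-intensity functions toward the prevailing intensity and produces
forward masking) -> sigmoidal rate-intensity function (threshold, dynamic
range) -> slow multiplicative gain drift over recording time -> counts drawn
per bin from Binomial(4, rate/4), which is bounded at 4 and analytically
underdispersed (Fano = 1 - rate/4); mixing with a clipped Poisson raises the
Fano factor toward 1 when less underdispersion is wanted.

This is not a biophysical cochlea/IC model; it only reproduces the listed
response statistics (tonotopy, underdispersion, adaptation, drift).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .errors import ShapeError, StimulusError
from .neural_preproc import MUAResponse, RawTrace
from .stimuli import DEFAULT_CONVENTION, SAMPLES_PER_BIN, Annotation, SoundStimulus

MAX_COUNT = 4


@dataclass(frozen=True)
class PopulationConfig:
    """Distributional parameters for drawing a synthetic population."""

    cf_range: tuple[float, float] = (300.0, 12000.0)
    tuning_width_oct: tuple[float, float] = (0.3, 0.7)
    threshold_db: tuple[float, float] = (15.0, 45.0)
    dynamic_range_db: tuple[float, float] = (25.0, 40.0)
    max_rate: tuple[float, float] = (2.0, 4.0)  # counts/bin at saturation
    spont_rate: float = 0.05  # counts/bin in silence
    adapt_tau_s: float = 0.1
    adapt_strength: float = 0.3
    poisson_mix: float = 0.0  # 0 = pure binomial (most underdispersed)
    drift_kind: str = "none"  # none | linear | exponential | sinusoidal
    drift_magnitude: float = 0.0  # fractional gain loss at session end
    session_s: float = 12 * 3600.0
    shared_noise_weight: float = 0.0


@dataclass
class SyntheticPopulation:
    """Ground-truth unit parameters (arrays of length M, CFs sorted)."""

    cf: np.ndarray
    tuning_width: np.ndarray
    threshold: np.ndarray
    dynamic_range: np.ndarray
    max_rate: np.ndarray
    config: PopulationConfig = field(default_factory=PopulationConfig)

    def __post_init__(self):
        if np.any(np.diff(self.cf) < 0):
            raise ShapeError("CFs must be sorted")
        if np.any(self.max_rate > MAX_COUNT):
            raise ShapeError("max rate cannot exceed the count bound")

    @property
    def n_units(self) -> int:
        return self.cf.size

    def drift_gain(self, rec_time_s) -> np.ndarray:
        """Multiplicative gain vs recording time (1 at session start)."""
        t = np.asarray(rec_time_s, dtype=float)
        c = self.config
        frac = np.clip(t / c.session_s, 0.0, 1.0)
        if c.drift_kind == "none" or c.drift_magnitude == 0.0:
            return np.ones_like(t)
        if c.drift_kind == "linear":
            return 1.0 - c.drift_magnitude * frac
        if c.drift_kind == "exponential":
            return (1.0 - c.drift_magnitude) ** frac
        if c.drift_kind == "sinusoidal":
            return 1.0 - 0.5 * c.drift_magnitude * (1.0 - np.cos(2 * np.pi * frac))
        raise ShapeError(f"unknown drift kind {c.drift_kind!r}")


def make_population(m: int, seed: int = 0, config: PopulationConfig | None = None) -> SyntheticPopulation:
    """Draw a reproducible population of ``m`` units with CFs uniform on a log
    scale over the configured range (sorted low to high)."""
    if m < 1:
        raise ShapeError("need at least one unit")
    config = config or PopulationConfig()
    rng = np.random.default_rng(seed)
    lo, hi = config.cf_range
    cf = np.sort(np.exp(rng.uniform(np.log(lo), np.log(hi), m)))
    u = lambda pair: rng.uniform(pair[0], pair[1], m)  # noqa: E731
    return SyntheticPopulation(
        cf=cf,
        tuning_width=u(config.tuning_width_oct),
        threshold=u(config.threshold_db),
        dynamic_range=u(config.dynamic_range_db),
        max_rate=u(config.max_rate),
        config=config,
    )


def _band_levels(stimulus: SoundStimulus, pop: SyntheticPopulation,
                 samples_per_bin: int, window: int | None) -> np.ndarray:
    """dB SPL of the energy around each unit's CF per count bin, (M, T)."""
    x = stimulus.samples
    rate = stimulus.rate
    hop = samples_per_bin
    if window is None:
        window = 8 * hop  # ~10 ms lookback: short enough for masking probes
    window = min(window, max(hop, 2 ** int(np.floor(np.log2(max(x.size, hop))))))
    t_bins = x.size // hop
    if t_bins == 0:
        raise StimulusError("stimulus shorter than one bin")
    pad = window - hop
    padded = np.concatenate([np.zeros(pad), x])
    frames = np.lib.stride_tricks.sliding_window_view(padded, window)[::hop][:t_bins]
    win = np.hanning(window)
    spec = np.abs(np.fft.rfft(frames * win, axis=1)) ** 2
    # scale so that summing over frequencies returns the frame mean square
    cf_scale = np.full(spec.shape[1], 2.0)
    cf_scale[0] = 1.0
    if window % 2 == 0:
        cf_scale[-1] = 1.0
    s = spec * cf_scale[None, :] / (window * np.sum(win**2))
    freqs = np.fft.rfftfreq(window, d=1.0 / rate)
    with np.errstate(divide="ignore"):
        logf = np.log2(np.maximum(freqs, 1e-6))
    # super-Gaussian on the log-frequency axis: near-flat passband of width
    # ~tuning_width octaves with steep skirts (Gaussian skirts are too shallow
    # on a dB scale to give realistic frequency selectivity)
    d = (logf[None, :] - np.log2(pop.cf)[:, None]) / pop.tuning_width[:, None]
    w = np.exp(-0.5 * d**4)
    w[:, 0] = 0.0
    band_ms = s @ w.T  # (T, M)
    ref = DEFAULT_CONVENTION.rms_ref**2
    with np.errstate(divide="ignore"):
        level = DEFAULT_CONVENTION.level_ref + 10.0 * np.log10(
            np.maximum(band_ms / ref, 1e-12)
        )
    return level.T  # (M, T)


def simulate_rates(
    pop: SyntheticPopulation,
    stimulus: SoundStimulus,
    rec_time_s: float | np.ndarray = 0.0,
    samples_per_bin: int = SAMPLES_PER_BIN,
    window: int | None = None,
) -> np.ndarray:
    """Deterministic per-unit per-bin firing rate (counts/bin) before count
    sampling: band level -> dB-domain adaptation -> sigmoid -> drift gain."""
    if stimulus.level_db_spl is None and not stimulus.annotations and stimulus.rms() > 0:
        raise StimulusError("stimulus must be calibrated (level or annotations set)")
    c = pop.config
    level = np.maximum(_band_levels(stimulus, pop, samples_per_bin, window), 0.0)
    bin_rate = stimulus.rate / samples_per_bin
    k = np.exp(-1.0 / (c.adapt_tau_s * bin_rate))
    # exponential average of the recent band level; subtracting a fraction of
    # it (divisive in energy) shifts the dynamic range toward the prevailing
    # intensity and suppresses probes after a masker
    mem = signal.lfilter([1.0 - k], [1.0, -k], level, axis=1)
    effective = level - c.adapt_strength * mem
    mid = (pop.threshold + pop.dynamic_range / 2.0)[:, None]
    slope = (pop.dynamic_range / 4.4)[:, None]
    adapted = pop.max_rate[:, None] / (1.0 + np.exp(-(effective - mid) / slope))
    t_bins = adapted.shape[1]
    t_rec = np.asarray(rec_time_s, dtype=float)
    if t_rec.ndim == 0:
        t_rec = t_rec + np.arange(t_bins) / bin_rate
    gain = pop.drift_gain(t_rec)[None, :]
    rate = (c.spont_rate + adapted) * gain
    return np.clip(rate, 0.0, MAX_COUNT)


def sample_counts(rates: np.ndarray, rng, poisson_mix: float = 0.0) -> np.ndarray:
    """Counts from Binomial(4, rate/4), optionally mixed with clipped Poisson."""
    binom = rng.binomial(MAX_COUNT, np.clip(rates, 0, MAX_COUNT) / MAX_COUNT)
    if poisson_mix > 0:
        pois = np.minimum(rng.poisson(rates), MAX_COUNT)
        pick = rng.random(rates.shape) < poisson_mix
        binom = np.where(pick, pois, binom)
    return binom.astype(np.uint8)


def simulate_counts(
    pop: SyntheticPopulation,
    stimulus: SoundStimulus,
    rec_time_s: float | np.ndarray = 0.0,
    trials: int = 1,
    seed: int = 0,
    samples_per_bin: int = SAMPLES_PER_BIN,
    window: int | None = None,
) -> np.ndarray:
    """Simulated MUA counts, (trials, M, T).  Reproducible from the seed."""
    rates = simulate_rates(pop, stimulus, rec_time_s, samples_per_bin, window)
    rng = np.random.default_rng(seed)
    c = pop.config
    out = np.empty((trials,) + rates.shape, dtype=np.uint8)
    for i in range(trials):
        r = rates
        if c.shared_noise_weight > 0:
            eta = rng.standard_normal(rates.shape[1])
            bin_rate = stimulus.rate / samples_per_bin
            k = np.exp(-1.0 / (0.05 * bin_rate))
            eta = signal.lfilter([1 - k], [1, -k], eta)
            r = np.clip(rates * np.exp(c.shared_noise_weight * eta)[None, :], 0, MAX_COUNT)
        out[i] = sample_counts(r, rng, c.poisson_mix)
    return out


def counts_to_response(counts: np.ndarray, bin_rate: float, pop: SyntheticPopulation | None = None,
                       start_time_s: float = 0.0) -> MUAResponse:
    """Wrap a (M, T) count array as an MUAResponse with unit metadata."""
    meta = {}
    if pop is not None:
        meta = {"cf_hz": pop.cf.copy()}
    return MUAResponse(counts, bin_rate=bin_rate, unit_meta=meta, start_time_s=start_time_s)


def training_soundscape(
    duration_s: float,
    rate: float,
    seed: int = 0,
    f_lo: float = 300.0,
    f_hi: float | None = None,
    level_range: tuple[float, float] = (30.0, 90.0),
    segment_s: float = 0.2,
) -> SoundStimulus:
    """A reproducible broadband soundscape for desk-scale model training.

    Alternating segments of band-limited noise and ripple-like multi-carrier
    complexes at random levels, covering the population's dynamic range and
    spectrum so every unit is driven.  Segments have 5-ms cosine gates to
    avoid clicks.
    """
    from .stimuli import calibrate_level, cosine_ramps

    rng = np.random.default_rng(seed)
    f_hi = f_hi or 0.45 * rate
    n_seg = max(int(np.ceil(duration_s / segment_s)), 1)
    n_samp = int(round(segment_s * rate))
    carriers = f_lo * 2.0 ** np.linspace(0, np.log2(f_hi / f_lo), 24)
    t = np.arange(n_samp) / rate
    out = np.empty(n_seg * n_samp)
    for i in range(n_seg):
        lv = rng.uniform(*level_range)
        if rng.random() < 0.5:
            seg = rng.standard_normal(n_samp)
        else:
            sel = rng.random(carriers.size) < 0.4
            sel[rng.integers(carriers.size)] = True
            seg = np.zeros(n_samp)
            for f in carriers[sel]:
                seg += np.sin(2 * np.pi * f * t + rng.uniform(0, 2 * np.pi))
            am = rng.uniform(2.0, 12.0)
            seg *= 0.5 * (1.0 + np.sin(2 * np.pi * am * t + rng.uniform(0, 2 * np.pi)))
        seg = seg * cosine_ramps(n_samp, 0.005, rate)
        seg = calibrate_level(seg, lv).samples
        out[i * n_samp : (i + 1) * n_samp] = seg
    out = out[: int(round(duration_s * rate))]
    return SoundStimulus(out, rate=rate,
                         annotations=[Annotation(0.0, duration_s, "soundscape", {"seed": seed})])


def spike_waveform(rate: float = 20000.0, dur_s: float = 0.0012) -> np.ndarray:
    """Biphasic extracellular spike template (unit positive peak)."""
    n = int(round(dur_s * rate))
    t = np.arange(n) / rate - dur_s / 3
    sigma = dur_s / 8
    w = -np.exp(-0.5 * (t / sigma) ** 2) * (t / sigma)
    return w / w.max()


def simulate_raw_trace(
    counts: np.ndarray,
    seed: int = 0,
    rate: float = 20000.0,
    bin_rate: float = 762.9395,
    noise_sd: float = 1.0,
    spike_amp: float = 10.0,
) -> RawTrace:
    """A 20-kHz extracellular trace realizing the given ground-truth counts.

    ``counts`` is (units, bins) with at most 10 units per channel; all units
    are summed onto one channel of Gaussian background noise with biphasic
    spike waveforms at count-derived event times.
    """
    counts = np.atleast_2d(np.asarray(counts))
    if counts.shape[0] > 10:
        raise ShapeError("at most 10 units per channel")
    rng = np.random.default_rng(seed)
    n_bins = counts.shape[1]
    n_samp = int(np.ceil(n_bins / bin_rate * rate))
    wave = spike_waveform(rate)
    trace = rng.standard_normal(n_samp) * noise_sd
    samples_per_bin = rate / bin_rate
    total = counts.sum(axis=0)
    for b in np.nonzero(total)[0]:
        for _ in range(int(total[b])):
            s0 = int(b * samples_per_bin) + int(rng.integers(0, max(int(samples_per_bin) - wave.size, 1)))
            seg = trace[s0 : s0 + wave.size]
            seg += spike_amp * noise_sd * wave[: seg.size]
    return RawTrace(trace[None, :], rate=rate)
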