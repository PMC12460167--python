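"""Multi-unit activity (MUA) extraction, characteristic-frequency estimation
and unit quality control.

MUA is defined as threshold-crossing counts on each recording channel: the raw
trace is band-pass filtered (700-5,000 Hz), the background-noise SD is
estimated robustly as MAD/0.6745, and positive-going crossings of 3.5 SD are
counted in bins of exactly 32/24,414.0625 s (~1.31 ms), clipped at 4.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal, stats

from .errors import PreprocError, ShapeError
from .stimuli import BIN_RATE

RAW_RATE = 20000.0
BIN_WIDTH_S = 1.0 / BIN_RATE  # 32 audio samples; keeps count bins sample-locked


@dataclass
class RawTrace:
    """Raw extracellular voltage traces, channels x samples at 20 kHz."""

    samples: np.ndarray
    rate: float = RAW_RATE
    channel_ids: np.ndarray | None = None

    def __post_init__(self):
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=np.float64))
        if not np.all(np.isfinite(self.samples)):
            raise PreprocError("raw trace contains non-finite samples")
        if self.channel_ids is None:
            self.channel_ids = np.arange(self.samples.shape[0])


@dataclass
class MUAResponse:
    """Integer spike counts per unit per bin (0-4 after clipping)."""

    counts: np.ndarray
    bin_rate: float = BIN_RATE
    unit_meta: dict = field(default_factory=dict)
    start_time_s: float = 0.0
    clipped_fraction: float = 0.0

    def __post_init__(self):
        self.counts = np.atleast_2d(np.asarray(self.counts))
        if self.counts.ndim != 2:
            raise ShapeError("counts must be units x bins")
        if self.counts.shape[0] < 1:
            raise ShapeError("need at least one unit")

    @property
    def n_units(self) -> int:
        return self.counts.shape[0]

    @property
    def n_bins(self) -> int:
        return self.counts.shape[1]

    def window_bins(self, a_s: float, b_s: float) -> slice:
        """Bins whose span overlaps the window [a, b) seconds:
        floor(a*rate) .. ceil(b*rate)-1 (a 7.9-ms start excludes exactly the
        first 6 bins at the canonical bin width)."""
        return slice(int(np.floor(a_s * self.bin_rate + 1e-9)),
                     int(np.ceil(b_s * self.bin_rate - 1e-9)))


@dataclass(frozen=True)
class UnitQC:
    """Inclusion decision from across-trial signal correlation."""

    signal_correlation: float
    include: bool


def bandpass_filter(trace: np.ndarray, band=(700.0, 5000.0), rate: float = RAW_RATE) -> np.ndarray:
    """Zero-phase (forward-backward) 4th-order Butterworth band-pass."""
    sos = signal.butter(4, band, btype="bandpass", fs=rate, output="sos")
    return signal.sosfiltfilt(sos, trace, axis=-1)


def count_threshold_crossings(filtered: np.ndarray, threshold: float) -> np.ndarray:
    """Sample indices where the signal makes a positive-going crossing of
    ``threshold`` (previous sample below, current at or above)."""
    above = filtered >= threshold
    return np.nonzero(~above[:-1] & above[1:])[0] + 1


def extract_mua(
    trace: RawTrace,
    band=(700.0, 5000.0),
    thresh_sd: float = 3.5,
    bin_s: float = BIN_WIDTH_S,
    clip: int = 4,
) -> MUAResponse:
    """Convert raw traces to binned MUA counts.

    The noise SD of the band-passed signal is estimated as MAD/0.6745 per
    channel (robust to spikes); crossings of ``thresh_sd`` SDs are counted per
    bin and clipped at ``clip``. The pre-clip fraction of counts above the
    clip value is reported on the result.
    """
    filt = bandpass_filter(trace.samples, band, trace.rate)
    n_bins = int(np.floor(filt.shape[1] / (bin_s * trace.rate)))
    if n_bins < 1:
        raise PreprocError("trace shorter than one bin")
    counts = np.zeros((filt.shape[0], n_bins), dtype=np.int64)
    for ch in range(filt.shape[0]):
        sd = np.median(np.abs(filt[ch] - np.median(filt[ch]))) / 0.6745
        if sd == 0:
            if np.ptp(filt[ch]) == 0:
                # constant trace: no crossings by definition
                continue
            raise PreprocError("zero noise-SD estimate on a non-constant trace")
        idx = count_threshold_crossings(filt[ch], thresh_sd * sd)
        bins = np.floor(idx / (bin_s * trace.rate)).astype(np.int64)
        bins = bins[bins < n_bins]
        np.add.at(counts[ch], bins, 1)
    pre_clip = float(np.mean(counts > clip))
    return MUAResponse(np.minimum(counts, clip).astype(np.uint8), bin_rate=1.0 / bin_s,
                       clipped_fraction=pre_clip)


def poisson_significance_threshold(mu: float, alpha: float = 1e-4) -> int:
    """Smallest count k with P(X >= k) < alpha under Poisson(mu) (exact tail)."""
    k = int(stats.poisson.ppf(1 - alpha, mu))
    while stats.poisson.sf(k - 1, mu) >= alpha:
        k += 1
    return k


def estimate_cf(
    tone_counts: np.ndarray,
    frequencies: np.ndarray,
    levels: np.ndarray,
    silence_rate: float,
    n_repeats: int = 8,
    alpha: float = 1e-4,
) -> float | None:
    """Characteristic frequency from a tone battery.

    ``tone_counts[i, j]`` is the total MUA count elicited by frequency i at
    level j, summed over repeats and the tone window.  A cell is significant
    when its count exceeds the exact Poisson upper tail at ``alpha`` with rate
    max(silence_rate, 1/8) scaled by the number of repeats (``silence_rate``
    is counts per single tone-duration window of silence).  The CF is the
    frequency of the significant cell at the lowest level; ties go to the
    largest count, then the lowest frequency.  Returns None when no cell is
    significant.
    """
    tone_counts = np.asarray(tone_counts)
    frequencies = np.asarray(frequencies, dtype=float)
    levels = np.asarray(levels, dtype=float)
    if tone_counts.shape != (frequencies.size, levels.size):
        raise ShapeError("tone_counts must be (n_frequencies, n_levels)")
    mu = max(silence_rate, 1.0 / 8.0) * n_repeats
    k_min = poisson_significance_threshold(mu, alpha)
    significant = tone_counts >= k_min
    order = np.argsort(levels)
    for j in order:
        col = significant[:, j]
        if col.any():
            cand = np.nonzero(col)[0]
            best = cand[np.argmax(tone_counts[cand, j])]
            ties = cand[tone_counts[cand, j] == tone_counts[best, j]]
            return float(frequencies[ties.min()])
    return None


def qc_units(trial1: MUAResponse, trial2: MUAResponse, threshold: float = 0.2) -> list[UnitQC]:
    """Signal correlation across two repeated broadband-noise trials per unit;
    units with correlation >= threshold (inclusive) are kept.  Zero-variance
    units have undefined correlation and are excluded."""
    if trial1.counts.shape != trial2.counts.shape:
        raise ShapeError("trials must have identical shape")
    out = []
    for r1, r2 in zip(np.asarray(trial1.counts, float), np.asarray(trial2.counts, float)):
        if r1.std() == 0 or r2.std() == 0:
            out.append(UnitQC(float("nan"), False))
            continue
        r = float(np.corrcoef(r1, r2)[0, 1])
        out.append(UnitQC(r, r >= threshold))
    return out
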