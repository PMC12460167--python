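"""Evaluation metrics for simulated vs recorded neural activity.

Implements the overall performance metrics (RMSE, log-likelihood), the
noise-corrected predictive-power metrics (fraction of explainable correlation
and variance explained, which use successive identical-stimulus trials to
estimate the trial-to-trial noise), coherence spectra, Fano factors,
modulation-transfer synchrony, tuning summaries, a non-stationarity index,
bottleneck PCA and bootstrap confidence intervals.

Conventions: responses are (units M, bins T) count arrays.  "Flattened"
metrics collapse units and time into one vector; per-unit variants compute
over time only.  Sampled predictions enter RMSE, correlation and coherence;
distribution expectations E_c enter the variance-explained numerator.
A time window [a, b) seconds maps to the bins whose span overlaps it:
floor(a*rate) .. ceil(b*rate)-1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal

from .errors import MetricError, ShapeError
from .model_core import CountDistribution
from .neural_preproc import MUAResponse
from .stimuli import BIN_RATE


def window_to_bins(a_s: float, b_s: float, bin_rate: float = BIN_RATE) -> slice:
    """Bins whose span overlaps [a, b) seconds:
    floor(a*rate) .. ceil(b*rate)-1 (used for every analysis window)."""
    return slice(int(np.floor(a_s * bin_rate + 1e-9)), int(np.ceil(b_s * bin_rate - 1e-9)))


@dataclass
class TrialPair:
    """Recorded responses on two successive identical-stimulus trials, with
    optional sampled predictions and their count distributions."""

    r1: np.ndarray
    r2: np.ndarray
    rhat1: np.ndarray | None = None
    rhat2: np.ndarray | None = None
    dist1: CountDistribution | None = None
    dist2: CountDistribution | None = None

    def __post_init__(self):
        self.r1 = np.atleast_2d(np.asarray(self.r1, dtype=float))
        self.r2 = np.atleast_2d(np.asarray(self.r2, dtype=float))
        if self.r1.shape != self.r2.shape:
            raise ShapeError("trial responses must have identical shape")
        for name in ("rhat1", "rhat2"):
            v = getattr(self, name)
            if v is not None:
                v = np.atleast_2d(np.asarray(v, dtype=float))
                if v.shape != self.r1.shape:
                    raise ShapeError(f"{name} shape differs from recordings")
                setattr(self, name, v)


@dataclass(frozen=True)
class MetricReport:
    """A metric value with its bootstrap median and 95% CI across units."""

    value: float
    median: float
    ci_low: float
    ci_high: float
    axis: str = "flattened"


# ---------------------------------------------------------------------------
# overall performance


def rmse_metric(r: np.ndarray, rhat: np.ndarray) -> float:
    """Root-mean-square error over all units and bins."""
    r = np.asarray(r, dtype=float)
    rhat = np.asarray(rhat, dtype=float)
    if r.shape != rhat.shape:
        raise ShapeError("shapes differ")
    if r.size == 0:
        raise MetricError("empty input")
    return float(np.sqrt(np.mean((r - rhat) ** 2)))


def loglik_metric(dist: CountDistribution, r: np.ndarray) -> float:
    """Mean log-probability mass of the observed counts under the predicted
    distribution (Poisson pmf for the Poisson head)."""
    lp = dist.log_pmf(np.asarray(r))
    if np.any(np.isneginf(lp)):
        warnings.warn("zero probability mass at an observed count")
    return float(np.mean(lp))


# ---------------------------------------------------------------------------
# noise-corrected predictive power


def _corr(a, b):
    a = a - a.mean()
    b = b - b.mean()
    den = np.sqrt((a * a).sum() * (b * b).sum())
    if den == 0:
        return np.nan
    return float((a * b).sum() / den)


def correlation_explained(pair: TrialPair, per_unit: bool = False):
    """Fraction of the explainable correlation explained (%):
    100/2 * (rho(R1,Rhat1) + rho(R2,Rhat2)) / rho(R1,R2).

    Flattened over units and bins by default; ``per_unit`` computes over time
    only and returns one value per unit (NaN where the trial-to-trial
    correlation is not positive).  Values above 100% are possible when the
    predictions out-correlate the two recordings.
    """
    if pair.rhat1 is None or pair.rhat2 is None:
        raise MetricError("correlation_explained needs sampled predictions")
    if per_unit:
        out = np.empty(pair.r1.shape[0])
        for m in range(out.size):
            denom = _corr(pair.r1[m], pair.r2[m])
            if not denom > 0:
                out[m] = np.nan
                continue
            num = _corr(pair.r1[m], pair.rhat1[m]) + _corr(pair.r2[m], pair.rhat2[m])
            out[m] = 50.0 * num / denom
        return out
    denom = _corr(pair.r1.ravel(), pair.r2.ravel())
    if not denom > 0:
        raise MetricError("trial-to-trial correlation is not positive")
    num = _corr(pair.r1.ravel(), pair.rhat1.ravel()) + _corr(pair.r2.ravel(), pair.rhat2.ravel())
    return 50.0 * num / denom


def variance_explained(pair: TrialPair, per_unit: bool = False):
    """Fraction of the explainable variance explained (%), noise-corrected by
    the across-trial difference: sigma2_noise = Var[R1 - R2]/2.

    The prediction enters through the distribution expectations E_c; the
    error terms are averaged over units and bins while the variances are
    computed on flattened responses (or over time only in per-unit mode).
    """
    if pair.dist1 is None or pair.dist2 is None:
        raise MetricError("variance_explained needs predicted distributions")
    e1 = pair.dist1.expected()
    e2 = pair.dist2.expected()
    if e1.shape != pair.r1.shape or e2.shape != pair.r2.shape:
        raise ShapeError("expectation shape differs from recordings")

    def _ve(r1, r2, m1, m2):
        noise = 0.5 * np.var(r1 - r2)
        err = 0.5 * np.mean((r1 - m1) ** 2) + 0.5 * np.mean((r2 - m2) ** 2)
        denom = 0.5 * (np.var(r1) + np.var(r2)) - noise
        if not denom > 0:
            return np.nan
        return 100.0 * (1.0 - (err - noise) / denom)

    if per_unit:
        return np.array(
            [_ve(pair.r1[m], pair.r2[m], e1[m], e2[m]) for m in range(pair.r1.shape[0])]
        )
    v = _ve(pair.r1.ravel(), pair.r2.ravel(), e1.ravel(), e2.ravel())
    if np.isnan(v):
        raise MetricError("explainable variance is not positive")
    return v


def coherence_metric(
    a: np.ndarray, b: np.ndarray, n_bins: int = 763
) -> tuple[np.ndarray, np.ndarray]:
    """Unit-averaged magnitude-squared coherence between two response arrays.

    Spectral densities are computed over time per unit with Hann windows and
    ``n_bins`` one-sided frequency bins (Welch averaging); bins with zero
    power in either signal are masked (NaN) before unit averaging.  Returns
    (normalized frequencies in cycles/bin, coherence spectrum).
    """
    a = np.atleast_2d(np.asarray(a, dtype=float))
    b = np.atleast_2d(np.asarray(b, dtype=float))
    if a.shape != b.shape:
        raise ShapeError("shapes differ")
    t = a.shape[1]
    nperseg = min(2 * (n_bins - 1), t)
    f, pab = signal.csd(a, b, window="hann", nperseg=nperseg, axis=1)
    _, paa = signal.welch(a, window="hann", nperseg=nperseg, axis=1)
    _, pbb = signal.welch(b, window="hann", nperseg=nperseg, axis=1)
    den = paa * pbb
    with np.errstate(divide="ignore", invalid="ignore"):
        coh = np.where(den > 0, np.abs(pab) ** 2 / den, np.nan)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return f, np.nanmean(coh, axis=0)


def prediction_coherence(pair: TrialPair, n_bins: int = 763):
    """Coherence between predicted and recorded activity, averaged over the
    two trial pairings (flagged single-pair behaviour applies when only one
    prediction exists)."""
    if pair.rhat1 is None:
        raise MetricError("prediction coherence needs sampled predictions")
    f, c1 = coherence_metric(pair.rhat1, pair.r1, n_bins)
    if pair.rhat2 is None:
        warnings.warn("single trial pairing only; coherence not averaged")
        return f, c1
    _, c2 = coherence_metric(pair.rhat2, pair.r2, n_bins)
    return f, 0.5 * (c1 + c2)


# ---------------------------------------------------------------------------
# response statistics


def fano_factor(trials: np.ndarray, window: slice | None = None,
                min_mean: float = 0.0) -> np.ndarray:
    """Across-trial variance/mean ratio per unit, averaged over window bins.

    ``trials`` is (n_trials, units, bins); bins with zero mean are masked.
    ``min_mean`` additionally masks weakly driven bins (the conventional
    Fano analysis uses bins within the stimulus-driven response).
    """
    trials = np.asarray(trials, dtype=float)
    if trials.ndim != 3 or trials.shape[0] < 2:
        raise ShapeError("need (n_trials, units, bins) with >= 2 trials")
    if window is not None:
        trials = trials[:, :, window]
    mean = trials.mean(axis=0)
    var = trials.var(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(mean > max(min_mean, 0.0), var / mean, np.nan)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return np.nanmean(ratio, axis=1)


def synchrony_mtf(
    trials: np.ndarray,
    mod_freq: float,
    bin_rate: float = BIN_RATE,
    window: slice | None = None,
) -> np.ndarray:
    """Envelope-locking synchrony per unit: the ratio of the modulation
    frequency component to the DC component of the magnitude-squared spectrum
    of the trial-averaged response."""
    trials = np.asarray(trials, dtype=float)
    if trials.ndim != 3:
        raise ShapeError("need (n_trials, units, bins)")
    mean_resp = trials.mean(axis=0)
    if window is not None:
        mean_resp = mean_resp[:, window]
    spec = np.abs(np.fft.rfft(mean_resp, axis=1)) ** 2
    freqs = np.fft.rfftfreq(mean_resp.shape[1], d=1.0 / bin_rate)
    idx = int(np.argmin(np.abs(freqs - mod_freq)))
    dc = spec[:, 0]
    out = np.full(dc.shape, np.nan)
    np.divide(spec[:, idx], dc, out=out, where=dc > 0)
    return out


def windowed_unit_means(
    resp: MUAResponse, annotations, window: tuple[float, float], label: str | None = None
) -> tuple[pd.DataFrame, np.ndarray]:
    """Mean count per unit in a window relative to each annotated event.

    Returns (events table, (n_events, n_units) array).  The window is in
    seconds relative to event onset, mapped to bins with the ceil rule.
    """
    rows, mats = [], []
    for ann in annotations:
        if label is not None and ann.label != label:
            continue
        sl = resp.window_bins(ann.onset + window[0], ann.onset + window[1])
        if sl.stop > resp.n_bins:
            raise MetricError("event window extends beyond the recording")
        rows.append({"onset": ann.onset, "label": ann.label, **ann.params})
        mats.append(np.asarray(resp.counts[:, sl], dtype=float).mean(axis=1))
    if not rows:
        raise MetricError("no matching annotated events")
    return pd.DataFrame(rows), np.array(mats)


def tuning_summary(
    resp: MUAResponse,
    annotations,
    window: tuple[float, float] = (0.0079, 0.05),
    label: str | None = None,
    by: list[str] | None = None,
) -> pd.DataFrame:
    """Windowed mean activity per stimulus condition (averaged over units and,
    when ``by`` is given, over repeats of the same parameter combination).

    Default window 7.9-50 ms after onset (frequency-response areas and
    rate-intensity functions); use (0.0079, 0.02) for masked probes and
    (0.0079, 0.1) for context-enhancement tests.
    """
    table, mat = windowed_unit_means(resp, annotations, window, label)
    table = table.assign(mean_count=mat.mean(axis=1))
    if by:
        table = table.groupby(by, as_index=False)["mean_count"].mean()
    return table


def nonstationarity_index(successive_pairs, separated_pairs) -> float:
    """|mean covariance over successive trial pairs - mean covariance over
    separated trial pairs|, covariances of flattened count vectors."""

    def _cov(pair):
        a, b = (np.asarray(x, dtype=float).ravel() for x in pair)
        if a.shape != b.shape:
            raise ShapeError("pair members must match in shape")
        return float(np.cov(a, b)[0, 1])

    succ = np.mean([_cov(p) for p in successive_pairs])
    sep = np.mean([_cov(p) for p in separated_pairs])
    return float(abs(succ - sep))


def bottleneck_pca(
    rb: np.ndarray, silence_rb: np.ndarray, scale: float = -500.0, n_components: int | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """PCA of the normalized bottleneck response for one sound.

    Channels are normalized by subtracting each channel's average response to
    silence and dividing by ``scale`` (-500 matches the MUA scale and sign).
    Returns (component time courses (n_comp, T), variance fractions).
    """
    rb = np.asarray(rb, dtype=float)
    silence_rb = np.atleast_2d(np.asarray(silence_rb, dtype=float))
    if rb.ndim != 2:
        raise ShapeError("bottleneck must be (channels, bins)")
    if rb.shape[1] < rb.shape[0]:
        raise MetricError("fewer bins than channels")
    norm = (rb - silence_rb.mean(axis=1, keepdims=True)) / scale
    centered = norm - norm.mean(axis=1, keepdims=True)
    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    var = s**2
    frac = var / var.sum() if var.sum() > 0 else np.zeros_like(var)
    comps = u.T @ centered  # projections onto principal axes, (n_comp, T)
    if n_components is not None:
        comps, frac = comps[:n_components], frac[:n_components]
    return comps, frac


# ---------------------------------------------------------------------------
# bootstrap


def bootstrap_report(
    per_unit_values: np.ndarray,
    statistic=np.nanmedian,
    n_boot: int = 1000,
    seed: int = 0,
    axis: str = "per-unit",
) -> MetricReport:
    """Bootstrap (resampling units with replacement) median and 95% CI of a
    statistic of per-unit metric values."""
    vals = np.asarray(per_unit_values, dtype=float)
    if vals.size == 0:
        raise MetricError("no per-unit values")
    rng = np.random.default_rng(seed)
    stats_ = np.empty(n_boot)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        for i in range(n_boot):
            stats_[i] = statistic(vals[rng.integers(0, vals.size, vals.size)])
        lo, med, hi = np.percentile(stats_, [2.5, 50.0, 97.5])
        return MetricReport(float(statistic(vals)), float(med), float(lo), float(hi), axis=axis)
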