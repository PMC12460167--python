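"""Desk-scale experiment recipes on the synthetic population.

These functions reproduce, at desk scale, the qualitative comparisons that
motivate the modelling choices: categorical vs Poisson likelihoods for
underdispersed counts, time-variant vs time-invariant conditioning under
recording drift, and encoder transfer to a new animal.  They are shared by
the test suite and the acceptance script so both run the identical protocol.

Problem sizes are deliberately small (a few dozen units, tens of seconds of
audio at a reduced rate, three-layer encoders) so each experiment fits in a
few minutes on one CPU; see docs/methods.md for the exact sizes and the
rationale.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from .metrics import fano_factor, rmse_metric
from .model_core import ModelConfig, build_model, sample_response, transfer_decoder
from .pipeline import TrainConfig, concat_frames, frame_dataset, predict_distribution, train
from .synthetic_ic import (
    PopulationConfig,
    make_population,
    simulate_counts,
    training_soundscape,
)

DESK_RATE = 4882.8125  # canonical rate / 5; bins stay power-of-two locked
DESK_SAMPLES_PER_BIN = 8
DESK_CF_RANGE = (300.0, 2000.0)


def desk_model_config(n_classes: int = 5, time_module: str = "none") -> ModelConfig:
    """Scaled-down architecture: 8 sinc filters (17 taps), three stride-2
    conv layers of 16 filters, a 16-channel bottleneck, 512-sample frames
    with 128 samples of context at 4,882.8125 Hz (64 bins per frame)."""
    return ModelConfig(
        rate=DESK_RATE, n_front_filters=8, front_kernel=17, encoder_layers=3,
        encoder_filters=16, encoder_kernel=8, bottleneck_filters=16, bottleneck_kernel=8,
        n_classes=n_classes, frame=512, context=128, time_module=time_module,
        front_f_min=100.0,
    )


def desk_population(m: int = 24, seed: int = 3, **config_kw):
    cfg = PopulationConfig(cf_range=DESK_CF_RANGE, **config_kw)
    return make_population(m, seed=seed, config=cfg)


def desk_simulate(pop, stim, **kw):
    """simulate_counts with the desk-scale bin size."""
    kw.setdefault("samples_per_bin", DESK_SAMPLES_PER_BIN)
    kw.setdefault("window", None)
    return simulate_counts(pop, stim, **kw)


_simulate = desk_simulate


def fano_comparison(
    seed: int = 0,
    n_units: int = 24,
    train_s: float = 40.0,
    test_s: float = 6.0,
    n_test_trials: int = 48,
    epochs: int = 30,
) -> dict:
    """Train matched categorical and Poisson models on underdispersed
    synthetic data and compare per-unit Fano-factor errors.

    Returns per-unit absolute Fano errors for both models, the sign-test
    p-value for the categorical model winning, and held-out RMSE and mean
    log-likelihood for both heads.
    """
    rng_seed = int(seed)
    pop = desk_population(n_units, seed=3 + rng_seed)
    scape = training_soundscape(train_s, DESK_RATE, seed=5 + rng_seed,
                                f_lo=DESK_CF_RANGE[0], f_hi=DESK_CF_RANGE[1])
    counts = _simulate(pop, scape, trials=1, seed=7 + rng_seed)[0]
    test = training_soundscape(test_s, DESK_RATE, seed=99 + rng_seed,
                               f_lo=DESK_CF_RANGE[0], f_hi=DESK_CF_RANGE[1])
    test_trials = _simulate(pop, test, trials=n_test_trials, seed=101 + rng_seed)
    # Fano over driven bins (mean >= 0.5 counts), where underdispersion is
    # expressed; weakly driven bins have binomial Fano near 1 by construction
    fano_true = fano_factor(test_trials, min_mean=0.5)

    out = {"fano_true": fano_true}
    for name, ncls in (("categorical", 5), ("poisson", 1)):
        cfg = desk_model_config(n_classes=ncls)
        frames = frame_dataset(scape.samples, counts, cfg, seed=1 + rng_seed)
        model = build_model(cfg, n_units, seed=11 + rng_seed)
        train(model, frames, TrainConfig(lr=3e-3, max_epochs=epochs, seed=2 + rng_seed))
        dist = predict_distribution(model, test.samples)
        sim = np.stack([
            sample_response(dist, 1000 + rng_seed + i) for i in range(n_test_trials)
        ])
        out[f"fano_{name}"] = fano_factor(sim, min_mean=0.5)
        out[f"rmse_{name}"] = rmse_metric(test_trials[0], sim[0])
        out[f"loglik_{name}"] = float(np.mean(dist.log_pmf(test_trials[0].astype(float))))
    err_cat = np.abs(out["fano_categorical"] - fano_true)
    err_poi = np.abs(out["fano_poisson"] - fano_true)
    ok = np.isfinite(err_cat) & np.isfinite(err_poi)
    wins = int(np.sum(err_cat[ok] < err_poi[ok]))
    out["fano_err_categorical"] = err_cat
    out["fano_err_poisson"] = err_poi
    out["n_units_compared"] = int(ok.sum())
    out["categorical_wins"] = wins
    out["sign_test_p"] = float(
        stats.binomtest(wins, int(ok.sum()), 0.5, alternative="greater").pvalue
    )
    return out


def drift_benefit(
    seed: int = 0,
    drift_levels=(0.2, 0.5, 0.8),
    n_units: int = 20,
    n_presentations: int = 8,
    present_s: float = 12.0,
    epochs: int = 50,
    session_s: float = 36000.0,
) -> dict:
    """Time-variant vs time-invariant models under late-session gain drift.

    The same soundscape is presented at times spread over the session with a
    linear multiplicative gain drop; both models are trained on all
    presentations and evaluated on a fresh late-session sound.  Returns
    held-out RMSE per model and drift level, and the time-variant benefit.
    """
    rng_seed = int(seed)
    present_times = np.linspace(0.0, 0.85 * session_s, n_presentations)
    test_time = 0.92 * session_s
    results = {"drift_levels": list(drift_levels), "rmse_invariant": [], "rmse_variant": []}
    for li, mag in enumerate(drift_levels):
        pop = desk_population(
            n_units, seed=31 + rng_seed, drift_kind="linear",
            drift_magnitude=float(mag), session_s=session_s,
        )
        # a different sound at every presentation time, as in a real session
        scapes = [
            training_soundscape(present_s, DESK_RATE, seed=55 + rng_seed + 7 * pi,
                                f_lo=DESK_CF_RANGE[0], f_hi=DESK_CF_RANGE[1])
            for pi in range(n_presentations)
        ]
        test = training_soundscape(present_s, DESK_RATE, seed=77 + rng_seed,
                                   f_lo=DESK_CF_RANGE[0], f_hi=DESK_CF_RANGE[1])
        test_counts = _simulate(pop, test, rec_time_s=test_time,
                                seed=400 + rng_seed + li)[0]
        for kind, tm in (("invariant", "none"), ("variant", "audio")):
            cfg = desk_model_config(n_classes=5, time_module=tm)
            sets = []
            for pi, t0 in enumerate(present_times):
                counts = _simulate(pop, scapes[pi], rec_time_s=t0,
                                   seed=200 + rng_seed + 10 * li + pi)[0]
                sets.append(frame_dataset(scapes[pi].samples, counts, cfg, rec_time_s=t0,
                                          seed=1 + pi))
            frames = concat_frames(sets)
            model = build_model(cfg, n_units, seed=13 + rng_seed)
            train(model, frames, TrainConfig(lr=3e-3, max_epochs=epochs, seed=2 + rng_seed))
            dist = predict_distribution(model, test.samples, rec_time_s=test_time)
            rhat = sample_response(dist, 900 + rng_seed + li)
            results[f"rmse_{kind}"].append(rmse_metric(test_counts, rhat))
    results["benefit"] = [
        float(i - v) for i, v in zip(results["rmse_invariant"], results["rmse_variant"])
    ]
    return results


def cf_recovery(
    seed: int = 0,
    n_units: int = 100,
    repeats: int = 4,
    tone_dur: float = 0.05,
    gap: float = 0.075,
) -> dict:
    """Recover generator CFs from a simulated tone battery.

    Synthesizes the CF battery (0.2-octave frequency steps from 294 Hz,
    4-85 dB SPL in 9-dB steps) truncated to the desk-scale band, simulates
    the population response, counts tone-evoked spikes per (frequency, level)
    cell, and applies the exact-Poisson significance rule.  Returns per-unit
    octave errors and the median error.
    """
    from .metrics import window_to_bins
    from .neural_preproc import estimate_cf
    from .stimuli import StimulusGrid, level_grid, octave_grid, synth_tone_battery

    rng_seed = int(seed)
    pop = desk_population(n_units, seed=9 + rng_seed)
    freqs = octave_grid(294.0, 2000.0, 0.2)
    levels = level_grid(4.0, 85.0, 9.0)
    grid = StimulusGrid(freqs, levels, duration=tone_dur, gap=gap, repeats=repeats)
    battery = synth_tone_battery(grid, seed=17 + rng_seed, rate=DESK_RATE)
    bin_rate = DESK_RATE / DESK_SAMPLES_PER_BIN
    counts = _simulate(pop, battery, trials=1, seed=23 + rng_seed)[0]
    cell = np.zeros((n_units, freqs.size, levels.size))
    sil = np.zeros(n_units)
    n_events = 0
    for ann in battery.annotations:
        sl = window_to_bins(ann.onset, ann.onset + tone_dur, bin_rate)
        fi = int(np.argmin(np.abs(freqs - ann.params["frequency"])))
        li = int(np.argmin(np.abs(levels - ann.params["level"])))
        cell[:, fi, li] += counts[:, sl].sum(axis=1)
        gap_sl = window_to_bins(ann.onset + tone_dur + 0.005,
                                ann.onset + 2 * tone_dur + 0.005, bin_rate)
        sil += counts[:, gap_sl].sum(axis=1)
        n_events += 1
    sil /= n_events  # mean counts per tone-duration window of silence
    errors = np.full(n_units, np.nan)
    for u in range(n_units):
        cf_est = estimate_cf(cell[u], freqs, levels, silence_rate=float(sil[u]),
                             n_repeats=repeats)
        if cf_est is not None:
            errors[u] = abs(np.log2(cf_est / pop.cf[u]))
    found = np.isfinite(errors)
    return {
        "errors_oct": errors,
        "n_found": int(found.sum()),
        "median_error_oct": float(np.median(errors[found])) if found.any() else np.inf,
    }


def transfer_experiment(
    seed: int = 0,
    n_units: int = 20,
    train_s: float = 40.0,
    test_s: float = 8.0,
    epochs: int = 25,
) -> dict:
    """Encoder transfer: train a model on animal A, freeze its encoder, fit a
    new decoder branch on animal B, and compare against a fully trained
    single-branch model of animal B on held-out data.

    Returns the two held-out mean losses and their relative difference.
    """
    rng_seed = int(seed)
    cfg = desk_model_config(n_classes=5, time_module="bottleneck")
    pop_a = desk_population(n_units, seed=41 + rng_seed)
    pop_b = desk_population(n_units, seed=42 + rng_seed)
    scape = training_soundscape(train_s, DESK_RATE, seed=61 + rng_seed,
                                f_lo=DESK_CF_RANGE[0], f_hi=DESK_CF_RANGE[1])
    test = training_soundscape(test_s, DESK_RATE, seed=88 + rng_seed,
                               f_lo=DESK_CF_RANGE[0], f_hi=DESK_CF_RANGE[1])
    counts_a = _simulate(pop_a, scape, trials=1, seed=71 + rng_seed)[0]
    counts_b = _simulate(pop_b, scape, trials=1, seed=72 + rng_seed)[0]
    test_b = _simulate(pop_b, test, trials=1, seed=73 + rng_seed)[0]
    tcfg = TrainConfig(lr=3e-3, max_epochs=epochs, seed=2 + rng_seed)

    frames_a = frame_dataset(scape.samples, counts_a, cfg, seed=1 + rng_seed)
    model_a = build_model(cfg, n_units, seed=21 + rng_seed)
    train(model_a, frames_a, tcfg)

    frames_b = frame_dataset(scape.samples, counts_b, cfg, seed=1 + rng_seed)
    branch, _ = transfer_decoder(model_a, frames_b, tcfg, seed=51 + rng_seed)

    model_full = build_model(cfg, n_units, seed=22 + rng_seed)
    train(model_full, frames_b, tcfg)

    def heldout_loss(model, br):
        dist = predict_distribution(model, test.samples, branch=br)
        return float(-np.mean(dist.log_pmf(test_b.astype(float))))

    loss_transfer = heldout_loss(model_a, branch)
    loss_full = heldout_loss(model_full, 0)
    return {
        "loss_transfer": loss_transfer,
        "loss_full": loss_full,
        "rel_gap": (loss_transfer - loss_full) / loss_full,
    }
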