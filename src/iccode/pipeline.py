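"""Dataset framing, the training protocol and end-to-end evaluation.

Sounds are cut into non-overlapping frames with left context (zero-padded at
the session start) and kept sample-locked to the count bins: count bin k of a
frame covers sound samples [k*stride, (k+1)*stride).  Training follows a
fixed protocol: adaptive-moment gradient descent, halve the learning rate
after two validation epochs without improvement, stop after four.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import MetricError, ShapeError, TrainingError
from .metrics import (
    TrialPair,
    bootstrap_report,
    correlation_explained,
    loglik_metric,
    rmse_metric,
    variance_explained,
)
from .model_core import (
    TIME_AUDIO,
    CountDistribution,
    EncoderDecoder,
    ModelConfig,
    sample_response,
)
from .nn import Adam


@dataclass
class TrainConfig:
    """Training protocol parameters (defaults follow the full-scale recipe)."""

    batch: int = 50
    lr: float = 4e-4
    lr_halve_patience: int = 2
    early_stop_patience: int = 4
    max_epochs: int = 100
    val_fraction: float = 0.10
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.val_fraction < 1:
            raise TrainingError("validation fraction must be in (0, 1)")


@dataclass
class FrameSet:
    """Aligned (sound, time, count) frames for one branch."""

    sound: np.ndarray  # (N, frame+context)
    counts: np.ndarray  # (N, M, frame/stride)
    time: np.ndarray | None = None  # (N, frame+context) audio-rate or (N, T_out)
    train_idx: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))
    val_idx: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))

    @property
    def n_frames(self) -> int:
        return self.sound.shape[0]

    def subset_time(self, idx):
        return None if self.time is None else self.time[idx]


def frame_dataset(
    samples: np.ndarray,
    counts: np.ndarray,
    cfg: ModelConfig,
    rec_time_s: float = 0.0,
    val_fraction: float = 0.10,
    seed: int = 0,
) -> FrameSet:
    """Cut a session into non-overlapping frames with left context.

    ``samples`` is the session sound at the model rate, ``counts`` the
    sample-locked (M, T) MUA; ``rec_time_s`` the recording time of the first
    sample.  A seeded random ``val_fraction`` of frames forms the validation
    split (by frame).
    """
    samples = np.asarray(samples, dtype=float)
    counts = np.atleast_2d(np.asarray(counts))
    stride = cfg.stride
    excess = samples.size - counts.shape[1] * stride
    if 0 < excess < stride:
        samples = samples[: counts.shape[1] * stride]  # sub-bin remainder
    elif excess != 0:
        raise ShapeError("sound and counts are not sample-locked")
    n_frames = samples.size // cfg.frame
    if n_frames < 1:
        raise ShapeError("session shorter than one frame")
    t_out = cfg.n_output_bins
    sound = np.zeros((n_frames, cfg.input_samples))
    count_frames = np.zeros((n_frames, counts.shape[0], t_out), dtype=counts.dtype)
    times = None
    for i in range(n_frames):
        s0 = i * cfg.frame
        left = max(s0 - cfg.context, 0)
        ctx = samples[left:s0]
        sound[i, cfg.context - ctx.size : cfg.context] = ctx
        sound[i, cfg.context :] = samples[s0 : s0 + cfg.frame]
        count_frames[i] = counts[:, i * t_out : (i + 1) * t_out]
    if cfg.time_module != "none":
        if cfg.time_module == TIME_AUDIO:
            starts = rec_time_s + (np.arange(n_frames) * cfg.frame - cfg.context) / cfg.rate
            offs = np.arange(cfg.input_samples) / cfg.rate
        else:
            starts = rec_time_s + np.arange(n_frames) * cfg.frame / cfg.rate
            offs = np.arange(t_out) / cfg.bin_rate
        times = np.maximum(starts[:, None] + offs[None, :], 0.0)
    rng = np.random.default_rng(seed)
    order = rng.permutation(n_frames)
    n_val = max(int(round(val_fraction * n_frames)), 1) if n_frames > 1 else 0
    return FrameSet(sound, count_frames, times,
                    train_idx=np.sort(order[n_val:]), val_idx=np.sort(order[:n_val]))


def concat_frames(frame_sets: list[FrameSet]) -> FrameSet:
    """Concatenate FrameSets from several sessions/sounds (same branch)."""
    sound = np.concatenate([f.sound for f in frame_sets])
    counts = np.concatenate([f.counts for f in frame_sets])
    time = None
    if frame_sets[0].time is not None:
        time = np.concatenate([f.time for f in frame_sets])
    offs = np.cumsum([0] + [f.n_frames for f in frame_sets[:-1]])
    train = np.concatenate([f.train_idx + o for f, o in zip(frame_sets, offs)])
    val = np.concatenate([f.val_idx + o for f, o in zip(frame_sets, offs)])
    return FrameSet(sound, counts, time, train_idx=train, val_idx=val)


def _mean_loss(model: EncoderDecoder, frames: FrameSet, idx, branch: int) -> float:
    total, n = 0.0, 0
    for i in range(0, idx.size, 64):
        sel = idx[i : i + 64]
        dist = model.distribution(frames.sound[sel], frames.subset_time(sel), branch)
        r = frames.counts[sel]
        lp = dist.log_pmf(np.asarray(r, dtype=float))
        total += -lp.sum()
        n += lp.size
    return total / max(n, 1)


def train(
    model: EncoderDecoder,
    frames: FrameSet,
    cfg: TrainConfig | None = None,
    branch: int = 0,
    trainable: str = "all",
) -> dict:
    """Fit the model on a FrameSet with the standard schedule.

    ``trainable='branch'`` freezes the encoder and updates only the given
    branch's time module and decoder (transfer learning).  Returns a history
    dict with per-epoch train/validation losses and learning rates.
    """
    cfg = cfg or TrainConfig()
    layers = (model.branch_layers(branch) if trainable == "branch" else
              model.encoder_layers() + model.branch_layers(branch))
    opt = Adam(layers, lr=cfg.lr)
    rng = np.random.default_rng(cfg.seed)
    history = {"train_loss": [], "val_loss": [], "lr": []}
    best = np.inf
    since_best = 0
    val_idx = frames.val_idx if frames.val_idx.size else frames.train_idx
    for _epoch in range(cfg.max_epochs):
        order = frames.train_idx[rng.permutation(frames.train_idx.size)]
        ep_loss, n_batches = 0.0, 0
        for i in range(0, order.size, cfg.batch):
            sel = order[i : i + cfg.batch]
            opt.zero_grads()
            loss = model.loss_and_grad(frames.sound[sel], frames.counts[sel],
                                       frames.subset_time(sel), branch)
            if not np.isfinite(loss):
                raise TrainingError("training loss diverged")
            opt.step()
            ep_loss += loss
            n_batches += 1
        val_loss = _mean_loss(model, frames, val_idx, branch)
        history["train_loss"].append(ep_loss / max(n_batches, 1))
        history["val_loss"].append(val_loss)
        history["lr"].append(opt.lr)
        if val_loss < best - 1e-12:
            best = val_loss
            since_best = 0
        else:
            since_best += 1
            if since_best and since_best % cfg.lr_halve_patience == 0:
                opt.lr /= 2.0
            if since_best >= cfg.early_stop_patience:
                break
    return history


def predict_distribution(
    model: EncoderDecoder,
    samples: np.ndarray,
    rec_time_s: float = 0.0,
    branch: int = 0,
    stationary_time_s: float | None = None,
) -> CountDistribution:
    """Run a sound of arbitrary length through the model frame by frame and
    concatenate the per-frame distributions into one (M, T) distribution.

    ``stationary_time_s`` fixes the time input to a constant (stationary
    simulation mode)."""
    cfg = model.cfg
    samples = np.asarray(samples, dtype=float)
    t_total = samples.size // cfg.stride
    n_frames = int(np.ceil(samples.size / cfg.frame))
    padded = np.concatenate([samples, np.zeros(n_frames * cfg.frame - samples.size)])
    lams, probs = [], []
    for i in range(n_frames):
        s0 = i * cfg.frame
        left = max(s0 - cfg.context, 0)
        frame = np.zeros(cfg.input_samples)
        ctx = padded[left:s0]
        frame[cfg.context - ctx.size : cfg.context] = ctx
        frame[cfg.context :] = padded[s0 : s0 + cfg.frame]
        time_in = None
        if cfg.time_module != "none":
            if stationary_time_s is not None:
                base = np.full(1, stationary_time_s)
                offs = 0.0
            else:
                base = np.full(1, rec_time_s)
                if cfg.time_module == TIME_AUDIO:
                    offs = (s0 - cfg.context + np.arange(cfg.input_samples)) / cfg.rate
                else:
                    offs = (s0 + np.arange(cfg.n_output_bins) * cfg.stride) / cfg.rate
            n_in = cfg.input_samples if cfg.time_module == TIME_AUDIO else cfg.n_output_bins
            time_in = np.maximum(np.broadcast_to(base[:, None] + offs, (1, n_in)), 0.0)
        dist = model.distribution(frame[None], time_in, branch)
        if dist.kind == "poisson":
            lams.append(dist.lam[0])
        else:
            probs.append(dist.probs[0])
    if lams:
        return CountDistribution("poisson", lam=np.concatenate(lams, axis=1)[:, :t_total])
    return CountDistribution("categorical", probs=np.concatenate(probs, axis=1)[:, :t_total, :])


def evaluate(
    model: EncoderDecoder,
    eval_sounds: dict,
    seed: int = 0,
    branch: int = 0,
    train_ids: set | None = None,
    stationary_time_s: float | None = None,
    n_boot: int = 200,
) -> pd.DataFrame:
    """Evaluate a model on held-out sounds.

    ``eval_sounds`` maps a sound id to a dict with keys ``samples`` (sound at
    the model rate), ``trials`` ((n_trials, M, T) recorded counts) and
    optionally ``rec_times`` (seconds per trial).  Sound ids overlapping
    ``train_ids`` are refused.  Predictions are sampled with the given seed;
    returns one row per sound and metric with bootstrap median and 95% CI.
    """
    train_ids = train_ids or set()
    overlap = set(eval_sounds) & train_ids
    if overlap:
        raise TrainingError(f"evaluation sounds overlap training set: {sorted(overlap)}")
    rng = np.random.default_rng(seed)
    rows = []
    for sid, item in eval_sounds.items():
        trials = np.asarray(item["trials"])
        rec_times = item.get("rec_times", [0.0] * trials.shape[0])
        dists = [
            predict_distribution(model, item["samples"], rt, branch, stationary_time_s)
            for rt in rec_times[:2]
        ]
        rhats = [sample_response(d, rng) for d in dists]
        r1 = np.asarray(trials[0], dtype=float)
        rows.append({"sound": sid, "metric": "rmse", "value": rmse_metric(r1, rhats[0])})
        rows.append({"sound": sid, "metric": "log_likelihood",
                     "value": loglik_metric(dists[0], trials[0])})
        if trials.shape[0] >= 2 and len(dists) >= 2:
            pair = TrialPair(trials[0], trials[1], rhats[0], rhats[1], dists[0], dists[1])
            for name, fn in (("correlation_explained", correlation_explained),
                             ("variance_explained", variance_explained)):
                try:
                    value = fn(pair)
                except MetricError:
                    value = float("nan")  # undefined explainable signal, flagged
                row = {"sound": sid, "metric": name, "value": value}
                per_unit = fn(pair, per_unit=True)
                if np.isfinite(per_unit).any():
                    rep = bootstrap_report(per_unit, n_boot=n_boot, seed=seed)
                    row.update({"unit_median": rep.median, "ci_low": rep.ci_low,
                                "ci_high": rep.ci_high})
                rows.append(row)
    return pd.DataFrame(rows)


def save_report(df: pd.DataFrame, csv_path=None, json_path=None):
    """Write an evaluation table as CSV and/or a JSON report."""
    if csv_path:
        df.to_csv(csv_path, index=False)
    if json_path:
        with open(json_path, "w") as fh:
            json.dump(df.to_dict(orient="records"), fh, indent=2)
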