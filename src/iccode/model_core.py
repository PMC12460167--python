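"""Sound-to-spike-count encoder-decoder models and count likelihoods.

The architecture maps a sound waveform to a per-unit, per-bin distribution of
MUA counts.  A bank of learnable band-pass (windowed-sinc) filters followed by
a symmetric-log activation feeds a causal strided convolutional encoder; a
bottleneck layer produces the latent response r_b at the count-bin rate; a
linear per-animal decoder (1x1 convolution, no bias) maps the bottleneck to
either a Poisson rate (N_c = 1, softplus head) or a 5-class categorical
distribution over counts 0-4 (N_c = 5, softmax head).  Counts in the inferior
colliculus are underdispersed (Fano factor < 1), which the categorical head
can represent and the Poisson head cannot.

Non-stationarity is handled by a recording-time input: either concatenated at
the audio rate after the front end (single-branch time-variant model) or as a
per-branch multiplicative modulation of the bottleneck (multi-branch model).
Time is supplied in seconds and scaled by 1/36,000 at the model boundary.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import special, stats

from .errors import ShapeError, TrainingError
from .nn import Adam, Conv1d, Crop, PReLU, SincConv, SymLog
from .nn.layers import conv1d_forward, symmetric_log  # noqa: F401
from .stimuli import AUDIO_RATE, SoundStimulus

TIME_SCALE = 1.0 / 36000.0
MAX_COUNT = 4

TIME_NONE = "none"
TIME_AUDIO = "audio"  # audio-rate concat after the front end
TIME_BOTTLENECK = "bottleneck"  # per-branch multiplicative, simple
TIME_BOTTLENECK_COMPLEX = "bottleneck-complex"  # 4-layer cascade variant


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyperparameters.

    Defaults follow the full-scale model: 48 sinc filters of 64 taps, five
    causal conv layers (128 filters, kernel 64, stride 2), a 64-channel
    bottleneck, 8,192-sample frames with 2,048 samples of left context at
    24,414.0625 Hz, giving 256 output bins at 762.9395 Hz.  Smaller values of
    every field produce desk-scale models with the same contracts.
    """

    rate: float = AUDIO_RATE
    n_front_filters: int = 48
    front_kernel: int = 64
    encoder_layers: int = 5
    encoder_filters: int = 128
    encoder_kernel: int = 64
    bottleneck_filters: int = 64
    bottleneck_kernel: int = 64
    n_classes: int = 5
    frame: int = 8192
    context: int = 2048
    time_module: str = TIME_NONE
    time_scale: float = TIME_SCALE
    front_f_min: float = 50.0
    front_f_max: float | None = None

    def __post_init__(self):
        if self.n_classes not in (1, MAX_COUNT + 1):
            raise ShapeError("n_classes must be 1 (Poisson) or 5 (categorical)")
        if self.frame % self.stride or self.context % self.stride:
            raise ShapeError("frame and context must be divisible by the total stride")
        if self.time_module not in (TIME_NONE, TIME_AUDIO, TIME_BOTTLENECK, TIME_BOTTLENECK_COMPLEX):
            raise ShapeError(f"unknown time_module {self.time_module!r}")

    @property
    def stride(self) -> int:
        return 2**self.encoder_layers

    @property
    def bin_rate(self) -> float:
        return self.rate / self.stride

    @property
    def n_output_bins(self) -> int:
        return self.frame // self.stride

    @property
    def input_samples(self) -> int:
        return self.frame + self.context


@dataclass
class CountDistribution:
    """Per-unit-per-bin predicted count distribution.

    ``kind='poisson'``: ``lam`` holds rates (>= 0).  ``kind='categorical'``:
    ``probs`` holds probabilities over counts 0..4 on the last axis (rows sum
    to 1).  Leading axes are (units, bins) or (batch, units, bins).
    """

    kind: str
    lam: np.ndarray | None = None
    probs: np.ndarray | None = None

    def __post_init__(self):
        if self.kind == "poisson":
            if self.lam is None or np.any(self.lam < 0) or not np.all(np.isfinite(self.lam)):
                raise ShapeError("Poisson rates must be finite and non-negative")
        elif self.kind == "categorical":
            if self.probs is None or self.probs.shape[-1] != MAX_COUNT + 1:
                raise ShapeError("categorical needs 5 classes on the last axis")
            if not np.allclose(self.probs.sum(axis=-1), 1.0, atol=1e-6):
                raise ShapeError("categorical rows must sum to 1")
        else:
            raise ShapeError(f"unknown distribution kind {self.kind!r}")

    @property
    def shape(self):
        return self.lam.shape if self.kind == "poisson" else self.probs.shape[:-1]

    def log_pmf(self, counts: np.ndarray) -> np.ndarray:
        counts = np.asarray(counts)
        if counts.shape != self.shape:
            raise ShapeError("counts shape does not match distribution")
        if self.kind == "poisson":
            return counts * np.log(np.maximum(self.lam, 1e-300)) - self.lam - special.gammaln(
                counts + 1.0
            )
        p = np.take_along_axis(self.probs, counts[..., None].astype(int), axis=-1)[..., 0]
        with np.errstate(divide="ignore"):
            return np.log(p)

    def expected(self) -> np.ndarray:
        if self.kind == "poisson":
            return self.lam
        return np.einsum("...c,c->...", self.probs, np.arange(MAX_COUNT + 1, dtype=float))

    def variance(self) -> np.ndarray:
        if self.kind == "poisson":
            return self.lam
        n = np.arange(MAX_COUNT + 1, dtype=float)
        m2 = np.einsum("...c,c->...", self.probs, n**2)
        return m2 - self.expected() ** 2

    def sample(self, seed_or_rng) -> np.ndarray:
        return sample_response(self, seed_or_rng)


def poisson_loss(lam: np.ndarray | CountDistribution, counts: np.ndarray) -> float:
    """Poisson negative log-likelihood (up to the count-factorial constant):
    sum over units and bins of lam - R*log(lam)."""
    if isinstance(lam, CountDistribution):
        lam = lam.lam
    lam = np.asarray(lam, dtype=float)
    counts = np.asarray(counts, dtype=float)
    if lam.shape != counts.shape:
        raise ShapeError("rate and count shapes differ")
    with np.errstate(divide="ignore", invalid="ignore"):
        term = np.where(counts > 0, counts * np.log(lam), 0.0)
    if np.any((lam == 0) & (counts > 0)):
        warnings.warn("zero rate at observed count: infinite Poisson loss")
        return float("inf")
    return float(np.sum(lam - term))


def categorical_loss(probs: np.ndarray | CountDistribution, counts: np.ndarray) -> float:
    """Cross-entropy of observed counts under a 5-class categorical model:
    the negative log-probability of the observed (clipped) count, summed over
    units and bins (one-hot indicator of R)."""
    if isinstance(probs, CountDistribution):
        probs = probs.probs
    probs = np.asarray(probs, dtype=float)
    counts = np.clip(np.asarray(counts), 0, MAX_COUNT).astype(int)
    if probs.shape[:-1] != counts.shape:
        raise ShapeError("probability and count shapes differ")
    p_obs = np.take_along_axis(probs, counts[..., None], axis=-1)[..., 0]
    if np.any(p_obs == 0):
        warnings.warn("zero probability at observed count: infinite loss")
        return float("inf")
    return float(-np.sum(np.log(p_obs)))


def expected_counts(dist: CountDistribution) -> np.ndarray:
    """E_c over the count distribution: lam for Poisson, sum n*p_n for categorical."""
    return dist.expected()


def sample_response(dist: CountDistribution, seed_or_rng) -> np.ndarray:
    """Draw simulated activity: independent per unit-bin, Poisson clipped at 4."""
    rng = np.random.default_rng(seed_or_rng) if not isinstance(
        seed_or_rng, np.random.Generator
    ) else seed_or_rng
    if dist.kind == "poisson":
        return np.minimum(rng.poisson(dist.lam), MAX_COUNT).astype(np.uint8)
    cdf = np.cumsum(dist.probs, axis=-1)
    u = rng.random(dist.shape)
    return np.sum(u[..., None] > cdf[..., :-1], axis=-1, dtype=np.int64).astype(np.uint8)


# ---------------------------------------------------------------------------
# encoder-decoder model


class _Branch:
    def __init__(self, cfg: ModelConfig, n_units: int, rng):
        self.n_units = n_units
        self.time_layers: list = []
        if cfg.time_module == TIME_BOTTLENECK:
            gate = Conv1d(1, cfg.bottleneck_filters, 1, bias=True, rng=rng)
            # near-identity gate at init: small weights, unit bias
            gate.params["w"] *= 0.1
            gate.params["b"][:] = 1.0
            self.time_layers = [gate, PReLU(cfg.bottleneck_filters)]
        elif cfg.time_module == TIME_BOTTLENECK_COMPLEX:
            layers, in_ch = [], 1
            for _ in range(4):
                layers += [Conv1d(in_ch, 128, 1, bias=True, rng=rng), PReLU(128)]
                in_ch = 128
            gate = Conv1d(128, cfg.bottleneck_filters, 1, bias=True, rng=rng)
            gate.params["w"] *= 0.1
            gate.params["b"][:] = 1.0
            layers += [gate, PReLU(cfg.bottleneck_filters)]
            self.time_layers = layers
        self.decoder = Conv1d(cfg.bottleneck_filters, n_units * cfg.n_classes, 1,
                              bias=False, rng=rng)

    def layers(self):
        return self.time_layers + [self.decoder]


class EncoderDecoder:
    """Encoder-decoder model with one or more per-animal decoder branches."""

    def __init__(self, cfg: ModelConfig, units_per_branch, seed=0):
        self.cfg = cfg
        rng = np.random.default_rng(seed)
        self.front = SincConv(cfg.n_front_filters, cfg.front_kernel, cfg.rate,
                              f_min=cfg.front_f_min, f_max=cfg.front_f_max, rng=rng)
        self.front_act = SymLog()
        self.time_audio: list = []
        enc_in = cfg.n_front_filters
        if cfg.time_module == TIME_AUDIO:
            tconv = Conv1d(1, cfg.n_front_filters, 1, bias=False, rng=rng)
            tconv.params["w"] *= 0.1  # auxiliary path starts near-neutral
            self.time_audio = [tconv, SymLog()]
            enc_in = 2 * cfg.n_front_filters
        self.encoder: list = []
        for _ in range(cfg.encoder_layers):
            self.encoder.append((Conv1d(enc_in, cfg.encoder_filters, cfg.encoder_kernel,
                                        stride=2, bias=True, rng=rng),
                                 PReLU(cfg.encoder_filters)))
            enc_in = cfg.encoder_filters
        self.bottleneck = Conv1d(enc_in, cfg.bottleneck_filters, cfg.bottleneck_kernel,
                                 stride=1, bias=True, rng=rng)
        self.bottleneck_act = PReLU(cfg.bottleneck_filters)
        self.crop = Crop(cfg.context // cfg.stride)
        self.branches = [_Branch(cfg, m, rng) for m in np.atleast_1d(units_per_branch)]

    # -- structure ----------------------------------------------------------

    @property
    def n_branches(self) -> int:
        return len(self.branches)

    def encoder_layers(self):
        layers = [self.front] + [l for l in self.time_audio] + [self.front_act]
        for conv, act in self.encoder:
            layers += [conv, act]
        layers += [self.bottleneck, self.bottleneck_act]
        return layers

    def branch_layers(self, branch: int):
        return self.branches[branch].layers()

    def all_layers(self):
        out = self.encoder_layers()
        for b in self.branches:
            out += b.layers()
        return out

    def add_branch(self, n_units: int, seed=0) -> int:
        self.branches.append(_Branch(self.cfg, n_units, np.random.default_rng(seed)))
        return len(self.branches) - 1

    # -- forward / backward --------------------------------------------------

    def _check_input(self, sound):
        sound = np.atleast_2d(np.asarray(sound, dtype=float))
        if sound.shape[1] != self.cfg.input_samples:
            raise ShapeError(
                f"input must be frame+context = {self.cfg.input_samples} samples, "
                f"got {sound.shape[1]}"
            )
        return sound

    def _forward(self, sound, time_s, branch):
        cfg = self.cfg
        sound = self._check_input(sound)
        x = sound[:, None, :]
        h = self.front_act.forward(self.front.forward(x))
        if cfg.time_module == TIME_AUDIO:
            if time_s is None:
                raise ShapeError("time-variant model needs a time input")
            t = np.atleast_2d(np.asarray(time_s, dtype=float)) * cfg.time_scale
            if t.shape != sound.shape:
                raise ShapeError("audio-rate time input must match the sound frame")
            tp = self.time_audio[1].forward(self.time_audio[0].forward(t[:, None, :]))
            h = np.concatenate([h, tp], axis=1)
        for conv, act in self.encoder:
            h = act.forward(conv.forward(h))
        rb = self.bottleneck_act.forward(self.bottleneck.forward(h))
        rb_c = self.crop.forward(rb)
        br = self.branches[branch]
        cache = {"rb_c": rb_c, "gate": None}
        out = rb_c
        if br.time_layers:
            if time_s is None:
                raise ShapeError("time-variant model needs a time input")
            tb = np.atleast_2d(np.asarray(time_s, dtype=float)) * cfg.time_scale
            if tb.shape[1] != rb_c.shape[2]:
                raise ShapeError("bottleneck-rate time input must match output bins")
            g = tb[:, None, :]
            for layer in br.time_layers:
                g = layer.forward(g)
            cache["gate"] = g
            out = rb_c * g
        z = br.decoder.forward(out)
        b, _, t_out = z.shape
        cache["z"] = z.reshape(b, br.n_units, cfg.n_classes, t_out)
        return cache

    def _backward(self, dz, cache, branch):
        cfg = self.cfg
        br = self.branches[branch]
        b, m, c, t = dz.shape
        d_out = br.decoder.backward(dz.reshape(b, m * c, t))
        if cache["gate"] is not None:
            g = cache["gate"]
            d_rb_c = d_out * g
            dg = d_out * cache["rb_c"]
            for layer in reversed(br.time_layers):
                dg = layer.backward(dg)
        else:
            d_rb_c = d_out
        d = self.crop.backward(d_rb_c)
        d = self.bottleneck.backward(self.bottleneck_act.backward(d))
        for conv, act in reversed(self.encoder):
            d = conv.backward(act.backward(d))
        if cfg.time_module == TIME_AUDIO:
            nf = cfg.n_front_filters
            d_sound_part, d_time = d[:, :nf, :], d[:, nf:, :]
            self.time_audio[0].backward(self.time_audio[1].backward(d_time))
            d = d_sound_part
        self.front.backward(self.front_act.backward(d))

    # -- public API ----------------------------------------------------------

    def bottleneck_response(self, sound, time_s=None, branch: int = 0) -> np.ndarray:
        """Latent bottleneck r_b after context cropping (before any branch
        time gating), shape (B, channels, T_out)."""
        return self._forward(sound, time_s, branch)["rb_c"]

    def distribution(self, sound, time_s=None, branch: int = 0) -> CountDistribution:
        """Forward pass: per-frame count distribution, shape (B, M, T_out)."""
        z = self._forward(sound, time_s, branch)["z"]
        if self.cfg.n_classes == 1:
            lam = np.logaddexp(z[:, :, 0, :], 0.0)  # softplus head
            return CountDistribution("poisson", lam=lam)
        zmax = z.max(axis=2, keepdims=True)
        e = np.exp(z - zmax)
        probs = e / e.sum(axis=2, keepdims=True)
        return CountDistribution("categorical", probs=np.moveaxis(probs, 2, -1))

    def loss_and_grad(self, sound, counts, time_s=None, branch: int = 0) -> float:
        """Mean per-unit-per-bin loss on one batch; accumulates parameter grads."""
        cache = self._forward(sound, time_s, branch)
        z = cache["z"]
        counts = np.asarray(counts)
        if counts.ndim == 2:
            counts = counts[None]
        if counts.shape != (z.shape[0], z.shape[1], z.shape[3]):
            raise ShapeError("count frame does not match model output shape")
        n = counts.size
        if self.cfg.n_classes == 1:
            zz = z[:, :, 0, :]
            lam = np.logaddexp(zz, 0.0)
            lam_safe = np.maximum(lam, 1e-12)
            loss = float(np.sum(lam - counts * np.log(lam_safe)) / n)
            sig = special.expit(zz)
            dz = ((1.0 - counts / lam_safe) * sig / n)[:, :, None, :]
        else:
            r = np.clip(counts, 0, MAX_COUNT).astype(int)
            zmax = z.max(axis=2, keepdims=True)
            e = np.exp(z - zmax)
            p = e / e.sum(axis=2, keepdims=True)
            logp = np.take_along_axis(np.log(np.maximum(p, 1e-300)), r[:, :, None, :], axis=2)
            loss = float(-np.sum(logp) / n)
            onehot = np.zeros_like(p)
            np.put_along_axis(onehot, r[:, :, None, :], 1.0, axis=2)
            dz = (p - onehot) / n
        if not np.isfinite(loss):
            raise TrainingError("non-finite loss")
        self._backward(dz, cache, branch)
        return loss


def build_model(cfg: ModelConfig, units_per_branch, seed: int = 0) -> EncoderDecoder:
    """Construct an encoder-decoder model; ``units_per_branch`` is an int for a
    single-branch model or a sequence of per-animal unit counts."""
    return EncoderDecoder(cfg, units_per_branch, seed=seed)


# ---------------------------------------------------------------------------
# Mel-spectrogram front end and LNP baseline


def _mel_filterbank(n_bands, n_fft, rate, f_lo, f_hi):
    def mel(f):
        return 2595.0 * np.log10(1.0 + f / 700.0)

    def imel(m):
        return 700.0 * (10.0 ** (m / 2595.0) - 1.0)

    edges = imel(np.linspace(mel(f_lo), mel(f_hi), n_bands + 2))
    freqs = np.fft.rfftfreq(n_fft, d=1.0 / rate)
    fb = np.zeros((n_bands, freqs.size))
    for i in range(n_bands):
        lo, ctr, hi = edges[i], edges[i + 1], edges[i + 2]
        up = (freqs - lo) / max(ctr - lo, 1e-12)
        down = (hi - freqs) / max(hi - ctr, 1e-12)
        fb[i] = np.clip(np.minimum(up, down), 0.0, None)
    return fb


def mel_spectrogram(
    x: SoundStimulus | np.ndarray,
    window: int = 512,
    hop: int = 32,
    n_bands: int = 96,
    f_lo: float = 50.0,
    f_hi: float = 12000.0,
    offset_db: float = 7.0,
    squash: bool = True,
    rate: float | None = None,
) -> np.ndarray:
    """Mel-band log-power spectrogram at the count-bin rate (rate/hop).

    Windows are left-aligned with reflect padding of window-hop samples so the
    frame count equals len(x)//hop, locking frames to count bins.  Power is
    floored at 1e-7 before the log so the offset keeps all values positive; a
    sigmoid normalizes the range.  Returns (n_bands, n_frames).
    """
    if isinstance(x, SoundStimulus):
        samples, rate = x.samples, x.rate
    else:
        samples = np.asarray(x, dtype=float)
        rate = rate or AUDIO_RATE
    if samples.size < window:
        raise ShapeError("input shorter than one analysis window")
    n_frames = samples.size // hop
    padded = np.concatenate([samples[window - hop - 1 :: -1], samples])
    frames = np.lib.stride_tricks.sliding_window_view(padded, window)[::hop][:n_frames]
    spec = np.abs(np.fft.rfft(frames * np.hanning(window), axis=1)) ** 2
    fb = _mel_filterbank(n_bands, window, rate, f_lo, f_hi)
    melspec = spec @ fb.T
    out = np.log10(np.maximum(melspec, 1e-7)) + offset_db
    if squash:
        out = special.expit(out)
    return out.T


def lnp_forward(spec: np.ndarray, kernels: np.ndarray) -> CountDistribution:
    """Linear-nonlinear-Poisson baseline: per-unit causal convolution of the
    spectrogram over time followed by an exponential nonlinearity.

    ``spec`` is (bands, frames); ``kernels`` is (units, bands, taps)."""
    spec = np.asarray(spec, dtype=float)
    kernels = np.asarray(kernels, dtype=float)
    if spec.shape[1] < kernels.shape[2]:
        raise ShapeError("spectrogram shorter than the kernel")
    xp = np.pad(spec[None], ((0, 0), (0, 0), (kernels.shape[2] - 1, 0)))
    z, _ = conv1d_forward(xp, kernels, 1)
    return CountDistribution("poisson", lam=np.exp(z[0]))


def fit_lnp(
    spec: np.ndarray,
    counts: np.ndarray,
    kernel_t: int = 64,
    l2: float = 1e-5,
    lr: float = 1e-2,
    epochs: int = 300,
    seed: int = 0,
) -> np.ndarray:
    """Fit LNP kernels by full-batch Poisson maximum likelihood with an L2
    penalty on the kernels. Returns (units, bands, taps)."""
    rng = np.random.default_rng(seed)
    m = counts.shape[0]
    conv = Conv1d(spec.shape[0], m, kernel_t, stride=1, bias=False, rng=rng)
    conv.params["w"] *= 0.01
    opt = Adam([conv], lr=lr)
    x = spec[None]
    r = np.asarray(counts, dtype=float)[None]
    n = r.size
    for _ in range(epochs):
        opt.zero_grads()
        z = conv.forward(x)
        z = np.clip(z, -30, 30)
        lam = np.exp(z)
        dz = (lam - r) / n
        conv.backward(dz)
        conv.grads["w"] += 2.0 * l2 * conv.params["w"]
        opt.step()
    return conv.params["w"].copy()


def transfer_decoder(
    model: EncoderDecoder,
    frames,
    cfg=None,
    n_units: int | None = None,
    seed: int = 0,
):
    """Freeze the encoder and fit a new decoder branch (plus its time module)
    on data from a new animal.  Returns (branch_index, history).

    ``frames`` is a FrameSet from :func:`iccode.pipeline.frame_dataset`;
    ``cfg`` a :class:`iccode.pipeline.TrainConfig`.
    """
    from .pipeline import TrainConfig, train

    cfg = cfg or TrainConfig()
    if n_units is None:
        n_units = frames.counts.shape[1]
    branch = model.add_branch(n_units, seed=seed)
    snapshot = [
        {k: v.copy() for k, v in layer.params.items()} for layer in model.encoder_layers()
    ]
    history = train(model, frames, cfg, branch=branch, trainable="branch")
    for layer, saved in zip(model.encoder_layers(), snapshot):
        for k, v in saved.items():
            if not np.array_equal(layer.params[k], v):
                raise TrainingError("encoder weights changed during transfer")
    return branch, history
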