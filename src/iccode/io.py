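"""File interfaces: WAV + JSON sidecars for stimuli, HDF5 for responses,
raw traces and model checkpoints."""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import h5py
import numpy as np
from scipy.io import wavfile

from .model_core import EncoderDecoder, ModelConfig
from .neural_preproc import MUAResponse, RawTrace
from .stimuli import Annotation, SoundStimulus


def save_wav(stim: SoundStimulus, path):
    """Float32 mono WAV plus a .json sidecar with rate, level and annotations."""
    path = Path(path)
    wavfile.write(path, int(round(stim.rate)), stim.samples.astype(np.float32))
    sidecar = {
        "rate": stim.rate,
        "level_db_spl": stim.level_db_spl,
        "annotations": [dataclasses.asdict(a) for a in stim.annotations],
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=2))


def load_wav(path) -> SoundStimulus:
    path = Path(path)
    rate_int, samples = wavfile.read(path)
    sidecar_path = path.with_suffix(path.suffix + ".json")
    rate, level, anns = float(rate_int), None, []
    if sidecar_path.exists():
        sidecar = json.loads(sidecar_path.read_text())
        rate = sidecar.get("rate", rate)
        level = sidecar.get("level_db_spl")
        anns = [Annotation(**a) for a in sidecar.get("annotations", [])]
    return SoundStimulus(np.asarray(samples, dtype=float), rate=rate,
                         level_db_spl=level, annotations=anns)


def save_response(resp: MUAResponse, path, stimulus_id: str = "", animal: str = ""):
    """HDF5 layout: /counts (units x bins, uint8), /bin_rate_hz,
    /units/{cf_hz, signal_corr, animal}, /trials/{stimulus_id, start_time_s}."""
    with h5py.File(path, "w") as f:
        f.create_dataset("counts", data=np.asarray(resp.counts, dtype=np.uint8))
        f.create_dataset("bin_rate_hz", data=resp.bin_rate)
        units = f.create_group("units")
        meta = resp.unit_meta or {}
        units.create_dataset("cf_hz", data=np.asarray(
            meta.get("cf_hz", np.full(resp.n_units, np.nan)), dtype=float))
        units.create_dataset("signal_corr", data=np.asarray(
            meta.get("signal_corr", np.full(resp.n_units, np.nan)), dtype=float))
        units.create_dataset("animal", data=np.bytes_(animal or meta.get("animal", "")))
        trials = f.create_group("trials")
        trials.create_dataset("stimulus_id", data=np.bytes_(stimulus_id))
        trials.create_dataset("start_time_s", data=resp.start_time_s)


def load_response(path) -> MUAResponse:
    with h5py.File(path, "r") as f:
        meta = {
            "cf_hz": f["units/cf_hz"][...],
            "signal_corr": f["units/signal_corr"][...],
            "animal": f["units/animal"][()].decode(),
        }
        return MUAResponse(f["counts"][...], bin_rate=float(f["bin_rate_hz"][()]),
                           unit_meta=meta, start_time_s=float(f["trials/start_time_s"][()]))


def save_raw_trace(trace: RawTrace, path):
    with h5py.File(path, "w") as f:
        d = f.create_dataset("traces", data=trace.samples)
        d.attrs["rate"] = trace.rate
        f.create_dataset("channel_ids", data=np.asarray(trace.channel_ids))


def load_raw_trace(path) -> RawTrace:
    with h5py.File(path, "r") as f:
        return RawTrace(f["traces"][...], rate=float(f["traces"].attrs["rate"]),
                        channel_ids=f["channel_ids"][...])


def save_checkpoint(model: EncoderDecoder, path):
    """Named weight groups plus a JSON config attribute."""
    with h5py.File(path, "w") as f:
        f.attrs["config"] = json.dumps(dataclasses.asdict(model.cfg))
        f.attrs["units_per_branch"] = [b.n_units for b in model.branches]
        enc = f.create_group("encoder")
        for i, layer in enumerate(model.encoder_layers()):
            g = enc.create_group(f"layer_{i:02d}")
            for k, v in layer.params.items():
                g.create_dataset(k, data=v)
        for bi, branch in enumerate(model.branches):
            bg = f.create_group(f"branch_{bi:02d}")
            for i, layer in enumerate(branch.layers()):
                g = bg.create_group(f"layer_{i:02d}")
                for k, v in layer.params.items():
                    g.create_dataset(k, data=v)


def load_checkpoint(path) -> EncoderDecoder:
    with h5py.File(path, "r") as f:
        cfg = ModelConfig(**json.loads(f.attrs["config"]))
        units = list(f.attrs["units_per_branch"])
        model = EncoderDecoder(cfg, units, seed=0)
        for i, layer in enumerate(model.encoder_layers()):
            g = f[f"encoder/layer_{i:02d}"]
            for k in layer.params:
                layer.params[k][...] = g[k][...]
        for bi, branch in enumerate(model.branches):
            for i, layer in enumerate(branch.layers()):
                g = f[f"branch_{bi:02d}/layer_{i:02d}"]
                for k in layer.params:
                    layer.params[k][...] = g[k][...]
    return model


def save_stimulus_set(stimuli: dict, path):
    """Batch container: one HDF5 group per stimulus with samples, rate, level
    and a JSON-encoded annotation list."""
    with h5py.File(path, "w") as f:
        for name, stim in stimuli.items():
            g = f.create_group(name)
            g.create_dataset("samples", data=stim.samples)
            g.attrs["rate"] = stim.rate
            g.attrs["level_db_spl"] = np.nan if stim.level_db_spl is None else stim.level_db_spl
            g.attrs["annotations"] = json.dumps(
                [dataclasses.asdict(a) for a in stim.annotations])


def load_stimulus_set(path) -> dict:
    out = {}
    with h5py.File(path, "r") as f:
        for name, g in f.items():
            level = float(g.attrs["level_db_spl"])
            out[name] = SoundStimulus(
                g["samples"][...], rate=float(g.attrs["rate"]),
                level_db_spl=None if np.isnan(level) else level,
                annotations=[Annotation(**a) for a in json.loads(g.attrs["annotations"])])
    return out


def save_bottleneck(rb: np.ndarray, bin_rate: float, path):
    """Bottleneck export: channels x bins with a rate attribute."""
    with h5py.File(path, "w") as f:
        d = f.create_dataset("bottleneck", data=np.asarray(rb, dtype=float))
        d.attrs["rate"] = bin_rate
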