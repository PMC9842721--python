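"""Readers, writers and run-configuration handling.

Acquisition formats: EEG comes in as EDF or BDF (read through MNE, channel
labels preserved) and stimuli as WAV (PCM 16/24/32-bit or float, read
through SciPy and scaled to [-1, 1]).  Everything downstream of
preprocessing uses one shared container: compressed ``.npz`` arrays with a
JSON sidecar holding sampling rate, split boundaries, normalization
statistics and pipeline parameters, so later stages never touch the
acquisition formats.

A small EDF/BDF writer is included for building fixtures and for
round-trip tests; it writes 16-bit (EDF) or 24-bit (BDF) records with
physical scaling.
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
import hashlib
import json
import time
from pathlib import Path

import numpy as np

from .containers import MultichannelRecording, NormalizationStats, SplitSpec, WindowPairSet
from .preprocessing import PreprocessedRecording

__all__ = [
    "read_recording",
    "read_wav",
    "write_recording",
    "write_edf_bdf",
    "write_preprocessed",
    "read_preprocessed",
    "save_checkpoint",
    "load_checkpoint",
    "load_run_config",
    "resolve_run_config",
    "config_hash",
    "append_run_log",
]


# --------------------------------------------------------------------------
# acquisition formats
# --------------------------------------------------------------------------

def read_recording(path: str | Path, subject_id: str = "", stimulus_id: str = "") -> MultichannelRecording:
    """Read EEG from EDF/BDF (via MNE) or from the ``.npz`` container."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such recording: {path}")
    suffix = path.suffix.lower()
    if suffix in (".edf", ".bdf"):
        import mne

        reader = mne.io.read_raw_bdf if suffix == ".bdf" else mne.io.read_raw_edf
        try:
            raw = reader(path, preload=True, verbose="error")
        except Exception as err:  # corrupt/truncated headers
            raise ValueError(f"could not parse {path.name}: {err}") from err
        return MultichannelRecording(
            raw.get_data(),
            float(raw.info["sfreq"]),
            channel_labels=list(raw.ch_names),
            subject_id=subject_id,
            stimulus_id=stimulus_id,
        )
    if suffix == ".npz":
        with np.load(path, allow_pickle=False) as z:
            return MultichannelRecording(
                z["samples"],
                float(z["fs"]),
                channel_labels=[str(s) for s in z["channel_labels"]],
                subject_id=str(z["subject_id"]) if "subject_id" in z else subject_id,
                stimulus_id=str(z["stimulus_id"]) if "stimulus_id" in z else stimulus_id,
            )
    raise ValueError(f"unsupported recording format: {path.suffix}")


def read_wav(path: str | Path) -> tuple[np.ndarray, float]:
    """Read a WAV file, returning ``(mono float64 samples in [-1, 1], fs)``.

    Integer PCM (16/24/32-bit) is scaled by its full-scale value; float
    data is passed through.  Multichannel audio is averaged to mono.
    """
    from scipy.io import wavfile

    fs, data = wavfile.read(path)
    data = np.asarray(data)
    if data.dtype.kind == "i":
        data = data.astype(np.float64) / float(np.iinfo(data.dtype).max)
    elif data.dtype.kind == "u":  # 8-bit unsigned
        data = (data.astype(np.float64) - 128.0) / 128.0
    else:
        data = data.astype(np.float64)
    if data.ndim == 2:
        data = data.mean(axis=1)
    return data, float(fs)


def write_recording(path: str | Path, rec: MultichannelRecording) -> None:
    """Write a recording into the compressed array container."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savez_compressed(
        path,
        samples=rec.samples.astype(np.float32),
        fs=rec.fs,
        channel_labels=np.array(rec.channel_labels),
        subject_id=rec.subject_id,
        stimulus_id=rec.stimulus_id,
    )


def _pad(text: str, width: int) -> bytes:
    b = text.encode("ascii")[:width]
    return b + b" " * (width - len(b))


def write_edf_bdf(path: str | Path, rec: MultichannelRecording) -> None:
    """Write a recording as EDF (16-bit) or BDF (24-bit), by file suffix.

    Data are split into 1 s records; the trailing partial second is
    dropped.  Physical minima/maxima are set per channel from the data so
    the full digital range is used.
    """
    path = Path(path)
    is_bdf = path.suffix.lower() == ".bdf"
    fs = rec.fs
    if abs(fs - round(fs)) > 1e-9:
        raise ValueError("EDF/BDF writing requires an integer sampling rate")
    spr = int(round(fs))
    n_rec = rec.n_samples // spr
    if n_rec < 1:
        raise ValueError("recording shorter than one 1 s data record")
    x = rec.samples[:, : n_rec * spr]
    n_sig = rec.n_channels
    dig_max = 8388607 if is_bdf else 32767
    dig_min = -dig_max - 1
    phys_max = np.maximum(np.abs(x).max(axis=1), 1e-9)
    phys_min = -phys_max

    header = bytearray()
    if is_bdf:
        header += b"\xffBIOSEMI"
    else:
        header += _pad("0", 8)
    header += _pad("synthetic subject", 80)
    header += _pad("synthetic recording", 80)
    now = _dt.datetime(2000, 1, 1)
    header += _pad(now.strftime("%d.%m.%y"), 8)
    header += _pad(now.strftime("%H.%M.%S"), 8)
    header += _pad(str(256 * (1 + n_sig)), 8)
    header += _pad("24BIT" if is_bdf else "", 44)
    header += _pad(str(n_rec), 8)
    header += _pad("1", 8)
    header += _pad(str(n_sig), 4)
    for label in rec.channel_labels:
        header += _pad(label, 16)
    header += _pad("", 80) * n_sig
    header += _pad("uV", 8) * n_sig
    for v in phys_min:
        header += _pad(f"{v:.6g}"[:8], 8)
    for v in phys_max:
        header += _pad(f"{v:.6g}"[:8], 8)
    header += _pad(str(dig_min), 8) * n_sig
    header += _pad(str(dig_max), 8) * n_sig
    header += _pad("", 80) * n_sig
    header += _pad(str(spr), 8) * n_sig
    header += _pad("", 32) * n_sig

    # re-read the physical extrema exactly as written, so scaling is
    # consistent with what any reader will parse from the ASCII header
    pmin = np.array([float(f"{v:.6g}"[:8]) for v in phys_min])
    pmax = np.array([float(f"{v:.6g}"[:8]) for v in phys_max])
    gain = (dig_max - dig_min) / (pmax - pmin)
    digital = np.rint((x - pmin[:, None]) * gain[:, None] + dig_min).astype(np.int64)
    digital = np.clip(digital, dig_min, dig_max)

    with open(path, "wb") as fh:
        fh.write(bytes(header))
        for r in range(n_rec):
            block = digital[:, r * spr : (r + 1) * spr]
            if is_bdf:
                flat = block.reshape(-1)
                raw = np.empty((flat.size, 3), dtype=np.uint8)
                u = flat.astype(np.int64) & 0xFFFFFF
                raw[:, 0] = u & 0xFF
                raw[:, 1] = (u >> 8) & 0xFF
                raw[:, 2] = (u >> 16) & 0xFF
                fh.write(raw.tobytes())
            else:
                fh.write(block.astype("<i2").tobytes())


# --------------------------------------------------------------------------
# preprocessed container
# --------------------------------------------------------------------------

def _windows_to_arrays(prefix: str, w: WindowPairSet) -> dict:
    return {
        f"{prefix}_eeg": w.eeg.astype(np.float32),
        f"{prefix}_env": w.envelope.astype(np.float32),
        f"{prefix}_starts": w.start_samples,
    }


def write_preprocessed(
    path: str | Path, pre: PreprocessedRecording, extra: dict | None = None
) -> None:
    """Write one preprocessed recording: ``.npz`` arrays + JSON sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    arrays: dict = {}
    for name in ("train", "val", "test"):
        arrays.update(_windows_to_arrays(name, getattr(pre, name)))
    for k, v in (extra or {}).items():
        arrays[f"extra_{k}"] = v
    np.savez_compressed(path, **arrays)
    sidecar = {
        "fs": pre.fs,
        "subject_id": pre.subject_id,
        "stimulus_id": pre.stimulus_id,
        "eeg_stats": {
            "mean": pre.eeg_stats.mean.tolist(),
            "scale": pre.eeg_stats.scale.tolist(),
            "scale_kind": pre.eeg_stats.scale_kind,
        },
        "env_stats": {
            "mean": pre.env_stats.mean.tolist(),
            "scale": pre.env_stats.scale.tolist(),
            "scale_kind": pre.env_stats.scale_kind,
        },
        "n_windows": {n: getattr(pre, n).n_windows for n in ("train", "val", "test")},
    }
    with open(path.with_suffix(".json"), "w") as fh:
        json.dump(sidecar, fh, indent=2, sort_keys=True)


def read_preprocessed(path: str | Path) -> PreprocessedRecording:
    path = Path(path)
    with open(path.with_suffix(".json")) as fh:
        side = json.load(fh)
    fs = float(side["fs"])
    subject_id = side["subject_id"]
    stimulus_id = side["stimulus_id"]
    sets = {}
    with np.load(path, allow_pickle=False) as z:
        for name in ("train", "val", "test"):
            sets[name] = WindowPairSet(
                eeg=z[f"{name}_eeg"],
                envelope=z[f"{name}_env"],
                fs=fs,
                start_samples=z[f"{name}_starts"],
                subject_ids=[subject_id] * z[f"{name}_eeg"].shape[0],
                stimulus_ids=[stimulus_id] * z[f"{name}_eeg"].shape[0],
            )

    def stats(d):
        return NormalizationStats(np.array(d["mean"]), np.array(d["scale"]), d["scale_kind"])

    return PreprocessedRecording(
        train=sets["train"],
        val=sets["val"],
        test=sets["test"],
        eeg_stats=stats(side["eeg_stats"]),
        env_stats=stats(side["env_stats"]),
        fs=fs,
        subject_id=subject_id,
        stimulus_id=stimulus_id,
    )


# --------------------------------------------------------------------------
# checkpoints
# --------------------------------------------------------------------------

def save_checkpoint(model, path: str | Path) -> None:
    """Save model weights + embedded config to one ``.npz`` file."""
    from .baselines import LinearDecoderModel
    from .model import VlaaiNetwork

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if isinstance(model, VlaaiNetwork):
        meta = {"kind": "vlaai", "config": model.config.to_dict(), "dtype": np.dtype(model.dtype).name}
    elif isinstance(model, LinearDecoderModel):
        meta = {"kind": "linear", "config": model.config, "ridge_lambda": model.ridge_lambda}
    else:
        raise TypeError(f"don't know how to checkpoint {type(model).__name__}")
    arrays = {f"param/{k}": v for k, v in model.state_arrays().items()}
    arrays["meta"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
    np.savez_compressed(path, **arrays)


def load_checkpoint(path: str | Path):
    from .baselines import LinearDecoderModel
    from .model import VlaaiConfig, VlaaiNetwork

    with np.load(Path(path), allow_pickle=False) as z:
        meta = json.loads(bytes(z["meta"]).decode())
        arrays = {k[len("param/") :]: z[k] for k in z.files if k.startswith("param/")}
    if meta["kind"] == "vlaai":
        model = VlaaiNetwork(VlaaiConfig.from_dict(meta["config"]), dtype=np.dtype(meta["dtype"]))
    elif meta["kind"] == "linear":
        c = meta["config"]
        model = LinearDecoderModel(c["n_channels"], c["n_lags"], c["fs"])
        model.ridge_lambda = meta.get("ridge_lambda")
    else:
        raise ValueError(f"unknown checkpoint kind {meta['kind']!r}")
    model.load_state_arrays(arrays)
    return model


# --------------------------------------------------------------------------
# run configuration
# --------------------------------------------------------------------------

_SECTION_FIELDS: dict[str, tuple] = {}


def _section_fields() -> dict[str, tuple]:
    if _SECTION_FIELDS:
        return _SECTION_FIELDS
    from .model import VlaaiConfig
    from .simulate import SimulationSpec
    from .training import FinetuneConfig, TrainingConfig

    def names(cls):
        return tuple(f.name for f in dataclasses.fields(cls))

    _SECTION_FIELDS.update(
        {
            "preprocessing": ("target_fs", "intermediate_fs", "window_s", "overlap",
                              "scale_kind", "train_fraction", "val_fraction", "test_fraction"),
            "model": names(VlaaiConfig),
            "training": names(TrainingConfig),
            "finetuning": names(FinetuneConfig),
            "simulation": names(SimulationSpec),
            "evaluation": ("min_subjects",),
        }
    )
    return _SECTION_FIELDS


def load_run_config(path: str | Path) -> dict:
    """Load a YAML run configuration, rejecting unknown keys."""
    import yaml

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such config file: {path}")
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError(f"config root must be a mapping, got {type(cfg).__name__}")
    allowed = set(_section_fields()) | {"seed", "output_dir"}
    unknown = set(cfg) - allowed
    if unknown:
        raise ValueError(f"unknown config section(s): {sorted(unknown)}")
    for section, keys in _section_fields().items():
        sub = cfg.get(section) or {}
        bad = set(sub) - set(keys)
        if bad:
            raise ValueError(f"unknown key(s) in [{section}]: {sorted(bad)}")
    return cfg


def resolve_run_config(cfg: dict, out_dir: str | Path) -> Path:
    """Write the fully resolved config next to the run's outputs."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    target = out / "resolved_config.json"
    with open(target, "w") as fh:
        json.dump(cfg, fh, indent=2, sort_keys=True, default=str)
    return target


def config_hash(cfg: dict) -> str:
    return hashlib.sha256(json.dumps(cfg, sort_keys=True, default=str).encode()).hexdigest()[:12]


def append_run_log(out_dir: str | Path, command: str, cfg: dict, seed: int | None) -> None:
    """Append one structured line (timestamp, command, seed, config hash)."""
    from . import __version__

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    entry = {
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "command": command,
        "seed": seed,
        "config_hash": config_hash(cfg),
        "version": __version__,
    }
    with open(out / "run_log.jsonl", "a") as fh:
        fh.write(json.dumps(entry) + "\n")
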