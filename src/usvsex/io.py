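"""File interchange: WAV recordings, annotation tables, HDF5 datasets."""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
from scipy.io import wavfile

from .synth import LabeledDataset, SyntheticRecording


def write_wav(path, waveform: np.ndarray, sample_rate: int = 300_000):
    """Write a float waveform as 16-bit PCM."""
    peak = np.max(np.abs(waveform))
    scaled = waveform / peak if peak > 0 else waveform
    wavfile.write(path, sample_rate, (scaled * 32000).astype(np.int16))


def read_wav(path, expected_rate: int | None = 300_000):
    rate, data = wavfile.read(path)
    if expected_rate is not None and rate != expected_rate:
        raise ValueError(f"expected {expected_rate} Hz recording, got {rate}")
    if data.dtype.kind == "i":
        data = data.astype(np.float64) / np.iinfo(data.dtype).max
    return rate, np.asarray(data, dtype=np.float64)


def write_recording(recording: SyntheticRecording, stem: Path):
    """WAV + annotation CSV + JSON sidecar with the trajectory specs."""
    stem = Path(stem)
    write_wav(stem.with_suffix(".wav"), recording.waveform,
              recording.sample_rate)
    recording.annotations.to_csv(stem.with_suffix(".csv"), index=False)
    specs = [{**dataclasses.asdict(s), "labels": s.labels}
             for s in recording.specs]
    stem.with_suffix(".json").write_text(json.dumps(
        {"snr_db": recording.snr_db, "specs": specs}, indent=1,
        default=str))


def save_dataset(ds: LabeledDataset, path):
    with h5py.File(path, "w") as f:
        f.create_dataset("images", data=ds.images, compression="gzip")
        f.create_dataset("y", data=ds.y)
        f.create_dataset("individuals", data=ds.individuals)
        f.attrs["class_names"] = list(ds.class_names)
        f.create_dataset("truth_csv", data=ds.truth.to_csv(index=False))


def load_dataset(path) -> LabeledDataset:
    import io as _io

    with h5py.File(path, "r") as f:
        images = f["images"][...]
        y = f["y"][...]
        individuals = f["individuals"][...]
        class_names = tuple(f.attrs["class_names"])
        truth = pd.read_csv(_io.StringIO(f["truth_csv"][()].decode()))
    return LabeledDataset(images=images, y=y, individuals=individuals,
                          truth=truth, specs=[], class_names=class_names)
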