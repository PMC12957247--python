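"""Readers, writers, and run configuration.

Recordings travel either as EDF (the clinical surface format; read through
``mne``, written by the minimal 16-bit writer below since no installed
library exports EDF) or as compressed numpy archives (the fast internal
path, lossless).  A cohort is a directory of per-subject files plus a CSV
manifest (subject_id, severity, path).  Feature matrices are stored as an
archive plus a CSV index map.  Run parameters round-trip through YAML.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .connectivity import ConnectivityFeatures, IndexMap
from .montage import CHANNELS
from .preprocessing import EEGRecording


# ---------------------------------------------------------------------------
# numpy-archive surface
# ---------------------------------------------------------------------------

def save_recording_npz(rec: EEGRecording, path: str | Path) -> Path:
    path = Path(path)
    if path.suffix != ".npz":
        path = path.parent / (path.name + ".npz")
    np.savez_compressed(path, signal=rec.signal, fs=rec.fs,
                        ch_names=np.array(rec.ch_names), label=rec.label,
                        subject_id=rec.subject_id)
    return path


def _load_recording_npz(path: Path) -> EEGRecording:
    with np.load(path, allow_pickle=False) as z:
        return EEGRecording(z["signal"], float(z["fs"]),
                            tuple(str(c) for c in z["ch_names"]),
                            float(z["label"]), str(z["subject_id"]))


# ---------------------------------------------------------------------------
# EDF surface
# ---------------------------------------------------------------------------

def _pad(text: str, width: int) -> bytes:
    b = text.encode("ascii", "replace")[:width]
    return b + b" " * (width - len(b))


def write_edf(rec: EEGRecording, path: str | Path) -> Path:
    """Write a plain EDF file (16-bit, one 1-second data record per second).

    ``fs`` must be an integer; a trailing sub-second remainder is dropped.
    """
    path = Path(path)
    fs = int(round(rec.fs))
    if abs(fs - rec.fs) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    n_records = rec.n_samples // fs
    if n_records < 1:
        raise ValueError("recording shorter than one EDF data record (1 s)")
    ns = rec.n_channels
    data = rec.signal[:, : n_records * fs]

    phys_min = np.floor(data.min(axis=1)) - 1.0
    phys_max = np.ceil(data.max(axis=1)) + 1.0
    dig_min, dig_max = -32768, 32767
    scale = (dig_max - dig_min) / (phys_max - phys_min)
    digital = np.rint((data - phys_min[:, None]) * scale[:, None] + dig_min)
    digital = digital.astype("<i2")

    with open(path, "wb") as f:
        f.write(_pad("0", 8))
        f.write(_pad(f"subject {rec.subject_id}", 80))
        f.write(_pad(f"label {rec.label:.4f}", 80))
        f.write(_pad("01.01.00", 8))
        f.write(_pad("00.00.00", 8))
        f.write(_pad(str(256 * (1 + ns)), 8))
        f.write(_pad("", 44))
        f.write(_pad(str(n_records), 8))
        f.write(_pad("1", 8))
        f.write(_pad(str(ns), 4))
        for name in rec.ch_names:
            f.write(_pad(name, 16))
        f.write(_pad("", 80) * ns)
        f.write(_pad("uV", 8) * ns)
        for v in phys_min:
            f.write(_pad(f"{v:g}", 8))
        for v in phys_max:
            f.write(_pad(f"{v:g}", 8))
        f.write(_pad(str(dig_min), 8) * ns)
        f.write(_pad(str(dig_max), 8) * ns)
        f.write(_pad("", 80) * ns)
        f.write(_pad(str(fs), 8) * ns)
        f.write(_pad("", 32) * ns)
        for r in range(n_records):
            f.write(digital[:, r * fs:(r + 1) * fs].tobytes())
    return path


def _load_recording_edf(path: Path, label: float | None,
                        subject_id: str | None) -> EEGRecording:
    import mne

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    fs = float(raw.info["sfreq"])
    available = {name.upper(): i for i, name in enumerate(raw.ch_names)}
    missing = [c for c in CHANNELS if c not in available]
    if missing:
        raise ValueError(f"EDF file missing montage channel(s): {missing}")
    order = [available[c] for c in CHANNELS]
    signal = raw.get_data()[order] * 1e6  # mne loads EEG in volts
    return EEGRecording(signal, fs, CHANNELS,
                        0.0 if label is None else float(label),
                        subject_id or path.stem)


def read_recording(path: str | Path, label: float | None = None,
                   subject_id: str | None = None) -> EEGRecording:
    """Load a recording from .npz or .edf; channels in canonical montage
    order.  EDF files carry no severity label — pass it (or use a cohort
    manifest)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() == ".npz":
        rec = _load_recording_npz(path)
        if label is not None:
            rec.label = float(label)
        if rec.ch_names != CHANNELS:
            idx = {c: i for i, c in enumerate(rec.ch_names)}
            missing = [c for c in CHANNELS if c not in idx]
            if missing:
                raise ValueError(f"archive missing montage channel(s): {missing}")
            rec = EEGRecording(rec.signal[[idx[c] for c in CHANNELS]], rec.fs,
                               CHANNELS, rec.label, rec.subject_id)
        return rec
    if path.suffix.lower() == ".edf":
        return _load_recording_edf(path, label, subject_id)
    raise ValueError(f"unsupported recording format: {path.suffix!r}")


# ---------------------------------------------------------------------------
# cohort manifest
# ---------------------------------------------------------------------------

def write_cohort(recordings: Sequence[EEGRecording], outdir: str | Path,
                 fmt: str = "npz") -> Path:
    """Write one file per subject plus a ``manifest.csv``; returns the
    manifest path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for rec in recordings:
        fname = f"{rec.subject_id}.{fmt}"
        if fmt == "npz":
            save_recording_npz(rec, outdir / fname)
        elif fmt == "edf":
            write_edf(rec, outdir / fname)
        else:
            raise ValueError("fmt must be 'npz' or 'edf'")
        rows.append({"subject_id": rec.subject_id, "severity": rec.label,
                     "path": fname})
    manifest = outdir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def read_cohort(manifest_path: str | Path) -> list[EEGRecording]:
    manifest_path = Path(manifest_path)
    df = pd.read_csv(manifest_path)
    recs = []
    for row in df.itertuples():
        p = manifest_path.parent / str(row.path)
        recs.append(read_recording(p, label=float(row.severity),
                                   subject_id=str(row.subject_id)))
    return recs


# ---------------------------------------------------------------------------
# feature archives
# ---------------------------------------------------------------------------

def save_features(feats: ConnectivityFeatures, path: str | Path) -> Path:
    path = Path(path)
    if path.suffix != ".npz":
        path = path.parent / (path.name + ".npz")
    np.savez_compressed(path, values=feats.values,
                        index_map=np.array([list(t) for t in feats.index_map]),
                        label=feats.label, subject_id=feats.subject_id)
    index_csv = path.with_suffix(".index.csv")
    pd.DataFrame(
        [(i, *t) for i, t in enumerate(feats.index_map)],
        columns=["feature_idx", "band", "electrode_i", "electrode_j"],
    ).to_csv(index_csv, index=False)
    return path


def load_features(path: str | Path) -> ConnectivityFeatures:
    with np.load(path, allow_pickle=False) as z:
        index_map: IndexMap = tuple(tuple(str(s) for s in row)
                                    for row in z["index_map"])
        return ConnectivityFeatures(z["values"], index_map, float(z["label"]),
                                    str(z["subject_id"]))


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Serializable configuration tying one pipeline run together.

    Defaults are the study conditions: 250 -> 125 Hz, 4th-order Butterworth
    4-30 Hz, the four analysis bands, 10-s windows, 3 x 5-fold CV, 30 TPE
    evaluations.
    """

    data_dir: str = "data"
    output_dir: str = "results"
    target_fs: float = 125.0
    filter_lo: float = 4.0
    filter_hi: float = 30.0
    filter_order: int = 4
    window_s: float = 10.0
    model: str = "conv_gmlp"
    model_params: dict = field(default_factory=dict)
    n_folds: int = 5
    n_repeats: int = 3
    grouping: str = "subject"
    average_epochs: bool = True
    tpe_max_evals: int = 30
    seed: int = 0

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(dataclasses.asdict(self),
                                       sort_keys=False))
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        return cls(**data)
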