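"""Readers and writers for the toolkit's on-disk formats.

Audio is mono 16-bit PCM RIFF WAV.  Annotations are per-recording CSVs with
header ``onset_s,offset_s,class`` (seconds, half-open intervals, 6 decimal
places).  The corpus manifest and label tables share one dialect:
``file,wheeze,rhonchus,fine_crackle,coarse_crackle,age_years,sex,point``
with 0/1 booleans.  Probability rasters are CSVs with one row per 10 ms
frame and one column per class.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.io import wavfile

from .phenomena import CLASSES, PhenomenonEvent

MANIFEST_COLUMNS = ["file", *CLASSES, "age_years", "sex", "point"]


class DataError(ValueError):
    """Malformed or inconsistent input data."""


def write_wav(path: str | Path, samples: np.ndarray, sample_rate: int) -> None:
    x = np.clip(np.asarray(samples, dtype=np.float64), -1.0, 1.0)
    wavfile.write(str(path), sample_rate, (x * 32767.0).astype(np.int16))


def read_wav(path: str | Path) -> tuple[np.ndarray, int]:
    """Returns (float samples in [-1, 1], sample rate)."""
    try:
        sample_rate, data = wavfile.read(str(path))
    except (ValueError, FileNotFoundError) as exc:
        raise DataError(f"cannot read WAV file {path}: {exc}") from exc
    if data.ndim != 1:
        raise DataError(f"{path}: expected mono audio, got shape {data.shape}")
    if data.dtype == np.int16:
        x = data.astype(np.float64) / 32767.0
    elif np.issubdtype(data.dtype, np.floating):
        x = data.astype(np.float64)
    else:
        raise DataError(f"{path}: unsupported sample dtype {data.dtype}")
    return x, int(sample_rate)


def write_annotations(path: str | Path, events: Sequence[PhenomenonEvent]) -> None:
    with open(path, "w", newline="") as fh:
        fh.write("onset_s,offset_s,class\n")
        for ev in events:
            fh.write(f"{ev.onset:.6f},{ev.offset:.6f},{ev.class_name}\n")


def read_annotations(path: str | Path) -> list[PhenomenonEvent]:
    df = pd.read_csv(path)
    expected = ["onset_s", "offset_s", "class"]
    if list(df.columns) != expected:
        raise DataError(f"{path}: expected columns {expected}, got {list(df.columns)}")
    return [
        PhenomenonEvent(str(r["class"]), float(r["onset_s"]), float(r["offset_s"]))
        for _, r in df.iterrows()
    ]


def write_manifest(path: str | Path, manifest: pd.DataFrame) -> None:
    missing = [c for c in MANIFEST_COLUMNS if c not in manifest.columns]
    if missing:
        raise DataError(f"manifest missing columns {missing}")
    manifest[MANIFEST_COLUMNS].to_csv(path, index=False, lineterminator="\n")


def read_manifest(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise DataError(f"{path}: manifest missing columns {missing}")
    for c in CLASSES:
        df[c] = df[c].astype(bool)
    return df


def read_label_table(path: str | Path, id_column: str = "file") -> pd.DataFrame:
    """Recording-id-indexed boolean label table in the manifest dialect
    (extra metadata columns optional)."""
    df = pd.read_csv(path)
    if id_column not in df.columns:
        raise DataError(f"{path}: missing id column {id_column!r}")
    missing = [c for c in CLASSES if c not in df.columns]
    if missing:
        raise DataError(f"{path}: missing label columns {missing}")
    out = df.set_index(id_column)[list(CLASSES)].astype(bool)
    if out.index.duplicated().any():
        dupes = out.index[out.index.duplicated()].unique().tolist()
        raise DataError(f"{path}: duplicate recording ids {dupes}")
    return out


def write_raster(path: str | Path, raster: np.ndarray, class_names: Sequence[str] = CLASSES) -> None:
    pd.DataFrame(np.asarray(raster), columns=list(class_names)).to_csv(
        path, index=False, float_format="%.6f", lineterminator="\n"
    )


def read_raster(path: str | Path) -> tuple[np.ndarray, list[str]]:
    df = pd.read_csv(path)
    return df.to_numpy(dtype=np.float64), list(df.columns)
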