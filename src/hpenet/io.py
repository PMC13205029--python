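"""CSV/EDF/JSON readers and writers for every stage boundary.

CSV is the interchange format between stages so any stage can be run
standalone; models and results serialize to JSON.  All readers validate
headers and fail with explicit messages rather than guessing.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .cte import BinaryAdjacency
from .neurometrics import EEGRecording, HFSeries

__all__ = [
    "read_eeg_csv",
    "read_eeg_edf",
    "read_artifact_mask_csv",
    "write_hf_csv",
    "read_hf_csv",
    "read_behavioural_csv",
    "write_adjacency_csv",
    "read_adjacency_csv",
]


def read_eeg_csv(path, artifact_mask=None) -> EEGRecording:
    """Wide EEG CSV: first column ``time`` (seconds), one column per channel
    named by its 10-20 label.  The sampling rate is inferred from the time
    column, which must be uniformly spaced."""
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected a time column plus channel columns")
    first = df.columns[0].strip().lower()
    if first != "time":
        raise ValueError(
            f"{path}: first column must be named 'time' (seconds), got {df.columns[0]!r}"
        )
    t = df.iloc[:, 0].to_numpy(dtype=float)
    dt = np.diff(t)
    if len(dt) == 0 or np.ptp(dt) > 1e-6 * dt[0]:
        raise ValueError(f"{path}: time column must be uniformly spaced")
    fs = 1.0 / dt[0]
    labels = tuple(c.strip() for c in df.columns[1:])
    data = df.iloc[:, 1:].to_numpy(dtype=float).T
    return EEGRecording(data=data, fs=fs, channel_labels=labels, artifact_mask=artifact_mask)


def read_eeg_edf(path, artifact_mask=None) -> EEGRecording:
    """EDF reader (requires the optional ``mne`` dependency)."""
    try:
        import mne
    except ImportError as exc:  # pragma: no cover - depends on extras
        raise ImportError(
            "EDF input requires the 'mne' package; install hpenet[edf] or "
            "convert the recording to wide CSV"
        ) from exc
    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    data = raw.get_data() * 1e6  # volts -> microvolts
    return EEGRecording(
        data=data,
        fs=float(raw.info["sfreq"]),
        channel_labels=tuple(raw.ch_names),
        artifact_mask=artifact_mask,
    )


def read_artifact_mask_csv(path) -> np.ndarray:
    """Single-column CSV of 0/1 per second (header optional)."""
    df = pd.read_csv(path, header=None)
    if df.shape[1] != 1:
        raise ValueError(f"{path}: artifact mask must be a single column of 0/1")
    col = df.iloc[:, 0]
    if isinstance(col.iloc[0], str) and not col.iloc[0].strip().isdigit():
        col = col.iloc[1:]  # tolerate a header line
    values = col.to_numpy(dtype=float)
    if not np.all(np.isin(values, [0.0, 1.0])):
        raise ValueError(f"{path}: artifact mask entries must be 0 or 1")
    return values.astype(bool)


def write_hf_csv(series: HFSeries, path) -> None:
    """Tidy HF CSV (epoch, hf, value); missing samples write empty cells."""
    n, L = series.values.shape
    epochs = np.tile(np.arange(L), n)
    hfs = np.repeat(list(series.names), L)
    values = series.values.ravel().copy()
    values[series.mask.ravel()] = np.nan
    pd.DataFrame({"epoch": epochs, "hf": hfs, "value": values}).to_csv(path, index=False)


def read_hf_csv(path, standardized: bool = False) -> HFSeries:
    """Read a tidy HF CSV back into an HFSeries (empty cells become gaps)."""
    df = pd.read_csv(path)
    needed = {"epoch", "hf", "value"}
    if set(df.columns) != needed:
        raise ValueError(f"{path}: expected exactly columns {sorted(needed)}, got {list(df.columns)}")
    names = tuple(dict.fromkeys(df["hf"]))
    wide = df.pivot(index="hf", columns="epoch", values="value").loc[list(names)]
    values = wide.to_numpy(dtype=float)
    return HFSeries(values=values, names=names, standardized=standardized)


def read_behavioural_csv(path) -> pd.DataFrame:
    """Behavioural table: minute, phase, atco_isa, atco_rt_s, sme_isa."""
    df = pd.read_csv(path)
    needed = {"minute", "phase", "atco_isa", "atco_rt_s", "sme_isa"}
    missing = needed - set(df.columns)
    if missing:
        raise ValueError(f"{path}: behavioural table lacks columns {sorted(missing)}")
    return df


def write_adjacency_csv(adj: BinaryAdjacency, path) -> None:
    np.savetxt(path, adj.Mbin.astype(int), fmt="%d", delimiter=",")


def read_adjacency_csv(path, rule: str = "file") -> BinaryAdjacency:
    mat = np.loadtxt(path, delimiter=",")
    if mat.ndim != 2 or mat.shape[0] != mat.shape[1]:
        raise ValueError(f"{path}: adjacency must be a square 0/1 matrix")
    if not np.all(np.isin(mat, [0, 1])):
        raise ValueError(f"{path}: adjacency entries must be 0 or 1")
    return BinaryAdjacency(Mbin=mat.astype(bool), rule=rule)
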