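"""EEG band-power neurometrics: from multichannel EEG to five human-factor series.

The five human factors (HFs) tracked here — mental workload, attention,
vigilance, stress, effort — are standard EEG neurometrics built from band
powers over frontal and parietal channel groups, with frequency bands
anchored to the Individual Alpha Frequency (IAF).  The output of this module
is a gap-free, z-scored 5 x L matrix sampled at 1 Hz, the input expected by
the sparse VAR / transfer-entropy stages.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import signal

__all__ = [
    "EEGRecording",
    "BandScheme",
    "BandPowerTable",
    "HFSeries",
    "HF_NAMES",
    "DEFAULT_CHANNEL_GROUPS",
    "KLIMESCH_OFFSETS",
    "bandpass_filter",
    "compute_iaf",
    "band_power",
    "compute_neurometrics",
    "impute_missing",
    "standardize",
]

#: Fixed HF order used everywhere downstream (VAR rows, polygon vertices).
HF_NAMES = ("mental_workload", "attention", "vigilance", "stress", "effort")

#: Default 10-20 channel groups for the frontal/parietal band-power averages.
DEFAULT_CHANNEL_GROUPS = {
    "frontal": ("Fpz", "F3", "Fz", "F4", "AF3", "AFz", "AF4"),
    "parietal": ("P3", "Pz", "P4", "POz"),
}

#: IAF-anchored band offsets (Hz relative to IAF), Klimesch convention.
#: Gamma is computed and carried but feeds no neurometric.
KLIMESCH_OFFSETS = {
    "theta": (-6.0, -2.0),
    "alpha": (-2.0, 2.0),
    "alpha_high": (0.0, 2.0),
    "beta": (2.0, 16.0),
    "gamma": (16.0, None),  # upper edge fixed at 30 Hz (band-pass ceiling)
}


@dataclass
class EEGRecording:
    """A multichannel EEG segment.

    Parameters
    ----------
    data : (n_channels, n_samples) array, microvolts.
    fs : sampling rate in Hz.
    channel_labels : ordered 10-20 names, one per row of ``data``.
    artifact_mask : per-second boolean vector, True = rejected epoch.
        Defaults to all-False.
    """

    data: np.ndarray
    fs: float
    channel_labels: tuple[str, ...]
    artifact_mask: np.ndarray = None

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be a 2-D (channels x samples) array")
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        self.channel_labels = tuple(self.channel_labels)
        if len(self.channel_labels) != self.data.shape[0]:
            raise ValueError("one channel label per data row is required")
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise ValueError("channel labels must be unique")
        n_epochs = int(self.data.shape[1] // self.fs)
        if self.artifact_mask is None:
            self.artifact_mask = np.zeros(n_epochs, dtype=bool)
        else:
            self.artifact_mask = np.asarray(self.artifact_mask, dtype=bool)
            if self.artifact_mask.shape != (n_epochs,):
                raise ValueError(
                    f"artifact_mask must have one entry per whole second "
                    f"({n_epochs}), got {self.artifact_mask.shape}"
                )

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.data.shape[1] / self.fs

    def channel_index(self, labels) -> np.ndarray:
        missing = [lb for lb in labels if lb not in self.channel_labels]
        if missing:
            raise KeyError(f"channels not in recording: {missing}")
        return np.array([self.channel_labels.index(lb) for lb in labels])


@dataclass
class BandScheme:
    """IAF-anchored band edges and channel groups."""

    iaf: float
    band_edges: dict[str, tuple[float, float]]
    channel_groups: dict[str, tuple[str, ...]] = field(
        default_factory=lambda: dict(DEFAULT_CHANNEL_GROUPS)
    )

    def __post_init__(self):
        for name, (lo, hi) in self.band_edges.items():
            if not lo < hi:
                raise ValueError(f"band {name!r}: low ({lo}) must be < high ({hi})")

    @classmethod
    def from_iaf(
        cls,
        iaf: float,
        offsets: dict | None = None,
        channel_groups: dict | None = None,
        upper_edge: float = 30.0,
    ) -> "BandScheme":
        """Anchor the band edges to an individual alpha frequency.

        Band = [IAF + lo_offset, IAF + hi_offset); a ``None`` upper offset is
        pinned at ``upper_edge`` (the band-pass ceiling).
        """
        offsets = dict(KLIMESCH_OFFSETS if offsets is None else offsets)
        edges = {}
        for name, (lo, hi) in offsets.items():
            high = upper_edge if hi is None else iaf + hi
            edges[name] = (iaf + lo, high)
        groups = dict(DEFAULT_CHANNEL_GROUPS if channel_groups is None else channel_groups)
        return cls(iaf=iaf, band_edges=edges, channel_groups=groups)


@dataclass
class BandPowerTable:
    """Per-epoch band power, indexed by (band, channel group).

    ``values`` is a DataFrame with a (band, group) MultiIndex on the rows and
    one column per epoch; NaN only where the artifact mask flagged the epoch.
    """

    values: pd.DataFrame
    epoch_duration: float = 1.0

    def __post_init__(self):
        finite = self.values.to_numpy()
        if np.any(finite[np.isfinite(finite)] < 0):
            raise ValueError("band powers must be non-negative")

    @property
    def n_epochs(self) -> int:
        return self.values.shape[1]

    def get(self, band: str, group: str) -> np.ndarray:
        return self.values.loc[(band, group)].to_numpy(dtype=float)


@dataclass
class HFSeries:
    """Five (or N) named series over time with a missingness mask.

    The canonical instance is the 5 x L human-factor matrix at 1 Hz, but the
    container is generic in N so VAR simulations of any size can reuse it.
    """

    values: np.ndarray
    names: tuple[str, ...] = HF_NAMES
    mask: np.ndarray = None
    standardized: bool = False

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] == 0:
            raise ValueError("values must be an N x L matrix with L > 0")
        self.names = tuple(self.names)
        if len(self.names) != self.values.shape[0]:
            raise ValueError("one name per series row is required")
        if self.mask is None:
            self.mask = np.isnan(self.values)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.values.shape:
                raise ValueError("mask must have the same shape as values")

    @property
    def n_series(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def is_gap_free(self) -> bool:
        return not self.mask.any() and np.isfinite(self.values).all()

    def require_gap_free(self, what: str = "this operation"):
        if not self.is_gap_free():
            raise ValueError(f"{what} requires a gap-free series; impute first")


def bandpass_filter(
    rec: EEGRecording, low: float = 2.0, high: float = 30.0, order: int = 5
) -> EEGRecording:
    """Zero-phase Butterworth band-pass, applied per channel.

    Forward-backward filtering doubles the effective order but preserves the
    phase of the 1 s epochs the band powers are computed on.
    """
    if not (0 < low < high < rec.fs / 2):
        raise ValueError(
            f"band edges must satisfy 0 < low < high < fs/2; got "
            f"low={low}, high={high}, fs={rec.fs}"
        )
    sos = signal.butter(order, (low, high), btype="bandpass", fs=rec.fs, output="sos")
    filtered = signal.sosfiltfilt(sos, rec.data, axis=1)
    return replace(rec, data=filtered)


def compute_iaf(
    baseline: EEGRecording,
    search_range: tuple[float, float] = (7.0, 13.0),
    group: tuple[str, ...] | None = None,
) -> float:
    """Individual alpha frequency: peak of the group-averaged spectrum.

    Estimated from an eyes-closed baseline of at least 10 s.  A flat spectrum
    (no unique peak in the search range) falls back to 10 Hz with a warning.
    """
    if baseline.duration < 10.0:
        raise ValueError(
            f"baseline must be at least 10 s long, got {baseline.duration:.1f} s"
        )
    idx = baseline.channel_index(group) if group is not None else slice(None)
    data = baseline.data[idx]
    # 2-s Hann segments give 0.5 Hz resolution over the alpha range.
    nperseg = min(int(2 * baseline.fs), data.shape[1])
    freqs, psd = signal.welch(data, fs=baseline.fs, nperseg=nperseg, axis=1)
    mean_psd = psd.mean(axis=0)
    lo, hi = search_range
    in_range = (freqs >= lo) & (freqs <= hi)
    if not in_range.any():
        raise ValueError(f"search range {search_range} contains no frequency bin")
    f_sel, p_sel = freqs[in_range], mean_psd[in_range]
    peak = p_sel.max()
    at_peak = f_sel[np.isclose(p_sel, peak, rtol=1e-9, atol=0.0)]
    if len(at_peak) > 1:
        warnings.warn(
            "no unique spectral peak in the IAF search range; defaulting to 10 Hz",
            stacklevel=2,
        )
        return 10.0
    return float(at_peak[0])


def band_power(rec: EEGRecording, scheme: BandScheme) -> BandPowerTable:
    """Per-second band power for every (band, channel group) pair.

    Each 1 s epoch is Hann-tapered and its periodogram summed over the band's
    bins (1 Hz resolution), then averaged over the group's channels — a
    group-mean realization of the global field power.  Epochs flagged in the
    artifact mask emit NaN.
    """
    nyq = rec.fs / 2
    for name, (lo, hi) in scheme.band_edges.items():
        if hi > nyq:
            raise ValueError(f"band {name!r} upper edge {hi} Hz exceeds Nyquist {nyq} Hz")
    epoch_len = int(rec.fs)
    n_epochs = rec.data.shape[1] // epoch_len
    if n_epochs < 1:
        raise ValueError("recording must contain at least one full 1 s epoch")

    # (channels, epochs, samples) view of whole epochs
    segs = rec.data[:, : n_epochs * epoch_len].reshape(rec.n_channels, n_epochs, epoch_len)
    freqs, psd = signal.periodogram(segs, fs=rec.fs, window="hann", axis=2)

    rows, index = [], []
    for band, (lo, hi) in scheme.band_edges.items():
        bins = (freqs >= lo) & (freqs < hi)
        for gname, labels in scheme.channel_groups.items():
            ch = rec.channel_index(labels)
            power = psd[ch][:, :, bins].sum(axis=2).mean(axis=0)
            power = power.copy()
            power[rec.artifact_mask[:n_epochs]] = np.nan
            rows.append(power)
            index.append((band, gname))
    values = pd.DataFrame(
        rows, index=pd.MultiIndex.from_tuples(index, names=["band", "group"])
    )
    return BandPowerTable(values=values, epoch_duration=1.0)


def compute_neurometrics(
    powers: BandPowerTable, alpha_parietal_band: str = "alpha"
) -> HFSeries:
    """Combine band powers into the five HF series (one sample per epoch).

    mental workload = theta(frontal) / alpha(parietal)
    attention       = -alpha(frontal)
    vigilance       = -beta(frontal)
    stress          = beta(parietal)
    effort          = theta(frontal)

    ``alpha_parietal_band`` selects the workload denominator: the full alpha
    band (default) or the upper-alpha sub-band (``"alpha_high"``).  A NaN in
    any operand propagates only to the metrics that use it; a zero parietal
    alpha denominator yields NaN at that epoch with a warning.
    """
    needed = [
        ("theta", "frontal"),
        (alpha_parietal_band, "parietal"),
        ("alpha", "frontal"),
        ("beta", "frontal"),
        ("beta", "parietal"),
    ]
    for key in needed:
        if key not in powers.values.index:
            raise KeyError(f"band-power table lacks required entry {key}")

    theta_f = powers.get("theta", "frontal")
    alpha_p = powers.get(alpha_parietal_band, "parietal")
    alpha_f = powers.get("alpha", "frontal")
    beta_f = powers.get("beta", "frontal")
    beta_p = powers.get("beta", "parietal")

    zero_denominator = (alpha_p == 0) & ~np.isnan(alpha_p)
    if zero_denominator.any():
        warnings.warn(
            f"parietal alpha power is zero at {int(zero_denominator.sum())} epoch(s); "
            "mental workload set to NaN there",
            stacklevel=2,
        )
    denom = np.where(zero_denominator, np.nan, alpha_p)
    with np.errstate(invalid="ignore", divide="ignore"):
        workload = theta_f / denom

    values = np.vstack([workload, -alpha_f, -beta_f, beta_p, theta_f])
    return HFSeries(values=values, names=HF_NAMES)


def _impute_row(row: np.ndarray, missing: np.ndarray, k: int, name: str) -> np.ndarray:
    observed = np.flatnonzero(~missing)
    if observed.size == 0:
        raise ValueError(f"series {name!r} is fully missing; cannot impute")
    if observed.size < k:
        raise ValueError(
            f"series {name!r} has only {observed.size} observed samples, "
            f"fewer than k={k}"
        )
    out = row.copy()
    for t in np.flatnonzero(missing):
        dist = np.abs(observed - t)
        # all neighbours tied with the k-th nearest are kept, so equal-distance
        # samples on both sides of a gap are averaged rather than one dropped
        kth = np.partition(dist, k - 1)[k - 1]
        sel = observed[dist <= kth]
        w = 1.0 / np.abs(sel - t)
        out[t] = np.sum(w * row[sel]) / np.sum(w)
    return out


def impute_missing(series: HFSeries, k: int = 5) -> HFSeries:
    """Fill gaps per HF row from its k temporally nearest observed samples.

    Each missing sample is replaced by the inverse-temporal-distance weighted
    average of the k nearest non-missing observations of that same series;
    distance ties at the k-th neighbour keep both sides.  Observed samples
    pass through bit-identically, and the operation is deterministic.
    """
    if k < 1:
        raise ValueError("k must be a positive integer")
    values = series.values.copy()
    for r in range(series.n_series):
        miss = series.mask[r] | np.isnan(series.values[r])
        if miss.any():
            values[r] = _impute_row(series.values[r], miss, k, series.names[r])
    return HFSeries(
        values=values,
        names=series.names,
        mask=np.zeros_like(series.mask),
        standardized=series.standardized,
    )


def standardize(series: HFSeries) -> HFSeries:
    """Z-score each row (sample standard deviation, ddof=1)."""
    series.require_gap_free("standardization")
    mu = series.values.mean(axis=1, keepdims=True)
    sd = series.values.std(axis=1, ddof=1, keepdims=True)
    flat = np.flatnonzero(sd.ravel() == 0)
    if flat.size:
        names = [series.names[i] for i in flat]
        raise ValueError(f"zero-variance series cannot be standardized: {names}")
    return HFSeries(
        values=(series.values - mu) / sd,
        names=series.names,
        mask=np.zeros_like(series.mask),
        standardized=True,
    )
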