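"""Photometry preprocessing: lock-in demodulation, dF/F, z-scoring and
event alignment into trial tensors.

Unit bookkeeping: a trace carries a ``units`` tag (``raw``, ``dF/F`` or
``zscore``) and operations refuse invalid orderings (e.g. dF/F of an already
normalised trace).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import h5py
import numpy as np
import pandas as pd
from scipy import signal

log = logging.getLogger(__name__)

#: default analysis bin width in seconds (54 ms)
BIN_WIDTH = 0.054


@dataclass
class PhotometryTrace:
    """Uniformly sampled continuous signal."""

    values: np.ndarray
    fs: float
    channel: str = ""
    units: str = "raw"
    t0: float = 0.0

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("trace contains non-finite values")

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(len(self.values)) / self.fs

    @property
    def duration(self) -> float:
        return len(self.values) / self.fs

    def to_hdf5(self, path, name: str | None = None) -> None:
        with h5py.File(path, "a") as fh:
            grp = fh.require_group(name or self.channel or "trace")
            for k in list(grp.keys()):
                del grp[k]
            grp.create_dataset("values", data=self.values)
            grp.attrs.update(
                fs=self.fs, channel=self.channel, units=self.units, t0=self.t0
            )

    @classmethod
    def from_hdf5(cls, path, name: str) -> "PhotometryTrace":
        with h5py.File(path, "r") as fh:
            grp = fh[name]
            return cls(
                values=grp["values"][:],
                fs=float(grp.attrs["fs"]),
                channel=str(grp.attrs["channel"]),
                units=str(grp.attrs["units"]),
                t0=float(grp.attrs["t0"]),
            )


@dataclass
class TrialTensor:
    """Trials x time-bins matrix aligned to a behavioural event.

    ``window = (pre, post)`` in seconds; bin ``k`` covers
    ``[-pre + k*bin_width, -pre + (k+1)*bin_width)`` relative to the event,
    so the alignment timestamp falls inside the bin with left edge <= 0 < right.
    """

    data: np.ndarray
    align_event: str
    window: tuple[float, float]
    bin_width: float
    trial_index: np.ndarray
    channel: str = ""
    dropped: list = field(default_factory=list)

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_bins(self) -> int:
        return self.data.shape[1]

    @property
    def bin_centers(self) -> np.ndarray:
        pre, _ = self.window
        return -pre + (np.arange(self.n_bins) + 0.5) * self.bin_width

    def window_mask(self, window: tuple[float, float]) -> np.ndarray:
        start, end = window
        if not start < end:
            raise ValueError("window start must precede end")
        mask = (self.bin_centers >= start) & (self.bin_centers < end)
        if not mask.any():
            raise ValueError(f"window {window} selects no bins")
        return mask

    def to_hdf5(self, path, name: str = "tensor") -> None:
        with h5py.File(path, "a") as fh:
            if name in fh:
                del fh[name]
            grp = fh.create_group(name)
            grp.create_dataset("data", data=self.data)
            grp.create_dataset("trial_index", data=self.trial_index)
            grp.attrs.update(
                align_event=self.align_event,
                pre=self.window[0],
                post=self.window[1],
                bin_width=self.bin_width,
                channel=self.channel,
            )

    @classmethod
    def from_hdf5(cls, path, name: str = "tensor") -> "TrialTensor":
        with h5py.File(path, "r") as fh:
            grp = fh[name]
            return cls(
                data=grp["data"][:],
                align_event=str(grp.attrs["align_event"]),
                window=(float(grp.attrs["pre"]), float(grp.attrs["post"])),
                bin_width=float(grp.attrs["bin_width"]),
                trial_index=grp["trial_index"][:],
                channel=str(grp.attrs["channel"]),
            )


# ---------------------------------------------------------------------------
# lock-in demodulation

def demodulate(
    raw: PhotometryTrace,
    carrier: float,
    lowpass_cutoff: float = 15.0,
    output_fs: float | None = None,
) -> PhotometryTrace:
    """Quadrature (I/Q) lock-in demodulation of an amplitude-modulated trace.

    The raw signal is multiplied by sine and cosine references at the carrier
    frequency, each product is low-pass filtered (4th-order Butterworth,
    forward-backward so zero phase), and the envelope is the gain-calibrated
    magnitude: a pure tone ``A*sin(2*pi*f*t)`` returns the constant ``A``.
    """
    if raw.fs <= 2 * carrier:
        raise ValueError(
            f"sampling rate {raw.fs} violates Nyquist for carrier {carrier}"
        )
    if lowpass_cutoff >= carrier:
        raise ValueError("lowpass_cutoff must be below the carrier frequency")
    t = raw.times
    ref = 2 * np.pi * carrier * t
    sos = signal.butter(4, lowpass_cutoff, fs=raw.fs, output="sos")
    i = signal.sosfiltfilt(sos, raw.values * np.sin(ref))
    q = signal.sosfiltfilt(sos, raw.values * np.cos(ref))
    env = 2.0 * np.hypot(i, q)  # lock-in gain: LP[x*sin] = A/2 for x = A*sin
    out = PhotometryTrace(env, raw.fs, channel=raw.channel, units="raw", t0=raw.t0)
    if output_fs is not None:
        factor = raw.fs / output_fs
        if abs(factor - round(factor)) > 1e-9:
            raise ValueError("output_fs must divide the input sampling rate")
        out = bin_decimate(out, int(round(factor)))
    return out


def bin_decimate(trace: PhotometryTrace, factor: int) -> PhotometryTrace:
    """Downsample by averaging non-overlapping blocks of ``factor`` samples."""
    n = (len(trace.values) // factor) * factor
    values = trace.values[:n].reshape(-1, factor).mean(axis=1)
    return replace(
        trace, values=values, fs=trace.fs / factor,
        t0=trace.t0 + (factor - 1) / (2 * trace.fs),
    )


# ---------------------------------------------------------------------------
# dF/F and z-score

def dff(
    trace: PhotometryTrace,
    baseline_mode: str = "running_percentile",
    window_s: float = 30.0,
    percentile: float = 10.0,
    f0: float | None = None,
) -> PhotometryTrace:
    """Fractional fluorescence change (F - F0) / F0.

    ``baseline_mode``: ``running_percentile`` (default 10th percentile over a
    30 s centred window), or ``constant`` (explicit ``f0``).
    """
    if trace.units != "raw":
        raise ValueError(f"dF/F expects a raw trace, got units={trace.units!r}")
    if baseline_mode == "running_percentile":
        w = max(int(round(window_s * trace.fs)), 3)
        f0_arr = (
            pd.Series(trace.values)
            .rolling(w, center=True, min_periods=max(w // 4, 1))
            .quantile(percentile / 100.0)
            .to_numpy()
        )
    elif baseline_mode == "constant":
        if f0 is None:
            raise ValueError("constant baseline requires f0")
        f0_arr = np.full_like(trace.values, float(f0))
    else:
        raise ValueError(f"unknown baseline_mode {baseline_mode!r}")
    bad = np.flatnonzero(f0_arr <= 0)
    if bad.size:
        raise ValueError(
            f"non-positive baseline F0 at {bad.size} samples "
            f"(first offenders: {bad[:5].tolist()})"
        )
    return replace(trace, values=(trace.values - f0_arr) / f0_arr, units="dF/F")


def zscore_session(trace: PhotometryTrace) -> PhotometryTrace:
    """Session-wide z-score: (x - mean) / sd."""
    sd = trace.values.std()
    if sd == 0:
        raise ValueError("cannot z-score a zero-variance trace")
    return replace(trace, values=(trace.values - trace.values.mean()) / sd,
                   units="zscore")


# ---------------------------------------------------------------------------
# trial alignment

def align_trials(
    trace: PhotometryTrace,
    trials: pd.DataFrame,
    align_event: str = "side_entry",
    window: tuple[float, float] = (1.0, 2.0),
    bin_width: float = BIN_WIDTH,
) -> TrialTensor:
    """Slice a trace into an event-aligned trials x bins tensor.

    Samples are aggregated into bins by their mean (no interpolation, so the
    noise statistics downstream covariance analyses rely on are preserved).
    Trials whose window exceeds the trace span are dropped and logged.
    """
    if bin_width < 1.0 / trace.fs:
        raise ValueError("bin_width must be at least one sample period")
    col = align_event if align_event.startswith("t_") else f"t_{align_event}"
    if col not in trials.columns:
        raise ValueError(f"unknown alignment event {align_event!r}")
    pre, post = window
    n_bins = int(round((pre + post) / bin_width))
    n = len(trace.values)

    # Epoching is index-based: the alignment timestamp is snapped to the
    # nearest sample, so when the bin width is a whole number of sample
    # periods every trial's bins aggregate the same samples with identical
    # phase (no trial-to-trial discretisation jitter).
    spb = bin_width * trace.fs
    integer_grid = abs(spb - round(spb)) < 1e-6
    k = int(round(spb))
    pre_samp = int(round(pre * trace.fs))

    rows, kept, dropped = [], [], []
    for idx, te in trials[col].items():
        i_event = int(round((te - trace.t0) * trace.fs))
        if integer_grid:
            i0 = i_event - pre_samp
            i1 = i0 + n_bins * k
            if i0 < 0 or i1 > n:
                dropped.append(idx)
                continue
            vals = trace.values[i0:i1].reshape(n_bins, k).mean(axis=1)
        else:
            start = te - pre
            i0 = int(np.ceil((start - trace.t0) * trace.fs - 1e-9))
            i1 = int(np.ceil((te + post - trace.t0) * trace.fs - 1e-9))
            if i0 < 0 or i1 > n:
                dropped.append(idx)
                continue
            st = trace.t0 + np.arange(i0, i1) / trace.fs
            which = np.clip(
                np.floor((st - start) / bin_width).astype(int), 0, n_bins - 1
            )
            sums = np.bincount(which, weights=trace.values[i0:i1], minlength=n_bins)
            counts = np.bincount(which, minlength=n_bins)
            with np.errstate(invalid="ignore"):
                vals = sums / counts
            empty = counts == 0
            if empty.any():
                filled = np.flatnonzero(~empty)
                vals[empty] = np.interp(np.flatnonzero(empty), filled, vals[filled])
        rows.append(vals)
        kept.append(idx)
    if dropped:
        log.info("align_trials dropped %d edge trials: %s", len(dropped), dropped)
    data = np.vstack(rows) if rows else np.empty((0, n_bins))
    return TrialTensor(
        data=data,
        align_event=align_event,
        window=window,
        bin_width=bin_width,
        trial_index=np.asarray(kept, dtype=int),
        channel=trace.channel,
        dropped=dropped,
    )


def sweep_baseline_subtract(
    tensor: TrialTensor, baseline_window: tuple[float, float]
) -> TrialTensor:
    """Subtract the scalar mean of the baseline window (pooled across all
    sweeps) from every bin — the pre-stimulus baseline convention used for
    optogenetic stimulation sweeps."""
    mask = tensor.window_mask(baseline_window)
    baseline = tensor.data[:, mask].mean()
    return replace(tensor, data=tensor.data - baseline)
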