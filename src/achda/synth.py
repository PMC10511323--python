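"""Synthetic DA/Ach photometry generator.

Builds continuous dopamine and acetylcholine traces from a behavioural
session by linear superposition of per-event kernels, with:

* outcome- and history-dependent amplitude rules on the side-entry response;
* per-trial multiplicative amplitude jitter (trial-to-trial variability of
  event-evoked release — the fluctuations that "noise correlation" analyses
  operate on);
* a slow band-limited intrinsic fluctuation per channel;
* a lagged negative DA -> Ach coupling acting on the clean (pre-observation-
  noise) DA signal, optionally gated off within a trial epoch;
* slow sinusoidal baseline drift and white observation noise;
* optional amplitude modulation onto 167/223 Hz carriers at 2 kHz for
  exercising lock-in demodulation.

Ground-truth kernels and coupling parameters are returned so downstream
modules can be validated against a known answer.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps

from .preprocess import BIN_WIDTH, PhotometryTrace

EVENT_TIME_COLS = {
    "centre_entry": "t_centre_entry",
    "centre_exit": "t_centre_exit",
    "side_entry": "t_side_entry",
    "side_exit": "t_side_exit",
}

BASE_EVENTS = ("centre_entry", "centre_exit", "side_entry", "side_exit", "lick", "reward")

#: events whose kernels are forced causal (no mass before the event)
CAUSAL_EVENTS = ("side_entry", "reward", "lick")


@dataclass
class KernelSet:
    """Per-feature time-lag coefficient vectors on a shared lag axis."""

    lags: np.ndarray
    coefs: dict[str, np.ndarray]

    def __post_init__(self):
        self.lags = np.asarray(self.lags, dtype=float)
        for name, c in self.coefs.items():
            c = np.asarray(c, dtype=float)
            if c.shape != self.lags.shape:
                raise ValueError(f"kernel {name!r} does not match the lag axis")
            if not np.all(np.isfinite(c)):
                raise ValueError(f"kernel {name!r} has non-finite coefficients")
            self.coefs[name] = c

    @property
    def features(self) -> list[str]:
        return list(self.coefs)

    @property
    def bin_width(self) -> float:
        return float(self.lags[1] - self.lags[0]) if len(self.lags) > 1 else np.nan

    def max_amplitude(self) -> float:
        return max(np.abs(c).max() for c in self.coefs.values())

    def to_json(self, path) -> None:
        out = {"lags": self.lags.tolist(),
               "coefs": {k: v.tolist() for k, v in self.coefs.items()}}
        with open(path, "w") as fh:
            json.dump(out, fh)

    @classmethod
    def from_json(cls, path) -> "KernelSet":
        with open(path) as fh:
            d = json.load(fh)
        return cls(np.asarray(d["lags"]),
                   {k: np.asarray(v) for k, v in d["coefs"].items()})


def _dog(lags, a1, mu1, s1, a2, mu2, s2, causal=False):
    k = a1 * np.exp(-0.5 * ((lags - mu1) / s1) ** 2) - a2 * np.exp(
        -0.5 * ((lags - mu2) / s2) ** 2
    )
    if causal:
        k = np.where(lags < 0, 0.0, k)
    return k

# difference-of-Gaussians shape parameters (amp, mu, sigma) x 2 per event;
# amplitudes keep z-scored traces roughly within [-3, +4]
_DOG_PARAMS = {
    "da": {
        "centre_entry": (0.5, 0.15, 0.10, 0.2, 0.5, 0.25),
        "centre_exit": (0.3, 0.10, 0.08, 0.1, 0.4, 0.20),
        "side_entry": (0.8, 0.20, 0.12, 0.3, 0.8, 0.30),
        "side_exit": (0.2, 0.15, 0.10, 0.1, 0.5, 0.20),
        "lick": (0.15, 0.10, 0.08, 0.05, 0.3, 0.15),
        "reward": (1.5, 0.30, 0.15, 0.5, 1.0, 0.40),
    },
    "ach": {
        "centre_entry": (0.6, 0.10, 0.08, 0.5, 0.35, 0.15),
        "centre_exit": (0.3, 0.10, 0.08, 0.4, 0.40, 0.20),
        "side_entry": (1.0, 0.10, 0.08, 0.8, 0.40, 0.20),
        "side_exit": (0.2, 0.10, 0.10, 0.1, 0.40, 0.20),
        "lick": (0.25, 0.10, 0.08, 0.1, 0.30, 0.10),
        "reward": (0.4, 0.50, 0.25, 0.3, 1.20, 0.40),
    },
}


def default_kernels(
    channel: str,
    fs: float = 2.0 / BIN_WIDTH,
    support: tuple[float, float] = (-0.5, 2.0),
    events: tuple[str, ...] = BASE_EVENTS,
) -> KernelSet:
    """Default multiphasic kernels for a channel (``da`` or ``ach``)."""
    params = _DOG_PARAMS[channel]
    lags = np.arange(round(support[0] * fs), round(support[1] * fs) + 1) / fs
    coefs = {
        ev: _dog(lags, *params[ev], causal=ev in CAUSAL_EVENTS) for ev in events
    }
    return KernelSet(lags=lags, coefs=coefs)


def default_amplitude_rules() -> dict:
    """Outcome / history gain rules, keyed [channel][event][label].

    Unrewarded trials flip the DA side-entry transient into a dip and enlarge
    the Ach excursion; an unexpected win ("lose-win" on a stay) boosts both,
    and an unexpected loss ("win-lose") deepens the DA dip — a reward-
    prediction-error-like ordering.
    """
    return {
        "da": {
            "side_entry": {
                "rewarded": 1.0,
                "unrewarded": -1.0,
                "stay_lose_win": 1.4,
                "stay_win_lose": 1.3,
            }
        },
        "ach": {
            "side_entry": {
                "rewarded": 0.8,
                "unrewarded": 1.4,
                "stay_lose_win": 1.3,
                "stay_win_lose": 1.2,
            }
        },
    }


@dataclass
class Coupling:
    """Lagged negative DA -> Ach interaction.

    ``gain >= 0`` scales the suppression; ``lag`` (s) is how long changes in
    DA precede the Ach response (~100 ms).  ``gate_event``/``gate_window``
    optionally zero the coupling inside a per-trial epoch, emulating the
    side-entry disappearance of the off-diagonal covariance.
    """

    gain: float = 0.5
    lag: float = 0.108
    gate_event: str | None = None
    gate_window: tuple[float, float] | None = None
    divisive: bool = False
    couple_to_noisy: bool = False

    def validate(self):
        if self.gain < 0 or self.lag < 0:
            raise ValueError("coupling gain and lag must be >= 0")


@dataclass
class GeneratorSpec:
    """Everything the synthetic photometry generator needs.

    The default sampling rate is two samples per 54 ms analysis bin so that
    bin-mean alignment onto the analysis grid never leaves empty bins.
    """

    fs: float = 2.0 / BIN_WIDTH
    kernels: dict[str, KernelSet] | None = None
    amplitude_rules: dict = field(default_factory=default_amplitude_rules)
    amp_jitter_sd: float = 0.2
    coupling: Coupling = field(default_factory=Coupling)
    intrinsic_sd: float = 0.3
    intrinsic_cutoff: float = 2.0
    noise_sd: float = 0.05
    drift_amp: float = 0.0
    drift_freqs: tuple[float, ...] = (0.003, 0.007)
    carriers: tuple[float, float] | None = None
    carrier_offset: float = 2.0
    baseline_offset: float = 0.0

    def get_kernels(self, channel: str) -> KernelSet:
        if self.kernels is not None and channel in self.kernels:
            return self.kernels[channel]
        return default_kernels(channel, fs=self.fs)


def _event_gain(rules: dict, channel: str, event: str, reward: int,
                history_label: str) -> float:
    ev = rules.get(channel, {}).get(event, {})
    g = ev.get("rewarded" if reward else "unrewarded", 1.0)
    if history_label:
        g *= ev.get(history_label, 1.0)
    return g


def _smooth_noise(rng, n, fs, sd, cutoff):
    if sd == 0:
        return np.zeros(n)
    x = rng.standard_normal(n)
    if cutoff < fs / 2:
        sos = sps.butter(2, cutoff, fs=fs, output="sos")
        x = sps.sosfiltfilt(sos, x)
    s = x.std()
    return x * (sd / s) if s > 0 else x


def _channel_clean(trials, spec, kernels, rng, channel):
    n = int(round((trials["t_side_exit"].max() + 3.0) * spec.fs))
    clean = np.zeros(n)
    lag0 = int(round(kernels.lags[0] * spec.fs))
    for row in trials.itertuples(index=False):
        occ: list[tuple[str, float]] = [
            (ev, getattr(row, col)) for ev, col in EVENT_TIME_COLS.items()
        ]
        occ += [("lick", t) for t in row.lick_times]
        if row.reward:
            occ.append(("reward", row.t_side_entry))
        for ev, t in occ:
            k = kernels.coefs.get(ev)
            if k is None:
                continue
            gain = _event_gain(
                spec.amplitude_rules, channel, ev, row.reward, row.history_label
            )
            amp = gain * (1.0 + spec.amp_jitter_sd * rng.standard_normal())
            i0 = int(round(t * spec.fs)) + lag0
            a, b = max(i0, 0), min(i0 + len(k), n)
            if b > a:
                clean[a:b] += amp * k[a - i0 : b - i0]
    clean += _smooth_noise(rng, n, spec.fs, spec.intrinsic_sd, spec.intrinsic_cutoff)
    return clean


def _drift(rng, n, fs, spec):
    if spec.drift_amp == 0:
        return np.zeros(n)
    t = np.arange(n) / fs
    out = np.zeros(n)
    for f in spec.drift_freqs:
        out += np.sin(2 * np.pi * f * t + rng.uniform(0, 2 * np.pi))
    return spec.drift_amp * out / max(len(spec.drift_freqs), 1)


def synthesize_traces(
    events: pd.DataFrame,
    trials: pd.DataFrame,
    spec: GeneratorSpec,
    seed: int,
) -> tuple[PhotometryTrace, PhotometryTrace, dict]:
    """Generate DA and Ach traces for a session plus the ground truth.

    Returns ``(da, ach, truth)`` where ``truth`` holds the kernel sets, the
    coupling parameters (including the lag snapped to the sample grid) and
    the gate placement.  Deterministic given ``seed`` (independent substreams
    per channel and for the observation noise).
    """
    spec.coupling.validate()
    ss = np.random.SeedSequence(seed).spawn(4)
    rng_da, rng_ach, rng_noise, rng_drift = (np.random.default_rng(s) for s in ss)

    kda = spec.get_kernels("da")
    kach = spec.get_kernels("ach")
    da_clean = _channel_clean(trials, spec, kda, rng_da, "da")
    ach_own = _channel_clean(trials, spec, kach, rng_ach, "ach")
    n = len(da_clean)

    cp = spec.coupling
    d = cp.lag * spec.fs
    d_samples = int(round(d))
    if abs(d - d_samples) > 1e-6:
        warnings.warn(
            f"coupling lag {cp.lag} s is not a multiple of the sample period; "
            f"rounded to {d_samples / spec.fs:.4f} s"
        )
    gate = np.full(n, cp.gain)
    if cp.gate_event is not None and cp.gate_window is not None:
        col = EVENT_TIME_COLS[cp.gate_event]
        a, b = cp.gate_window
        for te in trials[col]:
            i0 = max(int(round((te + a) * spec.fs)), 0)
            i1 = min(int(round((te + b) * spec.fs)), n)
            gate[i0:i1] = 0.0

    noise_da = spec.noise_sd * rng_noise.standard_normal(n)
    src = da_clean + noise_da if cp.couple_to_noisy else da_clean
    shifted = np.zeros(n)
    if d_samples < n:
        shifted[d_samples:] = src[: n - d_samples]
    if cp.divisive:
        ach_clean = ach_own * np.exp(-gate * shifted)
    else:
        ach_clean = ach_own - gate * shifted

    da_vals = (
        da_clean + noise_da + _drift(rng_drift, n, spec.fs, spec)
        + spec.baseline_offset
    )
    ach_vals = (
        ach_clean + spec.noise_sd * rng_noise.standard_normal(n)
        + _drift(rng_drift, n, spec.fs, spec) + spec.baseline_offset
    )
    da = PhotometryTrace(da_vals, spec.fs, channel="da", units="raw")
    ach = PhotometryTrace(ach_vals, spec.fs, channel="ach", units="raw")
    truth = {
        "kernels": {"da": kda, "ach": kach},
        "coupling": {
            "gain": cp.gain,
            "lag_s": d_samples / spec.fs,
            "lag_samples": d_samples,
            "gate_event": cp.gate_event,
            "gate_window": cp.gate_window,
        },
    }
    return da, ach, truth


def modulate_carriers(
    trace_a: PhotometryTrace, trace_b: PhotometryTrace, spec: GeneratorSpec
) -> PhotometryTrace:
    """Frequency-multiplex two envelopes onto sinusoidal carriers.

    ``raw(t) = (B + a(t)) sin(2 pi f_A t) + (B + b(t)) sin(2 pi f_B t)`` with
    a positive offset ``B`` keeping both envelopes non-negative.
    """
    if spec.carriers is None:
        raise ValueError("GeneratorSpec.carriers is not set")
    f_a, f_b = spec.carriers
    if trace_a.fs != trace_b.fs or len(trace_a.values) != len(trace_b.values):
        raise ValueError("envelope traces must share sampling grid")
    if trace_a.fs <= 2 * max(f_a, f_b):
        raise ValueError("sampling rate violates Nyquist for the carriers")
    off = spec.carrier_offset
    for tr in (trace_a, trace_b):
        if (off + tr.values).min() < 0:
            raise ValueError("envelope excursion below -carrier_offset")
    t = trace_a.times
    raw = (off + trace_a.values) * np.sin(2 * np.pi * f_a * t) + (
        off + trace_b.values
    ) * np.sin(2 * np.pi * f_b * t)
    return PhotometryTrace(raw, trace_a.fs, channel="raw", units="raw", t0=trace_a.t0)
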