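import numpy as np
import pytest

from achda.preprocess import PhotometryTrace
from achda.synth import (
    Coupling,
    GeneratorSpec,
    KernelSet,
    default_kernels,
    modulate_carriers,
    synthesize_traces,
)
from achda.task import events_from_trials
import pandas as pd

FS = 2.0 / 0.054


def one_trial_table(reward=1, t0=5.0):
    return pd.DataFrame(
        [dict(trial=0, choice=1, reward=reward, high_port=1, block_id=0,
              trials_from_block_switch=0, t_centre_entry=t0,
              t_centre_exit=t0 + 0.2, t_side_entry=t0 + 0.7,
              t_side_exit=t0 + 2.0, lick_times=[], history_label="")]
    )


def silent_spec(**kwargs):
    base = dict(
        fs=FS, amplitude_rules={}, amp_jitter_sd=0.0,
        coupling=Coupling(gain=0.0), intrinsic_sd=0.0, noise_sd=0.0,
    )
    base.update(kwargs)
    return GeneratorSpec(**base)


def test_all_zero_kernels_yield_zero_traces():
    trials = one_trial_table()
    empty = {ch: KernelSet(np.array([0.0]), {}) for ch in ("da", "ach")}
    spec = silent_spec(kernels=empty)
    da, ach, _ = synthesize_traces(events_from_trials(trials), trials, spec, seed=0)
    assert np.all(da.values == 0.0)
    assert np.all(ach.values == 0.0)


def test_single_event_places_kernel_at_event_sample():
    trials = one_trial_table(reward=0)
    lags = np.arange(0, 10) / FS
    k = np.linspace(1.0, 0.1, 10)
    kernels = {
        "da": KernelSet(lags, {"side_entry": k}),
        "ach": KernelSet(np.array([0.0]), {}),
    }
    spec = silent_spec(kernels=kernels)
    da, _, _ = synthesize_traces(events_from_trials(trials), trials, spec, seed=0)
    i0 = int(round(trials.loc[0, "t_side_entry"] * FS))
    assert np.allclose(da.values[i0 : i0 + 10], k)
    other = np.delete(da.values, np.arange(i0, i0 + 10))
    assert np.all(other == 0.0)


def test_synthesis_is_linear_in_kernels(session300):
    trials, events = session300
    trials = trials.head(40)
    events = events_from_trials(trials)
    k1 = default_kernels("da", fs=FS, support=(-0.2, 0.8))
    k2 = KernelSet(k1.lags, {f: c[::-1].copy() for f, c in k1.coefs.items()})
    ksum = KernelSet(k1.lags, {f: k1.coefs[f] + k2.coefs[f] for f in k1.coefs})
    out = {}
    for name, ks in (("k1", k1), ("k2", k2), ("sum", ksum)):
        spec = silent_spec(kernels={"da": ks, "ach": KernelSet(np.array([0.0]), {})})
        da, _, _ = synthesize_traces(events, trials, spec, seed=0)
        out[name] = da.values
    assert np.allclose(out["k1"] + out["k2"], out["sum"], atol=1e-12)


def test_synthesis_deterministic_given_seed(session300):
    trials, events = session300
    trials, events = trials.head(30), events
    spec = GeneratorSpec(fs=FS)
    da1, ach1, _ = synthesize_traces(events, trials, spec, seed=11)
    da2, ach2, _ = synthesize_traces(events, trials, spec, seed=11)
    assert np.array_equal(da1.values, da2.values)
    assert np.array_equal(ach1.values, ach2.values)


def test_outcome_gain_scales_side_entry_response():
    rules = {"da": {"side_entry": {"rewarded": 1.0, "unrewarded": -1.0}}}
    lags = np.arange(0, 10) / FS
    k = np.linspace(1.0, 0.1, 10)
    kernels = {"da": KernelSet(lags, {"side_entry": k}),
               "ach": KernelSet(np.array([0.0]), {})}
    responses = {}
    for r in (0, 1):
        trials = one_trial_table(reward=r)
        spec = silent_spec(kernels=kernels, amplitude_rules=rules)
        da, _, _ = synthesize_traces(events_from_trials(trials), trials, spec, 0)
        i0 = int(round(trials.loc[0, "t_side_entry"] * FS))
        responses[r] = da.values[i0 : i0 + 10]
    assert np.allclose(responses[1], -responses[0])


def test_coupling_lag_snapped_with_warning():
    trials = one_trial_table()
    spec = silent_spec(coupling=Coupling(gain=0.5, lag=0.05))  # not a multiple
    with pytest.warns(UserWarning, match="rounded"):
        _, _, truth = synthesize_traces(events_from_trials(trials), trials, spec, 0)
    assert truth["coupling"]["lag_samples"] == round(0.05 * FS)


def test_coupling_subtracts_shifted_da():
    trials = one_trial_table(reward=0)
    lags = np.arange(0, 10) / FS
    k = np.linspace(1.0, 0.1, 10)
    kernels = {"da": KernelSet(lags, {"side_entry": k}),
               "ach": KernelSet(np.array([0.0]), {})}
    d = 4  # samples
    spec = silent_spec(kernels=kernels, coupling=Coupling(gain=0.5, lag=d / FS))
    da, ach, _ = synthesize_traces(events_from_trials(trials), trials, spec, 0)
    assert np.allclose(ach.values[d:], -0.5 * da.values[:-d])


def test_two_tone_spectrum_has_only_carrier_lines():
    fs, dur = 2000.0, 1.0
    n = int(fs * dur)
    const = PhotometryTrace(np.zeros(n), fs)
    spec = GeneratorSpec(carriers=(167.0, 223.0), carrier_offset=1.0)
    raw = modulate_carriers(const, const, spec)
    power = np.abs(np.fft.rfft(raw.values)) ** 2
    carrier_power = power[167] + power[223]
    assert carrier_power / power.sum() > 1 - 1e-9


def test_modulation_rejects_negative_envelope():
    fs = 2000.0
    tr = PhotometryTrace(np.full(1000, -3.0), fs)
    spec = GeneratorSpec(carriers=(167.0, 223.0), carrier_offset=2.0)
    with pytest.raises(ValueError, match="envelope"):
        modulate_carriers(tr, tr, spec)


def test_modulation_respects_nyquist():
    tr = PhotometryTrace(np.zeros(100), fs=300.0)
    spec = GeneratorSpec(carriers=(167.0, 223.0))
    with pytest.raises(ValueError, match="Nyquist"):
        modulate_carriers(tr, tr, spec)
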