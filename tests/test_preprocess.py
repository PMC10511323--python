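import numpy as np
import pandas as pd
import pytest

from achda.preprocess import (
    PhotometryTrace,
    align_trials,
    demodulate,
    dff,
    sweep_baseline_subtract,
    zscore_session,
)
from achda.synth import GeneratorSpec, KernelSet, synthesize_traces
from achda.task import events_from_trials
from tests.conftest import make_tensor
from tests.test_synth import one_trial_table, silent_spec, FS


# ---------------------------------------------------------------------------
# demodulation

def test_pure_tone_demodulates_to_its_amplitude():
    fs, f, A = 2000.0, 167.0, 1.7
    t = np.arange(int(5 * fs)) / fs
    raw = PhotometryTrace(A * np.sin(2 * np.pi * f * t), fs)
    out = demodulate(raw, f)
    interior = out.values[int(fs) : -int(fs)]
    assert np.allclose(interior, A, rtol=1e-3)


def test_zero_input_gives_zero_output():
    raw = PhotometryTrace(np.zeros(4000), 2000.0)
    assert np.allclose(demodulate(raw, 167.0).values, 0.0)


def test_demodulation_rejects_bad_frequencies():
    raw = PhotometryTrace(np.zeros(1000), 300.0)
    with pytest.raises(ValueError, match="Nyquist"):
        demodulate(raw, 167.0)
    raw2 = PhotometryTrace(np.zeros(1000), 2000.0)
    with pytest.raises(ValueError, match="cutoff"):
        demodulate(raw2, 167.0, lowpass_cutoff=200.0)


def test_two_tone_crosstalk_is_small():
    fs = 2000.0
    t = np.arange(int(10 * fs)) / fs
    env_b = 1.0 + 0.5 * np.sin(2 * np.pi * 3.0 * t)
    raw = PhotometryTrace(
        1.0 * np.sin(2 * np.pi * 167.0 * t) + env_b * np.sin(2 * np.pi * 223.0 * t),
        fs,
    )
    out = demodulate(raw, 167.0).values[int(fs) : -int(fs)]
    crosstalk = out.std() / env_b.std()
    assert crosstalk < 0.01


# ---------------------------------------------------------------------------
# dF/F and z-score

def test_dff_constant_trace_is_zero():
    tr = PhotometryTrace(np.full(2000, 3.3), 100.0)
    assert np.allclose(dff(tr).values, 0.0)


def test_dff_single_sample_arithmetic():
    vals = np.ones(100)
    vals[50] = 1.1
    out = dff(PhotometryTrace(vals, 10.0), baseline_mode="constant", f0=1.0)
    assert out.values[50] == pytest.approx(0.1)
    assert out.values[0] == 0.0


def test_dff_rejects_nonpositive_baseline():
    with pytest.raises(ValueError, match="non-positive"):
        dff(PhotometryTrace(np.zeros(100), 10.0), baseline_mode="constant", f0=-1.0)


def test_dff_refuses_normalised_input():
    tr = zscore_session(PhotometryTrace(np.random.default_rng(0).normal(5, 1, 100), 10.0))
    with pytest.raises(ValueError, match="units"):
        dff(tr)


def test_running_percentile_dff_restores_amplitudes_under_drift():
    """Multiplicative slow drift is divided out: recovered event amplitudes
    stay within 5% of the drift-free truth."""
    fs = 50.0
    t = np.arange(int(900 * fs)) / fs
    drift = 1.0 + 0.2 * np.sin(2 * np.pi * 0.001 * t)
    bump_times = np.arange(10, 890, 10.0)
    bumps = np.zeros_like(t)
    for bt in bump_times:
        bumps += 0.5 * np.exp(-0.5 * ((t - bt) / 0.3) ** 2)
    raw = PhotometryTrace(drift * (1.0 + bumps), fs)
    out = dff(raw, window_s=30.0, percentile=10.0)
    peaks = [out.values[int(bt * fs)] for bt in bump_times[2:-2]]
    assert np.allclose(peaks, 0.5, rtol=0.05)


def test_zscore_properties():
    rng = np.random.default_rng(1)
    x = rng.normal(3.0, 2.0, 5000)
    z = zscore_session(PhotometryTrace(x, 100.0))
    assert z.values.mean() == pytest.approx(0.0, abs=1e-12)
    assert z.values.std() == pytest.approx(1.0, abs=1e-12)
    z2 = zscore_session(PhotometryTrace(5.0 * x - 2.0, 100.0))
    assert np.allclose(z.values, z2.values)
    assert np.allclose(zscore_session(z).values, z.values)
    assert z.units == "zscore"
    with pytest.raises(ValueError):
        zscore_session(PhotometryTrace(np.ones(10), 1.0))


# ---------------------------------------------------------------------------
# alignment

def test_align_bin_count_follows_contract(session300):
    trials, _ = session300
    trace = PhotometryTrace(np.zeros(int(trials["t_side_exit"].max() * FS) + 200), FS)
    tensor = align_trials(trace, trials, "side_entry", (1.0, 2.0), bin_width=0.054)
    assert tensor.n_bins == round(3.0 / 0.054)  # 56


def test_align_impulse_lands_in_time_zero_bin(session300):
    trials, _ = session300
    n = int(trials["t_side_exit"].max() * FS) + 200
    vals = np.zeros(n)
    idx = np.round(trials["t_side_entry"].to_numpy() * FS).astype(int)
    vals[idx] = 1.0
    tensor = align_trials(PhotometryTrace(vals, FS), trials, "side_entry", (1.0, 2.0))
    zero_bin = int(np.argmin(np.abs(tensor.bin_centers)))
    col = tensor.data[:, zero_bin]
    assert np.all(col > 0)
    others = np.delete(tensor.data, zero_bin, axis=1)
    assert others.sum() <= len(trials)  # at most neighbouring-event impulses


def test_alignment_conserves_signal_mass(session300):
    trials, _ = session300
    rng = np.random.default_rng(3)
    n = int(trials["t_side_exit"].max() * FS) + 200
    trace = PhotometryTrace(rng.normal(size=n), FS)
    tensor = align_trials(trace, trials, "side_entry", (1.0, 2.0))
    k = round(0.054 * FS)
    for row_i, trial_idx in list(enumerate(tensor.trial_index))[:10]:
        te = trials.loc[trial_idx, "t_side_entry"]
        i0 = int(round(te * FS)) - round(1.0 * FS)
        seg = trace.values[i0 : i0 + tensor.n_bins * k]
        assert tensor.data[row_i].sum() * k == pytest.approx(seg.sum(), rel=1e-9)


def test_edge_trials_are_dropped_not_padded(session300):
    trials, _ = session300
    short = PhotometryTrace(np.zeros(int(trials["t_side_entry"].iloc[5] * FS)), FS)
    tensor = align_trials(short, trials, "side_entry", (1.0, 2.0))
    assert len(tensor.dropped) > 0
    assert tensor.n_trials + len(tensor.dropped) == len(trials)


def test_trial_average_recovers_kernel():
    """With noise off and a single causal side-entry kernel, the
    trial-averaged tensor equals the binned kernel."""
    trials = pd.concat([one_trial_table(reward=0, t0=5.0 + 6.0 * i) for i in range(20)],
                       ignore_index=True)
    trials["trial"] = np.arange(len(trials))
    lags = np.arange(0, 38) / FS
    k = np.exp(-lags / 0.3)
    kernels = {"da": KernelSet(lags, {"side_entry": k}),
               "ach": KernelSet(np.array([0.0]), {})}
    da, _, _ = synthesize_traces(
        events_from_trials(trials), trials, silent_spec(kernels=kernels), 0
    )
    # pre = 19 whole bins so the kernel start coincides with a bin edge
    tensor = align_trials(da, trials, "side_entry", (19 * 0.054, 2.0))
    avg = tensor.data.mean(axis=0)
    binned_kernel = k.reshape(-1, 2).mean(axis=1)  # 2 samples per bin
    got = avg[19 : 19 + len(binned_kernel)]
    assert np.allclose(got, binned_kernel, atol=1e-9)


# ---------------------------------------------------------------------------
# sweep baseline

def test_sweep_baseline_trivials():
    tensor = make_tensor(np.full((5, 20), 2.5))
    out = sweep_baseline_subtract(tensor, (-0.3, 0.0))
    assert np.allclose(out.data, 0.0)
    rng = np.random.default_rng(0)
    data = rng.normal(size=(6, 20))
    t1 = sweep_baseline_subtract(make_tensor(data), (-0.3, 0.0))
    t2 = sweep_baseline_subtract(make_tensor(data + 7.0), (-0.3, 0.0))
    assert np.allclose(t1.data, t2.data)


def test_sweep_baseline_recovers_step_height():
    rng = np.random.default_rng(1)
    n_sweeps, n_bins = 20, 40
    data = rng.normal(0, 0.2, (n_sweeps, n_bins)) + 1.0
    data[:, n_bins // 2 :] += 0.8  # step after stimulation
    tensor = make_tensor(data)
    out = sweep_baseline_subtract(tensor, (tensor.bin_centers[0], 0.0))
    post = out.data[:, n_bins // 2 :].mean()
    se = 0.2 / np.sqrt(n_sweeps * n_bins // 2)
    assert abs(post - 0.8) < 4 * se
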