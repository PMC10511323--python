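"""Synthetic validation studies.

Each function here runs one end-to-end validation of the analysis stack on
generator data with known ground truth, at fixed study conditions, and
returns the measured quantities.  They are shared by the test suite, the
acceptance script and the numbered analysis drivers so that every reported
number is recomputed from scratch.

Study conditions (trial counts, noise levels, gains) are part of the study
definitions; see docs/methods.md for the rationale behind each.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import signal as sps

from . import covariance as cov
from . import glm as glm_mod
from .agents import AgentParams, RandomAgent, RFLRAgent
from .preprocess import BIN_WIDTH, PhotometryTrace, align_trials, demodulate
from .rflr import block_transition_summary, fit_rflr
from .synth import (
    Coupling,
    GeneratorSpec,
    KernelSet,
    default_kernels,
    modulate_carriers,
    synthesize_traces,
)
from .task import TaskConfig, simulate_session
from .trial_stats import (
    delta_signal,
    group_compare,
    lda_classify,
    lda_permutation_null,
    mean_signal,
)

GEN_FS = 2.0 / BIN_WIDTH  # two samples per analysis bin


def _seeds(seed: int, n: int) -> list[int]:
    return [int(s) for s in
            np.random.SeedSequence(seed).generate_state(n) % (2**31)]


# ---------------------------------------------------------------------------
# GLM studies

def _recovery_kernels(channel: str = "da") -> KernelSet:
    """Kernels confined to the GLM's +-T*bin lag window so that recovery is
    well-posed (a kernel extending past the window cannot be estimated)."""
    return default_kernels(channel, fs=GEN_FS, support=(-0.5, 1.05))


def glm_kernel_recovery(seed: int, n_trials: int = 300,
                        noise_sd: float = 0.1, n_runs: int = 3) -> dict:
    """OLS kernel recovery: six event features, uniform amplitudes, white
    observation noise.  Reports kernel RMSE as a fraction of the largest
    ground-truth kernel amplitude."""
    s_task, s_gen, s_fit = _seeds(seed, 3)
    trials, events = simulate_session(
        TaskConfig(n_trials=n_trials), RFLRAgent(AgentParams()), s_task
    )
    spec = GeneratorSpec(
        fs=GEN_FS, kernels={"da": _recovery_kernels()}, amplitude_rules={},
        amp_jitter_sd=0.0, coupling=Coupling(gain=0.0), intrinsic_sd=0.0,
        noise_sd=noise_sd,
    )
    da, _, truth = synthesize_traces(events, trials, spec, s_gen)
    cfg = glm_mod.GLMConfig(method="ols", n_runs=n_runs)
    design = glm_mod.build_design(events, trials, cfg, response=da)
    result = glm_mod.run_protocol(design, cfg, s_fit)
    kmean, _ = glm_mod.extract_kernels(result)
    kt = truth["kernels"]["da"]
    errs = [
        kmean.coefs[f] - np.interp(kmean.lags, kt.lags, kt.coefs[f], left=0, right=0)
        for f in design.features
    ]
    rmse = float(np.sqrt(np.mean(np.concatenate(errs) ** 2)))
    peak = kt.max_amplitude()
    return {
        "rmse": rmse,
        "peak_amplitude": peak,
        "rmse_pct_of_peak": 100 * rmse / peak,
        "test_r2": result.test_r2,
        "n_trials": n_trials,
    }


def glm_leave_out(seed: int, n_trials: int = 250, n_runs: int = 10) -> dict:
    """Leave-one-feature-out fidelity: the generator gives the lick kernel
    zero amplitude and triples the side-entry kernel, so dropping lick must
    be inert and dropping side entry must hurt the most."""
    s_task, s_gen, s_fit = _seeds(seed, 3)
    trials, events = simulate_session(
        TaskConfig(n_trials=n_trials), RFLRAgent(AgentParams()), s_task
    )
    kd = _recovery_kernels()
    kd.coefs["lick"][:] = 0.0
    kd.coefs["side_entry"] = kd.coefs["side_entry"] * 3.0
    spec = GeneratorSpec(
        fs=GEN_FS, kernels={"da": kd}, amplitude_rules={}, amp_jitter_sd=0.0,
        coupling=Coupling(gain=0.0), intrinsic_sd=0.0, noise_sd=0.1,
    )
    da, _, _ = synthesize_traces(events, trials, spec, s_gen)
    cfg = glm_mod.GLMConfig(method="ols", n_runs=n_runs)
    design = glm_mod.build_design(events, trials, cfg, response=da)
    table = glm_mod.leave_out_analysis(design, cfg, s_fit)
    by = table.set_index("feature")
    return {
        "table": table,
        "cv_noise_band": table.attrs["cv_noise_band"],
        "delta_zero_feature": float(by.loc["lick", "delta_val_mse"]),
        "delta_dominant": float(by.loc["side_entry", "delta_val_mse"]),
        "largest_feature": str(table.loc[table["delta_val_mse"].idxmax(), "feature"]),
        "zero_feature": "lick",
        "dominant_feature": "side_entry",
        "n_trials": n_trials,
    }


HISTORY_GAINS = {
    "stay_win_win": 1.0,
    "stay_win_lose": 1.6,
    "stay_lose_win": 1.8,
    "stay_lose_lose": 0.6,
    "switch_win_win": 1.3,
    "switch_win_lose": 0.5,
    "switch_lose_win": 1.5,
    "switch_lose_lose": 0.8,
}


def glm_history(seed: int, n_trials: int = 300, n_runs: int = 3) -> dict:
    """History-GLM discrimination: with history-dependent side-entry gains
    the history variant must lower test MSE; with none it must not change it
    beyond the CV noise band (no overfitting from the extra parameters)."""
    s_task, s_gen, s_fit = _seeds(seed, 3)
    trials, events = simulate_session(
        TaskConfig(n_trials=n_trials), RFLRAgent(AgentParams()), s_task
    )
    out = {"n_trials": n_trials}
    for label, rules in (
        ("with_history", {"da": {"side_entry": dict(HISTORY_GAINS)}}),
        ("no_history", {}),
    ):
        spec = GeneratorSpec(
            fs=GEN_FS, kernels={"da": _recovery_kernels()},
            amplitude_rules=rules, amp_jitter_sd=0.0,
            coupling=Coupling(gain=0.0), intrinsic_sd=0.0, noise_sd=0.1,
        )
        da, _, _ = synthesize_traces(events, trials, spec, s_gen)
        cfg = glm_mod.GLMConfig(method="ols", n_runs=n_runs)
        base = glm_mod.run_protocol(
            glm_mod.build_design(events, trials, cfg, response=da, variant="base"),
            cfg, s_fit,
        )
        hist = glm_mod.run_protocol(
            glm_mod.build_design(events, trials, cfg, response=da, variant="history"),
            cfg, s_fit,
        )
        out[label] = {
            "base_test_mse": base.test_mse,
            "history_test_mse": hist.test_mse,
            "reduction": base.test_mse - hist.test_mse,
            "cv_noise_band": base.cv_noise_band,
        }
    return out


# ---------------------------------------------------------------------------
# covariance studies

def stationary_spec(gain: float, lag: float,
                    gate: tuple[str, tuple[float, float]] | None = None) -> GeneratorSpec:
    """Generator configuration for covariance validation: no event kernels,
    so both channels are stationary band-limited fluctuations plus white
    noise, linked only by the lagged coupling.  Cross-covariance analysis
    assumes stationarity; event-locked variance breaks the exchangeability
    of the circular-shift null (see docs/methods.md)."""
    empty = {ch: KernelSet(np.array([0.0]), {}) for ch in ("da", "ach")}
    coupling = Coupling(gain=gain, lag=lag)
    if gate is not None:
        coupling.gate_event, coupling.gate_window = gate
    return GeneratorSpec(
        fs=GEN_FS, kernels=empty, amplitude_rules={}, amp_jitter_sd=0.0,
        coupling=coupling, intrinsic_sd=0.3, noise_sd=0.1,
    )


def coupling_lag_recovery(seed: int, lag: float, gain: float = 0.5,
                          n_trials: int = 500, max_lag: float = 0.3,
                          n_perm: int = 300) -> dict:
    """Recover the DA->Ach coupling delay from noise-mode cross-covariance
    and the off-diagonal of K(t1, t2), against a circular-shift null."""
    s_task, s_gen, s_null = _seeds(seed, 3)
    trials, events = simulate_session(
        TaskConfig(n_trials=n_trials), RFLRAgent(AgentParams()), s_task
    )
    da, ach, truth = synthesize_traces(
        events, trials, stationary_spec(gain, lag), s_gen
    )
    window = (1.0, 2.0)
    A = align_trials(da, trials, "side_entry", window)
    B = align_trials(ach, trials, "side_entry", window)
    reward = trials.loc[A.trial_index, "reward"].to_numpy()
    curve = cov.crosscov_lagged(A, B, max_lag, mode="noise", conditions=reward)
    lags, lo, hi = cov.null_controls(
        A, B, max_lag, mode="circular_shift", conditions=reward,
        n_perm=n_perm, seed=s_null, band="simultaneous",
    )
    i_min = int(np.argmin(curve.values))
    snapped = round(lag / A.bin_width) * A.bin_width
    K = cov.cov_matrix(A, B, mode="noise", conditions=reward)
    _, od = cov.off_diagonal(K, snapped, band_halfwidth=A.bin_width)
    return {
        "true_lag_s": truth["coupling"]["lag_s"],
        "snapped_lag_s": float(snapped),
        "recovered_lag_s": curve.argmin_lag_s,
        "min_cov": float(curve.values[i_min]),
        "min_outside_null": bool(curve.values[i_min] < lo[i_min]),
        "all_inside_null": bool(
            np.all((curve.values >= lo) & (curve.values <= hi))
        ),
        "offdiag_mean": float(np.nanmean(od)),
        "n_trials": n_trials,
    }


def gated_coupling(seed: int, gain: float = 0.5, lag: float = 0.108,
                   n_trials: int = 500,
                   gate_window: tuple[float, float] = (0.0, 1.0)) -> dict:
    """Time-varying coupling: g(t) is zeroed inside a post-side-entry epoch;
    the off-diagonal trace of K(t1, t2) must collapse there."""
    s_task, s_gen = _seeds(seed, 2)
    trials, events = simulate_session(
        TaskConfig(n_trials=n_trials), RFLRAgent(AgentParams()), s_task
    )
    spec = stationary_spec(gain, lag, gate=("side_entry", gate_window))
    da, ach, truth = synthesize_traces(events, trials, spec, s_gen)
    window = (1.0, 2.0)
    A = align_trials(da, trials, "side_entry", window)
    B = align_trials(ach, trials, "side_entry", window)
    reward = trials.loc[A.trial_index, "reward"].to_numpy()
    K = cov.cov_matrix(A, B, mode="noise", conditions=reward)
    snapped = truth["coupling"]["lag_s"]
    t1, od = cov.off_diagonal(K, snapped, band_halfwidth=A.bin_width)
    # the off-diagonal at t1 probes the gate state at t2 = t1 + lag
    margin = 3 * A.bin_width
    inside = (t1 + snapped >= gate_window[0] + margin) & (
        t1 + snapped <= gate_window[1] - margin
    )
    outside = (t1 + snapped <= gate_window[0] - margin) | (
        t1 + snapped >= gate_window[1] + margin
    )
    inside_abs = float(np.nanmean(np.abs(od[inside])))
    outside_abs = float(np.nanmean(np.abs(od[outside])))
    return {
        "inside_abs": inside_abs,
        "outside_abs": outside_abs,
        "ratio": inside_abs / outside_abs,
        "outside_mean": float(np.nanmean(od[outside])),
        "n_trials": n_trials,
    }


# ---------------------------------------------------------------------------
# behavioural studies

def rflr_recovery(seed: int, n_trials: int = 10_000,
                  truth: AgentParams | None = None) -> dict:
    """Parameter recovery of the RFLR agent plus the null check that a
    choice-randomised agent yields an evidence weight indistinguishable
    from zero."""
    truth = truth or AgentParams(alpha=1.0, beta=2.0, tau=1.5)
    s_task, s_null = _seeds(seed, 2)
    trials, _ = simulate_session(
        TaskConfig(n_trials=n_trials), RFLRAgent(truth), s_task
    )
    fit = fit_rflr(trials)
    rnd, _ = simulate_session(TaskConfig(n_trials=5_000), RandomAgent(), s_null)
    null_fit = fit_rflr(rnd)
    p = fit.params
    return {
        "alpha_hat": p.alpha,
        "beta_hat": p.beta,
        "tau_hat": p.tau,
        "alpha_err_pct": 100 * abs(p.alpha - truth.alpha) / abs(truth.alpha),
        "beta_err_pct": 100 * abs(p.beta - truth.beta) / abs(truth.beta),
        "tau_err_pct": 100 * abs(p.tau - truth.tau) / truth.tau,
        "z_beta_random": null_fit.z_values["beta"],
        "log_likelihood": fit.log_likelihood,
        "n_trials": n_trials,
    }


def behaviour_dynamics(seed: int, n_trials: int = 40_000, window: int = 8) -> dict:
    """Block-transition dynamics of an RFLR agent: P(high port) must rise
    over the first post-switch trials and P(switch) must peak just after the
    transition.  40k trials (~1,000 transitions) resolve the location of the
    P(switch) peak against its shallow plateau."""
    (s_task,) = _seeds(seed, 1)
    trials, _ = simulate_session(
        TaskConfig(n_trials=n_trials), RFLRAgent(AgentParams()), s_task
    )
    summary = block_transition_summary(trials, window=window)
    post = summary[summary["offset"].between(0, 4)].sort_values("offset")
    p_high = post["p_high"].to_numpy()
    peak_offset = int(summary.loc[summary["p_switch"].idxmax(), "offset"])
    return {
        "summary": summary,
        "p_high_post": p_high,
        "p_high_monotone": bool(np.all(np.diff(p_high) > 0)),
        "switch_peak_offset": peak_offset,
        "n_trials": n_trials,
    }


# ---------------------------------------------------------------------------
# demodulation study

def band_limited_envelope(rng: np.random.Generator, n: int, fs: float,
                          cutoff: float = 8.0, sd: float = 0.3) -> np.ndarray:
    pad = int(4 * fs)
    x = rng.standard_normal(n + 2 * pad)
    sos = sps.butter(4, cutoff, fs=fs, output="sos")
    e = sps.sosfiltfilt(sos, x)[pad:-pad]
    return e / e.std() * sd


def demodulation_roundtrip(seed: int, duration: float = 60.0,
                           fs: float = 2000.0,
                           carriers: tuple[float, float] = (167.0, 223.0)) -> dict:
    """Modulate band-limited envelopes onto the two carriers, demodulate,
    and measure envelope fidelity and cross-channel crosstalk."""
    rng = np.random.default_rng(_seeds(seed, 1)[0])
    n = int(duration * fs)
    ea = band_limited_envelope(rng, n, fs)
    eb = band_limited_envelope(rng, n, fs)
    spec = GeneratorSpec(carriers=carriers, carrier_offset=2.0)
    raw = modulate_carriers(
        PhotometryTrace(ea, fs, channel="da"),
        PhotometryTrace(eb, fs, channel="ach"),
        spec,
    )
    sl = slice(int(2 * fs), int((duration - 2) * fs))  # skip filter edges
    da = demodulate(raw, carriers[0])
    db = demodulate(raw, carriers[1])
    corr_a = float(np.corrcoef(da.values[sl], ea[sl])[0, 1])
    corr_b = float(np.corrcoef(db.values[sl], eb[sl])[0, 1])
    # crosstalk: channel A silent, channel B active
    raw2 = modulate_carriers(
        PhotometryTrace(np.zeros(n), fs, channel="da"),
        PhotometryTrace(eb, fs, channel="ach"),
        spec,
    )
    ct = demodulate(raw2, carriers[0]).values[sl]
    crosstalk = float(ct.std() / eb[sl].std())
    return {
        "corr_a": corr_a,
        "corr_b": corr_b,
        "crosstalk_rms_frac": crosstalk,
        "n_samples": n,
    }


# ---------------------------------------------------------------------------
# trial-metric dissociation study

def _dissociation_spec() -> GeneratorSpec:
    """Outcome-dependent amplitudes only after side entry: short causal
    side-entry-locked kernels with outcome gains, so everything before side
    entry is outcome-independent and post-trial tails have decayed before
    the next trial's pre-window."""
    kernels = {
        "da": default_kernels("da", fs=GEN_FS, support=(0.0, 0.8),
                              events=("side_entry", "reward")),
        "ach": default_kernels("ach", fs=GEN_FS, support=(0.0, 0.8),
                               events=("side_entry",)),
    }
    rules = {
        "da": {"side_entry": {"rewarded": 1.0, "unrewarded": -1.0}},
        "ach": {"side_entry": {"rewarded": 0.6, "unrewarded": 1.6}},
    }
    return GeneratorSpec(
        fs=GEN_FS, kernels=kernels, amplitude_rules=rules, amp_jitter_sd=0.15,
        coupling=Coupling(gain=0.5, lag=0.108), intrinsic_sd=0.3, noise_sd=0.1,
    )


def metric_dissociation(seed: int, n_mice: int = 8, n_trials: int = 250,
                        n_perm: int = 60) -> dict:
    """Mean-DA / delta-Ach dissociation across 8 simulated mice plus the
    pre/post LDA contrast against a permutation null."""
    pre_w, post_w = (-0.8, 0.0), (0.0, 0.8)
    mouse_seeds = _seeds(seed, 2 * n_mice + 2)
    spec = _dissociation_spec()
    vals: dict[str, list] = {k: [] for k in
                             ("mean_da_pre", "mean_da_post",
                              "delta_ach_pre", "delta_ach_post")}
    rewards, mice = [], []
    da_rows, ach_rows = [], []
    for m in range(n_mice):
        trials, events = simulate_session(
            TaskConfig(n_trials=n_trials), RFLRAgent(AgentParams()),
            mouse_seeds[2 * m],
        )
        da, ach, _ = synthesize_traces(events, trials, spec, mouse_seeds[2 * m + 1])
        # 19 x 54 ms pre, 28 x 54 ms post: t = 0 falls on a bin edge, so no
        # bin straddles side entry and the pre-window is strictly pre-event
        win = (19 * BIN_WIDTH, 28 * BIN_WIDTH)
        A = align_trials(da, trials, "side_entry", win)
        B = align_trials(ach, trials, "side_entry", win)
        r = trials.loc[A.trial_index, "reward"].to_numpy()
        vals["mean_da_pre"].append(mean_signal(A, pre_w))
        vals["mean_da_post"].append(mean_signal(A, post_w))
        vals["delta_ach_pre"].append(delta_signal(B, pre_w))
        vals["delta_ach_post"].append(delta_signal(B, post_w))
        rewards.append(r)
        mice.append(np.full(len(r), m))
        da_rows.append(A)
        ach_rows.append(B)

    reward = np.concatenate(rewards)
    mouse = np.concatenate(mice)
    out: dict = {"n_mice": n_mice, "n_trials_per_mouse": n_trials}
    for key in vals:
        res = group_compare(
            np.concatenate(vals[key]), reward, mouse, metric=key
        )
        out[f"p_{key}"] = res.p_value
        out[f"t_{key}"] = res.statistic

    # pooled LDA on the DA waveform, balanced classes
    from dataclasses import replace as _replace

    pooled = _replace(
        da_rows[0],
        data=np.vstack([t.data for t in da_rows]),
        trial_index=np.arange(len(reward)),
    )
    s_lda, s_perm = mouse_seeds[-2], mouse_seeds[-1]
    for name, w in (("pre", pre_w), ("post", post_w)):
        res = lda_classify(pooled, reward, w, seed=s_lda, balance=True)
        null = lda_permutation_null(
            pooled, reward, w, n_perm=n_perm, seed=s_perm, balance=True
        )
        lo, hi = np.percentile(null, [2.5, 97.5])
        out[f"lda_{name}_accuracy"] = res.mean_accuracy
        out[f"lda_{name}_null_low"] = float(lo)
        out[f"lda_{name}_null_high"] = float(hi)
        out[f"lda_{name}_above_null"] = bool(res.mean_accuracy > hi)
        out[f"lda_{name}_inside_null"] = bool(lo <= res.mean_accuracy <= hi)
    return out
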