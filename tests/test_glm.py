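import numpy as np
import pandas as pd
import pytest

from achda import glm as G
from achda.preprocess import PhotometryTrace
from achda.synth import GeneratorSpec, KernelSet, default_kernels, synthesize_traces
from achda.task import events_from_trials
from tests.test_synth import FS, silent_spec


@pytest.fixture(scope="module")
def small_design(session300):
    trials, events = session300
    trials = trials.head(120).copy()
    events = events_from_trials(trials)
    spec = silent_spec(
        kernels={"da": default_kernels("da", fs=FS, support=(-0.5, 1.05)),
                 "ach": KernelSet(np.array([0.0]), {})},
        noise_sd=0.1,
    )
    da, _, truth = synthesize_traces(events, trials, spec, seed=9)
    cfg = G.GLMConfig(method="ols", n_runs=2)
    design = G.build_design(events, trials, cfg, response=da)
    return design, cfg, truth


def test_design_has_expected_column_count(small_design):
    design, cfg, _ = small_design
    assert design.X.shape[1] == 6 * (2 * 20 + 1) == 246
    assert len(design.columns) == 246
    assert design.X.shape[0] == len(design.y)


def test_shifted_column_structure(session300):
    """A single event occurrence at bin b puts a 1 in column (f, l) exactly
    at row bin b + l."""
    trials, _ = session300
    trials = trials.head(3).copy()
    events = events_from_trials(trials)
    cfg = G.GLMConfig(T=4)
    resp = PhotometryTrace(np.zeros(int(trials["t_side_exit"].max() * FS) + 100), FS)
    design = G.build_design(events, trials, cfg, response=resp)
    b = int(np.floor(trials.loc[1, "t_side_entry"] / cfg.bin_width))
    for lag in (-4, 0, 3):
        col = design.columns.index(("side_entry", lag))
        rows = np.flatnonzero(design.X[:, col])
        assert b + lag in design.row_bins[rows]


def test_history_columns_partition_side_entries(session300):
    trials, events = session300
    trials = trials.head(100)
    cfg = G.GLMConfig()
    resp = PhotometryTrace(np.zeros(int(trials["t_side_exit"].max() * FS) + 100), FS)
    design = G.build_design(events, trials, cfg, response=resp, variant="history")
    hist_feats = [f for f in design.features if f.startswith("side_entry:")]
    assert len(hist_feats) == 8
    lag0 = [design.columns.index((f, 0)) for f in hist_feats]
    se_bins = np.array(
        [int(np.floor(t / cfg.bin_width)) for t in trials["t_side_entry"].iloc[1:]]
    )
    sums = design.X[:, lag0].sum(axis=1)
    in_se = np.isin(design.row_bins, se_bins)
    assert np.all(sums[in_se] >= 1)  # every labelled side entry covered once
    assert np.all(sums[~np.isin(design.row_bins, se_bins)] <= 1)


def test_ols_recovers_exact_linear_response(small_design):
    design, cfg, _ = small_design
    rng = np.random.default_rng(0)
    beta_true = rng.normal(size=design.X.shape[1])
    y = design.X @ beta_true + 0.7
    d2 = G.DesignMatrix(**{**design.__dict__, "y": y})
    fit = G.fit_glm(d2, cfg)
    # the design is collinear (reward ~ side_entry); compare predictions
    assert np.allclose(fit.predict(d2.X), y, atol=1e-6)


def test_ridge_shrinkage_is_monotone(small_design):
    design, _, _ = small_design
    norms = []
    for alpha in (0.0, 1.0, 10.0, 100.0, 1000.0):
        fit = G.fit_glm(design, G.GLMConfig(method="ridge", alpha=alpha))
        norms.append(np.linalg.norm(fit.beta))
    assert all(a >= b - 1e-9 for a, b in zip(norms[:-1], norms[1:]))


def test_lasso_limit_shrinks_to_mean_prediction(small_design):
    design, _, _ = small_design
    fit = G.fit_glm(design, G.GLMConfig(method="lasso", alpha=50.0))
    assert np.allclose(fit.beta, 0.0)
    assert fit.intercept == pytest.approx(design.y.mean(), rel=1e-6)


def test_elastic_net_ridge_alpha_conversion(small_design):
    design, _, _ = small_design
    rows = np.arange(0, design.X.shape[0], 4)
    n = len(rows)
    a_enet = 0.01
    enet = G.fit_glm(design, G.GLMConfig(method="elastic_net", alpha=a_enet,
                                         l1_ratio=0.0), rows=rows)
    ridge = G.fit_glm(design, G.GLMConfig(
        method="ridge", alpha=G.enet_to_ridge_alpha(a_enet, n)), rows=rows)
    assert np.allclose(enet.beta, ridge.beta, atol=5e-4)


def test_protocol_on_noiseless_data_has_zero_errors(small_design):
    design, cfg, _ = small_design
    beta_true = np.zeros(design.X.shape[1])
    beta_true[design.columns.index(("side_entry", 2))] = 1.0
    d2 = G.DesignMatrix(**{**design.__dict__, "y": design.X @ beta_true})
    res = G.run_protocol(d2, cfg, seed=1)
    assert res.val_mse < 1e-12 and res.test_mse < 1e-12


def test_pure_noise_response_does_not_generalise(small_design):
    design, cfg, _ = small_design
    rng = np.random.default_rng(5)
    d2 = G.DesignMatrix(**{**design.__dict__, "y": rng.normal(size=len(design.y))})
    res = G.run_protocol(d2, cfg, seed=1)
    assert res.test_r2 < 0.02


def test_splits_never_divide_a_trial(small_design):
    design, cfg, _ = small_design
    rng = np.random.default_rng(3)
    train, test = G._split_rows(design, rng, 0.5)
    assert not set(design.groups[train]) & set(design.groups[test])


def test_duplicate_overlap_fraction_reported(small_design):
    design, cfg, _ = small_design
    res = G.run_protocol(design, cfg, seed=2)
    fracs = [r.dup_overlap_fraction for r in res.runs]
    assert all(0.0 <= f < 0.5 for f in fracs)
    assert design.duplicated.mean() > 0  # margins do overlap at 1 s ITI


def test_redundant_duplicate_features_are_individually_droppable(session300):
    """Two columns marking the same bins: dropping either alone leaves the
    fit unchanged (centre entry/exit redundancy)."""
    trials, _ = session300
    trials = trials.head(120).copy()
    trials["t_centre_exit"] = trials["t_centre_entry"] + 1e-6  # same bin
    events = events_from_trials(trials)
    spec = silent_spec(
        kernels={"da": default_kernels("da", fs=FS, support=(-0.3, 0.8),
                                       events=("centre_entry", "side_entry")),
                 "ach": KernelSet(np.array([0.0]), {})},
        noise_sd=0.1,
    )
    da, _, _ = synthesize_traces(events, trials, spec, seed=4)
    cfg = G.GLMConfig(method="ridge", alpha=1e-6, n_runs=3,
                      features=("centre_entry", "centre_exit", "side_entry"))
    design = G.build_design(events, trials, cfg, response=da)
    table = G.leave_out_analysis(design, cfg, seed=6).set_index("feature")
    band = 3 * max(table.attrs["cv_noise_band"], 1e-12)
    assert abs(table.loc["centre_entry", "delta_val_mse"]) < band
    assert abs(table.loc["centre_exit", "delta_val_mse"]) < band


def test_extract_kernels_shapes_and_sd(small_design):
    design, cfg, _ = small_design
    res = G.run_protocol(design, G.GLMConfig(method="ols", n_runs=1), seed=0)
    kmean, ksd = G.extract_kernels(res)
    for f in design.features:
        assert len(kmean.coefs[f]) == 2 * design.T + 1
        assert np.all(ksd.coefs[f] == 0.0)  # single run: zero spread


def test_reconstruction_r2_definitions(small_design):
    design, cfg, _ = small_design
    fit = G.fit_glm(design, cfg)
    rec = G.reconstruct(design, fit.beta, fit.intercept, n_boot=20, seed=0)
    yhat = fit.predict(design.X)
    r2_manual = 1 - np.sum((design.y - yhat) ** 2) / np.sum(
        (design.y - design.y.mean()) ** 2
    )
    assert rec.r2 == pytest.approx(r2_manual, rel=1e-12)
    zero = G.reconstruct(design, np.zeros(design.X.shape[1]), 0.0, n_boot=5)
    r2_zero = 1 - np.sum(design.y**2) / np.sum((design.y - design.y.mean()) ** 2)
    assert zero.r2 == pytest.approx(r2_zero, rel=1e-12)
    assert np.all(zero.ci_low <= zero.ci_high)


def test_config_validation():
    with pytest.raises(ValueError):
        G.GLMConfig(method="huber").validate()
    with pytest.raises(ValueError):
        G.GLMConfig(l1_ratio=1.5).validate()
    with pytest.raises(ValueError):
        G.GLMConfig(alpha=-1.0).validate()
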