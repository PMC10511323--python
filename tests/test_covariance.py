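import numpy as np
import pytest

from achda.covariance import (
    CovMatrix,
    _lag_curve_values,
    condition_mean_residuals,
    cov_matrix,
    crosscov_lagged,
    null_controls,
    off_diagonal,
)
from tests.conftest import make_tensor


def bruteforce_lag_curve(a, b, max_bins):
    """Independent oracle: explicit python loops over lags, trials, bins."""
    n_t, n_b = a.shape
    out = []
    for lag in range(-max_bins, max_bins + 1):
        acc, cnt = 0.0, 0
        for i in range(n_t):
            for t in range(n_b):
                u = t + lag
                if 0 <= u < n_b:
                    acc += a[i, t] * b[i, u]
                    cnt += 1
        out.append(acc / cnt)
    return np.array(out)


def bruteforce_cov_matrix(a, b):
    n_t, n_b = a.shape
    K = np.zeros((n_b, n_b))
    for t1 in range(n_b):
        for t2 in range(n_b):
            K[t1, t2] = sum(a[i, t1] * b[i, t2] for i in range(n_t)) / n_t
    return K


def test_lag_curve_matches_bruteforce(rng):
    a = rng.normal(size=(12, 18))
    b = rng.normal(size=(12, 18))
    got = _lag_curve_values(a, b, 5)
    assert np.allclose(got, bruteforce_lag_curve(a, b, 5), atol=1e-12)


def test_delayed_copy_peaks_at_positive_lag(rng):
    """Lag-sign audit: B a delayed copy of A must peak at a positive lag
    under the 'A leads B' convention."""
    base = rng.normal(size=(30, 44))
    shift = 2
    b = np.zeros_like(base)
    b[:, shift:] = base[:, :-shift]
    A, B = make_tensor(base), make_tensor(b)
    curve = crosscov_lagged(A, B, max_lag=5 * 0.054, mode="raw")
    assert curve.argmax_lag_s == pytest.approx(shift * 0.054)


def test_crosscov_lag_zero_equals_cov_matrix_diagonal(rng):
    a = rng.normal(size=(25, 30))
    b = rng.normal(size=(25, 30))
    A, B = make_tensor(a), make_tensor(b)
    curve = crosscov_lagged(A, B, max_lag=3 * 0.054, mode="raw")
    K = cov_matrix(A, B, mode="raw")
    i0 = len(curve.values) // 2
    assert curve.values[i0] == pytest.approx(np.mean(np.diag(K.K)), rel=1e-12)


def test_cov_matrix_matches_double_loop(rng):
    a = rng.normal(size=(20, 30))
    b = rng.normal(size=(20, 30))
    conds = rng.integers(0, 2, 20)
    K = cov_matrix(make_tensor(a), make_tensor(b), mode="noise", conditions=conds)
    ares = a.copy()
    bres = b.copy()
    for c in (0, 1):
        sel = conds == c
        ares[sel] -= a[sel].mean(axis=0)
        bres[sel] -= b[sel].mean(axis=0)
    assert np.allclose(K.K, bruteforce_cov_matrix(ares, bres), atol=1e-12)


def test_condition_mean_residuals_properties(rng):
    data = rng.normal(size=(16, 10))
    conds = rng.integers(0, 2, 16)
    res = condition_mean_residuals(make_tensor(data), conds)
    for c in (0, 1):
        assert np.allclose(res.data[conds == c].mean(axis=0), 0.0, atol=1e-12)
    same = condition_mean_residuals(make_tensor(np.tile(data[0], (5, 1))))
    assert np.allclose(same.data, 0.0)
    with pytest.raises(ValueError):
        condition_mean_residuals(make_tensor(data), np.arange(16))  # singletons


def test_noise_mode_invariant_to_condition_waveforms(rng):
    a = rng.normal(size=(40, 26))
    b = rng.normal(size=(40, 26))
    conds = rng.integers(0, 2, 40)
    wave = 5.0 * np.sin(np.linspace(0, 3, 26))
    a2 = a + np.where(conds[:, None] == 1, wave, -wave)
    c1 = crosscov_lagged(make_tensor(a), make_tensor(b), 0.2, "noise", conds)
    c2 = crosscov_lagged(make_tensor(a2), make_tensor(b), 0.2, "noise", conds)
    assert np.allclose(c1.values, c2.values, atol=1e-10)


def test_independent_channels_stay_inside_simultaneous_band(rng):
    a = rng.normal(size=(400, 30))
    b = rng.normal(size=(400, 30))
    A, B = make_tensor(a), make_tensor(b)
    curve = crosscov_lagged(A, B, 4 * 0.054, mode="noise")
    _, lo, hi = null_controls(A, B, 4 * 0.054, n_perm=200, seed=5,
                              band="simultaneous")
    assert np.all((curve.values >= lo) & (curve.values <= hi))


def test_null_band_narrows_with_more_trials(rng):
    small = make_tensor(rng.normal(size=(60, 24))), make_tensor(rng.normal(size=(60, 24)))
    big = make_tensor(rng.normal(size=(500, 24))), make_tensor(rng.normal(size=(500, 24)))
    _, lo_s, hi_s = null_controls(*small, 0.2, n_perm=150, seed=1)
    _, lo_b, hi_b = null_controls(*big, 0.2, n_perm=150, seed=1)
    assert np.mean(hi_b - lo_b) < np.mean(hi_s - lo_s)


def test_zero_shift_reproduces_observed_curve(rng):
    a = rng.normal(size=(10, 15))
    b = rng.normal(size=(10, 15))
    rolled = np.stack([np.roll(b[i], 0) for i in range(10)])
    assert np.allclose(_lag_curve_values(a, b, 3), _lag_curve_values(a, rolled, 3))


def test_session_swap_requires_multiple_sessions(rng):
    A = make_tensor(rng.normal(size=(30, 12)))
    B = make_tensor(rng.normal(size=(30, 12)))
    with pytest.raises(ValueError, match="session"):
        null_controls(A, B, 0.1, mode="session_swap", n_perm=100)
    sessions = np.repeat([0, 1, 2], 10)
    lags, lo, hi = null_controls(A, B, 0.1, mode="session_swap",
                                 sessions=sessions, n_perm=120, seed=2)
    assert np.all(lo <= hi)


def test_off_diagonal_of_identity_like_matrix():
    n = 10
    bw = 0.054
    t = (np.arange(n) + 0.5) * bw
    K = CovMatrix(K=np.eye(n), t1=t, t2=t, n_trials=50, channels=("a", "b"),
                  mode="raw")
    _, vals0 = off_diagonal(K, offset=0.0, band_halfwidth=0.0)
    assert np.allclose(vals0, 1.0)
    _, vals2 = off_diagonal(K, offset=2 * bw, band_halfwidth=0.0)
    assert np.allclose(vals2[:-2], 0.0)
    assert np.all(np.isnan(vals2[-2:]))  # band truncated off the matrix edge
    with pytest.raises(ValueError):
        off_diagonal(K, offset=5.0)


def test_mismatched_tensors_rejected(rng):
    A = make_tensor(rng.normal(size=(10, 12)))
    B = make_tensor(rng.normal(size=(10, 14)))
    with pytest.raises(ValueError):
        crosscov_lagged(A, B, 0.1)
    with pytest.raises(ValueError):
        cov_matrix(make_tensor(rng.normal(size=(2, 12))),
                   make_tensor(rng.normal(size=(2, 12))))
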