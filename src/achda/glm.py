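"""Event-kernel encoding GLM for photometry signals.

A binary predictor matrix X (time bins x behavioural features) is expanded
into a design matrix phi(X) of T time shifts forward and backward per feature
(T = 20 shifts of 54 ms by default), so fitted coefficients are time-lag
kernels.  Only bins from shortly before centre entry to shortly after side
exit are modelled; when the shift window of one trial overlaps the next, the
overlapped bins are included once in each trial so every event is fully
represented in train/validation/test splits.

Cost functions:

    OLS          J = ||y - X b||^2
    ridge        J = ||y - X b||^2 + alpha ||b||^2
    elastic net  J = (1/2N) ||y - X b||^2 + alpha (l1_ratio ||b||_1
                     + (1 - l1_ratio)/2 ||b||^2)        (l1_ratio=1: lasso)

Note the ridge and elastic-net alphas live on different scales; for
``l1_ratio = 0`` an elastic-net alpha corresponds to a ridge alpha of
``N * alpha`` (see :func:`enet_to_ridge_alpha`).

Evaluation protocol: trials are split 50/50 into training and test halves;
a 10-fold group shuffle split (grouped by trial, 80-20 train/validation)
on the training half yields a cross-validated validation MSE (mean of the
concatenated squared residuals); the model is then refit on the whole
training half and scored on the held-out test half.  The whole procedure is
repeated for Y independent runs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.linear_model import ElasticNet
from sklearn.model_selection import GroupShuffleSplit

from .preprocess import BIN_WIDTH, PhotometryTrace
from .synth import BASE_EVENTS, EVENT_TIME_COLS, KernelSet
from .task import history_labels  # noqa: F401  (re-export convenience)

log = logging.getLogger(__name__)

HISTORY_LABELS = [
    f"{s}_{p}_{c}"
    for s in ("stay", "switch")
    for p in ("win", "lose")
    for c in ("win", "lose")
]


@dataclass
class GLMConfig:
    T: int = 20
    bin_width: float = BIN_WIDTH
    features: tuple[str, ...] = BASE_EVENTS
    method: str = "ols"  # ols | ridge | lasso | elastic_net
    alpha: float = 0.0
    l1_ratio: float = 0.5
    n_runs: int = 10  # Y model runs
    gss_folds: int = 10
    val_fraction: float = 0.2
    train_fraction: float = 0.5
    trial_margin: float = 1.0  # s before centre entry / after side exit

    def validate(self) -> None:
        if self.T < 0 or self.alpha < 0:
            raise ValueError("T and alpha must be >= 0")
        if not 0 <= self.l1_ratio <= 1:
            raise ValueError("l1_ratio must lie in [0, 1]")
        for f in (self.val_fraction, self.train_fraction):
            if not 0 < f < 1:
                raise ValueError("fractions must lie in (0, 1)")
        if self.method not in ("ols", "ridge", "lasso", "elastic_net"):
            raise ValueError(f"unknown method {self.method!r}")


def enet_to_ridge_alpha(alpha: float, n_samples: int, l1_ratio: float = 0.0) -> float:
    """Ridge-scale alpha equivalent to an elastic-net alpha at l1_ratio=0."""
    return n_samples * alpha * (1.0 - l1_ratio)


@dataclass
class DesignMatrix:
    X: np.ndarray  # N x F(2T+1)
    y: np.ndarray
    columns: list[tuple[str, int]]  # (feature, lag in bins)
    features: list[str]
    T: int
    bin_width: float
    groups: np.ndarray  # trial id per row
    duplicated: np.ndarray  # True where the bin also belongs to another trial
    row_bins: np.ndarray  # global bin index per row
    align_bin_by_group: dict  # trial id -> side-entry bin (for reconstruction)

    @property
    def n_lags(self) -> int:
        return 2 * self.T + 1

    def feature_cols(self, feature: str) -> np.ndarray:
        return np.flatnonzero([f == feature for f, _ in self.columns])

    def drop_feature(self, feature: str) -> "DesignMatrix":
        if feature not in self.features:
            raise ValueError(f"unknown feature {feature!r}")
        keep = np.flatnonzero([f != feature for f, _ in self.columns])
        return replace(
            self,
            X=self.X[:, keep],
            columns=[self.columns[i] for i in keep],
            features=[f for f in self.features if f != feature],
        )


def _bin_trace(trace: PhotometryTrace, bw: float, n_bins: int) -> np.ndarray:
    """Bin-mean a trace onto the global grid (bins without samples -> 0)."""
    idx = np.floor((trace.times) / bw).astype(int)
    ok = (idx >= 0) & (idx < n_bins)
    sums = np.bincount(idx[ok], weights=trace.values[ok], minlength=n_bins)
    counts = np.bincount(idx[ok], minlength=n_bins)
    out = np.zeros(n_bins)
    nz = counts > 0
    out[nz] = sums[nz] / counts[nz]
    return out


def build_design(
    events: pd.DataFrame,
    trials: pd.DataFrame,
    cfg: GLMConfig,
    response: PhotometryTrace,
    variant: str = "base",
    extra_traces: list[PhotometryTrace] | None = None,
) -> DesignMatrix:
    """Construct the time-shifted design matrix and aligned response.

    ``variant``: ``base`` (binary indicators for the six port/lick/reward
    events), ``history`` (side entry split into the eight action-outcome
    combinations) or ``photometry`` (``extra_traces`` appended as continuous
    predictors, e.g. DA predicting Ach).
    """
    cfg.validate()
    if variant not in ("base", "history", "photometry"):
        raise ValueError(f"unknown variant {variant!r}")
    bw = cfg.bin_width
    t_end = float(trials["t_side_exit"].max()) + cfg.trial_margin
    n_bins = int(np.ceil(t_end / bw)) + cfg.T + 1

    # --- global binary feature matrix ------------------------------------
    feat_bins: dict[str, np.ndarray] = {}

    def mark(name: str, times: np.ndarray) -> None:
        col = np.zeros(n_bins)
        idx = np.floor(np.asarray(times, float) / bw).astype(int)
        idx = idx[(idx >= 0) & (idx < n_bins)]
        col[idx] = 1.0
        feat_bins[name] = col

    for ev in cfg.features:
        if ev == "lick":
            times = np.concatenate([np.asarray(ts, float) for ts in trials["lick_times"]]) \
                if len(trials) else np.empty(0)
            mark("lick", times)
        elif ev == "reward":
            # reward delivery is triggered by side entry on rewarded trials
            mark("reward", trials.loc[trials["reward"] == 1, "t_side_entry"].to_numpy())
        elif ev == "side_entry" and variant == "history":
            n_unlabelled = int((trials["history_label"] == "").sum())
            if n_unlabelled:
                log.info("history variant: %d unlabelled trials omitted from "
                         "the side-entry features", n_unlabelled)
            for lab in HISTORY_LABELS:
                sel = trials.loc[trials["history_label"] == lab, "t_side_entry"]
                mark(f"side_entry:{lab}", sel.to_numpy())
        else:
            mark(ev, trials[EVENT_TIME_COLS[ev]].to_numpy())

    if variant == "photometry":
        if not extra_traces:
            raise ValueError("photometry variant requires extra_traces")
        for tr in extra_traces:
            feat_bins[f"phot:{tr.channel}"] = _bin_trace(tr, bw, n_bins)

    features = list(feat_bins)
    G = np.column_stack([feat_bins[f] for f in features])
    y_global = _bin_trace(response, bw, n_bins)

    # --- retained rows: trial spans plus margins, overlaps duplicated ----
    row_bins_parts, group_parts = [], []
    for row in trials.itertuples(index=False):
        b0 = max(int(np.floor((row.t_centre_entry - cfg.trial_margin) / bw)), 0)
        b1 = min(int(np.floor((row.t_side_exit + cfg.trial_margin) / bw)), n_bins - 1)
        row_bins_parts.append(np.arange(b0, b1 + 1))
        group_parts.append(np.full(b1 - b0 + 1, row.trial))
    row_bins = np.concatenate(row_bins_parts)
    groups = np.concatenate(group_parts)
    counts = np.bincount(row_bins, minlength=n_bins)
    duplicated = counts[row_bins] > 1
    if duplicated.any():
        log.info("build_design: %.2f%% of rows are boundary-duplicated",
                 100 * duplicated.mean())

    # --- shifted design: column (f, lag) at row b equals G[b - lag, f] ---
    T = cfg.T
    Gpad = np.vstack([np.zeros((T, G.shape[1])), G, np.zeros((T, G.shape[1]))])
    lags = np.arange(-T, T + 1)
    idx = row_bins[:, None] - lags[None, :] + T
    X = Gpad[idx, :].transpose(0, 2, 1).reshape(len(row_bins), -1)
    columns = [(f, int(l)) for f in features for l in lags]

    se_bins = {
        int(r.trial): int(np.floor(r.t_side_entry / bw))
        for r in trials.itertuples(index=False)
    }
    return DesignMatrix(
        X=X,
        y=y_global[row_bins],
        columns=columns,
        features=features,
        T=T,
        bin_width=bw,
        groups=groups,
        duplicated=duplicated,
        row_bins=row_bins,
        align_bin_by_group=se_bins,
    )


# ---------------------------------------------------------------------------
# fitting

@dataclass
class GLMFit:
    beta: np.ndarray
    intercept: float
    method: str
    n_iter: int | None = None
    converged: bool = True

    def predict(self, X: np.ndarray) -> np.ndarray:
        return X @ self.beta + self.intercept


def _solve_gram(G: np.ndarray, b: np.ndarray, cols: np.ndarray,
                method: str, alpha: float) -> np.ndarray:
    """Solve the (possibly ridge-penalised) normal equations on a column
    subset of a precomputed Gram system with an unpenalised intercept as the
    final column."""
    sub = np.append(cols, G.shape[0] - 1)
    Gs = G[np.ix_(sub, sub)]
    bs = b[sub]
    if method == "ridge" and alpha > 0:
        Gs = Gs + alpha * np.diag(np.r_[np.ones(len(sub) - 1), 0.0])
        return np.linalg.solve(Gs, bs)
    coef, *_ = np.linalg.lstsq(Gs, bs, rcond=None)
    return coef


def fit_glm(design: DesignMatrix, cfg: GLMConfig,
            rows: np.ndarray | None = None) -> GLMFit:
    """Fit the configured model on (a row subset of) the design matrix."""
    cfg.validate()
    X = design.X if rows is None else design.X[rows]
    y = design.y if rows is None else design.y[rows]
    n, p = X.shape
    if cfg.method == "ols" and n <= p:
        raise ValueError(
            f"OLS requires more rows ({n}) than columns ({p}); use ridge "
            "or elastic net"
        )
    if cfg.method in ("ols", "ridge"):
        Xa = np.column_stack([X, np.ones(n)])
        G = Xa.T @ Xa
        b = Xa.T @ y
        coef = _solve_gram(G, b, np.arange(p), cfg.method, cfg.alpha)
        return GLMFit(beta=coef[:-1], intercept=float(coef[-1]), method=cfg.method)
    l1 = 1.0 if cfg.method == "lasso" else cfg.l1_ratio
    model = ElasticNet(
        alpha=cfg.alpha, l1_ratio=l1, fit_intercept=True,
        tol=1e-6, max_iter=10_000,
    )
    import warnings as _w
    with _w.catch_warnings():
        _w.simplefilter("ignore")
        model.fit(X, y)
    converged = model.n_iter_ < 10_000
    if not converged:
        log.warning("coordinate descent hit max_iter=%d", model.n_iter_)
    return GLMFit(
        beta=model.coef_.copy(), intercept=float(model.intercept_),
        method=cfg.method, n_iter=int(model.n_iter_), converged=converged,
    )


def _mse(y, yhat) -> float:
    return float(np.mean((y - yhat) ** 2))


def _r2(y, yhat) -> float:
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - np.mean(y)) ** 2))
    return 1.0 - ss_res / ss_tot if ss_tot > 0 else np.nan


@dataclass
class RunRecord:
    beta: np.ndarray
    intercept: float
    train_mse: float
    val_mse: float
    test_mse: float
    train_r2: float
    test_r2: float
    fold_val_mse: np.ndarray
    dup_overlap_fraction: float


@dataclass
class GLMProtocolResult:
    runs: list[RunRecord]
    columns: list[tuple[str, int]]
    features: list[str]
    T: int
    bin_width: float
    config: GLMConfig
    seed: int

    @property
    def val_mse(self) -> float:
        return float(np.mean([r.val_mse for r in self.runs]))

    @property
    def test_mse(self) -> float:
        return float(np.mean([r.test_mse for r in self.runs]))

    @property
    def test_r2(self) -> float:
        return float(np.mean([r.test_r2 for r in self.runs]))

    @property
    def cv_noise_band(self) -> float:
        """Std of fold-level validation MSEs (scale of CV noise)."""
        return float(np.std(np.concatenate([r.fold_val_mse for r in self.runs])))


def _split_rows(design: DesignMatrix, rng: np.random.Generator,
                train_fraction: float) -> tuple[np.ndarray, np.ndarray]:
    trials_u = np.unique(design.groups)
    perm = rng.permutation(trials_u)
    n_train = int(round(train_fraction * len(trials_u)))
    train_g = set(perm[:n_train].tolist())
    in_train = np.fromiter((g in train_g for g in design.groups), bool,
                           len(design.groups))
    return np.flatnonzero(in_train), np.flatnonzero(~in_train)


def _dup_overlap(design: DesignMatrix, train_rows, test_rows) -> float:
    tr_bins = set(design.row_bins[train_rows].tolist())
    te_bins = design.row_bins[test_rows]
    both = np.fromiter((b in tr_bins for b in te_bins), bool, len(te_bins))
    n_rows = len(design.row_bins)
    return float(2 * both.sum() / n_rows) if n_rows else 0.0


def run_protocol(design: DesignMatrix, cfg: GLMConfig, seed: int) -> GLMProtocolResult:
    """Y-run train/validation/test evaluation (see module docstring)."""
    cfg.validate()
    if len(np.unique(design.groups)) < max(cfg.gss_folds, 20):
        raise ValueError("too few trials for the evaluation protocol")
    records = []
    for run_ss in np.random.SeedSequence(seed).spawn(cfg.n_runs):
        rng = np.random.default_rng(run_ss)
        records.append(_one_run(design, cfg, rng))
    return GLMProtocolResult(
        runs=records,
        columns=list(design.columns),
        features=list(design.features),
        T=design.T,
        bin_width=design.bin_width,
        config=cfg,
        seed=seed,
    )


def _one_run(design: DesignMatrix, cfg: GLMConfig,
             rng: np.random.Generator) -> RunRecord:
    train_rows, test_rows = _split_rows(design, rng, cfg.train_fraction)
    sq_res, fold_mses = [], []
    gss = GroupShuffleSplit(
        n_splits=cfg.gss_folds, test_size=cfg.val_fraction,
        random_state=int(rng.integers(2**31)),
    )
    for sub, val in gss.split(train_rows, groups=design.groups[train_rows]):
        fit = fit_glm(design, cfg, rows=train_rows[sub])
        res = design.y[train_rows[val]] - fit.predict(design.X[train_rows[val]])
        sq_res.append(res**2)
        fold_mses.append(float(np.mean(res**2)))
    val_mse = float(np.mean(np.concatenate(sq_res)))

    fit = fit_glm(design, cfg, rows=train_rows)
    yhat_tr = fit.predict(design.X[train_rows])
    yhat_te = fit.predict(design.X[test_rows])
    return RunRecord(
        beta=fit.beta,
        intercept=fit.intercept,
        train_mse=_mse(design.y[train_rows], yhat_tr),
        val_mse=val_mse,
        test_mse=_mse(design.y[test_rows], yhat_te),
        train_r2=_r2(design.y[train_rows], yhat_tr),
        test_r2=_r2(design.y[test_rows], yhat_te),
        fold_val_mse=np.asarray(fold_mses),
        dup_overlap_fraction=_dup_overlap(design, train_rows, test_rows),
    )


# ---------------------------------------------------------------------------
# leave-out analysis

def leave_out_analysis(design: DesignMatrix, cfg: GLMConfig, seed: int) -> pd.DataFrame:
    """Iteratively omit one feature and re-evaluate on identical splits.

    Returns one row per feature with validation/test MSE deltas relative to
    the full model; the full model's MSEs and the CV noise band (std of its
    fold-level validation MSEs) are attached as DataFrame attrs.

    For OLS/ridge the per-fold Gram matrix is computed once on the full
    column set and each leave-out solve reuses a column subset of it.
    """
    cfg.validate()
    if len(design.features) < 2:
        raise ValueError("leave-out requires at least 2 features")
    if cfg.method not in ("ols", "ridge"):
        return _leave_out_generic(design, cfg, seed)

    p = design.X.shape[1]
    models = {"__full__": np.arange(p)}
    for f in design.features:
        models[f] = np.flatnonzero([c != f for c, _ in design.columns])

    sq_res = {m: [] for m in models}
    test_mse = {m: [] for m in models}
    fold_full = []
    for run_ss in np.random.SeedSequence(seed).spawn(cfg.n_runs):
        rng = np.random.default_rng(run_ss)
        train_rows, test_rows = _split_rows(design, rng, cfg.train_fraction)
        gss = GroupShuffleSplit(
            n_splits=cfg.gss_folds, test_size=cfg.val_fraction,
            random_state=int(rng.integers(2**31)),
        )
        run_sq = {m: [] for m in models}
        for sub, val in gss.split(train_rows, groups=design.groups[train_rows]):
            rows = train_rows[sub]
            Xa = np.column_stack([design.X[rows], np.ones(len(rows))])
            G = Xa.T @ Xa
            b = Xa.T @ design.y[rows]
            Xv = design.X[train_rows[val]]
            yv = design.y[train_rows[val]]
            for m, cols in models.items():
                coef = _solve_gram(G, b, cols, cfg.method, cfg.alpha)
                res = yv - (Xv[:, cols] @ coef[:-1] + coef[-1])
                run_sq[m].append(res**2)
                if m == "__full__":
                    fold_full.append(float(np.mean(res**2)))
        for m in models:
            sq_res[m].append(float(np.mean(np.concatenate(run_sq[m]))))
        # refit on the full training half, evaluate on the test half
        Xa = np.column_stack([design.X[train_rows], np.ones(len(train_rows))])
        G = Xa.T @ Xa
        b = Xa.T @ design.y[train_rows]
        Xt = design.X[test_rows]
        yt = design.y[test_rows]
        for m, cols in models.items():
            coef = _solve_gram(G, b, cols, cfg.method, cfg.alpha)
            test_mse[m].append(_mse(yt, Xt[:, cols] @ coef[:-1] + coef[-1]))

    full_val = float(np.mean(sq_res["__full__"]))
    full_test = float(np.mean(test_mse["__full__"]))
    rows = []
    for f in design.features:
        rows.append(
            dict(
                feature=f,
                val_mse=float(np.mean(sq_res[f])),
                test_mse=float(np.mean(test_mse[f])),
                delta_val_mse=float(np.mean(sq_res[f])) - full_val,
                delta_test_mse=float(np.mean(test_mse[f])) - full_test,
            )
        )
    out = pd.DataFrame(rows)
    out.attrs["full_val_mse"] = full_val
    out.attrs["full_test_mse"] = full_test
    out.attrs["cv_noise_band"] = float(np.std(fold_full))
    return out


def _leave_out_generic(design, cfg, seed):
    full = run_protocol(design, cfg, seed)
    rows = []
    for f in design.features:
        sub = run_protocol(design.drop_feature(f), cfg, seed)
        rows.append(
            dict(
                feature=f,
                val_mse=sub.val_mse,
                test_mse=sub.test_mse,
                delta_val_mse=sub.val_mse - full.val_mse,
                delta_test_mse=sub.test_mse - full.test_mse,
            )
        )
    out = pd.DataFrame(rows)
    out.attrs["full_val_mse"] = full.val_mse
    out.attrs["full_test_mse"] = full.test_mse
    out.attrs["cv_noise_band"] = full.cv_noise_band
    return out


# ---------------------------------------------------------------------------
# kernels and reconstruction

def extract_kernels(result: GLMProtocolResult) -> tuple[KernelSet, KernelSet]:
    """Mean and sd kernels over the Y model runs."""
    if not result.runs:
        raise ValueError("no completed runs")
    betas = np.stack([r.beta for r in result.runs])  # Y x F(2T+1)
    L = 2 * result.T + 1
    mean = betas.mean(axis=0).reshape(len(result.features), L)
    sd = betas.std(axis=0).reshape(len(result.features), L)
    lags = np.arange(-result.T, result.T + 1) * result.bin_width
    mean_ks = KernelSet(lags, dict(zip(result.features, mean)))
    sd_ks = KernelSet(lags, dict(zip(result.features, sd)))
    return mean_ks, sd_ks


@dataclass
class Reconstruction:
    offsets_s: np.ndarray  # time relative to side entry
    mean_y: np.ndarray
    mean_yhat: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    r2: float


def reconstruct(design: DesignMatrix, beta: np.ndarray, intercept: float,
                n_boot: int = 500, seed: int = 0) -> Reconstruction:
    """Predicted trace, R^2 and the trial-averaged reconstruction (aligned on
    side entry) with a bootstrap-over-trials 95% CI."""
    if len(beta) != design.X.shape[1]:
        raise ValueError("beta does not match the design's column count")
    yhat = design.X @ beta + intercept
    r2 = _r2(design.y, yhat)

    se = np.array([design.align_bin_by_group[int(g)] for g in design.groups])
    off = design.row_bins - se
    off_u = np.arange(off.min(), off.max() + 1)
    shift = off - off.min()
    trials_u, trial_idx = np.unique(design.groups, return_inverse=True)
    n_t, n_o = len(trials_u), len(off_u)
    Ymat = np.full((n_t, n_o), np.nan)
    Hmat = np.full((n_t, n_o), np.nan)
    Ymat[trial_idx, shift] = design.y
    Hmat[trial_idx, shift] = yhat

    rng = np.random.default_rng(seed)
    with np.errstate(invalid="ignore"):
        mean_y = np.nanmean(Ymat, axis=0)
        mean_h = np.nanmean(Hmat, axis=0)
        boots = np.empty((n_boot, n_o))
        for i in range(n_boot):
            pick = rng.integers(0, n_t, n_t)
            boots[i] = np.nanmean(Hmat[pick], axis=0)
    lo, hi = np.nanpercentile(boots, [2.5, 97.5], axis=0)
    return Reconstruction(
        offsets_s=off_u * design.bin_width,
        mean_y=mean_y,
        mean_yhat=mean_h,
        ci_low=lo,
        ci_high=hi,
        r2=r2,
    )
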