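"""Per-trial scalar metrics and trial-type classification.

mean DA: mean of the z-scored signal in a window around side entry.
delta Ach: max minus min within a window (captures multiphasic excursions).
Group comparisons aggregate to per-mouse condition means first, then run a
paired two-sided t-test across mice.  LDA classifies trial type from the
binned waveform with stratified cross-validation.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.model_selection import StratifiedKFold

from .preprocess import TrialTensor

log = logging.getLogger(__name__)


def mean_signal(tensor: TrialTensor, window: tuple[float, float]) -> np.ndarray:
    """Per-trial mean over bins whose centres fall in ``window``."""
    mask = tensor.window_mask(window)
    return tensor.data[:, mask].mean(axis=1)


def delta_signal(tensor: TrialTensor, window: tuple[float, float]) -> np.ndarray:
    """Per-trial max - min over bins in ``window`` (always >= 0)."""
    mask = tensor.window_mask(window)
    seg = tensor.data[:, mask]
    return seg.max(axis=1) - seg.min(axis=1)


@dataclass
class MetricResult:
    metric: str
    window: tuple[float, float]
    per_mouse: pd.DataFrame  # mouse x condition means
    statistic: float
    p_value: float
    test_name: str = "paired t-test (two-sided)"
    significant: bool = False
    excluded_mice: list = field(default_factory=list)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "metric": self.metric,
                    "window": list(self.window),
                    "statistic": self.statistic,
                    "p_value": self.p_value,
                    "test_name": self.test_name,
                    "significant": self.significant,
                    "per_mouse": self.per_mouse.to_dict(),
                },
                fh,
                indent=2,
            )


def group_compare(
    values: np.ndarray,
    conditions: np.ndarray,
    mouse_ids: np.ndarray,
    metric: str = "metric",
    window: tuple[float, float] = (0.0, 0.0),
    alpha: float = 0.05,
) -> MetricResult:
    """Paired two-sided t-test across mice on per-mouse condition means.

    Aggregation precedes testing, so the result is invariant to unequal
    per-mouse trial counts.  Mice missing one of the two conditions are
    excluded (logged).
    """
    df = pd.DataFrame({"value": values, "cond": conditions, "mouse": mouse_ids})
    conds = sorted(df["cond"].unique())
    if len(conds) != 2:
        raise ValueError(f"group_compare needs exactly 2 conditions, got {conds}")
    table = df.groupby(["mouse", "cond"])["value"].mean().unstack("cond")
    excluded = table.index[table.isna().any(axis=1)].tolist()
    if excluded:
        log.info("group_compare excluded mice lacking a condition: %s", excluded)
        table = table.dropna()
    if len(table) < 2:
        raise ValueError("need at least 2 mice with both conditions")
    a, b = table[conds[0]].to_numpy(), table[conds[1]].to_numpy()
    if np.allclose(a, b):
        t, p = 0.0, 1.0
    else:
        t, p = stats.ttest_rel(a, b)
    return MetricResult(
        metric=metric,
        window=window,
        per_mouse=table,
        statistic=float(t),
        p_value=float(p),
        significant=bool(p < alpha),
        excluded_mice=excluded,
    )


@dataclass
class LDAResult:
    window: tuple[float, float]
    fold_accuracy: np.ndarray
    mean_accuracy: float
    n_per_class: dict
    seed: int

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "window": list(self.window),
                    "fold_accuracy": self.fold_accuracy.tolist(),
                    "mean_accuracy": self.mean_accuracy,
                    "n_per_class": {str(k): int(v) for k, v in self.n_per_class.items()},
                    "seed": self.seed,
                },
                fh,
                indent=2,
            )


def lda_classify(
    tensor: TrialTensor,
    labels: np.ndarray,
    window: tuple[float, float],
    cv_folds: int = 5,
    seed: int = 0,
    balance: bool = False,
) -> LDAResult:
    """Stratified k-fold LDA accuracy on waveform bins within ``window``.

    A shrinkage covariance estimator is used when the feature count exceeds
    one fifth of the trial count (waveform bins are strongly collinear).
    ``balance=True`` subsamples the majority class so chance is 50%.
    """
    labels = np.asarray(labels)
    mask = tensor.window_mask(window)
    X = tensor.data[:, mask]
    y = labels
    rng = np.random.default_rng(seed)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) != 2:
        raise ValueError("lda_classify expects binary labels")
    if counts.min() < 20:
        raise ValueError("need at least 20 trials per class")
    if balance:
        m = counts.min()
        keep = np.concatenate(
            [rng.choice(np.flatnonzero(y == c), size=m, replace=False) for c in classes]
        )
        keep.sort()
        X, y = X[keep], y[keep]
        classes, counts = np.unique(y, return_counts=True)
    if counts.min() < cv_folds:
        raise ValueError("a class has fewer trials than CV folds")

    shrink = X.shape[1] > len(y) / 5
    accs = []
    skf = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=int(seed) % (2**32))
    for tr, te in skf.split(X, y):
        clf = LinearDiscriminantAnalysis(
            solver="lsqr", shrinkage="auto" if shrink else None
        )
        clf.fit(X[tr], y[tr])
        accs.append(clf.score(X[te], y[te]))
    accs = np.asarray(accs)
    return LDAResult(
        window=window,
        fold_accuracy=accs,
        mean_accuracy=float(accs.mean()),
        n_per_class=dict(zip(classes.tolist(), counts.tolist())),
        seed=seed,
    )


def lda_permutation_null(
    tensor: TrialTensor,
    labels: np.ndarray,
    window: tuple[float, float],
    n_perm: int = 50,
    cv_folds: int = 5,
    seed: int = 0,
    balance: bool = False,
) -> np.ndarray:
    """Null distribution of mean LDA accuracy under label shuffling."""
    rng = np.random.default_rng(seed)
    labels = np.asarray(labels)
    out = []
    for i in range(n_perm):
        perm = rng.permutation(labels)
        res = lda_classify(
            tensor, perm, window, cv_folds=cv_folds,
            seed=int(rng.integers(2**31)), balance=balance,
        )
        out.append(res.mean_accuracy)
    return np.asarray(out)
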