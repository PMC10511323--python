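"""RFLR choice model fitting and behavioural summary statistics.

The recursively formulated logistic regression models the probability of the
next choice from a decaying action-reward evidence trace phi and a
perseveration term on the previous choice:

    phi_{t+1} = c_t * r_t + exp(-1/tau) * phi_t
    psi_t     = alpha * c_{t-1} + beta * phi_t
    P(c_t = right) = logistic(psi_t)

Fitting profiles the Bernoulli log-likelihood over a grid of decay constants
tau (for fixed tau the model is an ordinary logistic regression in the two
regressors [c_{t-1}, phi_t]) and then refines the best tau by bounded 1-D
optimisation.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.optimize import minimize_scalar

from .agents import AgentParams

DEFAULT_TAU_GRID = np.geomspace(0.25, 10.0, 25)


def evidence_series(
    choices: np.ndarray, rewards: np.ndarray, tau: float, phi0: float = 0.0
) -> np.ndarray:
    """Evidence trace phi of length ``n + 1`` (phi[t] uses trials < t)."""
    choices = np.asarray(choices, dtype=float)
    rewards = np.asarray(rewards, dtype=float)
    if choices.shape != rewards.shape:
        raise ValueError("choices and rewards must have equal length")
    if not tau > 0:
        raise ValueError(f"tau must be > 0, got {tau}")
    decay = np.exp(-1.0 / tau)
    phi = np.empty(len(choices) + 1)
    phi[0] = phi0
    for t in range(len(choices)):
        phi[t + 1] = choices[t] * rewards[t] + decay * phi[t]
    return phi


def choice_logodds(params: AgentParams, c_prev: float, phi: float) -> float:
    """Log-odds of choosing the right port: psi = alpha*c_prev + beta*phi."""
    return params.alpha * c_prev + params.beta * phi


@dataclass
class RFLRFit:
    params: AgentParams
    log_likelihood: float
    n_trials: int
    converged: bool
    z_values: dict = field(default_factory=dict)
    predicted_choice_prob: np.ndarray | None = None

    def to_json(self, path) -> None:
        out = {
            "params": asdict(self.params),
            "log_likelihood": self.log_likelihood,
            "n_trials": self.n_trials,
            "converged": self.converged,
            "z_values": self.z_values,
        }
        with open(path, "w") as fh:
            json.dump(out, fh, indent=2)


def _loglik_at_tau(c, r, tau):
    """Fit alpha, beta by logistic regression at fixed tau; return
    (loglik, alpha, beta, z_alpha, z_beta, converged, p_hat)."""
    phi = evidence_series(c, r, tau)
    X = np.column_stack([c[:-1], phi[1:-1]])  # predictors of c_t, t >= 1
    y = (c[1:] + 1) / 2
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.Logit(y, X).fit(disp=0, maxiter=200)
        except Exception:
            return -np.inf, np.nan, np.nan, np.nan, np.nan, False, None
    ok = bool(res.mle_retvals.get("converged", False)) and bool(
        np.all(np.isfinite(res.params))
    )
    return (
        float(res.llf),
        float(res.params[0]),
        float(res.params[1]),
        float(res.tvalues[0]),
        float(res.tvalues[1]),
        ok,
        res.predict(X),
    )


def fit_rflr(
    trials: pd.DataFrame,
    tau_grid: np.ndarray | None = None,
    refine: bool = True,
) -> RFLRFit:
    """Maximum-likelihood RFLR fit by profile likelihood over tau.

    Requires at least 50 trials.  Degenerate data (a single repeated choice)
    yields a non-converged fit rather than an exception.
    """
    if len(trials) < 50:
        raise ValueError("fit_rflr requires at least 50 trials")
    tau_grid = DEFAULT_TAU_GRID if tau_grid is None else np.asarray(tau_grid, float)
    if tau_grid.size == 0 or np.any(tau_grid <= 0):
        raise ValueError("tau_grid must be non-empty and positive")
    c = trials["choice"].to_numpy(dtype=float)
    r = trials["reward"].to_numpy(dtype=float)

    if np.all(c == c[0]):
        return RFLRFit(
            AgentParams(np.nan, np.nan, np.nan), -np.inf, len(c) - 1, False
        )

    lls = np.array([_loglik_at_tau(c, r, tau)[0] for tau in tau_grid])
    best = int(np.argmax(lls))
    tau_star = float(tau_grid[best])

    if refine and np.isfinite(lls[best]):
        lo = tau_grid[max(best - 1, 0)]
        hi = tau_grid[min(best + 1, len(tau_grid) - 1)]
        if lo < hi:
            res = minimize_scalar(
                lambda t: -_loglik_at_tau(c, r, t)[0],
                bounds=(lo, hi),
                method="bounded",
                options={"xatol": 1e-4},
            )
            if -res.fun >= lls[best]:
                tau_star = float(res.x)

    ll, alpha, beta, za, zb, ok, p_hat = _loglik_at_tau(c, r, tau_star)
    return RFLRFit(
        params=AgentParams(alpha=alpha, beta=beta, tau=tau_star),
        log_likelihood=ll,
        n_trials=len(c) - 1,
        converged=ok,
        z_values={"alpha": za, "beta": zb},
        predicted_choice_prob=p_hat,
    )


# ---------------------------------------------------------------------------
# behavioural summaries

def block_transition_summary(trials: pd.DataFrame, window: int = 10) -> pd.DataFrame:
    """P(switch) and P(high port) around block transitions.

    Offset 0 is the first trial after the high port moved.  Returns one row
    per offset in ``[-window, +window]`` with binomial standard errors.
    """
    if trials["block_id"].nunique() < 2:
        raise ValueError("need at least two blocks")
    if window > len(trials):
        warnings.warn("window exceeds available trials; truncating")
    c = trials["choice"].to_numpy()
    high = trials["high_port"].to_numpy()
    switch = np.zeros(len(c), dtype=float)
    switch[1:] = c[1:] != c[:-1]
    is_high = (c == high).astype(float)

    starts = trials.index[
        (trials["trials_from_block_switch"] == 0) & (trials["block_id"] > 0)
    ].to_numpy()
    rows = []
    for k in range(-window, window + 1):
        idx = starts + k
        idx = idx[(idx >= 1) & (idx < len(c))]
        if len(idx) == 0:
            continue
        ps, ph = switch[idx].mean(), is_high[idx].mean()
        n = len(idx)
        rows.append(
            dict(
                offset=k,
                p_switch=ps,
                se_switch=np.sqrt(ps * (1 - ps) / n),
                p_high=ph,
                se_high=np.sqrt(ph * (1 - ph) / n),
                n=n,
            )
        )
    return pd.DataFrame(rows)


def conditional_switch_table(trials: pd.DataFrame, k: int = 1) -> pd.DataFrame:
    """P(switch on trial t) conditioned on the preceding length-``k`` history.

    Each history token encodes (stay/switch, outcome) of one past trial,
    oldest first.  Histories with zero support are absent from the table.
    """
    if k not in (1, 2, 3):
        raise ValueError("k must be 1, 2 or 3")
    c = trials["choice"].to_numpy()
    r = trials["reward"].to_numpy()
    n = len(c)
    words: dict[str, list[int]] = {}
    for t in range(k + 1, n):
        toks = []
        for j in range(t - k, t):
            toks.append(
                ("stay" if c[j] == c[j - 1] else "switch")
                + ("-win" if r[j] else "-lose")
            )
        word = "|".join(toks)
        words.setdefault(word, []).append(int(c[t] != c[t - 1]))
    rows = [
        dict(history=w, p_switch=float(np.mean(v)), n=len(v))
        for w, v in sorted(words.items())
    ]
    return pd.DataFrame(rows)
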