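"""Two-armed bandit task (2ABT) simulation.

Mice self-initiate trials at a centre port and then choose a left or right
side port.  One port is the "high reward probability" port (``p_high``); the
other rewards at ``1 - p_high``.  After a fixed number of rewards
(``rewards_per_block``, 30 by default) the high port switches sides, so a
proficient agent must integrate choice/outcome history to track the block
structure.

Choices are coded as signed binaries throughout the package: left = -1,
right = +1.  Rewards are 0/1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .agents import Agent

#: canonical column order of a trial table
TRIAL_COLUMNS = [
    "trial",
    "choice",
    "reward",
    "high_port",
    "block_id",
    "trials_from_block_switch",
    "t_centre_entry",
    "t_centre_exit",
    "t_side_entry",
    "t_side_exit",
    "lick_times",
    "history_label",
]

EVENT_NAMES = (
    "centre_entry",
    "centre_exit",
    "side_entry",
    "side_exit",
    "lick_on",
    "lick_off",
    "led_on",
    "led_off",
    "reward",
)

LICK_DURATION = 0.05  # s, fixed lick_on -> lick_off interval


@dataclass
class TimingParams:
    """Inter-event latency model.

    Centre-port occupancy and the centre-to-side transit are log-normal
    (parameterised by the median in seconds and the log-space sd); side-port
    occupancy differs by outcome because mice linger to consume the reward.
    The inter-trial interval is a fixed minimum plus exponential jitter.
    """

    centre_occupancy_median: float = 0.15
    centre_occupancy_sigma: float = 0.3
    centre_to_side_median: float = 0.5
    centre_to_side_sigma: float = 0.3
    side_occupancy_rewarded_median: float = 1.5
    side_occupancy_rewarded_sigma: float = 0.25
    side_occupancy_unrewarded_median: float = 0.5
    side_occupancy_unrewarded_sigma: float = 0.3
    iti_jitter_scale: float = 0.5
    lick_rate: float = 8.0  # Hz during reward consumption
    unrewarded_lick_prob: float = 0.2

    def validate(self) -> None:
        for name, v in vars(self).items():
            if not name.endswith("prob") and v <= 0:
                raise ValueError(f"timing parameter {name} must be > 0, got {v}")
        if not 0 <= self.unrewarded_lick_prob <= 1:
            raise ValueError("unrewarded_lick_prob must lie in [0, 1]")


@dataclass
class TaskConfig:
    """2ABT environment parameters."""

    p_high: float = 0.95
    rewards_per_block: int = 30
    choice_window: float = 5.0
    iti: float = 1.0
    n_trials: int = 500
    timing: TimingParams = field(default_factory=TimingParams)

    @property
    def p_low(self) -> float:
        return 1.0 - self.p_high

    def validate(self) -> None:
        if not 0.5 < self.p_high <= 1.0:
            raise ValueError(
                f"p_high must lie in (0.5, 1]; got {self.p_high} — at or below "
                "0.5 the 'low' port would not be low"
            )
        if self.rewards_per_block < 1:
            raise ValueError("rewards_per_block must be >= 1")
        if self.n_trials <= 0:
            raise ValueError("n_trials must be positive")
        if self.iti <= 0 or self.choice_window <= 0:
            raise ValueError("iti and choice_window must be positive")
        self.timing.validate()


def history_labels(choices: np.ndarray, rewards: np.ndarray) -> list[str]:
    """Eight-way action-outcome labels: (stay/switch) x (prev outcome) x
    (current outcome).  The first trial, lacking a predecessor, gets ``""``.
    """
    labels = [""]
    for t in range(1, len(choices)):
        stay = "stay" if choices[t] == choices[t - 1] else "switch"
        prev = "win" if rewards[t - 1] else "lose"
        cur = "win" if rewards[t] else "lose"
        labels.append(f"{stay}_{prev}_{cur}")
    return labels


def simulate_session(
    config: TaskConfig, agent: Agent, seed: int
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate one 2ABT session.

    Returns ``(trials, events)``: a trial table (one row per trial) and the
    corresponding timestamped event stream.  Deterministic given ``seed``.
    """
    config.validate()
    rng = np.random.default_rng(seed)
    agent.reset()
    tp = config.timing

    high = -1 if rng.random() < 0.5 else 1
    block_id = 0
    rewards_in_block = 0
    trials_from_switch = 0

    rows = []
    t_cursor = 0.0
    for i in range(config.n_trials):
        t_ce = t_cursor + config.iti + rng.exponential(tp.iti_jitter_scale)
        t_cx = t_ce + rng.lognormal(
            np.log(tp.centre_occupancy_median), tp.centre_occupancy_sigma
        )
        t_se = t_cx + rng.lognormal(
            np.log(tp.centre_to_side_median), tp.centre_to_side_sigma
        )
        choice = agent.choose(rng)
        p_r = config.p_high if choice == high else config.p_low
        reward = int(rng.random() < p_r)
        agent.update(choice, reward)

        if reward:
            occ = rng.lognormal(
                np.log(tp.side_occupancy_rewarded_median),
                tp.side_occupancy_rewarded_sigma,
            )
        else:
            occ = rng.lognormal(
                np.log(tp.side_occupancy_unrewarded_median),
                tp.side_occupancy_unrewarded_sigma,
            )
        t_sx = t_se + occ

        if reward:
            n_licks = rng.poisson(tp.lick_rate * max(occ - 0.1, 0.0))
            licks = np.sort(rng.uniform(t_se + 0.1, t_sx, size=n_licks))
        else:
            licks = (
                np.array([rng.uniform(t_se, t_sx)])
                if rng.random() < tp.unrewarded_lick_prob
                else np.empty(0)
            )

        rows.append(
            dict(
                trial=i,
                choice=choice,
                reward=reward,
                high_port=high,
                block_id=block_id,
                trials_from_block_switch=trials_from_switch,
                t_centre_entry=t_ce,
                t_centre_exit=t_cx,
                t_side_entry=t_se,
                t_side_exit=t_sx,
                lick_times=list(licks),
                history_label="",
            )
        )

        rewards_in_block += reward
        trials_from_switch += 1
        if rewards_in_block >= config.rewards_per_block:
            high = -high
            block_id += 1
            rewards_in_block = 0
            trials_from_switch = 0
        t_cursor = t_sx

    trials = pd.DataFrame(rows, columns=TRIAL_COLUMNS)
    trials["history_label"] = history_labels(
        trials["choice"].to_numpy(), trials["reward"].to_numpy()
    )
    return trials, events_from_trials(trials)


# ---------------------------------------------------------------------------
# trial table <-> event stream

def events_from_trials(trials: pd.DataFrame) -> pd.DataFrame:
    """Flatten a trial table into a time-ordered event stream.

    The stream carries the high-port side on each trial's ``led_on`` record so
    that :func:`trials_from_events` is an exact inverse.
    """
    recs: list[tuple[str, float, str]] = []
    prev_end = -np.inf
    for row in trials.itertuples(index=False):
        if not (row.t_centre_entry < row.t_centre_exit < row.t_side_entry < row.t_side_exit):
            raise ValueError(f"trial {row.trial}: port timestamps not ordered")
        if row.t_centre_entry <= prev_end:
            raise ValueError(f"trial {row.trial}: overlaps previous trial")
        prev_end = row.t_side_exit
        side = "left" if row.choice < 0 else "right"
        high = "left" if row.high_port < 0 else "right"
        recs.append(("led_on", row.t_centre_entry, high))
        recs.append(("centre_entry", row.t_centre_entry, ""))
        recs.append(("centre_exit", row.t_centre_exit, ""))
        recs.append(("side_entry", row.t_side_entry, side))
        if row.reward:
            recs.append(("reward", row.t_side_entry, side))
        for lt in row.lick_times:
            recs.append(("lick_on", lt, side))
            recs.append(("lick_off", lt + LICK_DURATION, side))
        recs.append(("side_exit", row.t_side_exit, side))
    events = pd.DataFrame(recs, columns=["event", "time", "value"])
    return events.sort_values("time", kind="stable").reset_index(drop=True)


def trials_from_events(events: pd.DataFrame) -> pd.DataFrame:
    """Inverse of :func:`events_from_trials` (exact round trip)."""
    unknown = set(events["event"]) - set(EVENT_NAMES)
    if unknown:
        raise ValueError(f"unknown event names: {sorted(unknown)}")
    entries = events.index[events["event"] == "centre_entry"].to_numpy()
    rows = []
    bounds = list(entries) + [len(events)]
    prev_choice = None
    block_id = 0
    prev_high = None
    trials_from_switch = 0
    for i, (a, b) in enumerate(zip(bounds[:-1], bounds[1:])):
        chunk = events.iloc[a:b]
        led = events.iloc[max(a - 1, 0)]
        high_side = led["value"] if led["event"] == "led_on" else None

        def one(name: str) -> pd.Series:
            sel = chunk[chunk["event"] == name]
            if len(sel) != 1:
                raise ValueError(f"trial {i}: expected exactly one {name}")
            return sel.iloc[0]

        se = one("side_entry")
        choice = -1 if se["value"] == "left" else 1
        reward = int((chunk["event"] == "reward").any())
        high = -1 if high_side == "left" else 1
        if prev_high is not None and high != prev_high:
            block_id += 1
            trials_from_switch = 0
        rows.append(
            dict(
                trial=i,
                choice=choice,
                reward=reward,
                high_port=high,
                block_id=block_id,
                trials_from_block_switch=trials_from_switch,
                t_centre_entry=one("centre_entry")["time"],
                t_centre_exit=one("centre_exit")["time"],
                t_side_entry=se["time"],
                t_side_exit=one("side_exit")["time"],
                lick_times=list(chunk.loc[chunk["event"] == "lick_on", "time"]),
                history_label="",
            )
        )
        trials_from_switch += 1
        prev_high = high
        prev_choice = choice
    trials = pd.DataFrame(rows, columns=TRIAL_COLUMNS)
    if len(trials):
        trials["history_label"] = history_labels(
            trials["choice"].to_numpy(), trials["reward"].to_numpy()
        )
    return trials


# ---------------------------------------------------------------------------
# CSV round trip

def trials_to_csv(trials: pd.DataFrame, path) -> None:
    out = trials.copy()
    out["lick_times"] = out["lick_times"].map(
        lambda ts: ";".join(repr(float(t)) for t in ts)
    )
    out.to_csv(path, index=False)


def trials_from_csv(path) -> pd.DataFrame:
    trials = pd.read_csv(path, keep_default_na=False)
    trials["lick_times"] = trials["lick_times"].map(
        lambda s: [float(x) for x in s.split(";")] if s else []
    )
    return trials[TRIAL_COLUMNS]


def events_to_csv(events: pd.DataFrame, path) -> None:
    events.to_csv(path, index=False)


def events_from_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, keep_default_na=False)
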