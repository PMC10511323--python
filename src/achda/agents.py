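"""Generative choice agents for the 2ABT simulator.

Every agent exposes ``reset``, ``choose(rng)`` and ``update(choice, reward)``.
Choices are signed binaries (left = -1, right = +1).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Protocol, runtime_checkable

import numpy as np
from scipy.special import expit


@dataclass
class AgentParams:
    """RFLR parameters.

    alpha
        weight on repeating the last action (perseveration).
    beta
        weight on the accumulated action-reward evidence.
    tau
        evidence decay constant, in trials.
    phi0
        initial evidence.
    """

    alpha: float = 1.0
    beta: float = 2.0
    tau: float = 1.5
    phi0: float = 0.0

    def validate(self) -> None:
        if not self.tau > 0:
            raise ValueError(f"tau must be > 0, got {self.tau}")
        for name in ("alpha", "beta", "tau", "phi0"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")


@runtime_checkable
class Agent(Protocol):
    def reset(self) -> None: ...

    def choose(self, rng: np.random.Generator) -> int: ...

    def update(self, choice: int, reward: int) -> None: ...


class RFLRAgent:
    """Recursively formulated logistic regression agent.

    Evidence recursion  phi_{t+1} = c_t * r_t + exp(-1/tau) * phi_t  and
    choice log-odds     psi_t     = alpha * c_{t-1} + beta * phi_t,
    with P(choose right) = logistic(psi).  The first trial has no previous
    choice; its perseveration term is zero.
    """

    def __init__(self, params: AgentParams):
        params.validate()
        self.params = params
        self.reset()

    def reset(self) -> None:
        self.phi = self.params.phi0
        self.c_prev = 0

    def choose(self, rng: np.random.Generator) -> int:
        psi = self.params.alpha * self.c_prev + self.params.beta * self.phi
        return 1 if rng.random() < expit(psi) else -1

    def update(self, choice: int, reward: int) -> None:
        self.phi = choice * reward + np.exp(-1.0 / self.params.tau) * self.phi
        self.c_prev = choice


class WinStayLoseShiftAgent:
    """Deterministic win-stay / lose-shift (first choice random)."""

    def reset(self) -> None:
        self.c_prev = 0
        self.r_prev = 0

    def choose(self, rng: np.random.Generator) -> int:
        if self.c_prev == 0:
            return 1 if rng.random() < 0.5 else -1
        return self.c_prev if self.r_prev else -self.c_prev

    def update(self, choice: int, reward: int) -> None:
        self.c_prev = choice
        self.r_prev = reward


class RandomAgent:
    """Chooses each port with probability 1/2, ignoring outcomes."""

    def reset(self) -> None:
        pass

    def choose(self, rng: np.random.Generator) -> int:
        return 1 if rng.random() < 0.5 else -1

    def update(self, choice: int, reward: int) -> None:
        pass


class ConstantAgent:
    """Always chooses the same port."""

    def __init__(self, side: int = -1):
        if side not in (-1, 1):
            raise ValueError("side must be -1 (left) or +1 (right)")
        self.side = side

    def reset(self) -> None:
        pass

    def choose(self, rng: np.random.Generator) -> int:
        return self.side

    def update(self, choice: int, reward: int) -> None:
        pass
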