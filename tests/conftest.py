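import numpy as np
import pytest

from achda.agents import AgentParams, RFLRAgent
from achda.preprocess import TrialTensor
from achda.task import TaskConfig, simulate_session


@pytest.fixture(scope="session")
def session300():
    """A 300-trial RFLR session under the standard task conditions."""
    return simulate_session(
        TaskConfig(n_trials=300), RFLRAgent(AgentParams()), seed=101
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)


def make_tensor(data: np.ndarray, bin_width: float = 0.054,
                pre: float | None = None, channel: str = "x") -> TrialTensor:
    """Wrap a trials x bins array in a TrialTensor (alignment at pre)."""
    n_trials, n_bins = data.shape
    if pre is None:
        pre = bin_width * (n_bins // 2)
    post = bin_width * n_bins - pre
    return TrialTensor(
        data=np.asarray(data, float),
        align_event="side_entry",
        window=(pre, post),
        bin_width=bin_width,
        trial_index=np.arange(n_trials),
        channel=channel,
    )
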