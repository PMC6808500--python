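import numpy as np
import pytest

from walkvep.config import PipelineConfig
from walkvep.synth import SimConfig, simulate_session


@pytest.fixture(scope="session")
def pc() -> PipelineConfig:
    return PipelineConfig()


@pytest.fixture(scope="session")
def small_cfg() -> SimConfig:
    """One block per walking condition: 12 contrast periods, 72 targets."""
    return SimConfig(seed=11, n_blocks_per_condition=1)


@pytest.fixture(scope="session")
def small_session(small_cfg):
    """Fully rendered single-block-per-condition session with observer."""
    return simulate_session(small_cfg, participant=0)


def match_events(detected: np.ndarray, truth: np.ndarray,
                 tol_s: float = 0.05) -> tuple[float, float]:
    """Greedy 1:1 matching within ±tol; returns (recall, precision)."""
    detected = np.sort(np.asarray(detected, dtype=float))
    truth = np.sort(np.asarray(truth, dtype=float))
    if truth.size == 0:
        return 1.0, 1.0 if detected.size == 0 else 0.0
    if detected.size == 0:
        return 0.0, 1.0
    used = np.zeros(detected.size, dtype=bool)
    tp = 0
    for t in truth:
        d = np.abs(detected - t)
        d[used] = np.inf
        i = int(np.argmin(d))
        if d[i] <= tol_s:
            used[i] = True
            tp += 1
    return tp / truth.size, tp / detected.size
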