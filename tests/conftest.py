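import numpy as np
import pytest

from allelescan import (
    PositionFrequencyMatrix,
    SimulationConfig,
    pfm_to_pwm,
)
from allelescan.motif_analysis import PositionWeightMatrix


@pytest.fixture
def uniform_pwm():
    """Motif with no preference anywhere: every k-mer scores 0."""
    pfm = PositionFrequencyMatrix("uniform", np.ones((4, 11)))
    return pfm_to_pwm(pfm, pseudocount=0.0)


@pytest.fixture
def two_level_pwm():
    """L=2 motif: position 1 favors A/C equally, position 2 demands G.

    Built directly in log2-odds form so the disfavored cells are finite:
    AG and CG score 3.0; every other k-mer is at least 10 log2 units down.
    """
    log_odds = np.array(
        [
            [1.0, -10.0],  # A
            [1.0, -10.0],  # C
            [-10.0, 2.0],  # G
            [-10.0, -10.0],  # T
        ]
    )
    return PositionWeightMatrix(
        motif_id="two_level", log_odds=log_odds, background=np.full(4, 0.25)
    )


def random_count_pfm(rng: np.random.Generator, length: int) -> PositionFrequencyMatrix:
    """Random strictly positive count matrix (no pseudocount needed)."""
    counts = rng.integers(1, 50, size=(4, length)).astype(float)
    return PositionFrequencyMatrix(f"rand{length}", counts)


@pytest.fixture
def default_config():
    return SimulationConfig(seed=7)
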