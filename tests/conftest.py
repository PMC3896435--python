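import numpy as np
import pytest

import blockfc as b

PAIR = ("left_M1", "right_M1")
PAIR_COL = "left_M1-right_M1"


@pytest.fixture(scope="session")
def default_config():
    return b.SimulationConfig(seed=42)


@pytest.fixture(scope="session")
def small_config():
    """2 reps x 16 conditions over 2 runs = 32 blocks; fast."""
    return b.SimulationConfig(seed=11, reps_per_condition=2, n_runs=2)


@pytest.fixture(scope="session")
def full_session(default_config):
    """Full 128-block simulated session with default ground truth."""
    return b.simulate_session(default_config)


@pytest.fixture(scope="session")
def measure_table(full_session, default_config):
    """Preprocessed block-measure table joined with behavior."""
    design, log, tcs, truth = full_session
    clean, shifted = b.preprocess_session(tcs, design)
    behavior = b.score_log(log, shifted)
    table = b.build_block_measure_table(clean, shifted, pairs=[PAIR], behavior=behavior)
    return table, truth


def quiet_truth(rois=PAIR, conditions=None, coupling=None, beta=None,
                noise_sd=0.0, gains=None, error_prob=None, **kw):
    """Minimal ground truth: zero everything unless specified."""
    conditions = conditions or b.SimulationConfig().conditions
    zero = {c: 0.0 for c in conditions}
    return b.GroundTruth(
        rois=tuple(rois),
        beta={r: dict(beta[r] if beta else zero) for r in rois},
        coupling={tuple(rois[:2]): dict(coupling if coupling else zero)},
        noise_sd={r: noise_sd for r in rois},
        baseline={r: 100.0 for r in rois},
        nuisance_gains={r: np.asarray(gains, float) for r in rois} if gains else {},
        error_prob=error_prob or {},
        **kw,
    )
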