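"""Block-wise behavioral scoring of tapping logs.

Two measures per task block: the *actual* tapping speed, estimated from the
inter-response intervals of the right index finger, and the number of tapping
errors under sequence-specific rules:

a) unimanual — any press with the opposite (left) index finger;
b) synchronous / unbalanced — a press delayed by more than 100 ms relative to
   the expected-simultaneous press of the opposite finger (plus any press left
   without a partner);
c) alternating — each additional consecutive press with the same hand.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .simulate import COORDINATION_LEVEL, SessionDesign, TappingLog

#: Maximum left-right asynchrony (s) still counted as simultaneous.
SYNC_TOLERANCE_S = 0.100


def compute_actual_speed(log: TappingLog, block_id: int) -> float:
    """Tapping speed (Hz) as 1 / mean inter-response interval of right presses.

    Returns NaN (missing-value marker, never 0) for blocks with fewer than two
    right-finger presses.
    """
    presses = log.block_presses(block_id)
    right = np.sort(presses.loc[presses.hand == "R", "time_s"].values)
    if len(right) < 2:
        return float("nan")
    return 1.0 / float(np.mean(np.diff(right)))


def _greedy_pairs(left: np.ndarray, right: np.ndarray) -> tuple[list[tuple[int, int]], int]:
    """Globally greedy one-to-one pairing by ascending |dt|.

    Candidate pairs are sorted by (|dt|, right time) — ties resolved toward the
    earlier right press — and accepted while both presses are unused.  Returns
    the matched index pairs and the number of unpaired presses.
    """
    cand = sorted(
        ((abs(lt - rt), rt, i, j) for i, lt in enumerate(left) for j, rt in enumerate(right)),
        key=lambda c: (c[0], c[1]),
    )
    used_l: set[int] = set()
    used_r: set[int] = set()
    pairs: list[tuple[int, int]] = []
    for _, _, i, j in cand:
        if i in used_l or j in used_r:
            continue
        used_l.add(i)
        used_r.add(j)
        pairs.append((i, j))
    unpaired = (len(left) - len(pairs)) + (len(right) - len(pairs))
    return pairs, unpaired


def score_errors(log: TappingLog, block_id: int, sequence_type: str) -> int:
    """Number of tapping errors in one block under the sequence's rule."""
    presses = log.block_presses(block_id).sort_values("time_s", kind="stable")
    left = presses.loc[presses.hand == "L", "time_s"].values
    right = presses.loc[presses.hand == "R", "time_s"].values
    if sequence_type == "unimanual":
        return int(len(left))
    if sequence_type in ("synchronous", "unbalanced"):
        # expected-simultaneous right presses: all of them (synchronous) or
        # every other one, starting from the first (unbalanced half-pace rule)
        candidates = right if sequence_type == "synchronous" else right[::2]
        pairs, unpaired = _greedy_pairs(left, candidates)
        late = sum(1 for i, j in pairs if abs(left[i] - candidates[j]) > SYNC_TOLERANCE_S)
        return int(late + unpaired)
    if sequence_type == "alternating":
        hands = presses.hand.values
        return int(np.sum(hands[1:] == hands[:-1]))
    raise ValueError(f"unknown sequence type {sequence_type!r}")


@dataclass
class BlockBehavior:
    block_id: int
    condition: str
    sequence: str
    speed_hz: float
    actual_speed_hz: float
    n_errors: int
    error_rate: float
    n_right_presses: int
    n_left_presses: int


def score_log(log: TappingLog, design: SessionDesign) -> pd.DataFrame:
    """Score every task block; one row per block.

    ``error_rate`` normalises the error count by the expected number of
    right-finger presses (nominal pace x task duration).
    """
    rows = []
    for blk in design.blocks.itertuples():
        presses = log.block_presses(blk.block_id)
        n_r = int((presses.hand == "R").sum())
        n_l = int((presses.hand == "L").sum())
        n_err = score_errors(log, blk.block_id, blk.sequence)
        expected = blk.speed_hz * blk.duration_s
        rows.append(BlockBehavior(
            block_id=blk.block_id, condition=blk.condition, sequence=blk.sequence,
            speed_hz=blk.speed_hz,
            actual_speed_hz=compute_actual_speed(log, blk.block_id),
            n_errors=n_err,
            error_rate=n_err / expected if expected > 0 else float("nan"),
            n_right_presses=n_r, n_left_presses=n_l,
        ))
    df = pd.DataFrame([vars(b) for b in rows])
    df["coordination"] = df["sequence"].map(COORDINATION_LEVEL)
    return df


def behavioral_contrasts(table: pd.DataFrame, measure: str, dimension: str,
                         contrast_shape: str = "linear", scope: str = "subject",
                         levels=None):
    """Polynomial-contrast GLM on a block-behavior measure.

    Thin wrapper over :func:`blockfc.stats.contrast_glm`; see there for the
    model.  ``dimension`` is ``"speed"`` or ``"coordination"``.
    """
    from .stats import contrast_glm
    return contrast_glm(table, measure, dimension, shape=contrast_shape,
                        scope=scope, levels=levels)
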