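"""Plain-text readers and writers for the pipeline's tables.

Events are BIDS-style TSV (onset, duration, trial_type); tapping logs are TSV
(block_id, hand, time_s); time courses are a single TSV with run_id and
volume columns plus one column per ROI and nuisance trace.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .simulate import SessionDesign, TappingLog, TimecourseSet, parse_condition


def save_events(design: SessionDesign, path) -> None:
    design.events_frame().to_csv(path, sep="\t", index=False)


def load_events(path, tr_ms: float = 1000.0, run_volumes: int | None = None,
                block_rest_s: float = 20.0) -> SessionDesign:
    ev = pd.read_csv(path, sep="\t")
    blocks = ev.rename(columns={"onset": "onset_s", "duration": "duration_s",
                                "trial_type": "condition"})
    if "block_id" not in blocks:
        blocks["block_id"] = range(len(blocks))
    if "run_id" not in blocks:
        blocks["run_id"] = 0
    seq_speed = blocks["condition"].map(parse_condition)
    blocks["sequence"] = seq_speed.str[0]
    blocks["speed_hz"] = seq_speed.str[1]
    cols = ["block_id", "run_id", "condition", "sequence", "speed_hz",
            "onset_s", "duration_s"]
    if run_volumes is None:
        run_volumes = int((blocks.onset_s + blocks.duration_s).max() / (tr_ms / 1000.0)
                          + block_rest_s)
    return SessionDesign(blocks[cols], tr_ms, run_volumes, block_rest_s)


def save_tapping_log(log: TappingLog, path, injected_path=None) -> None:
    log.presses.to_csv(path, sep="\t", index=False)
    if injected_path is not None:
        log.injected_errors.to_csv(injected_path, sep="\t", index=False)


def load_tapping_log(path, injected_path=None) -> TappingLog:
    presses = pd.read_csv(path, sep="\t")
    injected = (pd.read_csv(injected_path, sep="\t") if injected_path
                else pd.DataFrame(columns=["block_id", "n_injected"]))
    return TappingLog(presses, injected)


def save_timecourses(tcs: TimecourseSet, path) -> None:
    tcs.to_frame().to_csv(path, sep="\t", index=False)


def load_timecourses(path, tr_ms: float = 1000.0) -> TimecourseSet:
    return TimecourseSet.from_frame(pd.read_csv(path, sep="\t"), tr_ms)


def save_roi_definitions(rois: list, path) -> None:
    Path(path).write_text(json.dumps([r.to_dict() for r in rois], indent=2))
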