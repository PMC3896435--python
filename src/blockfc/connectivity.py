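"""Block-wise windowed connectivity and activation measures.

For every task block, Pearson correlations between ROI pairs are computed in
three block-anchored windows — a 26-s "full task" window [+2, +28) covering
the rise and decline of the BOLD response, a 12-s "steady state" window
[+10, +22) covering only the plateau, and a 12-s "rest" window [-12, 0)
preceding the block — each Fisher-Z transformed; plus a per-ROI activation
level (percent signal change, steady-state vs. rest window means).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .simulate import COORDINATION_LEVEL, SessionDesign, TimecourseSet

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class WindowSpec:
    """Half-open time window [start, end) relative to block onset (seconds)."""

    name: str
    start_offset_s: float
    end_offset_s: float

    def __post_init__(self):
        if self.end_offset_s <= self.start_offset_s:
            raise ValueError("window end must be after start")

    def n_samples(self, tr_ms: float) -> int:
        return int(round((self.end_offset_s - self.start_offset_s) / (tr_ms / 1000.0)))


DEFAULT_WINDOWS = {
    "full_task": WindowSpec("full_task", 2.0, 28.0),
    "steady_state": WindowSpec("steady_state", 10.0, 22.0),
    "rest": WindowSpec("rest", -12.0, 0.0),
}


class WindowOutOfBounds(ValueError):
    """Raised when a block's window crosses the run boundary."""


def slice_block_window(series, block_onset_s: float, window: WindowSpec,
                       tr_ms: float = 1000.0) -> np.ndarray:
    """Samples of ``series`` in ``window`` anchored at ``block_onset_s``.

    The onset must sit on the volume grid (sub-TR onsets are rejected); the
    half-open convention makes the sample count exactly
    (end - start) / TR.
    """
    x = np.asarray(series, float)
    tr_s = tr_ms / 1000.0
    onset_vol = block_onset_s / tr_s
    if abs(onset_vol - round(onset_vol)) > 1e-6:
        raise ValueError(f"block onset {block_onset_s} s is not aligned to the "
                         f"{tr_ms:g}-ms volume grid")
    i0 = int(round(onset_vol + window.start_offset_s / tr_s))
    i1 = int(round(onset_vol + window.end_offset_s / tr_s))
    if i0 < 0 or i1 > len(x):
        raise WindowOutOfBounds(
            f"window {window.name} [{i0}, {i1}) crosses the run boundary [0, {len(x)})")
    return x[i0:i1]


def block_correlation(segment_a, segment_b) -> float:
    """Sample Pearson r; NaN (logged) when either segment has zero variance."""
    a = np.asarray(segment_a, float)
    b = np.asarray(segment_b, float)
    if len(a) != len(b):
        raise ValueError("segments differ in length")
    if len(a) < 3:
        raise ValueError("need at least 3 samples")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        log.warning("zero-variance segment; correlation undefined")
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1])


def fisher_z(r: float) -> float:
    """Variance-stabilising z = atanh(r), with |r| clipped to 1 - 1e-7."""
    return float(np.arctanh(np.clip(r, -1 + 1e-7, 1 - 1e-7)))


def block_activation_level(series, block_onset_s: float, tr_ms: float = 1000.0,
                           task_window: WindowSpec = DEFAULT_WINDOWS["steady_state"],
                           rest_window: WindowSpec = DEFAULT_WINDOWS["rest"]) -> float:
    """Percent signal change, steady-state task vs. preceding rest window.

    ``100 x (task mean - rest mean) / rest mean``; requires a positive rest
    mean (the series must carry its restored mean), else NaN (logged).
    """
    task = slice_block_window(series, block_onset_s, task_window, tr_ms)
    rest = slice_block_window(series, block_onset_s, rest_window, tr_ms)
    rest_mean = rest.mean()
    if rest_mean <= 0:
        log.warning("non-positive rest mean (%.3g); percent signal change undefined",
                    rest_mean)
        return float("nan")
    return float(100.0 * (task.mean() - rest_mean) / rest_mean)


def pair_column(roi_a: str, roi_b: str, window: str, stat: str) -> str:
    return f"{roi_a}-{roi_b}__{window}__{stat}"


def build_block_measure_table(tcs: TimecourseSet, design: SessionDesign,
                              windows: dict[str, WindowSpec] | None = None,
                              pairs: list[tuple[str, str]] | None = None,
                              behavior: pd.DataFrame | None = None,
                              subject: str | int = 1) -> pd.DataFrame:
    """One row per task block: windowed r/z per ROI pair + per-ROI activation.

    Blocks whose windows cross a run boundary are kept with NaN measures and a
    logged reason.  Columns follow ``pair__window__{r,z}`` and ``roi__psc``;
    behavioral columns are joined on ``block_id`` when provided.
    """
    windows = windows or DEFAULT_WINDOWS
    pairs = pairs or list(combinations(tcs.rois, 2))
    rows = []
    for blk in design.blocks.itertuples():
        frame = tcs.frames[blk.run_id]
        row: dict = {"subject": subject, "block_id": blk.block_id,
                     "run_id": blk.run_id, "condition": blk.condition,
                     "sequence": blk.sequence, "speed_hz": blk.speed_hz,
                     "coordination": COORDINATION_LEVEL.get(blk.sequence)}
        try:
            segs = {(roi, w): slice_block_window(frame[roi].values, blk.onset_s,
                                                 spec, tcs.tr_ms)
                    for w, spec in windows.items() for roi in tcs.rois}
        except WindowOutOfBounds as exc:
            log.warning("block %s skipped: %s", blk.block_id, exc)
            for a, b in pairs:
                for w in windows:
                    row[pair_column(a, b, w, "r")] = np.nan
                    row[pair_column(a, b, w, "z")] = np.nan
            for roi in tcs.rois:
                row[f"{roi}__psc"] = np.nan
            rows.append(row)
            continue
        for a, b in pairs:
            for w in windows:
                r = block_correlation(segs[(a, w)], segs[(b, w)])
                row[pair_column(a, b, w, "r")] = r
                row[pair_column(a, b, w, "z")] = fisher_z(r) if np.isfinite(r) else np.nan
        for roi in tcs.rois:
            row[f"{roi}__psc"] = block_activation_level(frame[roi].values, blk.onset_s,
                                                        tcs.tr_ms)
        rows.append(row)
    table = pd.DataFrame(rows)
    if behavior is not None:
        extra = behavior.drop(columns=[c for c in ("condition", "sequence", "speed_hz",
                                                   "coordination") if c in behavior],
                              errors="ignore")
        table = table.merge(extra, on="block_id", how="left")
    return table
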