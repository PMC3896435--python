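"""Temporal cleaning of ROI time courses.

Fixed order per run: (1) discard the leading T1-saturation volumes,
(2) high-pass filtering by regressing out a GLM Fourier basis (intercept,
linear trend, sine/cosine pairs at 1..n cycles per run), (3) nuisance
regression against the six rigid-body motion parameters plus white-matter and
ventricular traces.  Residuals keep the original series mean so percent signal
change stays well-defined downstream.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .simulate import NUISANCE_COLUMNS, SessionDesign, TimecourseSet

log = logging.getLogger(__name__)

STAGE_ORDER = ("discard", "highpass", "nuisance")


def discard_initial_volumes(series, k: int):
    """Drop the first ``k`` samples (rows).  Length must exceed ``k``."""
    n = len(series)
    if k < 0:
        raise ValueError("k must be >= 0")
    if n <= k:
        raise ValueError(f"cannot discard {k} volumes from a series of length {n}")
    if isinstance(series, pd.DataFrame):
        return series.iloc[k:].reset_index(drop=True)
    return np.asarray(series)[k:]


def fourier_basis(n_volumes: int, n_cycles: int) -> np.ndarray:
    """Columns: intercept, linear trend, sin/cos at 1..n_cycles cycles per run."""
    if n_cycles < 1:
        raise ValueError("n_cycles must be >= 1")
    if n_volumes <= 2 * n_cycles + 1:
        raise ValueError("series too short for the requested Fourier basis")
    t = np.arange(n_volumes) / n_volumes
    cols = [np.ones(n_volumes), t - t.mean()]
    for k in range(1, n_cycles + 1):
        cols.append(np.sin(2 * np.pi * k * t))
        cols.append(np.cos(2 * np.pi * k * t))
    basis = np.column_stack(cols)
    if np.linalg.matrix_rank(basis) < basis.shape[1]:
        raise ValueError("Fourier basis is rank-deficient")
    return basis


def highpass_fourier(series, n_cycles: int):
    """Residualise against the Fourier basis; the series mean is retained."""
    x = series.values if isinstance(series, pd.DataFrame) else np.asarray(series, float)
    one_d = x.ndim == 1
    x2 = x[:, None] if one_d else x
    basis = fourier_basis(x2.shape[0], n_cycles)
    beta, *_ = np.linalg.lstsq(basis, x2, rcond=None)
    out = x2 - basis @ beta + x2.mean(axis=0, keepdims=True)
    if isinstance(series, pd.DataFrame):
        return pd.DataFrame(out, columns=series.columns)
    return out[:, 0] if one_d else out


@dataclass
class NuisanceModel:
    """Design matrix of nuisance regressors (plus intercept when fitted).

    ``frame`` holds one column per regressor: three translations, three
    rotations, white-matter mean, ventricular mean.
    """

    frame: pd.DataFrame
    labels: tuple[str, ...] = field(init=False)

    def __post_init__(self):
        self.labels = tuple(self.frame.columns)
        demeaned = self.frame - self.frame.mean()
        zero = [c for c in demeaned.columns if np.allclose(demeaned[c], 0.0)]
        if zero:
            raise ValueError(f"all-zero nuisance regressors after demeaning: {zero}")

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, columns=NUISANCE_COLUMNS) -> "NuisanceModel":
        return cls(frame[list(columns)].reset_index(drop=True))

    def design_matrix(self) -> tuple[np.ndarray, list[str]]:
        """Demeaned regressors + intercept, collinear columns dropped."""
        X = self.frame.values - self.frame.values.mean(axis=0)
        keep = []
        for j in range(X.shape[1]):
            cand = X[:, keep + [j]]
            if np.linalg.matrix_rank(cand) == len(keep) + 1:
                keep.append(j)
            else:
                warnings.warn(f"dropping collinear nuisance regressor "
                              f"{self.labels[j]!r}", stacklevel=2)
        Xk = X[:, keep]
        cond = np.linalg.cond(Xk) if Xk.size else np.inf
        log.debug("nuisance design condition number: %.3g", cond)
        full = np.column_stack([np.ones(len(self.frame)), Xk])
        return full, ["intercept"] + [self.labels[j] for j in keep]


def nuisance_regression(series, model: NuisanceModel):
    """OLS residuals against the nuisance model, with the series mean restored.

    Residuals are exactly orthogonal to every retained regressor.
    """
    x = series.values if isinstance(series, pd.DataFrame) else np.asarray(series, float)
    one_d = x.ndim == 1
    x2 = x[:, None] if one_d else x
    if len(model.frame) != x2.shape[0]:
        raise ValueError("series and nuisance model have different lengths")
    X, _ = model.design_matrix()
    beta, *_ = np.linalg.lstsq(X, x2, rcond=None)
    out = x2 - X @ beta + x2.mean(axis=0, keepdims=True)
    if isinstance(series, pd.DataFrame):
        return pd.DataFrame(out, columns=series.columns)
    return out[:, 0] if one_d else out


def preprocess_session(tcs: TimecourseSet, design: SessionDesign,
                       k_discard: int = 5, n_cycles: int = 3,
                       order: tuple[str, ...] = STAGE_ORDER,
                       allow_reorder: bool = False,
                       ) -> tuple[TimecourseSet, SessionDesign]:
    """Run the full temporal-cleaning pipeline on every run.

    The stage order is fixed (discard -> high-pass -> nuisance regression);
    passing any other ``order`` is rejected unless ``allow_reorder`` is set,
    because reordering changes the results.
    """
    if tuple(order) != STAGE_ORDER and not allow_reorder:
        raise ValueError(f"preprocessing order {order} differs from {STAGE_ORDER}; "
                         "pass allow_reorder=True to override")
    frames = {}
    for run_id, frame in tcs.frames.items():
        df = frame
        for stage in order:
            if stage == "discard":
                df = discard_initial_volumes(df, k_discard)
            elif stage == "highpass":
                df = highpass_fourier(df, n_cycles)
            elif stage == "nuisance":
                model = NuisanceModel.from_frame(df, tcs.nuisance_columns)
                roi_cols = list(tcs.rois)
                cleaned = nuisance_regression(df[roi_cols], model)
                df = pd.concat([cleaned, df[list(tcs.nuisance_columns)]], axis=1)
            else:
                raise ValueError(f"unknown preprocessing stage {stage!r}")
        frames[run_id] = df.reset_index(drop=True)
    out = TimecourseSet(frames, tcs.tr_ms, tcs.rois, tcs.nuisance_columns, tcs.truth)
    return out, design.shifted(k_discard)
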