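"""Region-of-interest definition from a localizer run.

A voxelwise GLM (task boxcar convolved with the two-gamma HRF, plus nuisance
regressors) yields a t-map; ROIs are the up-to-20 most significant voxels of
the suprathreshold activation cluster closest to a seed coordinate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .hrf import HrfParams, convolve_boxcar
from .preprocess import NuisanceModel


@dataclass
class TMap:
    """Voxelwise t-statistics of the task contrast."""

    t: np.ndarray        # 3D
    df: int
    threshold_for = staticmethod(lambda p, df: float(stats.t.isf(p, df)))


def fit_localizer_glm(volume4d: np.ndarray, events: pd.DataFrame,
                      nuisance: NuisanceModel | None = None,
                      tr_ms: float = 1000.0, hrf: HrfParams = HrfParams()) -> TMap:
    """Voxelwise OLS of the localizer run; t of the mean task effect.

    One boxcar (x) HRF predictor per ``trial_type``, nuisance regressors, and
    an intercept; the contrast averages the task predictors.
    """
    shape = volume4d.shape[:3]
    n_vol = volume4d.shape[3]
    tr_s = tr_ms / 1000.0
    if (events.onset + events.duration).max() > n_vol * tr_s:
        raise ValueError("events extend beyond the series duration")
    task_cols = []
    for _, grp in events.groupby("trial_type"):
        task_cols.append(convolve_boxcar(grp.onset.values, grp.duration.values,
                                         n_vol, tr_s, hrf))
    n_task = len(task_cols)
    if n_task == 0 or all(np.ptp(c) == 0 for c in task_cols):
        raise ValueError("degenerate design: no task variance")
    cols = task_cols + [np.ones(n_vol)]
    if nuisance is not None:
        Xn, _ = nuisance.design_matrix()
        cols = task_cols + [Xn[:, j] for j in range(1, Xn.shape[1])] + [np.ones(n_vol)]
    X = np.column_stack(cols)
    Y = volume4d.reshape(-1, n_vol).T          # (T, V)
    pinv = np.linalg.pinv(X)
    beta = pinv @ Y
    resid = Y - X @ beta
    df = n_vol - X.shape[1]
    sigma2 = (resid ** 2).sum(axis=0) / df
    c = np.zeros(X.shape[1])
    c[:n_task] = 1.0 / n_task
    var_c = c @ np.linalg.inv(X.T @ X) @ c
    with np.errstate(invalid="ignore", divide="ignore"):
        t = (c @ beta) / np.sqrt(sigma2 * var_c)
    return TMap(t.reshape(shape), df)


@dataclass
class RoiDefinition:
    """Up to ``max_voxels`` suprathreshold voxels of the nearest cluster."""

    label: str
    seed_coord: tuple[float, float, float]
    voxels: np.ndarray            # (n, 3), sorted by descending t
    t_values: np.ndarray          # (n,)
    undersized: bool
    cluster_size: int
    meta: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {"label": self.label, "seed_coord": list(map(float, self.seed_coord)),
                "voxels": self.voxels.tolist(), "t_values": self.t_values.tolist(),
                "undersized": self.undersized, "cluster_size": self.cluster_size,
                **self.meta}


_SIX_CONN = ndimage.generate_binary_structure(3, 1)


def define_roi(tmap: TMap, threshold_p: float, seed_coord, max_voxels: int = 20,
               affine: np.ndarray | None = None, label: str = "roi") -> RoiDefinition:
    """Top-``max_voxels`` voxels of the suprathreshold cluster nearest the seed.

    The t-map is thresholded at positive t with p < ``threshold_p``
    (one-sided, activation); connected components use 6-connectivity; the
    component whose center of gravity lies nearest the seed (Euclidean, in mm
    when ``affine`` is given, voxel units otherwise) is selected, and its
    voxels are ranked by descending t (ties broken by flat voxel index).
    """
    if not np.all(np.isfinite(tmap.t)):
        raise ValueError("t-map contains non-finite values")
    t_crit = stats.t.isf(threshold_p, tmap.df)
    mask = tmap.t > t_crit
    labels, n_comp = ndimage.label(mask, structure=_SIX_CONN)
    if n_comp == 0:
        raise ValueError(
            f"no suprathreshold voxels at p<{threshold_p} (t>{t_crit:.2f}; "
            f"max t = {tmap.t.max():.2f})")
    seed = np.asarray(seed_coord, float)

    def to_space(vox):
        if affine is None:
            return np.asarray(vox, float)
        v = np.column_stack([np.atleast_2d(vox), np.ones(len(np.atleast_2d(vox)))])
        return (v @ affine.T)[:, :3]

    centers = ndimage.center_of_mass(mask, labels, range(1, n_comp + 1))
    dists = np.linalg.norm(to_space(centers) - seed, axis=1)
    best = int(np.argmin(dists)) + 1
    vox = np.argwhere(labels == best)
    tv = tmap.t[vox[:, 0], vox[:, 1], vox[:, 2]]
    flat = np.ravel_multi_index(vox.T, tmap.t.shape)
    order = np.lexsort((flat, -tv))           # descending t, ties by voxel index
    n = min(max_voxels, len(vox))
    return RoiDefinition(
        label=label, seed_coord=tuple(map(float, seed)),
        voxels=vox[order[:n]], t_values=tv[order[:n]],
        undersized=len(vox) < max_voxels, cluster_size=len(vox),
        meta={"threshold_p": threshold_p, "t_critical": float(t_crit),
              "cluster_distance": float(dists[best - 1])})


def extract_timecourse(volume4d: np.ndarray, roi: RoiDefinition) -> np.ndarray:
    """Unweighted mean time course over the ROI's voxels."""
    v = roi.voxels
    if (v < 0).any() or (v >= np.array(volume4d.shape[:3])).any():
        raise ValueError("ROI voxels fall outside the volume grid")
    return volume4d[v[:, 0], v[:, 1], v[:, 2], :].mean(axis=0)


def load_seed_table(path) -> pd.DataFrame:
    """Seed coordinates TSV with columns label, x, y, z."""
    df = pd.read_csv(path, sep="\t")
    missing = {"label", "x", "y", "z"} - set(df.columns)
    if missing:
        raise ValueError(f"seed table missing columns: {sorted(missing)}")
    return df
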