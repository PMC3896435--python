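"""Synthetic bimanual finger-tapping fMRI sessions with known ground truth.

The simulator emulates the study design downstream stages are built for: a
16-condition block design (4 tapping sequences of increasing bimanual
coordination demand x 4 right-finger speeds), 20-s task blocks alternating
with 20-s rest, 8 repetitions per condition spread over 8 runs (128 task
blocks), sampled at TR = 1000 ms.

Generated per session:

* a counterbalanced :class:`SessionDesign`,
* button-press logs with speed jitter and difficulty-scaled error injection,
* nuisance traces (6 motion parameters, white-matter, ventricle),
* ROI time courses built as boxcar (x) two-gamma-HRF responses whose amplitude
  is speed/hand modulated, plus a band-limited shared signal whose coupling
  tracks coordination demand, nuisance loadings, and AR(1) noise,
* optionally a small 4D localizer volume for the ROI-definition stage.

Every ground-truth parameter is recorded so recovery can be asserted exactly.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import signal as sp_signal

from .hrf import HrfParams, convolve_boxcar

SEQUENCES = ("unimanual", "synchronous", "alternating", "unbalanced")
#: Ordinal bimanual-coordination demand of each sequence (1 = unimanual).
COORDINATION_LEVEL = {seq: i + 1 for i, seq in enumerate(SEQUENCES)}

NUISANCE_COLUMNS = (
    "trans_x", "trans_y", "trans_z", "rot_x", "rot_y", "rot_z", "wm", "ventricle",
)


def condition_label(sequence: str, speed_hz: float) -> str:
    return f"{sequence}_{speed_hz:g}Hz"


def parse_condition(label: str) -> tuple[str, float]:
    sequence, speed = label.rsplit("_", 1)
    return sequence, float(speed.removesuffix("Hz"))


# ---------------------------------------------------------------------------
# configuration and ground truth
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SimulationConfig:
    """Session-level design parameters.

    Defaults reproduce the full design: 4 sequences x 4 speeds x 8 repetitions
    = 128 task blocks over 8 runs, 20-s task / 20-s rest at TR = 1000 ms, with
    5 discardable lead volumes plus one rest period before each run's first
    block.
    """

    tr_ms: float = 1000.0
    block_task_s: float = 20.0
    block_rest_s: float = 20.0
    n_runs: int = 8
    sequences: tuple[str, ...] = SEQUENCES
    speeds_hz: tuple[float, ...] = (1.0, 2.0, 3.0, 4.0)
    reps_per_condition: int = 8
    seed: int = 0
    discardable_lead_volumes: int = 5
    hrf: HrfParams = field(default_factory=HrfParams)

    def __post_init__(self):
        if self.tr_ms <= 0:
            raise ValueError("tr_ms must be positive")
        if self.reps_per_condition < 1 or self.n_runs < 1:
            raise ValueError("counts must be >= 1")

    @property
    def tr_s(self) -> float:
        return self.tr_ms / 1000.0

    @property
    def conditions(self) -> list[str]:
        return [condition_label(s, v) for s in self.sequences for v in self.speeds_hz]

    @property
    def n_blocks(self) -> int:
        return self.reps_per_condition * len(self.sequences) * len(self.speeds_hz)

    @property
    def run_volumes(self) -> int:
        """Volumes per run before lead-volume discard."""
        blocks_per_run = self.n_blocks // self.n_runs
        dur_s = (self.discardable_lead_volumes * self.tr_s + self.block_rest_s
                 + blocks_per_run * (self.block_task_s + self.block_rest_s))
        return int(round(dur_s / self.tr_s))


@dataclass
class GroundTruth:
    """Injected effect sizes for one simulated session.

    ``beta`` maps (roi, condition) to evoked BOLD amplitude (signal units on a
    ~100-unit baseline, so 1.0 ~= 1% signal change); ``coupling`` maps
    (roi_a, roi_b) pairs to per-condition shared-signal coupling lambda in
    [0, 1]; ``error_prob`` is the per-press behavioral error probability per
    sequence.
    """

    rois: tuple[str, ...]
    beta: dict[str, dict[str, float]]                       # roi -> condition -> amp
    coupling: dict[tuple[str, str], dict[str, float]]        # pair -> condition -> lambda
    coupling_gain: float = 2.0
    noise_sd: dict[str, float] = field(default_factory=dict)  # roi -> sd
    ar1_phi: float = 0.3
    baseline: dict[str, float] = field(default_factory=dict)
    nuisance_gains: dict[str, np.ndarray] = field(default_factory=dict)  # roi -> (8,)
    error_prob: dict[str, float] = field(default_factory=dict)            # sequence -> p
    jitter_sd_ms: float = 20.0
    shared_lowpass_hz: float = 0.15
    shared_lag_s: float = 2.0

    def __post_init__(self):
        for pair, per_cond in self.coupling.items():
            for lam in per_cond.values():
                if not 0.0 <= lam <= 1.0:
                    raise ValueError(f"coupling out of [0,1] for {pair}")
        if not -1.0 < self.ar1_phi < 1.0:
            raise ValueError("|ar1_phi| must be < 1")
        for p in self.error_prob.values():
            if not 0.0 <= p <= 1.0:
                raise ValueError("error_prob must lie in [0,1]")


def default_ground_truth(config: SimulationConfig) -> GroundTruth:
    """Ground truth reproducing the qualitative task effects the stages target.

    Left M1 amplitude rises with right-finger speed and falls mildly with
    coordination demand; right M1 is near-silent during unimanual (right-hand)
    tapping and speed-modulated otherwise.  Left-right M1 coupling rises
    strongly with coordination demand and mildly with speed, giving 16
    distinct coupling levels whose steady-state Fisher-z targets are evenly
    spaced (z = 0.25 ... 2.05), so the injected coupling ordering is
    recoverable from 8 blocks per condition.  Behavioral error probability
    scales with sequence difficulty.
    """
    rois = ("left_M1", "right_M1", "left_SMA", "right_SMA")
    beta: dict[str, dict[str, float]] = {r: {} for r in rois}
    pair = ("left_M1", "right_M1")
    coupling: dict[tuple[str, str], dict[str, float]] = {pair: {}}
    gain, noise_sd = 3.0, 0.3
    sigma_design = 0.45   # anticipated within-window non-shared SD
    for i, seq in enumerate(config.sequences):
        for j, v in enumerate(config.speeds_hz):
            c = condition_label(seq, v)
            beta["left_M1"][c] = 1.0 + 0.6 * j - 0.1 * i
            beta["right_M1"][c] = 0.0 if seq == "unimanual" else 0.8 + 0.5 * j - 0.1 * (i - 1)
            beta["left_SMA"][c] = 0.8 + 0.3 * j + 0.1 * i
            beta["right_SMA"][c] = 0.8 + 0.3 * j + 0.1 * i
            # invert r = (lambda g)^2 / ((lambda g)^2 + sigma^2) at the target z
            r_target = np.tanh(0.25 + 0.12 * (4 * i + j))
            lam = sigma_design / gain * np.sqrt(r_target / (1.0 - r_target))
            coupling[pair][c] = float(min(lam, 0.95))
    return GroundTruth(
        rois=rois,
        beta=beta,
        coupling=coupling,
        coupling_gain=gain,
        noise_sd={r: noise_sd for r in rois},
        baseline={r: 100.0 for r in rois},
        nuisance_gains={r: np.array([0.1] * 6 + [0.3, 0.3]) for r in rois},
        error_prob={"unimanual": 0.02, "synchronous": 0.05,
                    "alternating": 0.08, "unbalanced": 0.12},
    )


# ---------------------------------------------------------------------------
# session design
# ---------------------------------------------------------------------------

@dataclass
class SessionDesign:
    """Ordered task blocks with run-relative onsets (seconds, pre-discard)."""

    blocks: pd.DataFrame   # block_id, run_id, condition, sequence, speed_hz, onset_s, duration_s
    tr_ms: float
    run_volumes: int
    block_rest_s: float
    counterbalance: dict = field(default_factory=dict)

    @property
    def n_blocks(self) -> int:
        return len(self.blocks)

    def blocks_in_run(self, run_id: int) -> pd.DataFrame:
        return self.blocks[self.blocks.run_id == run_id]

    def shifted(self, k_volumes: int) -> "SessionDesign":
        """Design re-indexed after discarding ``k_volumes`` leading volumes."""
        blocks = self.blocks.copy()
        blocks["onset_s"] = blocks["onset_s"] - k_volumes * self.tr_ms / 1000.0
        return SessionDesign(blocks, self.tr_ms, self.run_volumes - k_volumes,
                             self.block_rest_s, dict(self.counterbalance))

    def events_frame(self) -> pd.DataFrame:
        """BIDS-style events table: onset, duration, trial_type (+ ids)."""
        ev = self.blocks.rename(columns={"onset_s": "onset", "duration_s": "duration",
                                         "condition": "trial_type"})
        return ev[["onset", "duration", "trial_type", "block_id", "run_id"]]


def generate_design(config: SimulationConfig) -> SessionDesign:
    """Counterbalanced block order for one session.

    The session order is ``reps_per_condition`` cycles of a seeded base
    permutation of the 16 conditions, each cycle rotated by
    ``round(n_conditions / reps)`` so every condition's mean serial position
    stays within one block of the grand mean.  Blocks are then split evenly
    across runs; each run opens with the discardable lead volumes plus one
    full rest period.
    """
    conditions = config.conditions
    n_cond = len(conditions)
    total = config.n_blocks
    if total % config.n_runs != 0:
        raise ValueError(
            f"{total} blocks cannot be divided evenly over {config.n_runs} runs")
    rng = np.random.default_rng(config.seed)
    base = list(rng.permutation(conditions))
    step = max(1, round(n_cond / config.reps_per_condition))
    order: list[str] = []
    for k in range(config.reps_per_condition):
        rot = (k * step) % n_cond
        order.extend(base[rot:] + base[:rot])

    blocks_per_run = total // config.n_runs
    lead_s = config.discardable_lead_volumes * config.tr_s
    period = config.block_task_s + config.block_rest_s
    rows = []
    for b, cond in enumerate(order):
        run_id = b // blocks_per_run
        j = b % blocks_per_run
        onset = lead_s + config.block_rest_s + j * period
        seq, speed = parse_condition(cond)
        rows.append((b, run_id, cond, seq, speed, onset, config.block_task_s))
    blocks = pd.DataFrame(rows, columns=["block_id", "run_id", "condition",
                                         "sequence", "speed_hz", "onset_s", "duration_s"])
    return SessionDesign(blocks, config.tr_ms, config.run_volumes, config.block_rest_s,
                         counterbalance={"base_order": base, "rotation_step": step})


# ---------------------------------------------------------------------------
# tapping logs
# ---------------------------------------------------------------------------

@dataclass
class TappingLog:
    """Button presses per block (times in seconds relative to block onset)."""

    presses: pd.DataFrame           # block_id, hand (L/R), time_s
    injected_errors: pd.DataFrame   # block_id, n_injected
    metadata: dict = field(default_factory=dict)

    def block_presses(self, block_id: int) -> pd.DataFrame:
        return self.presses[self.presses.block_id == block_id]


def _nonadjacent_choices(eligible: np.ndarray, p: float, rng, min_gap: int) -> np.ndarray:
    picks = eligible[rng.random(len(eligible)) < p]
    kept: list[int] = []
    for idx in picks:
        if not kept or idx - kept[-1] >= min_gap:
            kept.append(int(idx))
    return np.asarray(kept, dtype=int)


def generate_tapping_log(design: SessionDesign, truth: GroundTruth, seed: int) -> TappingLog:
    """Simulate button presses for every task block.

    Right-finger presses occur at the nominal pace with Gaussian timing jitter
    (clipped so that jitter alone can never violate an error rule); the left
    finger follows the sequence rule: absent (unimanual), simultaneous
    (synchronous), offset by half a period (alternating), or simultaneous with
    every other right press (unbalanced).  Errors are injected per sequence by
    the mechanism the scoring rules detect — a wrong-hand press, a 120-300 ms
    delayed left press, or an extra consecutive same-hand press — and the
    injected count per block is recorded.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xB10C]))
    jit = truth.jitter_sd_ms / 1000.0
    rows: list[tuple[int, str, float]] = []
    injected: list[tuple[int, int]] = []
    for blk in design.blocks.itertuples():
        seq, f, dur = blk.sequence, blk.speed_hz, blk.duration_s
        p_err = truth.error_prob.get(seq, 0.0)
        n_right = int(f * dur)
        period = 1.0 / f
        n_inj = 0
        # right-hand stream; jitter clipped to 40% of the half-period so the
        # alternating hand order is never scrambled by jitter alone
        clip = 0.4 * period / 2.0
        t_right = np.arange(n_right) * period + np.clip(
            rng.normal(0.0, jit, n_right), -clip, clip)
        t_right = np.clip(t_right, 0.0, np.nextafter(dur, 0.0))
        for t in t_right:
            rows.append((blk.block_id, "R", float(t)))

        if seq == "unimanual":
            extra = int((rng.random(n_right) < p_err).sum())
            for t in rng.uniform(0.0, dur, extra):
                rows.append((blk.block_id, "L", float(t)))  # wrong-hand errors
            n_inj = extra
        elif seq in ("synchronous", "unbalanced"):
            right_idx = np.arange(0, n_right, 1 if seq == "synchronous" else 2)
            # paired presses share the right press's jitter; asynchrony clipped
            # to +-80 ms keeps error-free pairs inside the 100-ms criterion
            async_sd = min(jit, 0.025)
            asyn = np.clip(rng.normal(0.0, async_sd, len(right_idx)), -0.08, 0.08)
            t_left = t_right[right_idx] + asyn
            interval = period * (1 if seq == "synchronous" else 2)
            delayed = _nonadjacent_choices(np.arange(len(t_left)), p_err, rng, min_gap=2)
            lo, hi = 0.12, min(0.30, 0.8 * interval)
            for i in delayed:
                t_left[i] = t_right[right_idx[i]] + rng.uniform(lo, hi)
            n_inj = len(delayed)
            for t in np.clip(t_left, 0.0, np.nextafter(dur, 0.0)):
                rows.append((blk.block_id, "L", float(t)))
        elif seq == "alternating":
            t_left = (np.arange(n_right) + 0.5) * period + np.clip(
                rng.normal(0.0, jit, n_right), -clip, clip)
            t_left = np.clip(t_left, 0.0, np.nextafter(dur, 0.0))
            for t in t_left:
                rows.append((blk.block_id, "L", float(t)))
            # extra consecutive same-hand presses, inserted mid-gap
            stream = sorted([(t, "R") for t in t_right] + [(t, "L") for t in t_left])
            picks = _nonadjacent_choices(np.arange(len(stream) - 1), p_err, rng, min_gap=1)
            for i in picks:
                t0, hand = stream[i]
                gap = stream[i + 1][0] - t0
                rows.append((blk.block_id, hand, float(t0 + rng.uniform(0.3, 0.7) * gap)))
            n_inj = len(picks)
        else:
            raise ValueError(f"unknown sequence type {seq!r}")
        injected.append((blk.block_id, n_inj))

    presses = pd.DataFrame(rows, columns=["block_id", "hand", "time_s"])
    presses = presses.sort_values(["block_id", "time_s"], kind="stable").reset_index(drop=True)
    inj = pd.DataFrame(injected, columns=["block_id", "n_injected"])
    return TappingLog(presses, inj, metadata={"jitter_sd_ms": truth.jitter_sd_ms,
                                              "error_prob": dict(truth.error_prob)})


# ---------------------------------------------------------------------------
# nuisance traces
# ---------------------------------------------------------------------------

def generate_nuisance(n_volumes: int, seed: int, tr_s: float = 1.0,
                      cardiac_aliased_hz: float = 0.05,
                      respiratory_hz: float = 0.30) -> pd.DataFrame:
    """Eight zero-mean nuisance traces: 6 motion, white matter, ventricle.

    Motion parameters are bounded random walks (tanh-saturated at ~1 mm /
    1 deg); the white-matter trace is a slow polynomial drift with occasional
    spikes; the ventricular trace is the sum of an aliased cardiac-like and a
    respiratory-like sinusoid plus noise.
    """
    if n_volumes < 2:
        raise ValueError("need at least 2 volumes")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x9015E]))
    t = np.arange(n_volumes) * tr_s
    cols = {}
    for name in NUISANCE_COLUMNS[:6]:
        walk = np.cumsum(rng.normal(0.0, 0.02, n_volumes))
        cols[name] = np.tanh(walk)  # soft bound at +-1
    drift = np.polyval(rng.normal(0.0, 0.5, 4), t / t[-1])
    spikes = np.zeros(n_volumes)
    for i in rng.choice(n_volumes, size=max(1, n_volumes // 200), replace=False):
        spikes[i] = rng.normal(0.0, 1.5)
    cols["wm"] = drift + spikes + rng.normal(0.0, 0.1, n_volumes)
    cols["ventricle"] = (np.sin(2 * np.pi * cardiac_aliased_hz * t + rng.uniform(0, 2 * np.pi))
                         + 0.7 * np.sin(2 * np.pi * respiratory_hz * t + rng.uniform(0, 2 * np.pi))
                         + rng.normal(0.0, 0.1, n_volumes))
    frame = pd.DataFrame(cols)
    return frame - frame.mean()


# ---------------------------------------------------------------------------
# ROI time courses
# ---------------------------------------------------------------------------

@dataclass
class TimecourseSet:
    """Per-run ROI time courses with nuisance traces attached.

    ``frames[run_id]`` holds one column per ROI plus the eight nuisance
    columns, one row per volume.
    """

    frames: dict[int, pd.DataFrame]
    tr_ms: float
    rois: tuple[str, ...]
    nuisance_columns: tuple[str, ...] = NUISANCE_COLUMNS
    truth: GroundTruth | None = None

    @property
    def run_ids(self) -> list[int]:
        return sorted(self.frames)

    def to_frame(self) -> pd.DataFrame:
        parts = []
        for run_id in self.run_ids:
            df = self.frames[run_id].copy()
            df.insert(0, "volume", np.arange(len(df)))
            df.insert(0, "run_id", run_id)
            parts.append(df)
        return pd.concat(parts, ignore_index=True)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, tr_ms: float) -> "TimecourseSet":
        rois = tuple(c for c in df.columns
                     if c not in ("run_id", "volume", "config_hash")
                     and c not in NUISANCE_COLUMNS)
        nuis = tuple(c for c in NUISANCE_COLUMNS if c in df.columns)
        drop = [c for c in ("run_id", "volume", "config_hash") if c in df.columns]
        frames = {int(r): g.drop(columns=drop).reset_index(drop=True)
                  for r, g in df.groupby("run_id")}
        return cls(frames, tr_ms, rois, nuis)


def _ar1_noise(n: int, phi: float, sd: float, rng) -> np.ndarray:
    e = rng.normal(0.0, sd, n)
    x = sp_signal.lfilter([1.0], [1.0, -phi], e)
    return x * np.sqrt(1.0 - phi ** 2)


def _shared_signal(n: int, fs: float, cutoff_hz: float, rng) -> np.ndarray:
    """Zero-mean unit-variance low-pass Gaussian signal of length ``n``."""
    pad = 30
    white = rng.normal(0.0, 1.0, n + 2 * pad)
    b, a = sp_signal.butter(2, min(0.99, cutoff_hz / (fs / 2.0)))
    s = sp_signal.lfilter(b, a, white)[pad:pad + n]
    s = s - s.mean()
    sd = s.std()
    return s / sd if sd > 0 else s


def generate_roi_timecourses(design: SessionDesign, truth: GroundTruth,
                             nuisance: dict[int, pd.DataFrame] | None = None,
                             seed: int = 0,
                             config: SimulationConfig | None = None) -> TimecourseSet:
    """Simulate ROI time courses for every run of ``design``.

    Signal model per ROI i:
    ``y_i(t) = baseline_i + sum_c beta_i(c) (boxcar_c (x) hrf)(t)
    + sum_pairs lambda_pair(c) g s_block(t) + gains_i . n(t) + AR(1) noise``
    where ``s_block`` is a zero-mean unit-variance <0.15 Hz signal restarted at
    each block onset and active from onset until 2 s past block offset
    (hemodynamic lag), so rest windows carry no shared signal.
    """
    cfg = config or SimulationConfig()
    tr_s = design.tr_ms / 1000.0
    fs = 1.0 / tr_s
    n_vol = design.run_volumes
    missing = set(design.blocks.condition) - set(next(iter(truth.beta.values())))
    if missing:
        raise ValueError(f"ground truth lacks conditions: {sorted(missing)}")
    ss = np.random.SeedSequence([seed, 0x7C5])
    run_seeds = ss.spawn(len(set(design.blocks.run_id)))
    frames: dict[int, pd.DataFrame] = {}
    for k, run_id in enumerate(sorted(set(design.blocks.run_id))):
        rng = np.random.default_rng(run_seeds[k])
        blocks = design.blocks_in_run(run_id)
        if nuisance is not None:
            nuis = nuisance[run_id]
        else:
            nuis = generate_nuisance(n_vol, seed=int(rng.integers(2 ** 31)), tr_s=tr_s)
        data = {r: np.full(n_vol, truth.baseline.get(r, 100.0)) for r in truth.rois}
        # evoked responses
        for cond, grp in blocks.groupby("condition"):
            x = convolve_boxcar(grp.onset_s.values, grp.duration_s.values,
                                n_vol, tr_s, cfg.hrf)
            for r in truth.rois:
                data[r] = data[r] + truth.beta[r][cond] * x
        # shared band-limited signal per block, per coupled pair
        for blk in blocks.itertuples():
            i0 = int(round(blk.onset_s / tr_s))
            i1 = min(n_vol, int(round((blk.onset_s + blk.duration_s + truth.shared_lag_s) / tr_s)))
            for (ra, rb), per_cond in truth.coupling.items():
                lam = per_cond[blk.condition]
                if lam == 0.0:
                    continue
                s = _shared_signal(i1 - i0, fs, truth.shared_lowpass_hz, rng)
                bump = lam * truth.coupling_gain * s
                data[ra][i0:i1] += bump
                data[rb][i0:i1] += bump
        # nuisance loadings and AR(1) noise
        nmat = nuis[list(NUISANCE_COLUMNS)].values
        for r in truth.rois:
            gains = truth.nuisance_gains.get(r)
            if gains is not None:
                data[r] = data[r] + nmat @ np.asarray(gains, float)
            sd = truth.noise_sd.get(r, 0.0)
            if sd > 0:
                data[r] = data[r] + _ar1_noise(n_vol, truth.ar1_phi, sd, rng)
        frame = pd.DataFrame({r: data[r] for r in truth.rois})
        for c in NUISANCE_COLUMNS:
            frame[c] = nuis[c].values
        frames[run_id] = frame
    return TimecourseSet(frames, design.tr_ms, truth.rois, NUISANCE_COLUMNS, truth)


def simulate_session(config: SimulationConfig, truth: GroundTruth | None = None,
                     ) -> tuple[SessionDesign, TappingLog, TimecourseSet, GroundTruth]:
    """Convenience wrapper: design + tapping log + time courses from one seed."""
    truth = truth or default_ground_truth(config)
    design = generate_design(config)
    log = generate_tapping_log(design, truth, seed=config.seed)
    tcs = generate_roi_timecourses(design, truth, seed=config.seed, config=config)
    return design, log, tcs, truth


# ---------------------------------------------------------------------------
# localizer volume
# ---------------------------------------------------------------------------

@dataclass
class ClusterSpec:
    center: tuple[int, int, int]
    n_voxels: int
    amplitude: float


@dataclass
class LocalizerVolume:
    data: np.ndarray                    # (x, y, z, t)
    events: pd.DataFrame                # onset, duration, trial_type
    clusters: list[np.ndarray]          # each (n, 3) voxel indices
    tr_ms: float

    def to_nifti(self, voxel_size_mm: float = 3.0):
        import nibabel as nib
        affine = np.diag([voxel_size_mm] * 3 + [1.0])
        return nib.Nifti1Image(self.data.astype(np.float32), affine)


def _grow_cluster(center: tuple[int, int, int], n: int, shape: tuple[int, int, int]) -> np.ndarray:
    """Deterministic 6-connected cluster of ``n`` voxels grown around ``center``."""
    heap = [(0.0, center)]
    seen = {center}
    out: list[tuple[int, int, int]] = []
    while heap and len(out) < n:
        _, v = heapq.heappop(heap)
        out.append(v)
        for d in ((1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)):
            w = (v[0] + d[0], v[1] + d[1], v[2] + d[2])
            if w in seen or not all(0 <= w[i] < shape[i] for i in range(3)):
                continue
            seen.add(w)
            dist = sum((w[i] - center[i]) ** 2 for i in range(3))
            heapq.heappush(heap, (float(dist), w))
    if len(out) < n:
        raise ValueError("cluster does not fit inside the grid")
    return np.array(out)


def generate_localizer_volume(grid_shape: tuple[int, int, int],
                              cluster_specs: list[ClusterSpec], seed: int,
                              n_blocks: int = 10, task_s: float = 20.0,
                              rest_s: float = 20.0, tr_ms: float = 1000.0,
                              noise_sd: float = 1.0, baseline: float = 100.0,
                              hrf: HrfParams = HrfParams()) -> LocalizerVolume:
    """Small 4D localizer fixture: task-locked signal in contiguous clusters.

    Each cluster's voxels carry ``amplitude x (boxcar (x) hrf)`` on top of the
    baseline; everywhere white Gaussian noise of ``noise_sd`` is added.
    """
    tr_s = tr_ms / 1000.0
    onsets = rest_s + np.arange(n_blocks) * (task_s + rest_s)
    n_vol = int(round((rest_s + n_blocks * (task_s + rest_s)) / tr_s))
    clusters = [_grow_cluster(cs.center, cs.n_voxels, grid_shape) for cs in cluster_specs]
    occupied: set[tuple[int, int, int]] = set()
    for vox in clusters:
        for v in map(tuple, vox):
            if v in occupied:
                raise ValueError("cluster specifications overlap")
            occupied.add(v)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x10CA]))
    x = convolve_boxcar(onsets, np.full(n_blocks, task_s), n_vol, tr_s, hrf)
    data = rng.normal(baseline, noise_sd, size=(*grid_shape, n_vol))
    for cs, vox in zip(cluster_specs, clusters):
        data[vox[:, 0], vox[:, 1], vox[:, 2], :] += cs.amplitude * x
    events = pd.DataFrame({"onset": onsets, "duration": task_s, "trial_type": "tap"})
    return LocalizerVolume(data, events, clusters, tr_ms)
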