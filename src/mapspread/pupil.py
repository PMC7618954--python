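"""Pupillometry preprocessing and the two-group cluster-permutation test.

Recordings are 500 Hz pupil-size traces with a missing-data mask and an
event table (regular vs oddball stimulus onsets).  The pipeline:
smoothing (120 ms Gaussian kernel) -> blink interpolation -> epoching
around stimulus onsets -> trial/subject QC (>1000 ms lost drops the
trial; >50% trials dropped flags the subject) -> per-block normalisation
(% difference from the block mean) -> baseline correction (mean of the
250 ms pre-stimulus window).  The oddball-minus-regular contrast per
subject feeds a cluster-based permutation test across groups.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import signal, stats

SAMPLE_RATE_HZ = 500.0


class UnusableRecordingError(RuntimeError):
    pass


class DataError(ValueError):
    pass


@dataclass
class PupilRecording:
    """One subject's continuous recording.

    ``events`` is a DataFrame with columns onset_s, condition
    ('regular' | 'oddball'); ``block`` labels samples by scan block.
    """

    time_s: np.ndarray
    pupil: np.ndarray
    missing: np.ndarray
    events: pd.DataFrame
    block: np.ndarray
    fs: float = SAMPLE_RATE_HZ

    def __post_init__(self) -> None:
        if np.any(np.diff(self.time_s) <= 0):
            raise DataError("sample times must be strictly increasing")
        if self.missing.shape != self.pupil.shape:
            raise DataError("missing mask not aligned to samples")

    def to_frame(self) -> pd.DataFrame:
        ev = np.full(self.time_s.size, "", object)
        for row in self.events.itertuples(index=False):
            i = int(round(row.onset_s * self.fs))
            if 0 <= i < ev.size:
                ev[i] = row.condition
        return pd.DataFrame({
            "time_s": self.time_s, "pupil": self.pupil,
            "missing": self.missing.astype(int), "event": ev,
            "block": self.block,
        })

    @classmethod
    def from_frame(cls, df: pd.DataFrame,
                   fs: float = SAMPLE_RATE_HZ) -> "PupilRecording":
        ev = df["event"].fillna("")
        has = ev != ""
        events = pd.DataFrame({
            "onset_s": df.loc[has, "time_s"].to_numpy(float),
            "condition": ev[has].to_numpy(object),
        })
        return cls(time_s=df["time_s"].to_numpy(float),
                   pupil=df["pupil"].to_numpy(float),
                   missing=df["missing"].to_numpy(bool),
                   events=events,
                   block=df["block"].to_numpy(int), fs=fs)


@dataclass
class EpochSet:
    """Trials x timepoints matrix of normalised, baseline-corrected pupil."""

    data: np.ndarray             # (n_trials, n_time), % of block mean
    times: np.ndarray            # seconds relative to stimulus onset
    condition: np.ndarray        # 'regular' | 'oddball' per retained trial
    n_dropped: int
    n_total: int
    subject_excluded: bool


def gaussian_kernel_sd_samples(kernel_ms: float, fs: float,
                               fwhm: bool = False) -> float:
    """Kernel width in samples; ``fwhm=True`` reads the width as FWHM."""
    sd_ms = kernel_ms / 2.3548200450309493 if fwhm else kernel_ms
    return sd_ms * 1e-3 * fs


def preprocess(rec: PupilRecording, kernel_ms: float = 120.0,
               fwhm: bool = False) -> PupilRecording:
    """Gaussian smoothing and linear blink interpolation.

    The kernel width is interpreted as the Gaussian SD by default (an
    FWHM reading is available).  Samples flagged missing are replaced by
    the straight line between the flanking valid samples *before*
    smoothing, so blinks do not bleed into neighbouring samples.
    """
    missing = rec.missing
    if missing.mean() > 0.5:
        raise UnusableRecordingError(
            f"{100 * missing.mean():.0f}% of the recording is missing")
    pupil = rec.pupil.astype(float).copy()
    if missing.any():
        valid = ~missing
        pupil[missing] = np.interp(rec.time_s[missing], rec.time_s[valid],
                                   pupil[valid])
    sd = gaussian_kernel_sd_samples(kernel_ms, rec.fs, fwhm=fwhm)
    half = int(np.ceil(4 * sd))
    kern = np.exp(-0.5 * (np.arange(-half, half + 1) / sd) ** 2)
    kern /= kern.sum()
    padded = np.concatenate([
        np.full(half, pupil[0]), pupil, np.full(half, pupil[-1])])
    smoothed = signal.fftconvolve(padded, kern, mode="same")[half:-half]
    return PupilRecording(time_s=rec.time_s, pupil=smoothed,
                          missing=missing.copy(), events=rec.events,
                          block=rec.block, fs=rec.fs)


def epoch_and_qc(rec: PupilRecording,
                 window: Tuple[float, float] = (-0.25, 10.0),
                 baseline_window: Tuple[float, float] = (-0.25, 0.0),
                 max_lost_ms: float = 1000.0,
                 max_dropped_frac: float = 0.5,
                 downsample: int = 1) -> EpochSet:
    """Cut, QC, normalise and baseline-correct epochs.

    A trial is dropped when more than ``max_lost_ms`` of its window was
    interpolated-missing; the subject is flagged excluded when more than
    ``max_dropped_frac`` of trials are dropped.  Normalisation expresses
    each sample as the percentage difference from the mean pupil size of
    its scan block; baseline correction subtracts the mean of the 250 ms
    pre-stimulus window.  ``downsample`` keeps every n-th sample of the
    epoch grid (applied after smoothing).
    """
    if len(rec.events) == 0:
        raise DataError("recording has no events to epoch around")
    fs = rec.fs
    lo = int(round(window[0] * fs))
    hi = int(round(window[1] * fs))
    n_time = hi - lo
    rel_t = np.arange(lo, hi) / fs

    # per-block normalisation
    norm = np.empty_like(rec.pupil)
    for b in np.unique(rec.block):
        selb = rec.block == b
        mu = rec.pupil[selb].mean()
        norm[selb] = 100.0 * (rec.pupil[selb] - mu) / mu

    max_lost = int(round(max_lost_ms * 1e-3 * fs))
    epochs, conds = [], []
    n_dropped = 0
    n_total = len(rec.events)
    for row in rec.events.itertuples(index=False):
        i0 = int(round(row.onset_s * fs))
        a, b_ = i0 + lo, i0 + hi
        if a < 0 or b_ > rec.pupil.size:
            n_dropped += 1
            continue
        if rec.missing[a:b_].sum() > max_lost:
            n_dropped += 1
            continue
        ep = norm[a:b_].copy()
        bl = slice(int(round(baseline_window[0] * fs)) - lo,
                   int(round(baseline_window[1] * fs)) - lo)
        ep -= ep[bl].mean()
        epochs.append(ep[::downsample])
        conds.append(row.condition)
    data = (np.asarray(epochs) if epochs
            else np.empty((0, len(rel_t[::downsample]))))
    return EpochSet(
        data=data, times=rel_t[::downsample],
        condition=np.asarray(conds, object),
        n_dropped=n_dropped, n_total=n_total,
        subject_excluded=(n_dropped > max_dropped_frac * n_total))


def oddball_contrast(epochs: EpochSet) -> np.ndarray:
    """Per-subject oddball-minus-regular mean time course."""
    odd = epochs.data[epochs.condition == "oddball"]
    reg = epochs.data[epochs.condition == "regular"]
    if odd.shape[0] == 0 or reg.shape[0] == 0:
        raise DataError("need retained trials in both conditions")
    return odd.mean(axis=0) - reg.mean(axis=0)


# ----------------------------------------------------------------------
@dataclass
class Cluster:
    start_s: float
    stop_s: float
    mass: float
    p_corrected: float


def _welch_t(a: np.ndarray, b: np.ndarray):
    """Pointwise Welch t statistic and df for (subjects x time) arrays."""
    na, nb = a.shape[0], b.shape[0]
    va = a.var(axis=0, ddof=1) / na
    vb = b.var(axis=0, ddof=1) / nb
    denom = np.sqrt(va + vb)
    denom[denom == 0] = np.inf
    t = (a.mean(axis=0) - b.mean(axis=0)) / denom
    df = (va + vb) ** 2 / (va ** 2 / (na - 1) + vb ** 2 / (nb - 1)
                           + 1e-300)
    return t, df


def _cluster_masses(t: np.ndarray, thresh: np.ndarray):
    """Contiguous supra-threshold runs of |t| scored by mass (sum |t|)."""
    at = np.abs(t)
    supra = at > thresh
    edges = np.diff(np.concatenate([[0], supra.astype(np.int8), [0]]))
    starts = np.flatnonzero(edges == 1)
    ends = np.flatnonzero(edges == -1)
    cs = np.concatenate([[0.0], np.cumsum(at)])
    masses = list(cs[ends] - cs[starts])
    bounds = list(zip(starts, ends))
    return masses, bounds


def cluster_permutation(group_a: np.ndarray, group_b: np.ndarray,
                        times: np.ndarray, n_perm: int = 10000,
                        alpha: float = 0.05,
                        cluster_alpha: float = 0.05,
                        rng: Optional[np.random.Generator] = None,
                        return_all: bool = False) -> List[Cluster]:
    """Two-group cluster-based permutation test on time courses.

    Pointwise Welch t values are thresholded at the two-sided
    ``cluster_alpha`` critical value; contiguous supra-threshold runs are
    scored by mass (sum of |t|) and compared against the permutation null
    of the maximum cluster mass obtained by shuffling subject labels.
    Returns clusters with corrected p < ``alpha`` (all clusters when
    ``return_all``).
    """
    a = np.atleast_2d(np.asarray(group_a, float))
    b = np.atleast_2d(np.asarray(group_b, float))
    if a.shape[1] != b.shape[1] or a.shape[1] != times.size:
        raise DataError("group time grids do not match")
    if a.shape[0] < 2 or b.shape[0] < 2:
        raise DataError("need at least 2 subjects per group")
    rng = rng or np.random.default_rng()
    na = a.shape[0]
    pooled = np.vstack([a, b])
    ntot = pooled.shape[0]

    # critical-value lookup over the attainable Welch df range (exact ppf
    # per timepoint per permutation would dominate the runtime)
    df_grid = np.linspace(1.0, ntot, 256)
    crit_grid = stats.t.ppf(1 - cluster_alpha / 2, df_grid)

    t_obs, df = _welch_t(a, b)
    thresh = np.interp(df, df_grid, crit_grid)
    masses, bounds = _cluster_masses(t_obs, thresh)
    if not masses:
        return []

    null_max = np.empty(n_perm)
    idx = np.arange(ntot)
    for i in range(n_perm):
        perm = rng.permutation(idx)
        pa, pb = pooled[perm[:na]], pooled[perm[na:]]
        t_p, df_p = _welch_t(pa, pb)
        th_p = np.interp(df_p, df_grid, crit_grid)
        m, _ = _cluster_masses(t_p, th_p)
        null_max[i] = max(m) if m else 0.0

    out = []
    for mass, (i, j) in zip(masses, bounds):
        p = float((1 + (null_max >= mass).sum()) / (1 + n_perm))
        if return_all or p < alpha:
            out.append(Cluster(start_s=float(times[i]),
                               stop_s=float(times[j - 1]),
                               mass=float(mass), p_corrected=p))
    return out
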