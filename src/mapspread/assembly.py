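"""Quantification of probe outcomes: rates, weight changes, overlap, spread.

All functions operate on :class:`~mapspread.network.ProtocolResult`
objects.  Ring distance between assemblies a and b on a k-ring is
min(|a-b|, k-|a-b|); on the 6-node ring the distances from assembly 1 are
1 (assemblies 2 and 6), 2 (3 and 5) and 3 (4).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional

import numpy as np
import pandas as pd
from scipy import stats

from .network import ProtocolResult, StageRecording


class DegenerateBaselineError(RuntimeError):
    """Baseline activity has zero variance everywhere; no threshold exists."""


def ring_distance(a: int, b: int, k: int) -> int:
    d = abs(a - b)
    return min(d, k - d)


@dataclass
class AssemblySummary:
    """Tidy per-assembly summary of one probe (1-based assembly ids)."""

    probe_id: int
    rate_stim: np.ndarray      # Hz, per assembly
    rate_base: np.ndarray      # Hz, per assembly
    overlap_pct: np.ndarray    # % of neurons recruited by the probe
    distance: np.ndarray       # ring distance to the probed assembly
    dw_from_probe: np.ndarray  # mean weight change probe->assembly (nS)

    def to_frame(self) -> pd.DataFrame:
        k = self.rate_stim.size
        return pd.DataFrame({
            "assembly": np.arange(1, k + 1),
            "distance": self.distance,
            "rate_stim": self.rate_stim,
            "rate_base": self.rate_base,
            "overlap_pct": self.overlap_pct,
            "dw_from_probe": self.dw_from_probe,
        })


def assembly_rates(stage: StageRecording, members: List[np.ndarray],
                   window: Optional[tuple] = None) -> np.ndarray:
    """Mean spike rate (Hz) per neuron per assembly within a time window.

    ``window`` is (start_s, stop_s) within the stage; default whole stage.
    Overlap neurons count toward every assembly containing them.
    """
    if window is None:
        lo_bin, hi_bin = 0, stage.n_bins
    else:
        lo, hi = window
        if hi <= lo:
            raise ValueError("empty analysis window")
        lo_bin = int(np.floor(lo / stage.bin_s))
        hi_bin = int(np.ceil(hi / stage.bin_s))
        if lo_bin < 0 or hi_bin > stage.n_bins:
            raise ValueError("window outside the recording")
    dur = (hi_bin - lo_bin) * stage.bin_s
    counts = stage.e_counts[lo_bin:hi_bin]
    return np.array([counts[:, m].sum() / m.size / dur for m in members])


def weight_change_matrix(before: np.ndarray, after: np.ndarray,
                         result: ProtocolResult) -> np.ndarray:
    """(k, k) mean weight change over existing E->E synapses per pair."""
    if before.shape != after.shape:
        raise ValueError("weight snapshots have mismatched sparsity pattern")
    dw = after - before
    k = len(result.members_E)
    out = np.zeros((k, k))
    pre_asm = _assembly_of(result, result.syn_pre)
    post_asm = _assembly_of(result, result.syn_post)
    for a in range(k):
        for b in range(k):
            sel = (pre_asm == a) & (post_asm == b)
            out[a, b] = dw[sel].mean() if sel.any() else 0.0
    return out


def _assembly_of(result: ProtocolResult, idx: np.ndarray) -> np.ndarray:
    """Assembly index per neuron id (-1 if none; overlap resolved to the
    lowest-numbered assembly for the pairwise weight table)."""
    lookup = np.full(result.config.N_E + result.config.N_I, -1)
    for a in reversed(range(len(result.members_E))):
        lookup[result.members_E[a]] = a
    return lookup[idx]


def functional_overlap(result: ProtocolResult, probe_id: int = 1,
                       k_sd: float = 2.0,
                       structural: bool = False) -> np.ndarray:
    """Percentage of each assembly's neurons recruited by the probe.

    Functional rule (default): a neuron is recruited when its mean rate in
    the stimulus window exceeds its own baseline mean + ``k_sd`` baseline
    SDs, where mean and SD are taken over the baseline's 100 ms bins.
    The structural variant instead counts neurons whose mean incoming
    weight from the probed assembly grew during the probe.
    """
    if structural:
        return _structural_overlap(result, probe_id)
    base = result.baseline
    stim = result.stimulus
    base_rates = base.neuron_bin_rates()        # (n_bins, N_E)
    mu = base_rates.mean(axis=0)
    sd = base_rates.std(axis=0)
    if np.all(sd == 0):
        raise DegenerateBaselineError(
            "baseline spike counts have zero variance for every neuron")
    stim_rate = stim.e_counts.sum(axis=0) / stim.duration_s
    recruited = stim_rate > mu + k_sd * sd
    return np.array([100.0 * recruited[m].mean() for m in result.members_E])


def _structural_overlap(result: ProtocolResult, probe_id: int) -> np.ndarray:
    dw = result.snapshots["post_probe"] - result.snapshots["pre_probe"]
    probe_members = result.members_E[probe_id - 1]
    pre_in_probe = np.zeros(result.config.N_E + result.config.N_I, bool)
    pre_in_probe[probe_members] = True
    sel = pre_in_probe[result.syn_pre] & (
        result.syn_post < result.config.N_E)
    gained = np.zeros(result.config.N_E)
    np.add.at(gained, result.syn_post[sel], dw[sel])
    out = []
    for m in result.members_E:
        out.append(100.0 * (gained[m] > 0).mean())
    return np.array(out)


def summarize(result: ProtocolResult, probe_id: int = 1,
              k_sd: float = 2.0) -> AssemblySummary:
    """Full per-assembly summary of a probe run."""
    k = len(result.members_E)
    rate_stim = assembly_rates(result.stimulus, result.members_E)
    rate_base = assembly_rates(result.baseline, result.members_E)
    overlap = functional_overlap(result, probe_id=probe_id, k_sd=k_sd)
    dwmat = weight_change_matrix(result.snapshots["pre_probe"],
                                 result.snapshots["post_probe"], result)
    p = probe_id - 1
    # symmetrised mean change between the probe and each assembly
    dw_from_probe = 0.5 * (dwmat[p, :] + dwmat[:, p])
    distance = np.array([ring_distance(probe_id, a, k)
                         for a in range(1, k + 1)])
    return AssemblySummary(probe_id=probe_id, rate_stim=rate_stim,
                           rate_base=rate_base, overlap_pct=overlap,
                           distance=distance, dw_from_probe=dw_from_probe)


def spread_gradient(summary: AssemblySummary):
    """Distance gradient of stimulus-window rates.

    Averages rates over assemblies at the same ring distance from the
    probe (on a 6-ring: d=1 -> {2,6}, d=2 -> {3,5}, d=3 -> {4}), then
    returns ``(rank_correlation, strict)`` where ``strict`` is True when
    the symmetric-averaged rates are strictly decreasing with distance.
    """
    k = summary.rate_stim.size
    if k < 4:
        raise ValueError("need at least 4 assemblies for a gradient")
    dists = np.unique(summary.distance[summary.distance > 0])
    means = np.array([summary.rate_stim[summary.distance == d].mean()
                      for d in dists])
    if np.allclose(means, means[0]):
        return 0.0, False
    rho = stats.spearmanr(dists, means).statistic
    strict = bool(np.all(np.diff(means) < 0))
    return float(rho), strict
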