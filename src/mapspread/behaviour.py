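"""Behavioural overgeneralisation statistics and resampling inference.

The task is an 11-node ring: eleven bird stimuli, each pair of
ring-adjacent birds sharing one context (sofa), so every bird belongs to
exactly two contexts.  The implicit memory test probes one bird against six
candidate contexts; errors to contexts *proximal* (one ring link away from
the correct context) rather than *distal* indicate a spread of association
around the ring.  Two per-subject scores quantify that spread:

* ``overgeneralisation_errors`` -- the per-trial-normalised excess of
  proximal over distal error choices, in percent (positive = proximal
  bias, 0 expected under uniform errors);
* ``mean_rank_proximity`` -- the mean rank of erroneous choices, where the
  correct context ranks 1, a neighbouring context 2, and so on.

Group inference uses label-permutation tests and bias-corrected bootstrap
effect sizes; the drug/placebo blinding check is Bang's Blinding Index.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

TRIAL_COLUMNS = ["subject", "group", "probe_bird", "options", "chosen",
                 "correct"]


class DataError(ValueError):
    pass


@dataclass(frozen=True)
class RingTask:
    """n-node ring of paired stimuli; context i joins birds i and i+1."""

    n_nodes: int = 11

    def __post_init__(self) -> None:
        if self.n_nodes < 4:
            raise ValueError("a ring task needs at least 4 nodes")

    def contexts_of(self, bird: int) -> Tuple[int, int]:
        """The two contexts a bird belongs to (pair-room with its
        clockwise neighbour, and with its anticlockwise neighbour)."""
        self._check(bird)
        return bird, (bird - 1) % self.n_nodes

    def correct_context(self, bird: int) -> int:
        """The designated correct context: the room shared with the
        clockwise neighbour (bird 1 -> sofa A convention)."""
        self._check(bird)
        return bird

    def _check(self, node: int) -> None:
        if not (0 <= node < self.n_nodes):
            raise IndexError(f"node {node} outside 0..{self.n_nodes - 1}")


@dataclass(frozen=True)
class ChoiceTrial:
    """One 6-alternative forced-choice probe."""

    subject: str
    group: str
    probe_bird: int
    options: Tuple[int, ...]
    chosen: int
    correct: int

    def __post_init__(self) -> None:
        if self.chosen not in self.options:
            raise DataError("chosen option not among the presented options")
        if self.correct not in self.options:
            raise DataError("correct option not among the presented options")

    @property
    def is_error(self) -> bool:
        return self.chosen != self.correct


def link_distance(i: int, j: int, n_nodes: int) -> int:
    """Shortest path between two nodes along the ring."""
    for x in (i, j):
        if not (0 <= x < n_nodes):
            raise IndexError(f"node {x} outside 0..{n_nodes - 1}")
    d = abs(i - j)
    return min(d, n_nodes - d)


def rank_proximity(trial: ChoiceTrial, task: RingTask) -> int:
    """Rank of the chosen context: correct = 1, one link off = 2, ..."""
    return link_distance(trial.correct, trial.chosen, task.n_nodes) + 1


def _classify_options(trial: ChoiceTrial, task: RingTask):
    """Split a trial's incorrect options into proximal (distance 1 from
    the correct context, either ring direction) and distal cues."""
    prox, dist = [], []
    for opt in trial.options:
        if opt == trial.correct:
            continue
        d = link_distance(trial.correct, opt, task.n_nodes)
        (prox if d == 1 else dist).append(opt)
    return prox, dist


def overgeneralisation_errors(trials: Sequence[ChoiceTrial],
                              task: RingTask) -> float:
    """Percentage excess of proximal over distal error choices.

    Per error trial, a proximal choice contributes 1/N_proximal and a
    distal choice -1/N_distal (each normalised by the number of such cues
    offered in that trial); the sum is divided by the number of trials
    with *opportunity* for an overgeneralisation error (error trials whose
    option set contains at least one proximal and one distal cue) and
    scaled to percent.  Uniform errors give 0 in expectation; returns NaN
    when no opportunity trial exists (undefined, distinct from 0).
    """
    num = 0.0
    n_opportunity = 0
    for tr in trials:
        if not tr.is_error:
            continue
        prox, dist = _classify_options(tr, task)
        if not prox or not dist:
            continue
        n_opportunity += 1
        if tr.chosen in prox:
            num += 1.0 / len(prox)
        else:
            num -= 1.0 / len(dist)
    if n_opportunity == 0:
        return float("nan")
    return 100.0 * num / n_opportunity


def mean_rank_proximity(trials: Sequence[ChoiceTrial],
                        task: RingTask) -> float:
    """Mean rank of erroneous choices (>= 2); NaN without error trials."""
    ranks = [rank_proximity(tr, task) for tr in trials if tr.is_error]
    if not ranks:
        return float("nan")
    return float(np.mean(ranks))


def topological_distance(bird_order: Sequence[int],
                         scene_between: Sequence[int],
                         task: RingTask) -> float:
    """Mean rank score of a participant's reconstructed ring.

    ``bird_order`` is the circular order the participant arranged the
    birds in; ``scene_between[i]`` is the scene they placed between
    ``bird_order[i]`` and ``bird_order[i+1]``.  A bird-bird adjacency
    scores its true link distance (correct neighbours score 1); a
    bird-scene placement scores the link distance between the placed
    scene and the true context of that adjacency, plus 1 (correct scene
    scores 1).
    """
    n = task.n_nodes
    if (len(bird_order) != n or len(scene_between) != n
            or set(bird_order) != set(range(n))):
        raise DataError("incomplete or invalid ring arrangement")
    scores = []
    for i in range(n):
        a, b = bird_order[i], bird_order[(i + 1) % n]
        scores.append(link_distance(a, b, n))
        # true context of the clockwise pair starting at a
        true_scene = task.correct_context(a)
        scores.append(link_distance(true_scene, scene_between[i], n) + 1)
    return float(np.mean(scores))


# ----------------------------------------------------------------------
# resampling inference

def permutation_test(group_a: np.ndarray, group_b: np.ndarray,
                     n_perm: int = 10000, sided: int = 2,
                     rng: Optional[np.random.Generator] = None) -> float:
    """Label-permutation p-value for a difference in group means.

    Two-sided by default; the add-one estimator
    p = (1 + #{|perm diff| >= |observed|}) / (1 + n_perm) avoids zero
    p-values.  ``sided=1`` tests mean(A) > mean(B).
    """
    a = np.asarray(group_a, float)
    b = np.asarray(group_b, float)
    if a.size < 2 or b.size < 2:
        raise DataError("need at least 2 values per group")
    rng = rng or np.random.default_rng()
    pooled = np.concatenate([a, b])
    if np.ptp(pooled) == 0:
        import warnings
        warnings.warn("constant pooled data; permutation p-value is 1")
        return 1.0
    obs = a.mean() - b.mean()
    na = a.size
    perm = np.empty(n_perm)
    for i in range(n_perm):
        shuffled = rng.permutation(pooled)
        perm[i] = shuffled[:na].mean() - shuffled[na:].mean()
    if sided == 2:
        exceed = np.abs(perm) >= abs(obs)
    elif sided == 1:
        exceed = perm >= obs
    else:
        raise ValueError("sided must be 1 or 2")
    return float((1 + exceed.sum()) / (1 + n_perm))


def bootstrap_effect(values: np.ndarray, n_boot: int = 10000,
                     alpha: float = 0.05, sided: int = 2,
                     rng: Optional[np.random.Generator] = None):
    """Bias-corrected bootstrap of the mean.

    Returns ``(effect, (lo, hi), p)``: the sample mean, a bias-corrected
    (BC) percentile confidence interval, and the add-one bootstrap
    p-value against a zero mean.
    """
    x = np.asarray(values, float)
    if x.size < 3:
        raise DataError("need at least 3 observations")
    rng = rng or np.random.default_rng()
    effect = float(x.mean())
    if np.ptp(x) == 0:
        import warnings
        warnings.warn("all values equal; bootstrap CI is degenerate")
        return effect, (effect, effect), 1.0 if effect == 0 else \
            1.0 / (1 + n_boot)
    idx = rng.integers(0, x.size, size=(n_boot, x.size))
    boots = x[idx].mean(axis=1)
    # bias correction: z0 from the fraction of resamples below the estimate
    prop = np.clip((boots < effect).mean(), 1.0 / n_boot,
                   1.0 - 1.0 / n_boot)
    z0 = stats.norm.ppf(prop)
    zlo, zhi = stats.norm.ppf(alpha / 2), stats.norm.ppf(1 - alpha / 2)
    lo = np.quantile(boots, stats.norm.cdf(2 * z0 + zlo))
    hi = np.quantile(boots, stats.norm.cdf(2 * z0 + zhi))
    n_le = (boots <= 0).sum()
    n_ge = (boots >= 0).sum()
    if sided == 2:
        p = 2.0 * (1 + min(n_le, n_ge)) / (1 + n_boot)
        p = min(p, 1.0)
    elif sided == 1:
        p = (1 + n_le) / (1 + n_boot)
    else:
        raise ValueError("sided must be 1 or 2")
    return effect, (float(lo), float(hi)), float(p)


def bangs_blinding_index(guesses_correct: Sequence[bool]) -> float:
    """Bang's Blinding Index for one treatment arm.

    2*(proportion of correct guesses) - 1: +1 means complete unblinding,
    -1 opposite guessing, 0 random guessing; |BI| <= 0.2 is conventionally
    classified as successful blinding.
    """
    g = np.asarray(list(guesses_correct), bool)
    if g.size == 0:
        return float("nan")
    return float(2.0 * g.mean() - 1.0)


def blinding_successful(bi: float, threshold: float = 0.2) -> bool:
    return bool(abs(bi) <= threshold)


# ----------------------------------------------------------------------
# trial-table I/O

def trials_to_frame(trials: Iterable[ChoiceTrial]) -> pd.DataFrame:
    rows = [{
        "subject": t.subject, "group": t.group, "probe_bird": t.probe_bird,
        "options": ";".join(map(str, t.options)),
        "chosen": t.chosen, "correct": t.correct,
    } for t in trials]
    return pd.DataFrame(rows, columns=TRIAL_COLUMNS)


def frame_to_trials(df: pd.DataFrame) -> List[ChoiceTrial]:
    out = []
    for row in df.itertuples(index=False):
        out.append(ChoiceTrial(
            subject=str(row.subject), group=str(row.group),
            probe_bird=int(row.probe_bird),
            options=tuple(int(x) for x in str(row.options).split(";")),
            chosen=int(row.chosen), correct=int(row.correct)))
    return out


def score_subjects(df: pd.DataFrame, task: RingTask) -> pd.DataFrame:
    """Per-subject metric table from a tidy trial table."""
    records = []
    for (subject, group), sub in df.groupby(["subject", "group"]):
        trials = frame_to_trials(sub)
        records.append({
            "subject": subject, "group": group,
            "accuracy": np.mean([not t.is_error for t in trials]),
            "og_errors": overgeneralisation_errors(trials, task),
            "rank_proximity": mean_rank_proximity(trials, task),
        })
    return pd.DataFrame(records)
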