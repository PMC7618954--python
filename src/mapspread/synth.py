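"""Synthetic data generators with known ground truth.

These stand in for the human cohort: behavioural choice tables on the
11-node ring task with a tunable spread-of-association parameter, 500 Hz
pupil recordings with phasic/tonic oddball structure and blinks, and
treatment-guess tables for the blinding index.  Every generator is a pure
function of its spec and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .behaviour import ChoiceTrial, RingTask, link_distance, trials_to_frame
from .pupil import PupilRecording


@dataclass(frozen=True)
class BehaviourGenSpec:
    """Choice-table generator settings.

    ``p_correct`` defaults to 0.25, mirroring the near-chance accuracy
    regime of the implicit test; ``spread_lambda`` controls how strongly
    errors concentrate at short link distance: an incorrect option at
    distance d from the correct context is drawn with probability
    proportional to exp(-lambda * (d - 1)).  lambda = 0 gives uniform
    errors and the proximal bias grows monotonically with lambda.
    """

    n_nodes: int = 11
    n_subjects: int = 22
    n_trials: int = 11
    p_correct: float = 0.25
    spread_lambda: float = 0.0
    n_options: int = 6
    group: str = "PLC"

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_correct <= 1.0):
            raise ValueError("p_correct must be in [0, 1]")
        if self.spread_lambda < 0:
            raise ValueError("spread_lambda must be >= 0")


@dataclass(frozen=True)
class PupilGenSpec:
    """Pupil-recording generator settings.

    Each subject gets ``n_trials`` stimulus events (oddball fraction
    ``p_oddball``, the ~9% regime) spaced ``event_spacing_s`` apart at
    500 Hz.  Oddballs evoke a phasic dilation for both groups; the
    ``tonic_amplitude`` adds a sustained oddball-only plateau over
    ``tonic_window_s`` (the 6-10 s window), which is where a group
    difference is injected by giving the groups different amplitudes.
    """

    n_subjects: int = 17
    n_trials: int = 44
    p_oddball: float = 0.09
    event_spacing_s: float = 11.5
    phasic_amplitude: float = 3.0      # % of block mean
    phasic_latency_s: float = 1.0
    phasic_width_s: float = 0.8
    tonic_amplitude: float = 0.0       # % of block mean, oddball only
    tonic_window_s: tuple = (6.0, 10.0)
    noise_sd: float = 1.0              # % of block mean, AR(1) smoothed
    blink_rate_hz: float = 0.05
    blink_duration_ms: tuple = (100.0, 400.0)
    baseline_au: float = 1000.0
    drift_amplitude: float = 5.0
    fs: float = 500.0


def gen_task(n_nodes: int = 11, seed: int | None = None) -> RingTask:
    """Ring task with pair (i, i+1 mod n) -> context i."""
    return RingTask(n_nodes=n_nodes)


def _error_probs(task: RingTask, correct: int, options: np.ndarray,
                 lam: float) -> np.ndarray:
    d = np.array([link_distance(correct, int(o), task.n_nodes)
                  for o in options], float)
    w = np.exp(-lam * (d - 1.0))
    return w / w.sum()


def gen_choices(spec: BehaviourGenSpec, task: RingTask,
                rng: np.random.Generator) -> pd.DataFrame:
    """Tidy trial table (one probe per bird per round, by default)."""
    trials: List[ChoiceTrial] = []
    n = task.n_nodes
    for s in range(spec.n_subjects):
        sid = f"{spec.group}{s:03d}"
        for t in range(spec.n_trials):
            probe = t % n
            correct = task.correct_context(probe)
            others = np.array([c for c in range(n) if c != correct])
            opts = rng.choice(others, size=spec.n_options - 1,
                              replace=False)
            options = tuple(np.concatenate([[correct], opts]))
            if rng.random() < spec.p_correct:
                chosen = correct
            else:
                incorrect = np.array(
                    [o for o in options if o != correct])
                p = _error_probs(task, correct, incorrect,
                                 spec.spread_lambda)
                chosen = int(rng.choice(incorrect, p=p))
            trials.append(ChoiceTrial(
                subject=sid, group=spec.group, probe_bird=probe,
                options=options, chosen=int(chosen), correct=correct))
    return trials_to_frame(trials)


def gen_cohort(spec_a: BehaviourGenSpec, spec_b: BehaviourGenSpec,
               task: RingTask, seed: int) -> pd.DataFrame:
    """Two-group cohort table (groups must carry distinct labels)."""
    rng = np.random.default_rng(seed)
    return pd.concat([gen_choices(spec_a, task, rng),
                      gen_choices(spec_b, task, rng)], ignore_index=True)


def gen_pupil(spec: PupilGenSpec, subject: str,
              rng: np.random.Generator) -> PupilRecording:
    """One subject's 500 Hz recording with events, blinks and noise."""
    fs = spec.fs
    spacing = spec.event_spacing_s
    pre = 2.0
    total_s = pre + spec.n_trials * spacing + 12.0
    n = int(round(total_s * fs))
    t = np.arange(n) / fs

    onsets = pre + np.arange(spec.n_trials) * spacing
    n_odd = max(1, int(round(spec.p_oddball * spec.n_trials)))
    odd_idx = rng.choice(spec.n_trials, size=n_odd, replace=False)
    conds = np.array(["regular"] * spec.n_trials, object)
    conds[odd_idx] = "oddball"

    # slow drift + AR(1)-smoothed noise, in % units around the baseline
    drift = spec.drift_amplitude * np.sin(
        2 * np.pi * t / (total_s / 1.5) + rng.uniform(0, 2 * np.pi))
    white = rng.normal(0.0, 1.0, n)
    phi = 0.995
    ar = lfilter([1.0], [1.0, -phi], white)
    ar *= spec.noise_sd / max(ar.std(), 1e-12)
    pct = drift + ar

    # stimulus-locked responses
    for onset, cond in zip(onsets, conds):
        i0 = int(round(onset * fs))
        # phasic: gamma-like bump for every stimulus, larger for oddballs
        span = int(round(4.0 * fs))
        tt = np.arange(span) / fs
        bump = (tt / spec.phasic_latency_s) ** 2 * np.exp(
            -tt / (spec.phasic_width_s / 2))
        bump = bump / max(bump.max(), 1e-12)
        amp = spec.phasic_amplitude * (1.5 if cond == "oddball" else 1.0)
        pct[i0:i0 + span] += amp * bump[:max(0, min(span, n - i0))][
            :len(pct[i0:i0 + span])]
        if cond == "oddball" and spec.tonic_amplitude != 0.0:
            w0, w1 = spec.tonic_window_s
            j0 = i0 + int(round(w0 * fs))
            j1 = i0 + int(round(w1 * fs))
            ramp_n = int(round(0.5 * fs))
            plateau = np.ones(j1 - j0)
            plateau[:ramp_n] = np.linspace(0, 1, ramp_n)
            plateau[-ramp_n:] *= np.linspace(1, 0, ramp_n)
            pct[j0:j1] += spec.tonic_amplitude * plateau[
                :len(pct[j0:j1])]

    pupil = spec.baseline_au * (1.0 + pct / 100.0)

    # blinks: Poisson process of short dropouts
    missing = np.zeros(n, bool)
    n_blinks = rng.poisson(spec.blink_rate_hz * total_s)
    for _ in range(n_blinks):
        start = rng.integers(0, n)
        dur = int(round(rng.uniform(*spec.blink_duration_ms) * 1e-3 * fs))
        missing[start:start + dur] = True

    events = pd.DataFrame({"onset_s": onsets, "condition": conds})
    return PupilRecording(time_s=t, pupil=pupil, missing=missing,
                          events=events, block=np.zeros(n, int), fs=fs)


def gen_pupil_cohort(spec_a: PupilGenSpec, spec_b: PupilGenSpec,
                     seed: int) -> Dict[str, List[PupilRecording]]:
    """Recordings for two groups ('A' gets spec_a, 'B' spec_b)."""
    rng = np.random.default_rng(seed)
    out: Dict[str, List[PupilRecording]] = {"A": [], "B": []}
    for g, spec in (("A", spec_a), ("B", spec_b)):
        for s in range(spec.n_subjects):
            out[g].append(gen_pupil(spec, f"{g}{s:03d}", rng))
    return out


def gen_blinding(n_per_group: int, p_correct_guess: float,
                 rng: np.random.Generator) -> pd.DataFrame:
    """Bernoulli guess table for one arm pair."""
    if not (0.0 <= p_correct_guess <= 1.0):
        raise ValueError("p_correct_guess must be in [0, 1]")
    rows = []
    for arm in ("ATX", "PLC"):
        correct = rng.random(n_per_group) < p_correct_guess
        for i, c in enumerate(correct):
            rows.append({"subject": f"{arm}{i:03d}", "arm": arm,
                         "guess_correct": bool(c)})
    return pd.DataFrame(rows)
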