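"""Behavioural overgeneralisation metrics and resampling inference."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mapspread.behaviour import (
    ChoiceTrial, DataError, RingTask, bangs_blinding_index,
    blinding_successful, bootstrap_effect, frame_to_trials, link_distance,
    mean_rank_proximity, overgeneralisation_errors, permutation_test,
    rank_proximity, topological_distance, trials_to_frame,
)

TASK = RingTask(11)


def _trial(probe, chosen, correct, options=None, subject="s0",
           group="PLC"):
    if options is None:
        opts = {correct, chosen}
        for c in range(11):
            if len(opts) == 6:
                break
            opts.add(c)
        options = tuple(sorted(opts))
    return ChoiceTrial(subject=subject, group=group, probe_bird=probe,
                       options=tuple(options), chosen=chosen,
                       correct=correct)


# ---------------------------------------------------------------- distances
@pytest.mark.parametrize("i,j,n,d", [(1, 1, 11, 0), (1, 2, 11, 1),
                                     (1, 7, 11, 5), (0, 10, 11, 1)])
def test_link_distance_examples(i, j, n, d):
    assert link_distance(i, j, n) == d


@given(st.integers(0, 10), st.integers(0, 10))
@settings(deadline=None, derandomize=True)
def test_link_distance_symmetric_and_bounded(i, j):
    d = link_distance(i, j, 11)
    assert d == link_distance(j, i, 11)
    assert 0 <= d <= 5
    # brute force over both ring directions
    assert d == min((i - j) % 11, (j - i) % 11)


def test_link_distance_range_check():
    with pytest.raises(IndexError):
        link_distance(0, 11, 11)


# ------------------------------------------------------------ rank proximity
def test_rank_proximity_worked_examples():
    # probe bird 1, correct context A (= context 1 in 0-based: bird 1's
    # pair-room with its clockwise neighbour); choosing the next context
    # around the ring ranks 2, three links off ranks 4
    correct = TASK.correct_context(1)
    assert rank_proximity(_trial(1, (correct + 1) % 11, correct), TASK) == 2
    assert rank_proximity(_trial(1, (correct + 3) % 11, correct), TASK) == 4
    assert rank_proximity(_trial(1, correct, correct), TASK) == 1


def test_choice_outside_options_is_a_data_error():
    with pytest.raises(DataError):
        ChoiceTrial(subject="s", group="PLC", probe_bird=0,
                    options=(0, 1, 2, 3, 4, 5), chosen=9, correct=0)


# --------------------------------------------------- overgeneralisation score
def test_always_proximal_chooser_scores_plus_100():
    trials = []
    for probe in range(11):
        c = TASK.correct_context(probe)
        prox = (c + 1) % 11
        distal = [(c + k) % 11 for k in (3, 4, 5)]
        trials.append(_trial(probe, prox, c,
                             options=(c, prox, *distal, (c + 7) % 11)))
    assert overgeneralisation_errors(trials, TASK) == pytest.approx(100.0)


def test_always_distal_chooser_scores_negative_per_normalisation():
    # a distal choice contributes -1/N_distal per trial; with 1 proximal
    # and 4 distal cues offered the always-distal policy scores -25
    trials = []
    for probe in range(11):
        c = TASK.correct_context(probe)
        prox = (c + 1) % 11
        distal = (c + 4) % 11
        trials.append(_trial(probe, distal, c,
                             options=(c, prox, distal, (c + 3) % 11,
                                      (c + 5) % 11, (c + 7) % 11)))
    assert overgeneralisation_errors(trials, TASK) == pytest.approx(-25.0)


def test_all_correct_subject_is_undefined_not_zero():
    trials = [_trial(p, TASK.correct_context(p), TASK.correct_context(p))
              for p in range(11)]
    assert np.isnan(overgeneralisation_errors(trials, TASK))
    assert np.isnan(mean_rank_proximity(trials, TASK))


def test_uniform_errors_score_near_zero(rng):
    # uniform choice among the 5 incorrect options has expectation 0
    from mapspread.synth import BehaviourGenSpec, gen_choices
    spec = BehaviourGenSpec(n_subjects=1, n_trials=10000, p_correct=0.0,
                            spread_lambda=0.0, group="N")
    trials = frame_to_trials(gen_choices(spec, TASK, rng))
    assert abs(overgeneralisation_errors(trials, TASK)) < 2.0


def test_mean_rank_proximity_bounds_and_chance():
    c = TASK.correct_context(3)
    assert mean_rank_proximity(
        [_trial(3, (c + 1) % 11, c)], TASK) == pytest.approx(2.0)
    # maximal-distance errors rank 6 on an 11-ring
    far = (c + 5) % 11
    assert mean_rank_proximity([_trial(3, far, c)], TASK) == 6.0
    # enumeration oracle for the chance level: sampling 5 of the 10
    # incorrect cues then choosing uniformly is choosing uniformly among
    # all 10, so chance = mean over d in {1..5} x2 of (d+1) = 4.0
    dists = [link_distance(c, o, 11) for o in range(11) if o != c]
    chance = np.mean([d + 1 for d in dists])
    assert chance == pytest.approx(4.0)


def test_uniform_errors_hit_the_enumeration_chance_level(rng):
    from mapspread.synth import BehaviourGenSpec, gen_choices
    spec = BehaviourGenSpec(n_subjects=1, n_trials=10000, p_correct=0.0,
                            spread_lambda=0.0, group="N")
    trials = frame_to_trials(gen_choices(spec, TASK, rng))
    assert mean_rank_proximity(trials, TASK) == pytest.approx(4.0, abs=0.06)


# --------------------------------------------------------- ring arrangement
def test_topological_distance_perfect_reconstruction():
    order = list(range(11))
    scenes = [TASK.correct_context(i) for i in order]
    assert topological_distance(order, scenes, TASK) == pytest.approx(1.0)


def test_topological_distance_scores_misplacements():
    order = list(range(11))
    scenes = [TASK.correct_context(i) for i in order]
    scenes[0] = (scenes[0] + 1) % 11  # one scene one link off
    score = topological_distance(order, scenes, TASK)
    assert score == pytest.approx(1.0 + 1.0 / 22.0)
    with pytest.raises(DataError):
        topological_distance(order[:-1], scenes, TASK)


# ------------------------------------------------------------- permutation
def test_permutation_test_null_and_extreme_cases(rng):
    a = rng.normal(0, 1, 20)
    p = permutation_test(a, a.copy(), n_perm=2000, rng=rng)
    assert p > 0.9
    b = rng.normal(0, 1, 20)
    p = permutation_test(a + 10.0, b, n_perm=2000, rng=rng)
    assert p == pytest.approx(1 / 2001)


def test_permutation_test_type_one_error_calibrated(rng):
    hits = 0
    reps = 400
    for _ in range(reps):
        a = rng.normal(0, 1, 22)
        b = rng.normal(0, 1, 22)
        if permutation_test(a, b, n_perm=400, rng=rng) < 0.05:
            hits += 1
    assert 0.02 <= hits / reps <= 0.08


def test_permutation_pvalues_superuniform_under_null(rng):
    ps = np.array([
        permutation_test(rng.normal(0, 1, 10), rng.normal(0, 1, 10),
                         n_perm=200, rng=rng)
        for _ in range(500)])
    grid = np.linspace(0.05, 0.95, 10)
    ecdf = np.array([(ps <= g).mean() for g in grid])
    assert np.all(ecdf <= grid + 0.06)


def test_permutation_constant_data_warns(rng):
    with pytest.warns(UserWarning):
        p = permutation_test(np.ones(5), np.ones(5), n_perm=100, rng=rng)
    assert p == 1.0


# --------------------------------------------------------------- bootstrap
def test_bootstrap_symmetric_data_and_degenerate(rng):
    a = rng.normal(0, 1, 15)
    x = np.concatenate([a, -a])  # exactly symmetric about 0
    eff, (lo, hi), p = bootstrap_effect(x, n_boot=2000, rng=rng)
    assert lo < 0 < hi
    assert p > 0.4
    with pytest.warns(UserWarning):
        eff, ci, _ = bootstrap_effect(np.full(5, 3.0), rng=rng)
    assert eff == 3.0 and ci == (3.0, 3.0)


def test_bootstrap_ci_coverage(rng):
    covered = 0
    reps = 300
    for _ in range(reps):
        x = rng.normal(1.0, 1.0, 22)
        _, (lo, hi), _ = bootstrap_effect(x, n_boot=600, rng=rng)
        covered += lo <= 1.0 <= hi
    assert 0.90 <= covered / reps <= 0.98


# ---------------------------------------------------------------- blinding
def test_blinding_index_anchors():
    assert bangs_blinding_index([True] * 10) == 1.0
    assert bangs_blinding_index([False] * 10) == -1.0
    assert bangs_blinding_index([True] * 5 + [False] * 5) == 0.0
    assert blinding_successful(0.15) and not blinding_successful(0.45)
    assert np.isnan(bangs_blinding_index([]))


# ------------------------------------------------------------------- I/O
def test_trial_table_roundtrip(rng):
    from mapspread.synth import BehaviourGenSpec, gen_choices
    spec = BehaviourGenSpec(n_subjects=3, n_trials=11)
    df = gen_choices(spec, TASK, rng)
    trials = frame_to_trials(df)
    df2 = trials_to_frame(trials)
    assert df.equals(df2)
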