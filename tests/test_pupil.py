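"""Pupillometry preprocessing, QC, contrast and cluster inference."""

import numpy as np
import pandas as pd
import pytest

from mapspread.pupil import (
    Cluster, DataError, EpochSet, PupilRecording, UnusableRecordingError,
    cluster_permutation, epoch_and_qc, gaussian_kernel_sd_samples,
    oddball_contrast, preprocess,
)
from mapspread.synth import PupilGenSpec, gen_pupil

FS = 500.0


def _recording(pupil, events=None, missing=None, fs=FS):
    n = pupil.size
    t = np.arange(n) / fs
    if events is None:
        events = pd.DataFrame({"onset_s": [], "condition": []})
    if missing is None:
        missing = np.zeros(n, bool)
    return PupilRecording(time_s=t, pupil=pupil, missing=missing,
                          events=events, block=np.zeros(n, int), fs=fs)


def test_constant_trace_unchanged_by_preprocessing():
    rec = _recording(np.full(5000, 1000.0))
    out = preprocess(rec)
    assert np.allclose(out.pupil, 1000.0)


def test_impulse_attenuated_by_kernel_gain():
    x = np.zeros(20001)
    x[10000] = 1.0
    out = preprocess(_recording(x + 100.0))
    sd = gaussian_kernel_sd_samples(120.0, FS)
    expected_peak = 1.0 / (np.sqrt(2 * np.pi) * sd)
    assert out.pupil[10000] - 100.0 == pytest.approx(expected_peak,
                                                     rel=1e-2)


def test_fwhm_convention_narrower_than_sd():
    assert gaussian_kernel_sd_samples(120.0, FS, fwhm=True) < \
        gaussian_kernel_sd_samples(120.0, FS)


def test_blink_gap_linearly_interpolated():
    x = np.linspace(0, 1, 3000) * 0.0 + 500.0
    x[1000:1100] = 0.0  # lost samples
    missing = np.zeros(3000, bool)
    missing[1000:1100] = True
    out = preprocess(_recording(x, missing=missing))
    assert np.allclose(out.pupil[1000:1100], 500.0, atol=1e-6)


def test_mostly_missing_recording_rejected():
    missing = np.ones(1000, bool)
    missing[:400] = False
    with pytest.raises(UnusableRecordingError):
        preprocess(_recording(np.ones(1000), missing=missing))


def _events(onsets, conds):
    return pd.DataFrame({"onset_s": onsets, "condition": conds})


def test_epoching_retains_clean_trials_and_flags_bad_subjects(rng):
    n = int(60 * FS)
    pupil = 1000.0 + rng.normal(0, 1, n)
    onsets = [5.0, 17.0, 29.0, 41.0]
    ev = _events(onsets, ["regular"] * 4)
    rec = _recording(pupil, events=ev)
    ep = epoch_and_qc(rec)
    assert ep.data.shape[0] == 4 and ep.n_dropped == 0
    assert not ep.subject_excluded
    # >1000 ms lost in three of four epochs: those drop, subject flagged
    missing = np.zeros(n, bool)
    for onset in onsets[:3]:
        i = int(onset * FS)
        missing[i:i + 600] = True
    rec = _recording(pupil, events=ev, missing=missing)
    ep = epoch_and_qc(rec)
    assert ep.data.shape[0] == 1 and ep.n_dropped == 3
    assert ep.subject_excluded


def test_flat_trace_gives_identically_zero_epochs():
    n = int(40 * FS)
    ev = _events([5.0, 20.0], ["regular", "oddball"])
    ep = epoch_and_qc(_recording(np.full(n, 800.0), events=ev))
    assert np.allclose(ep.data, 0.0)


def test_normalisation_invariant_to_gain():
    n = int(40 * FS)
    rng = np.random.default_rng(3)
    pupil = 1000.0 + np.cumsum(rng.normal(0, 0.1, n))
    ev = _events([5.0, 20.0], ["regular", "oddball"])
    e1 = epoch_and_qc(_recording(pupil, events=ev))
    e2 = epoch_and_qc(_recording(pupil * 3.7, events=ev))
    assert np.allclose(e1.data, e2.data, atol=1e-9)


def test_baseline_window_mean_is_zero():
    n = int(40 * FS)
    rng = np.random.default_rng(4)
    pupil = 1000.0 + np.cumsum(rng.normal(0, 0.2, n))
    ev = _events([5.0, 20.0], ["regular", "oddball"])
    ep = epoch_and_qc(_recording(pupil, events=ev))
    bl = ep.times < 0
    assert np.allclose(ep.data[:, bl].mean(axis=1), 0.0, atol=1e-9)


def test_no_events_is_a_data_error():
    with pytest.raises(DataError):
        epoch_and_qc(_recording(np.ones(1000)))


def test_oddball_contrast_reproduces_an_injected_bump():
    times = np.arange(100) / FS
    data = np.zeros((10, 100))
    cond = np.array(["regular"] * 7 + ["oddball"] * 3, object)
    data[7:, 50:60] = 2.0
    ep = EpochSet(data=data, times=times, condition=cond, n_dropped=0,
                  n_total=10, subject_excluded=False)
    c = oddball_contrast(ep)
    assert np.allclose(c[50:60], 2.0) and np.allclose(c[:50], 0.0)
    ep_bad = EpochSet(data=data[:7], times=times, condition=cond[:7],
                      n_dropped=0, n_total=7, subject_excluded=False)
    with pytest.raises(DataError):
        oddball_contrast(ep_bad)


def test_cluster_permutation_identical_groups_silent(rng):
    t = np.arange(100) / 50.0
    a = rng.normal(0, 1, (8, 100))
    clusters = cluster_permutation(a, a + rng.normal(0, 1e-6, a.shape),
                                   t, n_perm=300, rng=rng)
    assert clusters == []


def test_cluster_permutation_recovers_sustained_difference(rng):
    t = np.arange(200) / 20.0  # 0..10 s at 20 Hz
    a = rng.normal(0, 1, (10, 200))
    b = rng.normal(0, 1, (10, 200))
    window = (t >= 6.0) & (t <= 10.0)
    a[:, window] += 3.0
    clusters = cluster_permutation(a, b, t, n_perm=500, rng=rng)
    assert len(clusters) >= 1
    c = max(clusters, key=lambda c: c.mass)
    assert c.start_s < 10.0 and c.stop_s > 6.0
    assert c.p_corrected < 0.05


def test_cluster_permutation_grid_mismatch(rng):
    with pytest.raises(DataError):
        cluster_permutation(np.zeros((3, 10)), np.zeros((3, 12)),
                            np.arange(10.0), rng=rng)


def test_generated_recording_roundtrips_through_csv(rng):
    spec = PupilGenSpec(n_subjects=1, n_trials=4)
    rec = gen_pupil(spec, "A000", rng)
    df = rec.to_frame()
    back = PupilRecording.from_frame(df)
    assert np.allclose(back.pupil, rec.pupil)
    assert len(back.events) == len(rec.events)
    assert (back.events["condition"].to_numpy()
            == rec.events["condition"].to_numpy()).all()
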