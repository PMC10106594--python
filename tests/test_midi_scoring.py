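"""Performance scoring: segmentation, alignment (vs brute force), metrics."""

import itertools
import math

import numpy as np
import pytest

from practicescope.midi_scoring import (
    Alignment,
    NoteEvent,
    PerformanceRecording,
    align_to_score,
    assess_performance,
    practice_descriptors,
    segment_repetitions,
)
from practicescope.score import make_target_score

from conftest import perfect_events


# ---------------------------------------------------------------------------
# brute-force oracle: exhaustive minimum-cost injective matching


def _greedy_anchor_candidates(segment, score):
    nominal = score.nominal_onsets_s
    anchors = {segment[0].onset - nominal[0]}
    for ei in range(min(3, len(segment))):
        for ti in range(min(3, len(nominal))):
            if segment[ei].pitch == score.notes[ti].pitch:
                anchors.add(segment[ei].onset - nominal[ti])
    return sorted(anchors)


def brute_force_align(segment, score, tolerance):
    """Best injective pitch-equal matching over all anchors, by exhaustion.

    Maximizes the number of matches, then minimizes total |onset deviation|.
    Returns (n_matched, total_cost).
    """
    nominal = score.nominal_onsets_s
    best = (0, 0.0)
    for t0 in _greedy_anchor_candidates(segment, score):
        compat = []
        for ti, t_nom in enumerate(nominal):
            opts = [
                (ei, abs(ev.onset - (t0 + t_nom)))
                for ei, ev in enumerate(segment)
                if ev.pitch == score.notes[ti].pitch
                and abs(ev.onset - (t0 + t_nom)) <= tolerance
            ]
            compat.append(opts)

        def recurse(ti, used, n, cost):
            if ti == len(nominal):
                return (n, -cost)
            outcomes = [recurse(ti + 1, used, n, cost)]
            for ei, dt in compat[ti]:
                if ei not in used:
                    outcomes.append(recurse(ti + 1, used | {ei}, n + 1, cost + dt))
            return max(outcomes)

        n, neg_cost = recurse(0, frozenset(), 0, 0.0)
        best = max(best, (n, neg_cost))
    return best[0], -best[1]


def _perturbations(score, base):
    """All single perturbations of a perfect one-repetition rendition."""
    n = len(base)
    out = []
    for i in range(n):  # delete one note
        out.append(("del", base[:i] + base[i + 1 :]))
    for i in range(n):  # off-pitch-set insertion near note i
        ins = NoteEvent(base[i].pitch + 1, base[i].onset + 0.05, base[i].onset + 0.15, 70)
        out.append(("ins_off", tuple(sorted(base + (ins,), key=lambda e: e.onset))))
    for i in range(n):  # duplicate strike of a correct pitch
        ins = NoteEvent(base[i].pitch, base[i].onset + 0.08, base[i].onset + 0.18, 70)
        out.append(("dup", tuple(sorted(base + (ins,), key=lambda e: e.onset))))
    for i in range(n):  # onset shift within tolerance
        ev = base[i]
        shifted = NoteEvent(ev.pitch, ev.onset + 0.1, ev.offset + 0.1, ev.velocity)
        out.append(("shift", tuple(sorted(base[:i] + (shifted,) + base[i + 1 :],
                                          key=lambda e: e.onset))))
    return out


@pytest.mark.parametrize("n_notes", [3, 4, 5, 6])
def test_greedy_matches_brute_force_on_perturbed_renditions(n_notes):
    """Exhaustive check: greedy alignment attains the optimum matching.

    Every rendition of <= 6 target notes with <= 2 perturbations (deletion,
    off-pitch insertion, duplicate strike, in-tolerance onset shift) must
    give the same match count and total onset deviation as exhaustive
    minimum-cost search.
    """
    sc = make_target_score(n_notes=n_notes, n_repetitions=1)
    tol = (sc.nominal_onsets_s[1] - sc.nominal_onsets_s[0]) / 2
    base = perfect_events(sc, rep_offsets=[0.0])

    cases = [("none", base)]
    singles = _perturbations(sc, base)
    cases += singles
    # second perturbation applied on top of each deletion and insertion
    for tag, seg in singles[: 2 * n_notes]:
        if seg:
            cases += [(tag + "+" + t2, s2) for t2, s2 in _perturbations(sc, seg)[:n_notes]]

    for tag, seg in cases:
        if not seg:
            continue
        al = align_to_score(seg, sc)
        n_opt, _ = brute_force_align(seg, sc, tol)
        assert len(al.matched) == n_opt, f"case {tag}: match count suboptimal"
        assert len(al.matched) + len(al.missed_targets) == n_notes
        assert len(al.matched) + len(al.extra_events) == len(seg)


# ---------------------------------------------------------------------------
# segmentation


def test_five_repetitions_with_pauses_segment_cleanly(score, perfect_recording):
    segs = segment_repetitions(perfect_recording, score, gap_threshold=1.0)
    assert len(segs) == 5
    assert all(len(s) == len(score.notes) for s in segs)


def test_continuous_stream_is_one_segment(score):
    events = tuple(
        NoteEvent(60, 0.1 * i, 0.1 * i + 0.05, 64) for i in range(50)
    )
    rec = PerformanceRecording(events, phase="practice")
    assert len(segment_repetitions(rec, score, gap_threshold=1.0)) == 1


def test_zero_threshold_splits_every_event(score):
    events = tuple(NoteEvent(60, 0.5 * i, 0.5 * i + 0.1, 64) for i in range(4))
    rec = PerformanceRecording(events, phase="practice")
    assert len(segment_repetitions(rec, score, gap_threshold=0.0)) == 4


def test_empty_recording_gives_empty_list(score):
    rec = PerformanceRecording((), phase="baseline")
    assert segment_repetitions(rec, score, 1.0) == []


# ---------------------------------------------------------------------------
# alignment examples


def test_perfect_rendition_fully_matched(short_score):
    seg = perfect_events(short_score, rep_offsets=[0.0])
    al = align_to_score(seg, short_score)
    assert len(al.matched) == 6 and not al.missed_targets and not al.extra_events


def test_inserted_out_of_set_note_is_extra(short_score):
    seg = list(perfect_events(short_score, rep_offsets=[0.0]))
    seg.append(NoteEvent(61, 0.15, 0.2, 70))  # C#4: not in {C4, C5}
    seg.sort(key=lambda e: e.onset)
    al = align_to_score(tuple(seg), short_score)
    assert len(al.extra_events) == 1 and not al.missed_targets


def test_omitted_final_note_is_missed(short_score):
    seg = perfect_events(short_score, rep_offsets=[0.0])[:-1]
    al = align_to_score(seg, short_score)
    assert al.missed_targets == (5,) and not al.extra_events


def test_omitted_first_note_does_not_derail_anchor(short_score):
    seg = perfect_events(short_score, rep_offsets=[0.0])[1:]
    al = align_to_score(seg, short_score)
    assert al.missed_targets == (0,)
    assert len(al.matched) == 5 and not al.extra_events


# ---------------------------------------------------------------------------
# assessment metrics


def test_noiseless_rendition_scores_zero(score, perfect_recording):
    res = assess_performance(perfect_recording, score)
    assert (res.wrong_notes, res.missed_notes) == (0, 0)
    assert res.rhythmic_accuracy == pytest.approx(0.0, abs=1e-12)
    assert res.loudness_homogeneity == pytest.approx(0.0, abs=1e-12)


def test_loudness_homogeneity_closed_form():
    sc = make_target_score(n_notes=3, n_repetitions=1)
    events = tuple(
        NoteEvent(n.pitch, t, t + 0.2, v)
        for n, t, v in zip(sc.notes, sc.nominal_onsets_s, (60, 64, 68))
    )
    res = assess_performance(PerformanceRecording(events, "baseline"), sc)
    assert res.loudness_homogeneity == pytest.approx(4.0)  # sample SD


def test_rhythmic_accuracy_closed_form():
    sc = make_target_score(n_notes=4, n_repetitions=1)
    onsets = [0.0, 0.3, 0.6333, 1.0]  # IOIs 0.3, 0.3333, 0.3667
    events = tuple(
        NoteEvent(n.pitch, t, t + 0.2, 70) for n, t in zip(sc.notes, onsets)
    )
    res = assess_performance(PerformanceRecording(events, "baseline"), sc)
    expected = np.std([0.3, 0.3333, 0.3667], ddof=1)
    assert res.rhythmic_accuracy == pytest.approx(expected, abs=1e-6)


def test_single_ioi_flags_missing_sd():
    sc = make_target_score(n_notes=2, n_repetitions=1)
    events = tuple(
        NoteEvent(n.pitch, t, t + 0.2, 70)
        for n, t in zip(sc.notes, sc.nominal_onsets_s)
    )
    res = assess_performance(PerformanceRecording(events, "baseline"), sc)
    assert math.isnan(res.rhythmic_accuracy)  # < 2 IOIs: flagged, not zero


def test_constant_velocity_gives_zero_loudness_despite_errors(score):
    events = list(perfect_events(score, velocity=80))
    events.append(NoteEvent(61, 1.05, 1.1, 80))
    events.sort(key=lambda e: e.onset)
    res = assess_performance(PerformanceRecording(tuple(events), "baseline"), score)
    assert res.wrong_notes >= 1
    assert res.loudness_homogeneity == pytest.approx(0.0, abs=1e-12)


def test_adding_off_set_event_never_decreases_wrong(score, perfect_recording):
    base = assess_performance(perfect_recording, score)
    for t_ins in (1.1, 5.0, 12.0):
        events = sorted(
            perfect_recording.events + (NoteEvent(61, t_ins, t_ins + 0.1, 70),),
            key=lambda e: e.onset,
        )
        res = assess_performance(PerformanceRecording(tuple(events), "baseline"), score)
        assert res.wrong_notes >= base.wrong_notes + 1


def test_deleting_matched_event_increases_missed(score, perfect_recording):
    base = assess_performance(perfect_recording, score)
    for drop in (0, 7, 40):
        events = tuple(e for i, e in enumerate(perfect_recording.events) if i != drop)
        res = assess_performance(PerformanceRecording(events, "baseline"), score)
        assert res.missed_notes >= base.missed_notes + 1


def test_short_pause_between_repetitions_recovered(score):
    # a 0.8 s pause is below the 1.0 s gap threshold; score-aware
    # refinement must still separate the two repetitions
    span = score.repetition_span_s
    offsets = [1.0, 1.0 + span + 0.8] + [
        1.0 + i * (span + 2.2) for i in range(2, 5)
    ]
    rec = PerformanceRecording(perfect_events(score, rep_offsets=offsets), "baseline")
    res = assess_performance(rec, score)
    assert (res.wrong_notes, res.missed_notes) == (0, 0)


# ---------------------------------------------------------------------------
# practice descriptors


def test_practice_descriptors_counts_and_time(score):
    events = []
    for i in range(100):
        pitch = 60 if i % 2 else 72
        if i < 30:
            pitch = 65  # off the {C4, C5} pitch set
        t = i * (600.0 / 99)
        events.append(NoteEvent(pitch, t, t + 0.1, 70))
    rec = PerformanceRecording(tuple(events), phase="practice")
    d = practice_descriptors(rec, score)
    assert d.total_keystrokes == 100
    assert d.keystrokes_on_target == 70
    assert d.practice_time == pytest.approx(10.0)


def test_practice_descriptors_empty_recording(score):
    d = practice_descriptors(PerformanceRecording((), "practice"), score)
    assert (d.practice_time, d.keystrokes_on_target, d.total_keystrokes) == (0.0, 0, 0)
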