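import warnings

import numpy as np
import pytest

from practicescope.score import make_target_score
from practicescope.midi_scoring import NoteEvent, PerformanceRecording

warnings.filterwarnings("ignore", category=FutureWarning)


@pytest.fixture(scope="session")
def score():
    """Default octave-leap task: 16 eighth notes C4/C5 at 90 bpm, 5 reps."""
    return make_target_score()


@pytest.fixture(scope="session")
def short_score():
    """Six-note variant for exhaustive alignment enumeration."""
    return make_target_score(n_notes=6, n_repetitions=1)


def perfect_events(score, rep_offsets=None, velocity=70):
    """Noise-free rendition: one NoteEvent per target note per repetition."""
    if rep_offsets is None:
        span = score.repetition_span_s
        rep_offsets = [1.0 + i * (span + 2.2) for i in range(score.n_repetitions)]
    events = []
    for off in rep_offsets:
        for n, t in zip(score.notes, score.nominal_onsets_s):
            events.append(
                NoteEvent(n.pitch, off + t, off + t + 0.25, velocity)
            )
    return tuple(events)


@pytest.fixture
def perfect_recording(score):
    return PerformanceRecording(perfect_events(score), phase="baseline")
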