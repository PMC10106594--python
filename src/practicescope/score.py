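"""Target-score definition: the notated musical task.

The task is a short right-hand excerpt of bidirectional octave leaps in a
plain rhythmic texture, performed to a metronome.  Its exact note text is
configurable via JSON; the default is alternating C4/C5 eighth notes, a
declared stand-in with the same pitch-set structure (two octave-separated
pitch classes) rather than a reconstruction of any published score.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

PIANO_MIN, PIANO_MAX = 21, 108


@dataclass(frozen=True)
class ScoreNote:
    pitch: int
    onset_beats: float
    duration_beats: float


@dataclass(frozen=True)
class TargetScore:
    """The notated task: one repetition's notes plus performance context.

    Attributes
    ----------
    notes : nominal note list for a single repetition, onsets in beats.
    tempo_bpm : metronome tempo in beats per minute.
    n_repetitions : repetitions per assessment phase.
    """

    notes: tuple[ScoreNote, ...]
    tempo_bpm: float = 90.0
    n_repetitions: int = 5

    def __post_init__(self) -> None:
        if self.tempo_bpm <= 0:
            raise ValueError("tempo_bpm must be positive")
        if self.n_repetitions < 1:
            raise ValueError("n_repetitions must be >= 1")
        onsets = [n.onset_beats for n in self.notes]
        if any(b >= a for a, b in zip(onsets[1:], onsets)):
            # strictly increasing onsets within one repetition
            raise ValueError("note onsets must be strictly increasing")
        for n in self.notes:
            if not PIANO_MIN <= n.pitch <= PIANO_MAX:
                raise ValueError(f"pitch {n.pitch} outside piano range")

    @property
    def beat_s(self) -> float:
        return 60.0 / self.tempo_bpm

    @property
    def pitch_set(self) -> frozenset[int]:
        return frozenset(n.pitch for n in self.notes)

    @property
    def nominal_onsets_s(self) -> list[float]:
        """Nominal onset times of one repetition, seconds from its start."""
        return [n.onset_beats * self.beat_s for n in self.notes]

    @property
    def repetition_span_s(self) -> float:
        last = self.notes[-1]
        return (last.onset_beats + last.duration_beats) * self.beat_s


def make_target_score(
    tempo_bpm: float = 90.0,
    n_repetitions: int = 5,
    n_notes: int = 16,
    low_pitch: int = 60,
    note_value_beats: float = 0.5,
) -> TargetScore:
    """Build the default octave-leap task.

    Alternating low/high notes one octave apart, in even notes of
    ``note_value_beats`` (default eighth notes), ``n_notes`` per repetition.
    The nominal inter-onset interval is ``60/tempo_bpm * note_value_beats``
    seconds.
    """
    if tempo_bpm <= 0:
        raise ValueError("tempo_bpm must be positive")
    if n_repetitions < 1:
        raise ValueError("n_repetitions must be >= 1")
    notes = tuple(
        ScoreNote(
            pitch=low_pitch + 12 * (i % 2),
            onset_beats=i * note_value_beats,
            duration_beats=note_value_beats,
        )
        for i in range(n_notes)
    )
    return TargetScore(notes=notes, tempo_bpm=tempo_bpm, n_repetitions=n_repetitions)


def save_score(score: TargetScore, path: str | Path) -> None:
    payload = {
        "tempo_bpm": score.tempo_bpm,
        "n_repetitions": score.n_repetitions,
        "notes": [[n.pitch, n.onset_beats, n.duration_beats] for n in score.notes],
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def load_score(path: str | Path) -> TargetScore:
    payload = json.loads(Path(path).read_text())
    return TargetScore(
        notes=tuple(ScoreNote(int(p), float(o), float(d)) for p, o, d in payload["notes"]),
        tempo_bpm=float(payload["tempo_bpm"]),
        n_repetitions=int(payload["n_repetitions"]),
    )
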