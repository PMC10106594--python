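"""Minimal Standard MIDI File (SMF) reader/writer.

Only the subset needed for keyboard performance capture is supported:
format 0/1 files, note-on / note-off events on any channel (note-on with
velocity 0 is treated as note-off, per common practice) and the set-tempo
meta event.  Running status is handled on read; files are written as a
single-track format 0 stream without running status.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

DEFAULT_TICKS_PER_BEAT = 480
DEFAULT_TEMPO_US = 500_000  # microseconds per quarter note (120 bpm)


@dataclass(frozen=True)
class SmfNote:
    """One key press: pitch (0-127), onset/offset in seconds, velocity 1-127."""

    pitch: int
    onset: float
    offset: float
    velocity: int


def _write_varlen(value: int) -> bytes:
    if value < 0:
        raise ValueError("negative delta time")
    chunks = [value & 0x7F]
    value >>= 7
    while value:
        chunks.append(0x80 | (value & 0x7F))
        value >>= 7
    return bytes(reversed(chunks))


def _read_varlen(data: bytes, pos: int) -> tuple[int, int]:
    value = 0
    while True:
        b = data[pos]
        pos += 1
        value = (value << 7) | (b & 0x7F)
        if not b & 0x80:
            return value, pos


def write_smf(
    notes: Sequence[SmfNote],
    path: str | Path,
    tempo_bpm: float = 120.0,
    ticks_per_beat: int = DEFAULT_TICKS_PER_BEAT,
) -> None:
    """Write notes to a format-0 SMF, quantizing times to the tick grid."""
    tempo_us = int(round(60e6 / tempo_bpm))
    tick_s = tempo_us / 1e6 / ticks_per_beat

    # (tick, order, status byte, pitch, velocity); note-offs sort before
    # note-ons at the same tick so zero-length notes stay well-formed.
    events: list[tuple[int, int, int, int, int]] = []
    for n in notes:
        if not 0 <= n.pitch <= 127:
            raise ValueError(f"pitch {n.pitch} out of MIDI range")
        if not 1 <= n.velocity <= 127:
            raise ValueError(f"velocity {n.velocity} out of range 1-127")
        if n.offset < n.onset:
            raise ValueError("note offset precedes onset")
        on_tick = int(round(n.onset / tick_s))
        off_tick = max(int(round(n.offset / tick_s)), on_tick + 1)
        events.append((on_tick, 1, 0x90, n.pitch, n.velocity))
        events.append((off_tick, 0, 0x80, n.pitch, 0))
    events.sort()

    track = bytearray()
    track += _write_varlen(0) + bytes([0xFF, 0x51, 0x03]) + struct.pack(">I", tempo_us)[1:]
    prev = 0
    for tick, _, status, pitch, vel in events:
        track += _write_varlen(tick - prev) + bytes([status, pitch, vel])
        prev = tick
    track += _write_varlen(0) + bytes([0xFF, 0x2F, 0x00])  # end of track

    with open(path, "wb") as fh:
        fh.write(b"MThd" + struct.pack(">IHHH", 6, 0, 1, ticks_per_beat))
        fh.write(b"MTrk" + struct.pack(">I", len(track)) + bytes(track))


def read_smf(path: str | Path) -> list[SmfNote]:
    """Read all notes from an SMF, merging tracks, times in seconds.

    A single tempo map is assumed (tempo changes apply from their tick
    onwards); simultaneous note-ons on the same pitch are paired FIFO.
    """
    data = Path(path).read_bytes()
    if data[:4] != b"MThd":
        raise ValueError(f"{path}: not a Standard MIDI File")
    header_len, fmt, n_tracks, division = struct.unpack(">IHHH", data[4:14])
    if division & 0x8000:
        raise ValueError("SMPTE time division not supported")
    pos = 8 + header_len

    raw: list[tuple[int, int, int, int]] = []  # (tick, kind 0=off/1=on, pitch, vel)
    tempo_map: list[tuple[int, int]] = [(0, DEFAULT_TEMPO_US)]
    for _ in range(n_tracks):
        if data[pos : pos + 4] != b"MTrk":
            raise ValueError("missing MTrk chunk")
        (length,) = struct.unpack(">I", data[pos + 4 : pos + 8])
        p, end = pos + 8, pos + 8 + length
        tick = 0
        status = 0
        while p < end:
            delta, p = _read_varlen(data, p)
            tick += delta
            b = data[p]
            if b >= 0x80:
                status = b
                p += 1
            if status == 0xFF:
                meta = data[p]
                mlen, p = _read_varlen(data, p + 1)
                if meta == 0x51:
                    tempo_map.append((tick, int.from_bytes(data[p : p + 3], "big")))
                p += mlen
            elif status in (0xF0, 0xF7):
                slen, p = _read_varlen(data, p)
                p += slen
            else:
                kind = status & 0xF0
                if kind in (0x80, 0x90):
                    pitch, vel = data[p], data[p + 1]
                    p += 2
                    on = kind == 0x90 and vel > 0
                    raw.append((tick, 1 if on else 0, pitch, vel))
                elif kind in (0xA0, 0xB0, 0xE0):
                    p += 2
                elif kind in (0xC0, 0xD0):
                    p += 1
                else:
                    raise ValueError(f"unexpected status byte 0x{status:02x}")
        pos = end

    tempo_map.sort()

    def tick_to_s(tick: int) -> float:
        t = 0.0
        for (t0, tempo), nxt in zip(tempo_map, tempo_map[1:] + [(tick, 0)]):
            span = min(tick, nxt[0]) - t0
            if span > 0:
                t += span * tempo / 1e6 / division
            if nxt[0] >= tick:
                break
        return t

    raw.sort(key=lambda e: (e[0], e[1]))  # offs before ons at the same tick
    open_notes: dict[int, list[tuple[int, int]]] = {}
    notes: list[SmfNote] = []
    for tick, on, pitch, vel in raw:
        if on:
            open_notes.setdefault(pitch, []).append((tick, vel))
        elif open_notes.get(pitch):
            on_tick, on_vel = open_notes[pitch].pop(0)
            notes.append(SmfNote(pitch, tick_to_s(on_tick), tick_to_s(tick), on_vel))
    notes.sort(key=lambda n: (n.onset, n.pitch))
    return notes
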