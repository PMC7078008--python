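"""Minimal Standard MIDI File (SMF) reader/writer.

Supports exactly what protein scores need: format 0/1 files, note-on /
note-off pairs on any channel, a single tempo, and PPQ (ticks-per-quarter)
time division.  Written files are format 1 with one leading meta track
(tempo) followed by one track per score track; eighth-note units convert to
ticks at ppq/2 ticks per unit.

Running status, variable-length delta times and note-on-velocity-0 note
termination are handled on read.  SMPTE division and format 2 are rejected.
"""
from __future__ import annotations

import logging
import struct
from collections import defaultdict, deque

from .types import MidiScore, NoteEvent, ValidationError

logger = logging.getLogger(__name__)

_HEADER = b"MThd"
_TRACK = b"MTrk"


def _encode_vlq(value: int) -> bytes:
    """Variable-length-quantity encoding (7 bits per byte, MSB = continue)."""
    if value < 0:
        raise ValueError("VLQ values are non-negative")
    out = [value & 0x7F]
    value >>= 7
    while value:
        out.append((value & 0x7F) | 0x80)
        value >>= 7
    return bytes(reversed(out))


def _decode_vlq(data: bytes, pos: int) -> tuple[int, int]:
    value = 0
    while True:
        byte = data[pos]
        pos += 1
        value = (value << 7) | (byte & 0x7F)
        if not byte & 0x80:
            return value, pos


def units_to_ticks(units: float, ppq: int) -> int:
    """Eighth-note units -> ticks; ppq/2 ticks per unit, rounded to nearest."""
    return round(units * ppq / 2)


def ticks_to_units(ticks: int, ppq: int) -> float:
    return ticks * 2 / ppq


def write_midi(score: MidiScore, path) -> None:
    """Write a score as a format-1 SMF with a leading tempo track."""
    chunks = []
    # meta track: tempo only
    meta = b"\x00" + b"\xff\x51\x03" + struct.pack(">I", score.tempo)[1:]
    meta += b"\x00\xff\x2f\x00"
    chunks.append(meta)

    for track in score.tracks:
        # (tick, order) order: note-offs before note-ons at the same tick so
        # back-to-back sequential notes do not overlap
        events: list[tuple[int, int, bytes]] = []
        for note in sorted(track, key=lambda n: (n.onset, n.pitch)):
            on_tick = units_to_ticks(note.onset, score.ppq)
            off_tick = units_to_ticks(note.end, score.ppq)
            if off_tick <= on_tick:
                off_tick = on_tick + 1  # sub-tick note: keep it audible
            events.append((on_tick, 1, bytes([0x90, note.pitch, note.velocity])))
            events.append((off_tick, 0, bytes([0x80, note.pitch, 0x40])))
        events.sort(key=lambda e: (e[0], e[1]))
        data = b""
        prev = 0
        for tick, _, msg in events:
            data += _encode_vlq(tick - prev) + msg
            prev = tick
        data += b"\x00\xff\x2f\x00"
        chunks.append(data)

    with open(path, "wb") as fh:
        fh.write(_HEADER + struct.pack(">IHHH", 6, 1, len(chunks), score.ppq))
        for chunk in chunks:
            fh.write(_TRACK + struct.pack(">I", len(chunk)) + chunk)


def read_midi(path) -> MidiScore:
    """Read a format 0/1 SMF into a :class:`MidiScore`.

    Tracks containing no notes (e.g. the tempo track) are dropped.  Unmatched
    note-ons are closed at their track's end.  Overlapping notes on the first
    (monophonic main) track are retained with a logged warning.
    """
    with open(path, "rb") as fh:
        data = fh.read()
    if data[:4] != _HEADER or len(data) < 14:
        raise ValidationError(f"{path}: not a standard MIDI file")
    hlen, fmt, ntrks, division = struct.unpack(">IHHH", data[4:14])
    if fmt not in (0, 1):
        raise ValidationError(f"{path}: unsupported MIDI format {fmt}")
    if division & 0x8000:
        raise ValidationError(f"{path}: SMPTE time division not supported")
    ppq = division
    if ppq % 2:
        raise ValidationError(f"{path}: odd ppq {ppq} cannot represent eighth units")

    pos = 8 + hlen
    tempo = 500_000
    tracks: list[list[NoteEvent]] = []
    for _ in range(ntrks):
        if data[pos : pos + 4] != _TRACK:
            raise ValidationError(f"{path}: malformed track chunk at byte {pos}")
        (tlen,) = struct.unpack(">I", data[pos + 4 : pos + 8])
        body = data[pos + 8 : pos + 8 + tlen]
        pos += 8 + tlen

        notes: list[NoteEvent] = []
        open_notes: dict[int, deque] = defaultdict(deque)  # pitch -> onset ticks
        tick = 0
        cursor = 0
        status = 0
        while cursor < len(body):
            delta, cursor = _decode_vlq(body, cursor)
            tick += delta
            byte = body[cursor]
            if byte & 0x80:
                status = byte
                cursor += 1
            if status == 0xFF:  # meta
                mtype = body[cursor]
                mlen, cursor = _decode_vlq(body, cursor + 1)
                payload = body[cursor : cursor + mlen]
                cursor += mlen
                if mtype == 0x51 and mlen == 3:
                    tempo = int.from_bytes(payload, "big")
                if mtype == 0x2F:
                    break
                continue
            if status in (0xF0, 0xF7):  # sysex
                slen, cursor = _decode_vlq(body, cursor)
                cursor += slen
                continue
            kind = status & 0xF0
            n_data = 1 if kind in (0xC0, 0xD0) else 2
            params = body[cursor : cursor + n_data]
            cursor += n_data
            if kind == 0x90 and params[1] > 0:
                open_notes[params[0]].append((tick, params[1]))
            elif kind == 0x80 or (kind == 0x90 and params[1] == 0):
                pitch = params[0]
                if open_notes[pitch]:
                    on_tick, vel = open_notes[pitch].popleft()
                    dur = max(tick - on_tick, 1)
                    notes.append(
                        NoteEvent(
                            pitch,
                            ticks_to_units(on_tick, ppq),
                            ticks_to_units(dur, ppq),
                            vel,
                        )
                    )
        for pitch, pending in open_notes.items():
            for on_tick, vel in pending:
                logger.warning("unterminated note (pitch %d); closing at track end", pitch)
                notes.append(NoteEvent(pitch, ticks_to_units(on_tick, ppq), 1.0, vel))
        notes.sort(key=lambda n: (n.onset, n.pitch))
        if notes:
            tracks.append(notes)

    if tracks:
        main = tracks[0]
        for prev, nxt in zip(main, main[1:]):
            if nxt.onset < prev.end - 1e-9:
                logger.warning(
                    "overlapping notes on main track at %.3f units (retained)",
                    nxt.onset,
                )
                break
    return MidiScore(tracks=tracks, ppq=ppq, tempo=tempo)
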