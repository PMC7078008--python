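"""Coding of folded geometry as inserted melodies.

For each residue contact (i, j), the sequence fragment around j is inserted
as a second, overlapping melody starting at residue i's note (and the
fragment around i reciprocally at residue j).  Insertions are played much
faster and softer than the main line, with the contacting residue's own note
slightly louder than its fragment neighbours, so contacts remain audible and
— because the fragment spells out a sequence pattern — decodable: locating
the fragment string in the primary sequence identifies the neighbour.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

from . import sonics
from .types import (
    AmbiguityError,
    ContactTable,
    MidiScore,
    NoteEvent,
    SequenceRecord,
    ValidationError,
)

logger = logging.getLogger(__name__)


@dataclass
class FoldCodingParams:
    """Insertion style: fragment half-width and tempo/volume scaling."""

    window: int = 2  # residues either side of the neighbour; fragment = 2w+1
    duration_factor: float = 0.25  # "much faster"
    velocity_factor: float = 0.5  # "softer"
    center_boost: float = 1.5  # contacting residue "slightly louder"

    def __post_init__(self) -> None:
        if self.window < 1:
            raise ValidationError("window must be >= 1")
        if not 0 < self.duration_factor < 1:
            raise ValidationError("duration_factor must be in (0, 1)")
        if not 0 < self.velocity_factor < 1:
            raise ValidationError("velocity_factor must be in (0, 1)")
        if self.center_boost <= 1:
            raise ValidationError("center_boost must exceed 1")


def _single_chain(record: SequenceRecord):
    if len(record.chains) != 1:
        raise ValidationError("fold coding handles single-chain records")
    chain = record.chains[0]
    if chain.ss is None:
        raise ValidationError("secondary structure required for fold coding")
    return chain


def _fragment(
    chain,
    center: int,  # 1-based
    host_onset: float,
    pitch_map: sonics.PitchMap,
    style: sonics.SSStyle,
    params: FoldCodingParams,
) -> list[NoteEvent]:
    lo = max(1, center - params.window)
    hi = min(len(chain), center + params.window)
    positions = list(range(lo, hi + 1))
    velocities = [
        style.velocity(chain.ss[pos - 1]) * params.velocity_factor
        for pos in positions
    ]
    # The contacting residue must be the loudest note of its fragment or the
    # decoder cannot identify it, so the boost applies to the fragment's
    # loudest (pre-boost) velocity, not to the centre's own class velocity —
    # these coincide for structurally homogeneous fragments.
    center_vel = max(velocities) * params.center_boost
    notes = []
    cursor = host_onset
    for pos, vel in zip(positions, velocities):
        aa = chain.sequence[pos - 1]
        dur = style.duration(chain.ss[pos - 1]) * params.duration_factor
        if pos == center:
            vel = center_vel
        notes.append(
            NoteEvent(
                pitch_map.aa_to_pitch[aa],
                cursor,
                dur,
                max(1, min(127, round(vel))),
            )
        )
        cursor += dur
    return notes


def encode_folded(
    record: SequenceRecord,
    contacts: ContactTable,
    pitch_map: sonics.PitchMap | None = None,
    style: sonics.SSStyle | None = None,
    params: FoldCodingParams | None = None,
) -> MidiScore:
    """Two-track score: track 0 = plain encoding, track 1 = contact insertions.

    Every pair contributes two fragments (around j at i, and around i at j),
    clipped at chain ends.  Fragments at the same host overlap as chords and
    are allowed, with a logged notice.
    """
    pitch_map = pitch_map or sonics.PitchMap()
    style = style or sonics.SSStyle()
    params = params or FoldCodingParams()
    chain = _single_chain(record)
    contacts.validate_for_length(len(chain))

    main_score = sonics.encode([record], pitch_map, style)
    main = main_score.main_track
    onsets = [n.onset for n in main]

    insertions: list[NoteEvent] = []
    hosts_seen: set[int] = set()
    for i, j in contacts.pairs:
        for host, neighbor in ((i, j), (j, i)):
            if host in hosts_seen:
                logger.info("overlapping insertions at host residue %d", host)
            hosts_seen.add(host)
            insertions.extend(
                _fragment(chain, neighbor, onsets[host - 1], pitch_map, style, params)
            )
    insertions.sort(key=lambda n: (n.onset, n.pitch))
    return MidiScore(tracks=[main, insertions])


def _blocks(insertion_track: list[NoteEvent]) -> list[list[NoteEvent]]:
    """Split the insertion track into maximal contiguous fragment blocks.

    Notes separated by a gap smaller than one eighth unit belong to one
    block; fragments are internally gapless so any >= 1-unit silence marks a
    block boundary.
    """
    blocks: list[list[NoteEvent]] = []
    for note in sorted(insertion_track, key=lambda n: (n.onset, n.pitch)):
        if blocks and note.onset - max(n.end for n in blocks[-1]) < 1.0 - 1e-9:
            blocks[-1].append(note)
        else:
            blocks.append([note])
    return blocks


def _parse_merged(block, read_fragment, onset_to_host):
    """Read a merged block as a concatenation of unique fragments.

    Fragments start at main-note onsets, so candidate cut points are the
    interior notes aligned with a main onset.  Greedy with backtracking,
    longest prefix fragment first; returns None when no consistent reading
    exists (the caller re-raises the original ambiguity).
    """
    if not block:
        return []
    cuts = [
        t
        for t in range(1, len(block))
        if round(block[t].onset, 6) in onset_to_host
    ] + [len(block)]
    for cut in sorted(cuts, reverse=True):
        try:
            head = read_fragment(block[:cut])
        except (AmbiguityError, ValidationError):
            continue
        tail = _parse_merged(block[cut:], read_fragment, onset_to_host)
        if tail is not None:
            return [head] + tail
    return None


def count_insertions(score: MidiScore) -> int:
    """Number of contiguous insertion blocks on the second track."""
    if len(score.tracks) < 2:
        return 0
    return len(_blocks(score.tracks[1]))


def decode_contacts(
    score: MidiScore,
    pitch_map: sonics.PitchMap | None = None,
    style: sonics.SSStyle | None = None,
    params: FoldCodingParams | None = None,
) -> ContactTable:
    """Recover the contact table from an insertion-coded score.

    Each insertion block is read as a letter string and located in the main
    sequence; the loudest note in the block marks the contacting residue j,
    and the main-track note hosting the block's onset marks i.  A fragment
    string that occurs zero or several times in the main sequence raises an
    :class:`AmbiguityError` listing the candidate positions — no silent
    guessing.
    """
    pitch_map = pitch_map or sonics.PitchMap()
    style = style or sonics.SSStyle()
    params = params or FoldCodingParams()
    if len(score.tracks) < 2 or not score.tracks[1]:
        return ContactTable([])

    main = sorted(score.main_track, key=lambda n: n.onset)
    sep_pitches = {pitch_map.chain_sep_pitch, pitch_map.protein_sep_pitch}
    if any(n.pitch in sep_pitches for n in main):
        raise ValidationError("fold decoding expects a single-chain main track")
    sequence = "".join(pitch_map.invert(n.pitch) for n in main)

    onset_to_host = {round(n.onset, 6): idx + 1 for idx, n in enumerate(main)}

    def read_fragment(block: list[NoteEvent]) -> tuple[int, int] | None:
        letters = "".join(pitch_map.invert(n.pitch) for n in block)
        starts = [
            k + 1 for k in range(len(sequence)) if sequence.startswith(letters, k)
        ]
        if len(starts) != 1:
            raise AmbiguityError(
                f"insertion fragment {letters!r} has {len(starts)} matches in the "
                f"main sequence at positions {starts}",
                candidates=starts,
            )
        center_idx = max(range(len(block)), key=lambda k: block[k].velocity)
        neighbor = starts[0] + center_idx
        host = onset_to_host.get(round(block[0].onset, 6))
        if host is None:
            raise ValidationError(
                f"insertion block at onset {block[0].onset:g} is not aligned "
                "with any main-track note"
            )
        if host == neighbor:
            return None
        return (min(host, neighbor), max(host, neighbor))

    pairs: list[tuple[int, int]] = []
    for block in _blocks(score.tracks[1]):
        # Fragments at nearby hosts can be back-to-back in time and merge
        # into one gap-delimited block; the concatenated letter string then
        # matches nowhere.  Every fragment starts exactly at its host's
        # main-note onset, so on failure retry with the block split at
        # interior notes aligned with a main onset.
        try:
            read = [read_fragment(block)]
        except AmbiguityError:
            read = _parse_merged(block, read_fragment, onset_to_host)
            if read is None:
                raise
        pairs.extend(p for p in read if p is not None)
    return ContactTable(pairs)
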