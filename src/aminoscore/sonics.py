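"""Reversible sequence <-> score codec.

Each of the 20 amino acids is assigned a distinct pitch on the white keys
(C-major scale members) from C-2 upward; two reserved black keys act as
delimiters: A#-2 ('#') separates protein molecules and B-2 ('!') separates
chains within one protein.  Secondary structure modulates timing and volume:

    ==============  ========================  =================
    class           duration (eighth units)    velocity fraction
    ==============  ========================  =================
    E (sheet)       1.0  (eighth notes)        1.00
    H (helix)       0.5  (sixteenth notes)     0.50
    C (coil)        2.0  (quarter notes)       0.25
    chain break !   4.0                        1.00
    protein break # 8.0                        1.00
    ==============  ========================  =================

so sheets are loud and even, helices fast and soft, coils slow and soft.
Because pitch carries the residue identity alone, decoding needs only the
pitch stream; duration/velocity carry the secondary structure and are
recovered separately by :func:`infer_ss`.
"""
from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, field

from .types import (
    AA_ALPHABET,
    CHAIN_SEP,
    PROTEIN_SEP,
    ConfigError,
    MidiScore,
    NoteEvent,
    SequenceRecord,
    TokenString,
    ValidationError,
)

logger = logging.getLogger(__name__)

_PITCH_CLASSES = ["C", "C#", "D", "D#", "E", "F", "F#", "G", "G#", "A", "A#", "B"]
_WHITE_CLASSES = {0, 2, 4, 5, 7, 9, 11}

#: lowest octave name; MIDI pitch 0 is written C-2 (middle C = C3)
_OCTAVE_OFFSET = -2

CHAIN_SEP_PITCH = 11  # B-2
PROTEIN_SEP_PITCH = 10  # A#-2
PITCH_RANGE_TOP = 45  # A1, top of the amino-acid register


def note_name(pitch: int) -> str:
    """MIDI pitch number -> note name (pitch 0 = 'C-2', 45 = 'A1')."""
    octave = pitch // 12 + _OCTAVE_OFFSET
    return f"{_PITCH_CLASSES[pitch % 12]}{octave}"


def pitch_from_name(name: str) -> int:
    m = re.fullmatch(r"([A-G]#?)(-?\d+)", name.strip())
    if not m:
        raise ConfigError(f"cannot parse note name {name!r}")
    cls, octave = m.group(1), int(m.group(2))
    pitch = _PITCH_CLASSES.index(cls) + (octave - _OCTAVE_OFFSET) * 12
    if not 0 <= pitch <= 127:
        raise ConfigError(f"note {name!r} outside the MIDI pitch range")
    return pitch


def _default_white_keys() -> list[int]:
    """The 20 lowest white keys from C-2 upward, skipping reserved B-2."""
    keys = [
        p
        for p in range(0, PITCH_RANGE_TOP + 1)
        if p % 12 in _WHITE_CLASSES and p != CHAIN_SEP_PITCH
    ]
    return keys[:20]


@dataclass
class PitchMap:
    """Bijection between the 20 amino acids (+2 delimiters) and 22 pitches."""

    aa_to_pitch: dict[str, int] = field(default_factory=dict)
    chain_sep_pitch: int = CHAIN_SEP_PITCH
    protein_sep_pitch: int = PROTEIN_SEP_PITCH

    def __post_init__(self) -> None:
        if not self.aa_to_pitch:
            self.aa_to_pitch = dict(zip(AA_ALPHABET, _default_white_keys()))
        if sorted(self.aa_to_pitch) != sorted(AA_ALPHABET):
            raise ConfigError("pitch map must cover exactly the 20 amino acids")
        pitches = list(self.aa_to_pitch.values())
        if len(set(pitches)) != 20:
            raise ConfigError("pitch map is not a bijection (duplicate pitches)")
        reserved = {self.chain_sep_pitch, self.protein_sep_pitch}
        if len(reserved) != 2:
            raise ConfigError("chain and protein separator pitches must differ")
        for aa, p in self.aa_to_pitch.items():
            if p in reserved:
                raise ConfigError(
                    f"amino acid {aa!r} mapped to reserved separator pitch "
                    f"{note_name(p)}"
                )
            if not 0 <= p <= 127:
                raise ConfigError(f"pitch for {aa!r} outside 0..127")

    @property
    def pitch_to_token(self) -> dict[int, str]:
        inv = {p: aa for aa, p in self.aa_to_pitch.items()}
        inv[self.chain_sep_pitch] = CHAIN_SEP
        inv[self.protein_sep_pitch] = PROTEIN_SEP
        return inv

    def all_pitches(self) -> set[int]:
        return set(self.aa_to_pitch.values()) | {
            self.chain_sep_pitch,
            self.protein_sep_pitch,
        }

    def invert(self, pitch: int) -> str:
        try:
            return self.pitch_to_token[pitch]
        except KeyError:
            raise ValidationError(
                f"pitch {pitch} ({note_name(pitch)}) is not in the vocabulary"
            ) from None


def build_pitch_map(config: dict | None = None) -> PitchMap:
    """Build the default amino-acid pitch map, or one from a user table.

    ``config`` maps 1-letter amino-acid codes to note names (e.g. ``A: C-2``)
    or raw MIDI pitch numbers; optional ``chain_sep`` / ``protein_sep`` keys
    override the delimiter pitches.
    """
    if config is None:
        return PitchMap()
    cfg = dict(config)
    chain_sep = cfg.pop("chain_sep", None)
    protein_sep = cfg.pop("protein_sep", None)

    def as_pitch(value) -> int:
        return value if isinstance(value, int) else pitch_from_name(str(value))

    table = {str(aa).upper(): as_pitch(v) for aa, v in cfg.items()}
    return PitchMap(
        aa_to_pitch=table,
        chain_sep_pitch=as_pitch(chain_sep) if chain_sep is not None else CHAIN_SEP_PITCH,
        protein_sep_pitch=(
            as_pitch(protein_sep) if protein_sep is not None else PROTEIN_SEP_PITCH
        ),
    )


@dataclass
class SSStyle:
    """Per-class note timing/volume and delimiter styles.

    Durations are in eighth-note units; velocity fractions multiply
    ``reference_velocity`` and are realized as rounded integers.
    """

    class_style: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {"E": (1.0, 1.0), "H": (0.5, 0.5), "C": (2.0, 0.25)}
    )
    chain_sep: tuple[float, float] = (4.0, 1.0)
    protein_sep: tuple[float, float] = (8.0, 1.0)
    reference_velocity: int = 100
    notes_per_bar: int = 8

    def __post_init__(self) -> None:
        for cls, (dur, frac) in self.class_style.items():
            if cls not in "HEC":
                raise ConfigError(f"unknown secondary-structure class {cls!r}")
            if dur <= 0 or not 0 < frac <= 1:
                raise ConfigError(f"bad style for class {cls!r}: ({dur}, {frac})")

    def duration(self, cls: str) -> float:
        return self.class_style[cls][0]

    def velocity(self, cls: str) -> int:
        frac = self.class_style[cls][1]
        return max(1, min(127, round(frac * self.reference_velocity)))

    def sep_event(self, kind: str) -> tuple[float, int]:
        dur, frac = self.chain_sep if kind == CHAIN_SEP else self.protein_sep
        return dur, max(1, min(127, round(frac * self.reference_velocity)))


def encode(
    records: list[SequenceRecord],
    pitch_map: PitchMap | None = None,
    style: SSStyle | None = None,
) -> MidiScore:
    """Encode records as a single monophonic track of sequential notes.

    One note per residue (pitch = amino acid, duration/velocity = secondary
    structure class); a chain-separator note after every chain except a
    record's last; a protein-separator note after every record except the
    last.  Onsets are cumulative sums of durations.
    """
    pitch_map = pitch_map or PitchMap()
    style = style or SSStyle()
    notes: list[NoteEvent] = []
    cursor = 0.0

    def emit(pitch: int, dur: float, vel: int) -> None:
        nonlocal cursor
        notes.append(NoteEvent(pitch, cursor, dur, vel))
        cursor += dur

    for r_idx, rec in enumerate(records):
        for c_idx, chain in enumerate(rec.chains):
            if chain.ss is None:
                raise ValidationError(
                    f"record {rec.record_id!r} chain {c_idx + 1}: secondary "
                    "structure is required for encoding"
                )
            for aa, cls in zip(chain.sequence, chain.ss):
                emit(pitch_map.aa_to_pitch[aa], style.duration(cls), style.velocity(cls))
            if c_idx < len(rec.chains) - 1:
                dur, vel = style.sep_event(CHAIN_SEP)
                emit(pitch_map.chain_sep_pitch, dur, vel)
        if r_idx < len(records) - 1:
            dur, vel = style.sep_event(PROTEIN_SEP)
            emit(pitch_map.protein_sep_pitch, dur, vel)

    return MidiScore(tracks=[notes] if notes else [])


def decode(
    score: MidiScore, pitch_map: PitchMap | None = None, strict: bool = False
) -> TokenString:
    """Map the main track back to tokens, using pitch alone.

    Out-of-vocabulary pitches are skipped with a logged warning in lenient
    mode and raise in strict mode.
    """
    pitch_map = pitch_map or PitchMap()
    table = pitch_map.pitch_to_token
    tokens: list[str] = []
    for note in sorted(score.main_track, key=lambda n: n.onset):
        tok = table.get(note.pitch)
        if tok is None:
            msg = (
                f"out-of-vocabulary pitch {note.pitch} ({note_name(note.pitch)}) "
                f"at onset {note.onset:g}"
            )
            if strict:
                raise ValidationError(msg)
            logger.warning("%s; note skipped", msg)
            continue
        tokens.append(tok)
    return TokenString(tokens)


def infer_ss(
    score: MidiScore, style: SSStyle | None = None, strict: bool = False
) -> str:
    """Recover the secondary-structure string from note timing and volume.

    Each residue note is classified to the class whose (duration, velocity)
    style is nearest (exact match required when ``strict``); delimiter notes
    are excluded from the output.  Ties raise with the candidate classes.
    """
    style = style or SSStyle()
    sep_styles = {style.sep_event(CHAIN_SEP), style.sep_event(PROTEIN_SEP)}
    out: list[str] = []
    for note in sorted(score.main_track, key=lambda n: n.onset):
        if (note.duration, note.velocity) in sep_styles:
            continue
        dists: dict[str, float] = {}
        for cls in style.class_style:
            dur, vel = style.duration(cls), style.velocity(cls)
            dists[cls] = math.hypot(
                note.duration - dur,
                (note.velocity - vel) / style.reference_velocity,
            )
        best = min(dists.values())
        winners = sorted(c for c, d in dists.items() if abs(d - best) < 1e-9)
        if strict and best > 1e-9:
            raise ValidationError(
                f"note at onset {note.onset:g} (duration {note.duration:g}, "
                f"velocity {note.velocity}) matches no class exactly"
            )
        if len(winners) > 1:
            raise ValidationError(
                f"ambiguous secondary structure at onset {note.onset:g}: "
                f"candidates {winners}"
            )
        out.append(winners[0])
    return "".join(out)


def bar_count(score: MidiScore, style: SSStyle | None = None) -> int:
    """Number of bars spanned by the score (notes_per_bar eighth units each)."""
    style = style or SSStyle()
    total = score.total_units()
    if total <= 0:
        return 0
    return math.ceil(total / style.notes_per_bar - 1e-9)
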