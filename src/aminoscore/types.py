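"""Core domain containers shared across the toolkit.

A protein is represented as a :class:`SequenceRecord` — one or more chains,
each an amino-acid string over the canonical 20-letter alphabet with an
aligned 3-class secondary-structure string (H = helix, E = sheet, C = coil).
Musical scores are :class:`MidiScore` objects holding tracks of
:class:`NoteEvent`; all times are expressed in eighth-note units (the score
normalisation: 8 units per bar).
"""
from __future__ import annotations

from dataclasses import dataclass, field

# Canonical 20-letter amino-acid alphabet, alphabetical 1-letter order.
AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
SS_CLASSES = "HEC"

#: token marking the boundary between distinct protein molecules
PROTEIN_SEP = "#"
#: token marking the end of an amino-acid chain within one protein
CHAIN_SEP = "!"


class AminoscoreError(Exception):
    """Base class for toolkit errors."""


class ValidationError(AminoscoreError, ValueError):
    """Input violates a structural precondition (alphabet, alignment, range)."""


class ConfigError(AminoscoreError, ValueError):
    """User-supplied configuration is inconsistent (e.g. non-bijective map)."""


class AmbiguityError(AminoscoreError):
    """A decode step has several equally valid readings; candidates attached."""

    def __init__(self, message: str, candidates: list | None = None):
        super().__init__(message)
        self.candidates = candidates or []


@dataclass
class Chain:
    sequence: str
    ss: str | None = None

    def __post_init__(self) -> None:
        for pos, aa in enumerate(self.sequence):
            if aa not in AA_ALPHABET:
                raise ValidationError(
                    f"non-standard amino acid {aa!r} at position {pos + 1}"
                )
        if self.ss is not None:
            if len(self.ss) != len(self.sequence):
                raise ValidationError(
                    f"secondary structure length {len(self.ss)} != "
                    f"sequence length {len(self.sequence)}"
                )
            for pos, cls in enumerate(self.ss):
                if cls not in SS_CLASSES:
                    raise ValidationError(
                        f"secondary-structure symbol {cls!r} at position "
                        f"{pos + 1} (expected one of H, E, C)"
                    )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class SequenceRecord:
    """One protein: an id and one or more amino-acid chains."""

    record_id: str
    chains: list[Chain]

    def __post_init__(self) -> None:
        if not self.chains:
            raise ValidationError(f"record {self.record_id!r} has no chains")

    @classmethod
    def from_strings(
        cls, record_id: str, sequences: list[str], ss: list[str] | None = None
    ) -> "SequenceRecord":
        if ss is None:
            return cls(record_id, [Chain(s) for s in sequences])
        if len(ss) != len(sequences):
            raise ValidationError("chain count mismatch between sequence and ss")
        return cls(record_id, [Chain(s, x) for s, x in zip(sequences, ss)])


@dataclass
class NoteEvent:
    """One note: pitch (MIDI number), onset and duration in eighth-note units,
    velocity 1..127."""

    pitch: int
    onset: float
    duration: float
    velocity: int

    def __post_init__(self) -> None:
        if not 0 <= self.pitch <= 127:
            raise ValidationError(f"pitch {self.pitch} outside 0..127")
        if self.duration <= 0:
            raise ValidationError("note duration must be positive")
        if self.onset < 0:
            raise ValidationError("note onset must be non-negative")
        if not 1 <= self.velocity <= 127:
            raise ValidationError(f"velocity {self.velocity} outside 1..127")

    @property
    def end(self) -> float:
        return self.onset + self.duration


@dataclass
class MidiScore:
    """A score: ordered tracks of notes, with tick resolution and tempo.

    ``ppq`` (ticks per quarter note) must be even so eighth-note units map to
    an integer number of ticks (ppq/2 ticks per unit).
    """

    tracks: list[list[NoteEvent]] = field(default_factory=list)
    ppq: int = 480
    tempo: int = 500_000  # microseconds per quarter note (120 bpm)

    def __post_init__(self) -> None:
        if self.ppq <= 0 or self.ppq % 2:
            raise ValidationError("ppq must be a positive even integer")

    @property
    def main_track(self) -> list[NoteEvent]:
        return self.tracks[0] if self.tracks else []

    def total_units(self) -> float:
        """Span of the score in eighth-note units (max note end over tracks)."""
        return max((n.end for t in self.tracks for n in t), default=0.0)


@dataclass
class ContactTable:
    """Undirected residue contacts, 1-based indices stored with i < j."""

    pairs: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        norm: list[tuple[int, int]] = []
        seen = set()
        for i, j in self.pairs:
            if i == j:
                raise ValidationError(f"self-contact ({i}, {j}) not allowed")
            if i < 1 or j < 1:
                raise ValidationError(f"contact indices must be 1-based: ({i}, {j})")
            pair = (min(i, j), max(i, j))
            if pair not in seen:
                seen.add(pair)
                norm.append(pair)
        self.pairs = norm

    def __len__(self) -> int:
        return len(self.pairs)

    def validate_for_length(self, n_residues: int) -> None:
        for i, j in self.pairs:
            if j > n_residues:
                raise ValidationError(
                    f"contact ({i}, {j}) outside chain of length {n_residues}"
                )


@dataclass
class CaCoordinates:
    """C-alpha positions in Å, one (x, y, z) row per residue."""

    positions: "object"  # (N, 3) float array

    def __post_init__(self) -> None:
        import numpy as np

        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise ValidationError("coordinates must be an (N, 3) array")
        if self.positions.shape[0] < 2:
            raise ValidationError("need at least 2 residues")
        if not np.all(np.isfinite(self.positions)):
            raise ValidationError("coordinates must be finite")

    def __len__(self) -> int:
        return self.positions.shape[0]


@dataclass
class TokenString:
    """Amino-acid letters interleaved with '#' / '!' delimiter tokens."""

    tokens: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        allowed = set(AA_ALPHABET) | {PROTEIN_SEP, CHAIN_SEP}
        for pos, tok in enumerate(self.tokens):
            if tok not in allowed:
                raise ValidationError(f"unknown token {tok!r} at position {pos}")

    def __str__(self) -> str:
        return "".join(self.tokens)

    def __len__(self) -> int:
        return len(self.tokens)
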