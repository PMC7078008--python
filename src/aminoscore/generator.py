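"""Generative modelling of protein scores.

Scores are factored into a 62-symbol event vocabulary — (amino acid,
secondary-structure class) pairs plus the '#' and '!' delimiters — so a
single next-token model captures pitch, timing and volume jointly (each
token renders deterministically to one note through the codec styles).

The default :class:`NGramBackoffModel` is an interpolated back-off frequency
model: the next-token distribution mixes maximum-likelihood estimates at all
context lengths 0..order that were observed in training, with geometrically
decaying weight on shorter contexts.  It trains in seconds on a CPU and is
deliberately pluggable — any object with a ``next_distribution(context)``
method (e.g. a neural sequence model) can drive :func:`sample`.

Sampling follows the usual temperature semantics: the model distribution p
is reshaped to p^(1/T) and renormalised, so T = 1 samples the model as
trained, T < 1 sharpens toward the mode, and T > 1 flattens toward
uniform-over-support.  Because every level of the back-off is an empirical
frequency, the sampler's support never leaves the training vocabulary: all
generated tokens render onto the 22 training pitches at any temperature.
"""
from __future__ import annotations

import json
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import sonics
from .types import (
    AA_ALPHABET,
    CHAIN_SEP,
    PROTEIN_SEP,
    MidiScore,
    NoteEvent,
    SequenceRecord,
    TokenString,
    ValidationError,
)

#: event vocabulary: "A:H" residue tokens (aa x ss) then the two delimiters
VOCAB: tuple[str, ...] = tuple(
    f"{aa}:{cls}" for aa in AA_ALPHABET for cls in "HEC"
) + (PROTEIN_SEP, CHAIN_SEP)
VOCAB_INDEX: dict[str, int] = {tok: k for k, tok in enumerate(VOCAB)}


def residue_token(aa: str, cls: str) -> str:
    tok = f"{aa}:{cls}"
    if tok not in VOCAB_INDEX:
        raise ValidationError(f"({aa!r}, {cls!r}) is not in the event vocabulary")
    return tok


@dataclass
class GeneratorConfig:
    """Sampling/training knobs.

    ``temperature`` reshapes the next-token distribution (baseline 1.0; the
    useful operating range is about 1.0–2.0).  ``steps`` counts generated
    tokens.  ``smoothing`` is the geometric back-off decay: a context one
    token shorter receives ``smoothing`` times the weight of the longer one.
    """

    temperature: float = 1.0
    steps: int = 100
    rng_seed: int = 0
    model_order: int = 4
    smoothing: float = 0.3

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValidationError("temperature must be positive")
        if self.steps < 0:
            raise ValidationError("steps must be non-negative")
        if self.model_order < 1:
            raise ValidationError("model_order must be >= 1")
        if not 0 < self.smoothing <= 1:
            raise ValidationError("smoothing must be in (0, 1]")


def tokenize(source, pitch_map=None, style=None, strict: bool = False) -> list[str]:
    """Token stream from records or a score.

    Records tokenize exactly as the codec would play them: one (aa, ss)
    token per residue, '!' between chains of a record, '#' between records.
    A score tokenizes through decode + infer_ss.
    """
    if isinstance(source, MidiScore):
        return _tokenize_score(source, pitch_map, style, strict)
    records = [source] if isinstance(source, SequenceRecord) else list(source)
    stream: list[str] = []
    for r_idx, rec in enumerate(records):
        for c_idx, chain in enumerate(rec.chains):
            if chain.ss is None:
                raise ValidationError("secondary structure required to tokenize")
            stream.extend(
                residue_token(aa, cls) for aa, cls in zip(chain.sequence, chain.ss)
            )
            if c_idx < len(rec.chains) - 1:
                stream.append(CHAIN_SEP)
        if r_idx < len(records) - 1:
            stream.append(PROTEIN_SEP)
    return stream


def _tokenize_score(score, pitch_map, style, strict) -> list[str]:
    letters = sonics.decode(score, pitch_map, strict=strict)
    ss = sonics.infer_ss(score, style, strict=strict)
    stream: list[str] = []
    ss_iter = iter(ss)
    for tok in letters.tokens:
        if tok in (CHAIN_SEP, PROTEIN_SEP):
            stream.append(tok)
        else:
            stream.append(residue_token(tok, next(ss_iter)))
    return stream


def render(tokens: list[str], pitch_map=None, style=None) -> MidiScore:
    """Inverse of :func:`tokenize`: play a token stream as a score."""
    pitch_map = pitch_map or sonics.PitchMap()
    style = style or sonics.SSStyle()
    notes: list[NoteEvent] = []
    cursor = 0.0
    for tok in tokens:
        if tok not in VOCAB_INDEX:
            raise ValidationError(f"token {tok!r} is not in the event vocabulary")
        if tok == CHAIN_SEP:
            dur, vel = style.sep_event(CHAIN_SEP)
            pitch = pitch_map.chain_sep_pitch
        elif tok == PROTEIN_SEP:
            dur, vel = style.sep_event(PROTEIN_SEP)
            pitch = pitch_map.protein_sep_pitch
        else:
            aa, cls = tok.split(":")
            pitch = pitch_map.aa_to_pitch[aa]
            dur, vel = style.duration(cls), style.velocity(cls)
        notes.append(NoteEvent(pitch, cursor, dur, vel))
        cursor += dur
    return MidiScore(tracks=[notes] if notes else [])


def to_token_string(tokens: list[str]) -> TokenString:
    """Drop the secondary-structure half of residue tokens -> letter stream."""
    return TokenString(
        [t if t in (CHAIN_SEP, PROTEIN_SEP) else t.split(":")[0] for t in tokens]
    )


@dataclass
class NGramBackoffModel:
    """Interpolated back-off frequency model over the event vocabulary.

    ``counts[k]`` maps a length-k context tuple to a Counter of successor
    tokens.  The next-token distribution interpolates the ML estimates of
    every context length observed for the current history, with weight
    proportional to ``smoothing ** (longest_defined - k)`` — longest context
    dominates, and the order-0 (unigram) level guarantees a defined,
    training-supported distribution everywhere.
    """

    order: int = 4
    smoothing: float = 0.3
    counts: list[dict[tuple, Counter]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.counts:
            self.counts = [defaultdict(Counter) for _ in range(self.order + 1)]

    def observe(self, stream: list[str]) -> None:
        for t, tok in enumerate(stream):
            if tok not in VOCAB_INDEX:
                raise ValidationError(f"token {tok!r} outside the vocabulary")
            for k in range(min(self.order, t) + 1):
                self.counts[k][tuple(stream[t - k : t])][tok] += 1

    def next_distribution(self, context: list[str]) -> np.ndarray:
        """Probability vector over :data:`VOCAB` given the trailing context."""
        context = list(context)[-self.order :] if self.order else []
        levels: list[tuple[int, Counter]] = []
        for k in range(min(self.order, len(context)), -1, -1):
            ctx = tuple(context[len(context) - k :])
            counter = self.counts[k].get(ctx)
            if counter:
                levels.append((k, counter))
        if not levels:
            raise ValidationError("model is untrained (no counts at any order)")
        top = levels[0][0]
        dist = np.zeros(len(VOCAB))
        weights = np.array([self.smoothing ** (top - k) for k, _ in levels])
        weights /= weights.sum()
        for w, (_, counter) in zip(weights, levels):
            total = sum(counter.values())
            for tok, n in counter.items():
                dist[VOCAB_INDEX[tok]] += w * n / total
        return dist / dist.sum()

    # -- portable JSON serialization ------------------------------------
    def to_json(self, path) -> None:
        payload = {
            "order": self.order,
            "smoothing": self.smoothing,
            "counts": [
                {" ".join(ctx): dict(counter) for ctx, counter in level.items()}
                for level in self.counts
            ],
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path) -> "NGramBackoffModel":
        payload = json.loads(Path(path).read_text())
        model = cls(order=payload["order"], smoothing=payload["smoothing"])
        model.counts = [
            defaultdict(
                Counter,
                {
                    tuple(ctx.split(" ")) if ctx else (): Counter(successors)
                    for ctx, successors in level.items()
                },
            )
            for level in payload["counts"]
        ]
        return model


def train(corpus: list[list[str]], config: GeneratorConfig | None = None) -> NGramBackoffModel:
    """Fit the back-off model on a corpus of token streams (deterministic)."""
    config = config or GeneratorConfig()
    if not corpus or all(not s for s in corpus):
        raise ValidationError("training corpus is empty")
    model = NGramBackoffModel(order=config.model_order, smoothing=config.smoothing)
    for stream in corpus:
        model.observe(list(stream))
    return model


def apply_temperature(dist: np.ndarray, temperature: float) -> np.ndarray:
    """Reshape a probability vector to p^(1/T), renormalised.

    Computed in log space so extreme temperatures stay stable; zero entries
    stay zero (support is preserved).
    """
    if temperature <= 0:
        raise ValidationError("temperature must be positive")
    dist = np.asarray(dist, dtype=float)
    if dist.ndim != 1 or dist.size == 0 or np.any(dist < 0):
        raise ValidationError("expected a 1-d non-negative probability vector")
    total = dist.sum()
    if not np.isclose(total, 1.0, atol=1e-6):
        raise ValidationError("distribution does not sum to 1")
    support = dist > 0
    out = np.zeros_like(dist)
    logs = np.log(dist[support]) / temperature
    logs -= logs.max()
    expd = np.exp(logs)
    out[support] = expd / expd.sum()
    return out


def sample(
    model, seed_tokens: list[str], config: GeneratorConfig
) -> list[str]:
    """Generate ``config.steps`` tokens after the seed (seed kept verbatim).

    Fully deterministic given (model, seed, config): the output begins with
    the seed, and each following token is drawn from the temperature-shaped
    conditional using ``numpy`` RNG seeded with ``config.rng_seed``.
    """
    for tok in seed_tokens:
        if tok not in VOCAB_INDEX:
            raise ValidationError(f"seed token {tok!r} outside the vocabulary")
    rng = np.random.default_rng(config.rng_seed)
    stream = list(seed_tokens)
    for _ in range(config.steps):
        dist = model.next_distribution(stream)
        dist = apply_temperature(dist, config.temperature)
        stream.append(VOCAB[rng.choice(len(VOCAB), p=dist)])
    return stream
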