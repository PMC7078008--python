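"""Downstream interpretation of generated scores and designed sequences.

Four independent capabilities:

* :func:`parse_generated` — total grammar over the delimiter tokens: '#'
  opens a new protein molecule, '!' closes a chain, the prefix before the
  first '#' is the generation seed.
* :func:`local_align` / :func:`novelty_scan` — Smith–Waterman-style local
  alignment (linear gap penalty) reporting percent identity and query
  cover, used to flag generated chains that merely reproduce the training
  corpus versus genuinely novel designs.
* :func:`helix_segments` — run-length segmentation of the helical rhythm,
  counting distinct alpha-helical segments in a structure string or score.
* :func:`anm_modes` — anisotropic network model normal modes of a C-alpha
  trace: directional Hookean springs within a distance cutoff, full
  eigendecomposition, six rigid-body zero modes for a connected network.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import eigh
from scipy.spatial.distance import pdist, squareform

from . import sonics
from .types import (
    CHAIN_SEP,
    PROTEIN_SEP,
    CaCoordinates,
    MidiScore,
    ValidationError,
)

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# delimiter grammar
# ---------------------------------------------------------------------------

@dataclass
class ParsedGeneration:
    """A generated token stream split into seed, proteins and chains."""

    seed_part: str
    proteins: list[list[str]] = field(default_factory=list)
    trailing_incomplete: bool = False

    @property
    def chains(self) -> list[str]:
        return [chain for protein in self.proteins for chain in protein]


def parse_generated(tokens) -> ParsedGeneration:
    """Parse a token stream by the delimiter grammar (total — never fails).

    '#' opens a new protein (closing any open chain), '!' closes the current
    chain within the current protein; the prefix before the first '#' is the
    seed part.  Empty chains (e.g. from '!#' runs) are dropped; a final
    chain not closed by a delimiter is kept and flagged incomplete.
    """
    stream = [t for t in (tokens.tokens if hasattr(tokens, "tokens") else tokens)]
    first_sep = stream.index(PROTEIN_SEP) if PROTEIN_SEP in stream else len(stream)
    seed_part = "".join(t for t in stream[:first_sep] if t not in (CHAIN_SEP,))

    proteins: list[list[str]] = []
    current_protein: list[str] | None = None
    current_chain: list[str] = []
    trailing = False

    def close_chain() -> None:
        nonlocal current_chain
        if current_chain and current_protein is not None:
            current_protein.append("".join(current_chain))
        current_chain = []

    for tok in stream[first_sep:]:
        if tok == PROTEIN_SEP:
            close_chain()
            current_protein = []
            proteins.append(current_protein)
        elif tok == CHAIN_SEP:
            close_chain()
        else:
            current_chain.append(tok)
    if current_chain:
        close_chain()
        trailing = True
    proteins = [p for p in proteins if p]
    return ParsedGeneration(seed_part, proteins, trailing)


# ---------------------------------------------------------------------------
# local alignment novelty scan
# ---------------------------------------------------------------------------

@dataclass
class NoveltyHit:
    """Alignment of one query chain against one corpus target."""

    target_id: str
    alignment_score: int
    percent_identity: float  # matches / aligned columns x 100
    query_cover: float  # aligned query span / query length x 100
    query_span: tuple[int, int] = (0, 0)  # 1-based inclusive; (0,0) if none
    target_span: tuple[int, int] = (0, 0)

    @property
    def in_training(self) -> bool:
        return self.percent_identity == 100.0 and self.query_cover == 100.0


def local_align(
    query: str,
    target: str,
    match: int = 1,
    mismatch: int = -1,
    gap: int = -2,
    target_id: str = "",
) -> NoveltyHit:
    """Best local alignment (Smith–Waterman recurrence, linear gap penalty).

    Ties between equally scoring alignments resolve to the earliest
    (query_start, target_start).  A best score of zero reports 0% identity
    and 0% cover.
    """
    if not query or not target:
        raise ValidationError("local_align requires non-empty sequences")
    n, m = len(query), len(target)
    H = np.zeros((n + 1, m + 1), dtype=np.int64)
    q = np.frombuffer(query.encode(), dtype=np.uint8)
    t = np.frombuffer(target.encode(), dtype=np.uint8)
    for i in range(1, n + 1):
        sub = np.where(t == q[i - 1], match, mismatch)
        row_prev = H[i - 1]
        row = H[i]
        # vectorised over j for diag/up; the left dependency is sequential
        diag = row_prev[:-1] + sub
        up = row_prev[1:] + gap
        best_left = 0
        for j in range(1, m + 1):
            val = max(0, diag[j - 1], up[j - 1], best_left + gap)
            row[j] = val
            best_left = val
    score = int(H.max())
    if score <= 0:
        return NoveltyHit(target_id, 0, 0.0, 0.0)

    ends = np.argwhere(H == score)

    def traceback(ei: int, ej: int):
        i, j = ei, ej
        matches = columns = 0
        while i > 0 and j > 0 and H[i, j] > 0:
            here = H[i, j]
            sub = match if query[i - 1] == target[j - 1] else mismatch
            if H[i - 1, j - 1] + sub == here:
                matches += query[i - 1] == target[j - 1]
                columns += 1
                i, j = i - 1, j - 1
            elif H[i - 1, j] + gap == here:
                columns += 1
                i -= 1
            else:
                columns += 1
                j -= 1
        return (i + 1, j + 1, matches, columns)

    candidates = []
    for ei, ej in ends:
        qs, ts, matches, columns = traceback(int(ei), int(ej))
        candidates.append(((qs, ts, int(ei), int(ej)), matches, columns))
    (qs, ts, qe, te), matches, columns = min(candidates, key=lambda c: c[0])
    return NoveltyHit(
        target_id,
        score,
        100.0 * matches / columns,
        100.0 * (qe - qs + 1) / n,
        (qs, qe),
        (ts, te),
    )


def novelty_scan(chain: str, corpus: dict[str, str] | list[str]) -> list[NoveltyHit]:
    """Align a chain against every corpus sequence, ranked by score.

    A chain whose best hit has 100% identity and 100% query cover is a
    training-set reproduction rather than a novel design (exposed as
    ``hit.in_training``).
    """
    if isinstance(corpus, dict):
        items = list(corpus.items())
    else:
        items = [(f"target_{k + 1}", seq) for k, seq in enumerate(corpus)]
    hits = [local_align(chain, seq, target_id=tid) for tid, seq in items]
    hits.sort(key=lambda h: (-h.alignment_score, h.target_id))
    return hits


# ---------------------------------------------------------------------------
# helix rhythm segmentation
# ---------------------------------------------------------------------------

def helix_segments(source, min_len: int = 4) -> list[tuple[int, int]]:
    """Maximal helix runs of length >= min_len, 1-based inclusive coordinates.

    ``source`` is a 3-class structure string or a score (classified through
    :func:`sonics.infer_ss`).  Any non-H symbol breaks the helical rhythm.
    """
    ss = sonics.infer_ss(source) if isinstance(source, MidiScore) else str(source)
    segments = []
    start = None
    for idx, cls in enumerate(ss + "."):  # sentinel terminates the last run
        if cls == "H" and start is None:
            start = idx
        elif cls != "H" and start is not None:
            if idx - start >= min_len:
                segments.append((start + 1, idx))
            start = None
    return segments


# ---------------------------------------------------------------------------
# anisotropic network model
# ---------------------------------------------------------------------------

@dataclass
class AnmConfig:
    """ANM springs: interaction cutoff (Å) and uniform spring constant."""

    cutoff: float = 15.0
    gamma: float = 1.0

    def __post_init__(self) -> None:
        if self.cutoff <= 0 or self.gamma <= 0:
            raise ValidationError("cutoff and gamma must be positive")


@dataclass
class AnmResult:
    eigenvalues: np.ndarray  # ascending, length 3N
    frequencies: np.ndarray  # sqrt(max(eigenvalue, 0)), non-decreasing
    modes: np.ndarray  # columns are 3N-component mode vectors
    n_zero_modes: int


def anm_hessian(coords: CaCoordinates, config: AnmConfig | None = None) -> np.ndarray:
    """3N x 3N ANM Hessian of directional springs within the cutoff.

    Off-diagonal super-element H_ij = -gamma (r_ij r_ij^T) / |r_ij|^2 for
    contacting pairs; diagonal super-elements enforce translation invariance
    (row sums of super-elements vanish).
    """
    config = config or AnmConfig()
    xyz = coords.positions
    n = len(coords)
    dists = squareform(pdist(xyz))
    hessian = np.zeros((3 * n, 3 * n))
    for i in range(n):
        for j in range(i + 1, n):
            d = dists[i, j]
            if d == 0:
                raise ValidationError(f"coincident residues {i + 1} and {j + 1}")
            if d > config.cutoff:
                continue
            r = xyz[j] - xyz[i]
            block = -config.gamma * np.outer(r, r) / d**2
            hessian[3 * i : 3 * i + 3, 3 * j : 3 * j + 3] = block
            hessian[3 * j : 3 * j + 3, 3 * i : 3 * i + 3] = block
            hessian[3 * i : 3 * i + 3, 3 * i : 3 * i + 3] -= block
            hessian[3 * j : 3 * j + 3, 3 * j : 3 * j + 3] -= block
    return hessian


def anm_modes(coords: CaCoordinates, config: AnmConfig | None = None) -> AnmResult:
    """Normal modes of the ANM network: eigenvalues, frequencies, vectors.

    A connected, non-collinear network has exactly six zero modes (rigid
    translations and rotations); more signals a disconnected network at the
    chosen cutoff and is reported with a warning rather than an error.
    """
    config = config or AnmConfig()
    hessian = anm_hessian(coords, config)
    eigenvalues, modes = eigh(hessian)
    if eigenvalues[0] < -1e-8:
        raise ValidationError(
            f"Hessian is not positive semi-definite (min eigenvalue "
            f"{eigenvalues[0]:.3e})"
        )
    n_zero = int(np.sum(np.abs(eigenvalues) < 1e-8))
    if n_zero > 6:
        logger.warning(
            "network is disconnected at cutoff %.1f Å: %d zero modes (expected 6)",
            config.cutoff,
            n_zero,
        )
    frequencies = np.sqrt(np.clip(eigenvalues, 0.0, None))
    return AnmResult(eigenvalues, frequencies, modes, n_zero)
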