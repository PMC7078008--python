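# Methods

This note documents the models and procedures implemented in `aminoscore`,
the defaults they use, the design decisions taken where the mapping was
genuinely open, and what the synthetic fixtures do and do not establish.

## The sequence ↔ score codec

A protein record is one or more chains, each an amino-acid string over the
canonical 20-letter alphabet with an aligned secondary-structure string
over {H, E, C}. Encoding emits one note per residue on a single monophonic
track: pitch identifies the residue, duration and velocity identify the
structural class (sheet 1.0 eighth-units at velocity 100, helix 0.5 at 50,
coil 2.0 at 25), and onsets are the cumulative sum of durations. A B-2
note of 4.0 units follows every chain except a record's last; an A#-2 note
of 8.0 units follows every record except the last. Decoding uses pitch
alone, so it is exact for any pitch bijection; the structure string is
recovered separately by nearest-(duration, velocity) classification
(`infer_ss`), with an exact-match strict mode and an error on ties.

**Pitch assignment.** The published mapping places the 20 amino acids on
white keys from C-2 to A1 but does not enumerate which residue takes which
key. The default here assigns the amino acids in alphabetical 1-letter
order (A, C, D, …, Y) to the 20 lowest white keys from C-2 upward, skipping
the reserved B-2 — i.e. C-2, D-2, E-2, F-2, G-2, A-2, C-1, …, B0. The map
is a plain config (YAML: letter → note name), and every reversibility
guarantee holds for any bijection that avoids the two delimiter pitches.
Octave naming follows the middle-C = C3 convention, so MIDI pitch 0 is C-2,
A#-2 = 10, B-2 = 11, A1 = 45.

**MIDI realisation.** Scores are written as format-1 standard MIDI files
with PPQ 480 and a fixed 120 bpm tempo; one eighth-note unit is PPQ/2 = 240
ticks, which makes every codec duration an exact integer tick count. The
file layer is a small purpose-built reader/writer (note on/off, tempo meta,
running status, variable-length deltas); round trips are identity on
pitch/onset/duration/velocity up to tick quantisation. Delimiters are
sounded notes, not rests, because decoding identifies them by pitch.
Bar counts are `ceil(total units / 8)`.

## Fold-contact coding

For each undirected contact (i, j) the fragment of residues
j−w … j+w (default window w = 2, clipped at chain ends) is inserted on a
second track starting at residue i's onset, and reciprocally around i at
residue j — two insertions per pair. Insertion notes are scaled by
`duration_factor` 0.25 and `velocity_factor` 0.5 relative to their own
class style; the contacting residue's note is boosted by `center_boost`
1.5. The boost is applied to the fragment's loudest pre-boost velocity
rather than the centre's own class velocity: the decoder identifies the
neighbour as the loudest note of its block, and in a fragment mixing
structural classes a sheet neighbour would otherwise outvoice a boosted
helix centre. For structurally homogeneous fragments the two rules
coincide. The quantitative factors are declared defaults — the qualitative
contract is faster and softer than the main line, centre slightly louder.

Decoding groups insertion-track notes into blocks (a silence of ≥ 1
eighth-unit separates blocks; fragments are internally gapless), reads each
block as a letter string, and requires a unique occurrence in the decoded
main sequence; zero or multiple matches raise an ambiguity error listing
candidate positions rather than guessing. Fragments at nearby hosts can be
back-to-back in time and merge into one block; since every fragment starts
exactly at its host's main-note onset, a failed block is re-parsed as a
concatenation of uniquely matching fragments cut at main-onset-aligned
notes (longest-prefix-first with backtracking). Under the default fixture
settings (40-residue chains, 2 pairs, ≥ 6-residue separation, disjoint
coding windows) exact round trips were measured on 499 of 500 random
draws, the single residue being a truthfully reported ambiguity from a
clipped 3-letter end fragment occurring twice.

## The event model and temperature sampling

Scores are tokenised into a 62-symbol vocabulary — (amino acid, structure
class) pairs plus '#' and '!' — so one next-token distribution couples
pitch, timing and volume. The default model is an interpolated back-off
frequency model of order 4: for the current history it mixes the
maximum-likelihood successor distributions of every context length
0 … order that occurred in training, weighting a context one token shorter
by `smoothing` (default 0.3) relative to the longer one and renormalising
over the defined levels. The unigram level is always defined, so no
context is a dead end, and because every level is an empirical frequency
the sampler's support never leaves the training vocabulary — generated
tokens render onto the 22 training pitches at any temperature. This is a
documented divergence from large neural samplers, which can emit
out-of-vocabulary notes at high temperature. The model contract
(`next_distribution(context)` over the vocabulary) accepts any drop-in
replacement, e.g. a neural sequence model.

Temperature reshapes a distribution as `p' ∝ p^(1/T)` (computed in log
space; support preserved; T ≤ 0 rejected): T = 1 is the identity, T < 1
sharpens, T > 1 flattens, and Shannon entropy is non-decreasing in T.
"Steps" counts generated tokens; output always begins with the seed
verbatim, and (corpus, config, seed, rng seed) fully determine the result.

The end-to-end demo trains on the corpus as a single interleaved stream
with a terminal '#', so the delimiters are part of the learned
distribution and sampled scores terminate chains the way training scores
do; per-protein streams remain supported by `train()`. With a high model
order and near-zero smoothing the model memorises a small corpus, and
chains sampled at T = 1.0 reproduce training sequences — the behaviour
expected of a well-fit model at baseline temperature — while higher
temperatures yield progressively more novel chains.

## Analysis

**Delimiter grammar.** `parse_generated` is total: '#' opens a new protein
(closing any open chain), '!' closes the current chain, the prefix before
the first '#' is the seed part, empty chains (from '!#' runs) are dropped,
and an unterminated final chain is kept with a `trailing_incomplete` flag.

**Novelty scan.** Sequence similarity is computed by exact local alignment
(Smith–Waterman recurrence, match +1, mismatch −1, linear gap −2),
reporting the two headline metrics: percent identity (matches over aligned
columns) and query cover (aligned query span over query length). Ties
between equal-scoring alignments resolve to the earliest
(query start, target start). A chain whose best hit reaches 100% identity
at 100% cover is flagged as a training-set reproduction. These metrics are
analogous to, not numerically identical with, database-search percentages
on divergent pairs; there are no E-values and no database heuristics.

**Helix segmentation.** Maximal H-runs of length ≥ `min_len` (default 4,
one helical turn) in a structure string, or in a score via `infer_ss`;
any non-H symbol breaks the helical rhythm.

**Normal modes.** The anisotropic network model connects C-alpha atoms
within a cutoff (default 15 Å) by directional springs of stiffness gamma
(default 1, arbitrary units — standard choices, configurable). The
3N × 3N Hessian has off-diagonal super-elements
`−gamma·(r_ij r_ijᵀ)/|r_ij|²` for contacting pairs and diagonal
super-elements enforcing vanishing row sums; a full symmetric
eigendecomposition gives eigenvalues λ (ascending) and frequencies
√max(λ, 0). A connected, non-collinear network has exactly six zero modes
(|λ| < 1e−8); more are reported with a warning as a disconnectivity
diagnostic. Frequencies are in units of √(gamma/mass) with unit masses;
only relative spectra are meaningful.

**DSSP input.** Classic columnar DSSP output is collapsed to three classes
by the conventional reduction {H, G, I} → H, {E, B} → E, everything else
(T, S, blank) → C, with chain-break rows becoming '/' boundaries matching
the multi-chain FASTA convention ('/' inside a sequence line separates
chains). Running DSSP itself is out of scope.

## Synthetic fixtures

`fixtures.simulate_records` emulates a helix-rich training corpus:
secondary structure alternates geometric-length helix blocks (mean 10)
with geometric linkers (mean 3) that are sheet with probability 0.1 and
coil otherwise — expected helix fraction 10/13 ≈ 0.77 — and residues are
drawn uniformly (or from per-class propensity weights). Chain lengths are
uniform on 30–60. Contact fixtures enforce a minimum sequence separation
of 6 and disjoint ±2-residue coding windows. All draws are deterministic
per `rng_seed`.

These fixtures are deliberately minimal: uniform residue usage has no
hydrophobic periodicity, no composition bias, and no correlation between
sequence and structure, and the block model has no sheet pairing or
topology. Passing tests therefore establish the *symbolic* guarantees —
reversibility of both codecs, grammar correctness, sampler laws — on
arbitrary inputs, not that generated sequences are biophysically plausible
proteins; assessing designability of a generated chain requires external
structure prediction and simulation, which this package does not do.

## Problem sizes and numerical choices

Default test and demo sizes are chosen so the full suite runs in a few
seconds on one CPU: codec identity on 1000 random records, fold round
trips on 200 draws, alignment versus brute-force enumeration on strings of
length ≤ 6 over a 3-letter alphabet, 25–30-residue traces for normal
modes, and 120–200-token generations. Velocities are realised as rounded
integers of fraction × reference (100/50/25); note times are floats whose
codec values are exactly representable at PPQ 480; eigenvalue zero
thresholds are 1e−8 on Hessians of O(1) stiffness; the bar count uses a
1e−9 guard against float accumulation.
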