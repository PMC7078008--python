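# aminoscore

Reversible protein sonification and score-space sequence design.

`aminoscore` translates proteins — amino-acid sequence plus per-residue
3-class secondary structure — into musical scores and back, and builds a
small generative-design pipeline on top of that representation. It is aimed
at structural bioinformaticians and computational-materials researchers who
want to explore sequence→structure patterns through a symbolic, fully
reversible musical encoding: encode a training corpus of helix-rich
proteins as MIDI, train a sequence model on the event stream, sample new
scores at a chosen temperature, and decode them into candidate protein
sequences with an embedded secondary-structure signature.

## The encoding

Each of the 20 amino acids maps to a distinct pitch on the white keys
(C-major scale members) from C-2 upward. Two reserved black keys delimit
higher-order structure: **A#-2 (`#`)** separates protein molecules, **B-2
(`!`)** separates chains within one protein — 22 pitches in total.
Secondary structure modulates note timing and volume (durations in
eighth-note units, 8 per bar; velocities relative to a reference of 100):

| element            | duration | velocity |
|--------------------|---------:|---------:|
| sheet (E)          |      1.0 |      100 |
| helix (H)          |      0.5 |       50 |
| coil (C)           |      2.0 |       25 |
| chain break `!`    |      4.0 |      100 |
| protein break `#`  |      8.0 |      100 |

Pitch alone carries residue identity, so decoding is exact for any pitch
bijection; rhythm and volume carry the structural class and are recovered
independently (`infer_ss`). Residue contacts (i, j) can additionally be
coded as inserted melodies — the sequence fragment around j played fast and
soft at residue i's note, its centre slightly louder, and vice versa —
and decoded back to the contact table by fragment matching.

Generation uses an interpolated back-off n-gram event model over the
62-symbol vocabulary (20 amino acids × 3 structure classes + 2 delimiters),
sampled with the standard temperature transform `p ∝ p^(1/T)`: T = 1
replays the training distribution, T → 2 flattens it toward novelty. The
model is a pluggable stand-in for any neural sequence model with the same
`next_distribution(context)` contract.

Analysis utilities parse generated token streams by the delimiter grammar,
rank novelty by Smith–Waterman local alignment (percent identity and query
cover), segment the helical rhythm, and compute anisotropic-network-model
normal modes from C-alpha coordinates.

## Worked example

```python
from aminoscore import Chain, SequenceRecord, bar_count, decode, encode, infer_ss

record = SequenceRecord("5xdj", [Chain("GIFSKLAGKKIKNLLISGLKG", "H" * 21)])
score = encode([record])
print(len(score.main_track), "notes,", bar_count(score), "bars")
print(decode(score))
print(infer_ss(score))
```

prints

```
21 notes, 2 bars
GIFSKLAGKKIKNLLISGLKG
HHHHHHHHHHHHHHHHHHHHH
```

— the 21-residue helical peptide becomes 21 sixteenth notes at half volume
(10.5 eighth units → 2 bars), the decoded pitches reproduce the sequence
exactly, and the timing/volume pattern reads back as the all-helix
structure string. The `examples/` directory holds one narrative script per
capability (sonify/decode, fold-contact coding, temperature-sweep
generation with novelty scoring, normal modes); each prints the numbers it
computes and what they mean. A thin CLI mirrors the library:
`aminoscore encode|decode|infer-ss|encode-folded|decode-contacts|train|generate|parse|novelty|segments|anm|simulate|demo`.

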