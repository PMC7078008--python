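"""Train the event model on synthetic helix-rich proteins and sample new
sequences across a temperature sweep.

Near temperature 1.0 the sampler mostly replays training material; toward
2.0 the distribution flattens and novel chains appear.  Generated streams
are parsed by the delimiter grammar ('#' new protein, '!' chain end) and
every complete chain is scored against the training corpus by local
alignment (percent identity / query cover).
"""
from aminoscore import fixtures

report = fixtures.demo_end_to_end(
    fixtures.FixtureConfig(n_proteins=8, rng_seed=7),
    temperatures=(1.0, 1.2, 1.8),
    steps=200,
)

print(f"trained on {report['n_training_proteins']} proteins "
      f"({report['n_training_residues']} residues); "
      f"seed = {report['seed_length']} tokens")
for temp, block in report["temperatures"].items():
    print(f"\ntemperature {temp}: {block['n_generated_chains']} chains")
    for chain in block["chains"]:
        tag = "training-set reproduction" if chain["in_training"] else "novel"
        print(f"  len {chain['length']:3d}  best identity "
              f"{chain['best_identity']:5.1f}%  cover {chain['best_cover']:5.1f}%  "
              f"{chain['helix_segments']} helix segments  -> {tag}")
# Identity/cover of 100/100 flags a verbatim training chain; lower values
# mean the model recombined or invented sequence.
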