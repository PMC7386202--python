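"""Simulate a genome with planted transposon copies and inspect the truth.

Generates a 150-kb genome carrying five copies of each of the seven
packaged families, with 2% per-site decay and occasional truncation, then
prints what was planted. The TruthSet is the oracle used to score every
later pipeline stage.
"""
from collections import Counter

from pogoscout.synth import SynthSpec, generate_genome

spec = SynthSpec(rng_seed=1)  # defaults: 150 kb, 5 copies/family, 2% decay
contigs, truth = generate_genome(spec)

genome = contigs[0]
print(f"genome: {genome.id}, {len(genome):,} bp, "
      f"{len(truth.copies)} planted copies")
print("status tally:", dict(Counter(c.status for c in truth.copies)))
print()
print(f"{'copy':<14}{'family':<10}{'status':<11}{'TSD':<6}{'length':>7}")
for c in truth.copies[:10]:
    print(f"{c.copy_id:<14}{c.family:<10}{c.status:<11}{c.tsd:<6}"
          f"{len(c.element_seq):>7}")
print("...")
# Each planted copy sits between two identical TSD copies (TA, TAA or TAAA
# depending on family) and carries inverted terminal repeats; decayed copies
# have point substitutions, truncated ones lost a TIR and part of the ORF.
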