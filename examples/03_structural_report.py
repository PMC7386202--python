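"""Structural typing: triad spacing, DBD architecture, TIR types.

Runs the full pipeline on a small synthetic genome and prints the per-family
structural summary: element length ranges, TSD class tallies and DDE triad
labels (e.g. Passer DD35D, Mover DD36D).
"""
from pogoscout.pipeline import run_synthetic
from pogoscout.structure import build_structural_report
from pogoscout.synth import SynthSpec

spec = SynthSpec(genome_length=200_000, copies_per_family=4,
                 substitution_rate=0.0, truncation_probability=0.0,
                 rng_seed=11)
manifest, elements, truth = run_synthetic(spec, n_boot_family=25)

table, summary = build_structural_report(elements)
print(summary.to_string(index=False))
print()
print(table.head(8).to_string(index=False))
# The triad column shows the label read off the catalytic domain alignment;
# the tsd_classes tally shows TA for most families, TAA for Fot and TAAA for
# Fot-like, with zero cross-class confusion on clean data.
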