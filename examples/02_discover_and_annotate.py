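"""Discover candidate loci by translated homology and annotate boundaries.

Scans a clean synthetic genome with the packaged family transposases
(six-frame k-mer-seeded scan standing in for TBlastN), keeps the top
non-overlapping hits per query, refines element boundaries from the
multi-copy alignment, and calls TIRs and TSDs.
"""
from pogoscout.boundary import annotate_element, refine_boundaries
from pogoscout.config import PipelineConfig
from pogoscout.discovery import select_top_hits, translated_scan
from pogoscout.families import build_templates
from pogoscout.synth import SynthSpec, generate_genome

spec = SynthSpec(genome_length=120_000, copies_per_family=4,
                 substitution_rate=0.0, truncation_probability=0.0,
                 rng_seed=5)
templates = {"Fot": build_templates()["Fot"]}
contigs, truth = generate_genome(spec, templates)
genome = contigs[0]
config = PipelineConfig()

hits = translated_scan([("Fot", templates["Fot"].tpase_protein)], genome)
print(f"{len(hits)} translated hits (score-ranked)")

loci = select_top_hits(hits, genome, config)
print(f"{len(loci)} candidate loci with 2-kb flanks")

refined = refine_boundaries(loci, genome)
for coarse in refined:
    el = annotate_element(genome, coarse, config)
    tir = el.tirs.length if el.tirs else 0
    print(f"  {el.locus.start}-{el.locus.end}  status={el.status}  "
          f"TIR={tir} bp  TSD={el.tsd.repeat}  "
          f"tpase={len(el.tpase.protein) if el.tpase else 0} aa")
# All four planted Fot copies should come back FULL with a 48-bp TIR and the
# family's TAA target-site duplication.
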