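# pogoscout

Annotation of *pogo*-superfamily DNA transposons and detection of
domesticated transposase genes.

*pogo* elements are cut-and-paste DNA transposons of the *IS630–Tc1–mariner*
(ITm) group. An intact copy is bounded by terminal inverted repeats (TIRs)
and an insertion-generated target site duplication (TSD — here TA, TAA or
TAAA), and encodes a transposase with an N-terminal DNA-binding domain (DBD)
built from the motifs CENP-B_N, HTH_ABP1_N, HTH_Tnp_Tc5, BrkDBD and HTH_psq,
plus a catalytic DDE triad whose spacing between the last two acidic
residues varies across families (DD29–56D; e.g. DD35D in *Passer* and
*Fot/Fot-like*, DD36D in *Mover*). Some transposases have lost their TIRs
and mobility and persist as host genes ("molecular domestication", e.g.
CENPB, JRK, POGZ, TIGD2–7), recognisable by single-copy orthologs across
many species evolving under purifying selection (Ka/Ks ≪ 1).

`pogoscout` implements that whole inference chain as a tested Python
library:

- **synth** — synthetic genomes with planted element copies (TSD + TIR +
  transposase ORF + inverted TIR + duplicated TSD), decay, truncation,
  contaminant contigs, and codon-level evolution of domesticated-gene and
  pseudogene-like clades under a chosen dN/dS (ω); every planted feature is
  recorded in a `TruthSet`.
- **discovery** — a six-frame, k-mer-seeded, BLOSUM62 X-drop translated
  scan (or ingestion of 12-column tabular hits at e-value ≤ 1e−100), top-10
  non-overlapping hit selection with 2-kb flanks, copy counting
  (alignments > 1000 bp at > 80% identity) and a low-copy (< 3) flank-mapping
  contamination check.
- **boundary** — multi-copy boundary refinement, joint TIR+TSD boundary
  polishing, TIR detection, longest-exact-match TSD calling, and the
  validation rule: two TIRs + TSD ⇒ FULL; one TIR + TSD + transposase
  ≥ 300 aa ⇒ HALF; otherwise DISCARDED (with reason).
- **structure** — ORF extraction, DDE-triad labelling against the packaged
  reference panel, DBD architecture, TIR type bands (1: ≤ 40 bp, 2: ≤ 60,
  3: ≤ 200, 4: longer), and the per-family structural report.
- **phylo** — Poisson-corrected protein distances, from-scratch neighbor
  joining with deterministic tie-breaks, classical bootstrap, family
  placement against the panel, and relaxed-PHYLIP/FASTA export for external
  maximum-likelihood tools.
- **domestication** — transposon vs gene discrimination on flank evidence,
  a from-scratch Nei–Gojobori (NG86) Ka/Ks with Jukes–Cantor correction, a
  one-tailed bootstrap Z-test (purifying ⇔ Ka/Ks < 1 and P < 0.05), and the
  stringent clade filters (identity ≥ 70%, ≥ 5 species, ≤ 3 copies/genome).

The reference panel and family templates are synthetic, generated
deterministically inside the package (no third-party sequence data ships
with it); real-data users can substitute their own panel and hit tables
through the same interfaces.

## A worked example

```python
from pogoscout.pipeline import run_synthetic
from pogoscout.synth import SynthSpec

spec = SynthSpec(genome_length=200_000, copies_per_family=4,
                 substitution_rate=0.0, truncation_probability=0.0,
                 rng_seed=11)
manifest, elements, truth = run_synthetic(spec)
full = [e for e in elements if e.status == "FULL"]
print(len(truth.copies), len(full), full[0].family,
      full[0].tsd.repeat, full[0].tpase.triad.label)
```

prints

```
28 28 Fot TAA DD35D
```

— all 28 planted elements recovered as FULL; the first is a *Fot* copy with
its family-diagnostic TAA target site duplication and DD35D catalytic
triad. The scripts in `examples/` walk through each capability
(simulation, discovery and boundary annotation, structural typing, family
placement, Ka/Ks, domestication calls) with commented output.

A thin CLI wraps the same functions:

```sh
pogo-scout run --spec spec.json --out out/       # synthetic end-to-end run
pogo-scout discover --genome g.fa --queries q.fa --out loci.json
pogo-scout classify --proteins p.fa --out fam.tsv --export-ml aln.phy
```

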