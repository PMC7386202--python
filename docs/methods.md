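# Methods

This note documents the models, algorithms, parameter choices and known
limitations of `pogoscout`. Coordinates are 0-based half-open everywhere in
memory; GFF3 output converts to 1-based inclusive at the boundary.

## The annotation model

A *pogo*-style element is modelled as

```
TSD | TIR ... transposase ORF ... inverted TIR | TSD
```

with the TSD (TA, TAA or TAAA) duplicated at insertion and therefore
identical on both flanks, and the right TIR the reverse complement of the
left. Validation follows the mining rule of the field: an element with two
detectable TIRs and a TSD is FULL; one TIR plus a TSD plus a transposase of
at least 300 aa is HALF; anything less is DISCARDED but kept in the output
with its reason. Mining thresholds default to the standard survey values:
hits ingested at e-value ≤ 1e−100, top 10 non-overlapping hits per query,
2-kb flanks, copies counted from alignments > 1000 bp at > 80% identity, a
< 3-copy contamination gate, 100 bootstrap replicates for the selection
test.

## Translated scan

The built-in scan six-frame-translates the genome, seeds on exact 4-aa
k-mers, and extends without gaps under BLOSUM62 with an X-drop of 15,
reporting raw scores (no e-value statistics; precomputed tabular hits are
the route for score statistics from external engines). `min_score = 60` was
calibrated on null simulations (random 10-kb genomes vs a 380-aa query
yield no hits in ≥ 99% of seeds) while a single exact 4-mer chain across a
planted ORF scores in the thousands; 10% amino-acid divergence still leaves
hundreds of intact seeds on a 380-aa query, so recall there is ≥ 90%.

## Boundary determination

Boundaries are determined in three steps.

1. **Multi-copy refinement** (≥ 3 copies): copy-plus-flank sequences are
   multiply aligned and the element is the region whose per-column mean
   pairwise identity, smoothed over 10 columns, stays above 0.7 for at
   least 20 columns; the raw profile then sharpens the edge, and a
   per-copy pass anchors on a fully conserved column block and extends
   outward by exact pairwise matching (median over partners) because the
   pairwise edit paths can "cut the corner" at the flank/element junction.
   The multiple alignment is a center-star construction over edlib global
   pairwise paths, the center being the copy with the greatest summed
   k-mer similarity to the rest; an external MSA can be substituted via
   the same interface. With fewer than 3 copies the hit interval is kept
   with a warning.
2. **Polish**: both ends are shifted within ± 8 bp to maximise
   `IR + 3·min(TSD_k, 4) + 10·[TSD ∈ {TA, TAA, TAAA}]`, where IR is a
   mismatch-tolerant inverted-repeat extension score that requires the
   first 4 compared bases to match exactly (a TIR is terminal by
   definition). The capped TSD term and the canonical-class bonus are
   needed because TA is palindromic: without them the inverted repeat can
   absorb the duplication and shift both boundaries symmetrically.
3. **TIR/TSD calls**: the polished element's first `max_tir_len` bases are
   locally aligned to the reverse complement of its last `max_tir_len`
   bases (match +2 / mismatch −3 / gaps −5, −2); the alignment is trimmed
   to its best-scoring prefix, and accepted when anchored within 5 bp of
   both termini with ≥ 10 aligned bases at ≥ 80% identity
   (`min_tir_len = 10` calibrated on nulls: random 300-bp sequences pass
   in < 1% of seeds under the anchoring constraint). `max_tir_len = 1000`
   covers the longest published TIR class (hundreds of bp). The TSD is the
   longest k ∈ [2, 10] for which the last k bases of the left flank
   exactly equal the first k of the right flank — exact match only,
   because mismatch tolerance floods TA calls in AT-rich flanks, and
   longest-match so a TAAA site is never down-called to its substring TA.
   Truncated elements get a second chance through a known-TIR probe
   supplied by their cluster.

TIR type bands: 1 = [1, 40] bp (40 resolved downward, the sharper printed
bound), 2 = (40, 60], 3 = (60, 200], 4 = (200, ∞); the cut at 200 bp lies
in the gap between the observed ~100-bp and ≥ 392-bp classes and is
configurable.

## Structural typing

The transposase is the longest start-to-stop ORF over six frames (longest
stop-free stretch as fallback when no ATG-initiated ORF reaches 100 aa).
The DDE triad is read off a local BLOSUM62 alignment to the best-matching
panel reference: query residues aligned to the reference's annotated triad
columns, spacing counted on the query, label rendered e.g. DD35D; the call
is refused when a triad column lands in a gap or alignment identity falls
below 0.30. The third residue is reported as found (D/E/N/S/G all occur in
real data). DBD architecture scans consensus motif blocks at ≥ 70%
similarity (or ingests a per-domain table at domain e-value ≤ 1e−5),
resolving overlaps by best score; fusion domains (KRAB, ZNF, CENP-B
dimerisation) outside the transposase repertoire mark a protein chimeric.

## Phylogenetic placement

Distances are Poisson-corrected p-distances with pairwise gap deletion
(p ≥ 0.99 capped with a warning). Neighbor joining is the canonical
Q-criterion algorithm with lexicographic tie-breaks (a node's label is its
smallest descendant leaf), negative branch lengths clamped to zero with
the deficit moved to the sister branch. Bootstrap is classical column
resampling; supports are percentages of replicates containing each
original bipartition. A query is placed by profile-inserting its catalytic
domain into the panel alignment at its best reference's columns and
assigned to the family whose members plus the query form a bipartition in
the most replicates (Unclassified below 50%, or when the query has no
credible panel homology: identity < 0.30 or coverage < 0.6 against every
reference). Maximum-likelihood inference is deliberately delegated: the
alignment is exported in relaxed PHYLIP/FASTA for external tools, and
bootstrap values here are not comparable to ultrafast-bootstrap numbers.

## Ka/Ks and domestication

NG86 counts synonymous sites per codon as the synonymous fraction of the
nine single-nucleotide changes (mutations to stops nonsynonymous), averages
site counts over the two sequences, and classifies multi-change codons by
averaging over all mutational orderings whose intermediates are not stops
(if every ordering crosses a stop, all are used with stop steps counted
nonsynonymous — implementations differ here, so the choice is stated).
Proportions receive the Jukes–Cantor correction d = −(3/4)·ln(1 − 4p/3);
p ≥ 3/4 leaves that rate undefined. The selection test resamples codons
with replacement (100 replicates), estimates Var(Ks − Ka), and tests the
one-tailed purifying alternative Ks > Ka; the verdict is purifying iff
Ka < Ks and P < 0.05. Ks = 0 with Ka > 0 leaves the ratio undefined and
the verdict to the Z-test. Fewer than 10 comparable codons ⇒ undefined.

A clade is `stationary_domesticated` when mean pairwise protein identity
≥ 70%, ≥ 5 species, ≤ 3 copies per genome, and the purifying verdict holds
(majority of pairwise tests significant and mean ratio < 1; the pairing
scheme is all pairs of one representative per species, and is labelled as
such). Multi-copy or low-identity clades that still align to the panel are
`pseudogene_like`; the rest are `rejected` with reasons. Orthology/clade
grouping is taken as given; ortholog inference is out of scope.

Locus discrimination (transposon vs putative domesticated gene) scans the
hit ± 2 kb window for a TIR pair — with a raised minimum length of 16 bp,
because an unanchored scan over 2-kb windows would otherwise hit chance
inverted repeats — polishes the implied boundaries and demands a TSD
there; known family TIR probes catch single decayed TIRs. Any hallmark on
either side ⇒ transposon-like.

## The synthetic generator

The generator emulates the statistical structure the pipeline assumes, not
real genomes. Backgrounds are i.i.d. at a given GC (default 0.42). Each
family has one master element (its copies descend from one active element,
so they are near-identical over their whole length); elements run
1.2–1.4 kb with 380-aa transposases, within the published 1.2–5.2 kb /
300–977 aa ranges. Copies are spaced ≥ 2 kb apart so flanks are clean —
nested insertions and overlap handling are deliberately out of scope. The
TSD is written once and duplicated at insertion; the background base
adjacent to a planted TSD is adjusted when it would extend the duplication,
since otherwise the genome genuinely contains a longer repeat than the
recorded truth and the truth label itself would be wrong. Decayed copies
carry i.i.d. point substitutions (default 2%); truncated copies (default
probability 0.15) lose the left TIR and 40% of the ORF — which drops the
residual ORF below 300 aa, exactly the class the validation rule discards.
Stop codons are planted in all three frames between the ORF and its pads
so the planted ORF is recovered exactly by a longest-ORF scan. Defaults
(150-kb genome, 5 copies/family, 8 species, ω = 0.1, divergence 0.2) sit in
the middle of the regimes the method is meant for; copy numbers in real
fungal genomes span 1 to a few hundred.

Codon evolution proposes uniform single-nucleotide changes, rejects stops,
accepts synonymous changes always and nonsynonymous ones with probability
ω, until a Binomial(L, d) target of accepted substitutions is reached; a
clade is a star phylogeny with per-branch divergence d/2 (pairwise Ka/Ks
is the analysis, so no tree-shape confound is wanted). Under ω = 1 the
rule is mutation-blind except for stop rejection, and NG86 on such pairs
averages ≈ 0.98 — the small deficit (and the Z-test's size of ~8–9% at
α = 0.05 instead of 5%) comes from stop-adjacent codons contributing
nonsynonymous site counts that the process never realises. Pseudogene-like
clades are ≥ 4 copies per genome evolving neutrally at inflated divergence,
which pushes mean protein identity below 70%.

What passing on these synthetics does **not** show: tolerance to indels and
assembly gaps (the generator is substitution-only), nested or fragmented
copies, diverged real panels (the packaged panel is synthetic, with ~45%
inter-family and ~90% within-family identity), or e-value calibration of
the scan. Element orientation is always forward in generated genomes;
strand symmetry of the scan, ORF finder and TIR caller is tested directly
on reverse-complemented constructions instead.

## Numerical and degenerate-input choices

- Hit ingestion normalises reversed subject coordinates to (−) strand and
  divides the 0–100 identity scale by 100; filtering is monotone in the
  cutoff.
- N bases never count as matches in any identity computation.
- Boundary refinement declines (with a machine-parsable warning) on < 3
  copies, on no conserved block, and when copies share flanks (no identity
  drop at the margins).
- `find_tir` trims the local alignment to its best-scoring prefix before
  applying the identity threshold, because optimal local alignments drag
  in chance matches past the repeat.
- Bootstrap and family-assignment RNG streams are derived from the user
  seed (per-query streams via CRC32 of the query id), so results are
  independent of query order and reproducible across processes.
- Known residual failure modes of boundary recovery on clean data (≈ 1% of
  elements): a chance direct repeat a few bases outside a palindromic TA
  TSD can out-score the true decomposition, and a chance flank repeat can
  extend the planted duplication past what the disambiguation guard covers.
  Both are reported honestly as shifted boundaries or OTHER-class TSDs.

## Problem sizes

The test suite and the acceptance script run on one CPU in a few minutes
total. Scales used: 200-kb genomes with 28 planted elements for recovery;
3,721 codon pairs for the NG86 oracle; 100 seeds × 500 codons for Z-test
calibration; a 21-member panel for triad self-consistency and leave-one-out
placement; 4 clades × 8 species for domestication calls. These sizes give
binomial standard errors comfortably inside the asserted margins.
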