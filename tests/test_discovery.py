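"""Translated scan, top-hit selection, copy counting, contamination rule."""
import numpy as np
import pytest

from pogoscout.config import PipelineConfig
from pogoscout.discovery import (contamination_check, count_copies,
                                 select_top_hits, translated_scan)
from pogoscout.model import (CandidateLocus, CopyNumberReport,
                             GenomicSequence, HitRecord, Interval, revcomp)
from pogoscout.synth import SynthSpec, generate_genome


def _rand_dna(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


class TestTranslatedScan:
    def test_recall_on_planted_copies_is_total(self, clean_genome, templates):
        contigs, truth = clean_genome
        genome = contigs[0]
        queries = [(f, t.tpase_protein) for f, t in sorted(templates.items())]
        hits = translated_scan(queries, genome)
        for c in truth.copies:
            own = [h for h in hits
                   if h.query_id == c.family and h.target.overlaps(c.locus)]
            assert own, f"no hit for planted copy {c.copy_id}"

    def test_recall_above_90pct_at_10pct_aa_divergence(self, templates):
        rng = np.random.default_rng(21)
        tpl = templates["Passer"]
        aa = list("ACDEFGHIKLMNPQRSTVWY")
        found = 0
        n_trials = 20
        from pogoscout.synth import back_translate
        for t in range(n_trials):
            mutated = "".join(
                (rng.choice([x for x in aa if x != a]) if rng.random() < 0.10
                 else a) for a in tpl.tpase_protein)
            genome = GenomicSequence(
                id="g", residues=_rand_dna(rng, 3000) + back_translate(mutated)
                + _rand_dna(rng, 3000))
            hits = translated_scan([("q", tpl.tpase_protein)], genome)
            if hits:
                found += 1
        assert found >= 0.9 * n_trials

    def test_null_genome_yields_no_hits(self, templates):
        tpl = templates["Tigger"]
        empty = 0
        for seed in range(30):
            rng = np.random.default_rng(1000 + seed)
            genome = GenomicSequence(id="null", residues=_rand_dna(rng, 10_000))
            if not translated_scan([("q", tpl.tpase_protein)], genome):
                empty += 1
        assert empty >= 29  # >= 99% of seeds at desk scale

    def test_reverse_complemented_copy_hits_minus_strand(self, templates):
        from pogoscout.synth import back_translate
        rng = np.random.default_rng(8)
        tpl = templates["Mover"]
        orf = back_translate(tpl.tpase_protein)
        left, right = _rand_dna(rng, 2000), _rand_dna(rng, 2000)
        fwd = GenomicSequence(id="g", residues=left + orf + right)
        rev = GenomicSequence(id="g", residues=left + revcomp(orf) + right)
        q = [("q", tpl.tpase_protein)]
        h_fwd = translated_scan(q, fwd)[0]
        h_rev = translated_scan(q, rev)[0]
        assert h_fwd.target.strand == "+" and h_rev.target.strand == "-"
        assert h_fwd.bit_score == h_rev.bit_score

    def test_empty_query_rejected(self):
        g = GenomicSequence(id="g", residues="ACGT" * 100)
        with pytest.raises(ValueError, match="empty query"):
            translated_scan([("q", "")], g)


def _mk_hit(qid, start, end, score, seq_id="g"):
    return HitRecord(query_id=qid, target=Interval(seq_id, start, end),
                     percent_identity=0.9, alignment_length=end - start,
                     evalue=0.0, bit_score=score)


class TestSelectTopHits:
    GENOME = GenomicSequence(id="g", residues="A" * 50_000)

    def test_twelve_nonoverlapping_hits_capped_at_ten(self):
        hits = [_mk_hit("q", i * 2000, i * 2000 + 500, 100 - i)
                for i in range(12)]
        loci = select_top_hits(hits, self.GENOME, PipelineConfig())
        assert len(loci) == 10

    def test_overlapping_lower_scoring_hit_dropped(self):
        hits = [_mk_hit("q", 1000, 2000, 90), _mk_hit("q", 1500, 2500, 80)]
        loci = select_top_hits(hits, self.GENOME)
        assert len(loci) == 1 and loci[0].locus.start == 1000

    def test_flank_clipped_at_contig_start(self):
        hits = [_mk_hit("q", 500, 1500, 50)]
        loci = select_top_hits(hits, self.GENOME)
        assert len(loci[0].flank_left) == 500
        assert len(loci[0].flank_right) == 2000

    def test_cap_holds_for_any_input_size(self):
        hits = [_mk_hit("q", i * 1000, i * 1000 + 400, float(i))
                for i in range(40)]
        loci = select_top_hits(hits, self.GENOME)
        assert len(loci) <= PipelineConfig().top_hits_per_query


@pytest.fixture(scope="module")
def planted():
    spec = SynthSpec(genome_length=80_000, copies_per_family=5,
                     substitution_rate=0.0, truncation_probability=0.0,
                     rng_seed=13)
    from pogoscout.families import build_templates
    contigs, truth = generate_genome(spec, {"Fot": build_templates()["Fot"]})
    return contigs[0], truth


class TestCountCopies:

    def test_counts_planted_undecayed_copies(self, planted):
        genome, truth = planted
        rep = truth.copies[0].element_seq
        assert count_copies(rep, genome).n_copies == 5

    def test_short_fragment_not_counted(self, planted):
        genome, truth = planted
        rep = truth.copies[0].element_seq
        rng = np.random.default_rng(2)
        decoy = GenomicSequence(
            id="d", residues=_rand_dna(rng, 3000) + rep[:900]
            + _rand_dna(rng, 3000))
        assert count_copies(rep, decoy).n_copies == 1  # floor, nothing found

    def test_low_identity_copy_not_counted(self, planted):
        genome, truth = planted
        rep = truth.copies[0].element_seq
        rng = np.random.default_rng(3)
        diverged = "".join(
            (rng.choice([x for x in "ACGT" if x != b]) if rng.random() < 0.22
             else b) for b in rep)
        decoy = GenomicSequence(
            id="d", residues=_rand_dna(rng, 2000) + diverged
            + _rand_dna(rng, 2000))
        assert count_copies(rep, decoy).n_copies == 1

    def test_invariant_under_reverse_complement(self, planted):
        genome, truth = planted
        rep = truth.copies[0].element_seq
        rc = GenomicSequence(id="rc", residues=revcomp(genome.residues))
        assert count_copies(rep, genome).n_copies == \
            count_copies(rep, rc).n_copies

    def test_short_representative_rejected(self, planted):
        genome, _ = planted
        with pytest.raises(ValueError, match="copy_min_len_bp"):
            count_copies("ACGT" * 100, genome)


class TestContaminationCheck:
    def _locus(self, genome, start, end):
        hit = _mk_hit("q", start, end, 100.0, seq_id=genome.id)
        cfg = PipelineConfig()
        return CandidateLocus(
            locus=hit.target, supporting_hits=[hit],
            flank_left=genome.residues[max(0, start - cfg.flank_bp) : start],
            flank_right=genome.residues[end : end + cfg.flank_bp])

    def test_high_copy_element_skips_check(self):
        rng = np.random.default_rng(5)
        g = GenomicSequence(id="g", residues=_rand_dna(rng, 10_000))
        locus = self._locus(g, 4000, 5000)
        report = CopyNumberReport("r", n_copies=5)
        assert contamination_check(locus, report, [g]) is False

    def test_low_copy_with_duplicated_flanks_retained(self):
        rng = np.random.default_rng(6)
        flank_l, flank_r = _rand_dna(rng, 400), _rand_dna(rng, 400)
        element = _rand_dna(rng, 1200)
        # flanks genuinely occur elsewhere in the assembly
        residues = (_rand_dna(rng, 2000) + flank_l + element + flank_r
                    + _rand_dna(rng, 2000) + flank_l + flank_r
                    + _rand_dna(rng, 1000))
        g = GenomicSequence(id="g", residues=residues)
        start = 2000 + 400
        locus = self._locus(g, start, start + 1200)
        report = CopyNumberReport("r", n_copies=2)
        assert contamination_check(locus, report, [g]) is False

    def test_foreign_contig_with_unique_flanks_excluded(self):
        spec = SynthSpec(genome_length=60_000, copies_per_family=1,
                         substitution_rate=0.0, truncation_probability=0.0,
                         rng_seed=4, n_contaminant_contigs=1)
        contigs, truth = generate_genome(spec)
        contam = [c for c in truth.copies if c.contaminant][0]
        cg = contigs[1]
        locus = self._locus(cg, contam.locus.start, contam.locus.end)
        report = CopyNumberReport("r", n_copies=1)
        assert contamination_check(locus, report, contigs) is True

    def test_short_flanks_skip_check(self, caplog):
        rng = np.random.default_rng(7)
        g = GenomicSequence(id="g", residues=_rand_dna(rng, 2000))
        hit = _mk_hit("q", 10, 1500, 50.0, seq_id="g")
        locus = CandidateLocus(locus=hit.target, supporting_hits=[hit],
                               flank_left=g.residues[:10],
                               flank_right=g.residues[1500:1540])
        report = CopyNumberReport("r", n_copies=1)
        import logging
        with caplog.at_level(logging.WARNING):
            assert contamination_check(locus, report, [g]) is False
        assert any("skipped" in r.message for r in caplog.records)
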