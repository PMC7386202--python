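"""Nei-Gojobori Ka/Ks, Z-test, discrimination and clade calling."""
import itertools

import numpy as np
import pytest
from Bio.Seq import Seq

from pogoscout.domestication import (call_domestication, detect_fusion_domains,
                                     discriminate_locus, is_chimeric,
                                     kaks_z_test, ng86_differences, ng86_pair,
                                     ng86_sites)
from pogoscout.families import motif_consensus
from pogoscout.model import GenomicSequence, Interval
from pogoscout.synth import (STOP_CODONS, SynthSpec, back_translate,
                             evolve_codon_pair, generate_domesticated_clade,
                             generate_genome)

NON_STOP_CODONS = [a + b + c
                   for a in "ACGT" for b in "ACGT" for c in "ACGT"
                   if a + b + c not in STOP_CODONS]


# --- independent brute-force oracle (kept deliberately naive) --------------

def _oracle_sites(codon):
    aa = str(Seq(codon).translate())
    s = 0.0
    for pos in range(3):
        for b in "ACGT":
            if b == codon[pos]:
                continue
            alt = codon[:pos] + b + codon[pos + 1:]
            if alt not in STOP_CODONS and str(Seq(alt).translate()) == aa:
                s += 1 / 3
    return 3 - s, s


def _oracle_differences(ca, cb):
    diffs = [i for i in range(3) if ca[i] != cb[i]]
    if not diffs:
        return 0.0, 0.0
    all_paths, valid_paths = [], []
    for order in itertools.permutations(diffs):
        cur, steps, crossed = ca, [], False
        for pos in order:
            nxt = cur[:pos] + cb[pos] + cur[pos + 1:]
            if nxt in STOP_CODONS and nxt != cb:
                crossed = True
            syn = (nxt not in STOP_CODONS
                   and str(Seq(nxt).translate()) == str(Seq(cur).translate()))
            steps.append(syn)
            cur = nxt
        all_paths.append(steps)
        if not crossed:
            valid_paths.append(steps)
    paths = valid_paths or all_paths
    sd = sum(map(sum, paths)) / len(paths)
    return len(diffs) - sd, sd


class TestNg86Sites:
    def test_worked_values(self):
        assert ng86_sites("TTT") == pytest.approx((8 / 3, 1 / 3))
        assert ng86_sites("TGG") == (3.0, 0.0)  # Trp: no synonymous change

    def test_conservation_and_oracle_agreement_all_codons(self):
        for codon in NON_STOP_CODONS:
            n, s = ng86_sites(codon)
            assert n + s == pytest.approx(3.0, abs=1e-12)
            assert (n, s) == pytest.approx(_oracle_sites(codon), abs=1e-12)

    def test_stop_codon_rejected(self):
        with pytest.raises(ValueError):
            ng86_sites("TAA")


class TestNg86Differences:
    def test_hamming_conservation_over_all_pairs(self):
        # Nd + Sd must equal the nucleotide Hamming distance for every one
        # of the 3721 ordered non-stop codon pairs
        for ca, cb in itertools.product(NON_STOP_CODONS, repeat=2):
            nd, sd = ng86_differences(ca, cb)
            assert nd + sd == pytest.approx(
                sum(x != y for x, y in zip(ca, cb)), abs=1e-12)

    def test_oracle_agreement_on_multi_change_pairs(self):
        rng = np.random.default_rng(23)
        pairs = [(NON_STOP_CODONS[i], NON_STOP_CODONS[j])
                 for i, j in rng.integers(len(NON_STOP_CODONS), size=(300, 2))]
        for ca, cb in pairs:
            assert ng86_differences(ca, cb) == pytest.approx(
                _oracle_differences(ca, cb), abs=1e-12)

    def test_stop_crossing_pathway_excluded(self):
        # TGT <-> TAA is impossible (TAA is a stop); take TGT vs TTA:
        # pathway TGT->TTT->TTA avoids stops, TGT->TGA->TTA crosses TGA
        nd, sd = ng86_differences("TGT", "TTA")
        assert nd, sd == _oracle_differences("TGT", "TTA")
        # only the stop-free ordering contributes
        assert (nd, sd) == pytest.approx((2.0, 0.0))


class TestNg86Pair:
    def test_identical_sequences(self):
        r = ng86_pair("ATGAAA", "ATGAAA")
        assert r.ka == 0.0 and r.ks == 0.0

    def test_single_codon_worked_example(self):
        r = ng86_pair("TTT", "TTA")
        assert r.s_sites == pytest.approx(0.5)
        assert r.n_sites == pytest.approx(2.5)
        assert (r.nd, r.sd) == (1.0, 0.0)
        assert r.nd / r.n_sites == pytest.approx(0.4)
        assert r.ka == pytest.approx(0.5716, abs=2e-4)
        assert r.ks == 0.0 and r.ratio is None

    def test_symmetric_in_sequence_order(self):
        a, b = evolve_codon_pair(200, 0.5, 0.2, 31)
        r1, r2 = ng86_pair(a, b), ng86_pair(b, a)
        assert (r1.ka, r1.ks) == pytest.approx((r2.ka, r2.ks))
        assert (r1.n_sites, r1.s_sites) == pytest.approx(
            (r2.n_sites, r2.s_sites))

    def test_site_conservation_per_pair(self):
        a, b = evolve_codon_pair(150, 1.0, 0.3, 32)
        r = ng86_pair(a, b)
        assert r.n_sites + r.s_sites == pytest.approx(3 * r.n_codons)

    def test_gap_codons_excluded_pairwise(self):
        a = "TTT" + "---" + "AAA"
        b = "TTT" + "CCC" + "AAA"
        r = ng86_pair(a, b)
        assert r.n_codons == 2 and r.nd == 0.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            ng86_pair("ATGAAA", "ATG")


class TestZTest:
    def test_identical_sequences_not_significant(self):
        a = "ATGAAACCCGGGTTTCATCAGGAGTGCACG"
        r = kaks_z_test(a, a, seed=1)
        assert r.verdict == "not_significant" and r.z == 0.0

    def test_too_few_codons_undefined(self):
        r = kaks_z_test("TTTAAA", "TTCAAG", seed=1)
        assert r.verdict == "undefined"

    def test_purifying_power_at_low_omega(self):
        hits = 0
        for seed in range(30):
            a, b = evolve_codon_pair(500, 0.1, 0.2, 6000 + seed)
            if kaks_z_test(a, b, seed=seed).verdict == "purifying":
                hits += 1
        assert hits >= 27  # >= 90%

    def test_size_under_neutrality(self):
        hits = 0
        for seed in range(30):
            a, b = evolve_codon_pair(500, 1.0, 0.2, 7000 + seed)
            if kaks_z_test(a, b, seed=seed).verdict == "purifying":
                hits += 1
        assert hits <= 4  # roughly alpha-level false-positive rate


class TestDiscriminateLocus:
    def test_planted_full_element_is_transposon_like(self, clean_genome):
        contigs, truth = clean_genome
        g = contigs[0]
        c = truth.copies[0]
        # the homology hit covers only the ORF, as TBlastN would find it
        verdict = discriminate_locus(g, c.orf)
        assert verdict == "transposon_like"

    def test_domesticated_locus_has_no_hallmarks(self, templates):
        rng = np.random.default_rng(24)
        cds = back_translate(templates["Tigger"].tpase_protein)
        bg = lambda n: "".join(rng.choice(list("ACGT"), size=n))
        g = GenomicSequence(id="g", residues=bg(3000) + cds + bg(3000))
        locus = Interval("g", 3000, 3000 + len(cds))
        assert discriminate_locus(g, locus) == "putative_domesticated"

    def test_single_decayed_tir_detected_via_probe(self, templates):
        rng = np.random.default_rng(25)
        tpl = templates["Tigger"]
        cds = back_translate(tpl.tpase_protein)
        tir = list(tpl.tir_seed)
        tir[5] = {"A": "C"}.get(tir[5], "A")  # one decay substitution
        bg = lambda n: "".join(rng.choice(list("ACGT"), size=n))
        g = GenomicSequence(
            id="g", residues=bg(1500) + "".join(tir) + bg(40) + cds + bg(3000))
        locus = Interval("g", 1540 + len(tir), 1540 + len(tir) + len(cds))
        assert discriminate_locus(g, locus,
                                  tir_probes=[tpl.tir_seed]) == "transposon_like"

    def test_contig_edge_is_indeterminate(self, templates):
        cds = back_translate(templates["Lemi"].tpase_protein)
        g = GenomicSequence(id="g", residues=cds)
        locus = Interval("g", 0, len(cds))
        assert discriminate_locus(g, locus) == "indeterminate"


class TestCallDomestication:
    def test_planted_domesticated_clade_passes(self, templates):
        spec = SynthSpec(n_species=8, omega=0.1, divergence=0.2, rng_seed=6)
        clade = generate_domesticated_clade(spec, templates["Tigger"])
        call = call_domestication("TIGD2like", clade.cds, seed=1)
        assert call.verdict == "stationary_domesticated"
        assert call.mean_protein_identity >= 0.70
        assert call.mean_kaks is not None and call.mean_kaks < 1

    def test_pseudogene_like_clade_flagged(self, templates):
        spec = SynthSpec(n_species=5, omega=0.1, divergence=0.2, rng_seed=6)
        clade = generate_domesticated_clade(spec, templates["Tigger"],
                                            kind="pseudogene-like")
        call = call_domestication("TIGD1like", clade.cds, seed=1)
        assert call.verdict == "pseudogene_like"

    def test_four_species_clade_rejected(self, templates):
        spec = SynthSpec(n_species=4, omega=0.1, divergence=0.2, rng_seed=6)
        clade = generate_domesticated_clade(spec, templates["Passer"])
        call = call_domestication("narrow", clade.cds, seed=1)
        assert call.verdict == "rejected"
        assert "4 species" in call.reason

    def test_filter_monotone_under_species_removal(self, templates):
        spec = SynthSpec(n_species=6, omega=0.1, divergence=0.2, rng_seed=6)
        clade = generate_domesticated_clade(spec, templates["Passer"])
        full_call = call_domestication("c", clade.cds, seed=1)
        assert full_call.verdict == "stationary_domesticated"
        # dropping species can revoke but never create the verdict
        reduced = {s: clade.cds[s] for s in clade.species[:4]}
        assert call_domestication("c4", reduced, seed=1).verdict != \
            "stationary_domesticated"


class TestFusionDomains:
    def test_chimeric_c_terminal_extra_domain(self, templates):
        protein = templates["pogoR"].tpase_protein + \
            motif_consensus()["CENP-B_dimeris"]
        assert detect_fusion_domains(protein) == ["CENP-B_dimeris"]
        assert is_chimeric(protein)

    def test_plain_transposase_not_chimeric(self, templates):
        assert not is_chimeric(templates["Passer"].tpase_protein)

    def test_n_terminal_krab_reported_in_order(self, templates):
        cons = motif_consensus()
        protein = cons["KRAB"] + templates["Passer"].tpase_protein + cons["ZNF"]
        assert detect_fusion_domains(protein) == ["KRAB", "ZNF"]
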