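"""Distances, neighbor joining, bootstrap, family placement, ML export."""
import numpy as np
import pytest
from skbio import DistanceMatrix
from skbio.tree import nj as skbio_nj

from pogoscout.phylo import (FamilyAssignment, MultipleAlignment,
                             assign_family, bootstrap_support,
                             export_ml_alignment, extract_dde_domain,
                             insert_query, neighbor_joining, panel_alignment,
                             pairwise_distance, tree_bipartitions)

ADDITIVE_4 = DistanceMatrix(
    [[0.0, 0.2, 0.4, 0.5],
     [0.2, 0.0, 0.4, 0.5],
     [0.4, 0.4, 0.0, 0.3],
     [0.5, 0.5, 0.3, 0.0]], ["A", "B", "C", "D"])


class TestPairwiseDistance:
    def test_identical_rows_have_zero_distance(self):
        aln = MultipleAlignment(rows={"a": "MKLV" * 25, "b": "MKLV" * 25})
        assert pairwise_distance(aln)["a", "b"] == 0.0

    def test_poisson_correction_closed_form(self):
        a = "A" * 100
        b = "A" * 90 + "C" * 10
        d = pairwise_distance(MultipleAlignment(rows={"a": a, "b": b}))
        assert d["a", "b"] == pytest.approx(-np.log(0.9), abs=1e-9)

    def test_gapped_columns_pairwise_deleted(self):
        a = "AAAA" + "-" * 4
        b = "AAAC" + "CCCC"
        d = pairwise_distance(MultipleAlignment(rows={"a": a, "b": b}))
        # only the 4 shared columns count: p = 1/4, Poisson-corrected
        assert d["a", "b"] == pytest.approx(-np.log(0.75), abs=1e-12)

    def test_permutation_equivariant(self):
        rows = {"x": "MKLVWA" * 10, "y": "MKIVWA" * 10, "z": "MELVWA" * 10}
        d1 = pairwise_distance(MultipleAlignment(rows=dict(rows)))
        d2 = pairwise_distance(MultipleAlignment(
            rows={k: rows[k] for k in ["z", "x", "y"]}))
        for i in "xyz":
            for j in "xyz":
                assert d1[i, j] == d2[i, j]

    def test_zero_shared_columns_is_error(self):
        aln = MultipleAlignment(rows={"a": "AA--", "b": "--CC"})
        with pytest.raises(ValueError, match="a.*b|b.*a"):
            pairwise_distance(aln)


class TestNeighborJoining:
    def test_three_taxon_lengths_solve_three_point_formulas(self):
        dm = DistanceMatrix([[0, 0.3, 0.5], [0.3, 0, 0.6], [0.5, 0.6, 0]],
                            ["A", "B", "C"])
        tree = neighbor_joining(dm)
        lengths = {t.name: t.length for t in tree.tips()}
        assert lengths["A"] == pytest.approx((0.3 + 0.5 - 0.6) / 2)
        assert lengths["B"] == pytest.approx((0.3 + 0.6 - 0.5) / 2)
        assert lengths["C"] == pytest.approx((0.5 + 0.6 - 0.3) / 2)

    def test_additive_four_taxon_exact_topology_and_lengths(self):
        tree = neighbor_joining(ADDITIVE_4)
        bips = tree_bipartitions(tree)
        assert frozenset({"C", "D"}) in bips  # AB|CD split
        lengths = {t.name: t.length for t in tree.tips()}
        assert lengths == pytest.approx(
            {"A": 0.1, "B": 0.1, "C": 0.1, "D": 0.2})
        td = tree.tip_tip_distances(["A", "B", "C", "D"])
        assert np.allclose(td.data, ADDITIVE_4.data, atol=1e-9)

    def test_matches_independent_nj_implementation(self):
        rng = np.random.default_rng(15)
        # random additive matrix from a random tree: compare with skbio's NJ
        n = 6
        ids = [f"t{i}" for i in range(n)]
        base = rng.uniform(0.05, 0.4, size=(n, n))
        dm_data = np.zeros((n, n))
        # build additive distances from a caterpillar tree
        pos = np.cumsum(rng.uniform(0.05, 0.2, size=n))
        leaf = rng.uniform(0.02, 0.3, size=n)
        for i in range(n):
            for j in range(i + 1, n):
                dm_data[i, j] = dm_data[j, i] = \
                    leaf[i] + leaf[j] + abs(pos[i] - pos[j])
        dm = DistanceMatrix(dm_data, ids)
        ours = neighbor_joining(dm)
        ref = skbio_nj(dm)
        ours_d = ours.tip_tip_distances(ids)
        ref_d = ref.tip_tip_distances(ids)
        assert np.allclose(ours_d.data, ref_d.data, atol=1e-9)

    def test_additivity_reproduced_to_1e9(self):
        tree = neighbor_joining(ADDITIVE_4)
        td = tree.tip_tip_distances(["A", "B", "C", "D"])
        assert np.max(np.abs(td.data - ADDITIVE_4.data)) <= 1e-9

    def test_asymmetric_matrix_rejected(self):
        data = ADDITIVE_4.data.copy()
        dm = DistanceMatrix(data, ["A", "B", "C", "D"])
        dm.data[0, 1] = 0.25  # break symmetry in place
        with pytest.raises(ValueError, match="symmetric"):
            neighbor_joining(dm)


def _block_alignment(rng, n_cols=120, within=0.03, between=0.5):
    """Two 3-taxon blocks diverged from a shared ancestor."""
    aa = list("ACDEFGHIKLMNPQRSTVWY")
    anc = rng.choice(aa, size=n_cols)
    base1, base2 = anc.copy(), anc.copy()
    flip = rng.random(n_cols) < between / 2
    base1[flip] = rng.choice(aa, size=int(flip.sum()))
    flip = rng.random(n_cols) < between / 2
    base2[flip] = rng.choice(aa, size=int(flip.sum()))
    rows = {}
    for g, base in (("a", base1), ("b", base2)):
        for k in range(3):
            row = base.copy()
            flip = rng.random(n_cols) < within
            row[flip] = rng.choice(aa, size=int(flip.sum()))
            rows[f"{g}{k}"] = "".join(row)
    return MultipleAlignment(rows=rows)


class TestBootstrap:
    def test_strong_central_split_gets_high_support(self):
        rng = np.random.default_rng(16)
        aln = _block_alignment(rng)
        tree = bootstrap_support(aln, n_reps=100, seed=5)
        split = frozenset({"b0", "b1", "b2"})
        supports = {frozenset(
            {t.name for t in node.tips()}): getattr(node, "support", None)
            for node in tree.non_tips()}
        central = [s for bip, s in supports.items()
                   if bip == split or bip == frozenset({"a0", "a1", "a2"})]
        assert central and central[0] >= 95

    def test_zero_replicates_leave_supports_absent(self):
        rng = np.random.default_rng(17)
        aln = _block_alignment(rng)
        tree = bootstrap_support(aln, n_reps=0, seed=5)
        assert all(n.support is None for n in tree.non_tips())

    def test_same_seed_reproduces_supports(self):
        rng = np.random.default_rng(18)
        aln = _block_alignment(rng, within=0.15)
        t1 = bootstrap_support(aln, n_reps=50, seed=9)
        t2 = bootstrap_support(aln, n_reps=50, seed=9)
        s1 = sorted(n.support for n in t1.non_tips() if n.support is not None)
        s2 = sorted(n.support for n in t2.non_tips() if n.support is not None)
        assert s1 and s1 == s2


class TestDomainExtraction:
    def test_panel_member_yields_its_own_domain(self, panel):
        m = panel.members[0]
        dom = extract_dde_domain(m.domain, panel)
        assert dom is not None and dom[0] == m.domain

    def test_n_terminal_extension_shifts_coordinates(self, panel):
        rng = np.random.default_rng(19)
        ext = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=20))
        m = panel.members[0]
        dom = extract_dde_domain(ext + m.domain, panel)
        assert dom is not None
        assert dom[1] == (20, 20 + len(m.domain))

    def test_unrelated_protein_yields_nothing(self, panel):
        rng = np.random.default_rng(20)
        protein = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=300))
        assert extract_dde_domain(protein, panel) is None


class TestAssignFamily:
    def test_mutated_reference_recovers_its_family(self, panel):
        rng = np.random.default_rng(21)
        m = panel.get("Tigger_ref1")
        aa = list("ACDEFGHIKLMNPQRSTVWY")
        mutated = "".join(
            (rng.choice([x for x in aa if x != a]) if rng.random() < 0.10
             else a) for a in m.domain)
        res = assign_family({"q": mutated}, panel, n_reps=50, seed=3)
        assert res[0].family == "Tigger" and res[0].support >= 70

    def test_leave_one_out_recovery_is_total(self, panel):
        for m in panel.members:
            res = assign_family({m.id: m.domain}, panel.drop(m.id),
                                n_reps=25, seed=2)
            assert res[0].family == m.family, m.id

    def test_random_sequence_unclassified(self, panel):
        rng = np.random.default_rng(22)
        protein = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=130))
        res = assign_family({"rnd": protein}, panel, n_reps=25, seed=4)
        assert res[0].family == "Unclassified"

    def test_support_bounds_enforced(self):
        with pytest.raises(ValueError):
            FamilyAssignment("q", "Tigger", 140.0)


class TestMlExport:
    def test_phylip_header_and_round_trip(self, tmp_path):
        rows = {"taxon_with_a_long_name": "MKLVWAAGHI",
                "t2": "MKIVWAAGHI", "t3": "MELVWAAGHI", "t4": "MKLVWCAGHI"}
        aln = MultipleAlignment(rows=rows)
        phy = tmp_path / "a.phy"
        fas = tmp_path / "a.fasta"
        export_ml_alignment(aln, phy, fas)
        lines = phy.read_text().splitlines()
        assert lines[0] == "4 10"
        # relaxed dialect: long ids preserved verbatim
        assert lines[1].split()[0] == "taxon_with_a_long_name"
        from pogoscout.io import read_fasta
        back = dict(read_fasta(fas, dna=False))
        assert back == rows
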