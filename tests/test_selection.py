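"""Alignment, NJ, NG86 and contact-residue selection machinery."""

import itertools
import math
import random

import dendropy
import numpy as np
import pytest
from Bio.Align import substitution_matrices
from Bio.Data.CodonTable import standard_dna_table
from Bio.Seq import Seq

from zfte.selection import (
    DistanceMatrix,
    codon_align_from_protein,
    contact_enrichment,
    contact_site_indices,
    entropy_profile,
    needleman_wunsch,
    neighbor_joining,
    ng86_pairwise,
    pairwise_distance_matrix,
    protein_distance,
    select_clades,
    site_omega_profile,
)
from zfte.sim import simulate_codon_alignment, simulate_trait_tree
from zfte.sim.genome import _random_quads, make_finger, znf_protein

_B62 = substitution_matrices.load("BLOSUM62")
_AA = standard_dna_table.forward_table
_STOPS = set(standard_dna_table.stop_codons)


def _brute_nw_score(a, b, go=10.0, ge=0.5):
    """Exhaustive alignment enumeration oracle for short sequences."""
    best = [-math.inf]

    def rec(i, j, score, state):
        if i == len(a) and j == len(b):
            best[0] = max(best[0], score)
            return
        if i < len(a) and j < len(b):
            rec(i + 1, j + 1, score + _B62[a[i], b[j]], "M")
        if i < len(a):
            rec(i + 1, j, score - (ge if state == "X" else go + ge), "X")
        if j < len(b):
            rec(i, j + 1, score - (ge if state == "Y" else go + ge), "Y")

    rec(0, 0, 0.0, "M")
    return best[0]


class TestNeedlemanWunsch:
    def test_self_alignment_diagonal(self):
        (aa, bb), score = needleman_wunsch("MKVLW", "MKVLW")
        assert aa == bb == "MKVLW"
        assert score == sum(_B62[c, c] for c in "MKVLW")

    def test_matches_enumeration_oracle(self):
        random.seed(0)
        alpha = "ARNDCQEGHILKMFPSTWYV"
        for _ in range(25):
            a = "".join(random.choice(alpha) for _ in range(random.randint(1, 7)))
            b = "".join(random.choice(alpha) for _ in range(random.randint(1, 7)))
            _, got = needleman_wunsch(a, b)
            assert got == pytest.approx(_brute_nw_score(a, b), abs=1e-9)

    def test_score_symmetry(self):
        _, s1 = needleman_wunsch("MKTAYIAKQR", "MKTTAYQR")
        _, s2 = needleman_wunsch("MKTTAYQR", "MKTAYIAKQR")
        assert s1 == s2

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            needleman_wunsch("", "MK")


class TestProteinDistance:
    def test_identical_and_disjoint(self):
        assert protein_distance(("MKV", "MKV")) == 0.0
        assert protein_distance(("MKV", "APG")) == 1.0

    def test_partial_identity(self):
        assert protein_distance(("ABCDEFGHIJ", "ABCDEFGHXY")) == pytest.approx(0.2)

    def test_gap_gap_columns_excluded(self):
        with pytest.raises(ValueError):
            protein_distance(("--", "--"))


class TestNeighborJoining:
    def test_three_taxon_closed_form(self):
        d = np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], dtype=float)
        tree = neighbor_joining(DistanceMatrix(["A", "B", "C"], d))
        bl = {l.taxon.label: l.edge.length for l in tree.leaf_node_iter()}
        assert bl["A"] == pytest.approx((3 + 4 - 5) / 2)
        assert bl["B"] == pytest.approx((3 + 5 - 4) / 2)
        assert bl["C"] == pytest.approx((4 + 5 - 3) / 2)

    @pytest.mark.parametrize("seed", range(10))
    def test_additive_matrix_recovered_exactly(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 9))
        tree, _ = simulate_trait_tree(n, 0.0, seed=seed)
        for e in tree.preorder_edge_iter():
            if e.length is not None:
                e.length = float(rng.uniform(0.05, 1.0))
        pdm = tree.phylogenetic_distance_matrix()
        labels = sorted(t.label for t in tree.taxon_namespace)
        tx = {t.label: t for t in tree.taxon_namespace}
        d = np.zeros((n, n))
        for i, a in enumerate(labels):
            for j, b in enumerate(labels):
                if i != j:
                    d[i, j] = pdm.distance(tx[a], tx[b])
        nj = neighbor_joining(DistanceMatrix(labels, d))
        pdm2 = nj.phylogenetic_distance_matrix()
        tx2 = {t.label: t for t in nj.taxon_namespace}
        for i, a in enumerate(labels):
            for j in range(i + 1, n):
                b = labels[j]
                assert pdm2.distance(tx2[a], tx2[b]) == pytest.approx(
                    d[i, j], abs=1e-9
                )

    def test_label_order_invariance(self):
        rng = np.random.default_rng(3)
        tree, _ = simulate_trait_tree(6, 0.0, seed=3)
        pdm = tree.phylogenetic_distance_matrix()
        labels = sorted(t.label for t in tree.taxon_namespace)
        tx = {t.label: t for t in tree.taxon_namespace}
        d = np.array(
            [[0 if a == b else pdm.distance(tx[a], tx[b]) for b in labels] for a in labels]
        )
        t1 = neighbor_joining(DistanceMatrix(labels, d))
        perm = list(rng.permutation(len(labels)))
        t2 = neighbor_joining(
            DistanceMatrix([labels[i] for i in perm], d[np.ix_(perm, perm)])
        )
        b1 = {frozenset(x.leafset_bitmask for x in []) }  # placeholder
        s1 = {frozenset(l.taxon.label for l in e.head_node.leaf_iter())
              for e in t1.preorder_edge_iter()}
        s2 = {frozenset(l.taxon.label for l in e.head_node.leaf_iter())
              for e in t2.preorder_edge_iter()}
        assert s1 == s2


class TestSelectClades:
    def _tree(self):
        nwk = "(((a1:1,a2:1):1,(a3:1,a4:1):1):1,(b1:1,(a5:1,a6:1):1):1);"
        return dendropy.Tree.get(data=nwk, schema="newick")

    def test_size_and_spread_rules(self):
        tree = self._tree()
        species = {t: "zf" if t.startswith("a") else "other"
                   for t in ["a1", "a2", "a3", "a4", "a5", "a6", "b1"]}
        lengths = {t: 400 for t in species}
        clades = select_clades(tree, species, lengths, "zf", min_size=4)
        assert clades == [["a1", "a2", "a3", "a4"]]
        # spread rule: 45 > 30 rejects
        lengths["a1"] = 445
        assert select_clades(tree, species, lengths, "zf", min_size=4) == []
        # smaller min_size picks up the (a5,a6) pair as well
        lengths["a1"] = 400
        clades = select_clades(tree, species, lengths, "zf", min_size=2)
        assert [len(c) for c in clades] == [4, 2]

    def test_tip_order_invariance(self):
        tree = self._tree()
        species = {t: "zf" for t in ["a1", "a2", "a3", "a4", "a5", "a6", "b1"]}
        lengths = {t: 100 for t in species}
        c1 = select_clades(tree, species, lengths, "zf", min_size=2)
        nwk2 = "((b1:1,(a6:1,a5:1):1):1,((a4:1,a3:1):1,(a2:1,a1:1):1):1);"
        t2 = dendropy.Tree.get(data=nwk2, schema="newick")
        c2 = select_clades(t2, species, lengths, "zf", min_size=2)
        assert sorted(map(tuple, c1)) == sorted(map(tuple, c2))


class TestCodonBackthreading:
    def test_gap_columns_removed(self):
        prot_aln = {"s1": "MK-V", "s2": "MKAV"}
        cds = {"s1": "ATGAAAGTT", "s2": "ATGAAAGCTGTC"}
        out = codon_align_from_protein(cds, prot_aln)
        assert out["s1"] == "ATGAAAGTT"
        assert out["s2"] == "ATGAAAGTC"

    def test_translation_mismatch_named(self):
        with pytest.raises(ValueError, match="s1.*residue 1"):
            codon_align_from_protein({"s1": "ATGGCT"}, {"s1": "MK"})

    def test_frame_broken_cds_rejected(self):
        with pytest.raises(ValueError, match="3x"):
            codon_align_from_protein({"s1": "ATGGC"}, {"s1": "MA"})


def _brute_ng86_pair(c1, c2):
    """Independent oracle: enumerate all stop-free substitution pathways."""
    diff = [k for k in range(3) if c1[k] != c2[k]]
    results = []
    for order in itertools.permutations(diff):
        cur, sd, nd, ok = c1, 0, 0, True
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if nxt in _STOPS:
                ok = False
                break
            if _AA[cur] == _AA[nxt]:
                sd += 1
            else:
                nd += 1
            cur = nxt
        if ok:
            results.append((sd, nd))
    if not results:
        return None
    return (
        sum(r[0] for r in results) / len(results),
        sum(r[1] for r in results) / len(results),
    )


class TestNG86:
    def test_hand_cases(self):
        r = ng86_pairwise("AAA", "AAG")
        assert (r.Sd, r.Nd) == (1.0, 0.0)
        r = ng86_pairwise("TTT", "TTA")
        assert (r.Sd, r.Nd) == (0.0, 1.0)
        r = ng86_pairwise("ATGGCT", "ATGGCT")
        assert r.dN == r.dS == 0.0 and math.isnan(r.omega)

    def test_all_codon_pairs_match_pathway_oracle(self):
        sense = sorted(_AA)
        from zfte.selection import _pair_counts

        for c1 in sense:
            for c2 in sense:
                want = _brute_ng86_pair(c1, c2)
                got = _pair_counts(c1, c2)
                if want is None:
                    continue  # implementation falls back; oracle undefined
                assert got[0] == pytest.approx(want[0], abs=1e-12), (c1, c2)
                assert got[1] == pytest.approx(want[1], abs=1e-12), (c1, c2)

    def test_total_changes_conserved(self):
        sense = sorted(_AA)
        from zfte.selection import _pair_counts

        rng = np.random.default_rng(0)
        for _ in range(300):
            c1, c2 = rng.choice(sense, size=2)
            n_diff = sum(a != b for a, b in zip(c1, c2))
            sd, nd = _pair_counts(str(c1), str(c2))
            assert sd + nd == pytest.approx(n_diff, abs=1e-12)

    def test_saturation_flagged(self):
        # maximally dissimilar long stretches push p beyond the JC domain
        a = "GGT" * 40
        b = "CCA" * 40
        r = ng86_pairwise(a, b)
        assert r.saturated

    def test_stop_codon_rejected(self):
        with pytest.raises(ValueError):
            ng86_pairwise("TAA", "AAA")


class TestSiteProfile:
    def test_two_sequence_consistency_with_pairwise(self):
        a, b, c = "ATGGCTAAA", "ATGGCGAAA", "ATGGCTAAG"
        prof = site_omega_profile({"a": a, "b": b, "c": c})
        pair_sums_sd = sum(p.Sd for p in prof)
        want = (
            ng86_pairwise(a, b).Sd + ng86_pairwise(a, c).Sd + ng86_pairwise(b, c).Sd
        )
        assert pair_sums_sd == pytest.approx(want)

    def test_identical_column_flagged_nan(self):
        prof = site_omega_profile({"a": "ATG", "b": "ATG", "c": "ATG"})
        assert math.isnan(prof[0].omega)

    def test_positive_selection_recovered(self):
        tree, _ = simulate_trait_tree(10, 0.0, seed=42)
        for e in tree.preorder_edge_iter():
            if e.length:
                e.length *= 0.3
        omegas = [5.0] * 20 + [0.2] * 60
        aln, _ = simulate_codon_alignment(tree, omegas, seed=42)
        prof = site_omega_profile(aln)
        hi = np.nanmean([p.omega for p in prof[:20] if np.isfinite(p.omega)])
        lo = np.nanmean([p.omega for p in prof[20:] if np.isfinite(p.omega)])
        assert hi > lo


class TestContactEnrichment:
    def test_planted_contact_selection_detected(self):
        rng = np.random.default_rng(0)
        prot = znf_protein(rng, _random_quads(rng, 10))
        contact = contact_site_indices(prot)
        omegas = [5.0 if i in contact else 0.2 for i in range(len(prot))]
        tree, _ = simulate_trait_tree(12, 0.0, seed=0)
        for e in tree.preorder_edge_iter():
            if e.length:
                e.length *= 0.3
        aln, _ = simulate_codon_alignment(tree, omegas, seed=0)
        orr, p = contact_enrichment(site_omega_profile(aln, contact_sites=contact))
        assert orr > 1 and p < 0.05

    def test_all_low_omega_path(self):
        tree, _ = simulate_trait_tree(8, 0.0, seed=1)
        for e in tree.preorder_edge_iter():
            if e.length:
                e.length *= 0.2
        aln, _ = simulate_codon_alignment(tree, [0.05] * 60, seed=1)
        prof = site_omega_profile(aln, contact_sites={0, 1, 2, 3})
        orr, p = contact_enrichment(prof)
        assert p > 0.05 or math.isnan(orr)


class TestEntropyProfile:
    def test_identical_domains_zero_everywhere(self):
        rng = np.random.default_rng(2)
        dom = make_finger(rng, ("R", "D", "H", "R"))
        prof = entropy_profile([dom] * 30)
        assert all(p.entropy == 0.0 for p in prof if p.coverage > 0)

    def test_variable_position_entropy(self):
        rng = np.random.default_rng(3)
        residues = "ARND"
        doms = []
        for i in range(40):
            # vary only helix position +3 (x12 index 8)
            doms.append(make_finger(rng, ("R", "D", residues[i % 4], "R")))
        # rebuild with fixed filler so only +3 varies
        base = make_finger(np.random.default_rng(0), ("R", "D", "A", "R"))
        doms = []
        for i in range(40):
            d = list(base)
            d[4 + 8] = residues[i % 4]  # x12 index 8 = helix +3
            doms.append("".join(d))
        prof = {p.position: p for p in entropy_profile(doms)}
        assert prof["x.8"].entropy == pytest.approx(2.0)
        assert prof["x.0"].entropy == 0.0
        assert prof["C1"].entropy == 0.0

    def test_ambiguous_domain_skipped(self):
        prof = entropy_profile(["NOTADOMAIN"])
        assert all(p.coverage == 0 for p in prof)


class TestPairwiseDistanceToTree:
    def test_family_pipeline_runs(self):
        rng = np.random.default_rng(7)
        base = znf_protein(rng, _random_quads(rng, 3))
        prots = {}
        for i in range(4):
            mut = list(base)
            for _ in range(i * 3):
                k = int(rng.integers(0, len(mut)))
                mut[k] = "A"
            prots[f"g{i}"] = "".join(mut)
        dm = pairwise_distance_matrix(prots)
        assert dm.matrix.max() <= 1.0
        tree = neighbor_joining(dm)
        assert len(tree.leaf_nodes()) == 4
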