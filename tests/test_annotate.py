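"""Closest-fully-tryptic conversion, LCA taxonomy, and group assignment."""

import numpy as np
import pytest

import semipep as sp
from semipep.annotate import (CANONICAL_RANKS, ec_subclass, equate_il,
                              split_tryptic_units)
from semipep.errors import AnnotationError
from semipep.simulate import build_toy_taxonomy, tryptic_peptides
from semipep.tryptic import TrypticStatus

from conftest import make_record


class TestClosestFullyTryptic:
    def test_semi_n_extends_to_residue_after_k(self):
        rec = make_record("SDLER", nwin="QQQQQQQQQWETKGA")
        seq, ok = sp.closest_fully_tryptic(rec, TrypticStatus.SEMI_N)
        assert (seq, ok) == ("GASDLER", True)

    def test_semi_c_extends_through_k(self):
        rec = make_record("MNPQA", cwin="STKQQQQQQQQQQQQ")
        seq, ok = sp.closest_fully_tryptic(rec, TrypticStatus.SEMI_C)
        assert (seq, ok) == ("MNPQASTK", True)

    def test_no_boundary_in_window_unresolved(self):
        rec = make_record("SDLEG", cwin="A" * 15)
        seq, ok = sp.closest_fully_tryptic(rec, TrypticStatus.SEMI_C)
        assert (seq, ok) == ("SDLEG", False)

    def test_pad_is_a_valid_boundary(self):
        rec = make_record("SDLEG", cwin="AC___".ljust(15, "_"))
        seq, ok = sp.closest_fully_tryptic(rec, TrypticStatus.SEMI_C)
        assert (seq, ok) == ("SDLEGAC", True)

    def test_non_extends_both_sides(self):
        rec = make_record("SDLEG", nwin="QQQQQQQQQWETKGA",
                          cwin="STKQQQQQQQQQQQQ")
        seq, ok = sp.closest_fully_tryptic(rec, TrypticStatus.NON)
        assert (seq, ok) == ("GASDLEGSTK", True)

    def test_full_unchanged(self):
        rec = make_record("ACDEFGHIK")
        assert sp.closest_fully_tryptic(rec, TrypticStatus.FULL) == \
            ("ACDEFGHIK", True)

    def test_matches_enclosing_digest_oracle(self, null_bundle, null_result):
        """Resolved conversions equal the smallest enclosing tryptic
        peptide computed from the parent protein by brute force."""
        statuses = null_result.statuses
        by_seq = {r.sequence: r for r in null_result.consensus.records}
        truth = null_bundle.truth.set_index("sequence")
        n_checked = 0
        for seq, st in statuses.items():
            if st not in (TrypticStatus.SEMI_N, TrypticStatus.SEMI_C):
                continue
            rec = by_seq[seq]
            protein = null_bundle.db.entries[rec.protein_accessions[0]].sequence
            a, b = rec.start_pos - 1, rec.end_pos
            bounds = [0] + [i + 1 for i in range(len(protein) - 1)
                            if protein[i] in "KR"] + [len(protein)]
            ea = max(x for x in bounds if x <= a)
            eb = min(x for x in bounds if x >= b)
            expected = protein[ea:b] if st is TrypticStatus.SEMI_N \
                else protein[a:eb]
            got, ok = sp.closest_fully_tryptic(rec, st)
            # for SEMI_N the K/R at cut position ea sits at protein index
            # ea-1, i.e. it is visible in the 15-residue window only when
            # a - ea <= 14; for SEMI_C the K/R at index eb-1 is visible
            # when eb - b <= 15 (pads at protein termini always resolve)
            within = (a - ea <= 14) if st is TrypticStatus.SEMI_N \
                else (eb - b <= 15)
            if within:
                assert ok and got == expected
                n_checked += 1
            else:
                assert not ok and got == seq
        assert n_checked > 100

    def test_resolved_conversion_classifies_full(self, null_bundle,
                                                 null_result):
        """Regenerating context for a resolved conversion yields FULL."""
        by_seq = {r.sequence: r for r in null_result.consensus.records}
        n = 0
        for seq, st in null_result.statuses.items():
            if st is not TrypticStatus.SEMI_N or n >= 100:
                continue
            rec = by_seq[seq]
            conv, ok = sp.closest_fully_tryptic(rec, st)
            if not ok:
                continue
            protein = null_bundle.db.entries[rec.protein_accessions[0]].sequence
            pos = protein.find(conv)
            assert pos >= 0
            new = make_record(conv,
                              pre=protein[pos - 1] if pos else "-",
                              post=(protein[pos + len(conv)]
                                    if pos + len(conv) < len(protein) else "-"),
                              start=pos + 1, end=pos + len(conv))
            assert sp.classify_peptide(new) is TrypticStatus.FULL
            n += 1
        assert n >= 50


def _random_tree(rng, n_nodes):
    """Random rooted tree with rank-free internal nodes."""
    nodes = {1: (1, "no rank", "root")}
    ranks = list(CANONICAL_RANKS) + ["no rank"]
    for t in range(2, n_nodes + 1):
        parent = int(rng.integers(1, t))
        nodes[t] = (parent, str(rng.choice(ranks)), f"n{t}")
    return sp.TaxonomyTree(nodes, 1)


def _brute_lca(tree, taxids):
    paths = [tree.path(t) for t in taxids]
    common = set(paths[0])
    for p in paths[1:]:
        common &= set(p)
    # deepest common ancestor = the common node with the longest path
    return max(common, key=lambda t: len(tree.path(t)))


class TestLCA:
    def setup_method(self):
        self.tree, self.species = build_toy_taxonomy()

    def test_two_species_one_genus(self):
        lca = self.tree.lca(self.species[:2])  # both Faecalibacterium
        assert self.tree.name(lca) == "Faecalibacterium"
        assert self.tree.rank(lca) == "genus"

    def test_single_species(self):
        assert self.tree.lca([self.species[0]]) == self.species[0]

    def test_across_phyla_is_superkingdom(self):
        lca = self.tree.lca([self.species[0], self.species[-1]])
        assert self.tree.name(lca) == "Bacteria"

    def test_il_equated_lookup(self):
        pep2taxa = {equate_il("ILKDFK"): {self.species[0]}}
        t1, _ = sp.lca_assign("ILKDFK", pep2taxa, self.tree, equate=True)
        t2, _ = sp.lca_assign("LLKDFK", pep2taxa, self.tree, equate=True)
        assert t1 == t2 == self.species[0]

    def test_unmapped_peptide_unassigned(self):
        assert sp.lca_assign("AAAAAK", {}, self.tree) == (None, {})

    def test_missing_taxid_rejected(self):
        with pytest.raises(AnnotationError):
            self.tree.path(99999)

    def test_matches_brute_force_on_random_trees(self, rng):
        for _ in range(10):
            tree = _random_tree(rng, int(rng.integers(20, 120)))
            ids = list(tree.nodes)
            for _ in range(30):
                taxids = list(rng.choice(ids, size=int(rng.integers(1, 6))))
                assert tree.lca(taxids) == _brute_lca(tree, taxids)


class TestGroups:
    def test_lineage_closure(self):
        tree, species = build_toy_taxonomy()
        rec = make_record("ACDEFGHIK")
        ann = sp.AnnotatedPeptide(
            "ACDEFGHIK", TrypticStatus.FULL, "ACDEFGHIK", True,
            lca_taxid=species[4], lineage=tree.lineage(species[4]))
        membership = sp.assign_groups([ann])
        got = membership["ACDEFGHIK"]
        assert got == {"taxon:Bacteroides fragilis", "taxon:Bacteroides",
                       "taxon:Bacteroidaceae", "taxon:Bacteroidales",
                       "taxon:Bacteroidia", "taxon:Bacteroidetes",
                       "taxon:Bacteria"}

    def test_multiple_functional_groups(self):
        ann = sp.AnnotatedPeptide(
            "ACDEFGHIK", TrypticStatus.FULL, "ACDEFGHIK", True,
            go_terms={"protein transport", "cell motility"},
            ec_subclasses={"1.15"})
        membership = sp.assign_groups([ann])
        assert membership["ACDEFGHIK"] == {
            "go:protein transport", "go:cell motility", "ec:1.15"}

    def test_unannotated_peptide_has_no_groups(self):
        ann = sp.AnnotatedPeptide("ACDEFGHIK", TrypticStatus.FULL,
                                  "ACDEFGHIK", True)
        membership = sp.assign_groups([ann])
        assert membership["ACDEFGHIK"] == set()

    def test_lineage_closure_counts_monotone(self, null_result):
        """Counts at rank r are >= counts at any descendant rank."""
        memb = null_result.membership
        def count(group):
            return sum(1 for gs in memb.values() if group in gs)
        assert count("taxon:Bacteria") >= count("taxon:Firmicutes") \
            >= count("taxon:Clostridia") >= count("taxon:Clostridiales") \
            >= count("taxon:Ruminococcaceae") >= count("taxon:Faecalibacterium")


class TestHelpers:
    @pytest.mark.parametrize("ec,sub", [
        ("1.15.1.1", "1.15"), ("3.4", "3.4"), ("2", "2")])
    def test_ec_truncation(self, ec, sub):
        assert ec_subclass(ec) == sub

    def test_malformed_ec_rejected(self):
        with pytest.raises(AnnotationError):
            ec_subclass("x.1")

    def test_split_tryptic_units(self):
        assert split_tryptic_units("ACDEFKGHILMR", min_len=5) == \
            ["ACDEFK", "GHILMR"]
        # short units are dropped; if none survive the peptide is kept
        assert split_tryptic_units("AKCKDKEKF", min_len=5) == ["AKCKDKEKF"]
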