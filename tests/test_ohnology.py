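"""Stage-2 classification, duplication trees, nomenclature and lineage counts."""

import pytest

from karyotrace import data
from karyotrace.ohnology import (
    InconsistentOhnologyError,
    PairClassification,
    assign_nomenclature,
    build_duplication_tree,
    check_transitivity,
    classify_family_pairs,
    classify_pair,
    count_independent_lineages,
)


def by_name(assignments, species, name):
    return next(a for a in assignments
                if a.locus.species == species and a.locus.name == name)


class TestClassifyPair:
    def test_rln3_insl3_are_2r_ohnologs_not_tandem(self, assignments, model):
        a = by_name(assignments, "Homo_sapiens", "RLN3")
        b = by_name(assignments, "Homo_sapiens", "INSL3")
        assert classify_pair(a, b, model).verdict == "ohnolog_2R"

    def test_adjacent_same_segment_copies_are_local_duplicates(self, assignments, model):
        a = by_name(assignments, "Oryzias_latipes", "rxfp3-3a1")
        b = by_name(assignments, "Oryzias_latipes", "rxfp3-3a2")
        assert classify_pair(a, b, model).verdict == "local_SSD"

    def test_3r_subsegments_give_teleost_ohnologs(self, assignments, model):
        a = by_name(assignments, "Oryzias_latipes", "rln3a")
        b = by_name(assignments, "Oryzias_latipes", "rln3b")
        assert classify_pair(a, b, model).verdict == "ohnolog_3R"

    def test_foreign_vac_pair_is_flagged_not_resolved(self, assignments, model):
        a = by_name(assignments, "Gallus_gallus", "RXFP2")       # B0|F4
        b = by_name(assignments, "Gallus_gallus", "RXFP2ps")     # C2
        assert classify_pair(a, b, model).verdict == "translocated_or_ambiguous"

    def test_symmetric_in_pair_order(self, assignments, model):
        a = by_name(assignments, "Homo_sapiens", "RLN3")
        b = by_name(assignments, "Homo_sapiens", "INSL5")
        assert classify_pair(a, b, model) == classify_pair(b, a, model)

    def test_unassigned_member_defers(self, assignments, model):
        pmaps = data.load_segment_maps("P")
        from karyotrace.tracing import assign_gene
        rxfp4 = next(g for g in data.load_gene_table()
                     if g.species == "Homo_sapiens" and g.name == "RXFP4")
        unassigned = assign_gene(rxfp4, pmaps["Homo_sapiens"], model)
        assert unassigned.is_unassigned
        other = by_name(assignments, "Homo_sapiens", "RXFP3")
        cls = classify_pair(unassigned, other, model)
        assert cls.verdict == "deferred" and "unassigned" in cls.rationale["reason"]

    def test_verdict_transitivity_holds_on_fixture(self, family_assignments, model):
        for family in data.FAMILIES:
            check_transitivity(classify_family_pairs(family_assignments(family), model))

    def test_inconsistent_triple_is_rejected(self):
        # two tandem copies disagreeing in their ohnology to a third gene
        cls = [
            PairClassification(("a", "b"), "local_SSD"),
            PairClassification(("a", "c"), "ohnolog_2R"),
            PairClassification(("b", "c"), "translocated_or_ambiguous"),
        ]
        with pytest.raises(InconsistentOhnologyError, match="non-transitive"):
            check_transitivity(cls)

    def test_ohnology_claim_inside_one_lineage_is_rejected(self):
        cls = [
            PairClassification(("a", "b"), "local_SSD"),
            PairClassification(("b", "c"), "local_SSD"),
            PairClassification(("a", "c"), "ohnolog_2R"),
        ]
        with pytest.raises(InconsistentOhnologyError, match="one lineage"):
            check_transitivity(cls)


class TestDuplicationTree:
    def test_rxfp34_tree_shape_and_tetrapod_loss(self, trees):
        tree = trees["RXFP3/4"]
        assert tree.root.name == "AncRxfp3/4"
        post1r = [n.name for n in tree.root.children if n.kind == "post1R"]
        assert post1r == ["AncRxfp3-I", "AncRxfp3-II"]
        assert [n.name for n in tree.lineages()] == [
            "RXFP3-1", "RXFP3-2", "RXFP3-3", "RXFP3-4"]
        assert ("RXFP3-2", "tetrapod") in tree.losses()

    def test_ligand_tree_retains_all_four_lineages_in_tetrapods(self, trees):
        tree = trees["RLN/INSL"]
        assert len(tree.lineages()) == 4
        assert not any(clade == "tetrapod" for _n, clade in tree.losses())

    def test_rxfp2like_kept_unresolved_with_both_candidate_edges(self, trees):
        tree = trees["RXFP1/2"]
        unresolved = [n for n in tree.lineages() if n.unresolved]
        assert len(unresolved) == 1
        (node,) = unresolved
        assert node.name == "RXFP2-like" and len(node.candidate_edges) == 2
        assert any("transloc" in e for e in node.candidate_edges)

    def test_single_gene_family_gives_single_lineage_tree(self, model):
        from karyotrace.model import Assignment, GeneLocus
        locus = GeneLocus("sp", "solo", "FAM", "chr1", 0, 100)
        a = Assignment(locus, "A0", "A", 1.0)
        tree = build_duplication_tree("FAM", [a], model)
        assert len(tree.lineages()) == 1
        assert tree.lineages()[0].genes == [("sp", "solo", "gene")]

    def test_empty_family_gives_bare_root(self, model):
        tree = build_duplication_tree("RLN/INSL", [], model)
        assert tree.root.name == "AncRln-like" and tree.lineages() == []

    def test_parsimony_scores_favor_wgd_retention(self, trees):
        scores = trees["RLN/INSL"].scenario_scores
        assert scores["wgd_retention_losses"] < scores["ssd_alternative_losses"]


class TestNomenclature:
    def test_rxfp4_origin_name_is_rxfp3_4(self, trees):
        names = assign_nomenclature(trees["RXFP3/4"])
        assert names["Homo_sapiens/RXFP4"] == "RXFP3-4"

    def test_ligand_root_is_ancrln_like(self, trees):
        assert trees["RLN/INSL"].root.name == "AncRln-like"

    def test_zebrafish_third_local_copy_named_by_origin(self):
        # end-to-end: replay -> emit -> trace -> tree -> nomenclature
        from karyotrace import emit_fixture, load_scenario, replay, trace_family
        from karyotrace.model import read_gene_table, read_segment_map

        h = replay(load_scenario(data.scenario_path("fig2_fission")))
        import tempfile
        with tempfile.TemporaryDirectory() as d:
            paths = emit_fixture(h, d, nodes=["zebrafish"])
            loci = read_gene_table(paths["genes"])
            smap = read_segment_map(paths["segments_zebrafish"], "GAC",
                                    species="zebrafish")
            asg = trace_family([g for g in loci if g.family == "RXFP3/4"],
                               {"zebrafish": smap}, h.model)
        tree = build_duplication_tree("RXFP3/4", asg, h.model)
        names = assign_nomenclature(tree)
        third = names["zebrafish/rxfp3-3a3"]
        assert third == "rxfp3-3a3"

    def test_names_injective_within_species(self, trees):
        for tree in trees.values():
            names = assign_nomenclature(tree)
            per_species = {}
            for key, name in names.items():
                sp = key.split("/")[0]
                assert name not in per_species.get(sp, set()), (key, name)
                per_species.setdefault(sp, set()).add(name)


class TestLineageCounts:
    def test_seven_receptor_genes_of_independent_origin(self, trees):
        receptors = [trees["RXFP1/2"], trees["RXFP3/4"]]
        assert count_independent_lineages(receptors) == 7

    def test_four_ligand_lineages_in_gnathostome_ancestor(self, trees):
        assert count_independent_lineages([trees["RLN/INSL"]]) == 4

    def test_empty_tree_list_counts_zero(self):
        assert count_independent_lineages([]) == 0

    def test_clade_filter_drops_teleost_only_lineages(self, trees):
        n = count_independent_lineages(
            [trees["RXFP3/4"]], clade_species=data.CLADES["tetrapod"])
        assert n == 3  # RXFP3-2 has no tetrapod member
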