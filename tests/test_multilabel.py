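"""Label maps, locus-to-label assignment, export/import, tree audit."""

import pytest

from lineagesort import (
    audit_multilabel_tree,
    build_label_map,
    export_label_matrix,
    import_label_matrix,
    most_incongruent_gene,
    parse_newick,
)
from lineagesort.multilabel import LabelMap, write_nexus_alignment
from lineagesort.popgen import HaplotypeAlignment
from lineagesort.synthetic import simulate_sequences


@pytest.fixture(scope="module")
def hybrid_setup(hybrid_scenario):
    truth = hybrid_scenario.ground_truth
    samples = hybrid_scenario.posteriors
    return truth, samples


class TestMostIncongruentGene:
    def test_two_genes_error(self, hybrid_setup):
        truth, samples = hybrid_setup
        two = {k: samples[k] for k in list(samples)[:2]}
        with pytest.raises(ValueError, match="3"):
            most_incongruent_gene(truth["hybrid_taxon"], two)

    def test_absent_taxon_error(self, hybrid_setup):
        _, samples = hybrid_setup
        with pytest.raises(ValueError, match="absent"):
            most_incongruent_gene("spXX", samples)

    def test_identical_placement_ties_to_priority(self, null_scenario, caplog):
        # one gene's sample used three times: all scores equal -> priority
        s = null_scenario.posteriors["ITS"]
        samples = {"g1": s, "g2": s, "g3": s}
        taxon = sorted(s.taxa)[0]
        import logging

        with caplog.at_level(logging.WARNING, logger="lineagesort.multilabel"):
            got = most_incongruent_gene(taxon, samples, priority=["g2", "g1", "g3"])
        assert got == "g2"
        assert any("tie" in r.message for r in caplog.records)

    def test_injected_locus_recovered(self, hybrid_setup):
        truth, samples = hybrid_setup
        assert most_incongruent_gene(truth["hybrid_taxon"], samples) == (
            truth["affected_locus"]
        )


class TestLabelMap:
    def test_build_assigns_two_most_congruent_to_l1(self, hybrid_setup):
        truth, samples = hybrid_setup
        h = truth["hybrid_taxon"]
        lm = build_label_map([h], samples)
        taxon, l1_genes = lm.assignments[f"{h}_L1"]
        _, l2_genes = lm.assignments[f"{h}_L2"]
        assert taxon == h
        assert l2_genes == {truth["affected_locus"]}
        assert l1_genes == set(samples) - l2_genes

    def test_terminal_count_species_plus_hybrids(self, hybrid_setup):
        truth, samples = hybrid_setup
        lm = build_label_map([truth["hybrid_taxon"]], samples)
        n_species = len(samples["ITS"].taxa)
        assert lm.n_terminals() == n_species + 1

    def test_no_hybrids_identity_map(self, null_scenario):
        samples = null_scenario.posteriors
        lm = build_label_map([], samples)
        assert lm.n_terminals() == len(samples["ITS"].taxa)
        assert not any(l.endswith("_L2") for l in lm.labels)

    def test_mask_marks_unassigned_cells(self, hybrid_setup):
        truth, samples = hybrid_setup
        h = truth["hybrid_taxon"]
        lm = build_label_map([h], samples)
        mask = lm.mask()
        assert mask[(f"{h}_L2", truth["affected_locus"])] is False
        other = next(g for g in samples if g != truth["affected_locus"])
        assert mask[(f"{h}_L2", other)] is True

    def test_invariants_enforced(self):
        # L2 with two genes violates |L2| = 1
        with pytest.raises(ValueError, match="exactly one"):
            LabelMap(
                genes=["a", "b", "c"],
                assignments={
                    "H_L1": ("H", frozenset({"a"})),
                    "H_L2": ("H", frozenset({"b", "c"})),
                },
                hybrids=["H"],
            )


class TestExportImport:
    def _alignments(self, scenario):
        out = {}
        for i, (gene, tree) in enumerate(scenario.gene_trees_ma.items()):
            out[gene] = simulate_sequences(tree, length=40, rate=1e-3, seed=i)
        return out

    def test_round_trip(self, hybrid_scenario):
        truth = hybrid_scenario.ground_truth
        samples = hybrid_scenario.posteriors
        lm = build_label_map([truth["hybrid_taxon"]], samples)
        matrices = export_label_matrix(lm, self._alignments(hybrid_scenario))
        back = import_label_matrix(matrices, genes=lm.genes)
        assert back.assignments == lm.assignments
        assert back.hybrids == lm.hybrids

    def test_missing_rows_for_unassigned(self, hybrid_scenario):
        truth = hybrid_scenario.ground_truth
        h = truth["hybrid_taxon"]
        samples = hybrid_scenario.posteriors
        lm = build_label_map([h], samples)
        matrices = export_label_matrix(lm, self._alignments(hybrid_scenario))
        other = next(g for g in samples if g != truth["affected_locus"])
        aln = matrices[other]
        row = dict(zip(aln.labels, aln.sequences))[f"{h}_L2"]
        assert set(row) == {"?"}

    def test_missing_sequence_for_assigned_cell_errors(self, hybrid_scenario):
        truth = hybrid_scenario.ground_truth
        samples = hybrid_scenario.posteriors
        lm = build_label_map([truth["hybrid_taxon"]], samples)
        alns = self._alignments(hybrid_scenario)
        gene = truth["affected_locus"]
        aln = alns[gene]
        keep = [i for i, l in enumerate(aln.labels) if l != truth["hybrid_taxon"]]
        alns[gene] = HaplotypeAlignment(
            [aln.labels[i] for i in keep], [aln.sequences[i] for i in keep]
        )
        with pytest.raises(ValueError, match="missing sequence"):
            export_label_matrix(lm, alns)

    def test_nexus_write_parseable(self, tmp_path):
        import dendropy

        aln = HaplotypeAlignment(["sp one", "sp_two"], ["AC-T", "????"])
        path = tmp_path / "m.nex"
        write_nexus_alignment(aln, str(path))
        mat = dendropy.DnaCharacterMatrix.get(path=str(path), schema="nexus")
        assert len(mat) == 2


class TestAudit:
    def test_sister_labels_flagged_congruent(self, hybrid_setup):
        truth, samples = hybrid_setup
        h = truth["hybrid_taxon"]
        lm = build_label_map([h], samples)
        others = sorted(samples["ITS"].taxa - {h})
        nwk = (
            "((" + f"{h}_L1:1,{h}_L2:1):1,("
            + ",".join(f"{o}:2" for o in others)
            + "):1);"
        )
        report = audit_multilabel_tree(parse_newick(nwk), lm, samples)
        assert report[0]["congruent_placement"] is True

    def test_unknown_label_errors(self, hybrid_setup):
        truth, samples = hybrid_setup
        lm = build_label_map([truth["hybrid_taxon"]], samples)
        t = parse_newick("((a:1,b:1):1,c:2);")
        with pytest.raises(ValueError, match="absent"):
            audit_multilabel_tree(t, lm, samples)

    def test_true_gene_tree_placements_consistent(self, hybrid_scenario):
        """Using the true trees as the 'inferred' input, L2 sits in the
        donor clade and each label is consistent with its own loci."""
        truth = hybrid_scenario.ground_truth
        h, donor = truth["hybrid_taxon"], truth["donor_taxon"]
        samples = hybrid_scenario.posteriors
        lm = build_label_map([h], samples)
        # build a multilabelled tree: nuclear topology with H renamed to
        # H_L1, plus H_L2 grafted as sister to the donor
        import dendropy

        base = hybrid_scenario.gene_trees_ma["ITS"].clone(depth=1)
        for lf in base.leaf_node_iter():
            if lf.taxon.label == h:
                # fresh Taxon: the clone shares taxa with the fixture
                lf.taxon = dendropy.Taxon(label=f"{h}_L1")
        dleaf = [l for l in base.leaf_node_iter() if l.taxon.label == donor][0]
        parent = dleaf.parent_node
        mid = dendropy.Node()
        mid.edge.length = dleaf.edge.length / 2
        parent.remove_child(dleaf)
        parent.add_child(mid)
        dleaf.edge.length = mid.edge.length
        mid.add_child(dleaf)
        l2 = dendropy.Node()
        l2.taxon = dendropy.Taxon(label=f"{h}_L2")
        l2.edge.length = mid.edge.length
        mid.add_child(l2)
        base.update_taxon_namespace()
        report = audit_multilabel_tree(base, lm, samples, threshold=1.0)
        assert report[0]["congruent_placement"] is False
        # L1 follows the ITS topology, so its placement agrees with ITS;
        # the other nuclear locus may disagree by ILS in any one seed
        l1_entry = report[0]["labels"][f"{h}_L1"]
        assert l1_entry["median_drop"]["ITS"] <= 1.0
        # L2 was grafted next to the donor, matching its cpDNA assignment
        l2_entry = report[0]["labels"][f"{h}_L2"]
        assert l2_entry["assigned_genes"] == ["cpDNA"]
        assert l2_entry["median_drop"]["cpDNA"] <= 1.0
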