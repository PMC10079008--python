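import math

import numpy as np
import pytest
from Bio.Seq import Seq

from gcrescue import gc_fraction
from gcrescue import synthetic as syn


class TestScaffold:
    def test_planted_sites(self):
        p = syn.make_lat_like_protein(seed=1)
        r = p.residues
        assert r[0] == "M"
        assert r[25] == "C" and r[28] == "C"          # C-x-x-C pair at 26/29
        assert r[130] == "G" and r[131] == "Y"        # G131, Y132
        assert r[131:135] == "YLVV"
        for t in (171, 191, 226):
            assert r[t - 1] == "Y" and r[t + 1] == "N"

    def test_plc_context_residue_configurable(self):
        p = syn.make_lat_like_protein(syn.LatScaffoldParams(plc_context_residue="D"),
                                      seed=1)
        assert p.residues[130] == "D"

    def test_pip_motif_planted_on_request(self):
        p = syn.make_lat_like_protein(syn.LatScaffoldParams(include_pip_motif=True),
                                      seed=1)
        assert "PIPRSP" in p.residues
        default = syn.make_lat_like_protein(seed=1)
        assert "PIPRSP" not in default.residues

    def test_seeds_differ_outside_planted_sites_only(self):
        a = syn.make_lat_like_protein(seed=1).residues
        b = syn.make_lat_like_protein(seed=2).residues
        planted = [0, 25, 28, 130, 131, 132, 133, 134, 170, 172, 190, 192, 225, 227]
        assert all(a[i] == b[i] for i in planted)
        assert a != b

    def test_infeasible_placement_errors(self):
        with pytest.raises(ValueError):
            syn.make_lat_like_protein(
                syn.LatScaffoldParams(protein_length=100), seed=0)


class TestReverseTranslate:
    def test_translation_inverse_holds(self):
        from gcrescue import SequenceRecord
        rng = np.random.default_rng(3)
        for i in range(20):
            residues = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=60))
            protein = SequenceRecord(id=f"p{i}", residues=residues)
            cds = syn.reverse_translate_gc_biased(protein, 0.5, seed=i)
            assert len(cds.residues) == 3 * 60 + 3
            assert str(Seq(cds.residues).translate(to_stop=True)) == residues

    def test_gc_monotone_in_target(self, scaffold_protein):
        lo = syn.reverse_translate_gc_biased(scaffold_protein, 0.50, seed=4)
        hi = syn.reverse_translate_gc_biased(scaffold_protein, 0.75, seed=4)
        assert gc_fraction(hi.residues) > gc_fraction(lo.residues)

    def test_realized_gc_within_tolerance(self, scaffold_protein):
        for target in (0.45, 0.60, 0.72):
            cds = syn.reverse_translate_gc_biased(scaffold_protein, target, seed=5)
            assert abs(gc_fraction(cds.residues) - target) <= 0.02

    def test_polylysine_unreachable_target_reports_range(self):
        from gcrescue import SequenceRecord
        poly_k = SequenceRecord(id="k", residues="K" * 50)
        with pytest.raises(ValueError, match="achievable"):
            syn.reverse_translate_gc_biased(poly_k, 0.75, seed=0)
        # lysine codons AAA/AAG cap GC at 1/3
        cds = syn.reverse_translate_gc_biased(poly_k, 0.35, seed=0)
        assert gc_fraction(cds.residues) <= 1 / 3 + 1e-9


class TestEvolve:
    def test_zero_branch_lengths_give_identical_leaves(self, scaffold_protein):
        leaves = syn.evolve_orthologs(scaffold_protein, "(a:0,b:0,c:0);", seed=0)
        assert all(l.residues == scaffold_protein.residues for l in leaves)

    def test_substitution_probability_matches_closed_form(self):
        from gcrescue import SequenceRecord
        rng = np.random.default_rng(9)
        root = SequenceRecord(
            id="root",
            residues="".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=2000)))
        b = 0.2
        leaves = syn.evolve_orthologs(root, f"(x:{b});", seed=10)
        changed = sum(1 for a, c in zip(root.residues, leaves[0].residues) if a != c)
        p = 1 - math.exp(-b)
        se = math.sqrt(p * (1 - p) / 2000)
        assert abs(changed / 2000 - p) <= 3 * se

    def test_invariant_sites_untouched(self, scaffold_protein, ortholog_family):
        for pos in (1, 26, 29, 131, 132, 171, 191, 226):
            residues = {f.residues[pos - 1] for f in ortholog_family}
            assert residues == {scaffold_protein.residues[pos - 1]}


class TestReadSimulator:
    def test_error_free_reads_are_exact_substrings(self, gc_rich_cds):
        from gcrescue import revcomp
        reads = syn.simulate_reads([(gc_rich_cds, 1.0)], 200, 80, 0.0, seed=6)
        t = gc_rich_cds.residues
        assert all(r.residues in t or revcomp(r.residues) in t for r in reads)

    def test_template_sampling_follows_weights(self, gc_rich_cds):
        from gcrescue import SequenceRecord
        other = SequenceRecord(id="other", residues="AT" * (len(gc_rich_cds) // 2))
        reads = syn.simulate_reads([(gc_rich_cds, 9.0), (other, 1.0)],
                                   10_000, 50, 0.0, seed=7)
        n_target = sum(1 for r in reads if syn.read_origin(r.id)[0] == gc_rich_cds.id)
        sd = math.sqrt(10_000 * 0.9 * 0.1)
        assert abs(n_target - 9000) <= 3 * sd

    def test_determinism(self, gc_rich_cds):
        a = syn.simulate_reads([(gc_rich_cds, 1.0)], 50, 60, 0.02, seed=8)
        b = syn.simulate_reads([(gc_rich_cds, 1.0)], 50, 60, 0.02, seed=8)
        assert [(r.id, r.residues) for r in a] == [(r.id, r.residues) for r in b]


class TestTissuePanel:
    def test_expected_count_arithmetic(self):
        assert syn.expected_read_count(100.0, 500, 10**6) == pytest.approx(50.0)
        assert syn.expected_read_count(100.0, 500, 2 * 10**6) == pytest.approx(100.0)

    def test_zero_rpkm_yields_zero_target_reads(self, gc_rich_cds):
        bg = syn.make_background_genes(5, seed=1)
        truth = syn.TissuePanelTruth([
            syn.TissueTruth("spleen", 10_000, {gc_rich_cds.id: 0.0}, True),
            syn.TissueTruth("liver", 10_000, {gc_rich_cds.id: 0.0}, False),
        ])
        panel, table = syn.make_tissue_panel([gc_rich_cds] + bg, truth, seed=2)
        for reads in panel.values():
            assert all(syn.read_origin(r.id)[0] != gc_rich_cds.id for r in reads)
        assert (table.target_reads == 0).all()

    def test_panel_realizes_library_sizes_and_writes_files(self, gc_rich_cds, tmp_path):
        bg = syn.make_background_genes(5, seed=1)
        truth = syn.TissuePanelTruth([
            syn.TissueTruth("spleen", 10_000, {gc_rich_cds.id: 200.0}, True),
            syn.TissueTruth("liver", 10_000, {gc_rich_cds.id: 10.0}, False),
        ])
        panel, _ = syn.make_tissue_panel([gc_rich_cds] + bg, truth, seed=3,
                                         out_dir=tmp_path)
        assert {len(r) for r in panel.values()} == {10_000}
        assert (tmp_path / "spleen.fastq").exists()
        assert (tmp_path / "truth.tsv").exists()

    def test_panel_needs_both_flags(self):
        with pytest.raises(ValueError, match="immune"):
            syn.TissuePanelTruth([
                syn.TissueTruth("spleen", 10_000, {}, True),
            ])
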