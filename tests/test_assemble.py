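import numpy as np
import pytest

from gcrescue import (ReadRecord, SequenceRecord, find_orfs, greedy_assemble,
                      iterative_rescue, revcomp)
from gcrescue import synthetic as syn


class TestGreedyAssemble:
    def test_two_reads_exact_overlap_merge_length(self):
        rng = np.random.default_rng(0)
        template = "".join(rng.choice(list("ACGT"), size=150))
        r1 = ReadRecord(id="r1", residues=template[:100])
        r2 = ReadRecord(id="r2", residues=template[50:150])
        contigs = greedy_assemble([r1, r2], min_overlap=30)
        assert len(contigs) == 1
        assert len(contigs[0]) == 100 + 100 - 50
        assert contigs[0].consensus == template

    def test_insufficient_overlap_keeps_reads_apart(self):
        rng = np.random.default_rng(1)
        template = "".join(rng.choice(list("ACGT"), size=190))
        r1 = ReadRecord(id="r1", residues=template[:100])
        r2 = ReadRecord(id="r2", residues=template[90:190])  # 10 < min_overlap
        contigs = greedy_assemble([r1, r2], min_overlap=30)
        assert len(contigs) == 2

    def test_opposite_orientation_reads_merge(self):
        rng = np.random.default_rng(2)
        template = "".join(rng.choice(list("ACGT"), size=150))
        r1 = ReadRecord(id="r1", residues=template[:100])
        r2 = ReadRecord(id="r2", residues=revcomp(template[50:150]))
        contigs = greedy_assemble([r1, r2], min_overlap=30)
        assert len(contigs) == 1
        assert contigs[0].consensus in (template, revcomp(template))

    def test_error_free_tiling_reconstructs_template(self, planted_gene):
        _, cds = planted_gene
        tx = syn.embed_in_transcript(cds, 100, seed=31)
        reads = syn.simulate_reads([(tx, 1.0)], 40 * len(tx.residues) // 100,
                                   100, 0.0, seed=32)
        contigs = greedy_assemble(reads)
        top = contigs[0].consensus
        assert cds.residues in top or revcomp(cds.residues) in top
        assert all(d >= 1 for d in contigs[0].depth)
        assert len(contigs[0].depth) == len(top)

    def test_consensus_identity_with_read_errors(self, planted_gene):
        """At 1% substitution error and 40x depth the majority consensus is
        >= 99.9% identical to the template."""
        _, cds = planted_gene
        tx = syn.embed_in_transcript(cds, 100, seed=33)
        reads = syn.simulate_reads([(tx, 1.0)], 40 * len(tx.residues) // 100,
                                   100, 0.01, seed=34)
        top = greedy_assemble(reads)[0]
        cons = top.consensus
        if revcomp(cds.residues)[:50] in cons:
            cons = revcomp(cons)
        # align by locating an exact anchor of the template within consensus
        t = tx.residues
        anchor = cons.find(t[300:340])
        assert anchor >= 0
        offset = anchor - 300
        overlap = [(cons[i + offset], t[i]) for i in range(len(t))
                   if 0 <= i + offset < len(cons)]
        identity = sum(1 for a, b in overlap if a == b) / len(overlap)
        assert identity >= 0.999

    def test_determinism(self, planted_gene):
        _, cds = planted_gene
        reads = syn.simulate_reads([(cds, 1.0)], 100, 100, 0.01, seed=35)
        a = [c.consensus for c in greedy_assemble(reads)]
        b = [c.consensus for c in greedy_assemble(reads)]
        assert a == b


class TestIterativeRescue:
    def test_fragment_bait_extends_to_full_gene(self, planted_gene):
        protein, cds = planted_gene
        tx = syn.embed_in_transcript(cds, 100, seed=36)
        reads = syn.simulate_reads([(tx, 1.0)], 40 * len(tx.residues) // 100,
                                   100, 0.0, seed=37)
        bait = SequenceRecord(id="bait", residues=cds.residues[200:400],
                              alphabet="DNA")
        contig, counts = iterative_rescue(reads, bait)
        assert cds.residues in contig.consensus
        assert counts == sorted(counts), "recruited count must not decrease"

    def test_full_bait_converges_in_one_extra_round(self, planted_gene):
        _, cds = planted_gene
        reads = syn.simulate_reads([(cds, 1.0)], 120, 100, 0.0, seed=38)
        contig, counts = iterative_rescue(reads, cds)
        assert len(counts) <= 3
        assert counts[-1] == counts[0] or counts[-1] >= counts[0]

    def test_monotone_recruitment_over_seeds(self, planted_gene):
        """Recruited-read counts never decrease across rescue rounds."""
        _, cds = planted_gene
        tx = syn.embed_in_transcript(cds, 60, seed=39)
        bait = SequenceRecord(id="bait", residues=cds.residues[100:300],
                              alphabet="DNA")
        for seed in range(20):
            reads = syn.simulate_reads([(tx, 1.0)], 100, 100, 0.0, seed=seed)
            _, counts = iterative_rescue(reads, bait, max_rounds=3)
            assert counts == sorted(counts)

    def test_no_reads_recruited_is_an_error(self, planted_gene):
        _, cds = planted_gene
        rng = np.random.default_rng(40)
        unrelated = SequenceRecord(
            id="x", residues="".join(rng.choice(list("ACGT"), size=600)))
        reads = syn.simulate_reads([(unrelated, 1.0)], 50, 100, 0.0, seed=41)
        with pytest.raises(ValueError, match="diverged|threshold"):
            iterative_rescue(reads, cds)


class TestFindOrfs:
    def test_minimal_orf_translation(self):
        orfs = find_orfs("ATGAAATAA", min_aa=1)
        assert len(orfs) == 1
        assert orfs[0].translation == "MK"
        assert (orfs[0].start, orfs[0].end, orfs[0].strand) == (0, 9, "+")

    def test_reverse_strand_orf(self):
        orfs = find_orfs(revcomp("ATGAAATAA"), min_aa=1)
        assert len(orfs) == 1
        assert orfs[0].translation == "MK"
        assert orfs[0].strand == "-"

    def test_planted_cds_in_random_flanks_recovered(self, planted_gene):
        protein, cds = planted_gene
        tx = syn.embed_in_transcript(cds, 150, seed=42)
        orfs = find_orfs(tx.residues, min_aa=50)
        candidate = [o for o in orfs if o.is_candidate]
        assert candidate and candidate[0].translation == protein.residues

    def test_min_length_filter(self):
        assert find_orfs("ATGAAATAA", min_aa=50) == []
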