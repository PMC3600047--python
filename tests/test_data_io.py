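"""Alignment, partition, codon-extraction and tree I/O behaviour."""

import numpy as np
import pytest

from claderates.data_io import (
    Alignment,
    BRANCH_LENGTH_FLOOR,
    Partition,
    PartitionMap,
    check_labels_match,
    extract_codons,
    read_alignment,
    read_alignment_text,
    read_partition_table,
    read_richness_table,
    read_tree,
    write_alignment,
    write_partition_table,
    write_richness_table,
    write_tree,
)


class TestAlignmentIO:
    def test_smallest_valid_fasta(self, tmp_path):
        p = tmp_path / "two.fasta"
        p.write_text(">a\nACGTAC\n>b\nACG-TN\n")
        aln = read_alignment(p)
        assert aln.n_taxa == 2 and aln.length == 6
        assert aln.taxa == ["a", "b"]

    def test_invalid_symbol_rejected(self):
        with pytest.raises(ValueError, match="invalid alignment symbols"):
            read_alignment_text(">a\nACXGTA\n>b\nACGGTA\n")

    def test_ragged_rows_rejected(self):
        with pytest.raises(ValueError, match="ragged"):
            read_alignment_text(">a\nACGTA\n>b\nACG\n")

    def test_duplicate_labels_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            read_alignment_text(">a\nACG\n>a\nACG\n")

    def test_large_alignment_roundtrip_bytes(self, tmp_path):
        """write -> read -> write is byte-identical for a 62x6278 matrix."""
        rng = np.random.default_rng(42)
        symbols = np.array(list("ACGT") + ["-", "N", "R", "Y"])
        probs = [0.23, 0.23, 0.23, 0.23, 0.04, 0.02, 0.01, 0.01]
        sites = rng.choice(symbols, size=(62, 6278), p=probs)
        aln = Alignment([f"t{i:02d}" for i in range(62)], sites)
        p1, p2 = tmp_path / "a1.fasta", tmp_path / "a2.fasta"
        write_alignment(aln, p1)
        again = read_alignment(p1)
        write_alignment(again, p2)
        assert p1.read_bytes() == p2.read_bytes()
        assert np.array_equal(aln.sites, again.sites)


class TestPartitions:
    def test_coding_interval_must_be_triplet(self):
        with pytest.raises(ValueError, match="divisible by 3"):
            PartitionMap([Partition("g1", 0, 7, "coding")])

    def test_overlap_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            PartitionMap([
                Partition("g1", 0, 9, "coding"),
                Partition("g2", 6, 12, "coding"),
            ])

    def test_table_roundtrip(self, tmp_path):
        pmap = PartitionMap([
            Partition("g1", 0, 9, "coding"),
            Partition("i1", 9, 14, "noncoding"),
        ])
        path = tmp_path / "parts.tsv"
        write_partition_table(pmap, path)
        again = read_partition_table(path)
        assert again.partitions == pmap.partitions


class TestExtractCodons:
    def test_stop_codon_masked(self):
        aln = read_alignment_text(">a\nATGAAATAG\n>b\nATGAAAGAG\n")
        pmap = PartitionMap([Partition("g", 0, 9, "coding")])
        caln = extract_codons(aln, pmap)
        assert caln.length == 3
        assert caln.n_stops_masked == 1
        assert caln.codon_sites[0, 2] == -1  # TAG masked
        assert caln.codon_sites[1, 2] != -1  # GAG kept

    def test_ambiguity_masks_whole_codon(self):
        aln = read_alignment_text(">a\nATGA-AAAR\n>b\nATGAAAAAA\n")
        pmap = PartitionMap([Partition("g", 0, 9, "coding")])
        caln = extract_codons(aln, pmap)
        assert caln.codon_sites[0, 1] == -1 and caln.codon_sites[0, 2] == -1
        assert (caln.codon_sites[1] != -1).all()

    def test_masking_is_monotone(self):
        """Adding ambiguity to a sequence never unmasks a codon."""
        rng = np.random.default_rng(3)
        seq = "".join(rng.choice(list("ACGT"), 30))
        base = read_alignment_text(f">a\n{seq}\n")
        pmap = PartitionMap([Partition("g", 0, 30, "coding")])
        masked_before = extract_codons(base, pmap).codon_sites[0] == -1
        degraded = list(seq)
        for pos in rng.choice(30, size=8, replace=False):
            degraded[pos] = "N"
        after = extract_codons(
            read_alignment_text(f">a\n{''.join(degraded)}\n"), pmap
        ).codon_sites[0] == -1
        assert np.all(after[masked_before])

    def test_simulated_inframe_alignment_never_masked(self, pair_study, codon_model):
        from claderates.synthetic_data import simulate_alignment

        tree, _, _ = pair_study
        caln = simulate_alignment(tree, codon_model, 500, seed=11)
        assert caln.length == 500
        assert (caln.codon_sites != -1).all()

    def test_no_coding_partition_is_error(self):
        aln = read_alignment_text(">a\nACGTAA\n")
        with pytest.raises(ValueError, match="no coding"):
            extract_codons(aln, PartitionMap([Partition("i", 0, 6, "noncoding")]))


class TestTreeIO:
    def test_parse_counts_nodes(self):
        tree = read_tree("((A:0.1,B:0.2):0.05,C:0.3);")
        assert tree.n_tips == 3
        assert sum(1 for n in tree.postorder if not n.is_tip) == 2

    def test_roundtrip_identity(self):
        text = "((A:0.1,B:0.2):0.05,C:0.3);"
        assert read_tree(text).to_newick() == text

    def test_unbalanced_parentheses(self):
        with pytest.raises(ValueError, match="parse error"):
            read_tree("((A:0.1,B:0.2:0.05,C:0.3);")

    def test_zero_branch_floored(self):
        tree = read_tree("((A:0.0,B:0.2):0.05,C:0.3);")
        a = tree.postorder[tree.tip_index["A"]]
        assert a.length == BRANCH_LENGTH_FLOOR

    def test_polytomy_resolved_binary(self):
        tree = read_tree("(A:0.1,B:0.2,C:0.3,D:0.4);")
        assert tree.is_binary()
        assert tree.n_tips == 4

    def test_label_mismatch_lists_offender(self):
        aln = read_alignment_text(">A\nACG\n>B\nACG\n")
        tree = read_tree("((A:0.1,B:0.2):0.05,C:0.3);")
        with pytest.raises(ValueError, match="C"):
            check_labels_match(tree, aln)

    def test_branch_annotation_substitution(self):
        tree = read_tree("((A:0.1,B:0.2):0.05,C:0.3);")
        idx = tree.tip_index["A"]
        text = write_tree(tree, branch_lengths={idx: 0.9})
        assert "A:0.9" in text
        # original untouched
        assert tree.postorder[idx].length == 0.1


class TestRichnessTable:
    def test_roundtrip_and_validation(self, tmp_path):
        path = tmp_path / "rich.tsv"
        write_richness_table({"x": 5, "y": 1}, path)
        assert read_richness_table(path) == {"x": 5, "y": 1}
        bad = tmp_path / "bad.tsv"
        bad.write_text("lineage_id\tspecies_count\nx\t0\n")
        with pytest.raises(ValueError, match=">= 1"):
            read_richness_table(bad)
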