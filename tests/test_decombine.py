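"""Read classification: construction oracles, strand symmetry, round trips,
UMI extraction and FASTQ processing."""

import numpy as np
import pytest

from tcrtag.decombine import (
    AnnotatedRead,
    Classifier,
    NoCall,
    SequenceRead,
    canonical_classifier,
    decombine_read,
    extract_umi,
    process_fastq,
    read_decombinator,
    reconstruct_sequence,
    reverse_complement,
    write_decombinator,
)


def build_read(genes, v, j, v_del, j_del, insert):
    """Construction oracle: the read a given rearrangement produces, plus
    its canonical truth classifier."""
    clf = canonical_classifier(Classifier(v, j, v_del, j_del, insert), genes)
    return reconstruct_sequence(clf, genes), clf


class TestDecombineRead:
    @pytest.mark.parametrize(
        "v,j,v_del,j_del,insert",
        [
            (0, 3, 0, 0, ""),
            (0, 3, 2, 3, "GGC"),
            (1, 4, 5, 1, "T"),
            (2, 3, 0, 2, "GGCAAGCTTGGCAAG"),  # 15 nt insert recovered verbatim
        ],
    )
    def test_recovers_constructed_classifier(self, toy_genes, toy_tagset,
                                             v, j, v_del, j_del, insert):
        seq, truth = build_read(toy_genes, v, j, v_del, j_del, insert)
        res = decombine_read(SequenceRead("r", seq), toy_tagset)
        assert isinstance(res, AnnotatedRead)
        assert res.classifier == truth
        assert not res.reverse_complemented

    def test_random_dna_is_no_v(self, toy_tagset):
        rng = np.random.default_rng(0)
        seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 120))
        res = decombine_read(SequenceRead("r", seq), toy_tagset)
        assert isinstance(res, NoCall)
        assert res.reason == "no_v"

    def test_reverse_complement_flag(self, toy_genes, toy_tagset):
        seq, truth = build_read(toy_genes, 0, 3, 2, 3, "GGC")
        res = decombine_read(SequenceRead("r", reverse_complement(seq)), toy_tagset)
        assert isinstance(res, AnnotatedRead)
        assert res.classifier == truth
        assert res.reverse_complemented

    def test_strand_symmetry_property(self, toy_genes, toy_tagset):
        rng = np.random.default_rng(3)
        for _ in range(50):
            v, j = int(rng.integers(0, 3)), int(rng.integers(3, 5))
            ins = "".join("ACGT"[i] for i in rng.integers(0, 4, rng.poisson(5)))
            seq, _ = build_read(toy_genes, v, j, int(rng.integers(0, 5)),
                                int(rng.integers(0, 4)), ins)
            fwd = decombine_read(SequenceRead("r", seq), toy_tagset)
            rev = decombine_read(SequenceRead("r", reverse_complement(seq)), toy_tagset)
            assert fwd.classifier == rev.classifier
            assert fwd.inter_tag_seq == rev.inter_tag_seq
            assert (fwd.reverse_complemented, rev.reverse_complemented) == (False, True)

    def test_duplicated_tag_is_multiple_v(self, toy_genes, toy_tagset):
        seq, _ = build_read(toy_genes, 0, 3, 0, 0, "")
        v_tag = toy_tagset.tags[0].keyword
        res = decombine_read(SequenceRead("r", v_tag + seq), toy_tagset)
        assert isinstance(res, NoCall)
        assert res.reason == "multiple_v"

    def test_j_before_v_is_order_violation(self, toy_genes, toy_tagset):
        j_gene = toy_genes[3].sequence
        v_gene = toy_genes[0].sequence
        res = decombine_read(SequenceRead("r", j_gene + v_gene), toy_tagset)
        assert isinstance(res, NoCall)
        # The reverse complement of a J+V read is a V+J read on the other
        # strand, so this layout is only order-violating forward.
        assert res.reason in ("order_violation", "no_j")


class TestDeletionCounting:
    def test_full_germline_end_gives_zero_deletions(self, toy_genes, toy_tagset):
        seq, truth = build_read(toy_genes, 0, 3, 0, 0, "AATT")
        assert truth.v_deletions == 0
        res = decombine_read(SequenceRead("r", seq), toy_tagset)
        assert res.classifier.v_deletions == 0

    def test_maximal_deletion_case(self, toy_genes, toy_tagset):
        # Everything between the V tag end and the gene end deleted.
        tag = toy_tagset.tags[0]
        gene = toy_genes[0]
        max_del = len(gene) - (tag.offset + len(tag.keyword))
        seq, truth = build_read(toy_genes, 0, 3, max_del, 0, "CCGG")
        res = decombine_read(SequenceRead("r", seq), toy_tagset)
        assert res.classifier == truth
        assert res.classifier.v_deletions <= max_del

    def test_boundary_coincidence_resolved_v_first(self, toy_genes, toy_tagset):
        # Insert starting with the next germline V base: the canonical
        # classifier attributes it to germline V, and the annotator agrees.
        gene = toy_genes[0].sequence
        raw = Classifier(0, 3, 2, 0, gene[-2] + "T")
        canon = canonical_classifier(raw, toy_genes)
        assert canon.v_deletions == 1
        assert canon.insert == "T"
        seq = reconstruct_sequence(raw, toy_genes)
        res = decombine_read(SequenceRead("r", seq), toy_tagset)
        assert res.classifier == canon


class TestRoundTrip:
    def test_reannotation_is_idempotent(self, toy_genes, toy_tagset):
        rng = np.random.default_rng(11)
        for _ in range(100):
            clf = Classifier(
                int(rng.integers(0, 3)), int(rng.integers(3, 5)),
                int(rng.integers(0, 6)), int(rng.integers(0, 4)),
                "".join("ACGT"[i] for i in rng.integers(0, 4, rng.poisson(6))),
            )
            seq = reconstruct_sequence(clf, toy_genes)
            first = decombine_read(SequenceRead("r", seq), toy_tagset)
            assert isinstance(first, AnnotatedRead)
            seq2 = reconstruct_sequence(first.classifier, toy_genes)
            second = decombine_read(SequenceRead("r", seq2), toy_tagset)
            assert second.classifier == first.classifier
            assert seq2 == seq


class TestExtractUmi:
    def test_default_layout(self):
        read = "AAAAAA" + "TTTT" + "CCCCCC" + "GGGG"
        assert extract_umi(read, "N6S4N6") == "AAAAAACCCCCC"

    def test_too_short_is_none(self):
        assert extract_umi("AAAA", "N6S4N6") is None

    def test_plain_prefix_layout(self):
        assert extract_umi("ACGTACGTACGTTTTT", "N12") == "ACGTACGTACGT"

    def test_malformed_spec_rejected(self):
        with pytest.raises(ValueError):
            extract_umi("ACGT", "6N")


class TestProcessFastq:
    @staticmethod
    def write_pair(tmp_path, records):
        f1, f2 = tmp_path / "r1.fastq", tmp_path / "r2.fastq"
        with open(f1, "w") as a, open(f2, "w") as b:
            for rid, seq, umi in records:
                a.write(f"@{rid}\n{seq}\n+\n{'I' * len(seq)}\n")
                b.write(f"@{rid}\n{umi}\n+\n{'I' * len(umi)}\n")
        return f1, f2

    def test_error_free_reads_all_annotate(self, tmp_path, toy_genes, toy_tagset):
        rng = np.random.default_rng(5)
        records = []
        for i in range(100):
            seq, _ = build_read(toy_genes, int(rng.integers(0, 3)),
                                int(rng.integers(3, 5)), int(rng.integers(0, 4)),
                                int(rng.integers(0, 4)),
                                "".join("ACGT"[k] for k in rng.integers(0, 4, 6)))
            umi = "".join("ACGT"[k] for k in rng.integers(0, 4, 6)) + "TTTT" + \
                  "".join("ACGT"[k] for k in rng.integers(0, 4, 6))
            records.append((f"r{i}", seq, umi))
        f1, f2 = self.write_pair(tmp_path, records)
        annotated, stats = process_fastq(f1, f2, toy_tagset)
        assert stats["input"] == 100
        assert stats["annotated"] == 100
        assert len(annotated) == 100
        assert all(len(a.barcode) == 12 for a in annotated)

    def test_empty_fastq(self, tmp_path, toy_tagset):
        f1, f2 = self.write_pair(tmp_path, [])
        annotated, stats = process_fastq(f1, f2, toy_tagset)
        assert annotated == []
        assert sum(stats.values()) == 0

    def test_desynchronized_pair_raises(self, tmp_path, toy_genes, toy_tagset):
        seq, _ = build_read(toy_genes, 0, 3, 0, 0, "")
        f1, f2 = self.write_pair(tmp_path, [("a", seq, "A" * 16), ("b", seq, "A" * 16)])
        with open(f1, "a") as fh:
            fh.write(f"@c\n{seq}\n+\n{'I' * len(seq)}\n")
        with pytest.raises(ValueError, match="desynchronized"):
            process_fastq(f1, f2, toy_tagset)


def test_decombinator_format_round_trip(tmp_path, toy_genes, toy_tagset):
    seq, truth = build_read(toy_genes, 0, 3, 2, 1, "GGC")
    res = decombine_read(SequenceRead("r0", seq), toy_tagset, barcode="ACGTACGTACGT")
    path = tmp_path / "out.decombinator"
    write_decombinator([res], path)
    (back,) = read_decombinator(path)
    assert back.classifier == truth
    assert back.barcode == "ACGTACGTACGT"
    assert back.inter_tag_seq == res.inter_tag_seq
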