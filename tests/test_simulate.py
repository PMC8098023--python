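"""Simulator: determinism, degenerate limits, error-rate calibration and
scoring."""

import numpy as np
import pytest

from tcrtag.collapse import CollapseConfig, collapse_reads
from tcrtag.decombine import annotate_records
from tcrtag.simulate import (
    SimConfig,
    annotate_truth,
    score_annotation,
    score_collapse,
    simulate_pcr,
    simulate_repertoire,
    simulate_sequencing,
)


def hamming(a, b):
    return sum(x != y for x, y in zip(a, b))


def reads_of(truth, cfg, tagset, rng=None):
    rng = rng or np.random.default_rng(cfg.seed)
    molecules = simulate_pcr(truth, cfg, rng)
    return molecules, simulate_sequencing(molecules, cfg, rng)


class TestRepertoire:
    def test_deterministic_under_seed(self, bundled_tagset):
        cfg = SimConfig(n_tcrs=200, seed=5)
        a = simulate_repertoire(cfg, bundled_tagset)
        b = simulate_repertoire(cfg, bundled_tagset)
        assert a == b

    def test_sequences_distinct(self, bundled_tagset):
        truth = simulate_repertoire(SimConfig(n_tcrs=500, seed=1), bundled_tagset)
        assert len({t.sequence for t in truth}) == 500

    def test_degenerate_parameters_give_pure_vj_joins(self, bundled_tagset):
        cfg = SimConfig(n_tcrs=50, seed=2, v_del_mean=0, j_del_mean=0,
                        insert_len_mean=0)
        for t in simulate_repertoire(cfg, bundled_tagset):
            assert t.classifier.v_deletions == 0
            assert t.classifier.j_deletions == 0
            assert t.classifier.insert == ""
            v = bundled_tagset.genes[t.classifier.v_index]
            j = bundled_tagset.genes[t.classifier.j_index]
            assert t.sequence == v.sequence + j.sequence

    def test_truth_reconstructs_from_classifier(self, bundled_tagset):
        from tcrtag.decombine import reconstruct_sequence

        for t in simulate_repertoire(SimConfig(n_tcrs=100, seed=3), bundled_tagset):
            assert reconstruct_sequence(t.classifier, bundled_tagset.genes) == t.sequence
            assert t.abundance >= 1


class TestPcr:
    def test_zero_error_rate_copies_identical(self, bundled_tagset):
        cfg = SimConfig(n_tcrs=10, seed=4, pcr_error_rate=0.0, pcr_rounds=3)
        truth = simulate_repertoire(cfg, bundled_tagset)
        molecules = simulate_pcr(truth, cfg)
        for mol, _ in zip(molecules, truth):
            assert len(mol.seq_copies) == 1
        assert all(m.seq_copies[0][1] == 8 for m in molecules)

    def test_copy_number_conservation(self, bundled_tagset):
        cfg = SimConfig(n_tcrs=30, seed=6, pcr_rounds=4, pcr_error_rate=1e-3)
        truth = simulate_repertoire(cfg, bundled_tagset)
        molecules = simulate_pcr(truth, cfg)
        assert sum(m.copies for m in molecules) == sum(
            t.abundance for t in truth
        ) * 2 ** cfg.pcr_rounds

    def test_one_molecule_three_rounds_shares_umi(self, bundled_tagset):
        cfg = SimConfig(n_tcrs=1, seed=7, pcr_rounds=3)
        truth = simulate_repertoire(cfg, bundled_tagset)
        truth[0].abundance = 1
        (mol,) = simulate_pcr(truth, cfg)
        assert mol.copies == 8
        assert len(mol.umi) == cfg.umi_length

    def test_mutation_load_matches_expectation(self, bundled_tagset):
        # Mean per-copy substitution count ~ rate * length * rounds.
        cfg = SimConfig(n_tcrs=40, seed=8, pcr_rounds=3, pcr_error_rate=2e-3,
                        abundance_lambda=0.0)
        truth = simulate_repertoire(cfg, bundled_tagset)
        molecules = simulate_pcr(truth, cfg)
        total = expected = 0.0
        n_copies = 0
        for mol, t in zip(molecules, truth):
            for seq, count in mol.seq_copies:
                total += hamming(seq, t.sequence) * count
                n_copies += count
            expected += len(t.sequence) * cfg.pcr_error_rate * cfg.pcr_rounds * mol.copies
        # 4-sigma Poisson band around the expected total substitution count.
        assert abs(total - expected) < 4 * np.sqrt(expected) + 1


class TestSequencing:
    def test_zero_error_rate_reads_equal_molecules(self, bundled_tagset):
        cfg = SimConfig(n_tcrs=20, seed=9, pcr_error_rate=0.0, seq_error_rate=0.0)
        truth = simulate_repertoire(cfg, bundled_tagset)
        molecules, reads = reads_of(truth, cfg, bundled_tagset)
        assert len(reads) == sum(m.copies for m in molecules)
        by_id = {t.truth_id: t.sequence for t in truth}
        assert all(r.tcr_seq == by_id[r.origin_id] for r in reads)

    def test_umi_read_error_rate_within_binomial_ci(self, bundled_tagset):
        cfg = SimConfig(n_tcrs=150, seed=10, pcr_error_rate=0.0,
                        seq_error_rate=5e-3, pcr_rounds=3)
        truth = simulate_repertoire(cfg, bundled_tagset)
        molecules, reads = reads_of(truth, cfg, bundled_tagset)
        base_umis = {m.umi[:6] + cfg.umi_spacer + m.umi[6:] for m in molecules}
        base_len = len(next(iter(base_umis)))
        assert all(len(r.umi_read) == base_len for r in reads)  # substitutions only
        p = 1 - (1 - cfg.seq_error_rate) ** base_len
        n_err = sum(1 for r in reads if r.umi_read not in base_umis)
        n = len(reads)
        assert abs(n_err - n * p) < 4 * np.sqrt(n * p * (1 - p)) + 1


class TestScoring:
    def test_perfect_annotation_scores_one(self, toy_genes, toy_tagset):
        cfg = SimConfig(n_tcrs=50, seed=11, max_deletions=3, insert_len_mean=3)
        truth = simulate_repertoire(cfg, toy_tagset)
        from tcrtag.decombine import SequenceRead, decombine_read

        results = [decombine_read(SequenceRead(f"t{t.truth_id}", t.sequence), toy_tagset)
                   for t in truth]
        clf_acc, jct_acc = score_annotation(results, truth, toy_tagset)
        assert clf_acc == 1.0
        assert jct_acc == 1.0

    def test_swapped_truth_counts_as_incorrect(self, toy_genes, toy_tagset):
        cfg = SimConfig(n_tcrs=10, seed=12, max_deletions=3)
        truth = simulate_repertoire(cfg, toy_tagset)
        from tcrtag.decombine import SequenceRead, decombine_read

        results = [decombine_read(SequenceRead(f"t{t.truth_id}", t.sequence), toy_tagset)
                   for t in truth]
        sabotaged = list(truth)
        sabotaged[0] = truth[1]
        clf_acc, _ = score_annotation(results[:1] + results[1:], sabotaged, toy_tagset)
        assert clf_acc < 1.0

    def test_score_collapse_perfect_recovery(self):
        from tcrtag.collapse import CollapsedTCR
        from tcrtag.decombine import Classifier

        truth = {Classifier(0, 3, i, 0, ""): i + 1 for i in range(5)}
        collapsed = [CollapsedTCR(c, n, 1.0) for c, n in truth.items()]
        assert score_collapse(collapsed, truth) == (5, 0, pytest.approx(1.0))

    def test_score_collapse_counts_spurious(self):
        from tcrtag.collapse import CollapsedTCR
        from tcrtag.decombine import Classifier

        truth = {Classifier(0, 3, i, 0, ""): i + 1 for i in range(5)}
        collapsed = [CollapsedTCR(c, n, 1.0) for c, n in truth.items()]
        collapsed.append(CollapsedTCR(Classifier(9, 9, 0, 0, "TTTT"), 1, 1.0))
        n_rec, n_spur, _ = score_collapse(collapsed, truth)
        assert (n_rec, n_spur) == (5, 1)


class TestZeroErrorIdentityLimit:
    def test_collapse_recovers_truth_exactly(self, bundled_tagset):
        """With no PCR/sequencing error, collapse output equals the pre-PCR
        ground truth: every molecule one cluster, abundances exact, r = 1."""
        cfg = SimConfig(n_tcrs=100, seed=13, pcr_error_rate=0.0, seq_error_rate=0.0)
        truth = simulate_repertoire(cfg, bundled_tagset)
        _, reads = reads_of(truth, cfg, bundled_tagset)
        annotated, stats = annotate_records(
            ((r.read_id, r.tcr_seq, r.tcr_qual, r.umi_read, r.umi_qual)
             for r in reads),
            bundled_tagset, umi_spec=cfg.umi_spec)
        assert stats["annotated"] == stats["input"]
        collapsed = collapse_reads(annotated, CollapseConfig(th_bc=0, th_tcr=0))
        truth_abundance = annotate_truth(truth, bundled_tagset)
        n_rec, n_spur, r = score_collapse(collapsed, truth_abundance)
        assert n_rec == len(truth_abundance)
        assert n_spur == 0
        assert r == pytest.approx(1.0)
        by_clf = {t.classifier: t.tcr_count for t in collapsed}
        assert by_clf == truth_abundance
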