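import math

import numpy as np
import pytest

from circverify.annotation import concat_exon_sequence, read_gtf, write_gtf
from circverify.errors import ConfigError
from circverify.simulate import (
    SimConfig,
    apply_errors,
    corrupt_candidates,
    simulate_all,
    simulate_annotation,
    simulate_circ_truth,
    simulate_genome,
    simulate_long_reads,
)


class TestSimConfig:
    def test_profile_must_sum_to_one(self):
        with pytest.raises(ConfigError, match="sum to 1"):
            SimConfig(corruption_profile={"correct": 0.5})

    def test_unknown_mode_rejected(self):
        with pytest.raises(ConfigError, match="unknown corruption"):
            SimConfig(corruption_profile={"bogus": 1.0})

    def test_bad_range_rejected(self):
        with pytest.raises(ConfigError):
            SimConfig(exon_length=(200, 100))

    def test_nonpositive_length_rejected(self):
        with pytest.raises(ConfigError):
            SimConfig(genome_length=0)


class TestSimulateGenome:
    def test_deterministic(self):
        cfg = SimConfig(seed=1, genome_length=1000)
        g1 = simulate_genome(cfg)
        g2 = simulate_genome(cfg)
        assert g1["chr1"] == g2["chr1"]

    def test_gc_degenerate(self):
        cfg = SimConfig(seed=1, genome_length=500, gc_content=1.0)
        assert set(simulate_genome(cfg)["chr1"]) <= {"G", "C"}

    def test_length(self):
        cfg = SimConfig(seed=2, genome_length=1234)
        assert len(simulate_genome(cfg)["chr1"]) == 1234


class TestSimulateAnnotation:
    def test_counts(self):
        cfg = SimConfig(seed=3, n_genes=3, exons_per_gene=(3, 3), genome_length=30_000)
        ann = simulate_annotation(simulate_genome(cfg), cfg)
        assert len(ann) == 3
        assert sum(len(tx.exons) for tx in ann.transcripts.values()) == 9

    def test_deterministic_gtf_text(self, tmp_path):
        cfg = SimConfig(seed=4, n_genes=4, genome_length=40_000)
        texts = []
        for run in range(2):
            ann = simulate_annotation(simulate_genome(cfg), cfg)
            path = tmp_path / f"run{run}.gtf"
            write_gtf(ann, path)
            texts.append(path.read_text())
        assert texts[0] == texts[1]

    def test_exon_counts_within_range(self):
        cfg = SimConfig(
            seed=5, n_genes=100, exons_per_gene=(2, 8), genome_length=2_000_000
        )
        ann = simulate_annotation(simulate_genome(cfg), cfg)
        for tx in ann.transcripts.values():
            assert 2 <= len(tx.exons) <= 8

    def test_genome_too_short(self):
        cfg = SimConfig(seed=6, n_genes=50, genome_length=2_000)
        with pytest.raises(ConfigError, match="too short"):
            simulate_annotation(simulate_genome(cfg), cfg)

    def test_genes_non_overlapping(self):
        cfg = SimConfig(seed=7, n_genes=10, genome_length=100_000)
        ann = simulate_annotation(simulate_genome(cfg), cfg)
        spans = sorted(tx.span for tx in ann.transcripts.values())
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            assert e1 <= s2


class TestSimulateCircTruth:
    def test_sequence_is_chain_concatenation(self):
        cfg = SimConfig(seed=8, n_genes=5, n_circ=10, genome_length=60_000)
        genome = simulate_genome(cfg)
        ann = simulate_annotation(genome, cfg)
        truth = simulate_circ_truth(ann, genome, cfg)
        for t in truth:
            assert t.sequence == concat_exon_sequence(genome, list(t.chain), t.strand)
            assert t.start == t.chain[0].start
            assert t.end == t.chain[-1].end
            assert len(t.sequence) == sum(e.length for e in t.chain)

    def test_distinct_bsjs(self):
        cfg = SimConfig(seed=9, n_genes=8, n_circ=30, genome_length=100_000)
        genome = simulate_genome(cfg)
        ann = simulate_annotation(genome, cfg)
        truth = simulate_circ_truth(ann, genome, cfg)
        bsjs = {(t.chrom, t.start, t.end, t.strand) for t in truth}
        assert len(bsjs) == 30

    def test_too_many_requested(self):
        cfg = SimConfig(seed=10, n_genes=1, exons_per_gene=(2, 2), n_circ=50,
                        genome_length=10_000)
        genome = simulate_genome(cfg)
        ann = simulate_annotation(genome, cfg)
        with pytest.raises(ConfigError, match="boundary pairs"):
            simulate_circ_truth(ann, genome, cfg)


class TestApplyErrors:
    def test_zero_rates_identity(self):
        rng = np.random.default_rng(0)
        assert apply_errors("ACGTACGT", rng, 0, 0, 0) == "ACGTACGT"

    def test_full_substitution_changes_everything(self):
        rng = np.random.default_rng(1)
        seq = "ACGT" * 25
        out = apply_errors(seq, rng, 1.0, 0, 0)
        assert len(out) == len(seq)
        assert all(a != b for a, b in zip(seq, out))

    def test_substitution_rate_within_binomial_error(self):
        rng = np.random.default_rng(2)
        n = 200 * 500
        mismatches = total = 0
        for _ in range(200):
            seq = "".join(rng.choice(list("ACGT"), size=500))
            out = apply_errors(seq, rng, 0.05, 0, 0)
            mismatches += sum(a != b for a, b in zip(seq, out))
            total += len(seq)
        rate = mismatches / total
        se = math.sqrt(0.05 * 0.95 / n)
        assert abs(rate - 0.05) <= 3 * se


class TestSimulateLongReads:
    def test_sanity_mode_exact_copy(self):
        cfg = SimConfig(seed=11, n_genes=5, n_circ=5, n_reads=10,
                        copy_range=(1, 1), genome_length=60_000)
        genome = simulate_genome(cfg)
        ann = simulate_annotation(genome, cfg)
        truth = simulate_circ_truth(ann, genome, cfg)
        reads = simulate_long_reads(truth, ann, cfg)
        by_id = {t.circ_id: t for t in truth}
        for r in reads:
            circ_id, k, offset = r.truth
            circ = by_id[circ_id]
            expected = (circ.sequence[offset:] + circ.sequence[:offset]) * k
            assert r.sequence == expected

    def test_circular_substring_property(self):
        cfg = SimConfig(seed=12, n_genes=5, n_circ=8, n_reads=30, genome_length=60_000)
        genome = simulate_genome(cfg)
        ann = simulate_annotation(genome, cfg)
        truth = simulate_circ_truth(ann, genome, cfg)
        by_id = {t.circ_id: t for t in truth}
        for r in simulate_long_reads(truth, ann, cfg):
            circ = by_id[r.truth[0]]
            k = r.truth[1]
            doubled = circ.sequence * (k + 1)
            assert r.sequence in doubled

    def test_decoy_reads_tagged(self):
        cfg = SimConfig(seed=13, n_genes=5, n_circ=5, n_reads=20,
                        decoy_fraction=0.5, genome_length=60_000)
        genome = simulate_genome(cfg)
        ann = simulate_annotation(genome, cfg)
        truth = simulate_circ_truth(ann, genome, cfg)
        reads = simulate_long_reads(truth, ann, cfg, genome)
        decoys = [r for r in reads if r.read_id.startswith("decoy")]
        assert len(decoys) == 10
        assert all(r.truth[0].startswith("tx") for r in decoys)

    def test_decoys_require_genome(self):
        cfg = SimConfig(seed=13, n_genes=5, n_circ=5, n_reads=20,
                        decoy_fraction=0.5, genome_length=60_000)
        genome = simulate_genome(cfg)
        ann = simulate_annotation(genome, cfg)
        truth = simulate_circ_truth(ann, genome, cfg)
        with pytest.raises(ConfigError, match="genome"):
            simulate_long_reads(truth, ann, cfg)


class TestCorruptCandidates:
    def test_all_correct_profile(self):
        cfg = SimConfig(seed=14, n_genes=5, n_circ=10, genome_length=60_000,
                        corruption_profile={"correct": 1.0})
        res = simulate_all(cfg)
        by_id = {t.circ_id: t for t in res.truth}
        for c in res.candidates:
            assert c.truth_label == "correct"
            assert c.sequence == by_id[f"circ{c.candidate_id[4:]}"].sequence

    def test_exon_skip_length_arithmetic(self, mixed_fixture):
        by_id = {t.circ_id: t for t in mixed_fixture.truth}
        skipped = [c for c in mixed_fixture.candidates if c.truth_label == "exon_skip"]
        assert skipped
        for c in skipped:
            circ = by_id[f"circ{c.candidate_id[4:]}"]
            removed = len(circ.sequence) - len(c.sequence)
            assert removed in {e.length for e in circ.chain[1:-1]}

    def test_one_candidate_per_circ_plus_decoys(self):
        cfg = SimConfig(seed=15, n_genes=5, n_circ=10, genome_length=60_000,
                        n_decoy_candidates=4)
        res = simulate_all(cfg)
        assert len(res.candidates) == 14
        assert sum(1 for c in res.candidates if c.truth_label == "decoy") == 4

    def test_planted_correct_fraction_binomial(self):
        cfg = SimConfig(
            seed=16, n_genes=80, n_circ=500, n_reads=10, genome_length=1_500_000,
            corruption_profile={"correct": 0.6, "exon_skip": 0.1, "truncation": 0.1,
                                "intron_retention": 0.1, "false_bsj": 0.1},
        )
        genome = simulate_genome(cfg)
        ann = simulate_annotation(genome, cfg)
        truth = simulate_circ_truth(ann, genome, cfg)
        cands = corrupt_candidates(truth, ann, genome, cfg)
        frac = sum(1 for c in cands if c.truth_label == "correct") / len(cands)
        se = math.sqrt(0.6 * 0.4 / 500)
        assert abs(frac - 0.6) <= 3 * se

    def test_support_counts_at_least_two(self, mixed_fixture):
        assert all(c.support_reads >= 2 for c in mixed_fixture.candidates)


class TestDeterminism:
    def test_simulate_all_pure_function_of_config(self):
        cfg = SimConfig(seed=17, n_genes=6, n_circ=12, n_reads=40, genome_length=80_000,
                        corruption_profile={"correct": 0.5, "false_bsj": 0.5})
        r1 = simulate_all(cfg)
        r2 = simulate_all(cfg)
        assert [r.sequence for r in r1.reads] == [r.sequence for r in r2.reads]
        assert [c.sequence for c in r1.candidates] == [c.sequence for c in r2.candidates]
        assert [c.support_reads for c in r1.candidates] == [
            c.support_reads for c in r2.candidates
        ]
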