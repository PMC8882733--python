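import numpy as np
import pytest

from _oracles import enumerate_chains
from circverify.annotation import (
    Exon,
    GeneAnnotation,
    Transcript,
    classify_genomic_origin,
    concat_exon_sequence,
    exon_chain_between,
    read_genome_fasta,
    read_gtf,
    reverse_complement,
    write_gtf,
)
from circverify.annotation import GenomeSequence
from circverify.errors import BoundsError, FormatError


class TestReadGenomeFasta:
    def test_case_normalization(self, tmp_path):
        path = tmp_path / "g.fa"
        path.write_text(">chr1\nacgt\n")
        genome = read_genome_fasta(path)
        assert genome.chrom_names == ["chr1"]
        assert genome["chr1"] == "ACGT"

    def test_order_preserved(self, tmp_path):
        path = tmp_path / "g.fa"
        path.write_text(">chrB\nAAAA\n>chrA\nCCCC\n")
        genome = read_genome_fasta(path)
        assert genome.chrom_names == ["chrB", "chrA"]

    def test_duplicate_header_rejected(self, tmp_path):
        path = tmp_path / "g.fa"
        path.write_text(">chr1\nAAAA\n>chr1\nCCCC\n")
        with pytest.raises(FormatError, match="duplicate"):
            read_genome_fasta(path)

    def test_empty_file_rejected(self, tmp_path):
        path = tmp_path / "g.fa"
        path.write_text("")
        with pytest.raises(FormatError):
            read_genome_fasta(path)

    def test_non_nucleotide_rejected(self, tmp_path):
        path = tmp_path / "g.fa"
        path.write_text(">chr1\nACGU\n")
        with pytest.raises(FormatError, match="non-nucleotide"):
            read_genome_fasta(path)


class TestReadGtf:
    def _write(self, tmp_path, lines):
        path = tmp_path / "a.gtf"
        path.write_text("".join(line + "\n" for line in lines))
        return path

    def test_coordinate_conversion(self, tmp_path):
        path = self._write(tmp_path, [
            'chr1\tsrc\texon\t100\t200\t.\t+\t.\tgene_id "g"; transcript_id "t";'
        ])
        ann = read_gtf(path)
        exon = ann.transcripts["t"].exons[0]
        assert (exon.start, exon.end) == (99, 200)

    def test_shuffled_exons_sorted(self, tmp_path):
        rows = [(500, 600), (100, 200), (300, 400)]
        path = self._write(tmp_path, [
            f'chr1\tsrc\texon\t{s}\t{e}\t.\t+\t.\tgene_id "g"; transcript_id "t";'
            for s, e in rows
        ])
        ann = read_gtf(path)
        starts = [e.start for e in ann.transcripts["t"].exons]
        assert starts == sorted(starts) == [99, 299, 499]

    def test_gene_features_only_gives_empty(self, tmp_path, caplog):
        path = self._write(tmp_path, [
            'chr1\tsrc\tgene\t100\t200\t.\t+\t.\tgene_id "g";'
        ])
        ann = read_gtf(path)
        assert len(ann) == 0

    def test_missing_transcript_id_rejected(self, tmp_path):
        path = self._write(tmp_path, [
            'chr1\tsrc\texon\t100\t200\t.\t+\t.\tgene_id "g";'
        ])
        with pytest.raises(FormatError, match="transcript_id"):
            read_gtf(path)

    def test_roundtrip_exact(self, tmp_path, toy_annotation):
        out = tmp_path / "out.gtf"
        write_gtf(toy_annotation, out)
        again = read_gtf(out)
        orig = toy_annotation.transcripts["tx1"].exons
        back = again.transcripts["tx1"].exons
        assert [(e.start, e.end) for e in back] == [(e.start, e.end) for e in orig]


class TestExonChainBetween:
    def test_full_chain(self, toy_annotation):
        chains = exon_chain_between(toy_annotation, "chr1", 100, 600, "+", 0)
        assert len(chains) == 1
        assert len(chains[0]) == 3

    def test_prefix_chain(self, toy_annotation):
        chains = exon_chain_between(toy_annotation, "chr1", 100, 400, "+", 0)
        assert len(chains) == 1
        assert [(e.start, e.end) for e in chains[0]] == [(100, 200), (300, 400)]

    def test_non_boundary_start_empty(self, toy_annotation):
        assert exon_chain_between(toy_annotation, "chr1", 150, 600, "+", 0) == []

    def test_unknown_chromosome_empty(self, toy_annotation):
        assert exon_chain_between(toy_annotation, "chrX", 100, 600, "+", 0) == []

    def test_tolerance_anchoring(self, toy_annotation):
        assert exon_chain_between(toy_annotation, "chr1", 98, 601, "+", 2)

    def test_agrees_with_bruteforce_on_random_annotations(self):
        rng = np.random.default_rng(5)
        transcripts = []
        for t in range(40):
            n = int(rng.integers(1, 6))
            pos = int(rng.integers(0, 500))
            exons = []
            for _ in range(n):
                length = int(rng.integers(10, 50))
                exons.append(Exon("chr1", pos, pos + length, "+"))
                pos += length + int(rng.integers(10, 50))
            transcripts.append(Transcript(f"t{t}", f"g{t}", exons))
        ann = GeneAnnotation(transcripts)
        boundaries = sorted(
            {e.start for tx in transcripts for e in tx.exons}
            | {e.end for tx in transcripts for e in tx.exons}
        )
        for start in boundaries[::3]:
            for end in boundaries[::3]:
                if start >= end:
                    continue
                got = exon_chain_between(ann, "chr1", start, end, "+", 0)
                want = enumerate_chains(ann, "chr1", start, end, "+")
                key = lambda chains: sorted(
                    tuple((e.start, e.end) for e in c) for c in chains
                )
                assert key(got) == key(want)


class TestConcatExonSequence:
    def test_single_exon(self):
        genome = GenomeSequence([("c", "ACGTTT")])
        exon = Exon("c", 0, 4, "+")
        assert concat_exon_sequence(genome, [exon], "+") == "ACGT"

    def test_minus_strand_is_revcomp(self):
        genome = GenomeSequence([("c", "ACGTTTAA")])
        chain = [Exon("c", 0, 2, "-"), Exon("c", 4, 6, "-")]
        fwd = concat_exon_sequence(genome, chain, "+")
        rev = concat_exon_sequence(genome, chain, "-")
        assert fwd == "ACTT"
        assert rev == reverse_complement(fwd) == "AAGT"

    def test_length_equals_sum_of_exons(self, toy_genome, toy_annotation):
        chain = toy_annotation.transcripts["tx1"].exons
        seq = concat_exon_sequence(toy_genome, chain, "+")
        assert len(seq) == sum(e.length for e in chain)

    def test_out_of_bounds_rejected(self):
        genome = GenomeSequence([("c", "ACGT")])
        with pytest.raises(BoundsError):
            concat_exon_sequence(genome, [Exon("c", 0, 10, "+")], "+")


class TestClassifyGenomicOrigin:
    def test_exonic(self, toy_annotation):
        assert classify_genomic_origin(toy_annotation, "chr1", 100, 600, "+") == "exonic"

    def test_intronic(self, toy_annotation):
        assert classify_genomic_origin(toy_annotation, "chr1", 210, 290, "+") == "intronic"

    def test_intergenic(self, toy_annotation):
        assert classify_genomic_origin(toy_annotation, "chrX", 10, 50, "+") == "intergenic"

    def test_partition_is_total(self, toy_annotation):
        rng = np.random.default_rng(0)
        for _ in range(50):
            start = int(rng.integers(0, 650))
            end = start + int(rng.integers(1, 50))
            label = classify_genomic_origin(toy_annotation, "chr1", start, end, "+")
            assert label in {"exonic", "intronic", "intergenic"}
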