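"""Genome and gene-annotation model.

Internal coordinates are 0-based half-open throughout.  GTF input/output
converts from/to the 1-based inclusive convention at the parsing boundary;
BED-style coordinates pass through unchanged.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Iterable

from Bio import SeqIO

from .errors import BoundsError, FormatError

logger = logging.getLogger(__name__)

_VALID_BASES = frozenset("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    """Reverse complement of an uppercase DNA string (N maps to N)."""
    return seq.translate(_COMPLEMENT)[::-1]


class GenomeSequence:
    """An in-memory genome: ordered chromosomes of uppercase DNA.

    Alphabet is restricted to {A, C, G, T, N}; chromosome names are unique.
    """

    def __init__(self, records: Iterable[tuple[str, str]]):
        self.chrom_names: list[str] = []
        self._seqs: dict[str, str] = {}
        for name, seq in records:
            if name in self._seqs:
                raise FormatError(f"duplicate chromosome name: {name!r}")
            seq = seq.upper()
            bad = set(seq) - _VALID_BASES
            if bad:
                raise FormatError(
                    f"chromosome {name!r} contains non-nucleotide characters: {sorted(bad)}"
                )
            self.chrom_names.append(name)
            self._seqs[name] = seq
        if not self.chrom_names:
            raise FormatError("genome contains no sequences")

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._seqs

    def __getitem__(self, chrom: str) -> str:
        return self._seqs[chrom]

    def length(self, chrom: str) -> int:
        return len(self._seqs[chrom])

    def fetch(self, chrom: str, start: int, end: int) -> str:
        """Return the substring [start, end) of a chromosome."""
        if chrom not in self._seqs:
            raise BoundsError(f"unknown chromosome {chrom!r}")
        seq = self._seqs[chrom]
        if start < 0 or end > len(seq) or start > end:
            raise BoundsError(
                f"interval {chrom}:{start}-{end} outside chromosome of length {len(seq)}"
            )
        return seq[start:end]


@dataclass(frozen=True)
class Exon:
    """A genomic exon, 0-based half-open."""

    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise FormatError(f"invalid exon interval [{self.start}, {self.end})")
        if self.strand not in ("+", "-"):
            raise FormatError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class Transcript:
    """A linear transcript: ordered, non-overlapping exons on one chrom/strand."""

    transcript_id: str
    gene_id: str
    exons: list[Exon] = field(default_factory=list)

    def __post_init__(self):
        self.exons = sorted(self.exons, key=lambda e: e.start)
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start < a.end:
                raise FormatError(
                    f"transcript {self.transcript_id}: overlapping exons "
                    f"[{a.start},{a.end}) and [{b.start},{b.end})"
                )
        chroms = {e.chrom for e in self.exons}
        strands = {e.strand for e in self.exons}
        if len(chroms) > 1 or len(strands) > 1:
            raise FormatError(
                f"transcript {self.transcript_id} spans multiple chromosomes/strands"
            )

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def strand(self) -> str:
        return self.exons[0].strand

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0].start, self.exons[-1].end


class GeneAnnotation:
    """Transcripts indexed by id, with per-chromosome gene-span lookups."""

    def __init__(self, transcripts: Iterable[Transcript]):
        self.transcripts: dict[str, Transcript] = {}
        for tx in transcripts:
            if tx.transcript_id in self.transcripts:
                raise FormatError(f"duplicate transcript_id {tx.transcript_id!r}")
            self.transcripts[tx.transcript_id] = tx
        # gene span = hull of all exons sharing a gene_id
        self._gene_spans: dict[str, list[tuple[int, int, str]]] = {}
        by_gene: dict[tuple[str, str], list[Transcript]] = {}
        for tx in self.transcripts.values():
            by_gene.setdefault((tx.gene_id, tx.chrom), []).append(tx)
        for (gene_id, chrom), txs in by_gene.items():
            start = min(t.span[0] for t in txs)
            end = max(t.span[1] for t in txs)
            self._gene_spans.setdefault(chrom, []).append((start, end, gene_id))
        for spans in self._gene_spans.values():
            spans.sort()
        self._by_chrom_strand: dict[tuple[str, str], list[Transcript]] = {}
        for tx in self.transcripts.values():
            self._by_chrom_strand.setdefault((tx.chrom, tx.strand), []).append(tx)

    def __len__(self) -> int:
        return len(self.transcripts)

    def transcripts_on(self, chrom: str, strand: str) -> list[Transcript]:
        return self._by_chrom_strand.get((chrom, strand), [])

    def gene_spans(self, chrom: str) -> list[tuple[int, int, str]]:
        return self._gene_spans.get(chrom, [])


def read_genome_fasta(path) -> GenomeSequence:
    """Load a FASTA genome, uppercasing sequences and preserving record order."""
    records = [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]
    if not records:
        raise FormatError(f"no FASTA records in {path}")
    return GenomeSequence(records)


_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')


def _parse_gtf_attributes(text: str) -> dict[str, str]:
    return dict(_ATTR_RE.findall(text))


def read_gtf(path) -> GeneAnnotation:
    """Parse exon features of a GTF file into a :class:`GeneAnnotation`.

    GTF 1-based inclusive coordinates are converted to 0-based half-open.
    Non-exon features are ignored.
    """
    exons_by_tx: dict[str, list[Exon]] = {}
    gene_by_tx: dict[str, str] = {}
    n_lines = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                raise FormatError(f"{path}:{lineno}: expected 9 GTF columns")
            chrom, _source, feature, start, end, _score, strand, _frame, attrs = fields[:9]
            n_lines += 1
            if feature != "exon":
                continue
            attr = _parse_gtf_attributes(attrs)
            tx_id = attr.get("transcript_id")
            gene_id = attr.get("gene_id")
            if not tx_id:
                raise FormatError(f"{path}:{lineno}: exon without transcript_id")
            if not gene_id:
                raise FormatError(f"{path}:{lineno}: exon without gene_id")
            exon = Exon(chrom=chrom, start=int(start) - 1, end=int(end), strand=strand)
            exons_by_tx.setdefault(tx_id, []).append(exon)
            gene_by_tx[tx_id] = gene_id
    if not exons_by_tx:
        if n_lines:
            logger.warning("%s: no exon features found (%d feature lines)", path, n_lines)
        return GeneAnnotation([])
    return GeneAnnotation(
        Transcript(transcript_id=tx, gene_id=gene_by_tx[tx], exons=exs)
        for tx, exs in exons_by_tx.items()
    )


def write_gtf(annotation: GeneAnnotation, path) -> None:
    """Emit one exon line per exon, converting back to 1-based inclusive."""
    with open(path, "w") as fh:
        for tx_id in sorted(annotation.transcripts):
            tx = annotation.transcripts[tx_id]
            for exon in tx.exons:
                attrs = f'gene_id "{tx.gene_id}"; transcript_id "{tx.transcript_id}";'
                fh.write(
                    "\t".join(
                        [
                            exon.chrom,
                            "circverify",
                            "exon",
                            str(exon.start + 1),
                            str(exon.end),
                            ".",
                            exon.strand,
                            ".",
                            attrs,
                        ]
                    )
                    + "\n"
                )


def exon_chain_between(
    annotation: GeneAnnotation,
    chrom: str,
    bsj_start: int,
    bsj_end: int,
    strand: str,
    tolerance_bp: int = 0,
) -> list[list[Exon]]:
    """All per-transcript runs of consecutive exons anchored at both BSJ ends.

    For each transcript on (chrom, strand), returns exons[i..j] where exon i's
    start matches ``bsj_start`` and exon j's end matches ``bsj_end`` within
    ``tolerance_bp``.  Transcripts failing to anchor both ends contribute
    nothing; an unknown chromosome yields an empty list.
    """
    if bsj_start >= bsj_end:
        raise BoundsError(f"invalid BSJ interval [{bsj_start}, {bsj_end})")
    if tolerance_bp < 0:
        raise BoundsError("tolerance_bp must be >= 0")
    chains: list[list[Exon]] = []
    for tx in annotation.transcripts_on(chrom, strand):
        i = next(
            (k for k, e in enumerate(tx.exons) if abs(e.start - bsj_start) <= tolerance_bp),
            None,
        )
        if i is None:
            continue
        j = next(
            (
                k
                for k in range(len(tx.exons) - 1, -1, -1)
                if abs(tx.exons[k].end - bsj_end) <= tolerance_bp
            ),
            None,
        )
        if j is None or j < i:
            continue
        chains.append(tx.exons[i : j + 1])
    return chains


def concat_exon_sequence(genome: GenomeSequence, chain: list[Exon], strand: str) -> str:
    """Concatenate exon substrings in genomic order; reverse-complement for '-'."""
    if not chain:
        raise BoundsError("empty exon chain")
    chroms = {e.chrom for e in chain}
    if len(chroms) > 1:
        raise BoundsError("exon chain spans multiple chromosomes")
    seq = "".join(genome.fetch(e.chrom, e.start, e.end) for e in sorted(chain, key=lambda e: e.start))
    return reverse_complement(seq) if strand == "-" else seq


def classify_genomic_origin(
    annotation: GeneAnnotation,
    chrom: str,
    start: int,
    end: int,
    strand: str,
    tolerance_bp: int = 0,
) -> str:
    """Classify a BSJ interval as ``exonic``, ``intronic`` or ``intergenic``.

    Exonic: both endpoints coincide (within tolerance) with exon boundaries of
    one transcript on the same strand.  Intronic: the interval lies within a
    gene span but is not exonic.  Intergenic otherwise.
    """
    if exon_chain_between(annotation, chrom, start, end, strand, tolerance_bp):
        return "exonic"
    for g_start, g_end, _gene in annotation.gene_spans(chrom):
        if g_start <= start and end <= g_end:
            return "intronic"
    return "intergenic"
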