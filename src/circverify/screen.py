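"""Exon-chain structure classification and full-exon screening.

An exonic candidate whose sequence equals the complete annotated exon chain
between its back-splice sites is classed by chain length — one exon, two
adjacent exons, or three or more exons.  Everything else that anchors both
BSJ ends is partial/uncertain; candidates whose BSJ is not exonic are
non-exonic.  Screening retains only the full-chain classes.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from typing import Sequence

from .annotation import (
    GeneAnnotation,
    GenomeSequence,
    classify_genomic_origin,
    concat_exon_sequence,
    exon_chain_between,
)
from .rotation import CircCandidate

logger = logging.getLogger(__name__)

TYPE1 = "type1_single_exon_full"
TYPE2 = "type2_two_exons_full"
TYPE3 = "type3_multi_exon_full"
PARTIAL = "partial_or_uncertain"
NON_EXONIC = "non_exonic"

FULL_CHAIN_LABELS = frozenset({TYPE1, TYPE2, TYPE3})


@dataclass(frozen=True)
class StructureCall:
    candidate_id: str
    label: str
    matched_transcript_chain_len: int | None = None


def _edit_distance_leq(a: str, b: str, limit: int) -> bool:
    """Banded Levenshtein check: edit distance <= limit."""
    if abs(len(a) - len(b)) > limit:
        return False
    if limit == 0:
        return a == b
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        cur = [i]
        row_min = i
        for j, cb in enumerate(b, 1):
            v = min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + (ca != cb))
            cur.append(v)
            row_min = min(row_min, v)
        if row_min > limit:
            return False
        prev = cur
    return prev[-1] <= limit


def classify_structure(
    candidate: CircCandidate,
    annotation: GeneAnnotation,
    genome: GenomeSequence,
    tolerance_bp: int = 0,
    max_sequence_edits: int = 0,
) -> StructureCall:
    """Classify one candidate against annotated exon chains between its BSJ.

    A chain matches when its concatenated (strand-aware) sequence equals the
    candidate sequence exactly, or within ``max_sequence_edits`` Levenshtein
    edits when that is positive.  Any matching chain on any transcript
    suffices; multi-isoform genes therefore pass on any isoform.
    """
    origin = classify_genomic_origin(
        annotation,
        candidate.chrom,
        candidate.start,
        candidate.end,
        candidate.strand,
        tolerance_bp,
    )
    if origin != "exonic":
        return StructureCall(candidate.candidate_id, NON_EXONIC)
    chains = exon_chain_between(
        annotation,
        candidate.chrom,
        candidate.start,
        candidate.end,
        candidate.strand,
        tolerance_bp,
    )
    for chain in chains:
        expected = concat_exon_sequence(genome, chain, candidate.strand)
        if max_sequence_edits == 0:
            ok = expected == candidate.sequence
        else:
            ok = _edit_distance_leq(expected, candidate.sequence, max_sequence_edits)
        if ok:
            n = len(chain)
            label = TYPE1 if n == 1 else TYPE2 if n == 2 else TYPE3
            return StructureCall(candidate.candidate_id, label, n)
    return StructureCall(candidate.candidate_id, PARTIAL)


def screen_full_exon(
    candidates: Sequence[CircCandidate],
    annotation: GeneAnnotation,
    genome: GenomeSequence,
    tolerance_bp: int = 0,
    max_sequence_edits: int = 0,
) -> tuple[list[CircCandidate], list[StructureCall]]:
    """Retain candidates whose sequence is a complete exon chain.

    Returns (retained candidates, all structure calls).  Retained/discarded
    counts are logged per assembly-tool label.
    """
    calls = [
        classify_structure(c, annotation, genome, tolerance_bp, max_sequence_edits)
        for c in candidates
    ]
    retained = [
        c for c, call in zip(candidates, calls) if call.label in FULL_CHAIN_LABELS
    ]
    kept = Counter(c.asm_tool for c in retained)
    total = Counter(c.asm_tool for c in candidates)
    for tool in sorted(total):
        logger.info(
            "screen_full_exon[%s]: retained %d / %d candidates",
            tool or "<unlabeled>",
            kept.get(tool, 0),
            total[tool],
        )
    return retained, calls
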