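"""Read-based validation of assembled circRNA sequences (rotation strategy).

Each candidate sequence is rotated so the back-splice junction becomes
internal, long reads are aligned against the rotated reference, and
alignments are filtered by mapped_ratio (default 0.8..1.0) and total edit
bases (default <= 2).  A candidate is verified when enough alignments
survive the filters.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

from .alignment import AlignmentRecord, BuiltinAligner
from .errors import CircVerifyError

logger = logging.getLogger(__name__)

STRATEGY_ROTATION = "rotation"

DEFAULT_ROTATION_BP = 20
DEFAULT_MIN_RATIO = 0.8
DEFAULT_MAX_RATIO = 1.0
DEFAULT_MAX_EDIT_BP = 2


@dataclass(frozen=True)
class CircCandidate:
    """One assembled full-length circRNA candidate."""

    candidate_id: str
    chrom: str
    start: int
    end: int
    strand: str
    sequence: str
    support_reads: int = 0
    ident_tool: str = ""
    asm_tool: str = ""
    truth_label: str | None = None

    def __post_init__(self):
        if not self.sequence:
            raise ValueError(f"candidate {self.candidate_id}: empty sequence")
        if self.start >= self.end:
            raise ValueError(f"candidate {self.candidate_id}: start >= end")
        if self.support_reads < 0:
            raise ValueError(f"candidate {self.candidate_id}: negative support")

    @property
    def bsj_key(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}:{self.strand}"


@dataclass(frozen=True)
class Verdict:
    """Per-candidate boolean outcome of one evaluation strategy."""

    candidate_id: str
    strategy: str
    verified: bool
    support: int = 0
    best_ratio: float | None = None
    unverifiable: bool = False


def rotate_sequence(sequence: str, k: int) -> str:
    """Move the first ``k`` bases to the end: sequence[k:] + sequence[:k].

    After rotation the back-splice junction (originally between the last and
    first base of the circular sequence) lies ``k`` bases before the end.
    """
    if k < 0:
        raise CircVerifyError(f"rotation amount must be >= 0, got {k}")
    if len(sequence) <= k:
        raise CircVerifyError(
            f"cannot rotate sequence of length {len(sequence)} by {k}"
        )
    return sequence[k:] + sequence[:k]


def mapped_ratio(record: AlignmentRecord, L: int) -> float:
    """mapped_ratio = M / L with M the read bases aligned and L the candidate length."""
    if L <= 0:
        raise CircVerifyError(f"candidate length must be positive, got {L}")
    return record.query_aligned_bases / L


def passes_filters(
    record: AlignmentRecord,
    L: int,
    min_ratio: float = DEFAULT_MIN_RATIO,
    max_ratio: float = DEFAULT_MAX_RATIO,
    max_edit_bp: int = DEFAULT_MAX_EDIT_BP,
    per_category_edits: bool = False,
) -> bool:
    """Alignment filter: min_ratio <= M/L <= max_ratio and edits <= max_edit_bp.

    Boundary values pass (only strictly out-of-range records are discarded).
    ``per_category_edits`` switches the edit rule from a total over
    mismatch+insertion+deletion bases to a per-category cap.
    """
    ratio = mapped_ratio(record, L)
    if ratio < min_ratio or ratio > max_ratio:
        return False
    if per_category_edits:
        return (
            record.mismatches <= max_edit_bp
            and record.inserted_bases <= max_edit_bp
            and record.deleted_bases <= max_edit_bp
        )
    return record.total_edits <= max_edit_bp


DEFAULT_JUNCTION_MARGIN = 12


def _spans_junction(
    record: AlignmentRecord, rotated_len: int, rotation_bp: int, margin: int
) -> bool:
    # After rotation by k the junction sits between positions L-k-1 and L-k.
    # A margin well above the edit allowance is required on both sides so a
    # few chance-matched bases cannot fake a junction crossing.
    junction = rotated_len - rotation_bp
    lo = max(junction - margin, 0)
    hi = min(junction + margin, rotated_len)
    return record.ref_start <= lo and record.ref_end >= hi


def validate_by_reads(
    candidates: Sequence[CircCandidate],
    reads: Iterable[tuple[str, str]],
    aligner=None,
    rotation_bp: int = DEFAULT_ROTATION_BP,
    min_ratio: float = DEFAULT_MIN_RATIO,
    max_ratio: float = DEFAULT_MAX_RATIO,
    max_edit_bp: int = DEFAULT_MAX_EDIT_BP,
    min_support: int = 1,
    per_category_edits: bool = False,
    require_junction_span: bool = False,
    junction_span_margin: int = DEFAULT_JUNCTION_MARGIN,
) -> list[Verdict]:
    """Rotation-based verdict for every candidate.

    ``reads`` yields (read_id, sequence) pairs.  ``aligner`` is an object
    with ``map(read_id, seq) -> list[AlignmentRecord]`` built over the
    rotated candidate references; when None a :class:`BuiltinAligner` is
    constructed.  Candidates shorter than ``rotation_bp`` + 1 cannot be
    rotated and are reported as unverifiable.
    """
    if min_support < 1:
        raise CircVerifyError("min_support must be >= 1")
    rotated: dict[str, str] = {}
    unverifiable: list[str] = []
    by_id: dict[str, CircCandidate] = {}
    for cand in candidates:
        if cand.candidate_id in by_id:
            raise CircVerifyError(f"duplicate candidate_id {cand.candidate_id!r}")
        by_id[cand.candidate_id] = cand
        if len(cand.sequence) <= rotation_bp:
            logger.warning(
                "candidate %s shorter than rotation amount (%d <= %d): unverifiable",
                cand.candidate_id,
                len(cand.sequence),
                rotation_bp,
            )
            unverifiable.append(cand.candidate_id)
            continue
        rotated[cand.candidate_id] = rotate_sequence(cand.sequence, rotation_bp)
    if aligner is None:
        aligner = BuiltinAligner(rotated)
    support: dict[str, int] = {cid: 0 for cid in rotated}
    best_ratio: dict[str, float | None] = {cid: None for cid in rotated}
    n_records = n_pass = 0
    for read_id, seq in reads:
        for rec in aligner.map(read_id, seq):
            if rec.ref_id not in rotated:
                continue
            n_records += 1
            cand = by_id[rec.ref_id]
            L = len(cand.sequence)
            ratio = mapped_ratio(rec, L)
            prev = best_ratio[rec.ref_id]
            if prev is None or abs(ratio - 1.0) < abs(prev - 1.0):
                best_ratio[rec.ref_id] = ratio
            if not passes_filters(
                rec, L, min_ratio, max_ratio, max_edit_bp, per_category_edits
            ):
                continue
            if require_junction_span and not _spans_junction(
                rec, L, rotation_bp, junction_span_margin
            ):
                continue
            n_pass += 1
            support[rec.ref_id] += 1
    logger.info(
        "rotation validation: %d candidates (%d unverifiable), %d alignment "
        "records, %d passed filters",
        len(by_id),
        len(unverifiable),
        n_records,
        n_pass,
    )
    verdicts = []
    for cand in candidates:
        cid = cand.candidate_id
        if cid in rotated:
            verdicts.append(
                Verdict(
                    candidate_id=cid,
                    strategy=STRATEGY_ROTATION,
                    verified=support[cid] >= min_support,
                    support=support[cid],
                    best_ratio=best_ratio[cid],
                )
            )
        else:
            verdicts.append(
                Verdict(
                    candidate_id=cid,
                    strategy=STRATEGY_ROTATION,
                    verified=False,
                    support=0,
                    unverifiable=True,
                )
            )
    return verdicts
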