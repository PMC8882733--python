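"""Validation by matching against reference full-length isoform sets.

Strategies built on external long-read reconstructions (or the synthetic
truth set) share one engine: a candidate is verified when some reference
isoform agrees on the back-splice junction (within a bp tolerance) and the
rotation-maximized sequence identity reaches a threshold.

Identity between two circular sequences a, b is
``max over rotations r of b:  matches(a, r(b)) / max(|a|, |b|)``
with matches(x, y) the longest common subsequence — the match count of a
global alignment that scores matches only.  The metric is symmetric, lies
in [0, 1] and equals 1.0 exactly when a and b are rotations of each other.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

from .rotation import CircCandidate, Verdict

logger = logging.getLogger(__name__)

STRATEGY_ISOFORM = "isoform"

DEFAULT_IDENTITY_THRESHOLD = 0.95


@dataclass(frozen=True)
class ReferenceIsoform:
    """One reference full-length circRNA isoform."""

    isoform_id: str
    chrom: str
    start: int
    end: int
    strand: str
    sequence: str

    def __post_init__(self):
        if not self.sequence:
            raise ValueError(f"isoform {self.isoform_id}: empty sequence")


def _lcs_length(a: str, b: str) -> int:
    """Longest common subsequence length, O(|a|*|b|) rolling rows."""
    if not a or not b:
        return 0
    prev = [0] * (len(b) + 1)
    for ca in a:
        cur = [0]
        append = cur.append
        best = 0
        for j, cb in enumerate(b, 1):
            if ca == cb:
                v = prev[j - 1] + 1
            else:
                v = prev[j] if prev[j] >= best else best
            if v > best:
                best = v
            append(v)
        prev = cur
    return prev[-1]


def circular_identity(seq_a: str, seq_b: str) -> float:
    """Rotation-maximized global-alignment identity in [0, 1]."""
    if not seq_a or not seq_b:
        raise ValueError("sequences must be nonempty")
    la, lb = len(seq_a), len(seq_b)
    denom = max(la, lb)
    if la == lb and seq_b in seq_a + seq_a:
        return 1.0
    best = 0
    doubled = seq_b + seq_b
    for r in range(lb):
        rot = doubled[r : r + lb]
        score = _lcs_length(seq_a, rot)
        if score > best:
            best = score
            if best == min(la, lb):
                break  # cannot improve further
    return best / denom


def match_candidate(
    candidate: CircCandidate,
    reference_set: Sequence[ReferenceIsoform],
    identity_threshold: float = DEFAULT_IDENTITY_THRESHOLD,
    bsj_tolerance_bp: int = 0,
    strategy: str = STRATEGY_ISOFORM,
) -> Verdict:
    """Verdict for one candidate against a reference isoform set.

    The BSJ gate (same chrom/strand, endpoints within ``bsj_tolerance_bp``)
    is applied before any sequence comparison.  A cheap length-ratio upper
    bound on identity skips the rotation scan when it cannot reach the
    threshold.
    """
    if not 0 < identity_threshold <= 1:
        raise ValueError("identity_threshold must be in (0, 1]")
    support = 0
    for iso in reference_set:
        if iso.chrom != candidate.chrom or iso.strand != candidate.strand:
            continue
        if (
            abs(iso.start - candidate.start) > bsj_tolerance_bp
            or abs(iso.end - candidate.end) > bsj_tolerance_bp
        ):
            continue
        la, lb = len(candidate.sequence), len(iso.sequence)
        if min(la, lb) / max(la, lb) < identity_threshold:
            continue  # identity <= length ratio
        if circular_identity(candidate.sequence, iso.sequence) >= identity_threshold:
            support += 1
    return Verdict(
        candidate_id=candidate.candidate_id,
        strategy=strategy,
        verified=support > 0,
        support=support,
    )


def validate_by_isoforms(
    candidates: Iterable[CircCandidate],
    reference_set: Sequence[ReferenceIsoform],
    identity_threshold: float = DEFAULT_IDENTITY_THRESHOLD,
    bsj_tolerance_bp: int = 0,
    strategy: str = STRATEGY_ISOFORM,
) -> list[Verdict]:
    """Verdicts for a candidate set against one reference isoform set."""
    if not reference_set:
        logger.warning("empty reference isoform set: nothing can be verified")
    return [
        match_candidate(c, reference_set, identity_threshold, bsj_tolerance_bp, strategy)
        for c in candidates
    ]
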