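"""Read-to-reference alignment: built-in local aligner and SAM adapter.

The built-in aligner is a seed-and-extend banded Smith-Waterman with unit
costs (match +1, mismatch/indel -1).  It exists so synthetic pipelines run
without an external aligner; exactness is guaranteed only within the band
around seed diagonals (verified against a full-DP oracle in the test suite).

"Mapped bases" (M of mapped_ratio) are read bases consumed by
match/mismatch/insertion columns — the read-side count, not the reference
span.  A reference-side count is available via ``AlignmentRecord.ref_span``.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pysam

from .errors import FormatError

logger = logging.getLogger(__name__)

# traceback pointer codes
_STOP, _DIAG, _UP, _LEFT = 0, 1, 2, 3


@dataclass(frozen=True)
class AlignmentRecord:
    """One read-to-reference local alignment with per-category edit counts."""

    query_id: str
    ref_id: str
    query_aligned_bases: int  # read bases in match/mismatch/insertion columns
    ref_start: int
    ref_end: int
    mismatches: int
    inserted_bases: int
    deleted_bases: int
    score: int = 0
    query_start: int = -1
    query_end: int = -1

    def __post_init__(self):
        if min(
            self.query_aligned_bases,
            self.mismatches,
            self.inserted_bases,
            self.deleted_bases,
        ) < 0:
            raise ValueError("alignment counts must be non-negative")
        if self.query_aligned_bases < self.mismatches:
            raise ValueError("query_aligned_bases must be >= mismatches")

    @property
    def total_edits(self) -> int:
        return self.mismatches + self.inserted_bases + self.deleted_bases

    @property
    def ref_span(self) -> tuple[int, int]:
        return self.ref_start, self.ref_end


def _banded_core(q, r, d0, band):  # pragma: no cover - exercised via wrapper
    """Banded local-alignment core in diagonal coordinates (numba-friendly).

    Cells (i, j) with |i - j - d0| <= band are stored at column
    w = j - i + d0 + band of row i.  Transitions: diagonal keeps w, a read
    gap (deletion) moves to w+1 within the row, a reference gap (insertion)
    moves to w-1 of the previous row.  Cell preference on score ties is
    diagonal > up (insertion) > left (deletion) > stop; the best cell is
    the first maximum in (i, j) scan order.

    Returns int64[7]: score, matches, mismatches, ins, dels, ref_start,
    ref_end (score 0 means no positive-scoring alignment).
    """
    n = q.shape[0]
    m = r.shape[0]
    W = 2 * band + 1
    H = np.zeros((n + 1, W), dtype=np.int32)
    P = np.zeros((n + 1, W), dtype=np.int8)
    neg = -(1 << 30)
    best_score = 0
    best_i = -1
    best_w = -1
    row_lo = d0 - band + 1 if d0 - band + 1 > 1 else 1
    row_hi = d0 + m + band if d0 + m + band < n else n
    for i in range(row_lo, row_hi + 1):
        qi = q[i - 1]
        for w in range(W):
            j = i - d0 + w - band
            if j < 1 or j > m:
                continue
            # diagonal (i-1, j-1): same w
            if i == 1 or j == 1:
                diag_prev = 0
            else:
                diag_prev = H[i - 1, w]
            if qi == r[j - 1]:
                diag = diag_prev + 1
            else:
                diag = diag_prev - 1
            # up (i-1, j): w+1 in previous row
            if i == 1:
                up = -1
            elif w + 1 < W:
                up = H[i - 1, w + 1] - 1
            else:
                up = neg
            # left (i, j-1): w-1 in same row
            if j == 1:
                left = -1
            elif w - 1 >= 0:
                left = H[i, w - 1] - 1
            else:
                left = neg
            score = 0
            ptr = 0
            if diag > score:
                score = diag
                ptr = 1
            if up > score:
                score = up
                ptr = 2
            if left > score:
                score = left
                ptr = 3
            H[i, w] = score
            P[i, w] = ptr
            if score > best_score:
                best_score = score
                best_i = i
                best_w = w
    out = np.zeros(9, dtype=np.int64)
    if best_score <= 0:
        return out
    i = best_i
    w = best_w
    j = i - d0 + w - band
    ref_end = j
    query_end = i
    matches = 0
    mismatches = 0
    ins = 0
    dels = 0
    while i > 0 and j > 0 and H[i, w] > 0:
        ptr = P[i, w]
        if ptr == 1:
            if q[i - 1] == r[j - 1]:
                matches += 1
            else:
                mismatches += 1
            i -= 1
            j -= 1
        elif ptr == 2:
            ins += 1
            i -= 1
            w += 1
        elif ptr == 3:
            dels += 1
            j -= 1
            w -= 1
        else:
            break
    out[0] = best_score
    out[1] = matches
    out[2] = mismatches
    out[3] = ins
    out[4] = dels
    out[5] = j
    out[6] = ref_end
    out[7] = i
    out[8] = query_end
    return out


try:  # numba speeds the core up ~100x; the plain function remains the fallback
    from numba import njit

    _banded_core_fast = njit(cache=True)(_banded_core)
except Exception:  # pragma: no cover
    _banded_core_fast = _banded_core


def _encode(s: str) -> np.ndarray:
    return np.frombuffer(s.encode("ascii"), dtype=np.uint8)


def _banded_local_dp(q: str, r: str, d0: int, band: int) -> tuple | None:
    """Best local alignment within ``|i - j - d0| <= band`` (see _banded_core).

    Returns (score, matches, mismatches, ins, dels, ref_start, ref_end,
    query_start, query_end) or None.
    """
    out = _banded_core_fast(_encode(q), _encode(r), d0, band)
    if out[0] <= 0:
        return None
    return tuple(int(x) for x in out)


def _cluster_diagonals(diags: list[int], merge_gap: int) -> list[tuple[int, int]]:
    """Group sorted unique diagonals into (center, extra_halfwidth) clusters."""
    out = []
    uniq = sorted(set(diags))
    group = [uniq[0]]
    for d in uniq[1:]:
        if d - group[-1] <= merge_gap:
            group.append(d)
        else:
            out.append(group)
            group = [d]
    out.append(group)
    return [((g[0] + g[-1]) // 2, (g[-1] - g[0] + 1) // 2 + 1) for g in out]


class BuiltinAligner:
    """Seed-and-extend local aligner over a fixed set of references.

    Parameters mirror the scale of the synthetic pipeline: references are
    full-length (rotated) circRNA candidates of a few hundred bp and queries
    are rolling-circle long reads.
    """

    def __init__(
        self,
        references: Mapping[str, str],
        seed_len: int = 11,
        band: int = 12,
        max_edit_fraction: float = 0.3,
        max_band: int = 60,
    ):
        self.references = dict(references)
        self.seed_len = seed_len
        self.band = band
        self.max_edit_fraction = max_edit_fraction
        self.max_band = max_band
        self._index: dict[str, list[tuple[str, int]]] = {}
        k = seed_len
        for ref_id, seq in self.references.items():
            for pos in range(0, len(seq) - k + 1):
                self._index.setdefault(seq[pos : pos + k], []).append((ref_id, pos))

    def map(self, query_id: str, read: str) -> list[AlignmentRecord]:
        """All passing local alignments of ``read`` against the references."""
        k = self.seed_len
        hits: dict[str, list[int]] = {}
        for qpos in range(0, len(read) - k + 1):
            for ref_id, rpos in self._index.get(read[qpos : qpos + k], ()):
                hits.setdefault(ref_id, []).append(qpos - rpos)
        records: list[AlignmentRecord] = []
        for ref_id, diags in hits.items():
            ref = self.references[ref_id]
            seen: set[tuple] = set()
            for d0, extra in _cluster_diagonals(diags, self.band):
                band = min(self.band + extra, self.max_band)
                rec = self._align_cluster(query_id, read, ref_id, ref, d0, band)
                if rec is None:
                    continue
                key = (rec.query_start, rec.query_end, rec.ref_start, rec.ref_end,
                       rec.score)
                if key not in seen:
                    seen.add(key)
                    records.append(rec)
        records.sort(key=lambda r: (-r.score, r.ref_id, r.ref_start))
        return records

    def _align_cluster(
        self, query_id: str, read: str, ref_id: str, ref: str, d0: int, band: int
    ) -> AlignmentRecord | None:
        m = len(ref)
        # fast path: perfect full-reference match on this diagonal
        for d in range(d0 - band, d0 + band + 1):
            if 0 <= d <= len(read) - m and read[d : d + m] == ref:
                return AlignmentRecord(
                    query_id=query_id,
                    ref_id=ref_id,
                    query_aligned_bases=m,
                    ref_start=0,
                    ref_end=m,
                    mismatches=0,
                    inserted_bases=0,
                    deleted_bases=0,
                    score=m,
                    query_start=d,
                    query_end=d + m,
                )
        result = _banded_local_dp(read, ref, d0, band)
        if result is None:
            return None
        score, matches, mismatches, ins, dels, ref_start, ref_end, q_start, q_end = result
        aligned = matches + mismatches + ins
        if aligned == 0:
            return None
        edits = mismatches + ins + dels
        if edits / aligned > self.max_edit_fraction:
            return None
        return AlignmentRecord(
            query_id=query_id,
            ref_id=ref_id,
            query_aligned_bases=aligned,
            ref_start=ref_start,
            ref_end=ref_end,
            mismatches=mismatches,
            inserted_bases=ins,
            deleted_bases=dels,
            score=score,
            query_start=q_start,
            query_end=q_end,
        )


def align_local(
    read: str,
    reference: str,
    max_edit_fraction: float = 0.3,
    seed_len: int = 11,
    band: int = 12,
) -> list[AlignmentRecord]:
    """Align one read against one reference (see :class:`BuiltinAligner`)."""
    if not read or not reference:
        raise ValueError("read and reference must be nonempty")
    aligner = BuiltinAligner(
        {"ref": reference},
        seed_len=seed_len,
        band=band,
        max_edit_fraction=max_edit_fraction,
    )
    return aligner.map("query", read)


_MD_DEL_RE = re.compile(r"\^[A-Za-z]+")


def _mismatches_from_md(md: str) -> int:
    """Number of mismatch columns encoded in an MD tag."""
    no_dels = _MD_DEL_RE.sub("", md)
    return sum(1 for c in no_dels if c.isalpha())


def parse_alignment_file(
    path, references: Mapping[str, int] | None = None
) -> list[AlignmentRecord]:
    """Read mapped SAM records into :class:`AlignmentRecord` objects.

    query_aligned_bases = sum of M/=/X/I CIGAR lengths (clips excluded);
    mismatches come from NM minus indel bases, or from the MD tag when NM is
    absent.  Unmapped records are skipped; a mapped record with CIGAR '*' is
    skipped with a warning; a record with neither NM nor MD raises.
    """
    records: list[AlignmentRecord] = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for aln in sam:
            if aln.is_unmapped:
                continue
            if aln.cigartuples is None:
                logger.warning("mapped record %s has CIGAR '*'; skipped", aln.query_name)
                continue
            aligned = ins = dels = 0
            for op, length in aln.cigartuples:
                if op in (0, 7, 8):  # M, =, X
                    aligned += length
                elif op == 1:  # I
                    aligned += length
                    ins += length
                elif op == 2:  # D
                    dels += length
            if aln.has_tag("NM"):
                nm = aln.get_tag("NM")
                mismatches = nm - ins - dels
                if mismatches < 0:
                    raise FormatError(
                        f"record {aln.query_name}: NM={nm} smaller than indel bases"
                    )
            elif aln.has_tag("MD"):
                mismatches = _mismatches_from_md(str(aln.get_tag("MD")))
            else:
                raise FormatError(
                    f"record {aln.query_name}: neither NM nor MD tag present"
                )
            ref_id = aln.reference_name
            rec = AlignmentRecord(
                query_id=aln.query_name,
                ref_id=ref_id,
                query_aligned_bases=aligned,
                ref_start=aln.reference_start,
                ref_end=aln.reference_end,
                mismatches=mismatches,
                inserted_bases=ins,
                deleted_bases=dels,
            )
            if references is not None and ref_id in references:
                if rec.ref_end > references[ref_id]:
                    raise FormatError(
                        f"record {aln.query_name}: alignment beyond reference end"
                    )
            records.append(rec)
    return records


class SamAligner:
    """Adapter presenting a pre-computed SAM file through the aligner interface."""

    def __init__(self, path, references: Mapping[str, int] | None = None):
        self._by_query: dict[str, list[AlignmentRecord]] = {}
        for rec in parse_alignment_file(path, references):
            self._by_query.setdefault(rec.query_id, []).append(rec)

    def map(self, query_id: str, read: str) -> list[AlignmentRecord]:
        return self._by_query.get(query_id, [])


def make_aligner(spec: str, references: Mapping[str, str]):
    """Build an aligner from a CLI spec: ``builtin`` or ``sam:<path>``."""
    if spec == "builtin":
        return BuiltinAligner(references)
    if spec.startswith("sam:"):
        lengths = {name: len(seq) for name, seq in references.items()}
        return SamAligner(spec[4:], lengths)
    raise ValueError(f"unknown aligner spec {spec!r}")
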