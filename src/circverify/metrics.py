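"""Ensemble verdicts, cross-strategy confusion counts and benchmark metrics.

Cross-strategy definitions: for an assembly strategy S,
TP = candidates of S verified by long reads, FP = candidates of S not
verified, FN = candidates verified under any OTHER strategy that S did not
assemble at all.  Candidates are compared across strategies by an identity
key (default: BSJ coordinates + strand).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

from .errors import ConsistencyError
from .rotation import CircCandidate, Verdict


@dataclass(frozen=True)
class ConfusionCounts:
    strategy: str
    tp: int
    fp: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")


@dataclass
class MetricsReport:
    """Per-strategy precision/sensitivity/F1 plus auxiliary summaries."""

    per_strategy: dict[str, dict[str, float]] = field(default_factory=dict)
    assembly_rate: float | None = None
    stratified_precision: list[tuple[int, float | None, int]] = field(default_factory=list)

    def as_dict(self) -> dict:
        return {
            "per_strategy": self.per_strategy,
            "assembly_rate": self.assembly_rate,
            "stratified_precision": [
                {"min_support": t, "precision": p, "n": n}
                for t, p, n in self.stratified_precision
            ],
        }


def ensemble_verdict(per_strategy_verdicts: Sequence[bool], k: int) -> bool:
    """True iff at least ``k`` of the strategy verdicts are positive."""
    if not per_strategy_verdicts:
        raise ValueError("empty verdict list")
    if not 1 <= k <= len(per_strategy_verdicts):
        raise ValueError(
            f"k must be in [1, {len(per_strategy_verdicts)}], got {k}"
        )
    return sum(bool(v) for v in per_strategy_verdicts) >= k


def combine_verdicts(
    verdicts_by_strategy: Mapping[str, Sequence[Verdict]], k: int
) -> dict[str, bool]:
    """Per-candidate k-of-n combination of several validation strategies.

    Candidates missing from a strategy's verdict list count as not verified
    for that strategy.
    """
    all_ids: list[str] = []
    seen = set()
    for verdicts in verdicts_by_strategy.values():
        for v in verdicts:
            if v.candidate_id not in seen:
                seen.add(v.candidate_id)
                all_ids.append(v.candidate_id)
    lookup = {
        name: {v.candidate_id: v.verified for v in verdicts}
        for name, verdicts in verdicts_by_strategy.items()
    }
    return {
        cid: ensemble_verdict(
            [lookup[name].get(cid, False) for name in verdicts_by_strategy], k
        )
        for cid in all_ids
    }


def strategy_overlap(
    verdicts_by_strategy: Mapping[str, Sequence[Verdict]]
) -> dict[str, int]:
    """Venn-style region sizes over the strategies' verified candidate sets.

    Region keys are '&'-joined sorted strategy names; each candidate is
    counted once, in the region of exactly the strategies that verified it.
    """
    verified_by: dict[str, set[str]] = {}
    for name, verdicts in verdicts_by_strategy.items():
        for v in verdicts:
            if v.verified:
                verified_by.setdefault(v.candidate_id, set()).add(name)
    regions: dict[str, int] = {}
    for members in verified_by.values():
        key = "&".join(sorted(members))
        regions[key] = regions.get(key, 0) + 1
    return dict(sorted(regions.items()))


def confusion_counts(
    assembled_sets: Mapping[str, Iterable],
    verified_sets: Mapping[str, Iterable],
) -> list[ConfusionCounts]:
    """Cross-strategy TP/FP/FN under the other-strategies-as-FN-universe rule.

    ``assembled_sets`` maps strategy -> candidate keys it produced;
    ``verified_sets`` maps strategy -> the verified subset.  Keys must
    already be identity keys (e.g. BSJ strings).
    """
    assembled = {s: set(v) for s, v in assembled_sets.items()}
    verified = {s: set(v) for s, v in verified_sets.items()}
    out = []
    for strategy, asm in assembled.items():
        ver = verified.get(strategy, set())
        if not ver <= asm:
            raise ConsistencyError(
                f"strategy {strategy!r}: verified set is not a subset of assembled set"
            )
        others = set()
        for other, over in verified.items():
            if other != strategy:
                others |= over
        out.append(
            ConfusionCounts(
                strategy=strategy,
                tp=len(ver),
                fp=len(asm - ver),
                fn=len(others - asm),
            )
        )
    return out


def precision(counts: ConfusionCounts) -> float:
    """TP / (TP + FP); 0/0 defined as 0."""
    denom = counts.tp + counts.fp
    return counts.tp / denom if denom else 0.0


def sensitivity(counts: ConfusionCounts) -> float:
    """TP / (TP + FN); 0/0 defined as 0."""
    denom = counts.tp + counts.fn
    return counts.tp / denom if denom else 0.0


def f1(counts: ConfusionCounts) -> float:
    """Harmonic mean of precision and sensitivity; 0 when both are 0."""
    p, s = precision(counts), sensitivity(counts)
    return 2 * p * s / (p + s) if p + s else 0.0


def assembly_rate(n_assembled: int, n_identified: int) -> float:
    """A / I: assembled circRNA count over identified circRNA count."""
    if n_identified <= 0:
        raise ValueError("n_identified must be positive")
    if not 0 <= n_assembled <= n_identified:
        raise ValueError("n_assembled must be in [0, n_identified]")
    return n_assembled / n_identified


def min_support_filter(
    candidates: Iterable[CircCandidate], min_reads: int = 2
) -> list[CircCandidate]:
    """Retain candidates with at least ``min_reads`` back-splice reads."""
    if min_reads < 0:
        raise ValueError("min_reads must be >= 0")
    return [c for c in candidates if c.support_reads >= min_reads]


def stratified_precision(
    candidates: Sequence[CircCandidate],
    verdicts: Mapping[str, bool] | Sequence[Verdict],
    thresholds: Sequence[int],
) -> list[tuple[int, float | None, int]]:
    """Precision over candidates with support >= t, for each threshold t.

    Returns (threshold, precision, n) tuples; an empty stratum reports
    precision None rather than 0.
    """
    if list(thresholds) != sorted(thresholds):
        raise ValueError("thresholds must be ascending")
    if not isinstance(verdicts, Mapping):
        verdicts = {v.candidate_id: v.verified for v in verdicts}
    out = []
    for t in thresholds:
        stratum = [c for c in candidates if c.support_reads >= t]
        n = len(stratum)
        if n == 0:
            out.append((t, None, 0))
            continue
        tp = sum(1 for c in stratum if verdicts.get(c.candidate_id, False))
        out.append((t, tp / n, n))
    return out


def build_report(
    counts: Sequence[ConfusionCounts],
    assembly: tuple[int, int] | None = None,
    stratified: Sequence[tuple[int, float | None, int]] = (),
) -> MetricsReport:
    report = MetricsReport()
    for c in counts:
        report.per_strategy[c.strategy] = {
            "tp": c.tp,
            "fp": c.fp,
            "fn": c.fn,
            "precision": precision(c),
            "sensitivity": sensitivity(c),
            "f1": f1(c),
        }
    if assembly is not None:
        report.assembly_rate = assembly_rate(*assembly)
    report.stratified_precision = list(stratified)
    return report
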