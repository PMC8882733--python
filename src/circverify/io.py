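"""Readers and writers for candidate/isoform/verdict/report tables.

All tables are TSV with a header line and a stable column order so runs can
be compared byte-for-byte.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO

from .errors import FormatError
from .isomatch import ReferenceIsoform
from .metrics import MetricsReport
from .rotation import CircCandidate, Verdict
from .screen import StructureCall


def read_fasta_dict(path) -> dict[str, str]:
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in out:
            raise FormatError(f"{path}: duplicate record id {rec.id!r}")
        out[rec.id] = str(rec.seq).upper()
    if not out:
        raise FormatError(f"{path}: no FASTA records")
    return out


def read_fastq(path) -> list[tuple[str, str]]:
    reads = [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fastq")]
    if not reads:
        raise FormatError(f"{path}: no FASTQ records")
    return reads


def _read_bed(path, min_cols: int = 6) -> list[list[str]]:
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("#", "track")):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < min_cols:
                raise FormatError(f"{path}:{lineno}: expected >= {min_cols} BED columns")
            rows.append(fields)
    return rows


def read_candidates(fasta_path, bed_path, tsv_path=None) -> list[CircCandidate]:
    """Assemble CircCandidate objects from FASTA + BED6 (+ optional TSV).

    The BED name column links coordinates to FASTA records; the TSV (from
    the simulator or converted tool output) carries support counts, tool
    labels and truth labels, overriding the BED score column.
    """
    seqs = read_fasta_dict(fasta_path)
    meta: dict[str, dict[str, str]] = {}
    if tsv_path is not None:
        with open(tsv_path) as fh:
            for row in csv.DictReader(fh, delimiter="\t"):
                meta[row["candidate_id"]] = row
    candidates = []
    for fields in _read_bed(bed_path):
        chrom, start, end, name, score, strand = fields[:6]
        if name not in seqs:
            raise FormatError(f"candidate {name!r} in BED but not in FASTA")
        row = meta.get(name, {})
        candidates.append(
            CircCandidate(
                candidate_id=name,
                chrom=chrom,
                start=int(start),
                end=int(end),
                strand=strand,
                sequence=seqs[name],
                support_reads=int(row.get("support_reads", score if score.isdigit() else 0)),
                ident_tool=row.get("ident_tool", ""),
                asm_tool=row.get("asm_tool", ""),
                truth_label=row.get("truth_label") or None,
            )
        )
    return candidates


def read_isoforms(fasta_path, bed_path) -> list[ReferenceIsoform]:
    """Reference isoform set from FASTA + BED (name column joins the two)."""
    seqs = read_fasta_dict(fasta_path)
    isoforms = []
    for fields in _read_bed(bed_path):
        chrom, start, end, name, _score, strand = fields[:6]
        if name not in seqs:
            raise FormatError(f"isoform {name!r} in BED but not in FASTA")
        isoforms.append(
            ReferenceIsoform(
                isoform_id=name,
                chrom=chrom,
                start=int(start),
                end=int(end),
                strand=strand,
                sequence=seqs[name],
            )
        )
    return isoforms


def write_verdicts(verdicts: Sequence[Verdict], path) -> None:
    with open(path, "w") as fh:
        fh.write("candidate_id\tstrategy\tverified\tsupport\tbest_ratio\tunverifiable\n")
        for v in verdicts:
            ratio = "" if v.best_ratio is None else f"{v.best_ratio:.6f}"
            fh.write(
                f"{v.candidate_id}\t{v.strategy}\t{int(v.verified)}\t"
                f"{v.support}\t{ratio}\t{int(v.unverifiable)}\n"
            )


def read_verdicts(path) -> list[Verdict]:
    verdicts = []
    with open(path) as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            verdicts.append(
                Verdict(
                    candidate_id=row["candidate_id"],
                    strategy=row["strategy"],
                    verified=bool(int(row["verified"])),
                    support=int(row["support"]),
                    best_ratio=float(row["best_ratio"]) if row["best_ratio"] else None,
                    unverifiable=bool(int(row["unverifiable"])),
                )
            )
    return verdicts


def write_structure_calls(calls: Sequence[StructureCall], path) -> None:
    with open(path, "w") as fh:
        fh.write("candidate_id\tlabel\tchain_exon_count\n")
        for c in calls:
            n = "" if c.matched_transcript_chain_len is None else str(c.matched_transcript_chain_len)
            fh.write(f"{c.candidate_id}\t{c.label}\t{n}\n")


def write_metrics_report(report: MetricsReport, tsv_path, json_path) -> None:
    data = report.as_dict()
    with open(json_path, "w") as fh:
        json.dump(data, fh, indent=2, sort_keys=True)
        fh.write("\n")
    with open(tsv_path, "w") as fh:
        fh.write("strategy\ttp\tfp\tfn\tprecision\tsensitivity\tf1\n")
        for strategy in sorted(report.per_strategy):
            m = report.per_strategy[strategy]
            fh.write(
                f"{strategy}\t{int(m['tp'])}\t{int(m['fp'])}\t{int(m['fn'])}\t"
                f"{m['precision']:.6f}\t{m['sensitivity']:.6f}\t{m['f1']:.6f}\n"
            )


def write_ensemble(combined: Mapping[str, bool], path) -> None:
    with open(path, "w") as fh:
        fh.write("candidate_id\tverified\n")
        for cid in combined:
            fh.write(f"{cid}\t{int(combined[cid])}\n")


def write_stratified(rows: Iterable[tuple[int, float | None, int]], path) -> None:
    with open(path, "w") as fh:
        fh.write("min_support\tprecision\tn\n")
        for t, p, n in rows:
            fh.write(f"{t}\t{'NA' if p is None else f'{p:.6f}'}\t{n}\n")
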