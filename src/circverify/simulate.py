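"""Synthetic genome/annotation/circRNA/long-read generator.

Every generator is a deterministic pure function of :class:`SimConfig`
(stage-specific child seeds of ``config.seed``).  The simulator provides:

* a random genome and a non-overlapping multi-exon gene annotation;
* true circRNA isoforms formed from exon chains between back-splice sites;
* rolling-circle long reads (tandem copies, random rotation offset,
  substitution/insertion/deletion errors) plus linear-transcript decoys;
* assembled-candidate sets with controlled corruption (exon skip,
  truncation, intron retention, false BSJ) and planted correctness rates.

Corruption sites are placed centrally within the candidate so that every
corrupted candidate is unambiguously rejectable by both the read-alignment
filters and the sequence-identity threshold (no contiguous surviving match
can reach the 0.8 mapped_ratio bound, and the sequence change exceeds 5%
of the candidate length).
"""

from __future__ import annotations

import hashlib
import json
import math
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from .annotation import (
    Exon,
    GeneAnnotation,
    GenomeSequence,
    Transcript,
    concat_exon_sequence,
    reverse_complement,
    write_gtf,
)
from .errors import ConfigError
from .rotation import CircCandidate

logger = logging.getLogger(__name__)

_BASES = np.array(list("ACGT"))

CORRUPTION_MODES = ("correct", "exon_skip", "truncation", "intron_retention", "false_bsj")

# fraction of candidate length a corruption must change to defeat a 0.95
# identity threshold with margin
_MIN_CHANGE_FRACTION = 0.06
# both flanks of a corruption site must stay below this fraction of the
# corrupted length so no contiguous match reaches the 0.8 mapped_ratio bound;
# rotating the candidate before alignment can lengthen one flank by the
# rotation amount, hence the extra allowance
_MAX_FLANK_FRACTION = 0.75
_ROTATION_ALLOWANCE_BP = 20
_MIN_CHANGE_BP = 10


def _flanks_ok(before: int, after: int, new_len: int) -> bool:
    return max(before, after) + _ROTATION_ALLOWANCE_BP <= _MAX_FLANK_FRACTION * new_len


@dataclass
class SimConfig:
    """Full specification of one synthetic dataset."""

    seed: int = 0
    chrom_name: str = "chr1"
    genome_length: int = 120_000
    gc_content: float = 0.5
    n_genes: int = 10
    exons_per_gene: tuple[int, int] = (2, 5)
    exon_length: tuple[int, int] = (60, 200)
    intron_length: tuple[int, int] = (60, 300)
    intergene_gap: tuple[int, int] = (100, 300)
    n_circ: int = 20
    n_reads: int = 200
    copy_range: tuple[int, int] = (2, 4)
    sub_rate: float = 0.0
    ins_rate: float = 0.0
    del_rate: float = 0.0
    decoy_fraction: float = 0.0
    corruption_profile: dict = field(
        default_factory=lambda: {"correct": 1.0}
    )
    n_decoy_candidates: int = 0
    support_geom_p_correct: float = 0.15
    support_geom_p_false: float = 0.7
    min_support_base: int = 2

    def __post_init__(self):
        for name in ("genome_length", "n_genes", "n_circ", "n_reads"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        for name in ("exons_per_gene", "exon_length", "intron_length",
                     "intergene_gap", "copy_range"):
            lo, hi = getattr(self, name)
            if not (0 < lo <= hi):
                raise ConfigError(f"{name} range [{lo}, {hi}] is empty or invalid")
        for name in ("gc_content", "sub_rate", "ins_rate", "del_rate", "decoy_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {v}")
        profile = {m: float(p) for m, p in self.corruption_profile.items()}
        unknown = set(profile) - set(CORRUPTION_MODES)
        if unknown:
            raise ConfigError(f"unknown corruption modes: {sorted(unknown)}")
        if any(not 0 <= p <= 1 for p in profile.values()):
            raise ConfigError("corruption probabilities must be in [0, 1]")
        if abs(sum(profile.values()) - 1.0) > 1e-9:
            raise ConfigError("corruption-mode probabilities must sum to 1")
        self.corruption_profile = profile
        for name in ("support_geom_p_correct", "support_geom_p_false"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ConfigError(f"{name} must be in (0, 1]")

    def rng(self, stage: int) -> np.random.Generator:
        return np.random.default_rng([self.seed, stage])

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "SimConfig":
        data = dict(data)
        for name in ("exons_per_gene", "exon_length", "intron_length",
                     "intergene_gap", "copy_range"):
            if name in data:
                data[name] = tuple(data[name])
        return cls(**data)


@dataclass(frozen=True)
class TrueCirc:
    """A ground-truth circRNA isoform."""

    circ_id: str
    chrom: str
    start: int
    end: int
    strand: str
    transcript_id: str
    chain: tuple[Exon, ...]
    sequence: str
    expression: float

    def __post_init__(self):
        if self.expression <= 0:
            raise ConfigError("expression weight must be positive")


@dataclass(frozen=True)
class LongRead:
    """A simulated long read with its ground-truth origin."""

    read_id: str
    sequence: str
    truth: tuple[str, int, int] | None = None  # (source id, copy count, offset)

    def __post_init__(self):
        if not self.sequence:
            raise ValueError(f"read {self.read_id}: empty sequence")


def simulate_genome(config: SimConfig) -> GenomeSequence:
    """Random genome, uniform base composition unless gc_content is set."""
    rng = config.rng(1)
    gc = config.gc_content
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    seq = "".join(rng.choice(_BASES, size=config.genome_length, p=p))
    return GenomeSequence([(config.chrom_name, seq)])


def simulate_annotation(genome: GenomeSequence, config: SimConfig) -> GeneAnnotation:
    """Non-overlapping single-transcript genes tiled along the chromosome."""
    rng = config.rng(2)
    chrom = config.chrom_name
    chrom_len = genome.length(chrom)
    pos = int(rng.integers(config.intergene_gap[0], config.intergene_gap[1] + 1))
    transcripts = []
    for g in range(config.n_genes):
        n_exons = int(rng.integers(config.exons_per_gene[0], config.exons_per_gene[1] + 1))
        exon_lens = rng.integers(
            config.exon_length[0], config.exon_length[1] + 1, size=n_exons
        )
        intron_lens = rng.integers(
            config.intron_length[0], config.intron_length[1] + 1, size=max(0, n_exons - 1)
        )
        strand = "+" if rng.random() < 0.5 else "-"
        exons = []
        cursor = pos
        for i, el in enumerate(exon_lens):
            exons.append(Exon(chrom=chrom, start=cursor, end=cursor + int(el), strand=strand))
            cursor += int(el)
            if i < n_exons - 1:
                cursor += int(intron_lens[i])
        if cursor > chrom_len:
            raise ConfigError(
                f"genome too short: gene {g} would end at {cursor} > {chrom_len}"
            )
        transcripts.append(
            Transcript(transcript_id=f"tx{g:04d}", gene_id=f"gene{g:04d}", exons=exons)
        )
        pos = cursor + int(rng.integers(config.intergene_gap[0], config.intergene_gap[1] + 1))
    return GeneAnnotation(transcripts)


def simulate_circ_truth(
    annotation: GeneAnnotation, genome: GenomeSequence, config: SimConfig
) -> list[TrueCirc]:
    """Draw distinct-BSJ circRNAs anchored at exon boundaries of transcripts."""
    rng = config.rng(3)
    pool = []  # (tx_id, i, j) exon sub-chains
    for tx_id in sorted(annotation.transcripts):
        tx = annotation.transcripts[tx_id]
        n = len(tx.exons)
        for i in range(n):
            for j in range(i, n):
                pool.append((tx_id, i, j))
    if config.n_circ > len(pool):
        raise ConfigError(
            f"requested {config.n_circ} circRNAs but only {len(pool)} distinct "
            "exon-boundary pairs are available"
        )
    order = rng.permutation(len(pool))
    truth: list[TrueCirc] = []
    seen_bsj = set()
    for idx in order:
        tx_id, i, j = pool[idx]
        tx = annotation.transcripts[tx_id]
        chain = tuple(tx.exons[i : j + 1])
        bsj = (tx.chrom, chain[0].start, chain[-1].end, tx.strand)
        if bsj in seen_bsj:
            continue
        seen_bsj.add(bsj)
        seq = concat_exon_sequence(genome, list(chain), tx.strand)
        truth.append(
            TrueCirc(
                circ_id=f"circ{len(truth):04d}",
                chrom=tx.chrom,
                start=chain[0].start,
                end=chain[-1].end,
                strand=tx.strand,
                transcript_id=tx_id,
                chain=chain,
                sequence=seq,
                expression=float(rng.uniform(0.5, 2.0)),
            )
        )
        if len(truth) == config.n_circ:
            break
    if len(truth) < config.n_circ:
        raise ConfigError(
            f"only {len(truth)} distinct BSJs available, {config.n_circ} requested"
        )
    return truth


def apply_errors(
    seq: str, rng: np.random.Generator, sub_rate: float, ins_rate: float, del_rate: float
) -> str:
    """Per-base substitution/insertion/deletion error model.

    Substituted bases are always changed to a different base; insertions add
    one random base after the current one.
    """
    if sub_rate == ins_rate == del_rate == 0.0:
        return seq
    out = []
    n = len(seq)
    subs = rng.random(n) < sub_rate
    dels = rng.random(n) < del_rate
    inss = rng.random(n) < ins_rate
    for i, base in enumerate(seq):
        if dels[i]:
            pass
        elif subs[i]:
            alternatives = [b for b in "ACGT" if b != base]
            out.append(alternatives[int(rng.integers(3))])
        else:
            out.append(base)
        if inss[i]:
            out.append("ACGT"[int(rng.integers(4))])
    return "".join(out) if out else seq[:1]


def simulate_long_reads(
    truth: list[TrueCirc],
    annotation: GeneAnnotation,
    config: SimConfig,
    genome: GenomeSequence | None = None,
) -> list[LongRead]:
    """Rolling-circle reads from true circRNAs plus linear-transcript decoys.

    ``genome`` is required only when decoy reads are requested
    (decoy_fraction > 0): decoys are substrings of spliced linear transcripts.
    """
    rng = config.rng(4)
    n_decoy = int(round(config.decoy_fraction * config.n_reads))
    n_circ_reads = config.n_reads - n_decoy
    if n_circ_reads > 0 and not truth:
        raise ConfigError("no true circRNAs to read from (set decoy_fraction=1)")
    if n_decoy > 0 and genome is None:
        raise ConfigError("decoy reads require the genome argument")
    reads: list[LongRead] = []
    if truth:
        weights = np.array([t.expression for t in truth])
        weights = weights / weights.sum()
    for r in range(n_circ_reads):
        idx = int(rng.choice(len(truth), p=weights))
        circ = truth[idx]
        k = int(rng.integers(config.copy_range[0], config.copy_range[1] + 1))
        offset = int(rng.integers(0, len(circ.sequence)))
        template = (circ.sequence[offset:] + circ.sequence[:offset]) * k
        seq = apply_errors(template, rng, config.sub_rate, config.ins_rate, config.del_rate)
        reads.append(
            LongRead(
                read_id=f"read{r:05d}_{circ.circ_id}",
                sequence=seq,
                truth=(circ.circ_id, k, offset),
            )
        )
    tx_ids = sorted(annotation.transcripts)
    genome_cache: dict[str, str] = {}
    for d in range(n_decoy):
        tx_id = tx_ids[int(rng.integers(len(tx_ids)))]
        tx = annotation.transcripts[tx_id]
        spliced = genome_cache.get(tx_id)
        if spliced is None:
            spliced = concat_exon_sequence(genome, list(tx.exons), tx.strand)
            genome_cache[tx_id] = spliced
        L = len(spliced)
        m = int(rng.integers(max(20, L // 2), L + 1))
        start = int(rng.integers(0, L - m + 1))
        template = spliced[start : start + m]
        seq = apply_errors(template, rng, config.sub_rate, config.ins_rate, config.del_rate)
        reads.append(
            LongRead(
                read_id=f"decoy{d:05d}_{tx_id}",
                sequence=seq,
                truth=(tx_id, 0, start),
            )
        )
    return reads


def _cumulative_exon_offsets(chain: tuple[Exon, ...]) -> list[int]:
    cum = [0]
    for exon in chain:
        cum.append(cum[-1] + exon.length)
    return cum


def _min_change(L: int) -> int:
    return max(_MIN_CHANGE_BP, math.ceil(_MIN_CHANGE_FRACTION * L))


def _feasible_exon_skips(circ: TrueCirc) -> list[int]:
    chain = circ.chain
    if len(chain) < 3:
        return []
    cum = _cumulative_exon_offsets(chain)
    L = cum[-1]
    need = _min_change(L)
    out = []
    for i in range(1, len(chain) - 1):
        e_len = chain[i].length
        if e_len < need:
            continue
        new_len = L - e_len
        before, after = cum[i], L - cum[i + 1]
        if _flanks_ok(before, after, new_len):
            out.append(i)
    return out


def _feasible_truncations(circ: TrueCirc) -> list[tuple[int, str, int]]:
    """(exon index, end, removal size) options meeting the rejection margins."""
    chain = circ.chain
    if len(chain) < 3:
        return []
    cum = _cumulative_exon_offsets(chain)
    L = cum[-1]
    t_min = _min_change(L)
    out = []
    for i in range(1, len(chain) - 1):
        e_len = chain[i].length
        for which in ("left", "right"):
            for t in range(t_min, e_len - 4):
                cut = cum[i] if which == "left" else cum[i + 1] - t
                new_len = L - t
                if _flanks_ok(cut, new_len - cut, new_len):
                    out.append((i, which, t))
                    break  # smallest feasible t for this (exon, end)
    return out


def _feasible_retentions(circ: TrueCirc, genome: GenomeSequence) -> list[int]:
    chain = circ.chain
    if len(chain) < 2:
        return []
    cum = _cumulative_exon_offsets(chain)
    L = cum[-1]
    need = _min_change(L)
    out = []
    for i in range(len(chain) - 1):
        i_len = chain[i + 1].start - chain[i].end
        if i_len < need:
            continue
        cut = cum[i + 1]
        new_len = L + i_len
        if _flanks_ok(cut, L - cut, new_len):
            out.append(i)
    return out


def _genomic_concat(genome: GenomeSequence, circ: TrueCirc) -> str:
    return "".join(genome.fetch(e.chrom, e.start, e.end) for e in circ.chain)


def _orient(seq: str, strand: str) -> str:
    return reverse_complement(seq) if strand == "-" else seq


def corrupt_candidates(
    truth: list[TrueCirc],
    annotation: GeneAnnotation,
    genome: GenomeSequence,
    config: SimConfig,
) -> list[CircCandidate]:
    """One candidate per TrueCirc with a planted corruption mode, plus decoys.

    A drawn corruption mode that is infeasible for the chosen circRNA (e.g.
    exon_skip on a single-exon circle) is resampled to another corruption
    mode, ending at false_bsj which is always feasible; ``correct`` draws
    are never resampled, so the planted correct fraction is preserved.
    """
    rng = config.rng(5)
    modes = list(CORRUPTION_MODES)
    probs = np.array([config.corruption_profile.get(m, 0.0) for m in modes])
    candidates: list[CircCandidate] = []
    exon_boundaries = {
        (e.chrom, e.start) for tx in annotation.transcripts.values() for e in tx.exons
    } | {(e.chrom, e.end) for tx in annotation.transcripts.values() for e in tx.exons}

    def support(correct: bool) -> int:
        p = config.support_geom_p_correct if correct else config.support_geom_p_false
        return config.min_support_base + int(rng.geometric(p)) - 1

    for k, circ in enumerate(truth):
        mode = str(rng.choice(modes, p=probs))
        cand = None
        tried = []
        while cand is None:
            cand = _build_candidate(
                f"cand{k:04d}", circ, mode, genome, exon_boundaries, rng
            )
            if cand is None:
                tried.append(mode)
                fallback = [
                    m
                    for m in ("exon_skip", "truncation", "intron_retention", "false_bsj")
                    if m not in tried
                ]
                if not fallback:
                    raise ConfigError(
                        f"no feasible corruption mode for {circ.circ_id} "
                        f"(chain of {len(circ.chain)} exons, length "
                        f"{len(circ.sequence)}); increase exon lengths"
                    )
                next_mode = fallback[0]
                logger.info(
                    "circ %s: mode %s infeasible, resampled to %s",
                    circ.circ_id,
                    mode,
                    next_mode,
                )
                mode = next_mode
        candidates.append(
            CircCandidate(
                candidate_id=cand[0],
                chrom=circ.chrom,
                start=cand[1],
                end=cand[2],
                strand=circ.strand,
                sequence=cand[3],
                support_reads=support(mode == "correct"),
                ident_tool="sim_ident",
                asm_tool="sim_asm",
                truth_label=mode,
            )
        )
    # pure-false decoy candidates from non-boundary genomic intervals
    chrom = config.chrom_name
    chrom_len = genome.length(chrom)
    for d in range(config.n_decoy_candidates):
        while True:
            start = int(rng.integers(0, chrom_len - 400))
            length = int(rng.integers(100, 300))
            end = start + length
            if (chrom, start) not in exon_boundaries and (chrom, end) not in exon_boundaries:
                break
        candidates.append(
            CircCandidate(
                candidate_id=f"decoycand{d:04d}",
                chrom=chrom,
                start=start,
                end=end,
                strand="+",
                sequence=genome.fetch(chrom, start, end),
                support_reads=support(False),
                ident_tool="sim_ident",
                asm_tool="sim_asm",
                truth_label="decoy",
            )
        )
    return candidates


def _build_candidate(
    cand_id: str,
    circ: TrueCirc,
    mode: str,
    genome: GenomeSequence,
    exon_boundaries: set,
    rng: np.random.Generator,
) -> tuple[str, int, int, str] | None:
    """(id, start, end, sequence) for one corruption mode, or None if infeasible."""
    chain = circ.chain
    cum = _cumulative_exon_offsets(chain)
    L = cum[-1]
    G = _genomic_concat(genome, circ)
    if mode == "correct":
        return cand_id, circ.start, circ.end, circ.sequence
    if mode == "exon_skip":
        options = _feasible_exon_skips(circ)
        if not options:
            return None
        i = int(rng.choice(options))
        seq = G[: cum[i]] + G[cum[i + 1] :]
        return cand_id, circ.start, circ.end, _orient(seq, circ.strand)
    if mode == "truncation":
        options = _feasible_truncations(circ)
        if not options:
            return None
        i, which, t = options[int(rng.integers(len(options)))]
        if which == "left":
            block_start = cum[i]
        else:
            block_start = cum[i + 1] - t
        seq = G[:block_start] + G[block_start + t :]
        return cand_id, circ.start, circ.end, _orient(seq, circ.strand)
    if mode == "intron_retention":
        options = _feasible_retentions(circ, genome)
        if not options:
            return None
        i = int(rng.choice(options))
        intron = genome.fetch(circ.chrom, chain[i].end, chain[i + 1].start)
        seq = G[: cum[i + 1]] + intron + G[cum[i + 1] :]
        return cand_id, circ.start, circ.end, _orient(seq, circ.strand)
    if mode == "false_bsj":
        first_len, last_len = chain[0].length, chain[-1].length
        ds_max = min(30, first_len - 5, L - 40 - 10)
        if ds_max < 10:
            return None
        for _ in range(50):
            ds = int(rng.integers(10, ds_max + 1))
            de_max = min(30, last_len - 5, L - 40 - ds)
            if de_max < 10:
                continue
            de = int(rng.integers(10, de_max + 1))
            new_start, new_end = circ.start + ds, circ.end - de
            if (circ.chrom, new_start) in exon_boundaries:
                continue
            if (circ.chrom, new_end) in exon_boundaries:
                continue
            seq = G[ds : L - de]
            return cand_id, new_start, new_end, _orient(seq, circ.strand)
        return None
    raise ConfigError(f"unknown corruption mode {mode!r}")


@dataclass
class SimResult:
    """Everything one simulation run produced."""

    config: SimConfig
    genome: GenomeSequence
    annotation: GeneAnnotation
    truth: list[TrueCirc]
    reads: list[LongRead]
    candidates: list[CircCandidate]


def simulate_all(config: SimConfig) -> SimResult:
    """Run every stage of the simulator in order."""
    genome = simulate_genome(config)
    annotation = simulate_annotation(genome, config)
    truth = simulate_circ_truth(annotation, genome, config)
    reads = simulate_long_reads(truth, annotation, config, genome)
    candidates = corrupt_candidates(truth, annotation, genome, config)
    return SimResult(config, genome, annotation, truth, reads, candidates)


# ---------------------------------------------------------------------------
# fixture writers (plain-text formats only)


def write_genome_fasta(genome: GenomeSequence, path) -> None:
    with open(path, "w") as fh:
        for chrom in genome.chrom_names:
            fh.write(f">{chrom}\n")
            seq = genome[chrom]
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")


def write_truth(truth: list[TrueCirc], fasta_path, bed_path) -> None:
    """Truth isoforms as FASTA plus BED12 (blocks = exon chain)."""
    with open(fasta_path, "w") as fh:
        for t in truth:
            fh.write(f">{t.circ_id}\n{t.sequence}\n")
    with open(bed_path, "w") as fh:
        for t in truth:
            sizes = ",".join(str(e.length) for e in t.chain)
            starts = ",".join(str(e.start - t.start) for e in t.chain)
            fh.write(
                "\t".join(
                    [
                        t.chrom,
                        str(t.start),
                        str(t.end),
                        t.circ_id,
                        "0",
                        t.strand,
                        str(t.start),
                        str(t.end),
                        "0,0,0",
                        str(len(t.chain)),
                        sizes,
                        starts,
                    ]
                )
                + "\n"
            )


def write_reads_fastq(reads: list[LongRead], path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.read_id}\n{r.sequence}\n+\n{'I' * len(r.sequence)}\n")


def write_candidates(candidates: list[CircCandidate], fasta_path, bed_path, tsv_path) -> None:
    with open(fasta_path, "w") as fh:
        for c in candidates:
            fh.write(f">{c.candidate_id}\n{c.sequence}\n")
    with open(bed_path, "w") as fh:
        for c in candidates:
            fh.write(
                "\t".join(
                    [c.chrom, str(c.start), str(c.end), c.candidate_id,
                     str(c.support_reads), c.strand]
                )
                + "\n"
            )
    with open(tsv_path, "w") as fh:
        fh.write(
            "candidate_id\tchrom\tstart\tend\tstrand\tsupport_reads\t"
            "ident_tool\tasm_tool\ttruth_label\n"
        )
        for c in candidates:
            fh.write(
                "\t".join(
                    [
                        c.candidate_id,
                        c.chrom,
                        str(c.start),
                        str(c.end),
                        c.strand,
                        str(c.support_reads),
                        c.ident_tool,
                        c.asm_tool,
                        c.truth_label or "",
                    ]
                )
                + "\n"
            )


FIXTURE_FILES = (
    "genome.fasta",
    "annotation.gtf",
    "truth.fasta",
    "truth.bed",
    "reads.fastq",
    "candidates.fasta",
    "candidates.bed",
    "candidates.tsv",
    "sim_config.yaml",
)


def write_fixture(result: SimResult, outdir, force: bool = False) -> dict:
    """Write every fixture file plus a checksum manifest; returns the manifest."""
    outdir = Path(outdir)
    if outdir.exists() and any(outdir.iterdir()) and not force:
        raise ConfigError(f"output directory {outdir} is not empty (use force)")
    outdir.mkdir(parents=True, exist_ok=True)
    write_genome_fasta(result.genome, outdir / "genome.fasta")
    write_gtf(result.annotation, outdir / "annotation.gtf")
    write_truth(result.truth, outdir / "truth.fasta", outdir / "truth.bed")
    write_reads_fastq(result.reads, outdir / "reads.fastq")
    write_candidates(
        result.candidates,
        outdir / "candidates.fasta",
        outdir / "candidates.bed",
        outdir / "candidates.tsv",
    )
    with open(outdir / "sim_config.yaml", "w") as fh:
        yaml.safe_dump(result.config.to_dict(), fh, sort_keys=True)
    manifest = {}
    for name in FIXTURE_FILES:
        digest = hashlib.sha256((outdir / name).read_bytes()).hexdigest()
        manifest[name] = digest
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
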