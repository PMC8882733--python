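# circverify

Long-read-based validation of assembled full-length circRNA sequences.

Short-read assemblers reconstruct full-length circRNA sequences between
back-splice junction (BSJ) sites, but truncated, intron-retaining and
mis-anchored assemblies slip into their output. `circverify` evaluates such
candidate sets against long reads and reference isoform sets, and provides a
screening protocol that retains only candidates whose sequence equals the
complete annotated exon chain between their BSJ sites.

## What it does

* **Rotation validation** — each candidate sequence is rotated by 20 bp so
  the BSJ becomes internal, long reads are aligned to the rotated reference,
  and alignments are filtered by `mapped_ratio = M/L` (kept in `[0.8, 1.0]`)
  and total edit bases (kept `<= 2`). A candidate is verified when enough
  alignments survive. Optionally, passing alignments must span the rotated
  junction with a safety margin.
* **Isoform-set validation** — a candidate is verified when a reference
  full-length isoform (e.g. converted long-read tool output, or the
  simulator's truth set) agrees on the BSJ and reaches a rotation-maximized
  sequence identity threshold (default 0.95).
* **Ensemble + metrics** — k-of-n combination of strategy verdicts (default
  "at least 2"), cross-strategy TP/FP/FN with precision / sensitivity / F1,
  assembly rate, a `>= 2` back-splice-read input filter, and precision
  stratified by back-splice read count.
* **Structure screening** — exonic candidates are classified by their
  relationship to the annotated exon chain between their BSJ sites
  (single full exon / two full adjacent exons / full multi-exon chain /
  partial-or-uncertain / non-exonic); screening retains only the full-chain
  classes.
* **Synthetic data** — a deterministic generator for toy genomes,
  multi-exon annotations, true circRNA isoforms, rolling-circle long reads
  with a substitution/indel error model, linear-transcript decoy reads, and
  candidate sets with planted corruption modes (exon skip, truncation,
  intron retention, false BSJ) at controlled correctness rates. Every
  downstream stage is testable against planted truth labels.

Alignment uses a built-in seed-and-extend banded local aligner (unit costs,
verified against a full dynamic-programming oracle in the test suite); a SAM
adapter (`--aligner sam:PATH`) ingests pre-computed alignments from an
external long-read aligner instead.

## CLI

```bash
# generate a labeled synthetic fixture
circverify simulate --seed 1 --n-genes 20 --n-circ 60 --n-reads 400 --out fixture/

# end-to-end evaluation: strategies, ensemble, metrics, screening
circverify evaluate \
    --reads fixture/reads.fastq \
    --candidates-fasta fixture/candidates.fasta \
    --candidates-bed fixture/candidates.bed \
    --candidates-tsv fixture/candidates.tsv \
    --ref-isoforms fixture/truth.fasta,fixture/truth.bed \
    --strategies rotation --strategies isoform \
    --genome fixture/genome.fasta --gtf fixture/annotation.gtf \
    --require-junction-span \
    --k 2 --out results/
```

`circverify validate` runs individual strategies, `circverify screen` runs
only the structure screen, and `circverify report` recomputes ensemble and
metrics from existing verdict tables. All thresholds are exposed as flags
(`--min-ratio`, `--max-ratio`, `--max-edit-bp`, `--rotation-bp`,
`--identity-threshold`, `--bsj-tolerance`, `--min-support`,
`--min-bsj-reads`, `--aligner {builtin,sam:PATH}`). Every run writes its
resolved configuration (`run_config.yaml`) next to its outputs, and all
outputs are deterministic given the seed.

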