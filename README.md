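# ffpekit

Simulation and filtration of artifact chimeric reads in sequencing data
from formalin-fixed, paraffin-embedded (FFPE) samples.

FFPE processing denatures DNA; the resulting single-stranded fragments can
anneal at short reverse-complementary (SRC) regions and be end-repaired
into artifact chimeric fragments (ACFs). Reads from these fragments carry
spurious split-read signals that flood structural-variant callers with
false positives. `ffpekit` provides:

- **a read simulator** that generates FFPE-like libraries: a configurable
  mixture of normal fragments and ACFs, with within-window ("adjacent",
  lognormal SRC distance, unequal strand usage, optional enzymatic
  fragmentation) and between-window ("distant", Beta-weighted spike
  regions, equal strand usage) chimeras, positional Phred quality
  profiles, and ground-truth provenance encoded in every read name;
- **a two-step filter** for aligned BAMs: breakpoint-signature sharing
  counts identify candidate artifact reads (true SV junctions are shared
  by many reads, artifacts by at most a mate pair), and a read-space
  overlap check for the SRC footprint validates candidates before removal;
- **supporting machinery**: an SV spiker (DEL/DUP/INV/TRA truth sets), an
  idealized split-read aligner for end-to-end testing without an external
  aligner, positional Phred profile estimation from FASTQ, and
  breakpoint-matching metrics (PPV / sensitivity / F1 at a ±5 bp
  tolerance, plus read-level purity and recall against simulator tags).

## Command line

Every subcommand takes a `--seed` and writes a `*.config.yaml` snapshot
next to its outputs; rerunning with `--config <snapshot>` reproduces the
run byte for byte.

```sh
# plant SVs into a reference, get a mutated FASTA + truth table
ffpekit spike --ref ref.fasta --out sv --n-del 100 --n-dup 100 \
    --n-inv 100 --n-tra 100 --seed 1

# simulate an FFPE library (10% artifact chimeric fragments, 50x)
ffpekit simulate --ref ref.fasta --coverage 50 --acf-prop 0.1 \
    --seed 1 --out run

# idealized split alignments from the provenance table
ffpekit align-toy --provenance run_provenance.tsv --ref ref.fasta \
    --out run.bam

# two-step filtration (defaults: n=2 paired-end, m=1)
ffpekit filter --bam run.bam --out run.filtered.bam \
    --excluded excluded.txt --report report.json

# read-level metrics against the simulator's ground truth
ffpekit evaluate --excluded excluded.txt --provenance run_provenance.tsv \
    --bam run.bam --out metrics.json
```

WES-style simulation is available with `--target-bed`; an empirical
quality profile can be estimated from real FASTQ via
`ffpekit.phred_model.estimate_profile` and passed with `--profile`.

## Python API

Each module maps to one stage of the pipeline:

| module            | contents                                              |
| ----------------- | ----------------------------------------------------- |
| `genome_io`       | FASTA I/O, windows, reverse complement, motif search  |
| `sv_spiker`       | SV planning/application, breakpoint truth tables      |
| `phred_model`     | positional Phred profiles: estimate, sample, defaults |
| `ffpe_simulator`  | SRC-pair selection, fragment assembly, read emission  |
| `toy_aligner`     | provenance → sorted/indexed BAM with SA-tagged splits |
| `chimeric_filter` | signature sharing, SRC validation, BAM filtering      |
| `evaluation`      | purity/recall, ±tolerance SV matching, VCF/BEDPE I/O  |

All coordinates are 0-based half-open internally; conversion to 1-based
happens only at SAM/VCF boundaries.

## Tests and acceptance report

```sh
python -m pytest tests/            # full suite, ~3 minutes
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

The acceptance script regenerates four headline numbers from scratch
(filtration purity and chimeric-read recall on a 2 Mb / 50× simulated
sample, and the adjacent-category and same-strand fractions over 10,000
simulated ACFs) and writes them as JSON. `tests/test_acceptance.py` holds
the same criteria at their tolerances; the remaining tests cover the unit
contracts and property suites (filter ↔ brute-force oracle equivalence,
idempotence, name conservation, SRC structure checks, distribution
recovery, seeded byte-reproducibility).
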