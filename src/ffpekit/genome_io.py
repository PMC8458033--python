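"""Reference sequence handling.

FASTA input/output, genome window partitioning, reverse complementation and
exact motif search. All coordinates are 0-based half-open; conversion to
1-based happens only when records are serialized to SAM or VCF.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

__all__ = [
    "GenomeSequence",
    "GenomicInterval",
    "Window",
    "read_fasta",
    "write_fasta",
    "reverse_complement",
    "partition_windows",
    "find_motif_occurrences",
]

logger = logging.getLogger(__name__)

_VALID = set("ACGTN")
# IUPAC one-letter nucleotide codes beyond ACGTN collapse to N on load.
_IUPAC_EXTRA = set("RYSWKMBDHVU")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open interval on a named chromosome."""

    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}) on {self.chrom}"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class Window:
    """One tile of the genome partition (strand fixed to +)."""

    interval: GenomicInterval
    index: int

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def start(self) -> int:
        return self.interval.start

    @property
    def end(self) -> int:
        return self.interval.end

    def __len__(self) -> int:
        return len(self.interval)


@dataclass
class GenomeSequence:
    """Named chromosome sequences over the {A, C, G, T, N} alphabet."""

    chrom_names: list[str] = field(default_factory=list)
    sequences: dict[str, str] = field(default_factory=dict)

    @property
    def lengths(self) -> dict[str, int]:
        return {name: len(self.sequences[name]) for name in self.chrom_names}

    @property
    def total_length(self) -> int:
        return sum(len(self.sequences[name]) for name in self.chrom_names)

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.sequences

    def fetch(self, chrom: str, start: int, end: int) -> str:
        """Return the forward-strand sequence of ``[start, end)``."""
        seq = self.sequences[chrom]
        if not 0 <= start <= end <= len(seq):
            raise ValueError(
                f"[{start}, {end}) out of bounds for {chrom} (len {len(seq)})"
            )
        return seq[start:end]

    def add(self, name: str, seq: str) -> None:
        if name in self.sequences:
            raise ValueError(f"duplicate chromosome name {name!r}")
        self.chrom_names.append(name)
        self.sequences[name] = seq

    @classmethod
    def from_dict(cls, seqs: dict[str, str]) -> "GenomeSequence":
        genome = cls()
        for name, seq in seqs.items():
            genome.add(name, _normalize(seq, name))
        return genome


def _normalize(seq: str, name: str) -> str:
    seq = seq.upper()
    bad = set(seq) - _VALID
    if bad:
        extra = bad & _IUPAC_EXTRA
        if bad - _IUPAC_EXTRA:
            raise ValueError(
                f"non-nucleotide characters {sorted(bad - _IUPAC_EXTRA)} in {name!r}"
            )
        logger.warning(
            "converting %d IUPAC ambiguity codes %s to N in %s",
            sum(seq.count(c) for c in extra),
            sorted(extra),
            name,
        )
        seq = seq.translate(str.maketrans({c: "N" for c in extra}))
    return seq


def read_fasta(path: str | Path) -> GenomeSequence:
    """Load a multi-record FASTA file into memory.

    Sequences are uppercased; IUPAC ambiguity codes other than N are
    converted to N with a warning. Raises on a missing or empty file.
    """
    path = Path(path)
    genome = GenomeSequence()
    name: str | None = None
    chunks: list[str] = []
    with open(path) as handle:
        for line in handle:
            line = line.rstrip()
            if not line:
                continue
            if line.startswith(">"):
                if name is not None:
                    genome.add(name, _normalize("".join(chunks), name))
                name = line[1:].split()[0]
                chunks = []
            else:
                if name is None:
                    raise ValueError(f"{path}: sequence data before first header")
                chunks.append(line)
    if name is not None:
        genome.add(name, _normalize("".join(chunks), name))
    if not genome.chrom_names:
        raise ValueError(f"{path}: no records")
    return genome


def write_fasta(genome: GenomeSequence, path: str | Path, width: int = 80) -> None:
    with open(path, "w") as handle:
        for name in genome.chrom_names:
            handle.write(f">{name}\n")
            seq = genome.sequences[name]
            for i in range(0, len(seq), width):
                handle.write(seq[i : i + width] + "\n")


def reverse_complement(seq: str) -> str:
    """Watson-Crick reverse complement; N maps to N."""
    bad = set(seq) - _VALID
    if bad:
        raise ValueError(f"invalid characters {sorted(bad)}")
    return seq.translate(_COMPLEMENT)[::-1]


def partition_windows(genome: GenomeSequence, window_len: int) -> list[Window]:
    """Tile each chromosome with consecutive windows of ``window_len``.

    The last window on each chromosome may be shorter. Windows never span
    chromosome boundaries; indices are ordinal across the whole genome.
    """
    if window_len < 1:
        raise ValueError("window_len must be >= 1")
    windows: list[Window] = []
    index = 0
    for chrom in genome.chrom_names:
        length = len(genome.sequences[chrom])
        for start in range(0, length, window_len):
            end = min(start + window_len, length)
            windows.append(Window(GenomicInterval(chrom, start, end), index))
            index += 1
    return windows


def find_motif_occurrences(seq: str, motif: str) -> list[int]:
    """All exact forward-strand matches of ``motif``, overlapping included.

    Positions containing N never match because N is not in the motif
    alphabet and matching is exact.
    """
    if not motif:
        raise ValueError("empty motif")
    if set(motif) - set("ACGT"):
        raise ValueError("motif must be over {A,C,G,T}")
    positions: list[int] = []
    pos = seq.find(motif)
    while pos != -1:
        positions.append(pos)
        pos = seq.find(motif, pos + 1)
    return positions


def iter_windows_by_chrom(
    windows: list[Window],
) -> Iterator[tuple[str, list[Window]]]:
    """Group a window list by chromosome, preserving order."""
    current: str | None = None
    bucket: list[Window] = []
    for win in windows:
        if win.chrom != current:
            if bucket:
                yield current, bucket  # type: ignore[misc]
            current = win.chrom
            bucket = []
        bucket.append(win)
    if bucket:
        yield current, bucket  # type: ignore[misc]
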