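"""Structural-variant spiking.

Plants non-overlapping DEL/DUP/INV/TRA events into a reference genome and
emits a machine-readable breakpoint truth table. Translocations are modeled
as large insertions of segments copied from a donor chromosome. Truth
breakpoints are reported in original (unmutated) reference coordinates,
since downstream SV callers report against the unmutated reference.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .genome_io import GenomeSequence, GenomicInterval, reverse_complement

__all__ = [
    "SVTruthRecord",
    "SVTruthSet",
    "SV_TYPES",
    "plan_svs",
    "apply_svs",
    "truth_breakpoints",
    "write_truth_tsv",
    "read_truth_tsv",
    "write_breakpoints_bed",
]

SV_TYPES = ("DEL", "DUP", "INV", "TRA")

DEFAULT_GUARD_GAP = 500
_MAX_PLACEMENT_TRIES = 20_000


@dataclass(frozen=True)
class SVTruthRecord:
    """One planted structural variant.

    ``locus`` is the affected interval on the target chromosome; for TRA it
    is the zero-length insertion point, represented as ``start == end`` via
    the ``insertion_point`` field (GenomicInterval forbids empty intervals).
    """

    sv_id: str
    sv_type: str
    chrom: str
    start: int
    end: int
    length: int
    source: GenomicInterval | None = None

    def __post_init__(self) -> None:
        if self.sv_type not in SV_TYPES:
            raise ValueError(f"unknown SV type {self.sv_type!r}")
        if self.sv_type == "TRA":
            if self.start != self.end:
                raise ValueError("TRA locus must be a zero-length insertion point")
            if self.source is None:
                raise ValueError("TRA requires a source interval")
            if self.length != len(self.source):
                raise ValueError("TRA length must equal source length")
        else:
            if self.end - self.start != self.length:
                raise ValueError("locus span must equal length")

    def breakpoints(self) -> list[tuple[str, int, bool]]:
        """Reference breakpoints as (chrom, position, is_source_side)."""
        if self.sv_type == "TRA":
            assert self.source is not None
            return [
                (self.chrom, self.start, False),
                (self.chrom, self.start, False),
                (self.source.chrom, self.source.start, True),
                (self.source.chrom, self.source.end, True),
            ]
        return [(self.chrom, self.start, False), (self.chrom, self.end, False)]


@dataclass
class SVTruthSet:
    records: list[SVTruthRecord] = field(default_factory=list)
    reference_name: str = ""

    def __post_init__(self) -> None:
        self.records = sorted(self.records, key=lambda r: (r.chrom, r.start, r.sv_id))
        ids = [r.sv_id for r in self.records]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate sv_id in truth set")

    def by_type(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for rec in self.records:
            counts[rec.sv_type] = counts.get(rec.sv_type, 0) + 1
        return counts


def plan_svs(
    genome: GenomeSequence,
    counts_by_type: dict[str, int],
    length_range: tuple[int, int] = (1_000, 10_000),
    rng: np.random.Generator | None = None,
    *,
    target_chrom: str | None = None,
    donor_chrom: str | None = None,
    guard_gap: int = DEFAULT_GUARD_GAP,
) -> SVTruthSet:
    """Plan non-overlapping SV loci on the target chromosome.

    Lengths are uniform over ``length_range``; loci are separated by at
    least ``guard_gap`` bases so that junctions stay separable at read
    length. TRA source segments are drawn from ``donor_chrom``.

    Raises
    ------
    ValueError
        If the requested set cannot be packed after a bounded number of
        rejection-sampling attempts, or a donor chromosome is missing while
        translocations were requested.
    """
    if rng is None:
        rng = np.random.default_rng()
    lo, hi = length_range
    if not 1 <= lo <= hi:
        raise ValueError(f"invalid length range {length_range}")
    for sv_type in counts_by_type:
        if sv_type not in SV_TYPES:
            raise ValueError(f"unknown SV type {sv_type!r}")

    target_chrom = target_chrom or genome.chrom_names[0]
    n_tra = counts_by_type.get("TRA", 0)
    if n_tra > 0:
        if donor_chrom is None:
            others = [c for c in genome.chrom_names if c != target_chrom]
            if not others:
                raise ValueError(
                    "translocations require a donor chromosome distinct from "
                    "the target"
                )
            donor_chrom = others[0]
        if donor_chrom == target_chrom:
            raise ValueError("donor chromosome must differ from target")

    chrom_len = len(genome.sequences[target_chrom])
    total = sum(counts_by_type.values())
    demand = sum(
        hi * n for t, n in counts_by_type.items() if t != "TRA"
    ) + (total + 1) * guard_gap
    if demand > chrom_len:
        raise ValueError(
            f"cannot pack {total} SVs (worst case {demand} bp with guard gap "
            f"{guard_gap}) on {target_chrom} of {chrom_len} bp"
        )

    placed: list[tuple[int, int]] = []  # guard-expanded occupied spans

    def _try_place(span: int) -> int | None:
        for _ in range(_MAX_PLACEMENT_TRIES):
            start = int(rng.integers(guard_gap, chrom_len - span - guard_gap))
            lo_g, hi_g = start - guard_gap, start + span + guard_gap
            if all(hi_g <= s or lo_g >= e for s, e in placed):
                placed.append((start, start + span))
                return start
        return None

    records: list[SVTruthRecord] = []
    idx = 0
    for sv_type in SV_TYPES:
        for _ in range(counts_by_type.get(sv_type, 0)):
            length = int(rng.integers(lo, hi + 1))
            span = 0 if sv_type == "TRA" else length
            start = _try_place(max(span, 1))
            if start is None:
                raise ValueError(
                    f"failed to place {sv_type} of {length} bp after "
                    f"{_MAX_PLACEMENT_TRIES} attempts (guard gap {guard_gap})"
                )
            idx += 1
            sv_id = f"sv{idx:04d}_{sv_type.lower()}"
            if sv_type == "TRA":
                donor_len = len(genome.sequences[donor_chrom])  # type: ignore[index]
                if donor_len <= length:
                    raise ValueError(
                        f"donor chromosome {donor_chrom} too short for a "
                        f"{length} bp segment"
                    )
                src_start = int(rng.integers(0, donor_len - length))
                source = GenomicInterval(donor_chrom, src_start, src_start + length)
                records.append(
                    SVTruthRecord(sv_id, "TRA", target_chrom, start, start, length, source)
                )
            else:
                records.append(
                    SVTruthRecord(sv_id, sv_type, target_chrom, start, start + length, length)
                )
    return SVTruthSet(records, reference_name=target_chrom)


def apply_svs(genome: GenomeSequence, truth: SVTruthSet) -> GenomeSequence:
    """Return a mutated copy of the genome realizing every truth record.

    DEL removes the locus; DUP inserts one extra tandem copy directly after
    the unit; INV substitutes the reverse complement; TRA inserts the donor
    segment at the insertion point. Edits are applied right-to-left so that
    earlier reference coordinates stay valid throughout.
    """
    mutated = {name: genome.sequences[name] for name in genome.chrom_names}
    for rec in sorted(truth.records, key=lambda r: r.start, reverse=True):
        if rec.chrom not in mutated:
            raise ValueError(f"truth chromosome {rec.chrom!r} absent from genome")
        seq = mutated[rec.chrom]
        if rec.end > len(seq):
            raise ValueError(f"{rec.sv_id} extends past the end of {rec.chrom}")
        if rec.sv_type == "DEL":
            seq = seq[: rec.start] + seq[rec.end :]
        elif rec.sv_type == "DUP":
            unit = seq[rec.start : rec.end]
            seq = seq[: rec.end] + unit + seq[rec.end :]
        elif rec.sv_type == "INV":
            seq = seq[: rec.start] + reverse_complement(seq[rec.start : rec.end]) + seq[rec.end :]
        elif rec.sv_type == "TRA":
            assert rec.source is not None
            segment = genome.fetch(rec.source.chrom, rec.source.start, rec.source.end)
            seq = seq[: rec.start] + segment + seq[rec.start :]
        mutated[rec.chrom] = seq
    out = GenomeSequence()
    for name in genome.chrom_names:
        out.add(name, mutated[name])
    return out


def truth_breakpoints(
    truth: SVTruthSet,
) -> list[tuple[str, int, str, str, bool]]:
    """Flat, deduplicated, sorted (chrom, pos, sv_id, sv_type, source_side)."""
    seen: set[tuple[str, int, str, str, bool]] = set()
    for rec in truth.records:
        for chrom, pos, src in rec.breakpoints():
            seen.add((chrom, pos, rec.sv_id, rec.sv_type, src))
    return sorted(seen)


_TSV_COLUMNS = (
    "sv_id\tsv_type\tchrom\tstart\tend\tlength\t"
    "source_chrom\tsource_start\tsource_end"
)


def write_truth_tsv(truth: SVTruthSet, path: str | Path) -> None:
    with open(path, "w") as handle:
        handle.write(_TSV_COLUMNS + "\n")
        for rec in truth.records:
            if rec.source is not None:
                src = f"{rec.source.chrom}\t{rec.source.start}\t{rec.source.end}"
            else:
                src = ".\t.\t."
            handle.write(
                f"{rec.sv_id}\t{rec.sv_type}\t{rec.chrom}\t{rec.start}\t"
                f"{rec.end}\t{rec.length}\t{src}\n"
            )


def read_truth_tsv(path: str | Path) -> SVTruthSet:
    records: list[SVTruthRecord] = []
    with open(path) as handle:
        header = handle.readline().rstrip("\n")
        if header != _TSV_COLUMNS:
            raise ValueError(f"{path}: unexpected truth-table header")
        for line in handle:
            fields = line.rstrip("\n").split("\t")
            sv_id, sv_type, chrom, start, end, length, sc, ss, se = fields
            source = None
            if sc != ".":
                source = GenomicInterval(sc, int(ss), int(se))
            records.append(
                SVTruthRecord(sv_id, sv_type, chrom, int(start), int(end), int(length), source)
            )
    return SVTruthSet(records)


def write_breakpoints_bed(truth: SVTruthSet, path: str | Path) -> None:
    """Write each breakpoint as a 1 bp BED interval, name = sv_id:sv_type."""
    with open(path, "w") as handle:
        for chrom, pos, sv_id, sv_type, src in truth_breakpoints(truth):
            tag = f"{sv_id}:{sv_type}" + (":source" if src else "")
            handle.write(f"{chrom}\t{pos}\t{pos + 1}\t{tag}\n")
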