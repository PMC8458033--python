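"""Idealized split-alignment synthesis.

Converts simulator provenance directly into coordinate-sorted, indexed BAM
alignments, standing in for a real aligner: normal reads become one proper
pair, and artifact chimeric reads that cover their fragment junction with
enough bases on each side become a soft-clipped primary plus a
supplementary alignment with reciprocal SA tags. Alignments are positional
ground truth: MAPQ is fixed, NM is 0, and SEQ is taken from the reference,
so the filter (which consumes positions and CIGARs) sees an ideal mapping.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from tempfile import TemporaryDirectory

import pysam

from .genome_io import GenomeSequence, reverse_complement
from .ffpe_simulator import FragmentRecord, fragment_sequence

__all__ = ["align_reads", "DEFAULT_MIN_CLIP", "read_segments"]

logger = logging.getLogger(__name__)

DEFAULT_MIN_CLIP = 10

_FLAG_PAIRED = 0x1
_FLAG_PROPER = 0x2
_FLAG_REVERSE = 0x10
_FLAG_MATE_REVERSE = 0x20
_FLAG_READ1 = 0x40
_FLAG_READ2 = 0x80
_FLAG_SUPPLEMENTARY = 0x800


@dataclass(frozen=True)
class ReadSegment:
    """One aligned stretch of a read in original-read coordinates."""

    chrom: str
    ref_start: int  # 0-based
    ref_end: int
    read_start: int
    read_end: int
    reverse: bool  # read-as-sequenced aligns to the reverse strand


def _frag_segments(rec: FragmentRecord) -> list[tuple[str, int, int, str, int, int]]:
    """(chrom, g0, g1, dir, frag_start, frag_end) for each fragment segment."""
    j, L = rec.junction_offset, rec.src_len
    segs = [(rec.chrom_a, rec.a_start, rec.a_end, rec.a_dir, 0, j + L if rec.is_acf else rec.frag_len)]
    if rec.is_acf:
        segs.append((rec.chrom_b, rec.b_start, rec.b_end, rec.b_dir, j, rec.frag_len))
    return segs


def read_segments(rec: FragmentRecord, mate: int, read_len: int) -> list[ReadSegment]:
    """Project fragment segments into one mate's read coordinates.

    Mate 1 reads the first ``read_len`` bases of the top strand; mate 2
    reads the first ``read_len`` bases of the bottom strand (FR layout).
    Segments that the read does not touch are dropped.
    """
    flen = rec.frag_len
    out: list[ReadSegment] = []
    for chrom, g0, g1, direction, f0, f1 in _frag_segments(rec):
        if mate == 1:
            c0, c1 = max(f0, 0), min(f1, read_len)
            if c0 >= c1:
                continue
            r0, r1 = c0, c1
            reverse = direction == "-"
        else:
            lo = flen - read_len
            c0, c1 = max(f0, lo), min(f1, flen)
            if c0 >= c1:
                continue
            r0, r1 = flen - c1, flen - c0
            reverse = direction == "+"
        if direction == "+":
            gs, ge = g0 + (c0 - f0), g0 + (c1 - f0)
        else:
            gs, ge = g1 - (c1 - f0), g1 - (c0 - f0)
        out.append(ReadSegment(chrom, gs, ge, r0, r1, reverse))
    return out


def _cigar(seg: ReadSegment, read_len: int) -> str:
    left = seg.read_start
    mid = seg.read_end - seg.read_start
    right = read_len - seg.read_end
    if seg.reverse:
        left, right = right, left
    parts = []
    if left:
        parts.append(f"{left}S")
    parts.append(f"{mid}M")
    if right:
        parts.append(f"{right}S")
    return "".join(parts)


def _oriented_seq(read_seq: str, reverse: bool) -> str:
    return reverse_complement(read_seq) if reverse else read_seq


def align_reads(
    fragments: list[FragmentRecord],
    genome: GenomeSequence,
    out_bam: str | Path,
    read_len: int,
    min_clip: int = DEFAULT_MIN_CLIP,
    paired: bool = True,
) -> Path:
    """Write sorted, indexed BAM alignments for every simulated read.

    An ACF read is emitted as primary + supplementary iff both of its
    alignments would carry at least ``min_clip`` soft-clipped bases;
    otherwise only the dominant segment is aligned with the residue
    soft-clipped. Raises if provenance references loci outside the genome
    or mixes haplotypes (only single-reference alignment is meaningful).
    """
    out_bam = Path(out_bam)
    if any(rec.haplotype != "ref" for rec in fragments):
        raise ValueError(
            "provenance contains mutated-haplotype fragments; the idealized "
            "aligner only supports reads simulated from one reference"
        )
    for rec in fragments:
        for chrom, g0, g1, _, _, _ in _frag_segments(rec):
            if chrom not in genome or g1 > len(genome.sequences[chrom]):
                raise ValueError(
                    f"fragment {rec.frag_id} references {chrom}:{g0}-{g1} "
                    "outside the genome"
                )

    header_lines = ["@HD\tVN:1.6\tSO:unsorted"]
    for name in genome.chrom_names:
        header_lines.append(f"@SQ\tSN:{name}\tLN:{len(genome.sequences[name])}")
    header_lines.append("@PG\tID:ffpekit-toy\tPN:ffpekit-toy")

    mates = (1, 2) if paired else (1,)
    with TemporaryDirectory() as tmpdir:
        sam_path = Path(tmpdir) / "unsorted.sam"
        with open(sam_path, "w") as sam:
            sam.write("\n".join(header_lines) + "\n")
            for rec in fragments:
                frag_seq = fragment_sequence(genome, rec)
                per_mate: dict[int, list[tuple[ReadSegment, str, bool]]] = {}
                for mate in mates:
                    segs = read_segments(rec, mate, read_len)
                    read_seq = (
                        frag_seq[:read_len]
                        if mate == 1
                        else reverse_complement(frag_seq)[:read_len]
                    )
                    per_mate[mate] = _plan_mate(segs, read_seq, read_len, min_clip)
                _write_fragment(sam, rec, per_mate, read_len, paired)
        pysam.sort("-o", str(out_bam), str(sam_path))
    pysam.index(str(out_bam))
    return out_bam


def _plan_mate(
    segs: list[ReadSegment], read_seq: str, read_len: int, min_clip: int
) -> list[tuple[ReadSegment, str, bool]]:
    """Decide which alignments a mate gets: [(segment, seq, is_supp), ...]."""
    if not segs:
        return []
    segs = sorted(segs, key=lambda s: (s.read_end - s.read_start), reverse=True)
    primary = segs[0]
    plans = [(primary, read_seq, False)]
    if len(segs) == 2:
        supp = segs[1]
        clip_primary = read_len - (primary.read_end - primary.read_start)
        clip_supp = read_len - (supp.read_end - supp.read_start)
        if clip_primary >= min_clip and clip_supp >= min_clip:
            plans.append((supp, read_seq, True))
    return plans


def _sa_entry(seg: ReadSegment, read_len: int) -> str:
    strand = "-" if seg.reverse else "+"
    return f"{seg.chrom},{seg.ref_start + 1},{strand},{_cigar(seg, read_len)},60,0"


def _write_fragment(
    sam,
    rec: FragmentRecord,
    per_mate: dict[int, list[tuple[ReadSegment, str, bool]]],
    read_len: int,
    paired: bool,
) -> None:
    name = rec.read_name
    primaries = {m: plans[0] for m, plans in per_mate.items() if plans}
    for mate, plans in per_mate.items():
        other = 2 if mate == 1 else 1
        mate_primary = primaries.get(other) if paired else None
        for seg, read_seq, is_supp in plans:
            flag = 0
            if paired:
                flag |= _FLAG_PAIRED
                flag |= _FLAG_READ1 if mate == 1 else _FLAG_READ2
                if mate_primary is not None and mate_primary[0].reverse:
                    flag |= _FLAG_MATE_REVERSE
                if rec.kind == "NORMAL":
                    flag |= _FLAG_PROPER
            if seg.reverse:
                flag |= _FLAG_REVERSE
            if is_supp:
                flag |= _FLAG_SUPPLEMENTARY
            rnext = pnext = None
            tlen = 0
            if paired and mate_primary is not None:
                mseg = mate_primary[0]
                rnext = "=" if mseg.chrom == seg.chrom else mseg.chrom
                pnext = mseg.ref_start + 1
                if rec.kind == "NORMAL" and mseg.chrom == seg.chrom:
                    tlen = rec.frag_len if not seg.reverse else -rec.frag_len
            seq = _oriented_seq(read_seq, seg.reverse)
            tags = ["NM:i:0"]
            partner = [p for p in plans if p[0] is not seg]
            if partner:
                tags.append("SA:Z:" + _sa_entry(partner[0][0], read_len) + ";")
            sam.write(
                "\t".join(
                    [
                        name,
                        str(flag),
                        seg.chrom,
                        str(seg.ref_start + 1),
                        "60",
                        _cigar(seg, read_len),
                        rnext or "*",
                        str(pnext or 0),
                        str(tlen),
                        seq,
                        "*",
                    ]
                    + tags
                )
                + "\n"
            )
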