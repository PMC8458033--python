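"""Two-step filtration of artifact chimeric reads from aligned data.

Step 1 finds chimeric reads (primary + supplementary split alignments) and
counts, per breakpoint signature, how many reads share it: signatures with
at most ``n`` supporting reads mark their reads as artifact candidates
(true SV junctions accumulate many supporting reads, independent artifact
binding events do not — only a mate pair can share one). Step 2 keeps a
candidate only when the two split alignments overlap in read coordinates
by at least ``m`` bases, the footprint of the short reverse-complementary
(SRC) region that created the artifact junction. Excluded reads are
dropped by name (both mates and all their records) and listed in a text
file next to the filtered, indexed BAM.
"""

from __future__ import annotations

import json
import logging
from collections import defaultdict
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import pysam

__all__ = [
    "FilterConfig",
    "BreakpointSignature",
    "FilterReport",
    "AlnInfo",
    "aln_info_from_record",
    "collect_chimeric_groups",
    "breakpoint_signature",
    "count_signature_sharing",
    "src_overlap_length",
    "filter_bam",
]

logger = logging.getLogger(__name__)


@dataclass
class FilterConfig:
    """Filtration thresholds.

    ``max_sharing_n`` of None auto-detects: 2 when the BAM contains paired
    reads, 1 otherwise.
    """

    max_sharing_n: int | None = None
    min_src_len_m: int = 1
    two_step: bool = True
    position_tolerance: int = 0

    def __post_init__(self) -> None:
        if self.max_sharing_n is not None and self.max_sharing_n < 1:
            raise ValueError("max_sharing_n must be >= 1")
        if self.min_src_len_m < 1:
            raise ValueError("min_src_len_m must be >= 1")
        if self.position_tolerance < 0:
            raise ValueError("position_tolerance must be >= 0")


# A signature is a canonically sorted pair of (chrom, position, side) ends;
# side L = clipped boundary at the alignment start, R = at the alignment end.
BreakpointSignature = tuple[tuple[str, int, str], tuple[str, int, str]]


@dataclass(frozen=True)
class AlnInfo:
    """Minimal view of one alignment used by the filter."""

    is_supplementary: bool
    chrom: str
    ref_start: int  # 0-based
    ref_end: int  # 0-based exclusive
    read_start: int  # aligned interval in original-read coordinates
    read_end: int
    read_len: int
    clip_left: int  # clips in stored (SAM) orientation
    clip_right: int
    is_reverse: bool


_QUERY_CONSUMING = {0, 1, 7, 8}  # M, I, =, X
_CLIP_OPS = {4, 5}  # S, H


def aln_info_from_record(rec: pysam.AlignedSegment) -> AlnInfo:
    """Project a pysam record onto original-read coordinates.

    The aligned interval is expressed in the coordinates of the read as it
    was sequenced: for a reverse-strand alignment the SAM-space interval is
    mirrored. Hard clips count as clipped bases.
    """
    cigar = rec.cigartuples or []
    left = 0
    i = 0
    while i < len(cigar) and cigar[i][0] in _CLIP_OPS:
        left += cigar[i][1]
        i += 1
    right = 0
    j = len(cigar) - 1
    while j >= 0 and cigar[j][0] in _CLIP_OPS:
        right += cigar[j][1]
        j -= 1
    aligned = sum(ln for op, ln in cigar[i : j + 1] if op in _QUERY_CONSUMING)
    read_len = left + aligned + right
    if rec.is_reverse:
        read_start = right
    else:
        read_start = left
    return AlnInfo(
        is_supplementary=rec.is_supplementary,
        chrom=rec.reference_name,
        ref_start=rec.reference_start,
        ref_end=rec.reference_end,
        read_start=read_start,
        read_end=read_start + aligned,
        read_len=read_len,
        clip_left=left,
        clip_right=right,
        is_reverse=rec.is_reverse,
    )


GroupKey = tuple[str, int]  # (read name, mate index: 0 single / 1 / 2)


def _mate_index(rec: pysam.AlignedSegment) -> int:
    if not rec.is_paired:
        return 0
    return 2 if rec.is_read2 else 1


def collect_chimeric_groups(
    bam: pysam.AlignmentFile,
) -> tuple[dict[GroupKey, list[AlnInfo]], int, bool]:
    """One pass over a sorted BAM: group split alignments per (name, mate).

    Only primary and supplementary records participate; secondary and
    unmapped records are ignored. Returns the groups, the total number of
    primary reads seen, and whether any paired read was encountered.
    """
    groups: dict[GroupKey, list[AlnInfo]] = defaultdict(list)
    total_reads = 0
    any_paired = False
    for rec in bam.fetch(until_eof=True):
        if rec.is_unmapped or rec.is_secondary:
            continue
        if rec.is_paired:
            any_paired = True
        if not rec.is_supplementary:
            total_reads += 1
        if rec.is_supplementary or rec.has_tag("SA"):
            groups[(rec.query_name, _mate_index(rec))].append(aln_info_from_record(rec))
    # keep only groups that actually have a primary/supplementary split
    groups = {
        key: alns
        for key, alns in groups.items()
        if any(a.is_supplementary for a in alns)
        and any(not a.is_supplementary for a in alns)
    }
    return groups, total_reads, any_paired


def _junction_end(aln: AlnInfo, partner: AlnInfo) -> tuple[str, int, str] | None:
    """The clipped boundary of ``aln`` adjacent to the junction with
    ``partner``, as (chrom, position, side), or None without a soft clip
    on the junction side."""
    # clip intervals in original-read coordinates
    left_ov = min(aln.read_start, partner.read_end) - max(0, partner.read_start)
    right_ov = min(aln.read_len, partner.read_end) - max(aln.read_end, partner.read_start)
    left_ov = max(0, left_ov)
    right_ov = max(0, right_ov)
    if left_ov > right_ov:
        read_side_left = True
    elif right_ov > left_ov:
        read_side_left = False
    else:  # fallback: the larger soft clip
        read_side_left = aln.read_start >= aln.read_len - aln.read_end
    clip_len = aln.read_start if read_side_left else aln.read_len - aln.read_end
    if clip_len == 0:
        return None
    # map read-space side onto the reference
    if read_side_left != aln.is_reverse:
        return (aln.chrom, aln.ref_start, "L")
    return (aln.chrom, aln.ref_end, "R")


def breakpoint_signature(group: list[AlnInfo]) -> list[BreakpointSignature]:
    """Canonical breakpoint signature(s) of one split-read group.

    One signature per (primary, supplementary) pairing; pairings where
    either alignment lacks a soft clip on its junction side yield nothing.
    Constructing from the two alignments in either order gives an identical
    value (ends are sorted).
    """
    primaries = [a for a in group if not a.is_supplementary]
    supps = [a for a in group if a.is_supplementary]
    signatures: list[BreakpointSignature] = []
    for p in primaries:
        for s in supps:
            end_p = _junction_end(p, s)
            end_s = _junction_end(s, p)
            if end_p is None or end_s is None:
                continue
            pair = tuple(sorted((end_p, end_s)))
            signatures.append(pair)  # type: ignore[arg-type]
    return signatures


def src_overlap_length(primary_aln: AlnInfo, supp_aln: AlnInfo) -> int:
    """Overlap of the two aligned intervals in original-read coordinates.

    This is the read-space footprint of the SRC region joining the two
    segments of an artifact chimera; zero when the intervals are disjoint.
    """
    lo = max(primary_aln.read_start, supp_aln.read_start)
    hi = min(primary_aln.read_end, supp_aln.read_end)
    return max(0, hi - lo)


def _cluster_ids(
    signatures: list[BreakpointSignature], tolerance: int
) -> dict[BreakpointSignature, int]:
    """Map each distinct signature to a cluster id; with zero tolerance the
    mapping is the identity. Positive tolerance unions signatures whose two
    ends agree in chrom/side and lie within the tolerance."""
    distinct = sorted(set(signatures))
    ids = {sig: i for i, sig in enumerate(distinct)}
    if tolerance == 0:
        return ids

    parent = list(range(len(distinct)))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a: int, b: int) -> None:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[rb] = ra

    by_shape: dict[tuple, list[int]] = defaultdict(list)
    for i, sig in enumerate(distinct):
        shape = (sig[0][0], sig[0][2], sig[1][0], sig[1][2])
        by_shape[shape].append(i)
    for members in by_shape.values():
        members.sort(key=lambda i: distinct[i][0][1])
        for a_pos, i in enumerate(members):
            for k in members[a_pos + 1 :]:
                if distinct[k][0][1] - distinct[i][0][1] > tolerance:
                    break
                if abs(distinct[k][1][1] - distinct[i][1][1]) <= tolerance:
                    union(i, k)
    return {sig: find(i) for sig, i in ids.items()}


def count_signature_sharing(
    read_signatures: dict[GroupKey, list[BreakpointSignature]],
    config: FilterConfig,
) -> tuple[dict[int, int], set[GroupKey], dict[BreakpointSignature, int]]:
    """Count supporting reads per signature and derive the candidate set.

    Reads (not fragments) are counted; a read contributes once per distinct
    signature cluster. A read is a candidate only if every one of its
    signatures is rare (supported by at most ``max_sharing_n`` reads).
    """
    n = config.max_sharing_n if config.max_sharing_n is not None else 2
    all_sigs = [s for sigs in read_signatures.values() for s in sigs]
    cluster_of = _cluster_ids(all_sigs, config.position_tolerance)
    counts: dict[int, int] = defaultdict(int)
    for sigs in read_signatures.values():
        for cid in {cluster_of[s] for s in sigs}:
            counts[cid] += 1
    candidates = {
        key
        for key, sigs in read_signatures.items()
        if sigs and all(counts[cluster_of[s]] <= n for s in sigs)
    }
    return dict(counts), candidates, cluster_of


@dataclass
class FilterReport:
    """Outcome of one filtration run."""

    total_reads: int = 0
    chimeric_reads: int = 0
    candidate_reads: int = 0
    removed_reads: int = 0
    excluded_names: list[str] = dc_field(default_factory=list)
    sharing_histogram: dict[int, int] = dc_field(default_factory=dict)
    max_sharing_n: int = 2
    min_src_len_m: int = 1
    two_step: bool = True

    def to_dict(self) -> dict:
        return {
            "total_reads": self.total_reads,
            "chimeric_reads": self.chimeric_reads,
            "candidate_reads": self.candidate_reads,
            "removed_reads": self.removed_reads,
            "n_excluded_names": len(self.excluded_names),
            "sharing_histogram": {str(k): v for k, v in sorted(self.sharing_histogram.items())},
            "max_sharing_n": self.max_sharing_n,
            "min_src_len_m": self.min_src_len_m,
            "two_step": self.two_step,
        }

    def write_json(self, path: str | Path) -> None:
        with open(path, "w") as handle:
            json.dump(self.to_dict(), handle, indent=2)
            handle.write("\n")


def filter_bam(
    bam_path: str | Path,
    out_bam: str | Path,
    excluded_path: str | Path,
    config: FilterConfig | None = None,
) -> FilterReport:
    """Run the two-step filter on a coordinate-sorted, indexed BAM.

    Writes the filtered indexed BAM and the excluded-name list (one name
    per line); exclusion is by read name, dropping every record of the
    name. Returns a :class:`FilterReport`.
    """
    if config is None:
        config = FilterConfig()
    bam_path = Path(bam_path)
    out_bam = Path(out_bam)

    with pysam.AlignmentFile(str(bam_path), "rb") as bam:
        if (bam.header.get("HD", {}) or {}).get("SO") != "coordinate":
            raise ValueError(f"{bam_path}: BAM must be coordinate-sorted")
        try:
            bam.check_index()
        except (ValueError, AttributeError) as exc:
            raise ValueError(f"{bam_path}: BAM must be indexed") from exc
        groups, total_reads, any_paired = collect_chimeric_groups(bam)

    n = config.max_sharing_n
    if n is None:
        n = 2 if any_paired else 1
    resolved = FilterConfig(
        max_sharing_n=n,
        min_src_len_m=config.min_src_len_m,
        two_step=config.two_step,
        position_tolerance=config.position_tolerance,
    )

    read_signatures = {key: breakpoint_signature(alns) for key, alns in groups.items()}
    read_signatures = {k: v for k, v in read_signatures.items() if v}
    counts, candidates, _ = count_signature_sharing(read_signatures, resolved)

    removed: set[GroupKey] = set()
    for key in candidates:
        if not resolved.two_step:
            removed.add(key)
            continue
        alns = groups[key]
        primaries = [a for a in alns if not a.is_supplementary]
        supps = [a for a in alns if a.is_supplementary]
        if any(
            src_overlap_length(p, s) >= resolved.min_src_len_m
            for p in primaries
            for s in supps
        ):
            removed.add(key)

    excluded_names = sorted({name for name, _ in removed})
    if total_reads == 0:
        logger.warning("%s: empty input BAM; writing empty outputs", bam_path)

    excluded_set = set(excluded_names)
    with pysam.AlignmentFile(str(bam_path), "rb") as bam, pysam.AlignmentFile(
        str(out_bam), "wb", header=bam.header
    ) as out:
        for rec in bam.fetch(until_eof=True):
            if rec.query_name not in excluded_set:
                out.write(rec)
    pysam.index(str(out_bam))
    with open(excluded_path, "w") as handle:
        for name in excluded_names:
            handle.write(name + "\n")

    histogram: dict[int, int] = defaultdict(int)
    for count in counts.values():
        histogram[count] += 1
    return FilterReport(
        total_reads=total_reads,
        chimeric_reads=len(read_signatures),
        candidate_reads=len(candidates),
        removed_reads=len(removed),
        excluded_names=excluded_names,
        sharing_histogram=dict(histogram),
        max_sharing_n=n,
        min_src_len_m=resolved.min_src_len_m,
        two_step=resolved.two_step,
    )
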