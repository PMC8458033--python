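"""Performance metrics.

Read-level filtration metrics against simulator provenance tags (purity of
the removed set, recall on split-aligned artifact reads), and SV-call
matching against a breakpoint truth table with a positional tolerance,
yielding PPV / sensitivity / F1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import pysam

from .ffpe_simulator import FragmentRecord
from .sv_spiker import SVTruthSet, truth_breakpoints

__all__ = [
    "SVCall",
    "MatchMetrics",
    "ReadFilterMetrics",
    "read_filter_purity",
    "chimeric_acr_recall",
    "match_sv_calls",
    "load_sv_calls",
    "DEFAULT_TOLERANCE",
]

logger = logging.getLogger(__name__)

DEFAULT_TOLERANCE = 5


@dataclass(frozen=True)
class SVCall:
    """A normalized SV call: two breakpoints in 0-based coordinates."""

    sv_type: str
    chrom1: str
    pos1: int
    chrom2: str
    pos2: int
    caller_label: str = ""

    def breakpoints(self) -> list[tuple[str, int]]:
        return [(self.chrom1, self.pos1), (self.chrom2, self.pos2)]


@dataclass
class MatchMetrics:
    tp: int
    fp: int
    fn: int

    @property
    def ppv(self) -> float:
        return self.tp / (self.tp + self.fp) if self.tp + self.fp else 0.0

    @property
    def sensitivity(self) -> float:
        return self.tp / (self.tp + self.fn) if self.tp + self.fn else 0.0

    @property
    def f1(self) -> float:
        denom = self.ppv + self.sensitivity
        return 2 * self.ppv * self.sensitivity / denom if denom else 0.0

    def to_dict(self) -> dict:
        return {
            "tp": self.tp,
            "fp": self.fp,
            "fn": self.fn,
            "ppv": self.ppv,
            "sensitivity": self.sensitivity,
            "f1": self.f1,
        }


@dataclass
class ReadFilterMetrics:
    """Read-level filtration outcome relative to simulator ground truth."""

    purity: float
    n_excluded: int
    n_excluded_acf: int
    recall_chimeric: float | None = None
    n_chimeric_acf: int = 0
    n_chimeric_acf_removed: int = 0
    recall_all_acf: float | None = None
    n_acf_reads: int = 0


def _provenance_by_name(provenance: list[FragmentRecord]) -> dict[str, FragmentRecord]:
    return {rec.read_name: rec for rec in provenance}


def read_filter_purity(
    excluded_names: list[str] | set[str],
    provenance: list[FragmentRecord],
) -> ReadFilterMetrics:
    """Fraction of excluded reads that carry an ACF provenance tag.

    An empty exclusion list yields purity 1.0 by convention (logged).
    Raises if an excluded name is missing from the provenance table.
    """
    by_name = _provenance_by_name(provenance)
    excluded = set(excluded_names)
    if not excluded:
        logger.warning("empty exclusion set; purity is 1.0 by convention")
        return ReadFilterMetrics(purity=1.0, n_excluded=0, n_excluded_acf=0)
    n_acf = 0
    for name in excluded:
        rec = by_name.get(name)
        if rec is None:
            raise KeyError(f"excluded read {name!r} absent from provenance")
        if rec.is_acf:
            n_acf += 1
    return ReadFilterMetrics(
        purity=n_acf / len(excluded),
        n_excluded=len(excluded),
        n_excluded_acf=n_acf,
    )


def chimeric_acr_recall(
    excluded_names: list[str] | set[str],
    provenance: list[FragmentRecord],
    bam_path: str | Path,
) -> ReadFilterMetrics:
    """Fraction of split-aligned (chimeric) ACF reads that were removed.

    The denominator is the set of ACF-tagged reads that possess a
    supplementary alignment in the filter's *input* BAM; non-chimeric ACF
    reads produce no artifact split-read support and are never removed, so
    they are excluded from the denominator. The secondary recall against
    all ACF reads is reported as well.
    """
    by_name = _provenance_by_name(provenance)
    excluded = set(excluded_names)
    for name in excluded:
        if name not in by_name:
            raise KeyError(f"excluded read {name!r} absent from provenance")

    chimeric: set[tuple[str, int]] = set()
    acf_reads: set[tuple[str, int]] = set()
    with pysam.AlignmentFile(str(bam_path), "rb") as bam:
        for rec in bam.fetch(until_eof=True):
            if rec.is_unmapped or rec.is_secondary:
                continue
            prov = by_name.get(rec.query_name)
            if prov is None or not prov.is_acf:
                continue
            mate = 0 if not rec.is_paired else (2 if rec.is_read2 else 1)
            if not rec.is_supplementary:
                acf_reads.add((rec.query_name, mate))
            if rec.is_supplementary:
                chimeric.add((rec.query_name, mate))

    n_chimeric = len(chimeric)
    n_removed = sum(1 for name, _ in chimeric if name in excluded)
    purity_metrics = read_filter_purity(excluded, provenance)
    n_all = len(acf_reads)
    n_all_removed = sum(1 for name, _ in acf_reads if name in excluded)
    return ReadFilterMetrics(
        purity=purity_metrics.purity,
        n_excluded=purity_metrics.n_excluded,
        n_excluded_acf=purity_metrics.n_excluded_acf,
        recall_chimeric=(n_removed / n_chimeric) if n_chimeric else None,
        n_chimeric_acf=n_chimeric,
        n_chimeric_acf_removed=n_removed,
        recall_all_acf=(n_all_removed / n_all) if n_all else None,
        n_acf_reads=n_all,
    )


def _call_matches_truth(
    call: SVCall,
    truth_bps: list[tuple[str, int]],
    tolerance: int,
    any_end: bool,
) -> int | None:
    """Distance score if the call matches this truth SV, else None.

    Both call breakpoints must land within the tolerance of breakpoints of
    the single truth SV, assigned injectively; with ``any_end`` a single
    matching breakpoint suffices.
    """
    bp1, bp2 = call.breakpoints()

    def dist(bp: tuple[str, int], tbp: tuple[str, int]) -> int | None:
        if bp[0] != tbp[0]:
            return None
        d = abs(bp[1] - tbp[1])
        return d if d <= tolerance else None

    best: int | None = None
    for i, t1 in enumerate(truth_bps):
        d1 = dist(bp1, t1)
        if d1 is None:
            continue
        if any_end:
            best = d1 if best is None else min(best, d1)
        for j, t2 in enumerate(truth_bps):
            if j == i:
                continue
            d2 = dist(bp2, t2)
            if d2 is None:
                continue
            score = d1 + d2
            best = score if best is None else min(best, score)
    if best is None and any_end:
        for t2 in truth_bps:
            d2 = dist(bp2, t2)
            if d2 is not None:
                best = d2 if best is None else min(best, d2)
    return best


def match_sv_calls(
    calls: list[SVCall],
    truth: SVTruthSet,
    tolerance: int = DEFAULT_TOLERANCE,
    any_end: bool = False,
) -> MatchMetrics:
    """Match calls to truth SVs within a positional tolerance.

    Greedy nearest-first one-to-one assignment: all (call, truth) pairs
    whose breakpoints are compatible within the tolerance are ranked by
    total breakpoint distance (ties by lowest indices) and consumed
    greedily. Unmatched calls are false positives; unmatched truth SVs are
    false negatives. The result is independent of call order.
    """
    bps_by_sv: dict[str, list[tuple[str, int]]] = {}
    for chrom, pos, sv_id, _sv_type, _src in truth_breakpoints(truth):
        bps_by_sv.setdefault(sv_id, []).append((chrom, pos))
    sv_ids = sorted(bps_by_sv)

    scored: list[tuple[int, int, int]] = []  # (score, call_idx, sv_idx)
    for ci, call in enumerate(calls):
        for si, sv_id in enumerate(sv_ids):
            score = _call_matches_truth(call, bps_by_sv[sv_id], tolerance, any_end)
            if score is not None:
                scored.append((score, ci, si))
    scored.sort()
    used_calls: set[int] = set()
    used_svs: set[int] = set()
    tp = 0
    for _score, ci, si in scored:
        if ci in used_calls or si in used_svs:
            continue
        used_calls.add(ci)
        used_svs.add(si)
        tp += 1
    return MatchMetrics(tp=tp, fp=len(calls) - tp, fn=len(sv_ids) - tp)


def load_sv_calls(path: str | Path) -> list[SVCall]:
    """Read a minimal SV call set from VCF (SVTYPE/END/CHR2) or BEDPE.

    VCF positions (1-based) are converted to 0-based; BEDPE start
    coordinates are taken as-is. Unparseable records raise with the record
    number.
    """
    path = Path(path)
    if path.suffix.lower() == ".bedpe":
        return _load_bedpe(path)
    return _load_vcf(path)


def _load_vcf(path: Path) -> list[SVCall]:
    calls: list[SVCall] = []
    with pysam.VariantFile(str(path)) as vcf:
        for i, rec in enumerate(vcf, start=1):
            info = rec.info
            if "SVTYPE" not in info:
                raise ValueError(f"{path}: record {i}: missing SVTYPE")
            sv_type = str(info["SVTYPE"])
            pos1 = rec.pos - 1  # pysam rec.pos is 1-based
            chrom2 = str(info.get("CHR2", rec.chrom))
            end = rec.stop  # 0-based exclusive END
            pos2 = end - 1
            calls.append(
                SVCall(sv_type, rec.chrom, pos1, chrom2, pos2, caller_label=rec.id or "")
            )
    return calls


def _load_bedpe(path: Path) -> list[SVCall]:
    calls: list[SVCall] = []
    with open(path) as handle:
        for i, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ValueError(f"{path}: line {i}: expected >= 6 BEDPE columns")
            chrom1, start1, _end1, chrom2, start2, _end2 = fields[:6]
            sv_type = fields[6] if len(fields) > 6 else "BND"
            try:
                calls.append(
                    SVCall(sv_type, chrom1, int(start1), chrom2, int(start2))
                )
            except ValueError as exc:
                raise ValueError(f"{path}: line {i}: {exc}") from exc
    return calls
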