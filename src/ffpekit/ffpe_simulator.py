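"""FFPE artifact-read simulation.

Simulates sequencing libraries from formalin-fixed samples: a mixture of
normal fragments and artifact chimeric fragments (ACFs). An ACF joins two
genomic segments that share a short reverse-complementary (SRC) region;
the two segments come either from the same 5 kb genome window ("adjacent")
or from different windows ("distant"). Reads are emitted as paired-end or
single-end FASTQ with positional Phred qualities and random substitution
errors, and every read name carries its ground-truth provenance.

Geometry conventions
--------------------
A fragment's top strand is ``A_up + s + revcomp(B_up)`` where ``s`` is the
seed's SRC copy. Segment A covers fragment coordinates ``[0, j + L)`` and
segment B covers ``[j, frag_len)``, where ``j`` is the junction offset and
``L`` the SRC length; the two read-space segments overlap by exactly ``L``.
Each segment maps to a genomic interval with a direction flag: ``+`` means
ascending fragment coordinate equals ascending genome coordinate.
"""

from __future__ import annotations

import csv
import logging
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import stats

from .genome_io import (
    GenomeSequence,
    GenomicInterval,
    Window,
    find_motif_occurrences,
    partition_windows,
    reverse_complement,
)
from .phred_model import (
    PhredProfile,
    default_decay_profile,
    sample_quality_matrix,
)

__all__ = [
    "SimConfig",
    "SRCPair",
    "ChimericFragment",
    "FragmentRecord",
    "ReadProvenance",
    "SimResult",
    "SRC_LEN_MIN",
    "SRC_LEN_MAX",
    "sample_src_length",
    "sample_spike_weights",
    "select_adjacent_pair",
    "select_distant_pair",
    "build_chimeric_fragment",
    "generate_acfs",
    "simulate_reads",
    "inject_sequencing_errors",
    "prepare_context",
    "fragment_sequence",
    "write_provenance_tsv",
    "read_provenance_tsv",
]

logger = logging.getLogger(__name__)

SRC_LEN_MIN = 2
SRC_LEN_MAX = 30

KIND_NORMAL = "NORMAL"
KIND_ADJ = "ACF_ADJ"
KIND_DIST = "ACF_DIST"

_NAME_PREFIX = "SF"
_SEED_ATTEMPTS_PER_LEN = 50
_MAX_TOTAL_ATTEMPTS = 2_000


@dataclass
class SimConfig:
    """Simulation parameters; defaults follow the published tool's settings
    where the paper states them, documented fallbacks otherwise."""

    coverage: float = 30.0
    read_len: int = 150
    paired: bool = True
    frag_len_mean: float = 250.0
    frag_len_sd: float = 50.0
    acf_prop: float = 0.10
    window_len: int = 5_000
    same_chrom_prop: float = 0.43
    adj_given_same_chrom: float = 0.63
    same_strand_prop_adjacent: float = 0.65
    same_strand_prop_distant: float = 0.50
    src_len_mu: float = 1.8
    src_len_sigma: float = 0.55
    adj_dist_mu: float = 4.7
    adj_dist_sigma: float = 0.35
    spike_region_len: int = 1_500
    spike_alpha: float = 0.5
    spike_beta: float = 0.5
    enzymatic_prob: float = 0.0
    sub_error_from_quals: bool = True
    target_bed: str | None = None
    sv_frequency: float = 0.5
    seed: int | None = None

    def __post_init__(self) -> None:
        for name in (
            "acf_prop",
            "same_chrom_prop",
            "adj_given_same_chrom",
            "same_strand_prop_adjacent",
            "same_strand_prop_distant",
            "enzymatic_prob",
            "sv_frequency",
        ):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name}={value} outside [0, 1]")
        if self.coverage <= 0:
            raise ValueError("coverage must be > 0")
        if self.frag_len_mean < self.read_len:
            raise ValueError("frag_len_mean must be >= read_len")
        if self.window_len < 1 or self.spike_region_len < 1:
            raise ValueError("window/spike region lengths must be >= 1")

    @property
    def adjacent_fraction(self) -> float:
        """Overall probability that an ACF is adjacent (~0.2709 default)."""
        return self.same_chrom_prop * self.adj_given_same_chrom

    @property
    def distant_same_chrom_prob(self) -> float:
        """P(same chromosome | distant), derived so that the overall
        same-chromosome fraction equals ``same_chrom_prop``."""
        adj = self.adjacent_fraction
        return (self.same_chrom_prop - adj) / (1.0 - adj)


@dataclass(frozen=True)
class SRCPair:
    """A seed locus and its reverse-complementary target locus."""

    seed_locus: GenomicInterval  # strand always +
    target_locus: GenomicInterval
    src_len: int
    category: str  # adjacent | distant
    same_strand: bool
    distance: int | None = None  # adjacent only: |target.start - seed.start|

    def validate(self, genome: GenomeSequence) -> None:
        seed = genome.fetch(self.seed_locus.chrom, self.seed_locus.start, self.seed_locus.end)
        target = genome.fetch(
            self.target_locus.chrom, self.target_locus.start, self.target_locus.end
        )
        if self.target_locus.strand == "-":
            target = reverse_complement(target)
        if target != reverse_complement(seed):
            raise ValueError("SRC pair is not reverse complementary")


@dataclass
class ChimericFragment:
    """One artifact chimeric fragment with full segment geometry."""

    frag_id: int
    seg_a: GenomicInterval
    a_dir: str
    seg_b: GenomicInterval
    b_dir: str
    src_len: int
    junction_offset: int
    category: str
    same_strand: bool
    enzymatic: bool
    sequence: str
    distance: int | None = None

    @property
    def frag_len(self) -> int:
        return len(self.sequence)

    def src_copy(self) -> str:
        return self.sequence[self.junction_offset : self.junction_offset + self.src_len]

    def check_structure(self, genome: GenomeSequence) -> None:
        """Verify the SRC string invariant against the genome."""
        j, L = self.junction_offset, self.src_len
        a_seq = genome.fetch(self.seg_a.chrom, self.seg_a.start, self.seg_a.end)
        if self.a_dir == "-":
            a_seq = reverse_complement(a_seq)
        b_seq = genome.fetch(self.seg_b.chrom, self.seg_b.start, self.seg_b.end)
        if self.b_dir == "-":
            b_seq = reverse_complement(b_seq)
        if a_seq != self.sequence[: j + L]:
            raise ValueError("segment A does not match fragment prefix")
        if b_seq != self.sequence[j:]:
            raise ValueError("segment B does not match fragment suffix")
        if a_seq[-L:] != b_seq[:L]:
            raise ValueError("SRC copies disagree at the junction")


@dataclass(frozen=True)
class ReadProvenance:
    """Ground truth encoded in a read name.

    Grammar: ``SF:<frag_id>:<kind>:<junction_offset>:<src_len>`` with
    ``junction_offset = -1`` and ``src_len = 0`` for normal fragments. The
    name is shared by both mates of a pair (SAM requires identical QNAME);
    the mate index lives in FASTQ file membership and SAM flags.
    """

    frag_id: int
    kind: str
    junction_offset: int
    src_len: int

    def format(self) -> str:
        return (
            f"{_NAME_PREFIX}:{self.frag_id}:{self.kind}:"
            f"{self.junction_offset}:{self.src_len}"
        )

    @classmethod
    def parse(cls, name: str) -> "ReadProvenance":
        parts = name.split(":")
        if len(parts) != 5 or parts[0] != _NAME_PREFIX:
            raise ValueError(f"not a simulator read name: {name!r}")
        return cls(int(parts[1]), parts[2], int(parts[3]), int(parts[4]))

    @property
    def is_acf(self) -> bool:
        return self.kind != KIND_NORMAL


@dataclass
class FragmentRecord:
    """Provenance-table row: one simulated fragment (two reads if paired)."""

    frag_id: int
    kind: str
    haplotype: str
    frag_len: int
    chrom_a: str
    a_start: int
    a_end: int
    a_dir: str
    chrom_b: str = ""
    b_start: int = -1
    b_end: int = -1
    b_dir: str = "."
    junction_offset: int = -1
    src_len: int = 0
    same_strand: bool | None = None
    enzymatic: bool = False
    distance: int | None = None
    sequence: str | None = None  # cached for ACFs; not serialized

    @property
    def read_name(self) -> str:
        return ReadProvenance(
            self.frag_id, self.kind, self.junction_offset, self.src_len
        ).format()

    @property
    def is_acf(self) -> bool:
        return self.kind != KIND_NORMAL


# --------------------------------------------------------------------------
# elementary samplers


def sample_src_length(config: SimConfig, rng: np.random.Generator) -> int:
    """Lognormal SRC length, rounded and clamped to [2, 30] bases."""
    draw = rng.lognormal(config.src_len_mu, config.src_len_sigma)
    return int(min(SRC_LEN_MAX, max(SRC_LEN_MIN, round(draw))))


def sample_fragment_length(config: SimConfig, rng: np.random.Generator) -> int:
    """Normal fragment length truncated below at read_len."""
    while True:
        draw = rng.normal(config.frag_len_mean, config.frag_len_sd)
        if draw >= config.read_len:
            return int(round(draw))


def sample_spike_weights(
    n_regions: int, config: SimConfig, rng: np.random.Generator
) -> np.ndarray:
    """I.i.d. Beta(alpha, beta) draws normalized to sum to one."""
    if n_regions < 1:
        raise ValueError("n_regions must be >= 1")
    raw = rng.beta(config.spike_alpha, config.spike_beta, size=n_regions)
    total = raw.sum()
    if total == 0:
        return np.full(n_regions, 1.0 / n_regions)
    return raw / total


def inject_sequencing_errors(
    seq: str, quals: str, config: SimConfig, rng: np.random.Generator
) -> str:
    """Substitute each base with probability ``10^(-Q/10)``; no indels.

    ``quals`` is a Sanger-encoded quality string of the same length.
    """
    if len(seq) != len(quals):
        raise ValueError("sequence/quality length mismatch")
    if not seq:
        return seq
    seq_arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    q_arr = np.frombuffer(quals.encode("ascii"), dtype=np.uint8).astype(np.int32) - 33
    _inject_errors_matrix(seq_arr.reshape(1, -1), q_arr.reshape(1, -1), rng)
    return seq_arr.tobytes().decode("ascii")


_BASE_CODES = np.frombuffer(b"ACGT", dtype=np.uint8)
_CODE_TO_IDX = np.full(256, 255, dtype=np.uint8)
for _i, _c in enumerate(b"ACGT"):
    _CODE_TO_IDX[_c] = _i


def _inject_errors_matrix(
    seq_mat: np.ndarray, q_mat: np.ndarray, rng: np.random.Generator
) -> None:
    """In-place random substitutions on an ASCII base matrix (N untouched)."""
    p_err = np.power(10.0, -q_mat / 10.0)
    idx = _CODE_TO_IDX[seq_mat]
    mask = (rng.random(seq_mat.shape) < p_err) & (idx != 255)
    n_hit = int(mask.sum())
    if n_hit:
        shift = rng.integers(1, 4, size=n_hit).astype(np.uint8)
        seq_mat[mask] = _BASE_CODES[(idx[mask] + shift) % 4]


# --------------------------------------------------------------------------
# selection context (windows, spikes, eligibility)


@dataclass
class SelectionContext:
    """Precomputed per-genome structures used by the SRC-pair samplers."""

    genome: GenomeSequence
    windows: list[Window]
    seed_window_ids: np.ndarray  # eligible seed windows
    seed_window_cum: np.ndarray  # cumulative length weights over the above
    target_windows_by_chrom: dict[str, list[int]]
    spike_regions: list[GenomicInterval]
    spike_cum: np.ndarray  # cumulative spike weights

    def pick_seed_window(self, rng: np.random.Generator) -> Window:
        u = rng.random() * self.seed_window_cum[-1]
        pos = int(np.searchsorted(self.seed_window_cum, u, side="right"))
        pos = min(pos, len(self.seed_window_ids) - 1)
        return self.windows[int(self.seed_window_ids[pos])]

    def pick_spike_position(
        self, rng: np.random.Generator, margin: int
    ) -> tuple[str, int] | None:
        u = rng.random() * self.spike_cum[-1]
        pos = int(np.searchsorted(self.spike_cum, u, side="right"))
        pos = min(pos, len(self.spike_regions) - 1)
        region = self.spike_regions[pos]
        chrom_len = len(self.genome.sequences[region.chrom])
        hi = min(region.end, chrom_len - margin)
        if hi <= region.start:
            return None
        return region.chrom, int(rng.integers(region.start, hi))

    def window_of(self, chrom: str, pos: int, window_len: int) -> int | None:
        """Global index of the window containing (chrom, pos), if eligible."""
        for wid in self.target_windows_by_chrom.get(chrom, []):
            win = self.windows[wid]
            if win.start <= pos < win.end:
                return wid
        return None


def _n_fraction(seq: str) -> float:
    return seq.count("N") / len(seq) if seq else 1.0


def prepare_context(
    genome: GenomeSequence,
    config: SimConfig,
    rng: np.random.Generator,
    targets: list[GenomicInterval] | None = None,
) -> SelectionContext:
    """Build window partition, eligibility masks and spike weights.

    Windows with more than 50% N or shorter than ``2 * read_len`` are
    excluded from seed selection; N-heavy windows are also excluded as
    distant targets. In targeted (WES) mode only windows and spike regions
    overlapping a target are eligible for seeds. Consumes RNG state for the
    Beta spike weights.
    """
    windows = partition_windows(genome, config.window_len)

    def _on_target(chrom: str, start: int, end: int) -> bool:
        if targets is None:
            return True
        return any(
            t.chrom == chrom and t.start < end and start < t.end for t in targets
        )

    seed_ids: list[int] = []
    seed_weights: list[float] = []
    target_by_chrom: dict[str, list[int]] = {}
    for win in windows:
        seq = genome.fetch(win.chrom, win.start, win.end)
        heavy_n = _n_fraction(seq) > 0.5
        if not heavy_n:
            target_by_chrom.setdefault(win.chrom, []).append(win.index)
        if heavy_n or len(win) < 2 * config.read_len:
            continue
        if not _on_target(win.chrom, win.start, win.end):
            continue
        seed_ids.append(win.index)
        seed_weights.append(float(len(win)))
    if not seed_ids:
        raise ValueError("no eligible seed windows in genome")

    regions: list[GenomicInterval] = []
    for chrom in genome.chrom_names:
        clen = len(genome.sequences[chrom])
        for start in range(0, clen, config.spike_region_len):
            end = min(start + config.spike_region_len, clen)
            if _on_target(chrom, start, end):
                regions.append(GenomicInterval(chrom, start, end))
    if not regions:
        raise ValueError("no eligible spike regions in genome")
    weights = sample_spike_weights(len(regions), config, rng)

    return SelectionContext(
        genome=genome,
        windows=windows,
        seed_window_ids=np.array(seed_ids, dtype=np.int64),
        seed_window_cum=np.cumsum(seed_weights),
        target_windows_by_chrom=target_by_chrom,
        spike_regions=regions,
        spike_cum=np.cumsum(weights),
    )


# --------------------------------------------------------------------------
# SRC pair selection


def _occurrences_in_window(
    genome: GenomeSequence, window: Window, motif: str
) -> list[int]:
    wseq = genome.fetch(window.chrom, window.start, window.end)
    return [window.start + p for p in find_motif_occurrences(wseq, motif)]


def select_adjacent_pair(
    genome: GenomeSequence,
    window: Window,
    config: SimConfig,
    rng: np.random.Generator,
    src_len: int | None = None,
    same_strand: bool | None = None,
) -> SRCPair | None:
    """Sample one within-window SRC pair, or None if the window yields none.

    The seed is a random forward-strand locus in the window; candidate
    targets are every exact reverse-complement occurrence (on the strand
    implied by the strand decision), excluding the seed's own locus; one is
    chosen with probability proportional to the lognormal density of its
    distance to the seed. ``same_strand`` may be fixed by the caller so a
    retry loop does not redraw it (keeping the realized same-strand
    fraction at its configured value regardless of per-strand target
    availability); None draws it here.
    """
    L = src_len if src_len is not None else sample_src_length(config, rng)
    if len(window) < L + 1:
        return None
    s0 = int(rng.integers(window.start, window.end - L + 1))
    seed = genome.fetch(window.chrom, s0, s0 + L)
    if "N" in seed:
        return None
    if same_strand is None:
        same_strand = rng.random() < config.same_strand_prop_adjacent
    motif = reverse_complement(seed) if same_strand else seed
    candidates = [
        t0 for t0 in _occurrences_in_window(genome, window, motif) if t0 != s0
    ]
    if not candidates:
        return None
    distances = np.abs(np.array(candidates) - s0).astype(float)
    weights = stats.lognorm.pdf(
        distances, s=config.adj_dist_sigma, scale=math.exp(config.adj_dist_mu)
    )
    total = weights.sum()
    if total <= 0:
        weights = np.full(len(candidates), 1.0 / len(candidates))
    else:
        weights = weights / total
    choice = int(rng.choice(len(candidates), p=weights))
    t0 = candidates[choice]
    return SRCPair(
        seed_locus=GenomicInterval(window.chrom, s0, s0 + L, "+"),
        target_locus=GenomicInterval(
            window.chrom, t0, t0 + L, "+" if same_strand else "-"
        ),
        src_len=L,
        category="adjacent",
        same_strand=same_strand,
        distance=int(abs(t0 - s0)),
    )


def select_distant_pair(
    ctx: SelectionContext,
    config: SimConfig,
    rng: np.random.Generator,
    src_len: int | None = None,
    same_strand: bool | None = None,
) -> SRCPair | None:
    """Sample one between-window SRC pair, or None on a failed attempt.

    The seed position is drawn from the Beta-weighted spike regions; the
    target window is a different window on the seed's chromosome with the
    derived same-chromosome probability, otherwise a uniform window on
    another chromosome; the target occurrence is chosen uniformly.
    """
    genome = ctx.genome
    if len(ctx.windows) < 2:
        raise ValueError("distant ACF simulation requires >= 2 genome windows")
    L = src_len if src_len is not None else sample_src_length(config, rng)
    picked = ctx.pick_spike_position(rng, margin=L)
    if picked is None:
        return None
    chrom, s0 = picked
    seed = genome.fetch(chrom, s0, s0 + L)
    if "N" in seed:
        return None
    seed_wid = ctx.window_of(chrom, s0, config.window_len)
    if seed_wid is None:
        return None

    same_chrom_windows = [w for w in ctx.target_windows_by_chrom.get(chrom, []) if w != seed_wid]
    other_windows = [
        w
        for c, wins in ctx.target_windows_by_chrom.items()
        if c != chrom
        for w in wins
    ]
    use_same_chrom = rng.random() < config.distant_same_chrom_prob
    if not other_windows:
        use_same_chrom = True  # single-chromosome genome: no other choice
    if use_same_chrom and not same_chrom_windows:
        use_same_chrom = False
    pool = same_chrom_windows if use_same_chrom else other_windows
    if not pool:
        raise ValueError("no candidate target windows for distant ACF")
    target_win = ctx.windows[pool[int(rng.integers(0, len(pool)))]]

    if same_strand is None:
        same_strand = rng.random() < config.same_strand_prop_distant
    motif = reverse_complement(seed) if same_strand else seed
    candidates = [
        t0
        for t0 in _occurrences_in_window(genome, target_win, motif)
        if t0 != s0
    ]
    if not candidates:
        return None
    t0 = candidates[int(rng.integers(0, len(candidates)))]
    return SRCPair(
        seed_locus=GenomicInterval(chrom, s0, s0 + L, "+"),
        target_locus=GenomicInterval(
            target_win.chrom, t0, t0 + L, "+" if same_strand else "-"
        ),
        src_len=L,
        category="distant",
        same_strand=same_strand,
        distance=None,
    )


# --------------------------------------------------------------------------
# fragment construction


def build_chimeric_fragment(
    genome: GenomeSequence,
    pair: SRCPair,
    frag_len: int,
    config: SimConfig,
    rng: np.random.Generator,
    frag_id: int = 0,
) -> ChimericFragment | None:
    """Assemble the double-stranded fragment for one SRC pair.

    The top strand is ``A_up + s + revcomp(B_up)``; the split of the
    non-SRC length between the two sides is uniform with each side >= 1,
    constrained to the available chromosome context (None when no split
    fits, so the caller can resample). With probability ``enzymatic_prob``
    a same-strand adjacent fragment is instead cut so that both fragment
    ends map to the same genomic coordinate.
    """
    L = pair.src_len
    if frag_len < 2 * L + 2:
        raise ValueError(f"frag_len {frag_len} too small for src_len {L}")
    chrom_a = pair.seed_locus.chrom
    chrom_b = pair.target_locus.chrom
    s0 = pair.seed_locus.start
    t0 = pair.target_locus.start
    b_chrom_len = len(genome.sequences[chrom_b])

    rem = frag_len - L
    max_a = s0  # upstream bases available on the seed side
    if pair.same_strand:
        max_b = t0
    else:
        max_b = b_chrom_len - (t0 + L)

    enzymatic = False
    a_up = b_up = 0
    if (
        pair.category == "adjacent"
        and pair.same_strand
        and config.enzymatic_prob > 0
        and rng.random() < config.enzymatic_prob
    ):
        # Both fragment ends at the same genomic coordinate: b_up is slaved
        # to a_up through the seed/target offset; total length floats.
        offset = t0 - s0
        lo = max(
            1,
            1 - offset,
            math.ceil((config.read_len - L - offset) / 2),
            math.ceil((2 * L + 2 - L - offset) / 2),
        )
        hi = min(max_a, max_b - offset, rem - 1)
        if lo <= hi:
            a_up = int(rng.integers(lo, hi + 1))
            b_up = a_up + offset
            enzymatic = True
    if not enzymatic:
        lo = max(1, rem - max_b)
        hi = min(rem - 1, max_a)
        if lo > hi:
            return None
        a_up = int(rng.integers(lo, hi + 1))
        b_up = rem - a_up

    a_part = genome.fetch(chrom_a, s0 - a_up, s0 + L)
    if pair.same_strand:
        seg_b = GenomicInterval(chrom_b, t0 - b_up, t0 + L)
        b_dir = "-"
        b_part = reverse_complement(genome.fetch(chrom_b, t0 - b_up, t0 + L))
    else:
        seg_b = GenomicInterval(chrom_b, t0, t0 + L + b_up)
        b_dir = "+"
        b_part = genome.fetch(chrom_b, t0, t0 + L + b_up)
    if a_part[-L:] != b_part[:L]:
        raise AssertionError("SRC copies disagree at the junction")
    sequence = a_part + b_part[L:]
    if "N" in sequence:
        return None
    if len(sequence) < config.read_len:
        return None
    category = pair.category
    return ChimericFragment(
        frag_id=frag_id,
        seg_a=GenomicInterval(chrom_a, s0 - a_up, s0 + L),
        a_dir="+",
        seg_b=seg_b,
        b_dir=b_dir,
        src_len=L,
        junction_offset=a_up,
        category=category,
        same_strand=pair.same_strand,
        enzymatic=enzymatic,
        sequence=sequence,
        distance=pair.distance,
    )


def generate_acfs(
    genome: GenomeSequence,
    n: int,
    config: SimConfig,
    rng: np.random.Generator,
    ctx: SelectionContext | None = None,
    frag_id_start: int = 0,
) -> list[ChimericFragment]:
    """Generate ``n`` artifact chimeric fragments.

    The adjacent/distant category and the strand relation are decided up
    front per fragment (so their realized fractions track the configured
    proportions exactly), then seeds are resampled within the category
    until a valid pair and fragment are found; after every 50 failed seeds
    the SRC length is decremented (short SRCs always find targets
    eventually).
    """
    if ctx is None:
        ctx = prepare_context(genome, config, rng)
    fragments: list[ChimericFragment] = []
    for i in range(n):
        category = (
            "adjacent" if rng.random() < config.adjacent_fraction else "distant"
        )
        strand_prop = (
            config.same_strand_prop_adjacent
            if category == "adjacent"
            else config.same_strand_prop_distant
        )
        same_strand = bool(rng.random() < strand_prop)
        frag_len = sample_fragment_length(config, rng)
        src_len = sample_src_length(config, rng)
        frag_len = max(frag_len, 2 * src_len + 2)
        fragment: ChimericFragment | None = None
        failures = 0
        for _ in range(_MAX_TOTAL_ATTEMPTS):
            if category == "adjacent":
                window = ctx.pick_seed_window(rng)
                pair = select_adjacent_pair(
                    genome, window, config, rng, src_len, same_strand
                )
            else:
                pair = select_distant_pair(ctx, config, rng, src_len, same_strand)
            if pair is not None:
                fragment = build_chimeric_fragment(
                    genome, pair, frag_len, config, rng, frag_id=frag_id_start + i
                )
                if fragment is not None:
                    break
            failures += 1
            if failures % _SEED_ATTEMPTS_PER_LEN == 0 and src_len > SRC_LEN_MIN:
                src_len -= 1
        if fragment is None:
            raise RuntimeError(
                f"could not place an ACF after {_MAX_TOTAL_ATTEMPTS} attempts "
                f"(category {category})"
            )
        fragments.append(fragment)
    return fragments


def fragment_record(frag: ChimericFragment, haplotype: str = "ref") -> FragmentRecord:
    return FragmentRecord(
        frag_id=frag.frag_id,
        kind=KIND_ADJ if frag.category == "adjacent" else KIND_DIST,
        haplotype=haplotype,
        frag_len=frag.frag_len,
        chrom_a=frag.seg_a.chrom,
        a_start=frag.seg_a.start,
        a_end=frag.seg_a.end,
        a_dir=frag.a_dir,
        chrom_b=frag.seg_b.chrom,
        b_start=frag.seg_b.start,
        b_end=frag.seg_b.end,
        b_dir=frag.b_dir,
        junction_offset=frag.junction_offset,
        src_len=frag.src_len,
        same_strand=frag.same_strand,
        enzymatic=frag.enzymatic,
        distance=frag.distance,
        sequence=frag.sequence,
    )


def fragment_sequence(genome: GenomeSequence, rec: FragmentRecord) -> str:
    """Reconstruct a fragment's top-strand sequence from its geometry."""
    if rec.sequence is not None:
        return rec.sequence
    a_seq = genome.fetch(rec.chrom_a, rec.a_start, rec.a_end)
    if rec.a_dir == "-":
        a_seq = reverse_complement(a_seq)
    if not rec.is_acf:
        return a_seq
    b_seq = genome.fetch(rec.chrom_b, rec.b_start, rec.b_end)
    if rec.b_dir == "-":
        b_seq = reverse_complement(b_seq)
    return a_seq + b_seq[rec.src_len :]


# --------------------------------------------------------------------------
# read generation


@dataclass
class SimResult:
    fastq_r1: Path
    fastq_r2: Path | None
    provenance_path: Path
    fragments: list[FragmentRecord]
    n_reads: int
    read_len: int


def _load_targets(path: str | Path) -> list[GenomicInterval]:
    targets: list[GenomicInterval] = []
    with open(path) as handle:
        for line in handle:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            targets.append(GenomicInterval(fields[0], int(fields[1]), int(fields[2])))
    if not targets:
        raise ValueError(f"{path}: no target intervals")
    return targets


def _sample_normal_fragments(
    genome: GenomeSequence,
    n: int,
    config: SimConfig,
    rng: np.random.Generator,
    haplotype: str,
    frag_id_start: int,
    targets: list[GenomicInterval] | None,
) -> list[FragmentRecord]:
    records: list[FragmentRecord] = []
    chrom_names = genome.chrom_names
    lengths = np.array([len(genome.sequences[c]) for c in chrom_names], dtype=float)
    chrom_cum = np.cumsum(lengths / lengths.sum())
    pad = int(config.frag_len_mean // 2)
    if targets is not None:
        t_lens = np.array(
            [
                min(len(genome.sequences[t.chrom]), t.end + pad)
                - max(0, t.start - pad)
                for t in targets
            ],
            dtype=float,
        )
        t_cum = np.cumsum(t_lens / t_lens.sum())
    for i in range(n):
        flen = sample_fragment_length(config, rng)
        if targets is None:
            ci = int(np.searchsorted(chrom_cum, rng.random(), side="right"))
            ci = min(ci, len(chrom_names) - 1)
            chrom = chrom_names[ci]
            clen = len(genome.sequences[chrom])
            if clen < flen:
                flen = max(config.read_len, clen)
            start = int(rng.integers(0, clen - flen + 1))
        else:
            ti = int(np.searchsorted(t_cum, rng.random(), side="right"))
            ti = min(ti, len(targets) - 1)
            tgt = targets[ti]
            chrom = tgt.chrom
            clen = len(genome.sequences[chrom])
            if clen < flen:
                flen = max(config.read_len, clen)
            lo = max(0, tgt.start - pad)
            hi = min(clen, tgt.end + pad)
            mid = int(rng.integers(lo, hi))
            start = max(0, min(mid - flen // 2, clen - flen))
        records.append(
            FragmentRecord(
                frag_id=frag_id_start + i,
                kind=KIND_NORMAL,
                haplotype=haplotype,
                frag_len=flen,
                chrom_a=chrom,
                a_start=start,
                a_end=start + flen,
                a_dir="+",
            )
        )
    return records


def simulate_reads(
    genome: GenomeSequence,
    mutated_genome: GenomeSequence | None,
    profile: PhredProfile | None,
    config: SimConfig,
    rng: np.random.Generator,
    out_prefix: str | Path,
) -> SimResult:
    """Run the full simulation and write FASTQ plus a provenance table.

    Read count is ``round(coverage * genome_length / read_len)`` (target
    length in WES mode); a fraction ``acf_prop`` of fragments are ACFs.
    When a mutated genome is supplied, each fragment is drawn from it with
    probability ``sv_frequency``. Output is deterministic for a fixed
    seed/config.
    """
    if profile is None:
        profile = default_decay_profile(config.read_len)
    if profile.read_len != config.read_len:
        raise ValueError(
            f"profile read_len {profile.read_len} != config read_len {config.read_len}"
        )
    targets = _load_targets(config.target_bed) if config.target_bed else None

    basis_len = (
        sum(len(t) for t in targets) if targets is not None else genome.total_length
    )
    n_reads = int(round(config.coverage * basis_len / config.read_len))
    if config.paired:
        n_pairs = n_reads // 2
        n_frag = n_pairs
        n_reads = 2 * n_pairs
    else:
        n_frag = n_reads
    n_acf = int(round(config.acf_prop * n_frag))
    n_normal = n_frag - n_acf

    genomes = {"ref": genome}
    if mutated_genome is not None:
        genomes["mut"] = mutated_genome
    hap_draws = (
        rng.random(n_frag) < config.sv_frequency
        if mutated_genome is not None
        else np.zeros(n_frag, dtype=bool)
    )
    haps = np.where(hap_draws, "mut", "ref")

    contexts: dict[str, SelectionContext] = {}
    fragments: list[FragmentRecord] = []
    frag_id = 1
    # ACF fragments first, grouped by haplotype for context reuse.
    for hap in ("ref", "mut"):
        count = int(np.sum(haps[:n_acf] == hap))
        if count == 0:
            continue
        if hap not in contexts:
            contexts[hap] = prepare_context(genomes[hap], config, rng, targets)
        acfs = generate_acfs(
            genomes[hap], count, config, rng, contexts[hap], frag_id_start=frag_id
        )
        fragments.extend(fragment_record(f, haplotype=hap) for f in acfs)
        frag_id += count
    for hap in ("ref", "mut"):
        count = int(np.sum(haps[n_acf:] == hap))
        if count == 0:
            continue
        fragments.extend(
            _sample_normal_fragments(
                genomes[hap], count, config, rng, hap, frag_id, targets
            )
        )
        frag_id += count

    out_prefix = Path(out_prefix)
    out_prefix.parent.mkdir(parents=True, exist_ok=True)
    r1_path = Path(f"{out_prefix}_R1.fastq")
    r2_path = Path(f"{out_prefix}_R2.fastq") if config.paired else None
    prov_path = Path(f"{out_prefix}_provenance.tsv")

    _write_fastq(genomes, fragments, profile, config, rng, r1_path, r2_path)
    write_provenance_tsv(fragments, prov_path)
    return SimResult(
        fastq_r1=r1_path,
        fastq_r2=r2_path,
        provenance_path=prov_path,
        fragments=fragments,
        n_reads=n_reads,
        read_len=config.read_len,
    )


_CHUNK = 50_000


def _write_fastq(
    genomes: dict[str, GenomeSequence],
    fragments: list[FragmentRecord],
    profile: PhredProfile,
    config: SimConfig,
    rng: np.random.Generator,
    r1_path: Path,
    r2_path: Path | None,
) -> None:
    read_len = config.read_len
    with open(r1_path, "wb") as f1, (
        open(r2_path, "wb") if r2_path is not None else _null_handle()
    ) as f2:
        for lo in range(0, len(fragments), _CHUNK):
            chunk = fragments[lo : lo + _CHUNK]
            names = [rec.read_name for rec in chunk]
            r1_list: list[str] = []
            r2_list: list[str] = []
            for rec in chunk:
                genome = genomes[rec.haplotype]
                if rec.is_acf:
                    seq = fragment_sequence(genome, rec)
                    r1_list.append(seq[:read_len])
                    if r2_path is not None:
                        r2_list.append(reverse_complement(seq)[:read_len])
                else:
                    r1_list.append(
                        genome.fetch(rec.chrom_a, rec.a_start, rec.a_start + read_len)
                    )
                    if r2_path is not None:
                        r2_list.append(
                            reverse_complement(
                                genome.fetch(rec.chrom_a, rec.a_end - read_len, rec.a_end)
                            )
                        )
            _emit_chunk(f1, names, r1_list, profile, config, rng)
            if r2_path is not None:
                _emit_chunk(f2, names, r2_list, profile, config, rng)


class _null_handle:
    def __enter__(self):
        return None

    def __exit__(self, *exc):
        return False


def _emit_chunk(handle, names, seqs, profile, config, rng) -> None:
    n = len(seqs)
    read_len = profile.read_len
    seq_mat = np.frombuffer("".join(seqs).encode("ascii"), dtype=np.uint8).reshape(
        n, read_len
    ).copy()
    q_mat = sample_quality_matrix(profile, n, rng)
    if config.sub_error_from_quals:
        _inject_errors_matrix(seq_mat, q_mat, rng)
    q_ascii = (q_mat.astype(np.uint8) + 33).tobytes()
    s_ascii = seq_mat.tobytes()
    parts: list[bytes] = []
    for i, name in enumerate(names):
        s = s_ascii[i * read_len : (i + 1) * read_len]
        q = q_ascii[i * read_len : (i + 1) * read_len]
        parts.append(b"@" + name.encode() + b"\n" + s + b"\n+\n" + q + b"\n")
    handle.write(b"".join(parts))


# --------------------------------------------------------------------------
# provenance table I/O

_PROV_COLUMNS = [
    "read_name",
    "frag_id",
    "kind",
    "haplotype",
    "frag_len",
    "chrom_a",
    "a_start",
    "a_end",
    "a_dir",
    "chrom_b",
    "b_start",
    "b_end",
    "b_dir",
    "junction_offset",
    "src_len",
    "same_strand",
    "enzymatic",
    "distance",
]


def write_provenance_tsv(fragments: list[FragmentRecord], path: str | Path) -> None:
    with open(path, "w", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(_PROV_COLUMNS)
        for rec in fragments:
            writer.writerow(
                [
                    rec.read_name,
                    rec.frag_id,
                    rec.kind,
                    rec.haplotype,
                    rec.frag_len,
                    rec.chrom_a,
                    rec.a_start,
                    rec.a_end,
                    rec.a_dir,
                    rec.chrom_b or ".",
                    rec.b_start,
                    rec.b_end,
                    rec.b_dir,
                    rec.junction_offset,
                    rec.src_len,
                    {True: "1", False: "0", None: "."}[rec.same_strand],
                    "1" if rec.enzymatic else "0",
                    rec.distance if rec.distance is not None else ".",
                ]
            )


def read_provenance_tsv(path: str | Path) -> list[FragmentRecord]:
    records: list[FragmentRecord] = []
    with open(path, newline="") as handle:
        reader = csv.reader(handle, delimiter="\t")
        header = next(reader)
        if header != _PROV_COLUMNS:
            raise ValueError(f"{path}: unexpected provenance header")
        for row in reader:
            (
                _name,
                frag_id,
                kind,
                hap,
                frag_len,
                chrom_a,
                a_start,
                a_end,
                a_dir,
                chrom_b,
                b_start,
                b_end,
                b_dir,
                joff,
                src_len,
                same_strand,
                enzymatic,
                distance,
            ) = row
            records.append(
                FragmentRecord(
                    frag_id=int(frag_id),
                    kind=kind,
                    haplotype=hap,
                    frag_len=int(frag_len),
                    chrom_a=chrom_a,
                    a_start=int(a_start),
                    a_end=int(a_end),
                    a_dir=a_dir,
                    chrom_b="" if chrom_b == "." else chrom_b,
                    b_start=int(b_start),
                    b_end=int(b_end),
                    b_dir=b_dir,
                    junction_offset=int(joff),
                    src_len=int(src_len),
                    same_strand={"1": True, "0": False, ".": None}[same_strand],
                    enzymatic=enzymatic == "1",
                    distance=None if distance == "." else int(distance),
                )
            )
    return records
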