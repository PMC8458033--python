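"""Positional Phred quality profiles.

A profile holds, for each read position, a categorical distribution over
integer Phred scores 2..41. Profiles can be estimated empirically from a
FASTQ file, constructed degenerate (all mass at one score), or taken from
a built-in Illumina-like linear decay default. Encoding is Sanger +33.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = [
    "PhredProfile",
    "MIN_SCORE",
    "MAX_SCORE",
    "estimate_profile",
    "sample_quality_string",
    "sample_quality_matrix",
    "uniform_profile",
    "default_decay_profile",
    "read_profile_tsv",
    "write_profile_tsv",
]

logger = logging.getLogger(__name__)

MIN_SCORE = 2
MAX_SCORE = 41
N_SCORES = MAX_SCORE - MIN_SCORE + 1
PHRED_OFFSET = 33


@dataclass
class PhredProfile:
    """Per-position categorical Phred score distributions.

    Attributes
    ----------
    read_len:
        Read length in bases; one distribution per position.
    table:
        Array of shape ``(read_len, 40)``; column ``j`` is the probability
        of score ``MIN_SCORE + j``. Rows sum to 1.
    """

    read_len: int
    table: np.ndarray

    def __post_init__(self) -> None:
        self.table = np.asarray(self.table, dtype=float)
        if self.table.shape != (self.read_len, N_SCORES):
            raise ValueError(
                f"table shape {self.table.shape} != ({self.read_len}, {N_SCORES})"
            )
        if np.any(self.table < 0):
            raise ValueError("negative probability in profile")
        sums = self.table.sum(axis=1)
        if not np.allclose(sums, 1.0, atol=1e-9):
            raise ValueError("positional distributions must each sum to 1")

    @property
    def scores(self) -> np.ndarray:
        return np.arange(MIN_SCORE, MAX_SCORE + 1)

    def cdf(self) -> np.ndarray:
        return np.cumsum(self.table, axis=1)


def uniform_profile(read_len: int, q: int) -> PhredProfile:
    """Degenerate profile with all positional mass at score ``q``."""
    if not MIN_SCORE <= q <= MAX_SCORE:
        raise ValueError(f"q={q} outside [{MIN_SCORE}, {MAX_SCORE}]")
    table = np.zeros((read_len, N_SCORES))
    table[:, q - MIN_SCORE] = 1.0
    return PhredProfile(read_len, table)


def default_decay_profile(read_len: int) -> PhredProfile:
    """Built-in Illumina-like profile: a linear decay from Q38 to Q30.

    Each position is a two-point mixture {Qhigh: 0.8, Qhigh - 8: 0.2} where
    Qhigh declines linearly from 38 at the first position to 30 at the last.
    Fully synthetic but shaped like a typical short-read run; replace with
    :func:`estimate_profile` output when real data are available.
    """
    table = np.zeros((read_len, N_SCORES))
    for i in range(read_len):
        frac = i / (read_len - 1) if read_len > 1 else 0.0
        q_high = int(round(38 - 8 * frac))
        q_low = max(MIN_SCORE, q_high - 8)
        table[i, q_high - MIN_SCORE] += 0.8
        table[i, q_low - MIN_SCORE] += 0.2
    return PhredProfile(read_len, table)


def _open_maybe_gzip(path: Path):
    if str(path).endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path)


def estimate_profile(fastq_path: str | Path, read_len: int) -> PhredProfile:
    """Estimate a positional profile from the quality strings of a FASTQ.

    Reads shorter than ``read_len`` are skipped (count logged); longer reads
    contribute their first ``read_len`` positions. Raises if no read is long
    enough or the file is empty/malformed.
    """
    fastq_path = Path(fastq_path)
    counts = np.zeros((read_len, N_SCORES), dtype=np.int64)
    used = skipped = 0
    with _open_maybe_gzip(fastq_path) as handle:
        while True:
            header = handle.readline()
            if not header:
                break
            seq = handle.readline()
            plus = handle.readline()
            qual = handle.readline()
            if not qual:
                raise ValueError(f"{fastq_path}: truncated FASTQ record")
            if not header.startswith("@") or not plus.startswith("+"):
                raise ValueError(f"{fastq_path}: malformed FASTQ record")
            qual = qual.rstrip("\n")
            if len(qual) != len(seq.rstrip("\n")):
                raise ValueError(f"{fastq_path}: quality/sequence length mismatch")
            if len(qual) < read_len:
                skipped += 1
                continue
            scores = np.frombuffer(
                qual[:read_len].encode("ascii"), dtype=np.uint8
            ).astype(np.int64) - PHRED_OFFSET
            if scores.min() < MIN_SCORE or scores.max() > MAX_SCORE:
                raise ValueError(
                    f"{fastq_path}: Phred score outside [{MIN_SCORE}, {MAX_SCORE}]"
                )
            counts[np.arange(read_len), scores - MIN_SCORE] += 1
            used += 1
    if skipped:
        logger.info("skipped %d reads shorter than %d bp", skipped, read_len)
    if used == 0:
        raise ValueError(f"{fastq_path}: no usable reads of length >= {read_len}")
    table = counts / counts.sum(axis=1, keepdims=True)
    return PhredProfile(read_len, table)


def sample_quality_matrix(
    profile: PhredProfile, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw an ``(n, read_len)`` integer score matrix, positions independent."""
    cdf = profile.cdf()
    u = rng.random((n, profile.read_len))
    out = np.empty((n, profile.read_len), dtype=np.int16)
    for i in range(profile.read_len):
        out[:, i] = MIN_SCORE + np.searchsorted(cdf[i], u[:, i], side="right")
    np.clip(out, MIN_SCORE, MAX_SCORE, out=out)
    return out


def sample_quality_string(profile: PhredProfile, rng: np.random.Generator) -> str:
    """Draw one quality string (Sanger +33 encoded) from the profile."""
    scores = sample_quality_matrix(profile, 1, rng)[0]
    return encode_scores(scores)


def encode_scores(scores: np.ndarray) -> str:
    return (scores.astype(np.uint8) + PHRED_OFFSET).tobytes().decode("ascii")


def write_profile_tsv(profile: PhredProfile, path: str | Path) -> None:
    """Serialize as TSV with columns position, score, probability."""
    with open(path, "w") as handle:
        handle.write("position\tscore\tprobability\n")
        for pos in range(profile.read_len):
            for j, p in enumerate(profile.table[pos]):
                if p > 0:
                    handle.write(f"{pos}\t{MIN_SCORE + j}\t{p:.10g}\n")


def read_profile_tsv(path: str | Path) -> PhredProfile:
    rows: list[tuple[int, int, float]] = []
    with open(path) as handle:
        header = handle.readline()
        if not header.startswith("position"):
            raise ValueError(f"{path}: missing profile header")
        for line in handle:
            pos_s, score_s, prob_s = line.split("\t")
            rows.append((int(pos_s), int(score_s), float(prob_s)))
    if not rows:
        raise ValueError(f"{path}: empty profile")
    read_len = max(pos for pos, _, _ in rows) + 1
    table = np.zeros((read_len, N_SCORES))
    for pos, score, prob in rows:
        table[pos, score - MIN_SCORE] = prob
    return PhredProfile(read_len, table)
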