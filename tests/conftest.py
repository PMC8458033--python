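"""Shared fixtures and helpers for the test suite.

All fixtures are generated programmatically; no binary files live in the
repository. BAM fixtures are written from SAM text at test time.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pysam
import pytest

from ffpekit.genome_io import GenomeSequence

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def random_sequence(rng: np.random.Generator, length: int) -> str:
    return _BASES[rng.integers(0, 4, size=length)].tobytes().decode("ascii")


def random_genome(seed: int, lengths: dict[str, int]) -> GenomeSequence:
    rng = np.random.default_rng(seed)
    return GenomeSequence.from_dict(
        {name: random_sequence(rng, n) for name, n in lengths.items()}
    )


def build_bam(tmp_path: Path, header_lines: list[str], records: list[str], name="fixture") -> Path:
    """Write SAM text, coordinate-sort and index it, return the BAM path."""
    sam_path = tmp_path / f"{name}.sam"
    bam_path = tmp_path / f"{name}.bam"
    sam_path.write_text("\n".join(header_lines + records) + "\n")
    pysam.sort("-o", str(bam_path), str(sam_path))
    pysam.index(str(bam_path))
    return bam_path


def sam_header(chroms: dict[str, int]) -> list[str]:
    lines = ["@HD\tVN:1.6\tSO:unsorted"]
    for name, length in chroms.items():
        lines.append(f"@SQ\tSN:{name}\tLN:{length}")
    return lines


class ScriptedRng:
    """An rng facade whose ``integers`` draws can be scripted.

    Values queued via ``queue_integers`` are returned (in order) by
    ``integers``; once exhausted, calls fall through to the wrapped
    generator. All other methods delegate. Used to pin seed positions and
    split choices in construction tests.
    """

    def __init__(self, base: np.random.Generator, scripted: list[int] | None = None):
        self._base = base
        self._queue: list[int] = list(scripted or [])

    def queue_integers(self, *values: int) -> None:
        self._queue.extend(values)

    def integers(self, *args, **kwargs):
        if self._queue:
            return self._queue.pop(0)
        return self._base.integers(*args, **kwargs)

    def __getattr__(self, name):
        return getattr(self._base, name)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def small_genome() -> GenomeSequence:
    """200 kb two-chromosome random genome."""
    return random_genome(11, {"chr1": 120_000, "chr2": 80_000})


@pytest.fixture(scope="session")
def mb_genome() -> GenomeSequence:
    """1 Mb single-chromosome random genome."""
    return random_genome(12, {"chr1": 1_000_000})
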