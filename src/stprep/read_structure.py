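"""Per-platform read-1 layouts and paired-FASTQ reformatting.

Sequencing-based spatial platforms pack the spatial barcode and the UMI
into read 1 in platform-specific layouts: Visium uses a 16-bp barcode
followed by a 12-bp UMI; Slide-seq splits the barcode around an 18-bp
bridge sequence (8+8 bp with an 8-bp UMI in V1; 8+7 bp with a 9-bp UMI in
V2 and Curio Seeker); Stereo-seq uses a 25-bp coordinate barcode.  The
reformatter extracts both tags and moves them into the read-2 header as
``<barcode>_<umi>#<original_id>`` so that a single-end alignment of read 2
carries the spatial information in its query name.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterator, Sequence

import pysam

from ._util import open_text_write

__all__ = [
    "SegmentRole",
    "SegmentSpec",
    "ReadStructure",
    "ParsedTags",
    "RejectReason",
    "ReformatStats",
    "get_preset",
    "parse_read1",
    "reformat_fastq_pair",
    "SLIDE_SEQ_BRIDGE",
    "PLATFORMS",
]

#: Published Slide-seq bridge (linker) sequence separating the barcode halves.
SLIDE_SEQ_BRIDGE = "TCTTCAGCGTTCCCGAGA"

PLATFORMS = (
    "visium",
    "slide_seq_v1",
    "slide_seq_v2",
    "curio_seeker",
    "stereo_seq",
    "custom",
)


class SegmentRole(str, Enum):
    BARCODE = "barcode"
    UMI = "umi"
    LINKER = "linker"
    DISCARD = "discard"


class RejectReason(str, Enum):
    NONE = "none"
    TOO_SHORT = "too_short"
    LINKER_MISMATCH = "linker_mismatch"
    AMBIGUOUS_BASE_OVERFLOW = "ambiguous_base_overflow"


@dataclass(frozen=True)
class SegmentSpec:
    """One contiguous stretch of read 1 with a fixed role and length."""

    role: SegmentRole
    length: int
    expected_sequence: str | None = None
    max_mismatch: int = 0

    def __post_init__(self) -> None:
        role = SegmentRole(self.role)
        object.__setattr__(self, "role", role)
        if self.length <= 0:
            raise ValueError(f"segment length must be positive, got {self.length}")
        if role is SegmentRole.LINKER:
            if self.expected_sequence is None:
                raise ValueError("linker segments require expected_sequence")
            if len(self.expected_sequence) != self.length:
                raise ValueError(
                    "expected_sequence length "
                    f"{len(self.expected_sequence)} != segment length {self.length}"
                )
            if self.max_mismatch < 0:
                raise ValueError("max_mismatch must be >= 0")
        elif self.expected_sequence is not None:
            raise ValueError("expected_sequence is only valid for linker segments")


@dataclass(frozen=True)
class ReadStructure:
    """Ordered layout of read 1, consumed left to right."""

    platform: str
    segments: tuple[SegmentSpec, ...]

    def __post_init__(self) -> None:
        if self.platform not in PLATFORMS:
            raise ValueError(f"unknown platform {self.platform!r}; valid: {PLATFORMS}")
        object.__setattr__(self, "segments", tuple(self.segments))
        if not self.segments:
            raise ValueError("read structure needs at least one segment")

    @property
    def barcode_total_len(self) -> int:
        return sum(s.length for s in self.segments if s.role is SegmentRole.BARCODE)

    @property
    def umi_total_len(self) -> int:
        return sum(s.length for s in self.segments if s.role is SegmentRole.UMI)

    @property
    def min_read1_len(self) -> int:
        return sum(s.length for s in self.segments)


@dataclass(frozen=True)
class ParsedTags:
    barcode: str
    umi: str
    linker_ok: bool
    reject_reason: RejectReason = RejectReason.NONE

    @property
    def ok(self) -> bool:
        return self.reject_reason is RejectReason.NONE


@dataclass
class ReformatStats:
    total_pairs: int = 0
    passed: int = 0
    rejected_by_reason: Counter = field(default_factory=Counter)

    def check_conservation(self) -> bool:
        return self.passed + sum(self.rejected_by_reason.values()) == self.total_pairs


def _bc(n: int) -> SegmentSpec:
    return SegmentSpec(SegmentRole.BARCODE, n)


def _umi(n: int) -> SegmentSpec:
    return SegmentSpec(SegmentRole.UMI, n)


def _bridge(max_mismatch: int) -> SegmentSpec:
    return SegmentSpec(
        SegmentRole.LINKER,
        len(SLIDE_SEQ_BRIDGE),
        expected_sequence=SLIDE_SEQ_BRIDGE,
        max_mismatch=max_mismatch,
    )


def get_preset(
    platform: str,
    version: str | None = None,
    *,
    segments: Sequence[SegmentSpec] | None = None,
    stereo_umi_len: int = 10,
    linker_max_mismatch: int = 3,
) -> ReadStructure:
    """Return the built-in read-1 layout for a platform.

    ``custom`` requires explicit ``segments``.  The Stereo-seq UMI length is
    configurable (``stereo_umi_len``, default 10) since only the 25-nt
    coordinate barcode is fixed by the chemistry.
    """
    if version:  # version strings like "v1"/"v2" fold into the platform name
        candidate = f"{platform}_{version.lower()}"
        if candidate in PLATFORMS:
            platform = candidate
    if platform == "custom":
        if not segments:
            raise ValueError("custom platform requires explicit segments")
        return ReadStructure("custom", tuple(segments))
    if platform == "visium":
        return ReadStructure("visium", (_bc(16), _umi(12)))
    if platform == "slide_seq_v1":
        return ReadStructure(
            "slide_seq_v1", (_bc(8), _bridge(linker_max_mismatch), _bc(8), _umi(8))
        )
    if platform in ("slide_seq_v2", "curio_seeker"):
        return ReadStructure(
            platform, (_bc(8), _bridge(linker_max_mismatch), _bc(7), _umi(9))
        )
    if platform == "stereo_seq":
        return ReadStructure("stereo_seq", (_bc(25), _umi(stereo_umi_len)))
    raise ValueError(f"unknown platform {platform!r}; valid: {PLATFORMS}")


def _hamming(a: str, b: str) -> int:
    # 'N' never matches, so it naturally counts as a mismatch here
    return sum(x != y for x, y in zip(a, b))


def parse_read1(seq: str, structure: ReadStructure, max_n: int = 1) -> ParsedTags:
    """Extract barcode and UMI from a read-1 sequence.

    Pure function: segments are consumed left to right; linkers are checked
    at Hamming distance <= their ``max_mismatch``; at most ``max_n``
    ambiguous bases are tolerated in barcode+UMI combined.  Rejection is a
    return state, never an exception.
    """
    if len(seq) < structure.min_read1_len:
        return ParsedTags("", "", False, RejectReason.TOO_SHORT)
    pos = 0
    barcode_parts: list[str] = []
    umi_parts: list[str] = []
    linker_ok = True
    for seg in structure.segments:
        chunk = seq[pos : pos + seg.length]
        pos += seg.length
        if seg.role is SegmentRole.BARCODE:
            barcode_parts.append(chunk)
        elif seg.role is SegmentRole.UMI:
            umi_parts.append(chunk)
        elif seg.role is SegmentRole.LINKER:
            if _hamming(chunk, seg.expected_sequence) > seg.max_mismatch:
                return ParsedTags("", "", False, RejectReason.LINKER_MISMATCH)
    barcode = "".join(barcode_parts)
    umi = "".join(umi_parts)
    if (barcode + umi).count("N") > max_n:
        return ParsedTags(barcode, umi, linker_ok, RejectReason.AMBIGUOUS_BASE_OVERFLOW)
    return ParsedTags(barcode, umi, linker_ok, RejectReason.NONE)


def make_header(barcode: str, umi: str, original_id: str) -> str:
    """Encode tags into a read name: ``<barcode>_<umi>#<original_id>``."""
    return f"{barcode}_{umi}#{original_id}"


def split_header(name: str) -> tuple[str, str, str]:
    """Inverse of :func:`make_header`."""
    tags, _, original = name.partition("#")
    barcode, _, umi = tags.partition("_")
    return barcode, umi, original


def _open_out(path: str | Path):
    return open_text_write(path)


def _fastq_pairs(r1_path, r2_path) -> Iterator[tuple]:
    with pysam.FastxFile(str(r1_path)) as r1, pysam.FastxFile(str(r2_path)) as r2:
        it1, it2 = iter(r1), iter(r2)
        while True:
            rec1 = next(it1, None)
            rec2 = next(it2, None)
            if rec1 is None and rec2 is None:
                return
            if rec1 is None or rec2 is None:
                raise ValueError("paired FASTQ files have unequal read counts")
            yield rec1, rec2


def reformat_fastq_pair(
    r1_path: str | Path,
    r2_path: str | Path,
    structure: ReadStructure,
    out_path: str | Path,
    max_n: int = 1,
    max_pairs: int | None = None,
) -> ReformatStats:
    """Reformat a FASTQ pair into a single read-2 FASTQ with tagged headers.

    Rejected pairs (too-short read 1, linker mismatch, too many N bases) are
    dropped and tallied; output record order equals input order.
    ``max_pairs`` truncates the input for smoke runs.
    """
    stats = ReformatStats()
    with _open_out(out_path) as out:
        for rec1, rec2 in _fastq_pairs(r1_path, r2_path):
            if max_pairs is not None and stats.total_pairs >= max_pairs:
                break
            stats.total_pairs += 1
            tags = parse_read1(rec1.sequence.upper(), structure, max_n=max_n)
            if not tags.ok:
                stats.rejected_by_reason[tags.reject_reason.value] += 1
                continue
            stats.passed += 1
            name = make_header(tags.barcode, tags.umi, rec2.name)
            qual = rec2.quality if rec2.quality is not None else "I" * len(rec2.sequence)
            out.write(f"@{name}\n{rec2.sequence}\n+\n{qual}\n")
    return stats
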