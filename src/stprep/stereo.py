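"""Stereo-seq coordinate-barcode deconvolution.

Stereo-seq encodes each DNA nanoball's chip position in a 25-nt coordinate
barcode.  A chip mapping file translates barcodes to (x, y) grid
coordinates; deconvolution replaces the barcode with the location token
``<x>x<y>`` in the read-2 header so downstream stages can treat the token
as an opaque spatial barcode.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import pandas as pd

from .read_structure import ReadStructure, RejectReason, parse_read1

__all__ = [
    "CoordinateMap",
    "load_coordinate_map",
    "lookup_barcode",
    "deconvolve_pair",
    "deconvolve_fastq_pair",
    "DeconvStats",
    "location_token",
    "parse_location_token",
]

_BASES = "ACGT"


def location_token(x: int, y: int) -> str:
    return f"{x}x{y}"


def parse_location_token(token: str) -> tuple[int, int]:
    """Parse ``<x>x<y>`` back into integer coordinates."""
    xs, _, ys = token.partition("x")
    return int(xs), int(ys)


@dataclass
class CoordinateMap:
    """Barcode -> (x, y) chip-coordinate lookup table."""

    entries: dict[str, tuple[int, int]]
    barcode_len: int = 25

    def __post_init__(self) -> None:
        for bc, (x, y) in self.entries.items():
            if len(bc) != self.barcode_len:
                raise ValueError(
                    f"barcode {bc!r} has length {len(bc)}, expected {self.barcode_len}"
                )
            if x < 0 or y < 0:
                raise ValueError(f"negative coordinate for barcode {bc!r}")

    def __len__(self) -> int:
        return len(self.entries)


def load_coordinate_map(path: str | Path, format: str | None = None) -> CoordinateMap:
    """Load a barcode->(x, y) map from TSV (barcode, x, y + header) or HDF5.

    The HDF5 dialect is three parallel datasets: ``barcodes`` (fixed-length
    strings), ``x`` and ``y`` (non-negative integers).
    """
    path = Path(path)
    if format is None:
        format = "hdf5" if path.suffix in (".h5", ".hdf5") else "tsv"
    if format == "tsv":
        df = pd.read_csv(path, sep="\t", dtype={0: str})
        if list(df.columns[:3]) != ["barcode", "x", "y"]:
            raise ValueError(
                f"expected columns barcode, x, y; got {list(df.columns)}"
            )
        barcodes = df["barcode"].tolist()
        xs, ys = df["x"].tolist(), df["y"].tolist()
    elif format == "hdf5":
        with h5py.File(path, "r") as f:
            barcodes = [b.decode() if isinstance(b, bytes) else str(b) for b in f["barcodes"][:]]
            xs = [int(v) for v in f["x"][:]]
            ys = [int(v) for v in f["y"][:]]
    else:
        raise ValueError(f"unknown coordinate map format {format!r}")

    entries: dict[str, tuple[int, int]] = {}
    for bc, x, y in zip(barcodes, xs, ys):
        x, y = int(x), int(y)
        if bc in entries:
            raise ValueError(f"duplicate barcode in coordinate map: {bc!r}")
        entries[bc] = (x, y)
    barcode_len = len(next(iter(entries))) if entries else 25
    return CoordinateMap(entries, barcode_len=barcode_len)


def lookup_barcode(
    bc: str, cmap: CoordinateMap, rescue_1mm: bool = False
) -> tuple[int, int] | None:
    """Exact lookup with optional unique Hamming-1 rescue.

    Rescue accepts a hit only when exactly one single-substitution neighbor
    of ``bc`` is present in the map; two or more neighbors are ambiguous and
    rejected.
    """
    hit = cmap.entries.get(bc)
    if hit is not None:
        return hit
    if not rescue_1mm:
        return None
    found: tuple[int, int] | None = None
    n_found = 0
    for i, orig in enumerate(bc):
        for base in _BASES:
            if base == orig:
                continue
            neighbor = bc[:i] + base + bc[i + 1 :]
            coords = cmap.entries.get(neighbor)
            if coords is not None:
                n_found += 1
                if n_found > 1:
                    return None
                found = coords
    return found


@dataclass
class DeconvStats:
    total_pairs: int = 0
    passed: int = 0
    rejected_by_reason: Counter = field(default_factory=Counter)


def deconvolve_pair(
    r1_seq: str,
    r2_name: str,
    cmap: CoordinateMap,
    structure: ReadStructure,
    rescue_1mm: bool = False,
    max_n: int = 1,
) -> tuple[str | None, str]:
    """Resolve one read pair to (new read-2 header, reason).

    Returns ``(header, "none")`` on success where header is
    ``<x>x<y>_<umi>#<r2_name>``, else ``(None, reason)`` with reason one of
    the parse reject reasons or ``unmatched_coordinate``.
    """
    tags = parse_read1(r1_seq.upper(), structure, max_n=max_n)
    if not tags.ok:
        return None, tags.reject_reason.value
    coords = lookup_barcode(tags.barcode, cmap, rescue_1mm=rescue_1mm)
    if coords is None:
        return None, "unmatched_coordinate"
    x, y = coords
    return f"{location_token(x, y)}_{tags.umi}#{r2_name}", RejectReason.NONE.value


def deconvolve_fastq_pair(
    r1_path: str | Path,
    r2_path: str | Path,
    cmap: CoordinateMap,
    structure: ReadStructure,
    out_path: str | Path,
    rescue_1mm: bool = False,
    max_n: int = 1,
) -> DeconvStats:
    """Deconvolve a whole FASTQ pair into a tagged read-2 FASTQ."""
    from .read_structure import _fastq_pairs, _open_out

    stats = DeconvStats()
    with _open_out(out_path) as out:
        for rec1, rec2 in _fastq_pairs(r1_path, r2_path):
            stats.total_pairs += 1
            header, reason = deconvolve_pair(
                rec1.sequence, rec2.name, cmap, structure,
                rescue_1mm=rescue_1mm, max_n=max_n,
            )
            if header is None:
                stats.rejected_by_reason[reason] += 1
                continue
            stats.passed += 1
            qual = rec2.quality if rec2.quality is not None else "I" * len(rec2.sequence)
            out.write(f"@{header}\n{rec2.sequence}\n+\n{qual}\n")
    return stats
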