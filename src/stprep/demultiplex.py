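"""Spatial-barcode demultiplexing with bounded-distance error correction.

Each extracted barcode is assigned to a known spatial location barcode.
A barcode at Hamming distance <= ``max_dist`` from exactly one allow-list
entry at the minimal qualifying distance is corrected to it; ties at that
distance are ambiguous and left unassigned.  For ``max_dist=1`` the search
enumerates the 3L+1 single-substitution variants against a hash set, so
cost does not grow with allow-list size.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

__all__ = [
    "BarcodeAllowList",
    "DemuxStats",
    "MatchCategory",
    "match_barcode",
    "build_observed_allowlist",
]

_BASES = "ACGT"


class MatchCategory(str, Enum):
    EXACT = "exact_match"
    CORRECTED = "corrected"
    AMBIGUOUS = "ambiguous"
    UNMATCHED = "unmatched"


@dataclass(frozen=True)
class BarcodeAllowList:
    barcodes: frozenset[str]
    source: str = "layout_file"  # layout_file | observed_topk | coordinate_map

    def __post_init__(self) -> None:
        object.__setattr__(self, "barcodes", frozenset(self.barcodes))
        lengths = {len(b) for b in self.barcodes}
        if len(lengths) > 1:
            raise ValueError(f"allow-list barcodes have mixed lengths: {sorted(lengths)}")

    @property
    def barcode_len(self) -> int:
        return len(next(iter(self.barcodes))) if self.barcodes else 0

    def __len__(self) -> int:
        return len(self.barcodes)


@dataclass
class DemuxStats:
    exact_match: int = 0
    corrected: int = 0
    ambiguous: int = 0
    unmatched: int = 0

    @property
    def total(self) -> int:
        return self.exact_match + self.corrected + self.ambiguous + self.unmatched

    def record(self, category: MatchCategory) -> None:
        setattr(self, category.value, getattr(self, category.value) + 1)

    def as_dict(self) -> dict[str, int]:
        return {
            "exact_match": self.exact_match,
            "corrected": self.corrected,
            "ambiguous": self.ambiguous,
            "unmatched": self.unmatched,
        }


def _neighbors_1(bc: str):
    for i, orig in enumerate(bc):
        for base in _BASES:
            if base != orig:
                yield bc[:i] + base + bc[i + 1 :]


def _neighbors_2(bc: str):
    n = len(bc)
    for i in range(n):
        for j in range(i + 1, n):
            for bi in _BASES:
                if bi == bc[i]:
                    continue
                for bj in _BASES:
                    if bj == bc[j]:
                        continue
                    yield bc[:i] + bi + bc[i + 1 : j] + bj + bc[j + 1 :]


def match_barcode(
    bc: str, allow: BarcodeAllowList, max_dist: int = 1
) -> tuple[str | None, MatchCategory]:
    """Assign a barcode to the allow list.

    Resolution order: exact membership, then the unique entry at the
    minimal Hamming distance <= ``max_dist``.  Two or more entries tying at
    that minimal distance yield ``ambiguous``.  'N' counts as a mismatch.
    """
    if max_dist not in (0, 1, 2):
        raise ValueError(f"max_dist must be 0, 1 or 2, got {max_dist}")
    if allow.barcodes and len(bc) != allow.barcode_len:
        raise ValueError(
            f"barcode length {len(bc)} != allow-list length {allow.barcode_len}"
        )
    if bc in allow.barcodes:
        return bc, MatchCategory.EXACT
    for enumerate_neighbors, dist in ((_neighbors_1, 1), (_neighbors_2, 2)):
        if max_dist < dist:
            break
        hits = {n for n in enumerate_neighbors(bc) if n in allow.barcodes}
        if len(hits) == 1:
            return next(iter(hits)), MatchCategory.CORRECTED
        if len(hits) > 1:
            return None, MatchCategory.AMBIGUOUS
    return None, MatchCategory.UNMATCHED


def build_observed_allowlist(
    barcode_counts: dict[str, int], expected_n: int
) -> BarcodeAllowList:
    """Top ``expected_n`` barcodes by read count (ties lexicographic).

    Used for random-barcode platforms without a fixed allow list.  If fewer
    distinct barcodes than requested exist, all are returned.
    """
    if expected_n < 1:
        raise ValueError("expected_n must be >= 1")
    ranked = sorted(barcode_counts.items(), key=lambda kv: (-kv[1], kv[0]))
    if len(ranked) < expected_n:
        import warnings

        warnings.warn(
            f"only {len(ranked)} distinct barcodes observed, "
            f"fewer than expected_n={expected_n}; returning all",
            stacklevel=2,
        )
    top = [bc for bc, _ in ranked[:expected_n]]
    return BarcodeAllowList(frozenset(top), source="observed_topk")
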