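"""Join deduplicated counts with spatial coordinates.

Fixed-layout chips (Visium-like) carry a barcode -> coordinate table;
random-barcode platforms (Slide-seq, Curio) take a user-supplied per-sample
coordinate CSV; Stereo-seq location tokens of the form ``<x>x<y>`` are
parsed directly with no layout file.  Unmatched matrix barcodes are dropped
(with counts logged), never imputed; matched columns keep their counts
untouched.

Coordinate convention: x increases rightward (column direction, um),
y increases downward (row direction, um) — image-style ordering.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .dedup import CountMatrix
from .stereo import parse_location_token

__all__ = ["ChipLayout", "SpatialCounts", "load_layout", "match_locations"]

logger = logging.getLogger(__name__)

POSITION_COLUMNS = ["barcode", "in_tissue", "array_row", "array_col", "x_um", "y_um"]


@dataclass
class ChipLayout:
    """Barcode -> coordinate table plus spot geometry."""

    table: pd.DataFrame  # columns: barcode, x, y [, array_row, array_col]
    geometry: dict = field(
        default_factory=lambda: {"spot_diameter_um": 55.0, "center_spacing_um": 100.0}
    )

    def __post_init__(self) -> None:
        required = {"barcode", "x", "y"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"layout is missing columns: {sorted(missing)}")
        dup = self.table["barcode"].duplicated()
        if dup.any():
            raise ValueError(
                f"duplicate layout barcodes: {self.table['barcode'][dup].tolist()[:5]}"
            )
        if {"array_row", "array_col"} <= set(self.table.columns):
            pairs = self.table[["array_row", "array_col"]]
            if pairs.duplicated().any():
                raise ValueError("duplicate (array_row, array_col) pairs in layout")

    def __len__(self) -> int:
        return len(self.table)

    @property
    def barcodes(self) -> set[str]:
        return set(self.table["barcode"])


@dataclass
class SpatialCounts:
    """Sparse gene x location counts joined with per-location coordinates."""

    counts: CountMatrix
    locations: pd.DataFrame  # one row per matrix column, aligned order

    def __post_init__(self) -> None:
        if len(self.locations) != self.counts.shape[1]:
            raise ValueError(
                f"{len(self.locations)} location rows for "
                f"{self.counts.shape[1]} matrix columns"
            )
        if "qc_pass" not in self.locations.columns:
            self.locations = self.locations.assign(qc_pass=True)

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_locations(self) -> int:
        return self.counts.shape[1]


def load_layout(path: str | Path, geometry: dict | None = None) -> ChipLayout:
    """Load a chip-layout CSV/TSV with columns barcode, x, y (+ optional
    array_row, array_col)."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
    table = pd.read_csv(path, sep=sep, dtype={"barcode": str})
    kwargs = {"geometry": geometry} if geometry else {}
    return ChipLayout(table.reset_index(drop=True), **kwargs)


def match_locations(
    counts: CountMatrix,
    layout: ChipLayout | None,
    platform: str,
) -> tuple[SpatialCounts, dict[str, int | float]]:
    """Restrict matrix columns to locations with known coordinates.

    For ``stereo_seq`` the column names are ``<x>x<y>`` tokens parsed
    directly (layout optional); all other platforms require a layout.
    Returns the joined object plus
    ``{matched, unmatched_in_matrix, layout_unused, matched_fraction}``.
    """
    n_cols = len(counts.barcodes)
    if platform == "stereo_seq" and layout is None:
        rows, keep = [], []
        for j, token in enumerate(counts.barcodes):
            try:
                x, y = parse_location_token(token)
            except (ValueError, TypeError):
                continue
            keep.append(j)
            rows.append({"barcode": token, "x_um": float(x), "y_um": float(y)})
        locations = pd.DataFrame(rows, columns=["barcode", "x_um", "y_um"])
        layout_unused = 0
    else:
        if layout is None:
            raise ValueError(f"platform {platform!r} requires a layout file")
        lut = layout.table.set_index("barcode")
        keep, rows = [], []
        for j, bc in enumerate(counts.barcodes):
            if bc not in lut.index:
                continue
            keep.append(j)
            rec = lut.loc[bc]
            row = {"barcode": bc, "x_um": float(rec["x"]), "y_um": float(rec["y"])}
            for col in ("array_row", "array_col"):
                if col in lut.columns:
                    row[col] = int(rec[col])
            rows.append(row)
        locations = pd.DataFrame(
            rows, columns=["barcode", "x_um", "y_um"]
            + [c for c in ("array_row", "array_col") if c in lut.columns]
        )
        layout_unused = len(layout) - len(keep)

    matched = len(keep)
    if matched == 0:
        raise ValueError(
            "no matrix barcode matched the layout; check that the chip/layout "
            "file corresponds to this sample"
        )
    dropped = n_cols - matched
    if dropped:
        dropped_counts = int(
            counts.location_totals()[
                [j for j in range(n_cols) if j not in set(keep)]
            ].sum()
        )
        logger.info(
            "dropped %d unmatched matrix barcodes carrying %d molecules",
            dropped,
            dropped_counts,
        )

    sub = CountMatrix(
        counts.matrix[:, keep].tocsr(),
        counts.genes,
        [counts.barcodes[j] for j in keep],
    )
    locations = locations.assign(qc_pass=True).reset_index(drop=True)
    stats = {
        "matched": matched,
        "unmatched_in_matrix": dropped,
        "layout_unused": layout_unused,
        "matched_fraction": matched / n_cols if n_cols else float("nan"),
    }
    return SpatialCounts(sub, locations), stats


def positions_frame(sc: SpatialCounts) -> pd.DataFrame:
    """Exported positions table (barcode,in_tissue,array_row,array_col,x_um,y_um)."""
    loc = sc.locations
    return pd.DataFrame(
        {
            "barcode": loc["barcode"],
            "in_tissue": loc["qc_pass"].astype(int),
            "array_row": loc.get("array_row", pd.Series([-1] * len(loc))).astype(int),
            "array_col": loc.get("array_col", pd.Series([-1] * len(loc))).astype(int),
            "x_um": loc["x_um"],
            "y_um": loc["y_um"],
        }
    )
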