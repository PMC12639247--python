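"""Directional UMI deduplication per (barcode, gene) group.

PCR and sequencing errors inflate apparent molecule counts: an erroneous
copy of a UMI shows up as a near-neighbor sequence with far fewer reads
than its parent.  The directional rule absorbs a UMI ``v`` into a neighbor
``u`` when Hamming(u, v) <= ``hamming_max`` and reads(u) >= 2*reads(v) - 1,
following the established directional-adjacency criterion.  Groups are
independent: UMIs are never compared across genes or locations.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp

__all__ = ["UmiGraphNode", "DedupResult", "CountMatrix", "dedup_group", "dedup_table"]


@dataclass(frozen=True)
class UmiGraphNode:
    umi: str
    reads: int

    def __post_init__(self) -> None:
        if self.reads < 1:
            raise ValueError("reads must be >= 1")


@dataclass
class DedupResult:
    molecules: int
    cluster_map: dict[str, str]  # umi -> representative umi
    dup_histogram: Counter  # reads-per-molecule -> count


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def dedup_group(nodes: list[UmiGraphNode], hamming_max: int = 1) -> DedupResult:
    """Collapse one (barcode, gene) UMI group.

    Nodes are processed in deterministic order (descending reads, then
    lexicographic UMI).  Each unassigned node starts a cluster; the cluster
    absorbs every unassigned node reachable through directed edges
    u -> v with Hamming(u, v) <= hamming_max and reads(u) >= 2*reads(v) - 1.
    The cluster's representative is its root; the histogram counts total
    member reads per surviving molecule.
    """
    if not nodes:
        return DedupResult(0, {}, Counter())
    lengths = {len(n.umi) for n in nodes}
    if len(lengths) > 1:
        raise ValueError(f"mixed UMI lengths in group: {sorted(lengths)}")
    reads = {n.umi: n.reads for n in nodes}
    order = sorted(reads, key=lambda u: (-reads[u], u))

    cluster_map: dict[str, str] = {}
    histogram: Counter = Counter()
    for root in order:
        if root in cluster_map:
            continue
        cluster_map[root] = root
        members = [root]
        stack = [root]
        while stack:
            u = stack.pop()
            for v in order:
                if v in cluster_map:
                    continue
                if _hamming(u, v) <= hamming_max and reads[u] >= 2 * reads[v] - 1:
                    cluster_map[v] = root
                    members.append(v)
                    stack.append(v)
        histogram[sum(reads[m] for m in members)] += 1

    molecules = len(set(cluster_map.values()))
    return DedupResult(molecules, cluster_map, histogram)


@dataclass
class CountMatrix:
    """Sparse gene x location matrix of deduplicated molecule counts."""

    matrix: sp.csr_matrix  # genes x barcodes
    genes: list[str]
    barcodes: list[str]

    @property
    def shape(self) -> tuple[int, int]:
        return self.matrix.shape

    def location_totals(self) -> np.ndarray:
        return np.asarray(self.matrix.sum(axis=0)).ravel()

    def gene_totals(self) -> np.ndarray:
        return np.asarray(self.matrix.sum(axis=1)).ravel()

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.matrix.toarray(), index=self.genes, columns=self.barcodes
        )


def dedup_table(
    records: pd.DataFrame, hamming_max: int = 1
) -> tuple[CountMatrix, Counter]:
    """Deduplicate the molecular-info table into a molecule count matrix.

    ``records`` holds one row per (barcode, umi, gene_id) with its
    supporting read count; each (barcode, gene_id) group is collapsed
    independently and the duplication histograms are pooled.
    """
    histogram: Counter = Counter()
    cell_molecules: Counter = Counter()
    if len(records):
        for (barcode, gene), grp in records.groupby(["barcode", "gene_id"], sort=True):
            nodes = [
                UmiGraphNode(u, int(r)) for u, r in zip(grp["umi"], grp["reads"])
            ]
            result = dedup_group(nodes, hamming_max=hamming_max)
            cell_molecules[(barcode, gene)] = result.molecules
            histogram.update(result.dup_histogram)

    genes = sorted({g for _, g in cell_molecules})
    barcodes = sorted({b for b, _ in cell_molecules})
    gene_idx = {g: i for i, g in enumerate(genes)}
    bc_idx = {b: i for i, b in enumerate(barcodes)}
    rows = [gene_idx[g] for (_, g) in cell_molecules]
    cols = [bc_idx[b] for (b, _) in cell_molecules]
    vals = list(cell_molecules.values())
    matrix = sp.csr_matrix(
        (vals, (rows, cols)), shape=(len(genes), len(barcodes)), dtype=np.int64
    )
    return CountMatrix(matrix, genes, barcodes), histogram
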