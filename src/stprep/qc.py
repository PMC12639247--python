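"""Low-quality spatial-location filtering.

Two filters are provided.  ``max_slope`` finds the knee of the descending
UMI rank curve: ranks are plotted on log10-log10 axes and the rank with the
steepest drop between adjacent ranks marks the transition from tissue
signal to background; all locations at or above that count pass.  The
``empty_test`` is a Monte-Carlo ambient-profile test in the spirit of
empty-droplet detection: an ambient gene profile is estimated from
very-low-count locations and each location's composition is scored by the
statistic D(y) = -sum_g y_g * log(ambient_g); the null distribution comes
from multinomial draws of the same depth from the ambient profile, and
locations pass when their p-value or Benjamini-Hochberg FDR clears the
configured cut.  This is a simplified likelihood-style Monte-Carlo test,
not a reimplementation of the full published empty-droplet algorithm (no
knee-anchored retain set, no Dirichlet overdispersion).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .dedup import CountMatrix

__all__ = ["QcParams", "QcResult", "max_slope_threshold", "empty_location_test", "run_qc"]


@dataclass
class QcParams:
    method: str = "max_slope"  # max_slope | empty_test
    ratio_window: tuple[float, float] = (0.0, 1.0)
    mc_iterations: int = 2000
    p_cut: float = 0.05
    fdr_cut: float = 0.05
    ambient_max_count: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        low, high = self.ratio_window
        if not (0.0 <= low < high <= 1.0):
            raise ValueError(f"ratio_window must satisfy 0 <= low < high <= 1, got {self.ratio_window}")
        if not (0.0 < self.p_cut < 1.0 and 0.0 < self.fdr_cut < 1.0):
            raise ValueError("p_cut and fdr_cut must lie in (0, 1)")


@dataclass
class QcResult:
    per_location: pd.DataFrame  # barcode, total_umi [, p_value, fdr], pass
    n_before: int
    n_after: int
    method: str
    threshold_umi: int | None = None
    params: QcParams | None = field(default=None, repr=False)


def max_slope_threshold(
    totals: np.ndarray, ratio_window: tuple[float, float] = (0.0, 1.0)
) -> int:
    """Knee threshold from the steepest log-log drop of the rank curve.

    With counts sorted descending as c(1)..c(n), the slope between adjacent
    ranks i and i+1 is
    (log10 c(i+1) - log10 c(i)) / (log10(i+1) - log10 i);
    the knee is the rank minimizing it (steepest drop, ties to the smallest
    rank) among candidate ranks within the given fractional window.  The
    returned threshold is c(knee); locations with total >= threshold pass.
    """
    totals = np.asarray(totals)
    positive = np.sort(totals[totals > 0])[::-1].astype(float)
    n = len(positive)
    if n < 10:
        raise ValueError(
            f"only {n} locations with positive totals; max_slope needs >= 10 — "
            "use the empty-location test or a manual threshold"
        )
    low, high = ratio_window
    i_lo = max(1, math.ceil(n * low))
    i_hi = min(n - 1, math.floor(n * high))
    ranks = np.arange(i_lo, i_hi + 1)
    logc = np.log10(positive)
    slopes = (logc[ranks] - logc[ranks - 1]) / (np.log10(ranks + 1) - np.log10(ranks))
    knee = ranks[int(np.argmin(slopes))]  # argmin takes the first = smallest rank
    return int(positive[knee - 1])


def _max_slope_qc(counts: CountMatrix, params: QcParams) -> QcResult:
    totals = counts.location_totals()
    threshold = max_slope_threshold(totals, params.ratio_window)
    passed = totals >= threshold
    table = pd.DataFrame(
        {"barcode": counts.barcodes, "total_umi": totals.astype(int), "pass": passed}
    )
    return QcResult(
        table, len(totals), int(passed.sum()), "max_slope",
        threshold_umi=threshold, params=params,
    )


def empty_location_test(counts: CountMatrix, params: QcParams) -> QcResult:
    """Monte-Carlo ambient-profile test for non-empty locations.

    Ambient profile: per-gene sums over locations with total <=
    ``ambient_max_count``, plus a 0.5 pseudocount per gene, normalized.
    For a location with depth t and count vector y the statistic is
    D(y) = -sum_g y_g log(ambient_g); the p-value is
    (1 + #{D_sim >= D_obs}) / (mc_iterations + 1) over multinomial null
    draws of size t.  A location passes when p <= p_cut OR its BH FDR <=
    fdr_cut.  Fully reproducible given the seed.
    """
    if counts.shape[0] < 1 or counts.shape[1] < 20:
        raise ValueError("empty-location test needs >= 1 gene and >= 20 locations")
    totals = counts.location_totals()
    ambient_cols = np.flatnonzero(totals <= params.ambient_max_count)
    if ambient_cols.size == 0:
        raise ValueError(
            f"no locations with total <= ambient_max_count={params.ambient_max_count}; "
            "increase ambient_max_count"
        )
    dense = counts.matrix.toarray().astype(float)  # genes x locations
    ambient = dense[:, ambient_cols].sum(axis=1) + 0.5
    ambient /= ambient.sum()
    log_amb = np.log(ambient)

    rng = np.random.default_rng(params.seed)
    n_loc = counts.shape[1]
    p_values = np.ones(n_loc)
    tested = totals > 0
    for j in np.flatnonzero(tested):
        t = int(totals[j])
        d_obs = -float(dense[:, j] @ log_amb)
        sims = rng.multinomial(t, ambient, size=params.mc_iterations)
        d_sim = -(sims @ log_amb)
        p_values[j] = (1 + int(np.sum(d_sim >= d_obs))) / (params.mc_iterations + 1)

    _, fdr, _, _ = multipletests(p_values, method="fdr_bh")
    passed = (p_values <= params.p_cut) | (fdr <= params.fdr_cut)
    table = pd.DataFrame(
        {
            "barcode": counts.barcodes,
            "total_umi": totals.astype(int),
            "p_value": p_values,
            "fdr": fdr,
            "pass": passed,
        }
    )
    return QcResult(table, n_loc, int(passed.sum()), "empty_test", params=params)


def run_qc(counts: CountMatrix, params: QcParams) -> QcResult:
    """Dispatch to the configured QC method."""
    if params.method == "max_slope":
        return _max_slope_qc(counts, params)
    if params.method == "empty_test":
        return empty_location_test(counts, params)
    raise ValueError(f"unknown QC method {params.method!r}")
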