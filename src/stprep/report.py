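"""QC-metric aggregation and self-contained HTML report rendering.

Every pipeline stage leaves behind a small set of tallies (reformat
rejections, demultiplexing categories, gene-assignment categories, UMI
duplication histogram, QC threshold and before/after counts).  These are
collected into one :class:`MetricsBundle` per sample, serialized to a JSON
sidecar for machine reading, and rendered to a single HTML file with all
plots inlined as base64 PNGs — no external fetches.
"""

from __future__ import annotations

import base64
import io
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
from jinja2 import Template

__all__ = ["MetricsBundle", "collect_metrics", "render_html"]

SECTIONS = (
    "Barcode demultiplexing",
    "Mapping statistics",
    "UMI duplication",
    "UMI count distributions",
    "Location QC",
)


@dataclass
class MetricsBundle:
    sample_id: str
    reformat: dict = field(default_factory=dict)  # total_pairs, passed, rejected_by_reason
    demux: dict = field(default_factory=dict)  # exact_match, corrected, ambiguous, unmatched
    mapping_categories: dict = field(default_factory=dict)
    dup_histogram: dict = field(default_factory=dict)  # reads-per-molecule -> count
    qc: dict | None = None  # method, threshold?, n_before, n_after
    per_location_totals: list = field(default_factory=list)
    per_gene_totals: list = field(default_factory=list)

    def to_json(self, path: str | Path | None = None) -> str:
        payload = asdict(self)
        payload["dup_histogram"] = {str(k): v for k, v in self.dup_histogram.items()}
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "MetricsBundle":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        data = json.loads(text)
        data["dup_histogram"] = {int(k): v for k, v in data.get("dup_histogram", {}).items()}
        return cls(**data)


def collect_metrics(
    sample_id: str,
    reformat_stats=None,
    demux_stats=None,
    category_totals: dict | None = None,
    dup_histogram: dict | None = None,
    qc_result=None,
    per_location_totals=None,
    per_gene_totals=None,
) -> MetricsBundle:
    """Assemble stage outputs into one bundle.

    The reformat, mapping and duplication stages are required; QC is
    optional (its report section is omitted when absent).
    """
    missing = [
        name
        for name, value in (
            ("reformat", reformat_stats),
            ("mapping", category_totals),
            ("dedup", dup_histogram),
        )
        if value is None
    ]
    if missing:
        raise ValueError(f"missing stage output(s): {', '.join(missing)}")
    qc = None
    if qc_result is not None:
        qc = {
            "method": qc_result.method,
            "threshold_umi": qc_result.threshold_umi,
            "n_before": qc_result.n_before,
            "n_after": qc_result.n_after,
        }
    return MetricsBundle(
        sample_id=sample_id,
        reformat={
            "total_pairs": reformat_stats.total_pairs,
            "passed": reformat_stats.passed,
            "rejected_by_reason": dict(reformat_stats.rejected_by_reason),
        },
        demux=demux_stats.as_dict() if demux_stats is not None else {},
        mapping_categories=dict(category_totals),
        dup_histogram={int(k): int(v) for k, v in dup_histogram.items()},
        qc=qc,
        per_location_totals=[
            int(v) for v in (per_location_totals if per_location_totals is not None else [])
        ],
        per_gene_totals=[
            int(v) for v in (per_gene_totals if per_gene_totals is not None else [])
        ],
    )


def _fig_to_b64(fig) -> str:
    buf = io.BytesIO()
    fig.savefig(buf, format="png", dpi=90, bbox_inches="tight")
    plt.close(fig)
    return base64.b64encode(buf.getvalue()).decode()


def _demux_plot(bundles) -> str:
    cats = ["exact_match", "corrected", "ambiguous", "unmatched"]
    fig, ax = plt.subplots(figsize=(5, 3))
    width = 0.8 / max(len(bundles), 1)
    xs = np.arange(len(cats))
    for i, b in enumerate(bundles):
        vals = [b.demux.get(c, 0) for c in cats]
        ax.bar(xs + i * width, vals, width, label=b.sample_id)
    ax.set_xticks(xs + width * (len(bundles) - 1) / 2)
    ax.set_xticklabels(cats, rotation=20)
    ax.set_ylabel("reads")
    ax.legend(fontsize=7)
    return _fig_to_b64(fig)


def _mapping_plot(bundles) -> str:
    cats = ["exon", "intron", "ambiguous", "intergenic", "unmapped"]
    fig, ax = plt.subplots(figsize=(5, 3))
    bottoms = np.zeros(len(bundles))
    xs = np.arange(len(bundles))
    for cat in cats:
        vals = np.array([b.mapping_categories.get(cat, 0) for b in bundles], float)
        ax.bar(xs, vals, 0.6, bottom=bottoms, label=cat)
        bottoms += vals
    ax.set_xticks(xs)
    ax.set_xticklabels([b.sample_id for b in bundles], rotation=20)
    ax.set_ylabel("reads")
    ax.legend(fontsize=7)
    return _fig_to_b64(fig)


def _dup_plot(bundles) -> str:
    fig, ax = plt.subplots(figsize=(5, 3))
    for b in bundles:
        if not b.dup_histogram:
            continue
        ks = sorted(b.dup_histogram)
        ax.plot(ks, [b.dup_histogram[k] for k in ks], marker="o", label=b.sample_id)
    ax.set_xlabel("reads per molecule")
    ax.set_ylabel("molecules")
    ax.legend(fontsize=7)
    return _fig_to_b64(fig)


def _dist_plot(bundles) -> str:
    fig, axes = plt.subplots(1, 2, figsize=(8, 3))
    for b in bundles:
        if b.per_location_totals:
            axes[0].hist(b.per_location_totals, bins=30, alpha=0.5, label=b.sample_id)
        if b.per_gene_totals:
            axes[1].hist(
                np.log10(np.asarray(b.per_gene_totals, float) + 1),
                bins=30, alpha=0.5, label=b.sample_id,
            )
    axes[0].set_xlabel("UMI count per location")
    axes[1].set_xlabel("log10(UMI count per gene + 1)")
    for ax in axes:
        ax.set_ylabel("frequency")
        ax.legend(fontsize=7)
    return _fig_to_b64(fig)


_TEMPLATE = Template(
    """<!DOCTYPE html>
<html><head><meta charset="utf-8"><title>stprep report</title>
<style>body{font-family:sans-serif;max-width:60em;margin:auto}
h2{border-bottom:1px solid #ccc}table{border-collapse:collapse}
td,th{border:1px solid #ccc;padding:2px 8px}</style></head>
<body>
<h1>stprep QC report</h1>
<p>Samples: {% for b in bundles %}<b>{{ b.sample_id }}</b>{% if not loop.last %}, {% endif %}{% endfor %}</p>

<h2>Barcode demultiplexing</h2>
<img src="data:image/png;base64,{{ demux_png }}"/>

<h2>Mapping statistics</h2>
<img src="data:image/png;base64,{{ mapping_png }}"/>

<h2>UMI duplication</h2>
<img src="data:image/png;base64,{{ dup_png }}"/>

<h2>UMI count distributions</h2>
<img src="data:image/png;base64,{{ dist_png }}"/>

<h2>Location QC</h2>
{% if qc_rows %}
<table><tr><th>sample</th><th>method</th><th>threshold</th>
<th>locations before</th><th>locations after</th></tr>
{% for r in qc_rows %}
<tr><td>{{ r.sample }}</td><td>{{ r.method }}</td><td>{{ r.threshold }}</td>
<td>{{ r.n_before }}</td><td>{{ r.n_after }}</td></tr>
{% endfor %}</table>
{% else %}<p>QC filtering was not run for these samples.</p>{% endif %}
</body></html>
"""
)


def render_html(bundles: list[MetricsBundle], out_path: str | Path) -> Path:
    """Render one self-contained HTML report for one or more samples."""
    if not bundles:
        raise ValueError("need at least one metrics bundle")
    qc_rows = [
        {
            "sample": b.sample_id,
            "method": b.qc["method"],
            "threshold": b.qc.get("threshold_umi"),
            "n_before": b.qc["n_before"],
            "n_after": b.qc["n_after"],
        }
        for b in bundles
        if b.qc
    ]
    html = _TEMPLATE.render(
        bundles=bundles,
        demux_png=_demux_plot(bundles),
        mapping_png=_mapping_plot(bundles),
        dup_png=_dup_plot(bundles),
        dist_png=_dist_plot(bundles),
        qc_rows=qc_rows,
    )
    out_path = Path(out_path)
    out_path.write_text(html)
    return out_path
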