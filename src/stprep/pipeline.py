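"""Stage orchestration: reformat/deconvolve -> count -> dedup -> locmatch
-> qc -> report -> export.

Each sample is processed independently in its own output directory, so a
batch can run samples concurrently (up to ``threads``) with no shared
mutable state; a failure in one sample never aborts the others.  Stage
provenance is logged as stable ``sample=... stage=... wall=... sha256=...``
lines.  Mixed-platform batches are rejected before any work.

Inputs per sample in ``data_dir``: ``<sample>_R1.fastq[.gz]``,
``<sample>_R2.fastq[.gz]`` and an aligned ``<sample>.sam`` or
``<sample>.bam`` whose read names already carry the
``<barcode>_<umi>#<id>`` header (the aligner itself is external).
"""

from __future__ import annotations

import hashlib
import logging
import time
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass
from pathlib import Path

from .config import PipelineConfig
from .demultiplex import BarcodeAllowList
from .features import count_molecules, load_annotation, write_molecular_table
from .dedup import dedup_table
from .io_export import export
from .locations import load_layout, match_locations
from .qc import QcParams, run_qc
from .read_structure import get_preset, reformat_fastq_pair
from .report import MetricsBundle, collect_metrics, render_html
from .stereo import deconvolve_fastq_pair, load_coordinate_map

__all__ = ["SampleResult", "run_sample", "run_pipeline"]

logger = logging.getLogger(__name__)


@dataclass
class SampleResult:
    sample_id: str
    ok: bool
    bundle: MetricsBundle | None = None
    error: str | None = None
    out_dir: Path | None = None


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _log_stage(sample_id: str, stage: str, t0: float, artifact: Path | None = None):
    checksum = _sha256(artifact) if artifact is not None and artifact.exists() else "-"
    logger.info(
        "sample=%s stage=%s wall=%.3fs sha256=%s",
        sample_id, stage, time.perf_counter() - t0, checksum,
    )


def _find_input(data_dir: Path, stem: str, suffixes: tuple[str, ...]) -> Path:
    for suffix in suffixes:
        candidate = data_dir / f"{stem}{suffix}"
        if candidate.exists():
            return candidate
    raise FileNotFoundError(
        f"no input {stem}{{{','.join(suffixes)}}} under {data_dir}"
    )


def run_sample(config: PipelineConfig, sample_id: str) -> SampleResult:
    """Run the full stage graph for one sample."""
    out_dir = Path(config.output_dir) / sample_id
    out_dir.mkdir(parents=True, exist_ok=True)
    data_dir = Path(config.data_dir)
    stereo = config.technology == "stereo_seq"
    structure = get_preset(
        config.technology,
        config.technology_version,
        stereo_umi_len=config.stereo_umi_len,
    )

    r1 = _find_input(data_dir, f"{sample_id}_R1", (".fastq.gz", ".fastq", ".fq.gz", ".fq"))
    r2 = _find_input(data_dir, f"{sample_id}_R2", (".fastq.gz", ".fastq", ".fq.gz", ".fq"))
    aln = _find_input(data_dir, sample_id, (".sam", ".bam"))

    # --- reformat / deconvolve ---------------------------------------
    t0 = time.perf_counter()
    reformatted = out_dir / "reformatted.fastq.gz"
    if stereo:
        cmap = load_coordinate_map(config.coordinate_map)
        deconv = deconvolve_fastq_pair(r1, r2, cmap, structure, reformatted)
        from .read_structure import ReformatStats

        reformat_stats = ReformatStats(
            deconv.total_pairs, deconv.passed, deconv.rejected_by_reason
        )
    else:
        reformat_stats = reformat_fastq_pair(
            r1, r2, structure, reformatted, max_pairs=config.max_reads
        )
    _log_stage(sample_id, "reformat", t0, reformatted)

    # --- count --------------------------------------------------------
    t0 = time.perf_counter()
    layout = load_layout(config.coordinate_csv) if config.coordinate_csv else None
    allow = None
    if not stereo and layout is not None:
        allow = BarcodeAllowList(frozenset(layout.barcodes), source="layout_file")
    if config.protocol == "polya":
        annotation = load_annotation(config.annotation)
        result = count_molecules(
            aln, annotation, mode="genome", allow=allow,
            max_dist=config.max_dist, max_reads=config.max_reads,
        )
    else:
        result = count_molecules(
            aln, mode="probe", allow=allow,
            max_dist=config.max_dist, max_reads=config.max_reads,
        )
    table_path = out_dir / "molecular_info.tsv"
    write_molecular_table(result.records, table_path)
    _log_stage(sample_id, "count", t0, table_path)

    # --- dedup --------------------------------------------------------
    t0 = time.perf_counter()
    counts, dup_histogram = dedup_table(result.records, hamming_max=config.hamming_max)
    _log_stage(sample_id, "dedup", t0)

    # --- locmatch -----------------------------------------------------
    t0 = time.perf_counter()
    sc, match_stats = match_locations(counts, layout, config.technology)
    _log_stage(sample_id, "locmatch", t0)

    # --- qc -----------------------------------------------------------
    t0 = time.perf_counter()
    qc_result = None
    try:
        params = QcParams(
            method=config.qc_method,
            ratio_window=config.qc_ratio,
            p_cut=config.p_cut,
            fdr_cut=config.fdr_cut,
            ambient_max_count=config.ambient_max_count,
            seed=config.seed,
        )
        qc_result = run_qc(sc.counts, params)
        qc_path = out_dir / "qc.tsv"
        qc_result.per_location.to_csv(qc_path, sep="\t", index=False)
        passing = dict(zip(qc_result.per_location["barcode"], qc_result.per_location["pass"]))
        sc.locations["qc_pass"] = sc.locations["barcode"].map(passing).fillna(False)
    except ValueError as exc:
        logger.warning("sample=%s stage=qc skipped: %s", sample_id, exc)
    _log_stage(sample_id, "qc", t0)

    # --- report + export ---------------------------------------------
    t0 = time.perf_counter()
    bundle = collect_metrics(
        sample_id,
        reformat_stats=reformat_stats,
        demux_stats=result.demux_stats,
        category_totals=result.category_totals,
        dup_histogram=dup_histogram,
        qc_result=qc_result,
        per_location_totals=sc.counts.location_totals(),
        per_gene_totals=sc.counts.gene_totals(),
    )
    bundle.to_json(out_dir / "metrics.json")
    render_html([bundle], out_dir / "report.html")
    export(sc, out_dir, formats=("mtx_dir", "h5ad"), metrics={"match": match_stats})
    _log_stage(sample_id, "export", t0, out_dir / "mtx" / "matrix.mtx")
    return SampleResult(sample_id, True, bundle, out_dir=out_dir)


def run_pipeline(
    config: PipelineConfig, samples: list[str], platforms: dict[str, str] | None = None
) -> list[SampleResult]:
    """Run a batch of samples, concurrently up to ``config.threads``.

    ``platforms`` optionally declares a per-sample platform; all samples
    must share the config's platform (and species), enforced up front.
    """
    if platforms:
        mixed = {platforms.get(s, config.technology) for s in samples}
        if len(mixed) > 1:
            raise ValueError(
                f"batch mixes platforms {sorted(mixed)}; samples processed together "
                "must share one platform and species"
            )

    def _one(sample_id: str) -> SampleResult:
        try:
            return run_sample(config, sample_id)
        except Exception as exc:  # a failed sample must not abort the batch
            logger.error("sample=%s failed: %s", sample_id, exc)
            return SampleResult(sample_id, False, error=str(exc))

    if config.threads > 1 and len(samples) > 1:
        with ThreadPoolExecutor(max_workers=config.threads) as pool:
            results = list(pool.map(_one, samples))
    else:
        results = [_one(s) for s in samples]

    bundles = [r.bundle for r in results if r.ok and r.bundle]
    if bundles:
        render_html(bundles, Path(config.output_dir) / "report.html")
    return results
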