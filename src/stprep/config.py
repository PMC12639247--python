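"""Flat key=value configuration file parsing and validation.

A run is described by a small flat text file (``key = value`` lines, ``#``
comments).  Validation is platform-conditional: polyA (genome-mode)
protocols need ``fasta`` and ``annotation``; Stereo-seq needs
``coordinate_map``; Slide-seq and Curio Seeker need ``coordinate_csv``.
Unknown keys are warned about, never fatal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

from .read_structure import PLATFORMS

__all__ = ["PipelineConfig", "parse_config", "ConfigError"]


class ConfigError(ValueError):
    """A configuration value is missing or invalid."""


KNOWN_KEYS = {
    "data_dir", "output_dir", "species", "technology", "technology_version",
    "protocol", "threads", "max_reads", "expected_locations", "coordinate_csv",
    "fasta", "annotation", "coordinate_map", "qc_method", "qc_ratio_low",
    "qc_ratio_high", "p_cut", "fdr_cut", "ambient_max_count", "max_dist",
    "hamming_max", "stereo_umi_len", "seed",
}


@dataclass
class PipelineConfig:
    data_dir: Path
    output_dir: Path
    technology: str
    species: str = "unknown"
    technology_version: str | None = None
    protocol: str = "probe"  # probe | polya
    threads: int = 1
    max_reads: int | None = None  # None = all
    expected_locations: int | None = None
    coordinate_csv: Path | None = None
    fasta: Path | None = None
    annotation: Path | None = None
    coordinate_map: Path | None = None
    qc_method: str = "max_slope"
    qc_ratio: tuple[float, float] = (0.0, 1.0)
    p_cut: float = 0.05
    fdr_cut: float = 0.05
    ambient_max_count: int = 10
    max_dist: int = 1
    hamming_max: int = 1
    stereo_umi_len: int = 10
    seed: int = 0
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.technology not in PLATFORMS:
            raise ConfigError(
                f"unknown technology {self.technology!r}; valid: {PLATFORMS}"
            )
        if self.protocol not in ("probe", "polya"):
            raise ConfigError(f"protocol must be 'probe' or 'polya', got {self.protocol!r}")
        if self.threads < 1:
            raise ConfigError(f"threads must be >= 1, got {self.threads}")
        if self.protocol == "polya":
            for key in ("fasta", "annotation"):
                if getattr(self, key) is None:
                    raise ConfigError(
                        f"polyA (genome-mode) runs require '{key}' for technology "
                        f"{self.technology!r}"
                    )
        if self.technology == "stereo_seq" and self.coordinate_map is None:
            raise ConfigError("stereo_seq runs require 'coordinate_map'")
        if (
            self.technology in ("slide_seq_v1", "slide_seq_v2", "curio_seeker")
            and self.coordinate_csv is None
        ):
            raise ConfigError(
                f"{self.technology} runs require 'coordinate_csv' (bead coordinate table)"
            )


def parse_config(path: str | Path) -> PipelineConfig:
    """Parse a flat ``key = value`` file into a validated config."""
    raw: dict[str, str] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ConfigError(f"{path}:{lineno}: expected 'key = value', got {line!r}")
        key, value = (part.strip() for part in line.split("=", 1))
        raw[key] = value

    unknown = set(raw) - KNOWN_KEYS
    if unknown:
        warnings.warn(f"ignoring unknown config keys: {sorted(unknown)}", stacklevel=2)

    def need(key: str) -> str:
        if key not in raw:
            raise ConfigError(f"missing required config key '{key}'")
        return raw[key]

    def opt_path(key: str) -> Path | None:
        return Path(raw[key]) if key in raw else None

    max_reads_raw = raw.get("max_reads", "all")
    max_reads = None if max_reads_raw == "all" else int(max_reads_raw)

    return PipelineConfig(
        data_dir=Path(need("data_dir")),
        output_dir=Path(need("output_dir")),
        technology=need("technology"),
        species=raw.get("species", "unknown"),
        technology_version=raw.get("technology_version"),
        protocol=raw.get("protocol", "polya" if "annotation" in raw else "probe"),
        threads=int(raw.get("threads", 1)),
        max_reads=max_reads,
        expected_locations=(
            int(raw["expected_locations"]) if "expected_locations" in raw else None
        ),
        coordinate_csv=opt_path("coordinate_csv"),
        fasta=opt_path("fasta"),
        annotation=opt_path("annotation"),
        coordinate_map=opt_path("coordinate_map"),
        qc_method=raw.get("qc_method", "max_slope"),
        qc_ratio=(
            float(raw.get("qc_ratio_low", 0.0)),
            float(raw.get("qc_ratio_high", 1.0)),
        ),
        p_cut=float(raw.get("p_cut", 0.05)),
        fdr_cut=float(raw.get("fdr_cut", 0.05)),
        ambient_max_count=int(raw.get("ambient_max_count", 10)),
        max_dist=int(raw.get("max_dist", 1)),
        hamming_max=int(raw.get("hamming_max", 1)),
        stereo_umi_len=int(raw.get("stereo_umi_len", 10)),
        seed=int(raw.get("seed", 0)),
        extras={k: raw[k] for k in unknown},
    )
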