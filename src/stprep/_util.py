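"""Small shared helpers."""

from __future__ import annotations

import gzip
import io
from pathlib import Path

_COMP = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def open_text_write(path: str | Path):
    """Open for text writing; .gz output is reproducible (mtime pinned to 0)."""
    path = Path(path)
    if path.suffix == ".gz":
        raw = gzip.GzipFile(filename=str(path), mode="wb", mtime=0)
        return io.TextIOWrapper(raw)
    return open(path, "w")
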