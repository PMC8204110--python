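"""Table and alignment IO helpers.

All tables are tab-separated with a header row.  Writes are atomic: content
goes to ``<path>.partial`` first and is renamed into place only on success,
so an interrupted run never leaves a truncated table under its final name.
"""

from __future__ import annotations

import hashlib
import os
from pathlib import Path

import pandas as pd
from Bio import AlignIO


def read_tsv(path: str | os.PathLike, **kwargs) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"input table not found: {path}")
    return pd.read_csv(path, sep="\t", **kwargs)


def write_tsv(frame: pd.DataFrame, path: str | os.PathLike, index: bool = False) -> Path:
    """Atomically write ``frame`` as TSV (via a ``.partial`` temp file)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tmp = path.with_name(path.name + ".partial")
    frame.to_csv(tmp, sep="\t", index=index)
    os.replace(tmp, path)
    return path


def write_text(text: str, path: str | os.PathLike) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tmp = path.with_name(path.name + ".partial")
    tmp.write_text(text)
    os.replace(tmp, path)
    return path


def read_alignment(path: str | os.PathLike):
    """Read an aligned FASTA; raises on ragged rows (Bio.AlignIO enforces equal length)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"alignment not found: {path}")
    return AlignIO.read(str(path), "fasta")


def sha256_file(path: str | os.PathLike) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()
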