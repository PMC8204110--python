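"""Family x genome presence/absence matrices from homology-search hit tables.

A hit table has one row per HMM hit: ``family_id``, optional ``subfamily_id``,
``genome_id`` and ``evalue``.  Presence is binary: a family is present in a
genome iff at least one hit (directly or through a mapped subfamily) passes
the E-value threshold (default 0.001, the conventional hmmsearch cut-off).
Copy number is deliberately discarded; downstream clustering operates on
presence/absence profiles only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .io import read_tsv, write_tsv

DEFAULT_EVALUE = 0.001

HIT_COLUMNS = ("family_id", "subfamily_id", "genome_id", "evalue")


@dataclass(frozen=True)
class PresenceMatrix:
    """Boolean family x genome incidence with its provenance threshold.

    ``data`` is a pandas DataFrame of dtype bool; rows are family ids,
    columns genome ids, both unique and lexicographically sorted.
    """

    data: pd.DataFrame
    threshold: float = DEFAULT_EVALUE

    def __post_init__(self):
        object.__setattr__(self, "data", self.data.rename_axis("family_id"))
        if self.data.index.has_duplicates:
            raise ValueError("duplicate family ids in presence matrix")
        if self.data.columns.has_duplicates:
            raise ValueError("duplicate genome ids in presence matrix")

    @property
    def families(self) -> list[str]:
        return list(self.data.index)

    @property
    def genomes(self) -> list[str]:
        return list(self.data.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def to_tsv(self, path) -> Path:
        out = self.data.astype(int)
        out.index.name = "family_id"
        return write_tsv(out, path, index=True)

    @classmethod
    def from_tsv(cls, path, threshold: float = DEFAULT_EVALUE) -> "PresenceMatrix":
        df = read_tsv(path, index_col=0)
        df.index.name = "family_id"
        return cls(df.astype(bool).sort_index(axis=0).sort_index(axis=1), threshold)


def _as_presence_frame(matrix) -> pd.DataFrame:
    if isinstance(matrix, PresenceMatrix):
        return matrix.data
    return pd.DataFrame(matrix).astype(bool)


def validate_hits(hits: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in ("family_id", "genome_id", "evalue") if c not in hits.columns]
    if missing:
        raise ValueError(f"hit table missing columns: {missing}")
    hits = hits.copy()
    if "subfamily_id" not in hits.columns:
        hits["subfamily_id"] = pd.NA
    if (hits["evalue"] <= 0).any():
        bad = hits.loc[hits["evalue"] <= 0]
        raise ValueError(f"E-values must be positive; offending rows: {bad.index.tolist()[:5]}")
    return hits


def build_matrix(
    hits: pd.DataFrame,
    genomes: Iterable[str] | pd.DataFrame,
    threshold: float = DEFAULT_EVALUE,
    subfamily_map: pd.DataFrame | dict | None = None,
    keep_empty: bool = False,
    on_unknown_genome: Literal["error", "warn", "drop"] = "error",
) -> PresenceMatrix:
    """Build a boolean family x genome matrix from a hit table.

    ``genomes`` is either an iterable of genome ids or a metadata frame with a
    ``genome_id`` column; every listed genome becomes a column even if it has
    no passing hit (all-false), so genome-side clustering reflects it.

    ``subfamily_map`` maps subfamily_id -> family_id.  When given, hits whose
    ``subfamily_id`` is set are attributed to the mapped family (union over
    subfamilies); a subfamily absent from the map is an error listing the
    offenders.

    Families with zero passing hits are dropped unless ``keep_empty``.
    """
    hits = validate_hits(hits)
    if isinstance(genomes, pd.DataFrame):
        genome_ids = list(genomes["genome_id"])
    else:
        genome_ids = list(genomes)
    if len(set(genome_ids)) != len(genome_ids):
        raise ValueError("duplicate genome ids in genome list")
    known = set(genome_ids)

    unknown = sorted(set(hits["genome_id"]) - known)
    if unknown:
        if on_unknown_genome == "error":
            raise ValueError(f"hits reference genomes absent from metadata: {unknown[:10]}")
        if on_unknown_genome == "warn":
            warnings.warn(f"dropping hits for {len(unknown)} unknown genomes", stacklevel=2)
        hits = hits[hits["genome_id"].isin(known)]

    if subfamily_map is not None:
        if isinstance(subfamily_map, pd.DataFrame):
            mapping = dict(zip(subfamily_map["subfamily_id"], subfamily_map["family_id"]))
        else:
            mapping = dict(subfamily_map)
        has_sub = hits["subfamily_id"].notna() & (hits["subfamily_id"] != "")
        offenders = sorted(set(hits.loc[has_sub, "subfamily_id"]) - set(mapping))
        if offenders:
            raise KeyError(f"subfamilies missing from subfamily map: {offenders}")
        hits = hits.copy()
        hits.loc[has_sub, "family_id"] = hits.loc[has_sub, "subfamily_id"].map(mapping)

    passing = hits[hits["evalue"] <= threshold]
    families = sorted(set(hits["family_id"])) if keep_empty else sorted(set(passing["family_id"]))
    genome_ids = sorted(genome_ids)

    data = pd.DataFrame(False, index=pd.Index(families, name="family_id"), columns=genome_ids)
    if len(passing):
        present = passing.groupby(["family_id", "genome_id"]).size().index
        for fam, gen in present:
            data.at[fam, gen] = True
    return PresenceMatrix(data, threshold)


def traced_hits(matrix: PresenceMatrix) -> pd.DataFrame:
    """Minimal hit table whose true cells reproduce ``matrix`` (idempotence aid)."""
    fam, gen = np.nonzero(matrix.data.to_numpy())
    return pd.DataFrame(
        {
            "family_id": np.asarray(matrix.families)[fam],
            "subfamily_id": pd.NA,
            "genome_id": np.asarray(matrix.genomes)[gen],
            "evalue": matrix.threshold,
        }
    )


def jaccard_distance_matrix(
    matrix, axis: Literal["families", "genomes"] = "families"
) -> pd.DataFrame:
    """Pairwise Jaccard distances between presence profiles.

    d(x, y) = 1 - |P(x) & P(y)| / |P(x) | P(y)|; two empty profiles are at
    distance 0 (identical).  Symmetric, zero diagonal, values in [0, 1].
    """
    data = _as_presence_frame(matrix)
    if axis not in ("families", "genomes"):
        raise ValueError("axis must be 'families' or 'genomes'")
    if axis == "genomes":
        data = data.T
    if data.shape[0] == 0:
        raise ValueError(f"no {axis} in matrix")
    labels = list(data.index)
    x = data.to_numpy(dtype=bool)
    if data.shape[0] == 1:
        d = np.zeros((1, 1))
    else:
        d = squareform(pdist(x, metric="jaccard"))
    return pd.DataFrame(d, index=labels, columns=labels)
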