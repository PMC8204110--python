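"""Cross-domain "breadth" of archaeal protein families.

Breadth screens archaeal families for a bacteria-like distribution: for a
family with at least one above-threshold hit among the bacterial reference
genomes, breadth is the percentage of bacterial phyla in which at least one
third of that phylum's representative genomes encode a hit.  A family that
is common across many bacterial phyla (high breadth) either serves a core
function shared by both domains or marks an inter-domain lateral transfer;
families with no bacterial hit have undefined (null) breadth.

The "at least one third" phylum rule is inclusive: a phylum with exactly
2 hits among 6 genomes counts.  The denominator of breadth is every phylum
present in the supplied bacterial metadata, including phyla without a
single hit for the family; an optional minimum phylum size can exclude
barely-sampled phyla from the survey altogether.
"""

from __future__ import annotations

import warnings
from typing import Iterable

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .matrix import DEFAULT_EVALUE, validate_hits

DEFAULT_MIN_FRACTION = 1.0 / 3.0
_EPS = 1e-9  # absorbs last-ulp float noise at the inclusive 1/3 boundary


def per_phylum_incidence(
    hits: pd.DataFrame,
    bacterial_meta: pd.DataFrame,
    threshold: float = DEFAULT_EVALUE,
    subfamily_map: pd.DataFrame | dict | None = None,
    families: Iterable[str] | None = None,
    min_phylum_size: int = 1,
) -> pd.DataFrame:
    """Per-family per-phylum hit incidence (percent of genomes with a hit).

    For each (family, phylum): 100 * (#genomes of the phylum with >= 1 hit at
    evalue <= threshold) / (#genomes of the phylum).  Subfamily hits aggregate
    to families by union when a subfamily map is given.  Families listed in
    the hit table but without passing hits appear as all-zero rows.  Phyla
    with fewer than ``min_phylum_size`` genomes are excluded with a warning.
    """
    hits = validate_hits(hits)
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

    meta = bacterial_meta[["genome_id", "phylum"]].drop_duplicates("genome_id")
    sizes = meta.groupby("phylum")["genome_id"].nunique()
    too_small = sorted(sizes.index[sizes < min_phylum_size])
    if too_small:
        warnings.warn(
            f"excluding {len(too_small)} phyla below the minimum size "
            f"{min_phylum_size}: {too_small[:5]}",
            stacklevel=2,
        )
        meta = meta[~meta["phylum"].isin(too_small)]
        sizes = sizes.drop(too_small)
    phyla = sorted(sizes.index)
    if not phyla:
        raise ValueError("no bacterial phyla left to survey")

    fam_index = sorted(set(hits["family_id"]) if families is None else set(families))
    passing = hits[hits["evalue"] <= threshold]
    passing = passing.merge(meta, on="genome_id", how="inner")
    counts = (
        passing.groupby(["family_id", "phylum"])["genome_id"]
        .nunique()
        .unstack(fill_value=0)
        .reindex(index=fam_index, columns=phyla, fill_value=0)
    )
    pct = 100.0 * counts / sizes[phyla]
    pct.index.name = "family_id"
    return pct


def compute_breadth(
    per_phylum_pct: pd.DataFrame,
    min_fraction: float = DEFAULT_MIN_FRACTION,
    has_hit: pd.Series | None = None,
) -> pd.DataFrame:
    """Breadth from a per-family per-phylum incidence table.

    A phylum passes for a family iff its incidence >= 100 * min_fraction
    (inclusive); breadth = 100 * passing phyla / total surveyed phyla.
    Families without any bacterial hit (all-zero incidence unless ``has_hit``
    says otherwise) get null breadth and ``has_bacterial_hit`` False.
    """
    if per_phylum_pct.shape[1] < 1:
        raise ValueError("incidence must cover at least one phylum")
    cut = 100.0 * min_fraction - _EPS
    passing = (per_phylum_pct >= cut).sum(axis=1)
    n_phyla = per_phylum_pct.shape[1]
    if has_hit is None:
        has_hit = per_phylum_pct.sum(axis=1) > 0
    has_hit = has_hit.reindex(per_phylum_pct.index).fillna(False).astype(bool)
    breadth = pd.Series(100.0 * passing / n_phyla, index=per_phylum_pct.index)
    breadth[~has_hit] = np.nan
    out = pd.DataFrame(
        {
            "has_bacterial_hit": has_hit,
            "n_phyla_passing": passing.where(has_hit, 0),
            "breadth_pct": breadth,
        }
    )
    out.index.name = "family_id"
    return out


def breadth_report(
    profiles: pd.DataFrame,
    family_sizes: pd.Series | dict,
    annotations: pd.Series | dict | None = None,
) -> pd.DataFrame:
    """Ranked table of (family, size, breadth, category), sorted by descending
    breadth (undefined last), then descending size, then family id — the
    breadth-vs-size scatter input."""
    sizes = pd.Series(family_sizes)
    out = profiles.copy()
    out["family_size"] = sizes.reindex(out.index)
    if annotations is None:
        out["category"] = "unknown"
    else:
        ann = pd.Series(annotations)
        out["category"] = ann.reindex(out.index).fillna("unknown")
    out = out.reset_index()
    out["_b"] = out["breadth_pct"].fillna(-1.0)
    out = out.sort_values(
        ["_b", "family_size", "family_id"], ascending=[False, False, True], kind="stable"
    ).drop(columns="_b")
    return out.reset_index(drop=True)[
        ["family_id", "family_size", "has_bacterial_hit", "n_phyla_passing", "breadth_pct", "category"]
    ]


class BreadthScorer(BaseEstimator):
    """Fit-shaped wrapper: per-phylum incidence + breadth in one estimator.

    ``fit(hits, bacterial_meta)`` computes:

    incidence_ : per-family per-phylum percent table
    profiles_ : has_bacterial_hit / n_phyla_passing / breadth_pct per family
    n_phyla_ : number of surveyed phyla
    """

    def __init__(
        self,
        threshold: float = DEFAULT_EVALUE,
        min_fraction: float = DEFAULT_MIN_FRACTION,
        min_phylum_size: int = 1,
    ):
        self.threshold = threshold
        self.min_fraction = min_fraction
        self.min_phylum_size = min_phylum_size

    def fit(
        self,
        hits: pd.DataFrame,
        bacterial_meta: pd.DataFrame,
        subfamily_map=None,
        families=None,
    ):
        self.incidence_ = per_phylum_incidence(
            hits,
            bacterial_meta,
            threshold=self.threshold,
            subfamily_map=subfamily_map,
            families=families,
            min_phylum_size=self.min_phylum_size,
        )
        self.profiles_ = compute_breadth(self.incidence_, self.min_fraction)
        self.n_phyla_ = self.incidence_.shape[1]
        return self

    def report(self, family_sizes, annotations=None) -> pd.DataFrame:
        return breadth_report(self.profiles_, family_sizes, annotations)
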