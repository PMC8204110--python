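"""Genome quality control and dereplication.

Implements the filter cascade used to assemble a non-redundant set of
draft-quality genomes before gene-content analysis:

* completeness/contamination estimated from a panel of 38 single-copy genes
  (SCGs): completeness = 100 * present / 38, contamination = 100 * extra
  copies / 38;
* the draft-quality rule (strictly more than 22 SCGs present, strictly fewer
  than 4 duplicated);
* the representative-set rule (completeness >= 70%, contamination <= 10%,
  at least 50% of the columns of the concatenated 14-ribosomal-protein
  alignment covered, and the ribosomal proteins co-encoded on one scaffold);
* dereplication at >= 95% average nucleotide identity (single-linkage
  connected components), keeping the most complete / least contaminated
  genome of each cluster.

The 38-SCG contamination proxy (extra copies / 38) is monotone in
duplication; the panel itself is an input, not recomputed from sequence.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from sklearn.base import BaseEstimator

N_SCGS = 38
GAP_CHARS = ("-", ".")

# the 14 syntenic ribosomal proteins conventionally used for concatenated
# genome phylogenies
RIBOSOMAL_PROTEINS = (
    "L2", "L3", "L4", "L5", "L6", "L14", "L15", "L18", "L22", "L24",
    "S3", "S8", "S17", "S19",
)

DEFAULT_THRESHOLDS = dict(
    min_scgs=22,            # draft rule: strictly more than this
    max_duplicated=4,       # draft rule: strictly fewer than this
    min_completeness=70.0,  # representative rule: fail below
    max_contamination=10.0, # representative rule: fail above
    min_aln_coverage=0.5,   # representative rule: fail below
    ani=95.0,               # dereplication: edge at >= this
)


def estimate_completeness(scg_counts: pd.DataFrame) -> pd.DataFrame:
    """Per-genome completeness/contamination from a 38-SCG copy-number table.

    ``scg_counts`` is indexed by genome_id (or has a ``genome_id`` column)
    with exactly 38 copy-number columns.  Returns a frame with
    ``n_scgs_present`` (copy >= 1), ``n_scgs_duplicated`` (copy >= 2),
    ``completeness`` = 100 * present / 38 and ``contamination`` =
    100 * (total copies - present) / 38.
    """
    counts = scg_counts
    if "genome_id" in counts.columns:
        counts = counts.set_index("genome_id")
    if counts.shape[1] != N_SCGS:
        raise ValueError(
            f"SCG table must have exactly {N_SCGS} marker columns, got {counts.shape[1]}"
        )
    arr = counts.to_numpy()
    if (arr < 0).any():
        raise ValueError("SCG copy numbers must be >= 0")
    present = (arr >= 1).sum(axis=1)
    duplicated = (arr >= 2).sum(axis=1)
    total = arr.sum(axis=1)
    return pd.DataFrame(
        {
            "n_scgs_present": present,
            "n_scgs_duplicated": duplicated,
            "completeness": 100.0 * present / N_SCGS,
            "contamination": 100.0 * (total - present) / N_SCGS,
        },
        index=counts.index.rename("genome_id"),
    )


def draft_quality_filter(
    meta: pd.DataFrame, min_scgs: int = 22, max_duplicated: int = 4
) -> pd.DataFrame:
    """Draft-quality rule: pass iff n_scgs_present > min_scgs AND
    n_scgs_duplicated < max_duplicated (both strict)."""
    reasons = []
    for _, row in meta.iterrows():
        r = []
        if not row["n_scgs_present"] > min_scgs:
            r.append(f"scg-count (requires >{min_scgs} SCGs)")
        if not row["n_scgs_duplicated"] < max_duplicated:
            r.append(f"scg-duplication (requires <{max_duplicated} duplicated)")
        reasons.append(";".join(r))
    return pd.DataFrame(
        {"draft_pass": [r == "" for r in reasons], "draft_reason": reasons},
        index=meta.index,
    )


def results_filter(
    meta: pd.DataFrame,
    aln_coverage: pd.Series | Mapping[str, float],
    rp_single_scaffold: pd.Series | Mapping[str, bool],
    min_completeness: float = 70.0,
    max_contamination: float = 10.0,
    min_aln_coverage: float = 0.5,
) -> pd.DataFrame:
    """Representative-set rule: fail if completeness < 70, contamination > 10,
    alignment coverage < 0.5, or the ribosomal proteins span >1 scaffold.
    All triggered reasons are listed."""
    cov = pd.Series(aln_coverage)
    single = pd.Series(rp_single_scaffold)
    reasons = []
    for gid, row in meta.iterrows():
        r = []
        if row["completeness"] < min_completeness:
            r.append("completeness")
        if row["contamination"] > max_contamination:
            r.append("contamination")
        if cov[gid] < min_aln_coverage:
            r.append("alignment-coverage")
        if not bool(single[gid]):
            r.append("scaffold")
        reasons.append(";".join(r))
    return pd.DataFrame(
        {"results_pass": [r == "" for r in reasons], "results_reason": reasons},
        index=meta.index,
    )


def alignment_column_coverage(alignment, genome_id: str) -> float:
    """Fraction of alignment columns covered (non-gap) for one genome's row.

    ``alignment`` is a Bio.Align.MultipleSeqAlignment (all rows equal length
    by construction).  Gap characters are '-' and '.'.
    """
    for rec in alignment:
        if rec.id == genome_id:
            seq = str(rec.seq)
            if len(seq) == 0:
                return 0.0
            non_gap = sum(1 for c in seq if c not in GAP_CHARS)
            return non_gap / len(seq)
    raise KeyError(f"genome {genome_id!r} not present in alignment")


def rp_single_scaffold(rp_table: pd.DataFrame, genome_id: str) -> bool:
    """True iff the genome's listed ribosomal-protein genes all share one scaffold."""
    rows = rp_table[rp_table["genome_id"] == genome_id]
    if rows.empty:
        return False
    return rows["scaffold_id"].nunique() == 1


def _ani_square(ani: pd.DataFrame) -> pd.DataFrame:
    """Accept a square ANI frame or a long-form (genome_a, genome_b, ani) table."""
    if {"genome_a", "genome_b", "ani"}.issubset(ani.columns):
        ids = sorted(set(ani["genome_a"]) | set(ani["genome_b"]))
        sq = pd.DataFrame(0.0, index=ids, columns=ids)
        np.fill_diagonal(sq.values, 100.0)
        for a, b, v in ani[["genome_a", "genome_b", "ani"]].itertuples(index=False):
            sq.at[a, b] = v
            if sq.at[b, a] == 0.0 or sq.at[b, a] == v:
                sq.at[b, a] = v
            elif not np.isclose(sq.at[b, a], v):
                raise ValueError(f"asymmetric ANI for pair ({a}, {b})")
        return sq
    sq = ani.astype(float)
    if sq.shape[0] != sq.shape[1] or list(sq.index) != list(sq.columns):
        raise ValueError("ANI matrix must be square with matching labels")
    if not np.allclose(sq.to_numpy(), sq.to_numpy().T, atol=1e-8):
        raise ValueError("ANI matrix must be symmetric")
    return sq


class Dereplicator(BaseEstimator):
    """Single-linkage genome dereplication on a pairwise ANI table.

    Clusters are connected components of the graph with an edge wherever
    ANI >= ``threshold`` (inclusive, percent).  The representative of each
    cluster is the most complete genome, ties broken by least contamination,
    then lexicographic genome id.

    Attributes (after :meth:`fit`)
    ------------------------------
    labels_ : pd.Series mapping genome_id -> integer cluster label
    clusters_ : dict label -> sorted list of member genome ids
    representatives_ : pd.Series mapping cluster label -> representative id
    report_ : frame with genome_id, cluster_id, is_representative
    """

    def __init__(self, threshold: float = 95.0):
        self.threshold = threshold

    def fit(self, ani: pd.DataFrame, meta: pd.DataFrame):
        sq = _ani_square(ani)
        ids = list(sq.index)
        m = meta.set_index("genome_id") if "genome_id" in meta.columns else meta
        missing = [g for g in ids if g not in m.index]
        if missing:
            raise ValueError(f"genomes without metadata: {missing[:10]}")
        adj = csr_matrix((sq.to_numpy() >= self.threshold).astype(np.int8))
        n_comp, raw = connected_components(adj, directed=False)
        # relabel components deterministically by their lexicographically
        # smallest member
        order = sorted(range(n_comp), key=lambda c: min(ids[i] for i in range(len(ids)) if raw[i] == c))
        relabel = {old: new for new, old in enumerate(order)}
        labels = pd.Series([relabel[c] for c in raw], index=ids, name="cluster_id")
        clusters = {c: sorted(labels.index[labels == c]) for c in sorted(set(labels))}
        reps = {}
        for c, members in clusters.items():
            reps[c] = min(
                members,
                key=lambda g: (-float(m.at[g, "completeness"]), float(m.at[g, "contamination"]), g),
            )
        self.labels_ = labels
        self.clusters_ = clusters
        self.representatives_ = pd.Series(reps, name="representative")
        self.report_ = pd.DataFrame(
            {
                "genome_id": ids,
                "cluster_id": [labels[g] for g in ids],
                "is_representative": [reps[labels[g]] == g for g in ids],
            }
        )
        return self


def dereplicate(ani: pd.DataFrame, meta: pd.DataFrame, threshold: float = 95.0):
    """Functional wrapper over :class:`Dereplicator`; returns (clusters, representatives)."""
    d = Dereplicator(threshold=threshold).fit(ani, meta)
    return d.clusters_, dict(d.representatives_)


def run_qc(
    scg_counts: pd.DataFrame,
    ani: pd.DataFrame,
    alignment,
    rp_table: pd.DataFrame,
    thresholds: Mapping[str, float] | None = None,
) -> pd.DataFrame:
    """Full QC cascade: SCG estimates -> draft rule -> representative-set rule
    -> dereplication of the survivors.  Returns one row per genome.

    The two rule sets commute (each is a pure per-genome predicate), so the
    surviving set does not depend on application order; dereplication is run
    on the survivors and the per-cluster representative flagged.
    """
    t = dict(DEFAULT_THRESHOLDS)
    if thresholds:
        t.update(thresholds)
    est = estimate_completeness(scg_counts)
    draft = draft_quality_filter(est, t["min_scgs"], t["max_duplicated"])
    cov = pd.Series(
        {g: alignment_column_coverage(alignment, g) for g in est.index}, name="aln_coverage"
    )
    single = pd.Series(
        {g: rp_single_scaffold(rp_table, g) for g in est.index}, name="rp_single_scaffold"
    )
    res = results_filter(
        est, cov, single, t["min_completeness"], t["max_contamination"], t["min_aln_coverage"]
    )
    report = pd.concat([est, draft, cov, single, res], axis=1)
    report.index.name = "genome_id"
    report["qc_pass"] = report["draft_pass"] & report["results_pass"]

    survivors = report.index[report["qc_pass"]]
    report["cluster_id"] = pd.array([pd.NA] * len(report), dtype="Int64")
    report["is_representative"] = False
    if len(survivors) > 0:
        sq = _ani_square(ani)
        sub = sq.loc[survivors, survivors]
        meta = report.loc[survivors, ["completeness", "contamination"]].reset_index()
        derep = Dereplicator(threshold=t["ani"]).fit(sub, meta)
        for g in survivors:
            report.at[g, "cluster_id"] = int(derep.labels_[g])
            report.at[g, "is_representative"] = bool(
                derep.representatives_[derep.labels_[g]] == g
            )
    report.index.name = "genome_id"
    return report
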