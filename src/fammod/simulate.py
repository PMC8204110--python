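"""Synthetic datasets with planted, known structure.

The generator emulates the statistical shape of a comparative gene-content
study: lineage-labelled genomes, a family x genome incidence matrix made of
planted blocks of perfectly co-occurring families ("modules") on top of
sparse background families, symmetric presence/absence flip noise, hit
tables with E-values on either side of the 0.001 detection threshold, and a
bacterial survey with class-controlled per-phylum hit incidence.  It also
fabricates the QC-side inputs (SCG copy numbers, pairwise ANI, a
concatenated ribosomal-protein alignment, scaffold assignments) with a
configurable set of genomes planted to fail each filter rule.

Everything derives from a single integer seed through one independent
pseudo-random stream per output artifact, so adding an artifact never
perturbs another and identical configs are byte-identical.

The generator does not simulate sequence content, gene order, phylogenetic
trees or reads: the alignment rows are random residues with controlled gap
fractions, sufficient to exercise column-coverage accounting and nothing
else.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Align import MultipleSeqAlignment
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .io import write_text, write_tsv
from .qc import N_SCGS, RIBOSOMAL_PROTEINS

MIN_MODULE_SIZE = 20
AMINO_ACIDS = np.array(list("ACDEFGHIKLMNPQRSTVWY"))

_STREAMS = (
    "carriers", "background", "noise", "evalues", "bacterial",
    "scg", "ani", "alignment", "qc_plant",
)


@dataclass(frozen=True)
class Lineage:
    name: str
    is_dpann: bool = False
    domain: str = "archaea"


@dataclass(frozen=True)
class PlantedModule:
    """A block of ``size`` families perfectly co-occurring (before noise) in
    the carrier genomes drawn from ``carrier_lineages`` at ``occupancy``."""

    size: int
    carrier_lineages: tuple[str, ...]
    occupancy: float = 1.0


@dataclass(frozen=True)
class SimConfig:
    lineages: tuple[Lineage, ...]
    n_genomes_per_lineage: int
    n_background_families: int = 0
    background_presence_prob: float = 0.02
    planted_modules: tuple[PlantedModule, ...] = ()
    flip_noise: float = 0.0
    decoy_hit_prob: float = 0.02
    n_bacterial_phyla: int = 5
    genomes_per_phylum: int = 10
    per_phylum_hit_prob: Mapping[str, float] = field(
        default_factory=lambda: {"module": 0.05, "background": 0.25}
    )
    # QC planting: how many genomes fail each rule / how many >=95% ANI pairs
    n_fail_completeness: int = 1
    n_fail_contamination: int = 1
    n_fail_alignment: int = 1
    n_fail_scaffold: int = 1
    n_ani_pairs: int = 1
    alignment_length: int = 200
    seed: int = 0

    def __post_init__(self):
        if self.n_genomes_per_lineage < 1 or len(self.lineages) < 1:
            raise ValueError("need at least one lineage with at least one genome")
        names = [l.name for l in self.lineages]
        if len(set(names)) != len(names):
            raise ValueError("lineage names must be unique")
        for p in (
            self.background_presence_prob, self.flip_noise, self.decoy_hit_prob,
            *self.per_phylum_hit_prob.values(),
        ):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability out of [0, 1]: {p}")
        for mod in self.planted_modules:
            if mod.size < MIN_MODULE_SIZE:
                raise ValueError(
                    f"planted module size {mod.size} violates the rule that a "
                    f"module contains at least {MIN_MODULE_SIZE} families"
                )
            if not 0.0 <= mod.occupancy <= 1.0:
                raise ValueError("carrier occupancy must be in [0, 1]")
            unknown = set(mod.carrier_lineages) - set(names)
            if unknown:
                raise ValueError(f"unknown carrier lineages: {sorted(unknown)}")
        if self.n_bacterial_phyla < 1 or self.genomes_per_phylum < 1:
            raise ValueError("bacterial survey needs >=1 phylum and >=1 genome per phylum")

    def streams(self) -> dict[str, np.random.Generator]:
        children = np.random.SeedSequence(self.seed).spawn(len(_STREAMS))
        return {name: np.random.default_rng(c) for name, c in zip(_STREAMS, children)}


@dataclass
class SimulatedDataset:
    meta: pd.DataFrame
    hits: pd.DataFrame
    presence: pd.DataFrame          # post-noise truth incidence (families x genomes)
    family_truth: pd.DataFrame      # family_id -> planted module_id
    module_truth: pd.DataFrame      # module_id -> carrier lineages/genomes
    bacterial_meta: pd.DataFrame
    bacterial_hits: pd.DataFrame


@dataclass
class QCInputs:
    scg_counts: pd.DataFrame        # genome_id + 38 copy-number columns
    ani: pd.DataFrame               # square, symmetric, diagonal 100
    alignment: MultipleSeqAlignment
    rp_table: pd.DataFrame          # genome_id, protein_name, scaffold_id
    truth: pd.DataFrame             # planted pass/fail per rule


def _genome_meta(config: SimConfig) -> pd.DataFrame:
    rows = []
    for lin in config.lineages:
        for i in range(config.n_genomes_per_lineage):
            rows.append(
                {
                    "genome_id": f"{lin.name}_g{i:03d}",
                    "domain": lin.domain,
                    "phylum": lin.name,
                    "is_dpann": lin.is_dpann,
                }
            )
    return pd.DataFrame(rows)


def _pick_carriers(config: SimConfig, meta: pd.DataFrame, rng: np.random.Generator):
    """Carrier genome sets per planted module.

    Within each lineage, modules claiming it draw carriers from a single
    shuffled pool without replacement (emulating nested clade structure);
    if modules collectively demand more genomes than the lineage holds, the
    pool wraps around and carriers overlap.
    """
    by_lineage = {
        lin.name: list(meta.loc[meta["phylum"] == lin.name, "genome_id"])
        for lin in config.lineages
    }
    pools = {name: rng.permutation(g).tolist() for name, g in by_lineage.items()}
    offset = {name: 0 for name in pools}
    carriers: list[list[str]] = []
    for mod in config.planted_modules:
        chosen: list[str] = []
        for lname in mod.carrier_lineages:
            n = max(1, int(round(mod.occupancy * len(pools[lname]))))
            pool = pools[lname]
            start = offset[lname]
            picked = [pool[(start + j) % len(pool)] for j in range(n)]
            offset[lname] = (start + n) % len(pool)
            chosen.extend(picked)
        carriers.append(sorted(set(chosen)))
    return carriers


def _evalues_for_cells(n_present: int, n_absent: int, config: SimConfig, rng):
    """Passing E-values log-uniform in [1e-30, 1e-4]; decoys in (2e-3, 10]."""
    present_e = 10.0 ** rng.uniform(-30.0, -4.0, size=n_present)
    decoy_mask = rng.random(n_absent) < config.decoy_hit_prob
    decoy_e = 10.0 ** rng.uniform(np.log10(2e-3), 1.0, size=int(decoy_mask.sum()))
    return present_e, decoy_mask, decoy_e


def simulate_dataset(config: SimConfig) -> SimulatedDataset:
    """Generate genome metadata, archaeal and bacterial hit tables, and the
    planted-module truth tables."""
    streams = config.streams()
    meta = _genome_meta(config)
    genomes = list(meta["genome_id"])
    n_g = len(genomes)

    module_ids = [f"pm{k:02d}" for k in range(len(config.planted_modules))]
    fam_ids: list[str] = []
    fam_class: list[str] = []
    fam_module: list[str | None] = []
    for mid, mod in zip(module_ids, config.planted_modules):
        for j in range(mod.size):
            fam_ids.append(f"fam{len(fam_ids):05d}")
            fam_class.append("module")
            fam_module.append(mid)
    for _ in range(config.n_background_families):
        fam_ids.append(f"fam{len(fam_ids):05d}")
        fam_class.append("background")
        fam_module.append(None)
    n_f = len(fam_ids)

    carriers = _pick_carriers(config, meta, streams["carriers"])
    gindex = {g: i for i, g in enumerate(genomes)}
    presence = np.zeros((n_f, n_g), dtype=bool)
    row = 0
    for mod, carr in zip(config.planted_modules, carriers):
        idx = [gindex[g] for g in carr]
        presence[row : row + mod.size, idx] = True
        row += mod.size
    if config.n_background_families:
        presence[row:, :] = (
            streams["background"].random((config.n_background_families, n_g))
            < config.background_presence_prob
        )

    if config.flip_noise > 0:
        flips = streams["noise"].random((n_f, n_g)) < config.flip_noise
        presence ^= flips

    fi, gi = np.nonzero(presence)
    afi, agi = np.nonzero(~presence)
    present_e, decoy_mask, decoy_e = _evalues_for_cells(
        len(fi), len(afi), config, streams["evalues"]
    )
    fam_arr = np.asarray(fam_ids)
    gen_arr = np.asarray(genomes)
    hits = pd.DataFrame(
        {
            "family_id": np.concatenate([fam_arr[fi], fam_arr[afi[decoy_mask]]]),
            "subfamily_id": pd.NA,
            "genome_id": np.concatenate([gen_arr[gi], gen_arr[agi[decoy_mask]]]),
            "evalue": np.concatenate([present_e, decoy_e]),
        }
    ).sort_values(["family_id", "genome_id", "evalue"], kind="stable").reset_index(drop=True)

    family_truth = pd.DataFrame(
        {
            "family_id": [f for f, m in zip(fam_ids, fam_module) if m is not None],
            "module_id": [m for m in fam_module if m is not None],
        }
    )
    module_truth = pd.DataFrame(
        {
            "module_id": module_ids,
            "size": [m.size for m in config.planted_modules],
            "carrier_lineages": [";".join(m.carrier_lineages) for m in config.planted_modules],
            "carrier_genomes": [";".join(c) for c in carriers],
            "occupancy": [m.occupancy for m in config.planted_modules],
            "is_dpann": [
                all(
                    next(l for l in config.lineages if l.name == n).is_dpann
                    for n in m.carrier_lineages
                )
                for m in config.planted_modules
            ],
        }
    )

    bacterial_meta, bacterial_hits = _simulate_bacterial(
        config, fam_ids, fam_class, streams["bacterial"]
    )

    presence_df = pd.DataFrame(
        presence, index=pd.Index(fam_ids, name="family_id"), columns=genomes
    )
    return SimulatedDataset(
        meta=meta,
        hits=hits,
        presence=presence_df,
        family_truth=family_truth,
        module_truth=module_truth,
        bacterial_meta=bacterial_meta,
        bacterial_hits=bacterial_hits,
    )


def _simulate_bacterial(config, fam_ids, fam_class, rng):
    phyla = [f"BactPhylum{p:02d}" for p in range(config.n_bacterial_phyla)]
    rows = []
    for ph in phyla:
        for i in range(config.genomes_per_phylum):
            rows.append({"genome_id": f"{ph}_g{i:03d}", "domain": "bacteria", "phylum": ph})
    bmeta = pd.DataFrame(rows)
    bgen = np.asarray(bmeta["genome_id"])
    n_b = len(bgen)
    probs = np.array([config.per_phylum_hit_prob.get(c, 0.0) for c in fam_class])
    hit = rng.random((len(fam_ids), n_b)) < probs[:, None]
    fi, gi = np.nonzero(hit)
    evals = 10.0 ** rng.uniform(-30.0, -4.0, size=len(fi))
    bhits = pd.DataFrame(
        {
            "family_id": np.asarray(fam_ids)[fi],
            "subfamily_id": pd.NA,
            "genome_id": bgen[gi],
            "evalue": evals,
        }
    ).sort_values(["family_id", "genome_id"], kind="stable").reset_index(drop=True)
    return bmeta, bhits


def simulate_qc_inputs(config: SimConfig) -> QCInputs:
    """Generate the QC-stage inputs with genomes planted to fail each rule.

    Planted failures (counts from the config): low SCG completeness, high SCG
    duplication, <50% coverage of the ribosomal-protein alignment, ribosomal
    proteins split over two scaffolds, and >=95%-ANI redundant pairs (both
    members otherwise passing).  All remaining genomes are built to pass
    every rule.  The returned truth table marks each planted condition.
    """
    streams = config.streams()
    meta = _genome_meta(config)
    genomes = list(meta["genome_id"])
    n = len(genomes)
    need = (
        config.n_fail_completeness + config.n_fail_contamination
        + config.n_fail_alignment + config.n_fail_scaffold + 2 * config.n_ani_pairs
    )
    if need > n:
        raise ValueError(f"QC plan plants {need} genomes but only {n} exist")
    rng = streams["qc_plant"]
    picked = list(rng.choice(genomes, size=need, replace=False))
    cursor = 0

    def take(k):
        nonlocal cursor
        out = picked[cursor : cursor + k]
        cursor += k
        return out

    fail_completeness = take(config.n_fail_completeness)
    fail_contamination = take(config.n_fail_contamination)
    fail_alignment = take(config.n_fail_alignment)
    fail_scaffold = take(config.n_fail_scaffold)
    ani_pairs = [tuple(take(2)) for _ in range(config.n_ani_pairs)]

    # --- SCG copy-number table ---------------------------------------------
    scg_rng = streams["scg"]
    scg_cols = [f"scg{i:02d}" for i in range(N_SCGS)]
    counts = np.ones((n, N_SCGS), dtype=int)
    for i, g in enumerate(genomes):
        if g in fail_completeness:
            absent = scg_rng.choice(N_SCGS, size=N_SCGS - 19, replace=False)
            counts[i, absent] = 0
        elif g in fail_contamination:
            dup = scg_rng.choice(N_SCGS, size=6, replace=False)
            counts[i, dup] = 2  # 6 extra copies -> contamination 15.8% and >=4 duplicated
        else:
            n_dup = int(scg_rng.integers(0, 3))  # <=2 dups keeps contamination <= 5.3%
            if n_dup:
                dup = scg_rng.choice(N_SCGS, size=n_dup, replace=False)
                counts[i, dup] = 2
    scg = pd.DataFrame(counts, columns=scg_cols)
    scg.insert(0, "genome_id", genomes)

    # --- pairwise ANI -------------------------------------------------------
    ani_rng = streams["ani"]
    ani = ani_rng.uniform(75.0, 90.0, size=(n, n))
    ani = (ani + ani.T) / 2.0
    np.fill_diagonal(ani, 100.0)
    gidx = {g: i for i, g in enumerate(genomes)}
    for a, b in ani_pairs:
        ani[gidx[a], gidx[b]] = ani[gidx[b], gidx[a]] = 97.0
    ani_df = pd.DataFrame(ani, index=genomes, columns=genomes)

    # --- concatenated ribosomal-protein alignment --------------------------
    aln_rng = streams["alignment"]
    length = config.alignment_length
    records = []
    for g in genomes:
        residues = aln_rng.choice(AMINO_ACIDS, size=length)
        if g in fail_alignment:
            gap_frac = 0.60  # 40% column coverage, below the 50% rule
        else:
            gap_frac = float(aln_rng.uniform(0.0, 0.10))
        n_gap = int(round(gap_frac * length))
        if n_gap:
            gaps = aln_rng.choice(length, size=n_gap, replace=False)
            residues[gaps] = "-"
        records.append(SeqRecord(Seq("".join(residues)), id=g, description=""))
    alignment = MultipleSeqAlignment(records)

    # --- ribosomal-protein scaffold table ----------------------------------
    rp_rows = []
    for g in genomes:
        for j, rp in enumerate(RIBOSOMAL_PROTEINS):
            if g in fail_scaffold and j >= len(RIBOSOMAL_PROTEINS) // 2:
                scaf = f"{g}_scaffold_2"
            else:
                scaf = f"{g}_scaffold_1"
            rp_rows.append({"genome_id": g, "protein_name": rp, "scaffold_id": scaf})
    rp_table = pd.DataFrame(rp_rows)

    partner = {}
    for a, b in ani_pairs:
        partner[a], partner[b] = b, a
    truth = pd.DataFrame(
        {
            "genome_id": genomes,
            "fails_completeness": [g in fail_completeness for g in genomes],
            "fails_contamination": [g in fail_contamination for g in genomes],
            "fails_alignment": [g in fail_alignment for g in genomes],
            "fails_scaffold": [g in fail_scaffold for g in genomes],
            "ani_cluster_partner": [partner.get(g, "") for g in genomes],
        }
    )
    truth["expected_pass"] = ~(
        truth["fails_completeness"] | truth["fails_contamination"]
        | truth["fails_alignment"] | truth["fails_scaffold"]
    )
    return QCInputs(scg_counts=scg, ani=ani_df, alignment=alignment, rp_table=rp_table, truth=truth)


def recovery_benchmark_config(seed: int = 0) -> SimConfig:
    """The standard planted-recovery benchmark configuration.

    300 genomes in 6 lineages (3 DPANN, 3 other archaea), 1,500 sparse
    background families, 12 planted single-lineage modules with sizes
    spanning 20-60, two modules per lineage each carried by half of the
    lineage's genomes (disjoint halves, i.e. sub-clades), and 5% flip noise.
    """
    lineages = tuple(
        Lineage(name=f"Lineage{i:02d}", is_dpann=i < 3) for i in range(6)
    )
    sizes = (20, 24, 27, 31, 35, 38, 42, 45, 49, 53, 56, 60)
    modules = tuple(
        PlantedModule(size=s, carrier_lineages=(lineages[k % 6].name,), occupancy=0.5)
        for k, s in enumerate(sizes)
    )
    return SimConfig(
        lineages=lineages,
        n_genomes_per_lineage=50,
        n_background_families=1500,
        background_presence_prob=0.02,
        planted_modules=modules,
        flip_noise=0.05,
        seed=seed,
    )


def write_dataset(ds: SimulatedDataset, out_dir) -> dict[str, Path]:
    """Write the simulated analysis inputs as headed TSVs."""
    out = Path(out_dir)
    paths = {
        "meta": write_tsv(ds.meta, out / "genome_meta.tsv"),
        "hits": write_tsv(ds.hits, out / "hits.tsv"),
        "family_truth": write_tsv(ds.family_truth, out / "truth_families.tsv"),
        "module_truth": write_tsv(ds.module_truth, out / "truth_modules.tsv"),
        "bacterial_meta": write_tsv(ds.bacterial_meta, out / "bacterial_meta.tsv"),
        "bacterial_hits": write_tsv(ds.bacterial_hits, out / "bacterial_hits.tsv"),
    }
    return paths


def write_qc_inputs(qc: QCInputs, out_dir) -> dict[str, Path]:
    """Write the simulated QC inputs (TSVs + aligned FASTA)."""
    out = Path(out_dir)
    fasta = "".join(f">{rec.id}\n{rec.seq}\n" for rec in qc.alignment)
    ani_out = qc.ani.copy()
    ani_out.index.name = "genome_id"
    paths = {
        "scg": write_tsv(qc.scg_counts, out / "scg_counts.tsv"),
        "ani": write_tsv(ani_out, out / "ani.tsv", index=True),
        "alignment": write_text(fasta, out / "rp_alignment.fasta"),
        "rp_table": write_tsv(qc.rp_table, out / "rp_scaffolds.tsv"),
        "qc_truth": write_tsv(qc.truth, out / "truth_qc.tsv"),
    }
    return paths
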