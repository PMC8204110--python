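"""Family clustering, module extraction, taxonomy and occurrence rules."""

import numpy as np
import pandas as pd
import pytest

from fammod import (
    FamilyModuleDetector,
    Module,
    assign_module_taxonomy,
    build_matrix,
    classify_module_occurrence,
    cluster_families,
    cluster_genomes,
    extract_modules,
    jaccard_distance_matrix,
    simulate_dataset,
    summarize_modules,
)
from oracles import oracle_module_taxonomy


def block_distance(sizes, within=0.0, between=1.0):
    labels = [f"f{i:03d}" for i in range(sum(sizes))]
    arr = np.full((len(labels), len(labels)), between)
    start = 0
    for s in sizes:
        arr[start : start + s, start : start + s] = within
        start += s
    np.fill_diagonal(arr, 0.0)
    return pd.DataFrame(arr, index=labels, columns=labels)


class TestClusterFamilies:
    def test_separated_blocks_recovered(self):
        clusters = cluster_families(block_distance([5, 3, 4]))
        sizes = sorted(len(v) for v in clusters.values())
        assert sizes == [3, 4, 5]

    def test_all_distant_families_are_singletons(self):
        clusters = cluster_families(block_distance([1] * 6, between=1.0))
        assert sorted(len(v) for v in clusters.values()) == [1] * 6

    def test_all_identical_profiles_one_cluster(self):
        clusters = cluster_families(block_distance([6], within=0.0))
        assert len(clusters) == 1

    def test_cutoff_strictly_separates_heights_above(self):
        # merge height 0.96 > cutoff 0.95 stays split; 0.94 merges
        assert len(cluster_families(block_distance([1, 1], between=0.96))) == 2
        assert len(cluster_families(block_distance([1, 1], between=0.94))) == 1

    def test_asymmetric_distance_rejected(self):
        d = block_distance([2])
        d.iloc[0, 1] = 0.5
        with pytest.raises(ValueError, match="symmetric"):
            cluster_families(d)

    def test_result_independent_of_row_order(self, rng):
        d = block_distance([4, 5], within=0.2, between=0.99)
        perm = rng.permutation(len(d))
        shuffled = d.iloc[perm, perm]
        assert cluster_families(d) == cluster_families(shuffled)


class TestExtractModules:
    def test_min_size_rule(self):
        clusters = {
            1: [f"a{i}" for i in range(25)],
            2: [f"b{i}" for i in range(19)],
            3: [f"c{i}" for i in range(40)],
        }
        modules, residuals = extract_modules(clusters)
        assert len(modules) == 2
        assert set(residuals["family_id"]) == set(clusters[2])

    def test_no_cluster_large_enough(self):
        clusters = {1: ["a", "b"], 2: ["c"]}
        modules, residuals = extract_modules(clusters)
        assert modules == []
        assert len(residuals) == 3

    def test_numbering_by_descending_size_then_smallest_member(self):
        clusters = {
            1: [f"b{i:02d}" for i in range(20)],
            2: [f"a{i:02d}" for i in range(20)],
            3: [f"z{i:02d}" for i in range(30)],
        }
        modules, _ = extract_modules(clusters)
        assert [m.module_id for m in modules] == ["M001", "M002", "M003"]
        assert modules[0].family_ids[0].startswith("z")
        assert modules[1].family_ids[0].startswith("a")  # tie at 20 -> 'a' before 'b'


def presence_from_sets(fam_sets, genomes):
    data = pd.DataFrame(False, index=sorted(fam_sets), columns=genomes)
    for fam, gset in fam_sets.items():
        data.loc[fam, list(gset)] = True
    return data


class TestModuleTaxonomy:
    def test_hand_worked_median_rule(self):
        # per-family genome counts {3,2,4,3} -> m=3; carriage ranks g1..g3 top
        genomes = ["g1", "g2", "g3", "g4", "g5"]
        fam_sets = {
            "f1": {"g1", "g2", "g3"},
            "f2": {"g1", "g2"},
            "f3": {"g1", "g2", "g3", "g4"},
            "f4": {"g1", "g3", "g5"},
        }
        meta = pd.DataFrame(
            {
                "genome_id": genomes,
                "phylum": ["Pace", "Pace", "Woese", "Woese", "Woese"],
            }
        )
        mod = Module("M001", tuple(sorted(fam_sets)))
        data = presence_from_sets(fam_sets, genomes)
        assign_module_taxonomy(mod, data, meta)
        assert mod.m == 3
        assert set(mod.retained_genomes) == {"g1", "g2", "g3"}
        assert mod.taxon_distribution == {"Pace": 2, "Woese": 1}
        assert mod.assigned_single_lineage is None  # not unanimous
        assert mod.dominant_lineage == "Pace"

    def test_degenerate_identical_families_single_lineage(self):
        genomes = [f"g{i}" for i in range(1, 8)]
        carriers = {"g1", "g2", "g3", "g4", "g5"}
        fam_sets = {f"f{i}": set(carriers) for i in range(3)}
        meta = pd.DataFrame(
            {"genome_id": genomes, "phylum": ["Pace"] * 5 + ["Woese"] * 2}
        )
        mod = assign_module_taxonomy(
            Module("M001", tuple(sorted(fam_sets))), presence_from_sets(fam_sets, genomes), meta
        )
        assert mod.m == 5
        assert set(mod.retained_genomes) == carriers
        assert mod.assigned_single_lineage == "Pace"

    def test_integer_median_not_rounded(self):
        genomes = ["g1", "g2", "g3"]
        fam_sets = {"f1": {"g1", "g2"}, "f2": {"g1", "g3"}}
        meta = pd.DataFrame({"genome_id": genomes, "phylum": ["P"] * 3})
        mod = assign_module_taxonomy(
            Module("M", tuple(sorted(fam_sets))), presence_from_sets(fam_sets, genomes), meta
        )
        assert mod.m == 2

    def test_fractional_median_rounds_half_up(self):
        genomes = [f"g{i}" for i in range(5)]
        fam_sets = {"f1": {"g0", "g1"}, "f2": {"g0", "g1", "g2"}}  # median 2.5 -> 3
        meta = pd.DataFrame({"genome_id": genomes, "phylum": ["P"] * 5})
        mod = assign_module_taxonomy(
            Module("M", tuple(sorted(fam_sets))), presence_from_sets(fam_sets, genomes), meta
        )
        assert mod.m == 3

    def test_missing_family_is_error(self):
        meta = pd.DataFrame({"genome_id": ["g1"], "phylum": ["P"]})
        data = presence_from_sets({"f1": {"g1"}}, ["g1"])
        with pytest.raises(KeyError, match="fX"):
            assign_module_taxonomy(Module("M", ("f1", "fX")), data, meta)

    def test_agrees_with_brute_force_oracle(self, rng):
        for _ in range(100):
            n_g = int(rng.integers(3, 12))
            n_f = int(rng.integers(2, 8))
            genomes = [f"g{i:02d}" for i in range(n_g)]
            phyla = [f"P{int(rng.integers(0, 3))}" for _ in genomes]
            fam_sets = {
                f"f{i:02d}": set(
                    np.array(genomes)[rng.random(n_g) < rng.uniform(0.2, 0.9)]
                )
                for i in range(n_f)
            }
            meta = pd.DataFrame({"genome_id": genomes, "phylum": phyla})
            mod = assign_module_taxonomy(
                Module("M", tuple(sorted(fam_sets))),
                presence_from_sets(fam_sets, genomes),
                meta,
            )
            m, retained, dist = oracle_module_taxonomy(
                sorted(fam_sets), fam_sets, dict(zip(genomes, phyla))
            )
            assert mod.m == m
            assert list(mod.retained_genomes) == retained
            assert mod.taxon_distribution == dist


class TestOccurrence:
    @pytest.fixture
    def meta(self, small_meta):
        return small_meta

    def test_dpann_only_module_is_enriched(self, meta):
        fam_sets = {"f1": {"g1", "g2"}, "f2": {"g3"}}
        data = presence_from_sets(fam_sets, list(meta.genome_id))
        mod = classify_module_occurrence(Module("M", ("f1", "f2")), data, meta)
        assert mod.occurs_in_dpann and mod.enriched_in_dpann
        assert mod.nondpann_prevalence == 0.0

    def test_module_absent_from_dpann(self, meta):
        fam_sets = {"f1": {"g5", "g6"}}
        data = presence_from_sets(fam_sets, list(meta.genome_id))
        mod = classify_module_occurrence(Module("M", ("f1",)), data, meta)
        assert not mod.occurs_in_dpann
        assert not mod.enriched_in_dpann

    def test_mean_prevalence_hand_example(self, meta):
        # famA in 2/4 DPANN & 1/4 others; famB in 4/4 DPANN & 1/4 others
        fam_sets = {
            "famA": {"g1", "g2", "g5"},
            "famB": {"g1", "g2", "g3", "g4", "g6"},
        }
        data = presence_from_sets(fam_sets, list(meta.genome_id))
        mod = classify_module_occurrence(Module("M", ("famA", "famB")), data, meta)
        assert mod.dpann_prevalence == pytest.approx(0.75)
        assert mod.nondpann_prevalence == pytest.approx(0.25)
        assert mod.enriched_in_dpann

    def test_undefined_without_both_groups(self):
        meta = pd.DataFrame(
            {
                "genome_id": ["g1", "g2"],
                "domain": ["archaea", "archaea"],
                "phylum": ["P", "P"],
                "is_dpann": [True, True],
            }
        )
        data = presence_from_sets({"f1": {"g1"}}, ["g1", "g2"])
        mod = classify_module_occurrence(Module("M", ("f1",)), data, meta)
        assert not mod.prevalence_defined
        assert mod.dpann_prevalence is None


class TestGenomeClustering:
    def test_identical_genomes_merge_at_zero(self):
        data = presence_from_sets({"f1": {"g1", "g2"}, "f2": {"g1", "g2"}}, ["g1", "g2"])
        newick, ordered = cluster_genomes(data)
        assert newick.endswith(";")
        assert ":0" in newick
        assert list(ordered.columns) == ["g1", "g2"]

    def test_lineage_blocks_form_top_bipartition(self):
        genomes = ["a1", "a2", "a3", "b1", "b2", "b3"]
        fam_sets = {
            "f1": {"a1", "a2", "a3"},
            "f2": {"a1", "a2", "a3"},
            "f3": {"b1", "b2", "b3"},
            "f4": {"b1", "b2", "b3"},
        }
        _, ordered = cluster_genomes(presence_from_sets(fam_sets, genomes))
        cols = list(ordered.columns)
        first3 = {c[0] for c in cols[:3]}
        assert first3 in ({"a"}, {"b"})  # each block contiguous in leaf order

    def test_single_genome_is_error(self):
        data = presence_from_sets({"f1": {"g1"}}, ["g1"])
        with pytest.raises(ValueError, match="at least 2"):
            cluster_genomes(data)


class TestDetectorEndToEnd:
    def test_planted_modules_recovered_exactly_without_noise(self, noise_free_dataset):
        ds = noise_free_dataset
        pm = build_matrix(ds.hits, ds.meta)
        det = FamilyModuleDetector().fit(pm, ds.meta)
        detected = {frozenset(m.family_ids) for m in det.modules_}
        planted = {
            frozenset(grp.family_id) for _, grp in ds.family_truth.groupby("module_id")
        }
        assert detected == planted

    def test_family_assignment_is_a_partition(self, noise_free_dataset):
        ds = noise_free_dataset
        pm = build_matrix(ds.hits, ds.meta)
        det = FamilyModuleDetector().fit(pm, ds.meta)
        seen = set()
        for m in det.modules_:
            assert not (seen & set(m.family_ids))
            seen |= set(m.family_ids)

    def test_deterministic_across_runs(self, noise_free_dataset):
        ds = noise_free_dataset
        pm = build_matrix(ds.hits, ds.meta)
        a = FamilyModuleDetector().fit(pm, ds.meta)
        b = FamilyModuleDetector().fit(pm, ds.meta)
        assert [m.family_ids for m in a.modules_] == [m.family_ids for m in b.modules_]
        pd.testing.assert_series_equal(a.labels_, b.labels_)

    def test_sklearn_param_interface(self):
        det = FamilyModuleDetector(cutoff=0.9)
        assert det.get_params()["cutoff"] == 0.9
        det.set_params(min_size=25)
        assert det.min_size == 25


class TestSummarize:
    def test_zero_modules(self):
        assert summarize_modules([]) == {
            "n_modules_in_dpann": 0,
            "n_families_in_dpann_modules": 0,
            "n_modules_enriched": 0,
            "n_families_enriched": 0,
            "n_modules_single_lineage": 0,
        }

    def test_planted_dpann_fixture_counts(self, noise_free_dataset):
        ds = noise_free_dataset
        pm = build_matrix(ds.hits, ds.meta)
        det = FamilyModuleDetector().fit(pm, ds.meta)
        summary = summarize_modules(det.modules_)
        assert summary["n_modules_in_dpann"] == 3
        assert summary["n_families_in_dpann_modules"] == 75
        assert summary["n_modules_enriched"] == 3
        assert summary["n_families_enriched"] == 75
        assert summary["n_modules_single_lineage"] == 3

    def test_non_dpann_module_excluded_from_occurrence(self, small_meta):
        fam_sets_a = {f"a{i}": {"g1", "g2"} for i in range(2)}
        data = presence_from_sets(
            {**fam_sets_a, "b0": {"g5", "g6"}}, list(small_meta.genome_id)
        )
        mods = [
            classify_module_occurrence(Module("M001", tuple(sorted(fam_sets_a))), data, small_meta),
            classify_module_occurrence(Module("M002", ("b0",)), data, small_meta),
        ]
        summary = summarize_modules(mods)
        assert summary["n_modules_in_dpann"] == 1
        assert summary["n_families_in_dpann_modules"] == 2
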