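"""Specimen tables, MNI clustering, binning, FAD/LAD and composition."""

import itertools
import random

import numpy as np
import pytest

from paleospd import (SpecimenRecord, UncalDate, assign_mni_clusters,
                      calibrate_specimens, cave_composition, fad_lad,
                      fraction_after, load_specimens, make_bins)
from conftest import write_specimens


def make_records(rows, curve=None, level=0.954):
    """rows: (specimen_id, site_id, taxon, c14_age, c14_error)"""
    recs = [SpecimenRecord(sid, site, taxon,
                           UncalDate(sid, float(age), float(err)))
            for sid, site, taxon, age, err in rows]
    if curve is not None:
        recs = calibrate_specimens(recs, curve, level=level)
    return recs


class TestLoadSpecimens:
    def test_roundtrip(self, tmp_path):
        path = write_specimens(tmp_path / "s.csv", [
            ("A1", "cave-1", "Hyaena hyaena", 4000, 25, "collagen"),
            ("A2", "cave-1", "Panthera pardus", 9000, 30, "bioapatite"),
            ("A3", "cave-2", "Vulpes cana", 1500, 20, "scat"),
        ])
        recs = load_specimens(path)
        assert len(recs) == 3
        assert recs[0].date.c14_age == 4000
        assert recs[2].site_id == "cave-2"

    def test_duplicate_id_rejected(self, tmp_path):
        path = write_specimens(tmp_path / "s.csv", [
            ("A1", "cave-1", "Hyaena hyaena", 4000, 25),
            ("A1", "cave-2", "Hyaena hyaena", 4100, 25),
        ])
        with pytest.raises(ValueError, match="A1"):
            load_specimens(path)

    def test_zero_error_rejected(self, tmp_path):
        path = write_specimens(tmp_path / "s.csv", [("A1", "c", "Hyaena hyaena", 4000, 0)])
        with pytest.raises(ValueError, match="c14_error"):
            load_specimens(path)

    def test_missing_column_rejected(self, tmp_path):
        path = tmp_path / "s.csv"
        path.write_text("specimen_id,taxon,c14_age,c14_error,fraction\nA1,t,1,2,unknown\n")
        with pytest.raises(ValueError, match="site_id"):
            load_specimens(path)


class TestMNI:
    def test_same_site_identical_dates_merge(self, identity_curve):
        recs = make_records([("a", "cave-1", "Hyaena hyaena", 4000, 25),
                             ("b", "cave-1", "Hyaena hyaena", 4000, 25)],
                            identity_curve)
        res = assign_mni_clusters(recs, "Hyaena hyaena")
        assert res.mni == 1 and res.nisp == 2

    def test_different_sites_never_merge(self, identity_curve):
        recs = make_records([("a", "cave-1", "Hyaena hyaena", 4000, 25),
                             ("b", "cave-2", "Hyaena hyaena", 4000, 25)],
                            identity_curve)
        assert assign_mni_clusters(recs, "Hyaena hyaena").mni == 2

    def test_transitive_closure_chains_overlaps(self, identity_curve):
        # a-b overlap and b-c overlap, a-c do not: single linkage gives 1 cluster
        recs = make_records([("a", "s", "Panthera pardus", 4000, 30),
                             ("b", "s", "Panthera pardus", 4100, 30),
                             ("c", "s", "Panthera pardus", 4200, 30)],
                            identity_curve)
        res = assign_mni_clusters(recs, "Panthera pardus")
        assert res.mni == 1
        assert res.clusters == (frozenset({"a", "b", "c"}),)

    def test_modern_and_beyond_are_singletons(self, identity_curve):
        recs = make_records([("a", "s", "Hyaena hyaena", 4000, 25),
                             ("m", "s", "Hyaena hyaena", -500, 30),
                             ("o", "s", "Hyaena hyaena", 60000, 400)],
                            identity_curve)
        res = assign_mni_clusters(recs, "Hyaena hyaena")
        assert res.mni == 3 and res.nisp == 3

    def test_absent_taxon_empty_result(self, identity_curve):
        recs = make_records([("a", "s", "Hyaena hyaena", 4000, 25)], identity_curve)
        res = assign_mni_clusters(recs, "Canis lupus")
        assert res.mni == 0 and res.clusters == ()

    def test_mni_at_most_nisp_and_order_invariant(self, wiggly_curve):
        rng = np.random.default_rng(5)
        rows = [(f"s{i}", f"cave-{rng.integers(3)}", "Hyaena hyaena",
                 float(rng.uniform(1000, 9000)), 25.0) for i in range(12)]
        recs = make_records(rows, wiggly_curve)
        base = assign_mni_clusters(recs, "Hyaena hyaena")
        assert 1 <= base.mni <= base.nisp == 12
        shuffled = list(recs)
        random.Random(0).shuffle(shuffled)
        assert assign_mni_clusters(shuffled, "Hyaena hyaena").clusters == base.clusters


def brute_force_single_linkage(ages, h):
    """All-partitions check: the single-linkage clustering is the unique
    partition into maximal runs with consecutive gaps <= h."""
    ages = sorted(ages)
    clusters, current = [], [ages[0]]
    for prev, nxt in zip(ages, ages[1:]):
        if nxt - prev <= h:
            current.append(nxt)
        else:
            clusters.append(current)
            current = [nxt]
    clusters.append(current)
    return clusters


class TestBins:
    def test_cutoff_zero_separates_distinct_ages(self, identity_curve):
        recs = make_records([("a", "s", "T", 1000, 20), ("b", "s", "T", 1001, 20),
                             ("c", "s", "T", 1000, 20)])
        bs = make_bins(recs, h=0)
        assert bs.n_bins == 2
        assert frozenset({"a", "c"}) in bs.bins

    def test_gap_rule_matches_brute_force(self):
        recs = make_records([("a", "s", "T", 1000, 20), ("b", "s", "T", 1050, 20),
                             ("c", "s", "T", 1200, 20)])
        bs = make_bins(recs, h=100)
        assert sorted(map(sorted, bs.bins)) == [["a", "b"], ["c"]]
        assert [len(c) for c in brute_force_single_linkage([1000, 1050, 1200], 100)] == [2, 1]

    def test_bins_partition_and_respect_site_and_taxon(self):
        rng = np.random.default_rng(2)
        rows = [(f"s{i}", f"cave-{rng.integers(3)}", rng.choice(["A", "B"]),
                 float(rng.integers(500, 5000)), 20.0) for i in range(30)]
        recs = make_records(rows)
        bs = make_bins(recs, h=150)
        members = sorted(sid for b in bs.bins for sid in b)
        assert members == sorted(r.specimen_id for r in recs)
        by_id = {r.specimen_id: r for r in recs}
        for b, label, site in zip(bs.bins, bs.labels, bs.sites):
            assert {by_id[s].taxon for s in b} == {label}
            assert {by_id[s].site_id for s in b} == {site}

    def test_bin_count_order_invariant(self):
        rows = [(f"s{i}", "cave-1", "T", age, 20.0)
                for i, age in enumerate([900, 1000, 1050, 1900, 2000])]
        recs = make_records(rows)
        n = make_bins(recs, h=100).n_bins
        shuffled = list(recs)
        random.Random(3).shuffle(shuffled)
        assert make_bins(shuffled, h=100).n_bins == n


class TestFadLad:
    def test_singleton(self, identity_curve):
        recs = make_records([("a", "s", "T", 4000, 25)], identity_curve)
        occ = fad_lad(recs, "T")
        assert occ.fad == occ.lad == recs[0].density.median

    def test_extremes_are_member_medians(self, wiggly_curve):
        rng = np.random.default_rng(8)
        rows = [(f"s{i}", "s", "T", float(rng.uniform(1000, 9000)), 25.0)
                for i in range(10)]
        recs = make_records(rows, wiggly_curve)
        occ = fad_lad(recs, "T")
        medians = [r.density.median for r in recs]
        assert occ.fad == max(medians) and occ.lad == min(medians)
        assert occ.fad >= occ.lad

    def test_undefined_when_nothing_calibrates(self, identity_curve):
        recs = make_records([("m", "s", "T", -500, 30)], identity_curve)
        occ = fad_lad(recs, "T")
        assert not occ.defined and occ.fad is None
        assert occ.n_modern == 1

    def test_modern_beyond_counted_but_excluded(self, identity_curve):
        recs = make_records([("a", "s", "T", 4000, 25), ("m", "s", "T", -500, 30),
                             ("o", "s", "T", 60000, 400)], identity_curve)
        occ = fad_lad(recs, "T")
        assert occ.n_calibrated == 1 and occ.n_modern == 1 and occ.n_beyond == 1
        assert occ.fad == occ.lad


class TestFractionAfter:
    def test_strict_inequality_at_threshold(self, identity_curve):
        recs = make_records([("a", "s", "T", 3400, 25), ("b", "s", "T", 1000, 25)],
                            identity_curve)
        frac, k, n = fraction_after(recs, "T", threshold=recs[0].density.median)
        assert (k, n) == (1, 2)

    def test_threshold_older_than_all_gives_one(self, identity_curve):
        recs = make_records([("a", "s", "T", 3000, 25), ("b", "s", "T", 1000, 25)],
                            identity_curve)
        frac, k, n = fraction_after(recs, "T", threshold=9000)
        assert frac == 1.0

    def test_modern_excluded_from_denominator(self, identity_curve):
        recs = make_records([("a", "s", "T", 1000, 25), ("m", "s", "T", -500, 30)],
                            identity_curve)
        frac, k, n = fraction_after(recs, "T", threshold=3400)
        assert (k, n) == (1, 1)

    def test_no_calibrated_records_is_error(self, identity_curve):
        recs = make_records([("m", "s", "T", -500, 30)], identity_curve)
        with pytest.raises(ValueError):
            fraction_after(recs, "T", 3400)


class TestCaveComposition:
    def test_equal_split_and_degenerate(self):
        recs = make_records([
            ("a", "c1", "Hyaena hyaena", 1000, 20),
            ("b", "c1", "Hyaena hyaena", 2000, 20),
            ("c", "c1", "Panthera pardus", 3000, 20),
            ("d", "c1", "Panthera pardus", 4000, 20),
            ("e", "c2", "Vulpes rueppellii", 500, 20),
        ])
        df = cave_composition(recs).set_index("site_id")
        assert df.loc["c1", ["leopard", "hyena", "fox"]].tolist() == [0.5, 0.5, 0.0]
        assert df.loc["c2", ["leopard", "hyena", "fox"]].tolist() == [0.0, 0.0, 1.0]

    def test_proportions_sum_to_one(self):
        rng = np.random.default_rng(4)
        taxa = ["Hyaena hyaena", "Panthera pardus", "Vulpes cana", "Vulpes rueppellii"]
        recs = make_records([(f"s{i}", f"c{rng.integers(4)}",
                              taxa[rng.integers(4)], 1000.0, 20.0)
                             for i in range(40)])
        df = cave_composition(recs)
        assert np.allclose(df[["leopard", "hyena", "fox"]].sum(axis=1), 1.0)
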