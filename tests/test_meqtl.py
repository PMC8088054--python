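"""Cis pairing, nominal meQTL scan, and empirical overlap tests."""

import itertools

import numpy as np
import pandas as pd
import pytest

import ewaskit as ek
from ewaskit.intervals import IntervalCollection
from ewaskit.meqtl import CisWindowSpec

from conftest import cis_pairs_oracle, overlap_test_enumeration


def _snp_manifest(rows):
    return pd.DataFrame(rows, columns=["snp_id", "chrom", "pos"])


def _cpg_manifest(rows):
    return pd.DataFrame(rows, columns=["probe_id", "chrom", "pos"])


class TestCisPairs:
    def test_window_boundary_inclusive(self):
        snps = _snp_manifest([("rs1", "chr1", 1_000_000)])
        cpgs = _cpg_manifest([("cgA", "chr1", 2_000_000), ("cgB", "chr1", 2_000_001)])
        pairs = ek.cis_pairs(snps, cpgs, CisWindowSpec(1_000_000))
        assert list(pairs["cpg_id"]) == ["cgA"]
        assert pairs["distance"].iloc[0] == 1_000_000

    def test_chromosome_required(self):
        snps = _snp_manifest([("rs1", "chr1", 500)])
        cpgs = _cpg_manifest([("cgA", "chr2", 600)])
        assert len(ek.cis_pairs(snps, cpgs)) == 0

    def test_matches_all_pairs_brute_force(self):
        rng = np.random.default_rng(3)
        snps = _snp_manifest(
            [(f"rs{i}", f"chr{rng.integers(1, 3)}", int(rng.integers(1, 5_000_000))) for i in range(3)]
        )
        cpgs = _cpg_manifest(
            [(f"cg{i}", f"chr{rng.integers(1, 3)}", int(rng.integers(1, 5_000_000))) for i in range(4)]
        )
        window = 1_500_000
        got = sorted(map(tuple, ek.cis_pairs(snps, cpgs, CisWindowSpec(window)).to_numpy()))
        assert got == cis_pairs_oracle(snps, cpgs, window)


class TestMeqtlScan:
    def _setup(self, seed, n=500, effect=0.5):
        snps = _snp_manifest([("rs1", "chr1", 100_000), ("rs2", "chr1", 400_000)])
        cpgs = _cpg_manifest([("cgA", "chr1", 150_000), ("cgB", "chr1", 350_000)])
        pairs = ek.cis_pairs(snps, cpgs)
        g = ek.generate_genotypes(n, snps, planted_meqtls=(("rs1", "cgA", effect),), seed=seed)
        rng = np.random.default_rng(seed + 1000)
        m = pd.DataFrame(rng.normal(0, 1, (n, 2)), columns=["cgA", "cgB"])
        m = ek.add_meqtl_effects(m, g)
        cov = rng.normal(0, 1, (n, 2))
        return pairs, g, m, cov

    def test_planted_effect_recovered_on_average(self):
        ests = []
        for seed in range(20):
            pairs, g, m, cov = self._setup(seed)
            rec = ek.meqtl_scan(m, g, cov, pairs)
            ests.append(rec.set_index(["snp_id", "cpg_id"]).loc[("rs1", "cgA"), "effect"])
        assert np.mean(ests) == pytest.approx(0.5, abs=0.1)

    def test_null_pair_type_i_error(self):
        ps = []
        for seed in range(40):
            pairs, g, m, cov = self._setup(seed, n=200)
            rec = ek.meqtl_scan(m, g, cov, pairs).set_index(["snp_id", "cpg_id"])
            ps.append(rec.loc[("rs2", "cgB"), "p"])
        assert 0.0 <= np.mean(np.array(ps) < 0.05) <= 0.15

    def test_monomorphic_snp_skipped(self):
        pairs, g, m, cov = self._setup(0, n=50)
        g.dosages["rs2"] = 1.0
        rec = ek.meqtl_scan(m, g, cov, pairs)
        assert "rs2" not in set(rec["snp_id"])
        assert "rs1" in set(rec["snp_id"])


class TestClassification:
    def _records(self, rows):
        return pd.DataFrame(rows, columns=["snp_id", "cpg_id", "distance", "effect", "se", "p", "n"])

    def test_threshold_rules(self):
        rec = self._records(
            [
                ("s1", "c_assoc", 0, 1, 1, 0.04, 10),
                ("s1", "c_non", 0, 1, 1, 0.96, 10),
                ("s1", "c_gap", 0, 1, 1, 0.50, 10),
                ("s2", "c_mixed", 0, 1, 1, 0.96, 10),
                ("s3", "c_mixed", 0, 1, 1, 0.30, 10),
            ]
        )
        assoc, non = ek.classify_meqtl_cpgs(rec)
        assert assoc == {"c_assoc"}
        assert non == {"c_non"}
        assert not assoc & non


TOY_RECORDS = pd.DataFrame(
    {
        "snp_id": ["s1", "s1", "s2", "s3", "s4", "s5", "s6"],
        "cpg_id": ["c1", "c2", "c2", "c3", "c4", "c1", "c4"],
        "distance": 0,
        "effect": 1.0,
        "se": 1.0,
        "p": [0.01, 0.02, 0.01, 0.04, 0.01, 0.3, 0.02],
        "n": 10,
    }
)


class TestOverlapTests:
    def test_disjoint_dmp_set_gives_p_one(self):
        res = ek.snp_meqtl_dmp_overlap_test(
            ["s1", "s2"], TOY_RECORDS, {"never"}, ["s1", "s2", "s3", "s4"], n_sims=200, seed=0
        )
        assert res.observed == 0 and res.empirical_p == 1.0

    def test_maximal_signal_hits_floor(self):
        # query SNP targets all inside the DMP set, backgrounds have none
        records = pd.DataFrame(
            {
                "snp_id": ["q1", "q2"],
                "cpg_id": ["c1", "c2"],
                "distance": 0,
                "effect": 1.0,
                "se": 1.0,
                "p": 0.001,
                "n": 10,
            }
        )
        res = ek.snp_meqtl_dmp_overlap_test(
            ["q1", "q2"], records, {"c1", "c2"}, [f"b{i}" for i in range(30)], n_sims=999, seed=1
        )
        assert res.empirical_p == pytest.approx(1 / 1000)

    def test_matches_exhaustive_enumeration(self):
        pool = ["s1", "s2", "s3", "s4", "s5", "s6"]
        query = ["s1", "s4"]
        dmps = {"c1", "c4"}
        targets = {
            s: sub.loc[sub["p"] < 0.05, "cpg_id"].unique()
            for s, sub in TOY_RECORDS.groupby("snp_id")
        }
        observed, exact = overlap_test_enumeration(query, targets, dmps, pool, len(query))
        res = ek.snp_meqtl_dmp_overlap_test(query, TOY_RECORDS, dmps, pool, n_sims=40_000, seed=3)
        assert res.observed == observed
        assert res.empirical_p == pytest.approx(exact, abs=0.01)

    def test_statistic_monotone_in_dmp_set(self):
        pool = ["s1", "s2", "s3", "s4", "s5", "s6"]
        base = ek.snp_meqtl_dmp_overlap_test(["s1", "s2"], TOY_RECORDS, {"c1"}, pool, n_sims=50, seed=0)
        wider = ek.snp_meqtl_dmp_overlap_test(["s1", "s2"], TOY_RECORDS, {"c1", "c2"}, pool, n_sims=50, seed=0)
        assert wider.observed >= base.observed

    def test_pool_smaller_than_query_rejected(self):
        with pytest.raises(ValueError, match="pool"):
            ek.snp_meqtl_dmp_overlap_test(["s1", "s2"], TOY_RECORDS, set(), ["s1"], n_sims=10, seed=0)

    def test_hotspot_variant_enumeration(self):
        cpgs = pd.DataFrame(
            {
                "probe_id": ["c1", "c2", "c3", "c4"],
                "chrom": "chr1",
                "pos": [100, 200, 300, 400],
            }
        )
        iv = IntervalCollection(
            {"kidney": pd.DataFrame({"chrom": ["chr1", "chr1"], "start": [90, 390], "end": [110, 410]})}
        )
        keep = {"c1", "c4"}  # positions 100 and 400 covered
        pool = ["s1", "s2", "s3", "s4", "s5", "s6"]
        query = ["s1", "s6"]
        targets = {
            s: sub.loc[sub["p"] < 0.05, "cpg_id"].unique()
            for s, sub in TOY_RECORDS.groupby("snp_id")
        }
        observed, exact = overlap_test_enumeration(query, targets, keep, pool, len(query))
        res = ek.meqtl_hotspot_overlap_test(
            query, TOY_RECORDS, iv, "kidney", cpgs, pool, n_sims=40_000, seed=5
        )
        assert res.observed == observed
        assert res.empirical_p == pytest.approx(exact, abs=0.01)

    def test_no_intervals_for_tissue(self):
        cpgs = pd.DataFrame({"probe_id": ["c1"], "chrom": "chr1", "pos": [100]})
        iv = IntervalCollection({"kidney": pd.DataFrame(columns=["chrom", "start", "end"])})
        res = ek.meqtl_hotspot_overlap_test(
            ["s1"], TOY_RECORDS, iv, "kidney", cpgs, ["s1", "s2", "s3"], n_sims=100, seed=2
        )
        assert res.observed == 0 and res.empirical_p == 1.0


class TestBloodKidneyOverlap:
    def test_reference_cases(self):
        assert ek.blood_kidney_overlap_fraction({"a", "b"}, {"a", "b", "c"}) == 100.0
        assert ek.blood_kidney_overlap_fraction({"a"}, {"b"}) == 0.0
        kidney = {f"k{i}" for i in range(12)}
        blood = {f"k{i}" for i in range(7)} | {"x", "y"}
        assert ek.blood_kidney_overlap_fraction(kidney, blood) == 58.3

    def test_empty_kidney_set(self):
        with pytest.raises(ValueError):
            ek.blood_kidney_overlap_fraction(set(), {"a"})
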