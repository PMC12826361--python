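import numpy as np
import pandas as pd
import pytest

from tadmeqtl.core import GenomicInterval, PromoterRecord, TADRecord
from tadmeqtl.enrichment import (annotate_drivers, driver_tables,
                                 matched_randomization)
from tadmeqtl.partition import define_boundaries, partition_genome
from tadmeqtl.simulate import SimConfig, simulate_dataset, true_tad_copy

from oracles import brute_annotate_count


def _meqtls(probe_pos, chrom="chr1"):
    n = len(probe_pos)
    return pd.DataFrame({
        "snp_id": [f"rs{i}" for i in range(n)], "chrom": chrom,
        "pos": np.asarray(probe_pos) + 7, "ref": "A", "alt": "G",
        "pvalue": 1e-6, "maf": 0.2,
        "probe_id": [f"cg{i}" for i in range(n)], "probe_chrom": chrom,
        "probe_pos": probe_pos, "cancer_type": "BRCA"})


PROMS = [PromoterRecord(GenomicInterval("chr1", 1000, 2000), "TSG1"),
         PromoterRecord(GenomicInterval("chr1", 1500, 2500), "ONC1"),
         PromoterRecord(GenomicInterval("chr1", 9000, 9500), "NONE1")]
ROLES = {"TSG1": "TSG", "ONC1": "oncogene"}


class TestAnnotateDrivers:
    def test_probe_inside_promoter_flagged(self):
        out = annotate_drivers(_meqtls([1200]), PROMS, ROLES)
        assert out["driver_role"].tolist() == ["TSG"]
        assert out["driver_gene"].tolist() == ["TSG1"]

    def test_half_open_end_excluded(self):
        out = annotate_drivers(_meqtls([2500]), PROMS, ROLES)
        assert out["driver_role"].tolist() == ["none"]

    def test_roleless_gene_not_flagged(self):
        out = annotate_drivers(_meqtls([9200]), PROMS, ROLES)
        assert out["driver_role"].tolist() == ["none"]

    def test_dual_role_probe_duplicated(self):
        out = annotate_drivers(_meqtls([1700]), PROMS, ROLES)
        assert sorted(out["driver_role"]) == ["TSG", "oncogene"]
        assert len(out) == 2

    def test_flag_count_matches_brute_force(self, small_sim):
        out = annotate_drivers(small_sim.meqtls, small_sim.promoters,
                               small_sim.gene_roles)
        got = int((out["driver_role"] != "none").sum())
        expected = brute_annotate_count(small_sim.meqtls, small_sim.promoters,
                                        small_sim.gene_roles)
        assert got == expected
        # every planted driver is recovered
        planted = set.union(*(set(v) for v in
                              small_sim.truth["driver_snp_ids"].values()))
        flagged = set(out.loc[out["driver_role"] != "none", "snp_id"])
        assert planted <= flagged


class TestDriverTables:
    def test_split_by_role_and_pool(self, small_sim):
        ann = annotate_drivers(small_sim.meqtls, small_sim.promoters,
                               small_sim.gene_roles)
        clumped = small_sim.meqtls.drop_duplicates("snp_id")[
            ["snp_id", "chrom", "pos", "maf"]].copy()
        clumped["is_index"] = True
        drivers, pool = driver_tables(ann, clumped)
        truth = small_sim.truth["driver_snp_ids"]
        for role in ("oncogene", "TSG"):
            assert set(truth[role]) <= set(drivers[role]["snp_id"])
        assert set(pool["snp_id"]).isdisjoint(
            set(drivers["oncogene"]["snp_id"])
            | set(drivers["TSG"]["snp_id"]))


def _snp_frame(pos, maf, chrom="chr1"):
    return pd.DataFrame({
        "snp_id": [f"s{i}" for i in range(len(pos))], "chrom": chrom,
        "pos": pos, "maf": maf})


def _toy_partition():
    tads = [TADRecord(GenomicInterval("chr1", 1_000_000, 3_000_000),
                      category5="Active-1"),
            TADRecord(GenomicInterval("chr1", 4_000_000, 6_000_000),
                      category5="Inactive-1")]
    sizes = {"chr1": 8_000_000}
    return partition_genome(tads, define_boundaries(tads, sizes), sizes)


class TestMatchedRandomization:
    def test_identity_pool_equals_observed(self):
        part = _toy_partition()
        drv = _snp_frame([1_500_000, 2_000_000, 5_000_000], [0.1, 0.2, 0.3])
        pool = drv.copy()
        pool["snp_id"] = ["p0", "p1", "p2"]
        res = matched_randomization(drv, pool, part, n_trials=1,
                                    identity=True)
        for r in res.values():
            assert r.expected_mean == pytest.approx(r.observed_per_mb)

    def test_empirical_p_never_zero(self):
        part = _toy_partition()
        rng = np.random.default_rng(0)
        drv = _snp_frame([1_500_000] * 20, rng.uniform(0.1, 0.4, 20))
        pool = _snp_frame(rng.integers(0, 8_000_000, 500).tolist(),
                          rng.uniform(0.1, 0.4, 500))
        pool["snp_id"] = [f"p{i}" for i in range(500)]
        res = matched_randomization(drv, pool, part, n_trials=100, seed=1)
        for r in res.values():
            assert r.p_enrich >= 1 / 101 and r.p_deplete >= 1 / 101
            assert r.p_two <= 1.0
            assert r.expected_se == pytest.approx(
                r.expected_sd / np.sqrt(100))

    def test_unmatchable_driver_named(self):
        part = _toy_partition()
        drv = _snp_frame([1_500_000], [0.45])
        pool = _snp_frame([2_000_000], [0.05])
        with pytest.raises(ValueError, match="s0"):
            matched_randomization(drv, pool, part, maf_tol=0.05)

    def test_empty_pool_rejected(self):
        part = _toy_partition()
        drv = _snp_frame([1_500_000], [0.2])
        with pytest.raises(ValueError, match="pool"):
            matched_randomization(drv, pool=_snp_frame([], []),
                                  partition=part)

    def test_seed_reproducible(self):
        part = _toy_partition()
        rng = np.random.default_rng(5)
        drv = _snp_frame(rng.integers(0, 8_000_000, 30).tolist(),
                         rng.uniform(0.1, 0.4, 30))
        pool = _snp_frame(rng.integers(0, 8_000_000, 400).tolist(),
                          rng.uniform(0.1, 0.4, 400))
        pool["snp_id"] = [f"p{i}" for i in range(400)]
        r1 = matched_randomization(drv, pool, part, n_trials=50, seed=9)
        r2 = matched_randomization(drv, pool, part, n_trials=50, seed=9)
        for lab in r1:
            assert r1[lab].expected_mean == r2[lab].expected_mean
            assert r1[lab].p_two == r2[lab].p_two

    def test_planted_active_enrichment_detected(self):
        cfg = SimConfig(
            n_chroms=2, n_tads=30, chrom_length=36_000_000, n_meqtls=5000,
            n_epigenomes=0, n_samples=0, boundary_gradient=1.0, n_genes=200,
            n_driver_meqtls={"oncogene": 0, "TSG": 100},
            driver_enrichment={
                "oncogene": {},
                "TSG": {"Active": 3.0, "Inactive": 1.0, "Mixed": 1.0,
                        "Boundary": 1.0}},
            seed=77)
        sim = simulate_dataset(cfg)
        tads = true_tad_copy(sim)
        part = partition_genome(
            tads, define_boundaries(tads, sim.chrom_sizes), sim.chrom_sizes)
        snps = sim.meqtls.drop_duplicates("snp_id")[
            ["snp_id", "chrom", "pos", "maf"]].reset_index(drop=True)
        drv_ids = set(sim.truth["driver_snp_ids"]["TSG"])
        drv = snps[snps["snp_id"].isin(drv_ids)].reset_index(drop=True)
        pool = snps[~snps["snp_id"].isin(drv_ids)].reset_index(drop=True)
        res = matched_randomization(drv, pool, part, n_trials=1000, seed=1)
        assert res["ActiveTAD"].p_enrich <= 0.01
        assert res["ActiveTAD"].z > 2
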