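import numpy as np
import pandas as pd
import pytest
from scipy import stats

from tadmeqtl.core import GenomicInterval, PromoterRecord, TADRecord
from tadmeqtl.partition import (burden_by_label, define_boundaries,
                                partition_genome, per_tad_burden_test,
                                promoter_methylation_by_category,
                                unique_snps)
from tadmeqtl.simulate import (SimConfig, simulate_dataset,
                               simulate_promoter_betas, true_tad_copy)

from oracles import brute_kruskal_h, brute_point_label, brute_welch_t


def tad(chrom, start, end, cat):
    return TADRecord(GenomicInterval(chrom, start, end),
                     category5=cat if cat == "Mixed" else f"{cat}-1")


SIZES = {"chr1": 10_000_000}


class TestDefineBoundaries:
    def test_wide_gap_two_pieces(self):
        tads = [tad("chr1", 1_000_000, 2_000_000, "Active"),
                tad("chr1", 2_150_000, 3_000_000, "Inactive")]
        bounds = define_boundaries(tads, SIZES)
        inner = [(b.interval.start, b.interval.end, b.transition)
                 for b in bounds if b.transition == "AI"]
        assert inner == [(1_950_000, 2_050_000, "AI"),
                         (2_100_000, 2_200_000, "AI")]

    def test_narrow_gap_proximal_half_merged(self):
        tads = [tad("chr1", 1_000_000, 2_000_000, "Active"),
                tad("chr1", 2_060_000, 3_000_000, "Inactive")]
        bounds = define_boundaries(tads, SIZES)
        inner = [(b.interval.start, b.interval.end)
                 for b in bounds if b.transition == "AI"]
        # 60 kb gap: each side keeps inward 50 kb + proximal 30 kb of the
        # gap; the two abutting pieces merge into one 160 kb region
        assert inner == [(1_950_000, 2_110_000)]

    def test_chromosome_edge_clipped(self):
        tads = [tad("chr1", 10_000, 500_000, "Active"),
                tad("chr1", 700_000, 9_990_000, "Inactive")]
        bounds = define_boundaries(tads, SIZES)
        edges = sorted((b.interval.start, b.interval.end)
                       for b in bounds if b.transition == "chrom-edge")
        assert edges[0] == (0, 60_000)
        assert edges[-1] == (9_940_000, 10_000_000)

    def test_mixed_adjacent_tagged(self):
        tads = [tad("chr1", 1_000_000, 2_000_000, "Active"),
                tad("chr1", 2_500_000, 3_500_000, "Mixed")]
        tags = {b.transition for b in define_boundaries(tads, SIZES)}
        assert "mixed-adjacent" in tags and "AI" not in tags

    def test_half_width_zero_gives_none(self):
        tads = [tad("chr1", 1_000_000, 2_000_000, "Active"),
                tad("chr1", 2_500_000, 3_500_000, "Inactive")]
        assert define_boundaries(tads, SIZES, half_width=0) == []


class TestPartition:
    def _partition(self):
        tads = [tad("chr1", 1_000_000, 2_000_000, "Active"),
                tad("chr1", 2_150_000, 3_000_000, "Inactive"),
                tad("chr1", 3_400_000, 4_000_000, "Mixed")]
        bounds = define_boundaries(tads, SIZES)
        return tads, bounds, partition_genome(tads, bounds, SIZES)

    def test_boundary_precedence_inside_tad(self):
        _, _, part = self._partition()
        # 1.96 Mb lies inside the Active TAD but within 50 kb of its end
        lab = part.label_positions(np.array(["chr1"]), np.array([1_960_000]))
        assert lab[0] == "Boundary"
        lab = part.label_positions(np.array(["chr1"]), np.array([1_500_000]))
        assert lab[0] == "ActiveTAD"

    def test_tiling_exact(self):
        _, _, part = self._partition()
        assert sum(part.label_bp.values()) == SIZES["chr1"]

    def test_labels_match_brute_scan(self, rng):
        tads, bounds, part = self._partition()
        pos = rng.integers(0, SIZES["chr1"], 1000)
        got = part.label_positions(np.array(["chr1"] * 1000), pos)
        for p, g in zip(pos, got):
            assert g == brute_point_label(int(p), "chr1", tads, bounds)

    def test_overlapping_tads_rejected(self):
        tads = [tad("chr1", 0, 2_000_000, "Active"),
                tad("chr1", 1_000_000, 3_000_000, "Inactive")]
        with pytest.raises(ValueError):
            partition_genome(tads, [], SIZES)


def _meqtls(chroms, pos, snp_ids=None):
    n = len(pos)
    return pd.DataFrame({
        "snp_id": snp_ids or [f"rs{i}" for i in range(n)],
        "chrom": chroms, "pos": pos, "ref": "A", "alt": "G",
        "pvalue": 1e-6, "maf": 0.2,
        "probe_id": [f"cg{i}" for i in range(n)],
        "probe_chrom": chroms, "probe_pos": pos, "cancer_type": "BRCA"})


class TestBurden:
    def test_empty_table_all_zero(self):
        tads = [tad("chr1", 1_000_000, 2_000_000, "Active"),
                tad("chr1", 2_500_000, 3_500_000, "Inactive")]
        part = partition_genome(tads, define_boundaries(tads, SIZES), SIZES)
        burden = burden_by_label(_meqtls([], np.array([], dtype=int)), part)
        assert (burden["count"] == 0).all()
        assert (burden["density"] == 0).all()

    def test_counts_sum_to_unique_snps(self, small_sim):
        tads = true_tad_copy(small_sim)
        part = partition_genome(
            tads, define_boundaries(tads, small_sim.chrom_sizes),
            small_sim.chrom_sizes)
        burden = burden_by_label(small_sim.meqtls, part)
        assert burden["count"].sum() == small_sim.meqtls["snp_id"].nunique()

    def test_snp_with_many_probes_counts_once(self):
        tads = [tad("chr1", 1_000_000, 2_000_000, "Active"),
                tad("chr1", 2_500_000, 3_500_000, "Inactive")]
        part = partition_genome(tads, define_boundaries(tads, SIZES), SIZES)
        df = _meqtls(["chr1"] * 3, [1_500_000] * 3,
                     snp_ids=["rs1", "rs1", "rs1"])
        df["probe_id"] = ["cgA", "cgB", "cgC"]
        assert burden_by_label(df, part)["count"].sum() == 1


class TestPerTadBurden:
    def test_matches_welch_oracle_on_toy(self):
        tads = [tad("chr1", i * 1_000_000, i * 1_000_000 + 500_000,
                    "Active" if i < 3 else "Inactive") for i in range(6)]
        pos, chroms = [], []
        counts = [5, 9, 2, 11, 14, 3]
        for t, c in zip(tads, counts):
            for j in range(c):
                chroms.append("chr1")
                pos.append(t.start + 1000 * (j + 1))
        per_tad, t_stat, p = per_tad_burden_test(_meqtls(chroms, pos), tads)
        dens = np.array(counts) / 500_000
        expected = brute_welch_t(dens[:3], dens[3:])
        assert t_stat == pytest.approx(expected, abs=1e-12)
        assert list(per_tad["count"]) == counts

    def test_requires_two_per_group(self):
        tads = [tad("chr1", 0, 500_000, "Active"),
                tad("chr1", 1_000_000, 1_500_000, "Inactive"),
                tad("chr1", 2_000_000, 2_500_000, "Inactive")]
        with pytest.raises(ValueError):
            per_tad_burden_test(_meqtls(["chr1"], [100]), tads)

    def test_power_on_planted_inactive_excess(self):
        """1.5x inactive density is detected in most seeds."""
        hits = 0
        n_seeds = 30
        for seed in range(n_seeds):
            cfg = SimConfig(n_chroms=2, n_tads=60, chrom_length=70_000_000,
                            n_meqtls=12_000, n_epigenomes=0, n_samples=0,
                            n_driver_meqtls={"oncogene": 0, "TSG": 0},
                            tad_density={"Active": 1.0, "Inactive": 1.5,
                                         "Mixed": 1.0},
                            boundary_gradient=1.0, seed=seed)
            sim = simulate_dataset(cfg)
            _, _, p = per_tad_burden_test(sim.meqtls, true_tad_copy(sim))
            hits += p < 0.05
        assert hits / n_seeds >= 0.9

    def test_type_one_error_calibrated(self):
        """Equal planted densities reject at about the nominal 5% rate."""
        rej = 0
        n_seeds = 200
        for seed in range(n_seeds):
            cfg = SimConfig(n_chroms=1, n_tads=40, chrom_length=48_000_000,
                            n_meqtls=4_000, n_epigenomes=0, n_samples=0,
                            n_driver_meqtls={"oncogene": 0, "TSG": 0},
                            boundary_gradient=1.0, seed=10_000 + seed)
            sim = simulate_dataset(cfg)
            try:
                _, _, p = per_tad_burden_test(sim.meqtls, true_tad_copy(sim))
            except ValueError:      # a group with <2 TADs cannot be tested
                n_seeds -= 1
                continue
            rej += p < 0.05
        assert 0.03 <= rej / n_seeds <= 0.08


class TestPromoterMethylation:
    def _setup(self):
        tads = [tad("chr1", 0, 2_000_000, "Active"),
                tad("chr1", 3_000_000, 5_000_000, "Inactive"),
                tad("chr1", 6_000_000, 8_000_000, "Mixed")]
        proms = [PromoterRecord(GenomicInterval("chr1", s, s + 1000), f"G{s}")
                 for s in (100_000, 500_000, 900_000, 1_300_000,
                           3_100_000, 3_500_000, 3_900_000, 4_300_000,
                           6_100_000, 6_500_000, 6_900_000, 9_500_000)]
        return tads, proms

    def test_identical_betas_h_zero(self):
        tads, proms = self._setup()
        betas = np.full(len(proms), 0.5)
        _, h, p, n_drop = promoter_methylation_by_category(betas, proms, tads)
        assert h == 0.0
        assert n_drop == 1       # the promoter at 9.5 Mb is outside all TADs

    def test_h_matches_rank_oracle(self):
        tads, proms = self._setup()
        betas = np.array([.11, .23, .32, .18, .71, .64, .55, .80,
                          .41, .47, .52, .99])
        summary, h, p, _ = promoter_methylation_by_category(betas, proms, tads)
        groups = [betas[:4], betas[4:8], betas[8:11]]   # Act, Inact, Mixed
        expected = brute_kruskal_h([betas[:4], betas[8:11], betas[4:8]])
        assert h == pytest.approx(expected, abs=1e-10)

    def test_planted_shift_detected(self, small_sim):
        tads = true_tad_copy(small_sim)
        cats = []
        for p in small_sim.promoters:
            cat = None
            for t in tads:
                if t.chrom == p.interval.chrom and \
                        t.start <= p.interval.midpoint < t.end:
                    cat = t.category3
                    break
            cats.append(cat)
        betas = simulate_promoter_betas(small_sim.config, cats, seed=99)
        assert betas.min() >= 0 and betas.max() <= 1
        summary, h, p, _ = promoter_methylation_by_category(
            betas, small_sim.promoters, tads)
        assert p < 0.001
        m = dict(zip(summary["category3"], summary["mean_beta"]))
        assert m["Active"] < m["Inactive"]
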