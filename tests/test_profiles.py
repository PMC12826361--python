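import numpy as np
import pandas as pd
import pytest

from tadmeqtl.core import GenomicInterval, TADRecord
from tadmeqtl.profiles import (attach_null, bin_region, consecutive_gaps,
                               gap_density_matrix, half_deltas, profile,
                               shuffle_null, smooth, transition_of)
from tadmeqtl.profiles import test_vs_null as profile_test_vs_null
from tadmeqtl.simulate import SimConfig, simulate_dataset, true_tad_copy


def tad(chrom, start, end, cat):
    return TADRecord(GenomicInterval(chrom, start, end),
                     category5=cat if cat == "Mixed" else f"{cat}-1")


class TestBinRegion:
    def test_even_split(self):
        edges = bin_region(GenomicInterval("chr1", 0, 400_000), 40)
        assert len(edges) == 41
        assert np.all(np.diff(edges) == 10_000)

    def test_remainder_spread_left(self):
        edges = bin_region(GenomicInterval("chr1", 0, 4001), 40)
        widths = np.diff(edges)
        assert widths[0] == 101 and np.all(widths[1:] == 100)
        assert widths.sum() == 4001

    def test_too_short_errors(self):
        with pytest.raises(ValueError):
            bin_region(GenomicInterval("chr1", 0, 39), 40)

    def test_bins_tile_random_gaps(self, rng):
        for _ in range(200):
            start = int(rng.integers(0, 1_000_000))
            length = int(rng.integers(40, 500_000))
            gap = GenomicInterval("chr1", start, start + length)
            edges = bin_region(gap, 40)
            widths = np.diff(edges)
            assert edges[0] == gap.start and edges[-1] == gap.end
            assert widths.min() >= 1 and widths.max() - widths.min() <= 1


class TestSmooth:
    def test_window_one_identity(self, rng):
        d = rng.random(40)
        np.testing.assert_array_equal(smooth(d, 1), d)

    def test_constant_unchanged(self):
        d = np.full(40, 3.3)
        np.testing.assert_allclose(smooth(d, 5), d)

    def test_matches_naive_convolution(self, rng):
        d = rng.random(40)
        got = smooth(d, 5)
        for i in range(40):
            lo, hi = max(0, i - 2), min(40, i + 3)
            assert got[i] == pytest.approx(np.mean(d[lo:hi]))

    def test_even_window_rejected(self):
        with pytest.raises(ValueError):
            smooth(np.zeros(40), 4)


def _uniform_meqtls(rng, n, chrom="chr1", lo=0, hi=10_000_000):
    pos = rng.integers(lo, hi, n)
    return pd.DataFrame({
        "snp_id": [f"rs{i}" for i in range(n)], "chrom": chrom, "pos": pos,
        "ref": "A", "alt": "G", "pvalue": 1e-6, "maf": 0.2,
        "probe_id": [f"cg{i}" for i in range(n)], "probe_chrom": chrom,
        "probe_pos": pos, "cancer_type": "BRCA"})


class TestProfile:
    def test_meqtls_outside_gaps_give_zero(self, rng):
        tads = [tad("chr1", 0, 1_000_000, "Active"),
                tad("chr1", 1_400_000, 2_400_000, "Inactive")]
        mq = _uniform_meqtls(rng, 100, lo=0, hi=900_000)  # inside TAD 1 only
        profs = profile(mq, tads)
        assert np.all(profs["AI"].densities == 0)

    def test_count_conservation(self, small_sim):
        tads = true_tad_copy(small_sim)
        ts, gaps = consecutive_gaps(tads)
        dens, counts = gap_density_matrix(small_sim.meqtls, gaps)
        snps = small_sim.meqtls.drop_duplicates("snp_id")
        in_gaps = 0
        for g in gaps:
            iv = g.interval
            sel = (snps["chrom"] == iv.chrom) & (snps["pos"] >= iv.start) \
                & (snps["pos"] < iv.end)
            in_gaps += int(sel.sum())
        assert counts.sum() == in_gaps

    def test_mixed_flanked_spans_excluded(self, rng):
        tads = [tad("chr1", 0, 1_000_000, "Active"),
                tad("chr1", 1_400_000, 2_400_000, "Mixed"),
                tad("chr1", 2_800_000, 3_800_000, "Inactive")]
        profs = profile(_uniform_meqtls(rng, 500, hi=3_800_000), tads)
        assert set(profs) == set()

    def test_uniform_placement_near_flat(self):
        cfg = SimConfig(n_chroms=2, n_tads=40, chrom_length=48_000_000,
                        n_meqtls=1_000_000, boundary_gradient=1.0,
                        n_epigenomes=0, n_samples=0,
                        n_driver_meqtls={"oncogene": 0, "TSG": 0}, seed=5)
        sim = simulate_dataset(cfg)
        profs = profile(sim.meqtls, true_tad_copy(sim))
        pooled = np.mean([p.densities for p in profs.values()], axis=0)
        assert pooled.max() / pooled.min() < 1.2

    def test_planted_ramp_slope_signs(self):
        cfg = SimConfig(n_chroms=4, n_tads=40, chrom_length=48_000_000,
                        n_meqtls=100_000, boundary_gradient=2.0,
                        n_epigenomes=0, n_samples=0,
                        n_driver_meqtls={"oncogene": 0, "TSG": 0}, seed=6)
        sim = simulate_dataset(cfg)
        profs = profile(sim.meqtls, true_tad_copy(sim))
        x = np.arange(40)
        slope_ai = np.polyfit(x, profs["AI"].densities, 1)[0]
        slope_ia = np.polyfit(x, profs["IA"].densities, 1)[0]
        assert slope_ai > 0 and slope_ia < 0


class TestShuffleNull:
    def _sim(self, seed=7, g=1.0):
        cfg = SimConfig(n_chroms=2, n_tads=30, chrom_length=36_000_000,
                        n_meqtls=20_000, boundary_gradient=g,
                        n_epigenomes=0, n_samples=0,
                        n_driver_meqtls={"oncogene": 0, "TSG": 0}, seed=seed)
        return simulate_dataset(cfg)

    def test_identity_shuffle_null_equals_observed(self):
        sim = self._sim()
        tads = true_tad_copy(sim)
        profs = profile(sim.meqtls, tads)
        null = shuffle_null(tads, sim.meqtls, n_shuffles=5, identity=True)
        for tr, p in profs.items():
            np.testing.assert_allclose(null.null_mean[tr], p.densities)
            if p.n_boundaries >= 3:
                t, pval = profile_test_vs_null(null, tr)
                assert pval > 0.99

    def test_seed_reproducible(self):
        sim = self._sim()
        tads = true_tad_copy(sim)
        n1 = shuffle_null(tads, sim.meqtls, n_shuffles=20, seed=3)
        n2 = shuffle_null(tads, sim.meqtls, n_shuffles=20, seed=3)
        for tr in n1.null_mean:
            np.testing.assert_array_equal(n1.null_mean[tr], n2.null_mean[tr])
            np.testing.assert_array_equal(n1.null_deltas[tr],
                                          n2.null_deltas[tr])

    def test_strict_mode_preserves_transition_counts(self):
        # strict resampling only terminates quickly on small instances
        cfg = SimConfig(n_chroms=1, n_tads=10, chrom_length=12_000_000,
                        n_meqtls=2_000, n_epigenomes=0, n_samples=0,
                        n_driver_meqtls={"oncogene": 0, "TSG": 0}, seed=7)
        sim = simulate_dataset(cfg)
        tads = true_tad_copy(sim)
        strict = shuffle_null(tads, sim.meqtls, n_shuffles=10, seed=1,
                              strict=True, max_tries=20_000)
        obs = {tr: len(rows) for tr, rows in strict.observed_rows.items()}
        for tr, deltas in strict.null_deltas.items():
            assert len(deltas) == obs[tr] * 10

    def test_observed_within_null_band_under_null(self):
        sim = self._sim(seed=21)
        tads = true_tad_copy(sim)
        profs = profile(sim.meqtls, tads)
        null = shuffle_null(tads, sim.meqtls, n_shuffles=100, seed=2)
        ok = tot = 0
        for tr, p in profs.items():
            if tr not in null.null_mean:
                continue
            band = 3 * null.null_sd[tr]
            ok += int(np.sum(np.abs(p.densities - null.null_mean[tr]) <= band))
            tot += len(p.densities)
        assert ok / tot >= 0.95

    def test_attach_null_populates_profiles(self):
        sim = self._sim()
        tads = true_tad_copy(sim)
        profs = profile(sim.meqtls, tads)
        null = shuffle_null(tads, sim.meqtls, n_shuffles=40, seed=4)
        attach_null(profs, null)
        for p in profs.values():
            assert p.null_mean is not None
            if p.n_boundaries >= 3:
                assert p.pvalue is not None


def test_transition_tags():
    assert transition_of("Active", "Inactive") == "AI"
    assert transition_of("Inactive", "Inactive") == "II"
    assert transition_of("Active", "Mixed") is None
    assert transition_of(None, "Active") is None
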