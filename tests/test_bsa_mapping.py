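"""SNP-index arithmetic, window scan, null thresholds and region calling."""

import numpy as np
import pandas as pd
import pytest

from pithmap.bsa_mapping import (
    BsaConfig,
    GenomicInterval,
    SnpIndexRecord,
    attach_thresholds,
    call_candidate_regions,
    compute_snp_index,
    compute_snp_indices,
    shortlist_snps,
    simulate_null_deltas,
    simulate_thresholds,
    sliding_window_scan,
)
from pithmap.synthetic_data import DEFAULT_ROLES
from pithmap.variant_filtering import SampleCall, VariantSite


def _site(ad_alt_s, depth_s, pos=100, low_parent_gt=(0, 0), ad_alt_h=0, depth_h=10):
    parents_swap = low_parent_gt == (1, 1)
    return VariantSite(
        "1",
        pos,
        "A",
        "G",
        200.0,
        {
            "W": SampleCall((0, 0) if parents_swap else (1, 1), 10, 10 * parents_swap, 10 * (not parents_swap), 99.0),
            "K": SampleCall(low_parent_gt, 10, 10 * (not parents_swap), 10 * parents_swap, 99.0),
            "S": SampleCall((0, 1), depth_s, depth_s - ad_alt_s, ad_alt_s, 99.0),
            "H": SampleCall((0, 1), depth_h, depth_h - ad_alt_h, ad_alt_h, 99.0),
        },
    )


class TestSnpIndex:
    def test_all_high_parent_reads(self):
        assert compute_snp_index(_site(8, 8), "S", "K") == 1.0

    def test_half_high_parent_reads(self):
        assert compute_snp_index(_site(4, 8), "S", "K") == 0.5

    def test_low_parent_sample_scores_zero(self):
        # reference orientation: the low parent's own reads never count
        site = _site(0, 8)
        assert compute_snp_index(site, "K", "K") == 0.0

    def test_orientation_flips_with_low_parent_allele(self):
        # low parent homozygous ALT: the index counts REF reads instead
        site = _site(2, 8, low_parent_gt=(1, 1))
        assert compute_snp_index(site, "S", "K") == pytest.approx(6 / 8)

    def test_zero_coverage_flagged_none(self):
        assert compute_snp_index(_site(0, 0), "S", "K") is None

    def test_delta_is_s_minus_h_and_antisymmetric(self):
        sites = [_site(8, 8, pos=1, ad_alt_h=0, depth_h=8)]
        records, _ = compute_snp_indices(sites, DEFAULT_ROLES)
        assert records[0].delta_snp_index == pytest.approx(1.0)
        swapped = dict(DEFAULT_ROLES, bulk_high="H", bulk_low="S")
        rec_sw, _ = compute_snp_indices(sites, swapped)
        assert rec_sw[0].delta_snp_index == pytest.approx(-1.0)


def _records(positions, deltas, chrom="1", depth=10):
    return [
        SnpIndexRecord(chrom, int(p), float(d) if d >= 0 else 0.0,
                       0.0 if d >= 0 else float(-d), float(d), depth, depth)
        for p, d in zip(positions, deltas)
    ]


class TestSlidingWindowScan:
    CFG = BsaConfig(window_bp=5_000_000, step_bp=50_000)

    def test_constant_field_gives_constant_means(self):
        recs = _records(range(1_000_000, 60_000_001, 1_000_000), [0.3] * 60)
        win = sliding_window_scan(recs, self.CFG, {"1": 60_000_000})
        non_empty = win[win["n_snps"] > 0]
        assert np.allclose(non_empty["mean_delta"], 0.3)

    def test_single_snp_window_count(self):
        """An interior SNP falls in exactly ceil(window/step) windows."""
        recs = _records([30_000_000], [0.5])
        win = sliding_window_scan(recs, self.CFG, {"1": 100_000_000})
        covered = win[win["n_snps"] == 1]
        assert len(covered) == int(np.ceil(self.CFG.window_bp / self.CFG.step_bp))

    def test_matches_bruteforce_oracle(self, rng):
        """Scan means equal an O(n*w) per-window loop within 1e-12."""
        n = 1000
        positions = np.sort(rng.integers(1, 50_000_001, n))
        deltas = rng.uniform(-1, 1, n)
        recs = _records(positions, deltas)
        cfg = BsaConfig(window_bp=5_000_000, step_bp=250_000)
        win = sliding_window_scan(recs, cfg, {"1": 50_000_000})
        for row in win.itertuples(index=False):
            inside = [
                d
                for p, d in zip(positions, deltas)
                if row.start < p <= row.end  # 1-based pos in half-open 0-based window
            ]
            if inside:
                assert row.n_snps == len(inside)
                assert abs(row.mean_delta - np.mean(inside)) < 1e-12
            else:
                assert row.n_snps == 0

    def test_unsorted_input_sorted_internally(self):
        recs = _records([40_000_000, 10_000_000], [0.2, 0.8])
        win = sliding_window_scan(recs, self.CFG, {"1": 60_000_000})
        at_10 = win[(win["start"] <= 9_999_999) & (win["end"] > 10_000_000 - 1)]
        assert (at_10[at_10["n_snps"] == 1]["mean_delta"] == 0.8).all()


class TestSimulateThresholds:
    def test_degenerate_bulk_of_one(self):
        cfg = BsaConfig(bulk_size=1, n_null_sims=5000, seed=1)
        thr = simulate_thresholds(cfg, [10_000])
        # null delta is essentially {-1, 0, +1} with mass 1/4, 1/2, 1/4
        assert thr.iloc[0]["ci99_hi"] == pytest.approx(1.0)

    def test_high_depth_limit_matches_normal_approximation(self):
        """At depth >> bulk size the read noise vanishes: the 99% band
        approaches +/- 2.576 * sqrt(2 * 0.25 / bulk_size)."""
        cfg = BsaConfig(bulk_size=20, n_null_sims=40_000, seed=2)
        thr = simulate_thresholds(cfg, [100_000])
        expected = 2.576 * np.sqrt(2 * 0.25 / 20)
        assert thr.iloc[0]["ci99_hi"] == pytest.approx(expected, rel=0.10)

    def test_thresholds_nonincreasing_in_depth(self):
        cfg = BsaConfig(bulk_size=20, n_null_sims=30_000, seed=3)
        thr = simulate_thresholds(cfg, [2, 5, 10, 50, 500])
        hi = thr["ci99_hi"].to_numpy()
        assert all(b <= a + 0.03 for a, b in zip(hi, hi[1:]))  # MC slack

    def test_null_exceedance_self_consistency(self):
        """~1% of fresh null draws fall outside the fitted 99% band."""
        cfg = BsaConfig(bulk_size=20, n_null_sims=10_000, seed=4)
        thr = simulate_thresholds(cfg, [8])
        fresh = simulate_null_deltas(20, 8, 8, 10_000, np.random.default_rng(99))
        frac = np.mean(
            (fresh > thr.iloc[0]["ci99_hi"]) | (fresh < thr.iloc[0]["ci99_lo"])
        )
        mc_se = np.sqrt(0.01 * 0.99 / 10_000)
        assert abs(frac - 0.01) < 3 * mc_se + 0.003  # quantile discreteness slack

    def test_deterministic_under_seed(self):
        cfg = BsaConfig(seed=7, n_null_sims=2000)
        assert simulate_thresholds(cfg, [8]).equals(simulate_thresholds(cfg, [8]))


class TestRegions:
    def test_printed_interval_lengths(self):
        assert GenomicInterval("3B", 819_897_386, 826_725_912).length_mb == 6.83
        assert GenomicInterval("3B", 820_760_675, 822_192_510).length_mb == 1.43

    def test_no_window_above_threshold_gives_empty_list(self):
        recs = _records(range(1_000_000, 30_000_001, 1_000_000), [0.0] * 30)
        cfg = BsaConfig()
        win = sliding_window_scan(recs, cfg, {"1": 30_000_000})
        win = attach_thresholds(win, simulate_thresholds(cfg, [10]))
        assert call_candidate_regions(win) == []

    def test_flagged_windows_merge_and_clip_to_snp_span(self):
        positions = list(range(1_000_000, 30_000_001, 1_000_000))
        deltas = [0.95 if 10_000_000 <= p <= 20_000_000 else 0.0 for p in positions]
        cfg = BsaConfig()
        win = sliding_window_scan(_records(positions, deltas), cfg, {"1": 30_000_000})
        win = attach_thresholds(win, simulate_thresholds(cfg, [10]))
        regions = call_candidate_regions(win)
        assert len(regions) == 1
        # interval endpoints are SNP positions
        assert regions[0].start >= 1_000_000 and regions[0].end <= 30_000_000
        assert regions[0].start <= 10_000_000 and regions[0].end >= 20_000_000


class TestShortlist:
    def test_strict_threshold_boundary(self):
        positions = [10, 20, 30, 40, 50]
        deltas = [0.9, 0.8, 0.74, 0.5, -0.9]
        sites = [_site(8, 8, pos=p) for p in positions]
        recs = _records(positions, deltas)
        region = GenomicInterval("1", 1, 100)
        kept = shortlist_snps(sites, recs, region, BsaConfig())
        assert [s.pos for s in kept["all"]] == [10, 20]  # 0.74 itself excluded

    def test_partition_by_annotation(self):
        sites = [_site(8, 8, pos=10), _site(8, 8, pos=20)]
        sites[0].annotation = "exonic"
        recs = _records([10, 20], [0.9, 0.9])
        region = GenomicInterval("1", 1, 100)
        kept = shortlist_snps(sites, recs, region, BsaConfig())
        assert [s.pos for s in kept["exonic"]] == [10]
        assert [s.pos for s in kept["other"]] == [20]

    def test_outside_region_excluded(self):
        sites = [_site(8, 8, pos=500)]
        recs = _records([500], [0.99])
        kept = shortlist_snps(sites, recs, GenomicInterval("1", 1, 100), BsaConfig())
        assert kept["all"] == []


class TestWindowAntisymmetry:
    def test_bulk_relabeling_negates_window_means(self, small_cfg):
        from pithmap.synthetic_data import (
            simulate_bulk_allele_counts,
            simulate_dh_population,
            simulate_phenotypes,
        )
        from pithmap.phenotyping import select_bulks

        rng = small_cfg.rng()
        geno = simulate_dh_population(small_cfg, rng)
        phen = simulate_phenotypes(geno, small_cfg, rng)
        bulks = select_bulks(phen, k=20)
        sites = simulate_bulk_allele_counts(
            geno, bulks.high_bulk_ids, bulks.low_bulk_ids, small_cfg, rng
        )
        cfg = BsaConfig()
        rec_fwd, _ = compute_snp_indices(sites, DEFAULT_ROLES)
        swapped = dict(DEFAULT_ROLES, bulk_high="H", bulk_low="S")
        rec_rev, _ = compute_snp_indices(sites, swapped)
        win_fwd = sliding_window_scan(rec_fwd, cfg, small_cfg.chrom_lengths)
        win_rev = sliding_window_scan(rec_rev, cfg, small_cfg.chrom_lengths)
        fwd = win_fwd["mean_delta"].to_numpy()
        rev = win_rev["mean_delta"].to_numpy()
        mask = ~np.isnan(fwd)
        assert np.allclose(fwd[mask], -rev[mask], atol=1e-12)
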