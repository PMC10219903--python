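"""The DH population, bulk-read and expression generators."""

import numpy as np
import pytest

from pithmap import expression as ex
from pithmap.phenotyping import select_bulks, write_phenotypes
from pithmap.synthetic_data import (
    SAMPLE_NAMES,
    ExpressionSimSpec,
    PlantedDeg,
    SimConfig,
    haldane,
    simulate_bulk_allele_counts,
    simulate_dh_population,
    simulate_expression_counts,
    simulate_phenotypes,
)
from pithmap.variant_filtering import write_vcf


def _cfg(**kw):
    base = dict(
        chrom_lengths={"1": 200_000_000},
        marker_positions={"1": [1_000_000]},
        qtl_chrom="1",
        qtl_pos=1_000_000,
        n_lines=50,
        seed=1,
    )
    base.update(kw)
    return SimConfig(**base)


class TestDhPopulation:
    def test_dh_lines_are_fully_homozygous(self):
        geno = simulate_dh_population(_cfg(n_lines=4, bulk_size=2))
        assert geno.genotypes.shape == (4, 1)
        assert set(np.unique(geno.genotypes)) <= {0, 1}

    def test_zero_distance_markers_identical(self):
        cfg = _cfg(marker_positions={"1": [5_000_000, 5_000_000]}, n_lines=200)
        geno = simulate_dh_population(cfg)
        assert np.array_equal(geno.genotypes[:, 0], geno.genotypes[:, 1])

    def test_recombinant_fraction_matches_haldane(self):
        """100 Mb at 1 cM/Mb = 1 Morgan: r = (1 - e^-2)/2, within 3 SE."""
        cfg = _cfg(
            marker_positions={"1": [1, 100_000_001]}, n_lines=10_000, seed=5
        )
        geno = simulate_dh_population(cfg)
        observed = float(np.mean(geno.genotypes[:, 0] != geno.genotypes[:, 1]))
        expected = (1 - np.exp(-2)) / 2
        se = np.sqrt(expected * (1 - expected) / 10_000)
        assert abs(observed - expected) < 3 * se

    def test_recombinant_fraction_nondecreasing_in_distance(self):
        gaps = [5, 20, 50, 120]  # Mb
        positions = [1] + [1 + g * 1_000_000 for g in gaps]
        cfg = _cfg(marker_positions={"1": positions}, n_lines=10_000, seed=9)
        geno = simulate_dh_population(cfg)
        first = geno.genotypes[:, 0]
        fracs = [
            float(np.mean(first != geno.genotypes[:, j]))
            for j in range(1, len(positions))
        ]
        se = 3 * np.sqrt(0.25 / 10_000)
        assert all(b >= a - 3 * se for a, b in zip(fracs, fracs[1:]))

    def test_unsorted_markers_error_names_chromosome(self):
        cfg = _cfg()
        cfg.marker_positions = {"1": [5_000_000, 1_000_000]}
        with pytest.raises(ValueError, match="'1'"):
            simulate_dh_population(cfg)


class TestPhenotypes:
    def test_null_effect_groups_indistinguishable(self):
        cfg = _cfg(qtl_effect=0.0, n_lines=400, noise_sd=0.05, seed=3)
        rng = cfg.rng()
        geno = simulate_dh_population(cfg, rng)
        phen = simulate_phenotypes(geno, cfg, rng)
        g = geno.genotypes[:, 0]
        pt = np.array([p.pith_thickness for p in phen])
        se = np.sqrt(pt.var() / (g == 1).sum() + pt.var() / (g == 0).sum())
        assert abs(pt[g == 1].mean() - pt[g == 0].mean()) < 3 * se

    def test_noiseless_phenotype_is_exactly_bimodal(self):
        cfg = _cfg(noise_sd=0.0, diam_sd=0.0, qtl_effect=0.7, n_lines=100, seed=4)
        rng = cfg.rng()
        geno = simulate_dh_population(cfg, rng)
        phen = simulate_phenotypes(geno, cfg, rng)
        assert len({round(p.pith_thickness, 9) for p in phen}) == 2

    def test_parental_pi_classes_near_reported_ranges(self):
        """The two genotype classes centre near PI 0.58 and 0.24."""
        cfg = _cfg(n_lines=225, seed=8)
        rng = cfg.rng()
        geno = simulate_dh_population(cfg, rng)
        phen = simulate_phenotypes(geno, cfg, rng)
        g = geno.genotypes[:, 0]
        pi = np.array([p.pi for p in phen])
        assert abs(pi[g == 1].mean() - 0.58) < 0.05
        assert abs(pi[g == 0].mean() - 0.24) < 0.05


class TestBulkAlleleCounts:
    def test_fixed_bulk_gives_unit_alt_fraction(self):
        cfg = _cfg(n_lines=10, base_error=0.0, bulk_size=3, mean_depth=30, seed=2)
        geno = simulate_dh_population(cfg)
        geno.genotypes[:, :] = 1
        sites = simulate_bulk_allele_counts(
            geno, geno.line_ids[:3], geno.line_ids[3:6], cfg
        )
        s = sites[0].samples["S"]
        assert s.ad_alt == s.depth and s.ad_ref == 0

    def test_allele_counts_sum_to_depth(self, small_cfg):
        rng = small_cfg.rng()
        geno = simulate_dh_population(small_cfg, rng)
        phen = simulate_phenotypes(geno, small_cfg, rng)
        bulks = select_bulks(phen, k=20)
        sites = simulate_bulk_allele_counts(
            geno, bulks.high_bulk_ids, bulks.low_bulk_ids, small_cfg, rng
        )
        for site in sites[:200]:
            for call in site.samples.values():
                assert call.ad_ref + call.ad_alt == call.depth

    def test_half_frequency_observed_fraction_within_binomial_se(self):
        cfg = _cfg(n_lines=8, base_error=0.0, bulk_size=2, mean_depth=10_000, seed=6)
        geno = simulate_dh_population(cfg)
        geno.genotypes[:, :] = 0
        geno.genotypes[0, :] = 1  # bulk of lines 0,1 -> f = 0.5
        sites = simulate_bulk_allele_counts(
            geno, geno.line_ids[:2], geno.line_ids[2:4], cfg
        )
        s = sites[0].samples["S"]
        frac = s.ad_alt / s.depth
        assert abs(frac - 0.5) < 3 * np.sqrt(0.25 / s.depth)

    def test_extreme_bulks_fix_opposite_frequencies_at_qtl(self, small_cfg):
        """High bulk ~100% and low bulk ~0% high-parent allele at the locus."""
        rng = small_cfg.rng()
        geno = simulate_dh_population(small_cfg, rng)
        phen = simulate_phenotypes(geno, small_cfg, rng)
        bulks = select_bulks(phen, k=20)
        sites = simulate_bulk_allele_counts(
            geno, bulks.high_bulk_ids, bulks.low_bulk_ids, small_cfg, rng
        )
        at_qtl = next(
            s
            for s in sites
            if s.chrom == small_cfg.qtl_chrom and s.pos == small_cfg.qtl_pos
        )
        s, h = at_qtl.samples["S"], at_qtl.samples["H"]
        assert s.ad_alt / s.total_ad > 0.9
        assert h.ad_alt / h.total_ad < 0.1

    def test_empty_bulk_rejected(self):
        cfg = _cfg(n_lines=10, bulk_size=2)
        geno = simulate_dh_population(cfg)
        with pytest.raises(ValueError, match="non-empty"):
            simulate_bulk_allele_counts(geno, [], geno.line_ids[:2], cfg)

    def test_overlapping_bulks_rejected(self):
        cfg = _cfg(n_lines=10, bulk_size=2)
        geno = simulate_dh_population(cfg)
        with pytest.raises(ValueError, match="disjoint"):
            simulate_bulk_allele_counts(
                geno, geno.line_ids[:2], geno.line_ids[1:3], cfg
            )


class TestSeedDeterminism:
    def test_identical_config_gives_byte_identical_outputs(self, tmp_path):
        paths = []
        for run in ("a", "b"):
            cfg = _cfg(n_lines=30, bulk_size=5, seed=77)
            rng = cfg.rng()
            geno = simulate_dh_population(cfg, rng)
            phen = simulate_phenotypes(geno, cfg, rng)
            sites = simulate_bulk_allele_counts(
                geno, geno.line_ids[:5], geno.line_ids[5:10], cfg, rng
            )
            vcf = tmp_path / f"{run}.vcf"
            tsv = tmp_path / f"{run}.tsv"
            write_vcf(sites, vcf, list(SAMPLE_NAMES), cfg.chrom_lengths)
            write_phenotypes(phen, tsv)
            paths.append((vcf.read_bytes(), tsv.read_bytes()))
        assert paths[0] == paths[1]


class TestExpressionCounts:
    def test_null_spec_produces_no_degs(self):
        cfg = _cfg(seed=21)
        rng = cfg.rng()
        spec = ExpressionSimSpec(n_genes=500)
        counts, genes = simulate_expression_counts(spec, cfg, rng)
        fpkm = ex.compute_fpkm(counts, genes.set_index("gene_id")["length"])
        cols = {s: [c for c in counts.columns if c.startswith(s + "_")] for s in "WK"}
        calls = ex.call_degs(fpkm, cols["W"], cols["K"], "W_vs_K")
        assert int(calls["is_deg"].sum()) == 0

    def test_planted_concordant_deg_lands_in_scluster(self):
        cfg = _cfg(seed=22)
        rng = cfg.rng()
        spec = ExpressionSimSpec(
            n_genes=300, planted_degs=[PlantedDeg(7, 5.0, True)]
        )
        counts, genes = simulate_expression_counts(spec, cfg, rng)
        fpkm = ex.compute_fpkm(counts, genes.set_index("gene_id")["length"])
        cols = {
            s: [c for c in counts.columns if c.startswith(s + "_")] for s in "WKSH"
        }
        wk = ex.call_degs(fpkm, cols["W"], cols["K"], "W_vs_K")
        sh = ex.call_degs(fpkm, cols["S"], cols["H"], "S_vs_H")
        co = ex.assign_clusters(ex.intersect_coexisting(wk, sh))
        assert co.loc["gene00008", "cluster"] == "Scluster"

    def test_poisson_limit_variance_matches_mean(self):
        cfg = _cfg(seed=23, n_replicates=3)
        rng = cfg.rng()
        spec = ExpressionSimSpec(n_genes=3000, dispersion=1e9, baseline_mean=100.0)
        counts, _ = simulate_expression_counts(spec, cfg, rng)
        w_cols = [c for c in counts.columns if c.startswith("W_")]
        # compare across genes at a common library factor: one column's
        # gene-wise mean approximates its variance in the Poisson limit
        col = counts[w_cols[0]]
        assert abs(col.var() / col.mean() - 1.0) < 0.1


def test_haldane_limits():
    assert haldane(0.0) == 0.0
    assert haldane(50.0) == pytest.approx(0.5)
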