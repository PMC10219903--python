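"""Reproducible benchmark experiments on the synthetic study design.

Each function runs one self-contained computational experiment — null
calibration of the confidence thresholds, end-to-end QTL recovery, DEG
recovery, marker-layer consistency — at the study conditions the package
treats as its reference design (225 DH lines, bulks of 20, ~8x bulk
depth, 5 Mb / 50 kb windows).  The genome for the scan experiments is a
compact two-chromosome layout (150 Mb each, markers every 500 kb,
2 cM/Mb as on distal wheat 3BL) so that a hundred replicates run in
seconds while keeping the per-window SNP counts realistic.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import expression as ex
from .bsa_mapping import BsaConfig, simulate_null_deltas, simulate_thresholds
from .markers import genotype_line, insilico_pcr
from .pipeline import run_bsr_scan
from .synthetic_data import (
    ExpressionSimSpec,
    PlantedDeg,
    SimConfig,
    simulate_expression_counts,
    simulate_marker_templates,
)

__all__ = [
    "scan_sim_config",
    "null_threshold_calibration",
    "qtl_recovery_experiment",
    "deg_recovery_experiment",
    "marker_layer_experiment",
]

_CHROM_MB = 150
_MARKER_SPACING = 500_000


def scan_sim_config(seed: int) -> SimConfig:
    """Reference scan design: QTL mid-chromosome on 3B, null 1A."""
    length = _CHROM_MB * 1_000_000
    return SimConfig(
        chrom_lengths={"3B": length, "1A": length},
        marker_positions={
            c: list(range(_MARKER_SPACING, length + 1, _MARKER_SPACING))
            for c in ("3B", "1A")
        },
        qtl_chrom="3B",
        qtl_pos=length // 2,
        cm_per_mb=2.0,
        mean_depth=8.0,
        seed=seed,
    )


def null_threshold_calibration(
    seed: int,
    bulk_size: int = 20,
    depth: int = 8,
    n_sims: int = 10_000,
) -> float:
    """Fraction of fresh null draws outside the fitted 99% band.

    Thresholds are fitted on one stream of null draws; exceedance is then
    measured on an independent stream of per-window draws from the same
    doubled-haploid null (unlinked locus, bulks of ``bulk_size``, reads
    at ``depth``).  A calibrated band leaves ~1% outside.
    """
    cfg = BsaConfig(bulk_size=bulk_size, n_null_sims=n_sims, seed=seed)
    thr = simulate_thresholds(cfg, [depth])
    fresh = simulate_null_deltas(
        bulk_size, depth, depth, n_sims, np.random.default_rng((seed, 0xFEED))
    )
    hi = thr.iloc[0]["ci99_hi"]
    lo = thr.iloc[0]["ci99_lo"]
    return float(np.mean((fresh > hi) | (fresh < lo)))


def qtl_recovery_experiment(seed: int, n_runs: int = 100) -> dict[str, float]:
    """End-to-end parameter recovery over seeded replicates.

    Each replicate simulates a fresh population, selects the extreme
    bulks, samples reads, scans, and asks whether the primary called
    region (the one holding the top window) contains the true locus.
    Also reports how often the scan called exactly one region.
    """
    recovered = single = called = 0
    for i in range(n_runs):
        result = run_bsr_scan(scan_sim_config(seed + i))
        recovered += result.qtl_recovered
        single += result.uniquely_recovered
        called += len(result.regions) > 0
    return {
        "n_runs": n_runs,
        "recovery_rate_pct": 100.0 * recovered / n_runs,
        "single_region_rate_pct": 100.0 * single / n_runs,
        "any_region_rate_pct": 100.0 * called / n_runs,
    }


def deg_recovery_experiment(
    seed: int,
    n_rounds: int = 3,
    n_genes: int = 1500,
    n_planted: int = 40,
    n_concordant: int = 25,
    min_abs_log2fc: float = 2.5,
    max_abs_log2fc: float = 5.0,
) -> dict[str, float]:
    """Planted-truth recovery through the full DEG pipeline.

    Plants concordant DEGs (|log2FC| uniform on [2.5, 5], both signs)
    plus parent-only DEGs, runs FPKM -> per-comparison calls ->
    intersection -> clusters, and scores: sensitivity = planted
    concordant genes landing in their expected cluster; the null false
    DEG rate is measured on unplanted genes in the parent comparison.
    """
    hits = total = false_calls = n_null = 0
    for r in range(n_rounds):
        run_seed = seed + r
        cfg = SimConfig(seed=run_seed)
        rng = np.random.default_rng(run_seed)
        chosen = rng.choice(n_genes, n_planted, replace=False)
        planted = [
            PlantedDeg(
                int(g),
                float((1 if i % 2 else -1) * rng.uniform(min_abs_log2fc, max_abs_log2fc)),
                i < n_concordant,
            )
            for i, g in enumerate(chosen)
        ]
        spec = ExpressionSimSpec(n_genes=n_genes, planted_degs=planted)
        counts, genes = simulate_expression_counts(spec, cfg, rng)
        fpkm = ex.compute_fpkm(counts, genes.set_index("gene_id")["length"])
        cols = {
            s: [c for c in counts.columns if c.startswith(s + "_")] for s in "WKSH"
        }
        wk = ex.call_degs(fpkm, cols["W"], cols["K"], "W_vs_K")
        sh = ex.call_degs(fpkm, cols["S"], cols["H"], "S_vs_H")
        co = ex.assign_clusters(ex.intersect_coexisting(wk, sh))
        for p in planted:
            if not p.concordant:
                continue
            gid = f"gene{p.gene_index + 1:05d}"
            want = "Scluster" if p.log2fc > 0 else "Hcluster"
            total += 1
            hits += gid in co.index and co.loc[gid, "cluster"] == want
        planted_ids = {f"gene{p.gene_index + 1:05d}" for p in planted}
        null_ids = list(set(fpkm.index) - planted_ids)
        false_calls += int(wk.loc[null_ids, "is_deg"].sum())
        n_null += len(null_ids)
    return {
        "sensitivity_pct": 100.0 * hits / total,
        "n_concordant_planted": total,
        "null_false_rate_pct": 100.0 * false_calls / n_null,
        "n_null_genes": n_null,
    }


def marker_layer_experiment(seed: int, n_lines: int = 40) -> dict[str, float]:
    """Codominant indel sizing and dominant/codominant concordance.

    Builds the two synthetic promoter alleles (309-bp indel), assigns
    alternating alleles to ``n_lines`` lines, genotypes every line with
    both assays, and reports the product-length difference and the
    fraction of lines on which the two assays agree.
    """
    templates, assays, truth = simulate_marker_templates(np.random.default_rng(seed))
    dominant = next(a for a in assays if a.mode == "dominant")
    codominant = next(a for a in assays if a.mode == "codominant")
    pa = insilico_pcr(templates["TaVPE3cB.a"], codominant)
    pb = insilico_pcr(templates["TaVPE3cB.b"], codominant)
    product_diff = pb[0] - pa[0]

    agree = 0
    names = list(templates)
    for i in range(n_lines):
        seq = templates[names[i % 2]]
        call_dom = genotype_line(insilico_pcr(seq, dominant), dominant)
        call_co = genotype_line(insilico_pcr(seq, codominant), codominant)
        agree += call_dom == call_co
    return {
        "codominant_product_diff_bp": float(product_diff),
        "assay_agreement_pct": 100.0 * agree / n_lines,
    }
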