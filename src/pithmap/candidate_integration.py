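"""Candidate-gene integration inside the mapped interval.

Combines three lines of evidence around the called region: gene models
overlapping the interval (plus a configurable flank for the "adjacent
region"), the coexisting DEG set, and the shortlisted high-delta SNPs.
Genes are tiered: tier 1 carries both a coexisting DEG call and at least
one shortlist SNP, tier 2 only the DEG call, tier 3 only SNPs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .bsa_mapping import GenomicInterval
from .expression import EXPRESSION_FLOOR
from .variant_filtering import VariantSite

log = logging.getLogger(__name__)

__all__ = [
    "CandidateGene",
    "genes_in_interval",
    "categorize_expression",
    "integrate",
    "bulk_frequency_consistency",
    "DEFAULT_FLANK_BP",
]

DEFAULT_FLANK_BP = 2_000_000

ONLY_A = "only_A"
ONLY_B = "only_B"
UP_IN_A = "up_in_A"
UP_IN_B = "up_in_B"
BALANCED = "balanced"
NOT_EXPRESSED = "not_expressed"


@dataclass
class CandidateGene:
    gene_id: str
    interval: GenomicInterval
    expression_category: str
    n_shortlist_snps: int
    coexisting_deg: bool
    cluster: str | None
    log2fc: float
    rank_tier: int  # 1, 2, 3; 0 = unranked


def genes_in_interval(
    annotation: pd.DataFrame,
    interval: GenomicInterval,
    flank_bp: int = DEFAULT_FLANK_BP,
) -> pd.DataFrame:
    """Gene models overlapping the interval extended by ``flank_bp``.

    Overlap means any shared base pair, 1-based inclusive on both sides,
    so a gene exactly abutting ``end + flank`` is included.
    """
    if annotation.empty:
        return annotation.copy()
    lo = interval.start - flank_bp
    hi = interval.end + flank_bp
    mask = (
        (annotation["chrom"] == interval.chrom)
        & (annotation["start"] <= hi)
        & (annotation["end"] >= lo)
    )
    out = annotation[mask].copy()
    log.info(
        "%d gene(s) overlap %s with %.1f Mb flank", len(out), interval.label, flank_bp / 1e6
    )
    return out


def categorize_expression(
    mean_a: float, mean_b: float, floor: float = EXPRESSION_FLOOR
) -> str:
    """Four-way expression category relative to a detection floor.

    A gene expressed (mean >= floor) in only one sample is "only" that
    sample's category; expressed in both, the larger mean wins the "up"
    category; exactly equal means are "balanced" (excluded from candidate
    tiers); below the floor in both samples -> "not_expressed".
    """
    a_expr = mean_a >= floor
    b_expr = mean_b >= floor
    if a_expr and not b_expr:
        return ONLY_A
    if b_expr and not a_expr:
        return ONLY_B
    if not a_expr and not b_expr:
        return NOT_EXPRESSED
    if mean_a > mean_b:
        return UP_IN_A
    if mean_b > mean_a:
        return UP_IN_B
    return BALANCED


def integrate(
    region_genes: pd.DataFrame,
    coexisting: pd.DataFrame,
    shortlist_sites: list[VariantSite],
    interval: GenomicInterval,
    group_mean_a: pd.Series | None = None,
    group_mean_b: pd.Series | None = None,
) -> list[CandidateGene]:
    """Rank candidate genes by evidence tier.

    Tier 1: coexisting DEG with >= 1 shortlist SNP inside the gene span;
    tier 2: coexisting DEG only; tier 3: shortlist SNP only.  Within a
    tier genes sort by |log2FC| (bulk comparison) descending, ties by
    gene id.  Genes with neither line of evidence are omitted.
    """
    snp_count: dict[str, int] = {}
    for row in region_genes.itertuples(index=False):
        n = sum(
            1
            for s in shortlist_sites
            if s.chrom == row.chrom and row.start <= s.pos <= row.end
        )
        snp_count[row.gene_id] = n

    candidates: list[CandidateGene] = []
    for row in region_genes.itertuples(index=False):
        gid = row.gene_id
        is_deg = gid in coexisting.index
        n_snps = snp_count.get(gid, 0)
        if not is_deg and n_snps == 0:
            continue
        if group_mean_a is not None and group_mean_b is not None and gid in group_mean_a.index:
            category = categorize_expression(
                float(group_mean_a[gid]), float(group_mean_b[gid])
            )
        else:
            category = NOT_EXPRESSED
        cluster = str(coexisting.loc[gid, "cluster"]) if is_deg and "cluster" in coexisting else None
        log2fc = float(coexisting.loc[gid, "log2fc_sh"]) if is_deg else 0.0
        if category == BALANCED:
            tier = 0  # equal means: ambiguous, excluded from ranked tiers
        elif is_deg and n_snps >= 1:
            tier = 1
        elif is_deg:
            tier = 2
        else:
            tier = 3
        candidates.append(
            CandidateGene(
                gene_id=gid,
                interval=GenomicInterval(row.chrom, int(row.start), int(row.end)),
                expression_category=category,
                n_shortlist_snps=n_snps,
                coexisting_deg=is_deg,
                cluster=cluster,
                log2fc=log2fc,
                rank_tier=tier,
            )
        )
    ranked = [c for c in candidates if c.rank_tier > 0]
    ranked.sort(key=lambda c: (c.rank_tier, -abs(c.log2fc), c.gene_id))
    return ranked


def candidates_to_frame(candidates: list[CandidateGene]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gene_id": [c.gene_id for c in candidates],
            "chrom": [c.interval.chrom for c in candidates],
            "start": [c.interval.start for c in candidates],
            "end": [c.interval.end for c in candidates],
            "expression_category": [c.expression_category for c in candidates],
            "n_shortlist_snps": [c.n_shortlist_snps for c in candidates],
            "coexisting_deg": [c.coexisting_deg for c in candidates],
            "cluster": [c.cluster for c in candidates],
            "log2fc": [c.log2fc for c in candidates],
            "rank_tier": [c.rank_tier for c in candidates],
        }
    )


def bulk_frequency_consistency(
    snp_index_high_bulk: float,
    snp_index_low_bulk: float,
    tol: float = 0.1,
) -> bool:
    """True when bulk allele frequencies match the parental extremes.

    The diagnostic pattern for a causal variant: the high-parent allele
    at ~100% in the solid bulk and ~0% in the hollow bulk, within the
    tolerance band.
    """
    return (
        snp_index_high_bulk >= 1.0 - tol and snp_index_low_bulk <= tol
    )
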