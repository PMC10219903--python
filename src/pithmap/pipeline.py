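"""End-to-end convenience wrappers over the module layer.

These glue functions run the whole bulked-segregant scan on a synthetic
population — simulate genotypes and phenotypes, build the extreme bulks,
sample bulk reads, filter, scan, and call the candidate region — and are
what the CLI, the recovery experiments and the acceptance checks drive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import bsa_mapping, phenotyping, synthetic_data, variant_filtering
from .bsa_mapping import BsaConfig, GenomicInterval
from .synthetic_data import DEFAULT_ROLES, SimConfig

__all__ = ["ScanResult", "run_bsr_scan"]


@dataclass
class ScanResult:
    phenotypes: list
    bulks: phenotyping.BulkDesign
    sites: list
    records: list
    windows: pd.DataFrame
    regions: list[GenomicInterval]
    true_qtl: tuple[str, int]

    @property
    def primary_region(self) -> GenomicInterval | None:
        """The called region containing the genome-wide top window.

        Linked transition zones can shed small satellite regions beside
        the main signal; the region holding the highest window mean is
        the scan's single candidate region.
        """
        if not self.regions:
            return None
        w = self.windows
        flagged = w[(w["n_snps"] > 0) & (w["mean_delta"] > w["ci99_hi"])]
        if flagged.empty:
            return None
        top = flagged.loc[flagged["mean_delta"].idxmax()]
        mid = int((top["pos_min"] + top["pos_max"]) // 2)
        for region in self.regions:
            if region.contains(str(top["chrom"]), mid):
                return region
        return None

    @property
    def qtl_recovered(self) -> bool:
        """True when the primary called region contains the true locus."""
        region = self.primary_region
        return region is not None and region.contains(*self.true_qtl)

    @property
    def uniquely_recovered(self) -> bool:
        """Stricter readout: exactly one region called and it holds the QTL."""
        return len(self.regions) == 1 and self.regions[0].contains(*self.true_qtl)


def run_bsr_scan(
    cfg: SimConfig,
    bsa_cfg: BsaConfig | None = None,
    apply_filter: bool = True,
) -> ScanResult:
    """Simulate one BSR experiment and scan it for the planted locus."""
    bsa_cfg = bsa_cfg or BsaConfig(bulk_size=cfg.bulk_size, seed=cfg.seed)
    rng = cfg.rng()
    geno = synthetic_data.simulate_dh_population(cfg, rng)
    phen = synthetic_data.simulate_phenotypes(geno, cfg, rng)
    bulks = phenotyping.select_bulks(phen, k=cfg.bulk_size)
    sites = synthetic_data.simulate_bulk_allele_counts(
        geno, bulks.high_bulk_ids, bulks.low_bulk_ids, cfg, rng
    )
    if apply_filter:
        fcfg = variant_filtering.FilterConfig()
        sites = variant_filtering.filter_high_quality(sites, fcfg, DEFAULT_ROLES).kept
    records, _ = bsa_mapping.compute_snp_indices(sites, DEFAULT_ROLES)
    windows = bsa_mapping.sliding_window_scan(records, bsa_cfg, cfg.chrom_lengths)
    depths = windows.loc[windows["n_snps"] > 0, "depth_mean"].round().unique()
    thresholds = bsa_mapping.simulate_thresholds(bsa_cfg, depths)
    windows = bsa_mapping.attach_thresholds(windows, thresholds)
    regions = bsa_mapping.call_candidate_regions(windows)
    return ScanResult(
        phenotypes=phen,
        bulks=bulks,
        sites=sites,
        records=records,
        windows=windows,
        regions=regions,
        true_qtl=(cfg.qtl_chrom, cfg.qtl_pos),
    )
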