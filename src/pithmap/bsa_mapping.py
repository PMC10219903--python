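"""SNP-index / delta-SNP-index genome scan for bulked-segregant mapping.

At each filtered site, the SNP-index of a bulk is the fraction of its
reads carrying the allele *not* matching the low-phenotype parent (the
reference orientation), so it equals the high-parent allele frequency in
the bulk.  The delta-SNP-index is

    delta = SNP-index(solid bulk) - SNP-index(hollow bulk)

which is ~0 at unlinked loci and approaches +1 at a locus where the
high-phenotype allele is fixed in the solid bulk and absent from the
hollow bulk.  Window means over a 5 Mb sliding window (50 kb step) are
compared against confidence thresholds obtained by simulating the null:
for a doubled-haploid bulk of n lines, the bulk allele count at an
unlinked locus is Binomial(n, 1/2), and reads are a second binomial draw
at the observed depth.  Windows above the 99% band are merged into
candidate regions, and individual SNPs above a fixed delta cutoff form
the shortlist.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .variant_filtering import VariantSite

log = logging.getLogger(__name__)

__all__ = [
    "SnpIndexRecord",
    "GenomicInterval",
    "BsaConfig",
    "compute_snp_index",
    "compute_snp_indices",
    "sliding_window_scan",
    "simulate_null_deltas",
    "simulate_thresholds",
    "attach_thresholds",
    "call_candidate_regions",
    "shortlist_snps",
    "plot_scan",
]


@dataclass
class SnpIndexRecord:
    """Per-site SNP-index of both bulks and their difference."""

    chrom: str
    pos: int
    snp_index_high_bulk: float
    snp_index_low_bulk: float
    delta_snp_index: float
    depth_high: int
    depth_low: int

    def __post_init__(self) -> None:
        for v in (self.snp_index_high_bulk, self.snp_index_low_bulk):
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"SNP-index {v} outside [0, 1]")
        expected = self.snp_index_high_bulk - self.snp_index_low_bulk
        if abs(expected - self.delta_snp_index) > 1e-9:
            raise ValueError("delta inconsistent with the two indices")


@dataclass
class GenomicInterval:
    """1-based inclusive genomic interval."""

    chrom: str
    start: int
    end: int
    label: str = ""

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"interval start {self.start} > end {self.end}")

    @property
    def length_mb(self) -> float:
        """Length in Mb, reported to 2 decimals."""
        return round((self.end - self.start + 1) / 1e6, 2)

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos <= self.end


@dataclass
class BsaConfig:
    """Scan geometry, null-simulation settings and the shortlist cutoff."""

    window_bp: int = 5_000_000
    step_bp: int = 50_000
    confidence_levels: tuple[float, ...] = (0.95, 0.99)
    n_null_sims: int = 10_000
    bulk_size: int = 20
    delta_shortlist_threshold: float = 0.74
    seed: int = 0

    def __post_init__(self) -> None:
        if self.step_bp > self.window_bp:
            raise ValueError("step must not exceed the window size")
        if not all(0 < c < 1 for c in self.confidence_levels):
            raise ValueError("confidence levels must lie in (0, 1)")


def compute_snp_index(
    site: VariantSite, bulk_sample: str, low_parent_sample: str
) -> float | None:
    """Fraction of the bulk's reads carrying the non-low-parent allele.

    The low-phenotype parent is the reference orientation: if it is
    homozygous REF the index counts ALT reads, and vice versa.  Returns
    None when the bulk has no covering reads (site flagged by caller).
    """
    low = site.samples[low_parent_sample]
    if not low.is_hom:
        raise ValueError(
            f"{site.chrom}:{site.pos}: low parent is not homozygous; "
            "filter sites before computing SNP-index"
        )
    bulk = site.samples[bulk_sample]
    total = bulk.total_ad
    if total == 0:
        return None
    if low.genotype == (0, 0):
        return bulk.ad_alt / total
    return bulk.ad_ref / total


def compute_snp_indices(
    sites: list[VariantSite],
    sample_roles: dict[str, str],
) -> tuple[list[SnpIndexRecord], int]:
    """Per-site indices for both bulks; sites lacking coverage are dropped.

    Returns ``(records, n_excluded)`` where excluded sites had zero
    covering reads in at least one bulk.
    """
    bulk_hi = sample_roles["bulk_high"]
    bulk_lo = sample_roles["bulk_low"]
    low_parent = sample_roles["parent_low"]
    records: list[SnpIndexRecord] = []
    n_excluded = 0
    for site in sites:
        idx_hi = compute_snp_index(site, bulk_hi, low_parent)
        idx_lo = compute_snp_index(site, bulk_lo, low_parent)
        if idx_hi is None or idx_lo is None:
            n_excluded += 1
            continue
        records.append(
            SnpIndexRecord(
                chrom=site.chrom,
                pos=site.pos,
                snp_index_high_bulk=idx_hi,
                snp_index_low_bulk=idx_lo,
                delta_snp_index=idx_hi - idx_lo,
                depth_high=site.samples[bulk_hi].total_ad,
                depth_low=site.samples[bulk_lo].total_ad,
            )
        )
    if n_excluded:
        log.info("excluded %d site(s) with zero bulk coverage", n_excluded)
    return records, n_excluded


def records_to_frame(records: list[SnpIndexRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": [r.chrom for r in records],
            "pos": [r.pos for r in records],
            "snp_index_high_bulk": [r.snp_index_high_bulk for r in records],
            "snp_index_low_bulk": [r.snp_index_low_bulk for r in records],
            "delta_snp_index": [r.delta_snp_index for r in records],
            "depth_high": [r.depth_high for r in records],
            "depth_low": [r.depth_low for r in records],
        }
    )


def sliding_window_scan(
    records: list[SnpIndexRecord],
    cfg: BsaConfig,
    chrom_lengths: dict[str, int],
) -> pd.DataFrame:
    """Mean delta-SNP-index in sliding windows.

    Windows are anchored at 0, step, 2*step, ... on each chromosome and
    are half-open ``[a, a + window)`` in 0-based coordinates (truncated
    at the chromosome end).  The window mean is the unweighted mean over
    the SNPs inside; empty windows carry NaN and are excluded from
    region calling.

    Returns a frame with chrom, start, end, n_snps, mean_delta,
    depth_mean, pos_min, pos_max.
    """
    df = records_to_frame(records)
    if len(df) and not df.sort_values(["chrom", "pos"]).equals(df.reset_index(drop=True)):
        log.info("input records unsorted; sorting by (chrom, pos)")
    df = df.sort_values(["chrom", "pos"]).reset_index(drop=True)

    rows = []
    for chrom, length in chrom_lengths.items():
        sub = df[df["chrom"] == chrom]
        pos0 = sub["pos"].to_numpy(dtype=np.int64) - 1  # 0-based
        delta = sub["delta_snp_index"].to_numpy()
        depth = (sub["depth_high"].to_numpy() + sub["depth_low"].to_numpy()) / 2.0
        csum_delta = np.concatenate([[0.0], np.cumsum(delta)])
        csum_depth = np.concatenate([[0.0], np.cumsum(depth)])
        starts = np.arange(0, length, cfg.step_bp, dtype=np.int64)
        ends = np.minimum(starts + cfg.window_bp, length)
        lo = np.searchsorted(pos0, starts, side="left")
        hi = np.searchsorted(pos0, ends, side="left")
        n = hi - lo
        with np.errstate(invalid="ignore"):
            mean_delta = np.where(n > 0, (csum_delta[hi] - csum_delta[lo]) / np.maximum(n, 1), np.nan)
            depth_mean = np.where(n > 0, (csum_depth[hi] - csum_depth[lo]) / np.maximum(n, 1), np.nan)
        for i in range(len(starts)):
            pos_min = int(pos0[lo[i]]) + 1 if n[i] > 0 else -1
            pos_max = int(pos0[hi[i] - 1]) + 1 if n[i] > 0 else -1
            rows.append(
                (
                    chrom,
                    int(starts[i]),
                    int(ends[i]),
                    int(n[i]),
                    float(mean_delta[i]) if n[i] > 0 else np.nan,
                    float(depth_mean[i]) if n[i] > 0 else np.nan,
                    pos_min,
                    pos_max,
                )
            )
    return pd.DataFrame(
        rows,
        columns=[
            "chrom",
            "start",
            "end",
            "n_snps",
            "mean_delta",
            "depth_mean",
            "pos_min",
            "pos_max",
        ],
    )


def simulate_null_deltas(
    bulk_size: int,
    depth_high: int,
    depth_low: int,
    n_sims: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Null delta-SNP-index draws for an unlinked locus in a DH design.

    The bulk allele count is Binomial(bulk_size, 1/2) independently per
    bulk (doubled haploids segregate 1:1 with no heterozygotes); reads
    are a second binomial draw at the given depth.
    """
    f_hi = rng.binomial(bulk_size, 0.5, n_sims) / bulk_size
    f_lo = rng.binomial(bulk_size, 0.5, n_sims) / bulk_size
    p_hi = rng.binomial(depth_high, f_hi) / depth_high
    p_lo = rng.binomial(depth_low, f_lo) / depth_low
    return p_hi - p_lo


def _tail_quantile(null: np.ndarray, tail: float, upper: bool) -> float:
    """Nearest-tail empirical quantile for a (possibly discrete) null.

    At low read depth the null delta lives on a lattice (multiples of
    1/depth), so the plain empirical quantile can leave a strict-exceedance
    probability far from the nominal tail.  Among the observed support
    points, pick the one whose strict exceedance probability is closest to
    ``tail``; ties go to the more conservative (more extreme) point.  For
    effectively continuous nulls this coincides with the usual quantile.
    """
    values, counts = np.unique(null, return_counts=True)
    n = null.size
    if upper:
        exceed = (n - np.cumsum(counts)) / n  # P(X > v) per support point
    else:
        exceed = (np.cumsum(counts) - counts) / n  # P(X < v)
    dist = np.abs(exceed - tail)
    best = dist.min()
    candidates = np.flatnonzero(dist == best)
    i = candidates[-1] if upper else candidates[0]
    return float(values[i])


def simulate_thresholds(
    cfg: BsaConfig, depths: list[int] | np.ndarray
) -> pd.DataFrame:
    """Empirical two-sided confidence bands per depth.

    For each requested depth d the null is simulated ``cfg.n_null_sims``
    times with both bulks at depth d, and the (1±level)/2 quantiles are
    recorded.  Deterministic under ``cfg.seed``; thresholds are
    (stochastically) non-increasing in depth.

    Returns a frame indexed by depth with columns like ci95_lo/ci95_hi.
    """
    depths = sorted({max(1, int(d)) for d in np.asarray(depths, dtype=float)})
    if cfg.bulk_size < 1:
        raise ValueError("bulk_size must be >= 1")
    rows = {}
    for d in depths:
        # child seed per depth: determinism independent of the depth set
        rng = np.random.default_rng((cfg.seed, d))
        null = simulate_null_deltas(cfg.bulk_size, d, d, cfg.n_null_sims, rng)
        row = {}
        for level in cfg.confidence_levels:
            tail = (1.0 - level) / 2.0
            pct = int(round(level * 100))
            row[f"ci{pct}_lo"] = _tail_quantile(null, tail, upper=False)
            row[f"ci{pct}_hi"] = _tail_quantile(null, tail, upper=True)
        rows[d] = row
    return pd.DataFrame.from_dict(rows, orient="index").rename_axis("depth")


def attach_thresholds(windows: pd.DataFrame, thresholds: pd.DataFrame) -> pd.DataFrame:
    """Join per-window confidence bands by the rounded window mean depth."""
    out = windows.copy()
    depth_keys = np.asarray(thresholds.index)
    rounded = (
        out["depth_mean"]
        .fillna(float(depth_keys.min()))
        .round()
        .clip(lower=depth_keys.min(), upper=depth_keys.max())
    )
    # snap to nearest available depth
    nearest = depth_keys[
        np.argmin(np.abs(rounded.to_numpy()[:, None] - depth_keys[None, :]), axis=1)
    ]
    for col in thresholds.columns:
        out[col] = thresholds[col].to_numpy()[
            np.searchsorted(depth_keys, nearest)
        ]
        out.loc[out["n_snps"] == 0, col] = np.nan
    return out


def call_candidate_regions(
    windows: pd.DataFrame,
    threshold_col: str = "ci99_hi",
    merge_gap_bp: int | None = None,
) -> list[GenomicInterval]:
    """Merge windows whose mean delta exceeds the upper confidence band.

    Overlapping or adjacent flagged windows are merged; flagged runs
    separated by less than ``merge_gap_bp`` (default: one window width,
    the smoothing scale of the scan — a single noisy 5 Mb stretch of
    SNPs suppresses a full window-width of flagged starts) are likewise
    treated as one signal.  The merged span is then intersected with the
    span of the contributing SNPs so the interval endpoints are actual
    variant positions.  An empty list (no window exceeds the band) is a
    valid outcome.
    """
    if merge_gap_bp is None:
        non_empty = windows[windows["n_snps"] > 0]
        merge_gap_bp = (
            int((non_empty["end"] - non_empty["start"]).max()) if len(non_empty) else 0
        )
    flagged = windows[
        (windows["n_snps"] > 0) & (windows["mean_delta"] > windows[threshold_col])
    ]
    intervals: list[GenomicInterval] = []
    for chrom, sub in flagged.groupby("chrom", sort=False):
        sub = sub.sort_values("start")
        cur = None
        for row in sub.itertuples(index=False):
            if cur is None or row.start > cur["end"] + merge_gap_bp:
                if cur is not None:
                    intervals.append(_finalize_region(cur))
                cur = {
                    "chrom": chrom,
                    "start": row.start,
                    "end": row.end,
                    "pos_min": row.pos_min,
                    "pos_max": row.pos_max,
                }
            else:
                cur["end"] = max(cur["end"], row.end)
                cur["pos_min"] = min(cur["pos_min"], row.pos_min)
                cur["pos_max"] = max(cur["pos_max"], row.pos_max)
        if cur is not None:
            intervals.append(_finalize_region(cur))
    return intervals


def _finalize_region(cur: dict) -> GenomicInterval:
    start = max(cur["start"] + 1, cur["pos_min"])  # 1-based inclusive
    end = min(cur["end"], cur["pos_max"])
    return GenomicInterval(
        chrom=cur["chrom"],
        start=start,
        end=end,
        label=f"{cur['chrom']}:{start}-{end}",
    )


def shortlist_snps(
    sites: list[VariantSite],
    records: list[SnpIndexRecord],
    region: GenomicInterval,
    cfg: BsaConfig,
) -> dict[str, list[VariantSite]]:
    """High-confidence SNPs: delta strictly above the shortlist cutoff.

    Only sites inside ``region`` are considered; the strict inequality
    means a site at exactly the cutoff is excluded.  The result is
    partitioned by annotation class ("exonic" vs "other") when any site
    carries an annotation, else everything lands under "all".
    """
    delta_by_pos = {(r.chrom, r.pos): r.delta_snp_index for r in records}
    kept = [
        s
        for s in sites
        if region.contains(s.chrom, s.pos)
        and delta_by_pos.get((s.chrom, s.pos), float("-inf"))
        > cfg.delta_shortlist_threshold
    ]
    if any(s.annotation for s in kept):
        return {
            "exonic": [s for s in kept if s.annotation == "exonic"],
            "other": [s for s in kept if s.annotation != "exonic"],
        }
    return {"all": kept}


def regions_to_bed(regions: list[GenomicInterval], path) -> None:
    """Write regions as 0-based half-open BED."""
    with open(path, "w") as fh:
        for r in regions:
            fh.write(f"{r.chrom}\t{r.start - 1}\t{r.end}\t{r.label}\n")


def plot_scan(
    windows: pd.DataFrame,
    path,
    regions: list[GenomicInterval] | None = None,
) -> None:
    """Per-chromosome window-mean delta with confidence bands (PNG/PDF)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    chroms = list(windows["chrom"].unique())
    fig, axes = plt.subplots(
        len(chroms), 1, figsize=(10, 2.5 * len(chroms)), squeeze=False
    )
    for ax, chrom in zip(axes[:, 0], chroms):
        sub = windows[(windows["chrom"] == chrom) & (windows["n_snps"] > 0)]
        mid = (sub["start"] + sub["end"]) / 2e6
        ax.plot(mid, sub["mean_delta"], color="tab:blue", lw=1, label="window mean")
        for col, color in (("ci99_hi", "tab:red"), ("ci95_hi", "tab:purple")):
            if col in sub:
                ax.plot(mid, sub[col], color=color, lw=0.8, label=col)
        if regions:
            for r in regions:
                if r.chrom == chrom:
                    ax.axvspan(r.start / 1e6, r.end / 1e6, color="orange", alpha=0.3)
        ax.set_ylim(-1, 1)
        ax.set_ylabel("delta SNP-index")
        ax.set_title(chrom)
    axes[-1, 0].set_xlabel("position (Mb)")
    axes[0, 0].legend(loc="upper right", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
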