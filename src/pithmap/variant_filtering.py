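"""Multi-sample variant parsing and high-quality SNP filtering.

The bulked-segregant scan works on biallelic SNPs carried by four samples:
the two parents of the doubled-haploid population and the two phenotypic
bulks.  Sites are kept only when

* every sample is covered at depth >= 5,
* the site quality (QUAL) is >= 50,
* every sample genotype quality (GQ) is >= 20, and
* the two parents are homozygous for different alleles

so that each retained site is a fixed parental difference that can be
oriented to the low-phenotype parent.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

from cyvcf2 import VCF

log = logging.getLogger(__name__)

__all__ = [
    "SampleCall",
    "VariantSite",
    "FilterConfig",
    "FilterResult",
    "read_variants",
    "filter_high_quality",
    "write_vcf",
]

#: canonical sample roles: high-PT parent, low-PT parent, solid bulk, hollow bulk
ROLES = ("parent_high", "parent_low", "bulk_high", "bulk_low")


@dataclass
class SampleCall:
    """Per-sample genotype evidence at one site."""

    genotype: tuple[int, int] | None  # allele indices (0=ref, 1=alt); None=missing
    depth: int
    ad_ref: int
    ad_alt: int
    gq: float

    def __post_init__(self) -> None:
        if self.ad_ref + self.ad_alt > self.depth:
            raise ValueError(
                f"allele depths {self.ad_ref}+{self.ad_alt} exceed DP {self.depth}"
            )

    @property
    def is_hom(self) -> bool:
        return self.genotype is not None and self.genotype[0] == self.genotype[1]

    @property
    def total_ad(self) -> int:
        return self.ad_ref + self.ad_alt


@dataclass
class VariantSite:
    """One biallelic SNP with per-sample calls keyed by sample name."""

    chrom: str
    pos: int  # 1-based
    ref_allele: str
    alt_allele: str
    variant_quality: float
    samples: dict[str, SampleCall] = field(default_factory=dict)
    annotation: str | None = None  # optional effect class, e.g. "exonic"

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")


@dataclass
class FilterConfig:
    """Thresholds for the high-quality SNP filter."""

    min_depth: int = 5
    min_variant_quality: float = 50.0
    min_genotype_quality: float = 20.0
    require_parental_homozygous_diff: bool = True
    #: apply the depth rule to "all" samples or only to the two bulks
    depth_scope: str = "all"

    def __post_init__(self) -> None:
        if self.min_depth < 0 or self.min_variant_quality < 0 or self.min_genotype_quality < 0:
            raise ValueError("filter thresholds must be non-negative")
        if self.depth_scope not in ("all", "bulks"):
            raise ValueError("depth_scope must be 'all' or 'bulks'")


@dataclass
class FilterResult:
    kept: list[VariantSite]
    tally: dict[str, int]  # rejection count per rule; sums to n rejected


def read_variants(
    vcf_path, sample_roles: dict[str, str]
) -> tuple[list[VariantSite], int]:
    """Parse a VCF into :class:`VariantSite` records.

    Parameters
    ----------
    vcf_path
        Path to a VCFv4.x file with at least the four role samples.
    sample_roles
        Mapping from role (``parent_high``, ``parent_low``, ``bulk_high``,
        ``bulk_low``) to the sample name in the VCF header.  Samples are
        resolved by name, never by column position.

    Returns
    -------
    (sites, n_skipped_multiallelic)
        Multiallelic records are skipped (and counted); the scan operates
        on biallelic parental SNPs only.
    """
    vcf_path = str(vcf_path)
    if not Path(vcf_path).exists():
        raise FileNotFoundError(vcf_path)
    vcf = VCF(vcf_path)
    available = list(vcf.samples)
    for role in ROLES:
        if role not in sample_roles:
            raise ValueError(f"sample_roles is missing role {role!r}")
        if sample_roles[role] not in available:
            raise ValueError(
                f"sample {sample_roles[role]!r} (role {role}) not in VCF; "
                f"available samples: {available}"
            )
    sample_idx = {name: i for i, name in enumerate(available)}

    sites: list[VariantSite] = []
    n_multi = 0
    for v in vcf:
        if len(v.ALT) != 1:
            n_multi += 1
            continue
        try:
            ad = v.format("AD")
        except KeyError:
            ad = None
        if ad is None:
            raise ValueError(
                f"VCF record {v.CHROM}:{v.POS} lacks the AD FORMAT field "
                "(per-sample allele depths are required)"
            )
        try:
            dp = v.format("DP")
        except KeyError:
            dp = None
        try:
            gq = v.format("GQ")
        except KeyError:
            gq = None
        calls: dict[str, SampleCall] = {}
        for name, i in sample_idx.items():
            g = v.genotypes[i]
            alleles = tuple(a for a in g[:-1] if a >= 0)
            genotype = (alleles[0], alleles[-1]) if alleles else None
            ad_ref, ad_alt = int(ad[i][0]), int(ad[i][1])
            ad_ref = max(ad_ref, 0)  # cyvcf2 encodes missing as negative
            ad_alt = max(ad_alt, 0)
            depth = int(dp[i][0]) if dp is not None else ad_ref + ad_alt
            calls[name] = SampleCall(
                genotype=genotype,
                depth=max(depth, ad_ref + ad_alt),
                ad_ref=ad_ref,
                ad_alt=ad_alt,
                gq=float(gq[i][0]) if gq is not None else float("nan"),
            )
        info_eff = dict(v.INFO).get("EFF")
        sites.append(
            VariantSite(
                chrom=v.CHROM,
                pos=v.POS,
                ref_allele=v.REF,
                alt_allele=v.ALT[0],
                variant_quality=float(v.QUAL) if v.QUAL is not None else 0.0,
                samples=calls,
                annotation=str(info_eff) if info_eff is not None else None,
            )
        )
    if n_multi:
        log.info("skipped %d multiallelic record(s) in %s", n_multi, vcf_path)
    return sites, n_multi


# rejection rule keys, evaluated in order; a rejected site is attributed to
# the first failing rule so that the tally sums to the rejected count
RULE_DEPTH = "depth"
RULE_SITE_QUALITY = "variant_quality"
RULE_GENOTYPE_QUALITY = "genotype_quality"
RULE_PARENTS = "parental_genotypes"


def filter_high_quality(
    sites: list[VariantSite],
    cfg: FilterConfig,
    sample_roles: dict[str, str],
) -> FilterResult:
    """Apply the high-quality SNP filter, preserving input order.

    A site is kept iff (a) sample depth >= ``min_depth`` (all samples, or
    bulks only per ``depth_scope``), (b) QUAL >= ``min_variant_quality``,
    (c) every sample GQ >= ``min_genotype_quality``, and (d) both parents
    are homozygous for different alleles.
    """
    p_hi = sample_roles["parent_high"]
    p_lo = sample_roles["parent_low"]
    if cfg.depth_scope == "bulks":
        depth_samples = [sample_roles["bulk_high"], sample_roles["bulk_low"]]
    else:
        depth_samples = None  # all samples present at the site

    kept: list[VariantSite] = []
    tally = {
        RULE_DEPTH: 0,
        RULE_SITE_QUALITY: 0,
        RULE_GENOTYPE_QUALITY: 0,
        RULE_PARENTS: 0,
    }
    for site in sites:
        names = depth_samples if depth_samples is not None else list(site.samples)
        if any(site.samples[n].depth < cfg.min_depth for n in names):
            tally[RULE_DEPTH] += 1
            continue
        if site.variant_quality < cfg.min_variant_quality:
            tally[RULE_SITE_QUALITY] += 1
            continue
        if any(c.gq < cfg.min_genotype_quality for c in site.samples.values()):
            tally[RULE_GENOTYPE_QUALITY] += 1
            continue
        if cfg.require_parental_homozygous_diff:
            gh = site.samples.get(p_hi)
            gl = site.samples.get(p_lo)
            if (
                gh is None
                or gl is None
                or not gh.is_hom
                or not gl.is_hom
                or gh.genotype == gl.genotype
            ):
                tally[RULE_PARENTS] += 1
                continue
        kept.append(site)
    return FilterResult(kept=kept, tally=tally)


def write_vcf(
    sites: list[VariantSite],
    path,
    sample_names: list[str],
    chrom_lengths: dict[str, int] | None = None,
) -> None:
    """Write sites as a plain-text VCFv4.2 file with FORMAT GT:AD:DP:GQ.

    Output is fully deterministic (byte-identical for identical inputs).
    """
    chroms: dict[str, int] = dict(chrom_lengths or {})
    for s in sites:
        chroms.setdefault(s.chrom, 0)
        chroms[s.chrom] = max(chroms[s.chrom], s.pos)
    lines = [
        "##fileformat=VCFv4.2",
        "##source=pithmap",
        '##INFO=<ID=EFF,Number=1,Type=String,Description="Variant effect class">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allele depths (ref,alt)">',
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
        '##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">',
    ]
    for chrom, length in chroms.items():
        lines.append(f"##contig=<ID={chrom},length={length}>")
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(sample_names)
    )
    for s in sites:
        info = f"EFF={s.annotation}" if s.annotation else "."
        fields = [
            s.chrom,
            str(s.pos),
            ".",
            s.ref_allele,
            s.alt_allele,
            f"{s.variant_quality:g}",
            "PASS",
            info,
            "GT:AD:DP:GQ",
        ]
        for name in sample_names:
            c = s.samples[name]
            if c.genotype is None:
                gt = "./."
            else:
                gt = f"{c.genotype[0]}/{c.genotype[1]}"
            fields.append(f"{gt}:{c.ad_ref},{c.ad_alt}:{c.depth}:{c.gq:.0f}")
        lines.append("\t".join(fields))
    Path(path).write_text("\n".join(lines) + "\n")
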