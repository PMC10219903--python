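"""Synthetic bulked-segregant data with the structure the pipeline assumes.

Emulates a doubled-haploid (DH) wheat population segregating a single
large-effect pith-thickness locus:

* DH genotypes — every line is one recombinant gamete, fully homozygous,
  with recombination between adjacent markers from the Haldane map
  function at a uniform cM/Mb rate;
* phenotypes — a single additive locus plus Gaussian environmental noise,
  which at a large effect size produces the bimodal pith-index
  distribution expected for monogenic inheritance;
* bulk sequencing — Poisson site depth and binomial sampling of the
  bulk allele frequency with a small per-read miscall rate, written as a
  four-sample VCF (two parents, two bulks);
* expression — negative-binomial counts for the four samples (two
  parents, two bulks) with three replicates each and planted log2 fold
  changes;
* marker templates — two synthetic promoter alleles differing by a
  constructed 309-bp insertion, with matching dominant and codominant
  PCR assays.

All draws flow from one ``numpy`` Generator seeded from the config, so a
given config yields byte-identical output files.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .markers import MarkerAssay
from .phenotyping import PhenotypeRecord, compute_pith_index, grade_pith
from .variant_filtering import SampleCall, VariantSite, write_vcf

__all__ = [
    "SimConfig",
    "GenotypeMatrix",
    "ExpressionSimSpec",
    "PlantedDeg",
    "simulate_dh_population",
    "simulate_phenotypes",
    "simulate_bulk_allele_counts",
    "simulate_expression_counts",
    "simulate_gene_annotation",
    "annotate_sites",
    "simulate_marker_templates",
    "haldane",
    "SAMPLE_NAMES",
    "DEFAULT_ROLES",
]

#: sample naming: W = high-PT parent, K = low-PT parent (reference),
#: S = solid (high-PT) bulk, H = hollow (low-PT) bulk
SAMPLE_NAMES = ("W", "K", "S", "H")
DEFAULT_ROLES = {
    "parent_high": "W",
    "parent_low": "K",
    "bulk_high": "S",
    "bulk_low": "H",
}


def haldane(distance_morgans: float) -> float:
    """Recombination fraction for a map distance via the Haldane function."""
    return 0.5 * (1.0 - np.exp(-2.0 * distance_morgans))


def _default_marker_positions(chrom_lengths, spacing=1_000_000):
    return {
        chrom: list(range(spacing, length + 1, spacing))
        for chrom, length in chrom_lengths.items()
    }


@dataclass
class SimConfig:
    """Study design and noise parameters for the synthetic population.

    Defaults mirror a 225-line DH population with a single large-effect
    pith locus, bulk size 20 and ~8x bulk sequencing depth; parental PI
    means sit near 0.58 (solid parent) and 0.24 (hollow parent).
    """

    n_lines: int = 225
    chrom_lengths: dict[str, int] = field(
        default_factory=lambda: {"3B": 830_000_000}
    )
    #: per-chromosome sorted 1-based bp positions of parental SNPs;
    #: derived at 1 Mb spacing when not given
    marker_positions: dict[str, list[int]] | None = None
    qtl_chrom: str = "3B"
    qtl_pos: int = 821_500_000
    qtl_effect: float = 0.68  # additive effect on pith thickness, mm
    base_pt: float = 0.48  # pith thickness of the low-allele class, mm
    noise_sd: float = 0.06  # environmental SD of pith thickness, mm
    diam_mean: float = 4.0  # stem diameter mean, mm
    diam_sd: float = 0.2
    mean_depth: float = 8.0  # expected reads per site per bulk
    base_error: float = 0.001  # per-read allele miscall probability
    bulk_size: int = 20
    n_replicates: int = 3
    cm_per_mb: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.marker_positions is None:
            self.marker_positions = _default_marker_positions(self.chrom_lengths)
        if self.n_lines < 2 * self.bulk_size:
            raise ValueError(
                f"n_lines ({self.n_lines}) must be >= twice the bulk size "
                f"({self.bulk_size})"
            )
        if self.qtl_chrom not in self.chrom_lengths:
            raise ValueError(f"qtl_chrom {self.qtl_chrom!r} not in chrom_lengths")
        if not 1 <= self.qtl_pos <= self.chrom_lengths[self.qtl_chrom]:
            raise ValueError("qtl_pos outside its chromosome")
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be positive")
        if not 0 <= self.base_error < 0.5:
            raise ValueError("base_error must lie in [0, 0.5)")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass
class GenotypeMatrix:
    """DH line genotypes: lines x markers, entries 0/1 (1 = high-PT parent allele)."""

    line_ids: list[str]
    chroms: np.ndarray  # per-marker chromosome, sorted by (chrom, pos)
    positions: np.ndarray  # per-marker 1-based bp
    genotypes: np.ndarray  # (n_lines, n_markers) int8 in {0, 1}

    @property
    def n_lines(self) -> int:
        return len(self.line_ids)

    @property
    def n_markers(self) -> int:
        return len(self.positions)

    def line_index(self, line_id: str) -> int:
        return self.line_ids.index(line_id)

    def nearest_marker(self, chrom: str, pos: int) -> int:
        """Index of the marker on ``chrom`` closest to ``pos``."""
        on_chrom = np.flatnonzero(self.chroms == chrom)
        if on_chrom.size == 0:
            raise ValueError(f"no markers on chromosome {chrom!r}")
        return int(on_chrom[np.argmin(np.abs(self.positions[on_chrom] - pos))])


def simulate_dh_population(
    cfg: SimConfig, rng: np.random.Generator | None = None
) -> GenotypeMatrix:
    """Draw ``cfg.n_lines`` independent DH gametes.

    The allele at the first marker of each chromosome is Bernoulli(0.5);
    between adjacent markers a crossover occurs with the Haldane
    recombination fraction for the physical gap at ``cfg.cm_per_mb``.
    """
    rng = cfg.rng() if rng is None else rng
    chrom_blocks = []
    chrom_names = []
    pos_all = []
    for chrom in cfg.chrom_lengths:
        pos = np.asarray(cfg.marker_positions.get(chrom, []), dtype=np.int64)
        if pos.size == 0:
            continue
        if np.any(np.diff(pos) < 0):
            raise ValueError(f"marker positions on chromosome {chrom!r} are not sorted")
        first = rng.random(cfg.n_lines) < 0.5
        if pos.size > 1:
            gaps_morgan = np.diff(pos) * cfg.cm_per_mb / 1e6 / 100.0
            r = haldane(gaps_morgan)
            switches = rng.random((cfg.n_lines, pos.size - 1)) < r
            parity = np.cumsum(switches, axis=1) % 2
            block = np.concatenate(
                [first[:, None], first[:, None] ^ parity.astype(bool)], axis=1
            )
        else:
            block = first[:, None]
        chrom_blocks.append(block.astype(np.int8))
        chrom_names.append(np.repeat(chrom, pos.size))
        pos_all.append(pos)
    if not chrom_blocks:
        raise ValueError("no markers defined on any chromosome")
    width = len(str(cfg.n_lines))
    return GenotypeMatrix(
        line_ids=[f"DH{i + 1:0{width}d}" for i in range(cfg.n_lines)],
        chroms=np.concatenate(chrom_names),
        positions=np.concatenate(pos_all),
        genotypes=np.concatenate(chrom_blocks, axis=1),
    )


def simulate_phenotypes(
    geno: GenotypeMatrix, cfg: SimConfig, rng: np.random.Generator | None = None
) -> list[PhenotypeRecord]:
    """Single additive locus model: PT = base + effect * g + N(0, noise_sd).

    The causal genotype is read from the marker nearest ``cfg.qtl_pos``.
    Stem diameter is Gaussian truncated positive; PI is computed from the
    simulated measurements and clamped to [0, 1].
    """
    rng = cfg.rng() if rng is None else rng
    g = geno.genotypes[:, geno.nearest_marker(cfg.qtl_chrom, cfg.qtl_pos)]
    pt = cfg.base_pt + cfg.qtl_effect * g + rng.normal(0.0, cfg.noise_sd, geno.n_lines)
    diam = rng.normal(cfg.diam_mean, cfg.diam_sd, geno.n_lines)
    while np.any(diam <= 0):  # truncate positive by redrawing
        bad = diam <= 0
        diam[bad] = rng.normal(cfg.diam_mean, cfg.diam_sd, int(bad.sum()))
    pt = np.clip(pt, 0.0, diam / 2.0)
    records = []
    for i, line_id in enumerate(geno.line_ids):
        pi = compute_pith_index(float(pt[i]), float(diam[i]))
        records.append(
            PhenotypeRecord(line_id, float(pt[i]), float(diam[i]), pi, grade_pith(pi))
        )
    return records


def simulate_bulk_allele_counts(
    geno: GenotypeMatrix,
    bulk_line_ids_high: list[str],
    bulk_line_ids_low: list[str],
    cfg: SimConfig,
    rng: np.random.Generator | None = None,
    vcf_path=None,
) -> list[VariantSite]:
    """Binomial read sampling of the two bulks' allele frequencies.

    At each marker the true bulk frequency of the high-parent allele is
    the mean of the 0/1 genotypes over the bulk's lines; observed depth
    is Poisson(``mean_depth``) and the high-parent read count is
    Binomial(depth, f(1-e) + (1-f)e).  Parents are emitted as homozygous
    opposite genotypes (REF = low-PT parent allele).  When ``vcf_path``
    is given the sites are also written as a four-sample VCF.
    """
    rng = cfg.rng() if rng is None else rng
    if not bulk_line_ids_high or not bulk_line_ids_low:
        raise ValueError("bulks must be non-empty")
    if set(bulk_line_ids_high) & set(bulk_line_ids_low):
        raise ValueError("bulks must be disjoint")
    idx_hi = [geno.line_index(l) for l in bulk_line_ids_high]
    idx_lo = [geno.line_index(l) for l in bulk_line_ids_low]

    f_hi = geno.genotypes[idx_hi, :].mean(axis=0)
    f_lo = geno.genotypes[idx_lo, :].mean(axis=0)
    n = geno.n_markers
    e = cfg.base_error
    bases = np.array(list("ACGT"))
    ref_idx = rng.integers(0, 4, n)
    alt_idx = (ref_idx + rng.integers(1, 4, n)) % 4

    sites: list[VariantSite] = []
    w, k, s, h = SAMPLE_NAMES
    for j in range(n):
        depth_s = int(rng.poisson(cfg.mean_depth))
        depth_h = int(rng.poisson(cfg.mean_depth))
        p_s = f_hi[j] * (1 - e) + (1 - f_hi[j]) * e
        p_h = f_lo[j] * (1 - e) + (1 - f_lo[j]) * e
        alt_s = int(rng.binomial(depth_s, p_s)) if depth_s else 0
        alt_h = int(rng.binomial(depth_h, p_h)) if depth_h else 0
        depth_w = int(rng.poisson(cfg.mean_depth))
        depth_k = int(rng.poisson(cfg.mean_depth))

        def bulk_call(alt: int, depth: int) -> SampleCall:
            frac = alt / depth if depth else 0.5
            gt = (1, 1) if frac > 0.9 else (0, 0) if frac < 0.1 else (0, 1)
            return SampleCall(gt, depth, depth - alt, alt, 99.0)

        sites.append(
            VariantSite(
                chrom=str(geno.chroms[j]),
                pos=int(geno.positions[j]),
                ref_allele=str(bases[ref_idx[j]]),
                alt_allele=str(bases[alt_idx[j]]),
                variant_quality=200.0,
                samples={
                    w: SampleCall((1, 1), depth_w, 0, depth_w, 99.0),
                    k: SampleCall((0, 0), depth_k, depth_k, 0, 99.0),
                    s: bulk_call(alt_s, depth_s),
                    h: bulk_call(alt_h, depth_h),
                },
            )
        )
    if vcf_path is not None:
        write_vcf(sites, vcf_path, list(SAMPLE_NAMES), cfg.chrom_lengths)
    return sites


# ---------------------------------------------------------------------------
# expression counts


@dataclass
class PlantedDeg:
    """A gene with a planted log2 fold change (solid over hollow samples).

    ``concordant`` genes carry the fold change in both the parent (W vs K)
    and bulk (S vs H) comparison; discordant ones only in the parents.
    """

    gene_index: int
    log2fc: float
    concordant: bool = True


@dataclass
class ExpressionSimSpec:
    """Negative-binomial expression design: 4 samples x 3 replicates."""

    n_genes: int = 2000
    gene_lengths: np.ndarray | None = None  # bp; drawn U(500, 5000) if None
    baseline_mean: float = 200.0  # NB mean count per replicate
    dispersion: float = 200.0  # NB size; larger = closer to Poisson
    planted_degs: list[PlantedDeg] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")
        if self.gene_lengths is not None:
            self.gene_lengths = np.asarray(self.gene_lengths)
            if np.any(self.gene_lengths <= 0):
                raise ValueError("gene lengths must be positive")
            if len(self.gene_lengths) != self.n_genes:
                raise ValueError("gene_lengths must have n_genes entries")


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, size_param: float):
    if size_param > 1e6:  # Poisson limit
        return rng.poisson(mean)
    p = size_param / (size_param + mean)
    return rng.negative_binomial(size_param, p)


def simulate_expression_counts(
    spec: ExpressionSimSpec,
    cfg: SimConfig,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Counts for samples W, K, S, H with ``cfg.n_replicates`` replicates each.

    Returns ``(counts, genes)``: counts indexed by gene id with columns
    like ``W_1``; genes holds id, chrom, start, end and length (synthetic
    coordinates laid end-to-end along the first chromosome).
    """
    rng = cfg.rng() if rng is None else rng
    lengths = spec.gene_lengths
    if lengths is None:
        lengths = rng.integers(500, 5001, spec.n_genes)
    # per-sample library size factors around 1
    samples = [f"{s}_{r + 1}" for s in SAMPLE_NAMES for r in range(cfg.n_replicates)]
    size_factors = rng.uniform(0.8, 1.2, len(samples))

    log2fc = np.zeros(spec.n_genes)
    concordant = np.zeros(spec.n_genes, dtype=bool)
    for deg in spec.planted_degs:
        log2fc[deg.gene_index] = deg.log2fc
        concordant[deg.gene_index] = deg.concordant

    base = np.full(spec.n_genes, spec.baseline_mean)
    # fold change applied to the solid-phenotype member of each comparison
    mean_by_sample = {
        "W": base * 2.0**log2fc,
        "K": base,
        "S": np.where(concordant, base * 2.0**log2fc, base),
        "H": base,
    }
    counts = np.empty((spec.n_genes, len(samples)), dtype=np.int64)
    for jcol, (sample, sf) in enumerate(zip(samples, size_factors)):
        group = sample.split("_")[0]
        counts[:, jcol] = _nb_draw(rng, mean_by_sample[group] * sf, spec.dispersion)

    gene_ids = [f"gene{i + 1:05d}" for i in range(spec.n_genes)]
    counts_df = pd.DataFrame(counts, index=pd.Index(gene_ids, name="gene_id"), columns=samples)
    first_chrom = next(iter(cfg.chrom_lengths))
    starts = np.concatenate([[1], np.cumsum(lengths)[:-1] + 1]).astype(np.int64)
    genes_df = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "chrom": first_chrom,
            "start": starts,
            "end": starts + np.asarray(lengths) - 1,
            "length": np.asarray(lengths),
        }
    )
    return counts_df, genes_df


def simulate_gene_annotation(
    cfg: SimConfig,
    n_genes: int,
    rng: np.random.Generator | None = None,
    gene_length: int = 3000,
) -> pd.DataFrame:
    """Uniformly placed non-overlapping-ish gene models across the genome."""
    rng = cfg.rng() if rng is None else rng
    rows = []
    total = sum(cfg.chrom_lengths.values())
    i = 0
    for chrom, length in cfg.chrom_lengths.items():
        k = max(1, round(n_genes * length / total))
        starts = np.sort(rng.integers(1, max(2, length - gene_length), k))
        for s in starts:
            i += 1
            rows.append((f"gene{i:05d}", chrom, int(s), int(s) + gene_length - 1, gene_length))
    return pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end", "length"])


def annotate_sites(sites: list[VariantSite], genes: pd.DataFrame) -> None:
    """Mark sites falling inside a gene model as exonic (in place)."""
    by_chrom = {c: g for c, g in genes.groupby("chrom")}
    for site in sites:
        g = by_chrom.get(site.chrom)
        if g is None:
            continue
        hit = (g["start"] <= site.pos) & (site.pos <= g["end"])
        if hit.any():
            site.annotation = "exonic"


# ---------------------------------------------------------------------------
# marker templates

#: constructed promoter indel: length and distance upstream of the start codon
PROMOTER_INSERTION_BP = 309
INSERTION_OFFSET_FROM_END = 284


def simulate_marker_templates(
    rng: np.random.Generator | None = None,
    promoter_length: int = 1000,
) -> tuple[dict[str, str], list[MarkerAssay], dict[str, str]]:
    """Two synthetic promoter alleles and their diagnostic PCR assays.

    Allele ``b`` (high-PT) carries a 309-bp insertion 284 bp upstream of
    the start codon; allele ``a`` lacks it.  Returns ``(templates,
    assays, truth)`` where templates maps allele name to sequence, assays
    holds one dominant (insertion-specific primer; product only from b)
    and one codominant assay (primers flanking the indel; 325 vs 634 bp
    products), and truth maps template name to allele letter.
    """
    rng = np.random.default_rng(7) if rng is None else rng
    bases = np.array(list("ACGT"))

    def draw(n: int) -> str:
        return "".join(rng.choice(bases, n))

    ins_at = promoter_length - INSERTION_OFFSET_FROM_END
    for _ in range(100):
        backbone = draw(promoter_length)
        insertion = draw(PROMOTER_INSERTION_BP)
        allele_a = backbone
        allele_b = backbone[:ins_at] + insertion + backbone[ins_at:]

        # codominant assay: primers flank the insertion point; product on
        # allele a is 325 bp, on allele b 325 + 309 = 634 bp
        f_start = ins_at - 150
        fwd_co = allele_a[f_start : f_start + 22]
        rev_site = allele_a[f_start + 303 : f_start + 325]
        rev_co = _revcomp(rev_site)

        # dominant assay: forward primer inside the insertion, product 200 bp
        b_f = ins_at + 20
        fwd_dom = allele_b[b_f : b_f + 22]
        dom_product = 200
        rev_dom = _revcomp(allele_b[b_f + dom_product - 22 : b_f + dom_product])

        seqs = (allele_a, allele_b)
        primers = (fwd_co, rev_site, fwd_dom, allele_b[b_f + dom_product - 22 : b_f + dom_product])
        if all(_count_hits(s, p) <= 1 for s in seqs for p in primers):
            break
    else:  # pragma: no cover - vanishingly unlikely
        raise RuntimeError("could not construct unique primer sites")

    templates = {"TaVPE3cB.a": allele_a, "TaVPE3cB.b": allele_b}
    assays = [
        MarkerAssay(
            name="Qpt3B-F1/R1",
            forward_primer=fwd_dom,
            reverse_primer=rev_dom,
            mode="dominant",
            expected_products={"b": dom_product},
        ),
        MarkerAssay(
            name="Qpt3B-F2/R2",
            forward_primer=fwd_co,
            reverse_primer=rev_co,
            mode="codominant",
            expected_products={"a": 325, "b": 325 + PROMOTER_INSERTION_BP},
        ),
    ]
    truth = {"TaVPE3cB.a": "a", "TaVPE3cB.b": "b"}
    return templates, assays, truth


def _revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGTN", "TGCAN"))[::-1]


def _count_hits(template: str, primer: str) -> int:
    n = start = 0
    while True:
        i = template.find(primer, start)
        if i < 0:
            return n
        n += 1
        start = i + 1


# ---------------------------------------------------------------------------
# file writers


def write_counts(counts: pd.DataFrame, path) -> None:
    counts.to_csv(path, sep="\t")


def write_genes(genes: pd.DataFrame, path) -> None:
    genes.to_csv(path, sep="\t", index=False)


def write_templates_fasta(templates: dict[str, str], path) -> None:
    with open(path, "w") as fh:
        for name, seq in templates.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


def write_markers(assays: list[MarkerAssay], path) -> None:
    rows = [
        {
            "name": a.name,
            "forward_primer": a.forward_primer,
            "reverse_primer": a.reverse_primer,
            "mode": a.mode,
            "expected_products": ";".join(
                f"{allele}={size}" for allele, size in a.expected_products.items()
            ),
        }
        for a in assays
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_markers(path) -> list[MarkerAssay]:
    df = pd.read_csv(path, sep="\t")
    assays = []
    for row in df.itertuples(index=False):
        expected = {}
        if isinstance(row.expected_products, str):
            for part in row.expected_products.split(";"):
                allele, size = part.split("=")
                expected[allele] = int(size)
        assays.append(
            MarkerAssay(
                name=row.name,
                forward_primer=row.forward_primer,
                reverse_primer=row.reverse_primer,
                mode=row.mode,
                expected_products=expected,
            )
        )
    return assays
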