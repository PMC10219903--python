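# Methods

`pithmap` reimplements a bulked-segregant RNA-seq (BSR-seq) workflow for
mapping a large-effect wheat stem pith-thickness locus and nominating
candidate genes.  Because the original sequencing data are not deposited,
the package pairs every analysis stage with a synthetic-data generator
that reproduces the statistical structure the analysis assumes; all
quantitative claims the tests make are therefore claims about that
generative model, stated explicitly below.

## Phenotype layer

The pith-thickness index of a stem cross-section is

    PI = 2 * PT / D

with PT the radial pith thickness and D the outer stem diameter (both
mm), so PI = 1 for a solid stem and 0 for a fully hollow one.  The
five-grade rating uses equal-width PI bins (grade = min(5,
floor(PI/0.2) + 1)); the historical grading protocol does not publish
its bin edges, so equal-width bins keep the grade a pure, monotone
function of PI.  A 1e-9 nudge inside the floor keeps exact bin
boundaries (0.2, 0.4, ...) in the upper grade despite binary-float
division.

Extreme bulks are the top and bottom `k = 20` lines ranked by PI, ties
broken by line id.  Bulk selection refuses designs where the two bulks
are not separated in PI, since such bulks carry no mapping signal.

## Doubled-haploid population model

Each simulated line is one recombinant gamete, fully homozygous (a DH
population segregates 1:1 with no heterozygotes).  The allele at the
first marker of each chromosome is Bernoulli(1/2); between adjacent
markers a crossover occurs with the Haldane recombination fraction
r = (1 - e^(-2d))/2 for map distance d, at a uniform configurable
cM/Mb rate.  The package default is 1 cM/Mb; the scan benchmark design
uses 2 cM/Mb, anchored on the published fine-mapping of this locus
(3.0 cM corresponding to 1.43 Mb on distal 3BL, i.e. ~2.1 cM/Mb — the
distal segments of wheat chromosomes recombine far above the genome
average).

Phenotypes follow a single additive locus: PT = base + effect * g +
N(0, noise_sd), with stem diameter Gaussian truncated positive.
Defaults (base 0.48 mm, effect 0.68 mm, noise SD 0.06 mm, diameter
4.0 ± 0.2 mm) put the two genotype classes at PI ≈ 0.24 and 0.58 —
matching the reported parental ranges (0.22–0.27 hollow, 0.55–0.61
solid) — and produce the bimodal PI distribution expected for
monogenic inheritance.  With a large effect the model yields clean
bimodality; it does not attempt polygenic background variation or
genotype-by-year effects.

## Bulk sequencing model

At each parental SNP the true bulk frequency f of the high-parent
allele is the mean of the bulk's 0/1 genotypes.  Observed site depth is
Poisson(mean_depth) per sample (default 8, within the 6.84–9.93x range
reported for these libraries) and the high-parent read count is
Binomial(depth, f(1-e) + (1-f)e) with per-read miscall probability
e = 0.001.  Parents are emitted as homozygous opposite genotypes with
the low-PT parent as the reference allele.  Sites are written as a
four-sample VCFv4.2 with FORMAT GT:AD:DP:GQ — GQ is included beyond
the minimal GT:AD:DP because the SNP filter needs per-sample genotype
qualities.

## SNP filtering

A site is kept iff every sample has DP >= 5, site QUAL >= 50, every
sample GQ >= 20, and the parents are homozygous for different alleles.
The published "minimum quality score of 20" does not say whether it is
a base or genotype quality; a post-calling VCF carries GQ, so the
filter reads it as per-sample genotype quality (configurable).  The
depth rule can be restricted to the bulks.  Multiallelic records are
skipped (the scan operates on biallelic parental SNPs) and counted.
Rejections are tallied by the first failing rule so the tally sums to
the rejected count; the filter is idempotent and order-preserving.

## SNP-index scan

The SNP-index of a bulk at a site is the fraction of its reads carrying
the allele not matching the low-PT parent; delta = index(solid bulk) -
index(hollow bulk).  Sites with zero covering reads in a bulk are
excluded from windows.  Windows of 5 Mb step 50 kb are anchored at
multiples of the step from position 0, half-open, and carry the
unweighted mean delta of the SNPs inside; empty windows are excluded
from region calling.

Confidence thresholds come from simulating the null for a DH bulk at an
unlinked locus: bulk allele count ~ Binomial(bulk_size, 1/2), then a
binomial read draw at the observed depth, independently per bulk;
10 000 draws per depth, looked up per window by its rounded mean
depth.  At low depth the null delta lives on a lattice (multiples of
1/depth), so the band uses a nearest-tail quantile: among observed
support points, the one whose strict exceedance probability is closest
to the nominal tail (ties to the more extreme point).  For continuous
nulls this coincides with the ordinary empirical quantile; on discrete
nulls it keeps the realized two-sided exceedance near the nominal 1%
(the plain quantile can leave it at 0.3%).

Windows whose mean exceeds the upper 99% band are merged into candidate
regions.  Flagged runs separated by less than one window width are
treated as a single signal — one noisy 5 Mb stretch of SNPs suppresses
a full window-width of flagged starts, so sub-window gaps are scan
artifacts, not evidence of two loci.  The merged span is intersected
with the span of contributing SNPs so interval endpoints are variant
positions; lengths are reported in Mb to 2 decimals.  Two-sided bands
are computed (the 95% track is reported but not used for calling);
calling uses the upper band because the high-PT allele is oriented
positive.  The shortlist keeps sites with delta strictly above 0.74,
partitioned into exonic vs other when annotations are present.

With extreme bulks selected on a large-effect locus, the delta profile
decays along the chromosome roughly as e^(-2d) in map distance, so the
region above the band is intrinsically tens of cM wide with ragged
edges, and the transition zone can shed small satellite regions.  The
scan therefore exposes both readouts: the full region list, and the
primary region — the one containing the genome-wide top window — which
is the single-candidate readout used in recovery experiments.

## Expression layer

FPKM = count * 1e9 / (length * library size).  A gene is a DEG in one
comparison when |log2FC| >= 1 and BH FDR < 0.001; log2FC uses
group-mean FPKM with a pseudo-count of 1 (bounds fold changes for
zeros).  Evidence p-values come from a moderated t on log2(FPKM+1)
replicate values: per-gene pooled variances are shrunk toward the
across-gene mean variance with 20 prior df, limma-style, and referred
to a t with (prior + residual) df.  With three replicates a raw
per-gene variance has 4 df and cannot clear a 1e-3 FDR even for strong
true effects; moderation borrows strength across genes exactly as the
field's standard tools do.  A plain Welch t remains available
(`test="welch"`).  The moderation assumes variances are exchangeable
across genes on the log scale; data with strongly mean-dependent
log-scale variance would need a trended prior, which is not
implemented.  Genes with zero FPKM everywhere in both groups are
excluded from testing.

Coexisting DEGs are genes significant with the same direction in both
the parent comparison (W vs K) and the bulk comparison (S vs H); they
partition into Scluster (up in solid samples) and Hcluster (up in
hollow samples).  The expression generator draws negative-binomial
counts (4 samples x 3 replicates) at a common baseline mean (200) with
NB size 200: the published replicates are library replicates of the
same pooled RNA, so only a small technical overdispersion on top of
Poisson is appropriate.  Planted DEGs multiply the solid-side mean by
2^log2FC, in both comparisons (concordant) or only the parent one.
Because all genes share the baseline mean, the generator does not probe
sensitivity at low expression; recovery results say nothing about genes
near the detection floor.

## Candidate integration

Genes overlapping the called region plus a 2 Mb flank ("adjacent
region" — several discussed candidates sit just outside the strict
interval; the exact span used originally is unstated) are crossed with
the coexisting DEG set and the SNP shortlist.  Expression categories
relative to a detection floor of mean FPKM 0.1 (safely below the 0.8
treated as low-abundance expression): expressed in only one sample,
or expressed in both and up in one; exactly equal means are "balanced"
and tier-excluded.  Tier 1 = coexisting DEG with >= 1 shortlist SNP in
its span, tier 2 = DEG only, tier 3 = SNP only; within tiers, sort by
|log2FC| descending then gene id.  The tier scheme mirrors the informal
evidence ordering of the original analysis (DEG+SNP > DEG > SNP).  A
site is "bulk-frequency consistent" when index(S) >= 1 - tol and
index(H) <= tol (default tol 0.1), the ~100%/0% diagnostic pattern of
a causal variant.

## Marker layer

In-silico PCR uses perfect-match primer binding (IUPAC codes in primers
expand to their degenerate sets; template N never matches): forward
sites on the plus strand, reverse-complemented reverse primer sites
downstream, every pair within 5 kb reported, product length = reverse
3' end - forward 5' start.  No mismatch or thermodynamic model is
attempted — the assays modelled are presence/absence and size assays.
Dominant assays call the amplifying allele on any product; codominant
assays match product sizes within ±5 bp (a gel-resolution analog) of
the two expected lengths, ambiguous or unmatched -> missing.  The
synthetic promoter pair carries a constructed 309 bp insertion 284 bp
upstream of the start codon, with a codominant assay flanking it
(325 vs 634 bp products) and a dominant assay priming inside it.

Discrimination rates stratify lines at PI > 0.6 (expect allele b) and
PI < 0.4 (expect allele a), excluding missing calls, reported to 2
decimals.  Marker-phenotype association is a tie-corrected Spearman
correlation of the allele code (a=0, b=1) against PI.  Relative
expression follows 2^(-ddCt) with dCt = Ct_target - Ct_reference and
ddCt relative to a named calibrator.

## Benchmark experiment sizes

The reference scan design used by `pithmap.experiments` is two
150 Mb chromosomes (markers every 500 kb, 2 cM/Mb), the QTL
mid-chromosome on one of them, 225 lines, bulks of 20, depth 8, with
the full-scale 5 Mb / 50 kb windows — compact enough that 100
end-to-end replicates run in a few seconds while keeping per-window SNP
counts (~10) realistic for RNA-seq-derived SNP densities.  DEG
experiments use 1500 genes with 40 planted DEGs (|log2FC| uniform on
[2.5, 5], both signs, 25 concordant) over 3 rounds.  Null calibration
uses 10 000 threshold draws and 10 000 fresh draws.

## Known limitations

* The generator models one biallelic causal locus; multi-locus traits,
  segregation distortion and polyploid homoeolog interference are out
  of scope.
* SNP annotation is a single optional effect class; no functional
  scoring (e.g. deleteriousness prediction) is performed.
* The DE test is a stand-in: absolute DEG counts from the original
  libraries are not reproducible targets, only the planted-truth
  operating characteristics checked by the tests.
* Thresholds are simulated per rounded depth, not per exact per-site
  depth pair; at the depths used the difference is below the
  Monte-Carlo resolution of the band.
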