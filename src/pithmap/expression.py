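"""FPKM normalisation, DEG calling and two-comparison intersection.

Expression is normalised as fragments per kilobase of transcript per
million mapped fragments (FPKM).  A gene is a significant DEG in one
comparison when |fold change| >= 2 (i.e. |log2FC| >= 1) at FDR < 0.001
(Benjamini-Hochberg).  Only genes called DEG with the same direction in
both the parent comparison (W vs K) and the bulk comparison (S vs H) are
treated as trait-related ("coexisting"); they partition into the solid
cluster (higher in high-pith samples) and hollow cluster (higher in
low-pith samples).

The evidence test behind the p-values runs on log2(FPKM + 1) replicate
values.  The default is a moderated t: per-gene pooled variances are
shrunk toward the across-gene mean variance with a fixed prior degrees
of freedom, in the spirit of limma's empirical-Bayes moderation — with
three replicates a per-gene variance estimate has far too few degrees
of freedom to clear a 1e-3 FDR on its own.  A plain Welch t is
available via ``test="welch"``.  The thresholds above, not the test,
define the DEG contract.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

log = logging.getLogger(__name__)

__all__ = [
    "compute_fpkm",
    "call_degs",
    "intersect_coexisting",
    "assign_clusters",
    "group_means",
    "EXPRESSION_FLOOR",
]

#: group-mean FPKM at or above which a gene counts as "expressed"
EXPRESSION_FLOOR = 0.1

UP_IN_SOLID = "up_in_solid"
UP_IN_HOLLOW = "up_in_hollow"


def compute_fpkm(counts: pd.DataFrame, gene_lengths: pd.Series) -> pd.DataFrame:
    """FPKM = count * 1e9 / (length_bp * library_size), per sample column.

    ``counts`` is genes x samples; ``gene_lengths`` (bp) is aligned on the
    counts index.  Raises on a zero library or a non-positive length.
    """
    lengths = gene_lengths.reindex(counts.index)
    if lengths.isna().any():
        missing = counts.index[lengths.isna()][:5].tolist()
        raise ValueError(f"gene lengths missing for {missing} ...")
    if (lengths <= 0).any():
        raise ValueError("gene lengths must be positive")
    lib = counts.sum(axis=0)
    if (lib == 0).any():
        empty = lib.index[lib == 0].tolist()
        raise ValueError(f"zero library size in sample(s) {empty}")
    return counts * 1e9 / np.outer(lengths.to_numpy(), lib.to_numpy())


def group_means(fpkm: pd.DataFrame, columns: list[str]) -> pd.Series:
    return fpkm[columns].mean(axis=1)


#: prior degrees of freedom for the moderated variance estimate
MODERATION_PRIOR_DF = 20.0


def _moderated_t_pvalues(xs: np.ndarray, ys: np.ndarray) -> np.ndarray:
    """Two-sample test with empirical-Bayes variance moderation.

    Per-gene pooled variances are shrunk toward their across-gene mean
    with ``MODERATION_PRIOR_DF`` prior df; the t statistic is referred
    to a t distribution with (prior + residual) df.  With few replicates
    this borrows strength across genes exactly as limma does.
    """
    n1, n2 = xs.shape[1], ys.shape[1]
    df_resid = n1 + n2 - 2
    diff = xs.mean(axis=1) - ys.mean(axis=1)
    s2 = (xs.var(axis=1, ddof=1) * (n1 - 1) + ys.var(axis=1, ddof=1) * (n2 - 1)) / df_resid
    s2_prior = float(np.mean(s2[np.isfinite(s2)])) if np.isfinite(s2).any() else 0.0
    s2_prior = max(s2_prior, 1e-12)
    s2_tilde = (MODERATION_PRIOR_DF * s2_prior + df_resid * s2) / (
        MODERATION_PRIOR_DF + df_resid
    )
    se = np.sqrt(s2_tilde * (1.0 / n1 + 1.0 / n2))
    with np.errstate(invalid="ignore", divide="ignore"):
        t = diff / se
    p = 2.0 * stats.t.sf(np.abs(t), MODERATION_PRIOR_DF + df_resid)
    return np.where(np.isfinite(p), p, 1.0)


def call_degs(
    fpkm: pd.DataFrame,
    high_cols: list[str],
    low_cols: list[str],
    comparison: str,
    fdr_threshold: float = 0.001,
    min_abs_log2fc: float = 1.0,
    test: str = "moderated",
) -> pd.DataFrame:
    """Per-gene DEG calls for one comparison.

    ``high_cols``/``low_cols`` are the replicate FPKM columns of the
    high-pith and low-pith member of the comparison.  log2FC is taken on
    group-mean FPKM with a pseudo-count of 1; the p-value comes from a
    moderated t (default) or a Welch t (``test="welch"``) on
    log2(FPKM + 1) replicate values; FDR is Benjamini-Hochberg across
    all tested genes.  Genes with zero FPKM in every replicate of both
    groups are excluded from testing (``tested`` False) and logged.

    Returns a frame with gene_id, comparison, log2fc, p_value, fdr,
    is_deg, direction, tested, and the two group means.
    """
    if len(high_cols) < 2 or len(low_cols) < 2:
        raise ValueError("need >= 2 replicates per group for the dispersion estimate")
    if test not in ("moderated", "welch"):
        raise ValueError("test must be 'moderated' or 'welch'")
    mean_high = group_means(fpkm, high_cols)
    mean_low = group_means(fpkm, low_cols)
    log2fc = np.log2((mean_high + 1.0) / (mean_low + 1.0))

    tested = ~((fpkm[high_cols].eq(0).all(axis=1)) & (fpkm[low_cols].eq(0).all(axis=1)))
    if (~tested).any():
        log.info(
            "%s: excluded %d gene(s) unexpressed in both groups",
            comparison,
            int((~tested).sum()),
        )
    xs = np.log2(fpkm[high_cols].to_numpy() + 1.0)
    ys = np.log2(fpkm[low_cols].to_numpy() + 1.0)
    if test == "moderated":
        pvals = _moderated_t_pvalues(xs, ys)
    else:
        with np.errstate(invalid="ignore", divide="ignore"):
            _, pvals = stats.ttest_ind(xs, ys, axis=1, equal_var=False)
        pvals = np.where(np.isfinite(pvals), pvals, 1.0)  # zero-variance ties

    fdr = np.full(len(fpkm), np.nan)
    mask = tested.to_numpy()
    if mask.any():
        fdr[mask] = multipletests(pvals[mask], method="fdr_bh")[1]

    is_deg = tested.to_numpy() & (np.abs(log2fc) >= min_abs_log2fc) & (fdr < fdr_threshold)
    direction = np.where(log2fc > 0, UP_IN_SOLID, UP_IN_HOLLOW)
    return pd.DataFrame(
        {
            "gene_id": fpkm.index,
            "comparison": comparison,
            "log2fc": log2fc.to_numpy(),
            "p_value": pvals,
            "fdr": fdr,
            "is_deg": is_deg,
            "direction": direction,
            "tested": tested.to_numpy(),
            "mean_high": mean_high.to_numpy(),
            "mean_low": mean_low.to_numpy(),
        }
    ).set_index("gene_id")


def intersect_coexisting(calls_wk: pd.DataFrame, calls_sh: pd.DataFrame) -> pd.DataFrame:
    """Genes called DEG with the same direction in both comparisons.

    Both frames must cover the same gene universe.  The result carries
    per-comparison log2FCs and the shared direction.
    """
    if not calls_wk.index.equals(calls_sh.index):
        raise ValueError("the two comparisons must cover the same gene universe")
    both = (
        calls_wk["is_deg"]
        & calls_sh["is_deg"]
        & (calls_wk["direction"] == calls_sh["direction"])
    )
    out = pd.DataFrame(
        {
            "log2fc_wk": calls_wk.loc[both, "log2fc"],
            "log2fc_sh": calls_sh.loc[both, "log2fc"],
            "direction": calls_wk.loc[both, "direction"],
        }
    )
    log.info("coexisting DEGs: %d", len(out))
    return out


def assign_clusters(coexisting: pd.DataFrame) -> pd.DataFrame:
    """Partition coexisting DEGs into the solid and hollow clusters.

    Scluster = consistently higher in high-pith samples (up_in_solid);
    Hcluster = consistently higher in low-pith samples.
    """
    out = coexisting.copy()
    out["cluster"] = np.where(
        out["direction"] == UP_IN_SOLID, "Scluster", "Hcluster"
    )
    return out
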