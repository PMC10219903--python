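"""Allele-specific PCR markers: in-silico genotyping, association, qPCR.

A dominant marker scores presence/absence of a product (the primer sits
on allele-specific sequence, e.g. inside a promoter insertion); a
codominant marker amplifies both alleles but yields distinguishable
product sizes across an indel.  Genotype calls are joined to the pith
index for discrimination rates and a tie-corrected Spearman rank
correlation.  Relative expression from qPCR follows the 2^-ddCt method.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

__all__ = [
    "MarkerAssay",
    "GenotypeCall",
    "insilico_pcr",
    "genotype_line",
    "discrimination_rate",
    "marker_phenotype_correlation",
    "relative_expression",
]

# IUPAC nucleotide codes and the bases each matches; template N never
# matches because N is not included in any expansion
_IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT",
}
_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _primer_regex(primer: str) -> re.Pattern:
    try:
        body = "".join(
            f"[{_IUPAC[base]}]" if len(_IUPAC[base]) > 1 else _IUPAC[base]
            for base in primer
        )
    except KeyError as exc:
        raise ValueError(
            f"primer {primer!r} contains non-IUPAC character {exc.args[0]!r}"
        ) from None
    return re.compile(f"(?=({body}))")  # lookahead: overlapping matches


@dataclass
class MarkerAssay:
    """One allele-specific PCR assay."""

    name: str
    forward_primer: str
    reverse_primer: str
    mode: str  # "dominant" or "codominant"
    #: expected product length per allele; dominant assays list only the
    #: amplifying allele (the other allele gives no product)
    expected_products: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.forward_primer or not self.reverse_primer:
            raise ValueError(f"{self.name}: primers must be non-empty")
        if self.mode not in ("dominant", "codominant"):
            raise ValueError(f"{self.name}: mode must be dominant or codominant")
        if self.mode == "codominant":
            if len(set(self.expected_products.values())) < 2:
                raise ValueError(
                    f"{self.name}: codominant assay needs two distinct product sizes"
                )
        self.forward_primer = self.forward_primer.upper()
        self.reverse_primer = self.reverse_primer.upper()


@dataclass
class GenotypeCall:
    line_id: str
    allele: str  # "a", "b" or "missing"


def insilico_pcr(template: str, assay: MarkerAssay, max_product: int = 5000) -> list[int]:
    """Predict amplicon lengths from perfect-match primer binding.

    The forward primer binds the plus strand; the reverse primer binds the
    minus strand, i.e. its reverse complement is searched on the template.
    Every forward-site x downstream reverse-site pair spanning at most
    ``max_product`` bp is reported; product length is the distance from
    the forward site's 5' start to the reverse site's 3' end.
    """
    template = template.upper()
    fwd = _primer_regex(assay.forward_primer)
    rev = _primer_regex(_revcomp(assay.reverse_primer))
    f_starts = [m.start() for m in fwd.finditer(template)]
    r_ends = [m.start() + len(assay.reverse_primer) for m in rev.finditer(template)]
    min_len = max(len(assay.forward_primer), len(assay.reverse_primer))
    products = sorted(
        r_end - f_start
        for f_start in f_starts
        for r_end in r_ends
        if min_len <= r_end - f_start <= max_product
    )
    return products


def genotype_line(
    products: list[int], assay: MarkerAssay, size_tolerance: int = 5
) -> str:
    """Call an allele from observed product lengths.

    Dominant: any product -> the amplifying allele, none -> the other.
    Codominant: the product within ``size_tolerance`` bp of exactly one
    expected size gives that allele; ambiguous or unmatched -> missing.
    """
    if assay.mode == "dominant":
        amplifying = next(iter(assay.expected_products), "b")
        other = "a" if amplifying == "b" else "b"
        return amplifying if products else other
    matched = {
        allele
        for allele, size in assay.expected_products.items()
        if any(abs(p - size) <= size_tolerance for p in products)
    }
    return matched.pop() if len(matched) == 1 else "missing"


def discrimination_rate(
    calls: pd.DataFrame,
    phenotypes: pd.DataFrame,
    hi_cut: float = 0.6,
    lo_cut: float = 0.4,
) -> dict[str, float]:
    """Marker discrimination in the phenotypic extremes.

    ``high_rate`` is the percentage of lines with PI > ``hi_cut`` that
    carry allele b; ``low_rate`` the percentage of lines with PI <
    ``lo_cut`` carrying allele a.  Missing calls are excluded; an empty
    stratum yields NaN and a warning.  Rates are reported to 2 decimals.

    ``calls`` needs columns line_id/allele, ``phenotypes`` line_id/pi.
    """
    merged = calls.merge(phenotypes[["line_id", "pi"]], on="line_id")
    merged = merged[merged["allele"] != "missing"]
    out = {}
    for key, mask, allele in (
        ("high_rate", merged["pi"] > hi_cut, "b"),
        ("low_rate", merged["pi"] < lo_cut, "a"),
    ):
        stratum = merged[mask]
        if len(stratum) == 0:
            log.warning("empty %s stratum; rate undefined", key)
            out[key] = float("nan")
            out[f"n_{key.split('_')[0]}"] = 0
        else:
            out[key] = round(100.0 * (stratum["allele"] == allele).mean(), 2)
            out[f"n_{key.split('_')[0]}"] = int(len(stratum))
    return out


def marker_phenotype_correlation(
    calls: pd.DataFrame, phenotypes: pd.DataFrame
) -> tuple[float, float]:
    """Tie-corrected Spearman correlation of allele code (a=0, b=1) with PI."""
    merged = calls.merge(phenotypes[["line_id", "pi"]], on="line_id")
    merged = merged[merged["allele"].isin(["a", "b"])]
    codes = (merged["allele"] == "b").astype(float)
    if codes.nunique() < 2:
        raise ValueError("allele vector is constant; correlation undefined")
    rho, p = stats.spearmanr(codes, merged["pi"])
    return float(rho), float(p)


def relative_expression(
    measurements: pd.DataFrame, calibrator_id: str
) -> pd.DataFrame:
    """Relative expression by the 2^-ddCt method.

    ``measurements`` needs columns sample_id, ct_target, ct_reference.
    dCt = ct_target - ct_reference; ddCt is taken relative to the
    calibrator sample (whose relative expression is therefore exactly 1).
    Samples with a missing reference Ct are skipped with a log message.
    """
    df = measurements.copy()
    missing = df["ct_reference"].isna() | df["ct_target"].isna()
    if missing.any():
        log.info("skipping %d sample(s) with missing Ct", int(missing.sum()))
        df = df[~missing]
    if calibrator_id not in set(df["sample_id"]):
        raise ValueError(f"calibrator {calibrator_id!r} not among measured samples")
    df = df.copy()
    df["delta_ct"] = df["ct_target"] - df["ct_reference"]
    calibrator_dct = float(df.loc[df["sample_id"] == calibrator_id, "delta_ct"].mean())
    df["delta_delta_ct"] = df["delta_ct"] - calibrator_dct
    df["rel_expr"] = np.power(2.0, -df["delta_delta_ct"])
    return df
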