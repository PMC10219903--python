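"""Stem pith-thickness phenotyping.

The pith-thickness index (PI) of a wheat stem cross-section is

    PI = 2 * pith_thickness / stem_diameter

so that a fully solid stem (pith reaching the epidermis on both sides)
scores 1 and a fully hollow stem scores 0.  Lines are additionally rated
on a five-grade scale and the phenotypic extremes are pooled into a
solid bulk (high PI) and a hollow bulk (low PI) for bulked-segregant
sequencing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd

__all__ = [
    "PhenotypeRecord",
    "BulkDesign",
    "compute_pith_index",
    "grade_pith",
    "select_bulks",
    "read_phenotypes",
    "write_phenotypes",
    "records_to_frame",
    "frame_to_records",
]

#: width of one grade bin on the PI scale (five equal bins on [0, 1])
GRADE_BIN = 0.2

# nudge so exact bin boundaries (0.2, 0.4, ...) land in the upper grade
# despite binary-float division
_BIN_EPS = 1e-9


def compute_pith_index(pith_thickness: float, stem_diameter: float) -> float:
    """Pith-thickness index PI = 2 * PT / D, dimensionless in [0, 1].

    Parameters
    ----------
    pith_thickness
        Radial pith thickness in mm; must satisfy 0 <= PT <= D/2.
    stem_diameter
        Outer stem diameter in mm; must be positive.
    """
    if stem_diameter <= 0:
        raise ValueError(f"stem diameter must be positive, got {stem_diameter}")
    if pith_thickness < 0:
        raise ValueError(f"pith thickness must be non-negative, got {pith_thickness}")
    if pith_thickness > stem_diameter / 2 + 1e-9:
        raise ValueError(
            f"pith thickness {pith_thickness} exceeds the stem radius "
            f"{stem_diameter / 2} (physically impossible)"
        )
    return min(1.0, 2.0 * pith_thickness / stem_diameter)


def grade_pith(pi: float) -> int:
    """Five-grade pith rating from PI: equal-width bins, grade 1 = hollow.

    grade = min(5, floor(PI / 0.2) + 1), monotone in PI.
    """
    if not 0.0 <= pi <= 1.0:
        raise ValueError(f"PI must lie in [0, 1], got {pi}")
    return min(5, int(math.floor(pi / GRADE_BIN + _BIN_EPS)) + 1)


@dataclass
class PhenotypeRecord:
    """One line's stem phenotype: raw measurements plus derived PI and grade."""

    line_id: str
    pith_thickness: float  # mm
    stem_diameter: float  # mm
    pi: float
    grade: int

    def __post_init__(self) -> None:
        if self.stem_diameter <= 0:
            raise ValueError(f"{self.line_id}: stem diameter must be positive")
        expected = 2.0 * self.pith_thickness / self.stem_diameter
        if abs(min(1.0, expected) - self.pi) > 1e-9:
            raise ValueError(
                f"{self.line_id}: PI {self.pi} inconsistent with 2*PT/D = {expected}"
            )

    @classmethod
    def from_measurements(
        cls, line_id: str, pith_thickness: float, stem_diameter: float
    ) -> "PhenotypeRecord":
        pi = compute_pith_index(pith_thickness, stem_diameter)
        return cls(line_id, pith_thickness, stem_diameter, pi, grade_pith(pi))


@dataclass
class BulkDesign:
    """The two phenotypic extreme pools used for bulked-segregant sequencing."""

    high_bulk_ids: list[str] = field(default_factory=list)
    low_bulk_ids: list[str] = field(default_factory=list)
    high_pi_range: tuple[float, float] = (0.0, 0.0)  # (min, max) observed
    low_pi_range: tuple[float, float] = (0.0, 0.0)


def select_bulks(phenotypes: list[PhenotypeRecord], k: int = 20) -> BulkDesign:
    """Pick the top-k (solid bulk) and bottom-k (hollow bulk) lines by PI.

    Ties are broken by lexicographic line id so the selection is fully
    deterministic.  Raises if fewer than ``2 * k`` lines are available or if
    the two bulks would not be separated in PI (uninformative design).
    """
    if k < 1:
        raise ValueError("bulk size k must be >= 1")
    if len(phenotypes) < 2 * k:
        raise ValueError(
            f"need at least {2 * k} phenotyped lines to build two bulks of {k}, "
            f"got {len(phenotypes)}"
        )
    by_high = sorted(phenotypes, key=lambda r: (-r.pi, r.line_id))
    by_low = sorted(phenotypes, key=lambda r: (r.pi, r.line_id))
    high = by_high[:k]
    low = by_low[:k]
    high_pis = [r.pi for r in high]
    low_pis = [r.pi for r in low]
    if min(high_pis) <= max(low_pis):
        raise ValueError(
            "bulks are not separated in PI (min high-bulk PI "
            f"{min(high_pis):.3f} <= max low-bulk PI {max(low_pis):.3f}); "
            "the design is uninformative"
        )
    return BulkDesign(
        high_bulk_ids=[r.line_id for r in high],
        low_bulk_ids=[r.line_id for r in low],
        high_pi_range=(min(high_pis), max(high_pis)),
        low_pi_range=(min(low_pis), max(low_pis)),
    )


def records_to_frame(phenotypes: list[PhenotypeRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "line_id": [r.line_id for r in phenotypes],
            "pith_thickness": [r.pith_thickness for r in phenotypes],
            "stem_diameter": [r.stem_diameter for r in phenotypes],
            "pi": [r.pi for r in phenotypes],
            "grade": [r.grade for r in phenotypes],
        }
    )


def frame_to_records(df: pd.DataFrame) -> list[PhenotypeRecord]:
    return [
        PhenotypeRecord(
            str(row.line_id),
            float(row.pith_thickness),
            float(row.stem_diameter),
            float(row.pi),
            int(row.grade),
        )
        for row in df.itertuples(index=False)
    ]


def write_phenotypes(phenotypes: list[PhenotypeRecord], path) -> None:
    records_to_frame(phenotypes).to_csv(path, sep="\t", index=False)


def read_phenotypes(path) -> list[PhenotypeRecord]:
    return frame_to_records(pd.read_csv(path, sep="\t"))
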