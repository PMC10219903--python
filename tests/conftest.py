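"""Shared fixtures: small synthetic datasets built at test time."""

from __future__ import annotations

import numpy as np
import pytest

from pithmap.synthetic_data import SimConfig


@pytest.fixture
def small_cfg() -> SimConfig:
    """A compact two-chromosome design with the QTL mid-chromosome."""
    length = 60_000_000
    return SimConfig(
        chrom_lengths={"3B": length, "1A": length},
        marker_positions={
            c: list(range(500_000, length + 1, 500_000)) for c in ("3B", "1A")
        },
        qtl_chrom="3B",
        qtl_pos=30_000_000,
        cm_per_mb=2.0,
        seed=42,
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240701)
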