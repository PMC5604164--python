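"""Relative qPCR validation of a transcriptome map.

The wet-lab readout is the threshold cycle Ct (mean of triplicates) per
gene. With a reference gene of intermediate expression, the *observed
ratio* between target and reference follows the 2^dCt rule:

    OR = 2^(Ct_reference - Ct_target)

assuming 100% amplification efficiency (the exponent base is exposed for
sensitivity checks). The *expected ratio* is the map's value for the
target divided by the map's value for the reference. Agreement between
the two, over a gene panel spanning the expression range, is summarized
by the Pearson correlation of the raw (ER, OR) pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .downstream import correlate_maps

__all__ = [
    "QPCRMeasurement",
    "ValidationReport",
    "observed_ratio",
    "expected_ratio",
    "validate",
]


@dataclass(frozen=True)
class QPCRMeasurement:
    """One gene's mean threshold cycle in the validation panel."""

    symbol: str
    ct_mean: float
    is_reference: bool = False


@dataclass
class ValidationReport:
    """Per-gene expected/observed ratios plus their correlation."""

    genes: pd.DataFrame  # symbol, map_value, expected_ratio, ct_mean, observed_ratio
    pearson_r: float
    p_value: float
    n_used: int
    excluded: list[str] = field(default_factory=list)


def observed_ratio(ct_target: float, ct_reference: float, base: float = 2.0) -> float:
    """Relative quantity of target vs reference from threshold cycles."""
    return float(base ** (ct_reference - ct_target))


def expected_ratio(map_value_target: float, map_value_reference: float) -> float:
    """Map-predicted target/reference expression ratio."""
    if map_value_target <= 0 or map_value_reference <= 0:
        raise ValueError("map values must be positive")
    return float(map_value_target / map_value_reference)


def validate(
    map_values: Mapping[str, float],
    qpcr_table: pd.DataFrame,
    reference: str,
    base: float = 2.0,
) -> ValidationReport:
    """Compare map-expected with qPCR-observed ratios across a gene panel.

    ``qpcr_table`` has columns symbol, ct_mean (NaN = undetectable).
    Genes with a missing Ct or absent from the map are excluded and
    reported; the reference gene must be present in both the map and the
    panel. The correlation includes every usable (ER, OR) pair — the
    reference contributes the anchor pair (1, 1).
    """
    if reference not in map_values:
        raise ValueError(f"reference gene {reference!r} missing from the map")
    ref_rows = qpcr_table[qpcr_table["symbol"] == reference]
    if ref_rows.empty or not np.isfinite(ref_rows["ct_mean"].iloc[0]):
        raise ValueError(f"reference gene {reference!r} has no usable Ct")
    ct_ref = float(ref_rows["ct_mean"].iloc[0])
    ref_value = float(map_values[reference])

    rows, excluded = [], []
    for row in qpcr_table.itertuples(index=False):
        if row.symbol not in map_values or not np.isfinite(row.ct_mean):
            excluded.append(row.symbol)
            continue
        mv = float(map_values[row.symbol])
        rows.append({
            "symbol": row.symbol,
            "map_value": mv,
            "expected_ratio": expected_ratio(mv, ref_value),
            "ct_mean": float(row.ct_mean),
            "observed_ratio": observed_ratio(float(row.ct_mean), ct_ref, base=base),
        })
    genes = pd.DataFrame(rows, columns=["symbol", "map_value", "expected_ratio",
                                        "ct_mean", "observed_ratio"])
    n_nonref = (genes["symbol"] != reference).sum()
    if n_nonref < 3:
        raise ValueError(
            f"need >= 3 non-reference genes with map and Ct values, got {n_nonref}"
        )
    r, p = correlate_maps(genes["expected_ratio"].to_numpy(),
                          genes["observed_ratio"].to_numpy())
    return ValidationReport(genes=genes, pearson_r=r, p_value=p,
                            n_used=len(genes), excluded=excluded)
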