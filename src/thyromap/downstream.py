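"""Secondary map analyses: housekeeping screen, phenotype association,
between-map correlation.

The housekeeping screen looks for loci that behave like stable reference
genes inside one map: expression above the genome mean (value > 100 on
the mean == 100 scale), measured in at least half the samples of the
pool, and with a standard deviation of at most 30% of the mean.

The phenotype-association test asks whether the most tissue-enriched
genes are more likely to carry a known mutant phenotype: among the top
2 x 25 known genes of a differential map sorted by descending A/B ratio,
it compares phenotype-flag counts of the first versus the second group
of 25 with a two-sided Fisher's exact test.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .map_builder import DifferentialRecord
from .normalization import LocusStats

__all__ = [
    "HousekeepingCriteria",
    "ContingencyResult",
    "find_housekeeping",
    "phenotype_association_test",
    "association_test_from_flags",
    "correlate_maps",
    "is_known_gene",
]

# EST-cluster / provisional-locus identifiers are not "known genes"
_UNKNOWN_PATTERN = re.compile(r"^(Hs\.|LOC)")


def is_known_gene(symbol: str) -> bool:
    """True for official gene symbols, False for EST clusters (Hs.*) / LOC*."""
    return _UNKNOWN_PATTERN.match(symbol) is None


@dataclass(frozen=True)
class HousekeepingCriteria:
    """Thresholds for the stable-reference-gene screen."""

    min_value: float = 100.0
    min_data_points: int | None = None  # default: ceil(n_samples / 2)
    max_sd_percent: float = 30.0


@dataclass
class ContingencyResult:
    """2x2 phenotype-association table and its Fisher p-value."""

    table: list[list[int]]
    p_value: float
    group_size: int = 25
    top_symbols: list[str] = field(default_factory=list)
    second_symbols: list[str] = field(default_factory=list)


def find_housekeeping(
    locus_stats: Sequence[LocusStats],
    n_samples: int,
    criteria: HousekeepingCriteria | None = None,
) -> list[LocusStats]:
    """Return loci passing all three stability thresholds, most stable first.

    Data-point support must reach half the pool's sample count (rounded
    up) unless the criteria override it; output is sorted by ascending
    sd_percent.
    """
    criteria = criteria or HousekeepingCriteria()
    min_dp = criteria.min_data_points
    if min_dp is None:
        min_dp = math.ceil(n_samples / 2)
    passing = [
        s for s in locus_stats
        if s.value > criteria.min_value
        and s.data_points >= min_dp
        and s.sd_percent <= criteria.max_sd_percent
    ]
    return sorted(passing, key=lambda s: (s.sd_percent, s.symbol))


def phenotype_association_test(
    differential: Sequence[DifferentialRecord],
    phenotype_flags: Mapping[str, bool],
    group_size: int = 25,
    min_dp: int = 5,
    max_sd_percent: float = 200.0,
    sd_filter_min_value: float = 50.0,
    known_only: bool = True,
) -> ContingencyResult:
    """Fisher test of phenotype enrichment among the top differential genes.

    Loci are filtered first: at least ``min_dp`` data points in both
    pools, and sd_percent below ``max_sd_percent`` in a pool whenever that
    pool's value exceeds ``sd_filter_min_value`` (high spread is tolerated
    only near the detection floor). Optionally only known genes (not
    EST clusters / LOC IDs) are ranked. The survivors are sorted by
    descending A/B ratio; the first ``group_size`` are compared with the
    next ``group_size`` on their phenotype-flag counts.
    """
    def passes(r: DifferentialRecord) -> bool:
        if r.data_points_a < min_dp or r.data_points_b < min_dp:
            return False
        if r.value_a > sd_filter_min_value and r.sd_percent_a >= max_sd_percent:
            return False
        if r.value_b > sd_filter_min_value and r.sd_percent_b >= max_sd_percent:
            return False
        if known_only and not is_known_gene(r.symbol):
            return False
        return True

    survivors = sorted((r for r in differential if passes(r)),
                       key=lambda r: -r.ratio)
    if len(survivors) < 2 * group_size:
        raise ValueError(
            f"need at least {2 * group_size} loci after filtering, "
            f"got {len(survivors)}"
        )
    top = [r.symbol for r in survivors[:group_size]]
    second = [r.symbol for r in survivors[group_size:2 * group_size]]
    return association_test_from_flags(top, second, phenotype_flags)


def association_test_from_flags(
    top_symbols: Sequence[str],
    second_symbols: Sequence[str],
    phenotype_flags: Mapping[str, bool],
) -> ContingencyResult:
    """Build the 2x2 (flagged/unflagged x top/second) table and test it."""
    a = sum(1 for s in top_symbols if phenotype_flags.get(s, False))
    c = sum(1 for s in second_symbols if phenotype_flags.get(s, False))
    table = [[a, len(top_symbols) - a], [c, len(second_symbols) - c]]
    _, p = stats.fisher_exact(table, alternative="two-sided")
    return ContingencyResult(
        table=table, p_value=float(p), group_size=len(top_symbols),
        top_symbols=list(top_symbols), second_symbols=list(second_symbols),
    )


def correlate_maps(
    values_x: Sequence[float],
    values_y: Sequence[float],
) -> tuple[float, float]:
    """Pearson correlation between two maps' paired per-locus values.

    Returns (r, two-sided p from the t distribution with n-2 d.f.).
    Raises on fewer than 3 pairs or zero variance in either vector.
    """
    x = np.asarray(values_x, dtype=np.float64)
    y = np.asarray(values_y, dtype=np.float64)
    if x.shape != y.shape:
        raise ValueError("paired value vectors must have equal length")
    if x.size < 3:
        raise ValueError("correlation needs at least 3 paired values")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance in one of the value vectors")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)
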