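"""Transcriptome-map construction: genomic segments and expression calls.

A map summarizes per-locus values (absolute reference values, or A/B
ratios in differential mode) over half-overlapping genomic windows —
500 kb wide with a 250 kb shift by default, or 12.5 kb in single-gene
mode. A window's value is the mean of its member loci; a locus belongs
to every window containing its start coordinate.

Loci in the highest or lowest 2.5th percentile of the genome-wide value
distribution are flagged *extreme*, and each window is tested for an
excess of extreme loci with the hypergeometric distribution (over- and
under-tails separately, each against its own genome-wide extreme count).
P-values are corrected across all non-empty windows of the map
(Benjamini-Hochberg by default) and a window is called over- or
underexpressed when q < 0.05 and it holds at least three extreme loci of
that sign (one in single-gene mode, where a dominance rule additionally
requires the extreme locus to contribute more than half the window's
summed expression).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .io import GeneLocus
from .normalization import LocusStats

__all__ = [
    "SegmentRecord",
    "DifferentialRecord",
    "segment_genome",
    "compute_segment_values",
    "flag_extreme_loci",
    "segment_enrichment_test",
    "call_segments",
    "differential_map",
    "filter_called_segments",
    "build_segment_map",
    "SINGLE_GENE_WINDOW_BP",
]

SINGLE_GENE_WINDOW_BP = 12_500


@dataclass
class SegmentRecord:
    """One genomic window of the map and its expression call."""

    chromosome: str
    start: int
    end: int
    members: list[str] = field(default_factory=list)
    value: float | None = None
    n_genes: int = 0
    n_extreme_high: int = 0
    n_extreme_low: int = 0
    p_value: float = float("nan")
    q_value: float = float("nan")
    call: str = "none"  # over | under | none


@dataclass(frozen=True)
class DifferentialRecord:
    """Per-locus two-pool comparison: reference values and their A/B ratio."""

    symbol: str
    value_a: float
    value_b: float
    ratio: float
    data_points_a: int
    data_points_b: int
    sd_percent_a: float
    sd_percent_b: float


# ---------------------------------------------------------------------------
# windows
# ---------------------------------------------------------------------------

def segment_genome(
    annotation: Mapping[str, GeneLocus],
    window_bp: int = 500_000,
    shift_bp: int = 250_000,
) -> list[SegmentRecord]:
    """Tile every chromosome with half-overlapping windows and assign loci.

    Windows on a chromosome are [k*shift + 1, k*shift + window] for
    k = 0, 1, ... while the window start does not pass the last gene end.
    A locus is a member of every window containing its start coordinate,
    so at 50% overlap each locus (beyond the first half-window) belongs to
    exactly two windows.
    """
    if not annotation:
        raise ValueError("empty annotation: nothing to segment")
    if window_bp % shift_bp != 0:
        raise ValueError(
            f"window_bp ({window_bp}) must be a multiple of shift_bp ({shift_bp})"
        )
    by_chrom: dict[str, list[GeneLocus]] = {}
    for locus in annotation.values():
        by_chrom.setdefault(locus.chromosome, []).append(locus)

    segments: list[SegmentRecord] = []
    for chrom in sorted(by_chrom):
        loci = sorted(by_chrom[chrom], key=lambda l: (l.start, l.symbol))
        last_end = max(l.end for l in loci)
        k = 0
        while k * shift_bp + 1 <= last_end:
            ws = k * shift_bp + 1
            we = k * shift_bp + window_bp
            members = [l.symbol for l in loci if ws <= l.start <= we]
            segments.append(SegmentRecord(chromosome=chrom, start=ws, end=we,
                                          members=members))
            k += 1
    return segments


def compute_segment_values(
    values: Mapping[str, float],
    segments: Sequence[SegmentRecord],
) -> list[SegmentRecord]:
    """Fill each segment's value with the mean over member loci.

    Only members with a value in ``values`` count; segments left with no
    valued member carry no value and are excluded from testing.
    """
    for seg in segments:
        member_vals = [values[s] for s in seg.members if s in values]
        seg.n_genes = len(member_vals)
        seg.value = float(np.mean(member_vals)) if member_vals else None
    return list(segments)


# ---------------------------------------------------------------------------
# extreme loci and enrichment
# ---------------------------------------------------------------------------

def flag_extreme_loci(
    values: Mapping[str, float],
    tail: float = 0.025,
) -> dict[str, str]:
    """Flag loci in the top/bottom ``tail`` of the genome-wide distribution.

    Thresholds are the empirical (linear-interpolation) quantiles; loci
    exactly at a threshold are included in the tail. If the two thresholds
    coincide (degenerate data) nothing is flagged.
    """
    symbols = list(values)
    vals = np.array([values[s] for s in symbols], dtype=np.float64)
    lo = float(np.quantile(vals, tail))
    hi = float(np.quantile(vals, 1.0 - tail))
    if lo == hi:
        return {s: "none" for s in symbols}
    flags = {}
    for s, v in zip(symbols, vals):
        if v >= hi:
            flags[s] = "high"
        elif v <= lo:
            flags[s] = "low"
        else:
            flags[s] = "none"
    return flags


def segment_enrichment_test(x: int, k: int, M: int, m: int) -> float:
    """Upper-tail hypergeometric probability of >= x extreme loci.

    X ~ Hypergeometric(population M loci, m extreme, k drawn into the
    segment); returns P(X >= x). Over- and under-tails are tested
    separately, each against its own m.
    """
    if m > M:
        raise ValueError(f"extreme count m={m} exceeds population M={M}")
    if x > k:
        raise ValueError(f"observed x={x} exceeds segment size k={k}")
    if x <= 0:
        return 1.0
    return float(hypergeom.sf(x - 1, M, m, k))


def call_segments(
    segments: Sequence[SegmentRecord],
    flags: Mapping[str, str],
    values: Mapping[str, float],
    min_extreme: int = 3,
    alpha: float = 0.05,
    correction: str = "bh",
    prevails_threshold: float = 0.5,
) -> list[SegmentRecord]:
    """Test every non-empty segment and call over/underexpression.

    Each segment's p-value is the smaller of its over- and under-tail
    hypergeometric probabilities (with that tail's direction); q-values
    come from correcting across all tested segments of the map. A call
    requires q < alpha and at least ``min_extreme`` extreme loci of the
    called sign. With ``min_extreme == 1`` (single-gene mode) a call is
    additionally retained only if the most-expressed extreme locus of that
    sign contributes more than ``prevails_threshold`` of the summed
    expression of all valued loci in the window.
    """
    M = len(values)
    m_high = sum(1 for s in values if flags.get(s) == "high")
    m_low = sum(1 for s in values if flags.get(s) == "low")

    tested = [seg for seg in segments if seg.n_genes > 0]
    directions: list[str] = []
    for seg in tested:
        members = [s for s in seg.members if s in values]
        seg.n_extreme_high = sum(1 for s in members if flags.get(s) == "high")
        seg.n_extreme_low = sum(1 for s in members if flags.get(s) == "low")
        p_over = segment_enrichment_test(seg.n_extreme_high, seg.n_genes, M, m_high)
        p_under = segment_enrichment_test(seg.n_extreme_low, seg.n_genes, M, m_low)
        if p_over <= p_under:
            seg.p_value, direction = p_over, "over"
        else:
            seg.p_value, direction = p_under, "under"
        directions.append(direction)

    if tested:
        method = {"bh": "fdr_bh", "bonferroni": "bonferroni"}.get(correction)
        if method is None:
            raise ValueError(f"unknown correction {correction!r}")
        _, q, _, _ = multipletests([seg.p_value for seg in tested], method=method)
        for seg, qv, direction in zip(tested, q, directions):
            seg.q_value = max(float(qv), seg.p_value)
            n_extreme = (seg.n_extreme_high if direction == "over"
                         else seg.n_extreme_low)
            seg.call = "none"
            if seg.q_value < alpha and n_extreme >= min_extreme:
                seg.call = direction
                if min_extreme == 1 and not _prevails(
                    seg, flags, values, direction, prevails_threshold
                ):
                    seg.call = "none"
    return list(segments)


def _prevails(
    seg: SegmentRecord,
    flags: Mapping[str, str],
    values: Mapping[str, float],
    direction: str,
    threshold: float,
) -> bool:
    """Dominance rule for single-gene windows holding several loci.

    The call stands only when the most-expressed extreme locus of the
    called sign holds more than ``threshold`` of the window's summed
    expression — otherwise the window's significance cannot be credited
    to that locus.
    """
    members = [s for s in seg.members if s in values]
    total = sum(values[s] for s in members)
    if total <= 0:
        return False
    want = "high" if direction == "over" else "low"
    extreme_vals = [values[s] for s in members if flags.get(s) == want]
    if not extreme_vals:
        return False
    return max(extreme_vals) / total > threshold


# ---------------------------------------------------------------------------
# differential maps
# ---------------------------------------------------------------------------

def differential_map(
    stats_a: Sequence[LocusStats],
    stats_b: Sequence[LocusStats],
) -> tuple[list[DifferentialRecord], list[str]]:
    """Per-locus A/B comparison over loci present in both pools.

    Returns the records plus the symbols excluded because they were
    present in only one pool (reported, never silently dropped).
    """
    a = {s.symbol: s for s in stats_a}
    b = {s.symbol: s for s in stats_b}
    shared = [s for s in a if s in b]
    excluded = sorted(set(a) ^ set(b))
    records = [
        DifferentialRecord(
            symbol=s,
            value_a=a[s].value,
            value_b=b[s].value,
            ratio=a[s].value / b[s].value,
            data_points_a=a[s].data_points,
            data_points_b=b[s].data_points,
            sd_percent_a=a[s].sd_percent,
            sd_percent_b=b[s].sd_percent,
        )
        for s in shared
    ]
    return records, excluded


def filter_called_segments(
    segments: Sequence[SegmentRecord],
    differential: Mapping[str, DifferentialRecord],
    flags: Mapping[str, str],
    min_dp: int = 5,
) -> list[SegmentRecord]:
    """Demote differential calls resting on poorly supported loci.

    A called segment drops to "none" when any of its extreme member loci
    has fewer than ``min_dp`` data points in either compared pool.
    """
    for seg in segments:
        if seg.call == "none":
            continue
        extreme = [s for s in seg.members
                   if flags.get(s) in ("high", "low") and s in differential]
        for s in extreme:
            rec = differential[s]
            if rec.data_points_a < min_dp or rec.data_points_b < min_dp:
                seg.call = "none"
                break
    return list(segments)


# ---------------------------------------------------------------------------
# convenience: one-shot map construction
# ---------------------------------------------------------------------------

def build_segment_map(
    annotation: Mapping[str, GeneLocus],
    values: Mapping[str, float],
    window_bp: int = 500_000,
    shift_bp: int = 250_000,
    tail: float = 0.025,
    min_extreme: int = 3,
    alpha: float = 0.05,
    correction: str = "bh",
    prevails_threshold: float = 0.5,
) -> tuple[list[SegmentRecord], dict[str, str]]:
    """Segment the genome, value the windows, flag extremes, and call.

    Returns the segment list and the per-locus extreme flags used.
    """
    segments = segment_genome(annotation, window_bp=window_bp, shift_bp=shift_bp)
    compute_segment_values(values, segments)
    flags = flag_extreme_loci(values, tail=tail)
    call_segments(segments, flags, values, min_extreme=min_extreme,
                  alpha=alpha, correction=correction,
                  prevails_threshold=prevails_threshold)
    return segments, flags
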