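"""Expression normalization and per-locus aggregation.

The integration model runs three stages on every sample pool, in order:

1. **thresholding** — values <= 0 are replaced by 95% of the sample's
   minimum positive value, so that downstream A/B ratios stay defined
   while a "below detection" reading keeps a meaningfully small value;
2. **intra-sample normalization** — every value is rescaled to a
   percentage of its sample's mean, putting each sample on a mean == 100
   scale regardless of platform dynamic range;
3. **scaled quantile normalization** — a generalization of classical
   quantile normalization to samples of unequal length: each sample's
   ranks are mapped onto the rank grid of the largest sample, a reference
   distribution is built by averaging all samples at every grid position
   (linear interpolation between a sample's scaled ranks), and each value
   is replaced by the reference distribution interpolated at its own
   scaled rank. With equal-length samples this reduces exactly to
   classical quantile normalization.

After normalization, every probe measurement is a *data point* for its
locus and the locus's reference value is the plain arithmetic mean of its
data points, with spread reported as the standard deviation expressed as
a percentage of that mean.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .io import DataPoint, SampleExpression

__all__ = [
    "LocusStats",
    "threshold_nonpositive",
    "intra_sample_normalize",
    "scaled_quantile_normalize",
    "aggregate_loci",
    "normalize_pool",
]


@dataclass(frozen=True)
class LocusStats:
    """Per-locus integrated result on the genome-mean == 100 scale.

    ``sd_percent`` is the n-1 standard deviation of the locus's data
    points as a percentage of their mean; with a single data point it is
    reported as 0 (there is no spread to estimate).
    """

    symbol: str
    value: float
    sd_percent: float
    data_points: int
    n_samples: int


def threshold_nonpositive(sample: SampleExpression) -> SampleExpression:
    """Replace every value <= 0 with 95% of the sample's minimum positive value.

    Idempotent: a second application changes nothing. A sample with no
    positive value at all is unusable and raises ``ValueError``.
    """
    v = sample.values
    positive = v[v > 0]
    if positive.size == 0:
        raise ValueError(
            f"sample {sample.sample_id!r}: no positive values, cannot threshold"
        )
    floor = 0.95 * float(positive.min())
    out = np.where(v <= 0, floor, v)
    return sample.with_values(out)


def intra_sample_normalize(sample: SampleExpression) -> SampleExpression:
    """Rescale so each value is a percentage of the sample mean (mean -> 100)."""
    if len(sample) == 0:
        raise ValueError(f"sample {sample.sample_id!r}: empty sample")
    mean = float(sample.values.mean())
    if mean <= 0:
        raise ValueError(
            f"sample {sample.sample_id!r}: non-positive mean; threshold first"
        )
    return sample.with_values(100.0 * sample.values / mean)


def _scaled_positions(n: int, grid_size: int) -> np.ndarray:
    """Rank positions of an n-value sample on the 0..grid_size-1 grid."""
    if n == 1:
        return np.array([(grid_size - 1) / 2.0])
    return np.arange(n) * (grid_size - 1) / (n - 1)


def scaled_quantile_normalize(
    samples: Sequence[SampleExpression],
) -> list[SampleExpression]:
    """Quantile-normalize samples of (possibly) unequal length.

    Let N be the largest sample length. Sample j's r-th smallest value sits
    at scaled position r·(N−1)/(n_j−1) on the grid 0…N−1 (a single-value
    sample sits at the grid midpoint). The reference distribution averages,
    at every grid position, each sample linearly interpolated at that
    position; each value is then replaced by the reference linearly
    interpolated back at its own scaled position. Within-sample rank order
    is preserved, and tied input values receive the mean reference value
    over their tied positions so equal inputs map to equal outputs.
    """
    if len(samples) == 0:
        raise ValueError("scaled quantile normalization needs at least one sample")
    if len(samples) == 1:
        return [samples[0].with_values(samples[0].values)]
    grid_size = max(len(s) for s in samples)
    grid = np.arange(grid_size, dtype=np.float64)

    # reference distribution: mean over samples, interpolated on the grid
    reference = np.zeros(grid_size, dtype=np.float64)
    for s in samples:
        sorted_vals = np.sort(s.values)
        pos = _scaled_positions(len(s), grid_size)
        reference += np.interp(grid, pos, sorted_vals)
    reference /= len(samples)

    out: list[SampleExpression] = []
    for s in samples:
        n = len(s)
        order = np.argsort(s.values, kind="stable")
        sorted_vals = s.values[order]
        pos = _scaled_positions(n, grid_size)
        new_sorted = np.interp(pos, grid, reference)
        # ties: equal inputs get the mean of the reference over their span
        _, inverse, counts = np.unique(sorted_vals, return_inverse=True,
                                       return_counts=True)
        sums = np.bincount(inverse, weights=new_sorted)
        new_sorted = (sums / counts)[inverse]
        new_vals = np.empty(n, dtype=np.float64)
        new_vals[order] = new_sorted
        out.append(s.with_values(new_vals))
    return out


def aggregate_loci(
    points: Mapping[str, Sequence[DataPoint]],
) -> list[LocusStats]:
    """Collapse each locus's data points into its reference value.

    value = arithmetic mean; sd_percent = 100 x sd(n-1)/mean; data point
    and distinct-sample counts are exact.
    """
    out: list[LocusStats] = []
    for symbol, dps in points.items():
        if len(dps) == 0:
            continue
        values = np.array([dp.value for dp in dps], dtype=np.float64)
        mean = float(values.mean())
        if len(dps) > 1 and mean != 0:
            sd_percent = 100.0 * float(values.std(ddof=1)) / mean
        else:
            sd_percent = 0.0
        out.append(LocusStats(
            symbol=symbol,
            value=mean,
            sd_percent=sd_percent,
            data_points=len(dps),
            n_samples=len({dp.sample_id for dp in dps}),
        ))
    return out


def normalize_pool(
    samples: Sequence[SampleExpression],
) -> list[SampleExpression]:
    """Run the full per-pool normalization: threshold -> intra-sample -> scaled quantile."""
    staged = [intra_sample_normalize(threshold_nonpositive(s)) for s in samples]
    return scaled_quantile_normalize(staged)
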