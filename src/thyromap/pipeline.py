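"""High-level glue: raw samples -> per-locus reference map.

One call runs the whole per-pool chain — thresholding, intra-sample
normalization, scaled quantile normalization, probe-to-locus assignment
and per-locus aggregation — and returns the locus statistics that every
downstream analysis (segment maps, differential maps, housekeeping
screen, qPCR validation) consumes.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import pandas as pd

from .io import GeneLocus, MappingResult, SampleExpression, map_probes_to_loci
from .normalization import LocusStats, aggregate_loci, normalize_pool

__all__ = ["build_reference_map"]


def build_reference_map(
    samples: Sequence[SampleExpression],
    probe_map: pd.DataFrame,
    annotation: Mapping[str, GeneLocus],
) -> tuple[list[LocusStats], MappingResult]:
    """Normalize one sample pool and aggregate it into per-locus values.

    Returns the locus statistics (genome-mean == 100 scale) and the
    probe-mapping report (unmapped probes, unannotated symbols).
    """
    normalized = normalize_pool(samples)
    mapping = map_probes_to_loci(normalized, probe_map, annotation)
    stats = aggregate_loci(mapping.points)
    return stats, mapping
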