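"""Tabular input/output and probe-to-locus assignment.

All interchange formats are plain tab-delimited text:

* expression sample table: ``probe_id<TAB>value`` (header optional);
* probe map: ``probe_id<TAB>platform_id<TAB>symbol``;
* annotation: ``symbol<TAB>chromosome<TAB>start<TAB>end[<TAB>cytoband]``
  with 1-based inclusive coordinates;
* phenotype table: ``symbol<TAB>flag`` with flag in {0, 1};
* qPCR table: ``symbol<TAB>ct_mean`` (``NA``/empty means undetectable).

Gene identifiers are matched case-sensitively and may be official symbols
or EST-cluster IDs (e.g. ``Hs.732685``). Strand is never used: maps are
built from chromosome and position only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("thyromap")

__all__ = [
    "GeneLocus",
    "SampleExpression",
    "DataPoint",
    "MappingResult",
    "read_sample_table",
    "read_annotation",
    "read_probe_map",
    "read_phenotype_table",
    "read_qpcr_table",
    "map_probes_to_loci",
    "write_locus_table",
    "read_locus_table",
    "write_segment_table",
    "read_segment_table",
    "write_differential_table",
    "read_differential_table",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneLocus:
    """A mapped locus: gene symbol or EST-cluster ID plus genomic interval.

    Coordinates are 1-based and inclusive on both ends.
    """

    symbol: str
    chromosome: str
    start: int
    end: int
    cytoband: str | None = None

    def __post_init__(self) -> None:
        if self.start < 1:
            raise ValueError(f"{self.symbol}: start must be >= 1, got {self.start}")
        if self.end < self.start:
            raise ValueError(
                f"{self.symbol}: end ({self.end}) < start ({self.start})"
            )


@dataclass
class SampleExpression:
    """One sample's probe-level expression values on a single platform."""

    sample_id: str
    platform_id: str
    probe_ids: np.ndarray  # dtype object/str, unique within the sample
    values: np.ndarray     # float64, finite

    def __post_init__(self) -> None:
        self.probe_ids = np.asarray(self.probe_ids, dtype=object)
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.probe_ids.shape != self.values.shape:
            raise ValueError("probe_ids and values must have identical shape")

    def __len__(self) -> int:
        return int(self.values.size)

    def with_values(self, values: np.ndarray) -> "SampleExpression":
        """Copy of this sample with a replaced value vector (same probes)."""
        return SampleExpression(
            self.sample_id, self.platform_id, self.probe_ids.copy(), np.asarray(values, dtype=np.float64)
        )


class DataPoint(NamedTuple):
    """One probe measurement contributing to a locus's reference value."""

    value: float
    sample_id: str
    probe_id: str


@dataclass
class MappingResult:
    """Outcome of assigning probe measurements to loci.

    ``points`` holds data points for loci present in the annotation;
    ``unannotated_points`` keeps measurements whose probe maps to a symbol
    absent from the annotation (they are reported, never silently lost);
    ``unmapped_probes`` lists (platform_id, probe_id) pairs with no
    assignment at all.
    """

    points: dict[str, list[DataPoint]]
    unannotated_points: dict[str, list[DataPoint]]
    unmapped_probes: list[tuple[str, str]]

    @property
    def n_mapped(self) -> int:
        return sum(len(v) for v in self.points.values())

    @property
    def n_unannotated(self) -> int:
        return sum(len(v) for v in self.unannotated_points.values())


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def _has_header(path: Path) -> bool:
    """A sample table has a header iff line 1's second field is non-numeric."""
    with open(path) as fh:
        first = fh.readline()
    if not first.strip():
        return False
    fields = first.rstrip("\n").split("\t")
    if len(fields) < 2:
        return False
    try:
        float(fields[1])
    except ValueError:
        return True
    return False


def read_sample_table(path: str | Path, sample_id: str, platform_id: str) -> SampleExpression:
    """Read a two-column ``probe_id<TAB>value`` expression table.

    Non-finite values (``NaN``, ``inf``, unparseable numbers) are dropped
    with a logged count. An empty file or a duplicated probe_id is a hard
    error.
    """
    path = Path(path)
    header = 0 if _has_header(path) else None
    try:
        df = pd.read_csv(
            path, sep="\t", header=header, names=["probe_id", "value"],
            usecols=[0, 1], dtype={"probe_id": str},
        )
    except pd.errors.EmptyDataError:
        raise ValueError(f"{path}: empty sample table") from None
    if df.empty:
        raise ValueError(f"{path}: empty sample table")
    dup = df["probe_id"][df["probe_id"].duplicated()]
    if not dup.empty:
        raise ValueError(
            f"{path}: duplicate probe_id(s) in sample table: {sorted(set(dup))}"
        )
    values = pd.to_numeric(df["value"], errors="coerce").to_numpy(dtype=np.float64)
    finite = np.isfinite(values)
    n_dropped = int((~finite).sum())
    if n_dropped:
        logger.info("%s: dropped %d non-finite value(s)", path, n_dropped)
    return SampleExpression(
        sample_id=sample_id,
        platform_id=platform_id,
        probe_ids=df["probe_id"].to_numpy(dtype=object)[finite],
        values=values[finite],
    )


def read_annotation(path: str | Path) -> dict[str, GeneLocus]:
    """Read a gene annotation table into a symbol-keyed dict of loci."""
    df = pd.read_csv(
        path, sep="\t", header=0,
        dtype={"symbol": str, "chromosome": str},
    )
    required = {"symbol", "chromosome", "start", "end"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: annotation needs columns {sorted(required)}")
    dup = df["symbol"][df["symbol"].duplicated()]
    if not dup.empty:
        raise ValueError(f"{path}: duplicate symbol(s): {sorted(set(dup))}")
    out: dict[str, GeneLocus] = {}
    has_band = "cytoband" in df.columns
    for row in df.itertuples(index=False):
        band = getattr(row, "cytoband", None) if has_band else None
        if band is not None and (band != band):  # NaN
            band = None
        out[row.symbol] = GeneLocus(
            symbol=row.symbol, chromosome=row.chromosome,
            start=int(row.start), end=int(row.end), cytoband=band,
        )
    return out


def read_probe_map(path: str | Path) -> pd.DataFrame:
    """Read ``probe_id<TAB>platform_id<TAB>symbol`` assignments.

    Probes assigned to more than one symbol on the same platform are
    rejected with an error naming the offenders: ambiguity must be resolved
    upstream, before the pipeline runs.
    """
    df = pd.read_csv(path, sep="\t", header=0, dtype=str)
    required = {"probe_id", "platform_id", "symbol"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: probe map needs columns {sorted(required)}")
    key = df[["probe_id", "platform_id"]]
    dups = df[key.duplicated(keep=False)]
    if not dups.empty:
        offenders = sorted(
            set(map(tuple, dups[["probe_id", "platform_id"]].values))
        )
        raise ValueError(
            f"{path}: probes with multiple assignments: {offenders}"
        )
    return df


def read_phenotype_table(path: str | Path) -> dict[str, bool]:
    """Read a ``symbol<TAB>flag`` table (flag 0/1) into a bool dict."""
    df = pd.read_csv(path, sep="\t", header=0, dtype={"symbol": str})
    if not {"symbol", "flag"}.issubset(df.columns):
        raise ValueError(f"{path}: phenotype table needs columns symbol, flag")
    flags = df["flag"].astype(int)
    if not flags.isin([0, 1]).all():
        raise ValueError(f"{path}: phenotype flag must be 0 or 1")
    return dict(zip(df["symbol"], flags.astype(bool)))


def read_qpcr_table(path: str | Path) -> pd.DataFrame:
    """Read a ``symbol<TAB>ct_mean`` table; missing Ct means undetectable."""
    df = pd.read_csv(path, sep="\t", header=0, dtype={"symbol": str},
                     na_values=["NA", "N/A", ""])
    if not {"symbol", "ct_mean"}.issubset(df.columns):
        raise ValueError(f"{path}: qPCR table needs columns symbol, ct_mean")
    df["ct_mean"] = pd.to_numeric(df["ct_mean"], errors="coerce")
    return df[["symbol", "ct_mean"]]


# ---------------------------------------------------------------------------
# probe -> locus assignment
# ---------------------------------------------------------------------------

def map_probes_to_loci(
    samples: Sequence[SampleExpression],
    probe_map: pd.DataFrame,
    annotation: Mapping[str, GeneLocus],
) -> MappingResult:
    """Assign every probe measurement to its target locus.

    Mapping is value-agnostic (run it on raw or normalized samples). Every
    assigned probe contributes exactly one data point to exactly one locus;
    multiple probes per locus yield multiple data points — there is no
    pre-averaging. Probes without an assignment are reported as unmapped.
    """
    lookup: dict[tuple[str, str], str] = {
        (r.platform_id, r.probe_id): r.symbol
        for r in probe_map.itertuples(index=False)
    }
    points: dict[str, list[DataPoint]] = {}
    unannotated: dict[str, list[DataPoint]] = {}
    unmapped: list[tuple[str, str]] = []
    for sample in samples:
        for probe_id, value in zip(sample.probe_ids, sample.values):
            symbol = lookup.get((sample.platform_id, probe_id))
            if symbol is None:
                unmapped.append((sample.platform_id, probe_id))
                continue
            dp = DataPoint(float(value), sample.sample_id, probe_id)
            bucket = points if symbol in annotation else unannotated
            bucket.setdefault(symbol, []).append(dp)
    if unmapped:
        logger.info("%d probe measurement(s) had no locus assignment", len(unmapped))
    return MappingResult(points=points, unannotated_points=unannotated,
                         unmapped_probes=unmapped)


# ---------------------------------------------------------------------------
# writers (and read-backs for round-tripping)
# ---------------------------------------------------------------------------

_LOCUS_COLUMNS = ["symbol", "value", "sd_percent", "data_points", "n_samples"]
_SEGMENT_COLUMNS = [
    "chromosome", "start", "end", "value", "n_genes",
    "n_extreme_high", "n_extreme_low", "p_value", "q_value", "call",
]
_DIFF_COLUMNS = [
    "symbol", "value_a", "value_b", "ratio",
    "data_points_a", "data_points_b", "sd_percent_a", "sd_percent_b",
]


def _write_tsv(df: pd.DataFrame, path: str | Path, float_cols: Iterable[str],
               sci_cols: Iterable[str] = ()) -> None:
    out = df.copy()
    for c in float_cols:
        out[c] = out[c].map(lambda v: f"{v:.2f}" if v == v else "NA")
    for c in sci_cols:
        out[c] = out[c].map(lambda v: f"{v:.6g}" if v == v else "NA")
    try:
        out.to_csv(path, sep="\t", index=False)
    except OSError as exc:
        raise OSError(f"cannot write table to {path}: {exc}") from exc


def write_locus_table(locus_stats: Sequence, path: str | Path) -> None:
    """Write per-locus reference values, two decimals, one row per locus."""
    df = pd.DataFrame(
        [(s.symbol, s.value, s.sd_percent, s.data_points, s.n_samples)
         for s in locus_stats],
        columns=_LOCUS_COLUMNS,
    )
    _write_tsv(df, path, float_cols=["value", "sd_percent"])


def read_locus_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=0, dtype={"symbol": str})
    missing = set(_LOCUS_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: locus table missing columns {sorted(missing)}")
    return df


def write_segment_table(segments: Sequence, path: str | Path) -> None:
    """Write one row per genomic segment (p/q in scientific notation)."""
    df = pd.DataFrame(
        [(s.chromosome, s.start, s.end, s.value, s.n_genes,
          s.n_extreme_high, s.n_extreme_low, s.p_value, s.q_value, s.call)
         for s in segments],
        columns=_SEGMENT_COLUMNS,
    )
    _write_tsv(df, path, float_cols=["value"], sci_cols=["p_value", "q_value"])


def read_segment_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=0,
                     dtype={"chromosome": str, "call": str},
                     na_values=["NA"])
    missing = set(_SEGMENT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: segment table missing columns {sorted(missing)}")
    return df


def write_differential_table(records: Sequence, path: str | Path) -> None:
    """Write the two-pool comparison table (value A, value B, A/B ratio)."""
    df = pd.DataFrame(
        [(r.symbol, r.value_a, r.value_b, r.ratio,
          r.data_points_a, r.data_points_b, r.sd_percent_a, r.sd_percent_b)
         for r in records],
        columns=_DIFF_COLUMNS,
    )
    _write_tsv(df, path,
               float_cols=["value_a", "value_b", "ratio",
                           "sd_percent_a", "sd_percent_b"])


def read_differential_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=0, dtype={"symbol": str})
    missing = set(_DIFF_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: differential table missing columns {sorted(missing)}")
    return df
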