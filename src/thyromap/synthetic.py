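"""Synthetic multi-platform expression studies with known ground truth.

The generator emulates the statistical structure a cross-platform
microarray meta-analysis has to cope with:

* several platforms with heterogeneous probe counts, each covering a
  different (overlapping) gene subset with 1-4 probes per gene;
* per-probe affinity constants (log-normal), per-sample and per-platform
  scale factors, and multiplicative log-normal measurement noise;
* a small fraction of non-positive raw values, exercising thresholding;
* planted features with recorded ground truth: co-located overexpressed
  gene clusters, sex-biased genes (hard on/off, XIST/chrY-like),
  low-variance housekeeping genes, tissue-enriched genes with a known
  condition A vs B fold, and phenotype flags whose probability rises
  with tissue-fold rank.

Gene bodies average 67 kb — the mean size of a human protein-coding
gene — with exponential spacing, giving a gene density of roughly one
locus per 100 kb so that 500 kb map windows hold a handful of loci.

Everything is reproducible bit-for-bit from a seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import GeneLocus, SampleExpression

__all__ = [
    "PlatformSpec",
    "TruthConfig",
    "GroundTruth",
    "StudyData",
    "default_platforms",
    "generate_annotation",
    "generate_study",
    "generate_qpcr",
    "write_study",
]


@dataclass(frozen=True)
class PlatformSpec:
    """One simulated array platform.

    ``coverage`` is the fraction of annotated genes the platform measures;
    ``max_probes_per_gene`` bounds the uniform 1..max probe count.
    """

    platform_id: str
    coverage: float = 0.9
    max_probes_per_gene: int = 4

    def __post_init__(self) -> None:
        if not 0 < self.coverage <= 1:
            raise ValueError(f"{self.platform_id}: coverage must be in (0, 1]")
        if self.max_probes_per_gene < 1:
            raise ValueError(f"{self.platform_id}: need >= 1 probe per gene")


def default_platforms() -> list[PlatformSpec]:
    """Two platforms with clearly different probe counts and coverage."""
    return [
        PlatformSpec("GPL_hi", coverage=0.95, max_probes_per_gene=4),
        PlatformSpec("GPL_lo", coverage=0.60, max_probes_per_gene=2),
    ]


@dataclass
class TruthConfig:
    """Effect sizes and noise levels of the simulated study.

    Expression is log-normal with natural-log spread ``log_sd``;
    measurement noise is multiplicative log-normal with spread
    ``noise_sd`` (housekeeping genes instead use ``housekeeping_cv`` for
    both their probe-affinity and measurement spread).
    """

    log_mean: float = math.log(50.0)
    log_sd: float = 1.0
    noise_sd: float = 0.3
    probe_affinity_sd: float = 0.5
    sample_scale_sd: float = 0.3
    platform_scale_sd: float = 0.5
    frac_nonpositive: float = 0.01
    n_spiked_clusters: int = 0
    cluster_size: int = 5
    cluster_fold: float = 20.0
    n_housekeeping: int = 0
    housekeeping_cv: float = 0.05
    n_sex_biased: int = 0
    sex_off_factor: float = 0.01
    n_tissue_fold_genes: int = 0
    tissue_fold: float = 10.0
    phenotype_base_rate: float = 0.05
    phenotype_top_rate: float = 0.6
    phenotype_decay: float = 25.0

    def validate(self, n_genes: int) -> None:
        planted = (self.n_spiked_clusters * self.cluster_size
                   + self.n_housekeeping + self.n_sex_biased
                   + self.n_tissue_fold_genes)
        if planted > n_genes:
            raise ValueError(
                f"planted features need {planted} genes but annotation has {n_genes}"
            )
        if not 0 <= self.frac_nonpositive < 1:
            raise ValueError("frac_nonpositive must be in [0, 1)")
        for name in ("cluster_fold", "tissue_fold", "sex_off_factor"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


@dataclass
class GroundTruth:
    """What was planted, per locus, for comparison with pipeline output."""

    true_expression: dict[str, float]
    spiked_segments: list[tuple[str, int, int, float]]  # chrom, start, end, fold
    spiked_genes: dict[str, float]
    sex_biased: dict[str, str]          # male_only | female_only | none
    housekeeping: dict[str, bool]
    phenotype_flag: dict[str, bool]
    tissue_fold: dict[str, float]       # condition A vs B multiplier


@dataclass
class StudyData:
    """A full simulated two-condition, multi-platform study."""

    annotation: dict[str, GeneLocus]
    samples_a: list[SampleExpression]
    samples_b: list[SampleExpression]
    sex_a: list[str]                    # 'M'/'F' per condition-A sample
    sex_b: list[str]
    probe_map: pd.DataFrame             # probe_id, platform_id, symbol
    truth: GroundTruth


# ---------------------------------------------------------------------------
# annotation
# ---------------------------------------------------------------------------

def generate_annotation(
    n_genes: int,
    n_chromosomes: int,
    mean_gene_size_bp: float = 67_000,
    mean_gap_bp: float = 33_000,
    seed: int | None = 0,
) -> dict[str, GeneLocus]:
    """Generate non-overlapping loci with exponential sizes and spacing.

    Genes are spread evenly over ``n_chromosomes`` chromosomes named
    chr1..chrN; sizes average ``mean_gene_size_bp`` (floor 200 bp) and
    intergenic gaps average ``mean_gap_bp``.
    """
    if n_genes < 40:
        raise ValueError("need n_genes >= 40 so percentile tails are non-empty")
    if n_chromosomes < 1:
        raise ValueError("need at least one chromosome")
    rng = np.random.default_rng(seed)
    per_chrom = np.full(n_chromosomes, n_genes // n_chromosomes)
    per_chrom[: n_genes % n_chromosomes] += 1
    annotation: dict[str, GeneLocus] = {}
    gene_idx = 0
    for c in range(n_chromosomes):
        chrom = f"chr{c + 1}"
        pos = 1
        for _ in range(int(per_chrom[c])):
            gap = int(rng.exponential(mean_gap_bp))
            size = max(200, int(rng.exponential(mean_gene_size_bp)))
            start = pos + gap
            end = start + size - 1
            symbol = f"G{gene_idx:05d}"
            annotation[symbol] = GeneLocus(symbol, chrom, start, end)
            pos = end + 1
            gene_idx += 1
    return annotation


# ---------------------------------------------------------------------------
# study
# ---------------------------------------------------------------------------

def _pick_clusters(
    loci: Sequence[GeneLocus],
    n_clusters: int,
    cluster_size: int,
    window_bp: int,
    rng: np.random.Generator,
) -> list[list[GeneLocus]]:
    """Pick runs of consecutive same-chromosome loci that fit one window."""
    by_chrom: dict[str, list[GeneLocus]] = {}
    for l in loci:
        by_chrom.setdefault(l.chromosome, []).append(l)
    candidates: list[list[GeneLocus]] = []
    for chrom_loci in by_chrom.values():
        chrom_loci = sorted(chrom_loci, key=lambda l: l.start)
        for i in range(len(chrom_loci) - cluster_size + 1):
            run = chrom_loci[i:i + cluster_size]
            if run[-1].start - run[0].start < window_bp:
                candidates.append(run)
    if len(candidates) < n_clusters:
        raise ValueError(
            f"annotation too sparse: only {len(candidates)} candidate runs of "
            f"{cluster_size} loci within {window_bp} bp, need {n_clusters}"
        )
    chosen: list[list[GeneLocus]] = []
    used: set[str] = set()
    order = rng.permutation(len(candidates))
    for idx in order:
        run = candidates[idx]
        if any(l.symbol in used for l in run):
            continue
        chosen.append(run)
        used.update(l.symbol for l in run)
        if len(chosen) == n_clusters:
            return chosen
    raise ValueError("could not place non-overlapping spiked clusters")


def generate_study(
    annotation: Mapping[str, GeneLocus],
    truth_config: TruthConfig,
    platform_specs: Sequence[PlatformSpec] | None = None,
    n_samples_a: int = 6,
    n_samples_b: int = 6,
    seed: int | None = 0,
    cluster_window_bp: int = 450_000,
) -> StudyData:
    """Simulate raw probe tables for a two-condition study.

    Raw value = platform scale x sample scale x true expression
    x tissue fold (condition A only) x sex factor x probe affinity
    x multiplicative noise; a ``frac_nonpositive`` fraction of readings
    is then zeroed to exercise thresholding. Condition-A samples
    alternate male/female so sex-stratified maps can be built.
    """
    platform_specs = list(platform_specs or default_platforms())
    if len(platform_specs) < 1:
        raise ValueError("need at least one platform spec")
    symbols = sorted(annotation, key=lambda s: (annotation[s].chromosome,
                                                annotation[s].start))
    n_genes = len(symbols)
    truth_config.validate(n_genes)
    rng = np.random.default_rng(seed)

    # base expression
    true_expr = dict(zip(symbols, np.exp(
        rng.normal(truth_config.log_mean, truth_config.log_sd, n_genes))))

    # planted clusters (co-located, overexpressed in condition A)
    loci = [annotation[s] for s in symbols]
    spiked_segments: list[tuple[str, int, int, float]] = []
    spiked_genes: dict[str, float] = {}
    tissue_fold = {s: 1.0 for s in symbols}
    if truth_config.n_spiked_clusters > 0:
        runs = _pick_clusters(loci, truth_config.n_spiked_clusters,
                              truth_config.cluster_size, cluster_window_bp, rng)
        for run in runs:
            for l in run:
                tissue_fold[l.symbol] = truth_config.cluster_fold
                spiked_genes[l.symbol] = truth_config.cluster_fold
            spiked_segments.append((run[0].chromosome, run[0].start,
                                    run[-1].end, truth_config.cluster_fold))

    # remaining planted features on genes not already used
    free = [s for s in symbols if s not in spiked_genes]
    free = [free[i] for i in rng.permutation(len(free))]
    cursor = 0

    housekeeping = {s: False for s in symbols}
    hk_genes = free[cursor:cursor + truth_config.n_housekeeping]
    cursor += truth_config.n_housekeeping
    for s in hk_genes:
        housekeeping[s] = True
        # high and tight: comfortably above the genome mean
        true_expr[s] = float(np.exp(
            truth_config.log_mean + 1.5 * truth_config.log_sd
            + rng.normal(0.0, 0.2)))

    sex_biased = {s: "none" for s in symbols}
    sex_genes = free[cursor:cursor + truth_config.n_sex_biased]
    cursor += truth_config.n_sex_biased
    for i, s in enumerate(sex_genes):
        sex_biased[s] = "male_only" if i % 2 == 0 else "female_only"

    tf_genes = free[cursor:cursor + truth_config.n_tissue_fold_genes]
    cursor += truth_config.n_tissue_fold_genes
    for s in tf_genes:
        tissue_fold[s] = truth_config.tissue_fold

    # phenotype flags: probability decays with tissue-fold rank
    rank_order = sorted(symbols, key=lambda s: (-tissue_fold[s], s))
    phenotype_flag: dict[str, bool] = {}
    for rank, s in enumerate(rank_order):
        p = (truth_config.phenotype_base_rate
             + (truth_config.phenotype_top_rate - truth_config.phenotype_base_rate)
             * math.exp(-rank / truth_config.phenotype_decay))
        phenotype_flag[s] = bool(rng.random() < p)

    # platforms: covered genes, probes, affinities
    probe_rows = []
    affinities: dict[tuple[str, str], float] = {}  # (platform, probe) -> affinity
    probes_by_platform: dict[str, list[tuple[str, str]]] = {}
    hk_set = set(hk_genes)
    for spec in platform_specs:
        n_cov = max(1, int(round(spec.coverage * n_genes)))
        covered = {str(s) for s in rng.choice(symbols, size=n_cov, replace=False)}
        covered |= hk_set  # housekeeping genes are measured on all platforms
        plist: list[tuple[str, str]] = []
        for s in sorted(covered):
            n_probes = int(rng.integers(1, spec.max_probes_per_gene + 1))
            sd = (truth_config.housekeeping_cv if s in hk_set
                  else truth_config.probe_affinity_sd)
            for j in range(n_probes):
                probe_id = f"{spec.platform_id}_{s}_p{j}"
                probe_rows.append((probe_id, spec.platform_id, s))
                affinities[(spec.platform_id, probe_id)] = float(
                    np.exp(rng.normal(0.0, sd)))
                plist.append((probe_id, s))
        probes_by_platform[spec.platform_id] = plist
    probe_map = pd.DataFrame(probe_rows,
                             columns=["probe_id", "platform_id", "symbol"])
    platform_scale = {
        spec.platform_id: float(np.exp(rng.normal(0.0, truth_config.platform_scale_sd)))
        for spec in platform_specs
    }

    def make_samples(n: int, condition: str) -> tuple[list[SampleExpression], list[str]]:
        samples, sexes = [], []
        for i in range(n):
            spec = platform_specs[i % len(platform_specs)]
            # alternate sex in platform-sized blocks so sex is balanced
            # across platforms rather than confounded with them
            sex = "M" if (i // len(platform_specs)) % 2 == 0 else "F"
            plist = probes_by_platform[spec.platform_id]
            scale = platform_scale[spec.platform_id] * float(
                np.exp(rng.normal(0.0, truth_config.sample_scale_sd)))
            probe_ids = np.array([p for p, _ in plist], dtype=object)
            vals = np.empty(len(plist))
            for idx, (probe_id, s) in enumerate(plist):
                expr = true_expr[s]
                if condition == "A":
                    expr *= tissue_fold[s]
                if sex_biased[s] == "male_only" and sex == "F":
                    expr *= truth_config.sex_off_factor
                elif sex_biased[s] == "female_only" and sex == "M":
                    expr *= truth_config.sex_off_factor
                noise_sd = (truth_config.housekeeping_cv if s in hk_set
                            else truth_config.noise_sd)
                noise = float(np.exp(rng.normal(0.0, noise_sd)))
                vals[idx] = scale * expr * affinities[(spec.platform_id, probe_id)] * noise
            if truth_config.frac_nonpositive > 0:
                mask = rng.random(len(vals)) < truth_config.frac_nonpositive
                vals[mask] = 0.0
            samples.append(SampleExpression(
                sample_id=f"{condition}{i:02d}", platform_id=spec.platform_id,
                probe_ids=probe_ids, values=vals,
            ))
            sexes.append(sex)
        return samples, sexes

    samples_a, sex_a = make_samples(n_samples_a, "A")
    samples_b, sex_b = make_samples(n_samples_b, "B")

    truth = GroundTruth(
        true_expression=true_expr,
        spiked_segments=spiked_segments,
        spiked_genes=spiked_genes,
        sex_biased=sex_biased,
        housekeeping=housekeeping,
        phenotype_flag=phenotype_flag,
        tissue_fold=tissue_fold,
    )
    return StudyData(
        annotation=dict(annotation), samples_a=samples_a, samples_b=samples_b,
        sex_a=sex_a, sex_b=sex_b, probe_map=probe_map, truth=truth,
    )


# ---------------------------------------------------------------------------
# qPCR
# ---------------------------------------------------------------------------

def generate_qpcr(
    expression: Mapping[str, float],
    reference_symbol: str,
    n_genes: int = 16,
    ct_ref: float = 20.44,
    noise_sd: float = 0.2,
    seed: int | None = 0,
) -> pd.DataFrame:
    """Invert the 2^dCt relation to simulate a validation panel.

    Ct(gene) = ct_ref - log2(expression ratio to reference) + N(0, noise_sd).
    The ``n_genes`` targets are spread evenly across the expression range
    (reference included in the returned table). With zero noise,
    validation against the same expression values returns r = 1.
    """
    if reference_symbol not in expression:
        raise ValueError(f"reference {reference_symbol!r} not in expression values")
    rng = np.random.default_rng(seed)
    others = sorted((s for s in expression if s != reference_symbol),
                    key=lambda s: -expression[s])
    if n_genes - 1 > len(others):
        raise ValueError("not enough genes for the requested panel size")
    idx = np.unique(np.linspace(0, len(others) - 1, n_genes - 1).astype(int))
    panel = [others[i] for i in idx] + [reference_symbol]
    ref_val = expression[reference_symbol]
    rows = []
    for s in panel:
        ct = ct_ref - math.log2(expression[s] / ref_val)
        if noise_sd > 0 and s != reference_symbol:
            ct += float(rng.normal(0.0, noise_sd))
        rows.append((s, ct))
    return pd.DataFrame(rows, columns=["symbol", "ct_mean"])


# ---------------------------------------------------------------------------
# on-disk study (for the CLI / end-to-end file round trips)
# ---------------------------------------------------------------------------

def write_study(study: StudyData, outdir: str | Path) -> None:
    """Write a simulated study in the exact TSV formats the pipeline reads."""
    outdir = Path(outdir)
    (outdir / "pool_a").mkdir(parents=True, exist_ok=True)
    (outdir / "pool_b").mkdir(parents=True, exist_ok=True)
    ann = pd.DataFrame(
        [(l.symbol, l.chromosome, l.start, l.end)
         for l in study.annotation.values()],
        columns=["symbol", "chromosome", "start", "end"],
    )
    ann.to_csv(outdir / "annotation.tsv", sep="\t", index=False)
    study.probe_map.to_csv(outdir / "probe_map.tsv", sep="\t", index=False)
    for pool, samples in (("pool_a", study.samples_a), ("pool_b", study.samples_b)):
        for s in samples:
            df = pd.DataFrame({"probe_id": s.probe_ids, "value": s.values})
            df.to_csv(outdir / pool / f"{s.sample_id}.{s.platform_id}.tsv",
                      sep="\t", index=False)
    flags = pd.DataFrame(
        [(s, int(f)) for s, f in study.truth.phenotype_flag.items()],
        columns=["symbol", "flag"],
    )
    flags.to_csv(outdir / "phenotype.tsv", sep="\t", index=False)
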