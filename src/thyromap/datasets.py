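"""Bundled reference values from a published human thyroid transcriptome map.

These small tables carry printed results of a cross-platform meta-analysis
of whole normal human thyroid (35 thyroid microarray samples integrated
against a pool of 624 non-thyroid samples). They serve as worked-example
inputs: the qPCR validation panel lets the 2^dCt arithmetic and the
expected/observed-ratio correlation be recomputed from raw Ct means, and
the top-50 differential gene list with OMIM phenotype flags lets the
phenotype-association Fisher test be recomputed from counts.

Values are on the map's genome-mean == 100 scale. ``None`` marks an
undetectable qPCR measurement.
"""

from __future__ import annotations

import pandas as pd

__all__ = [
    "qpcr_validation_panel",
    "QPCR_REFERENCE_GENE",
    "phenotype_top50",
    "reference_map_values",
    "differential_map_values",
]

QPCR_REFERENCE_GENE = "SDC2"

# symbol, map expression value (EEV), SD as % of mean, mean threshold cycle
_QPCR_PANEL = [
    ("TG",       8662.34,  33.14, 17.55),
    ("RPL41",    5903.29,  51.15, 17.11),
    ("B2M",      2988.28,  64.22, 18.22),
    ("ACTB",     2338.95,  63.50, 19.38),
    ("TPO",      2245.11,  54.57, 19.38),
    ("IYD",       890.07,  65.51, 21.16),
    ("SDC2",      752.49,  59.44, 20.44),
    ("TSHR",      487.64,  91.14, 21.34),
    ("SERPINF1",  320.48,  65.03, 23.63),
    ("MYH9",      315.95, 104.13, 24.19),
    ("BACE2",     105.67,  47.06, 24.75),
    ("REEP3",      85.88, 108.64, None),   # undetectable by RT-PCR
    ("YKT6",       29.63,  96.23, 26.08),
    ("NTNG1",      17.89,  83.44, 32.51),
    ("RIPPLY3",    16.88,  97.44, 33.10),
    ("NPTX1",      16.77,  79.37, 33.37),
    ("TBX18",      11.52, 100.73, 28.63),
]


def qpcr_validation_panel() -> pd.DataFrame:
    """The 17-gene thyroid RT-PCR validation panel.

    Columns: symbol, map_value (expected expression value), sd_percent,
    ct_mean (NaN where the transcript was undetectable). The reference
    gene is ``QPCR_REFERENCE_GENE``, chosen for its intermediate
    expression level.
    """
    return pd.DataFrame(_QPCR_PANEL,
                        columns=["symbol", "map_value", "sd_percent", "ct_mean"])


# The 50 known genes with the highest thyroid vs non-thyroid A/B ratio
# (after the >= 5 data-point and SD filters), with their ratio and whether
# an OMIM thyroid phenotype is recorded for mutations of the gene.
_PHENOTYPE_TOP50 = [
    ("TG", 188.22, 1), ("TPO", 151.17, 1), ("SLC26A7", 66.94, 0),
    ("IYD", 66.25, 1), ("TSHR", 49.36, 1), ("SLC26A4", 44.46, 1),
    ("SNORA26", 40.26, 0), ("PRH2", 37.53, 0), ("SLC26A4-AS1", 36.09, 0),
    ("SFTA3", 34.92, 0), ("HIST2H4B", 32.52, 0), ("HSP90AA2", 19.71, 0),
    ("NKX2-1", 18.20, 1), ("LIPG", 17.93, 0), ("C16orf89", 17.27, 0),
    ("DIO1", 15.19, 1), ("FOXE1", 13.91, 1), ("TNFRFS11B", 13.52, 0),
    ("RMST", 13.14, 0), ("HHEX", 12.93, 0), ("SNORD22", 12.16, 0),
    ("INPP5J", 11.14, 0), ("CLIC3", 9.99, 0), ("OTOS", 9.19, 0),
    ("SLC25A29", 9.09, 0),
    ("SGK223", 8.99, 0), ("ID4", 8.97, 0), ("PDE8B", 8.84, 0),
    ("LRP2", 8.42, 0), ("ZBED2", 8.33, 0), ("ST6GAL2", 8.14, 0),
    ("DIO2", 8.00, 0), ("CLDN3", 7.39, 0), ("DUOX2", 7.26, 1),
    ("MGAT4C", 7.04, 0), ("IPCEF1", 6.93, 0), ("COL23A1", 6.88, 0),
    ("CRABP1", 6.78, 0), ("CYS1", 6.51, 0), ("SHISA2", 6.46, 0),
    ("PKHD1L1", 6.36, 0), ("WDR72", 6.35, 0), ("TCERG1L", 6.19, 0),
    ("MPPED2", 6.18, 0), ("IGFBPL1", 6.13, 0), ("NEUROG2", 6.13, 0),
    ("GABRA6", 6.08, 0), ("ID3", 5.75, 0), ("HIRA", 5.66, 0),
    ("MT1F", 5.49, 0),
]


def phenotype_top50() -> pd.DataFrame:
    """Top-50 thyroid-enriched known genes with OMIM phenotype flags.

    Columns: symbol, ratio (thyroid vs non-thyroid pool A/B),
    flag (1 = mutant thyroid phenotype recorded). Sorted by descending
    ratio; the first 25 versus the next 25 form the association test's
    two groups.
    """
    return pd.DataFrame(_PHENOTYPE_TOP50, columns=["symbol", "ratio", "flag"])


def reference_map_values() -> dict[str, float]:
    """Selected absolute reference values from the thyroid map."""
    return {
        "Hs.732685": 10763.93, "TG": 8662.34, "RPL41": 5903.29,
        "TPT1": 5743.83, "EEF1A1": 5537.45, "TFF3": 2726.93,
        "CSTB": 1271.11, "SOD1": 1156.80, "IYD": 890.07,
        "SDC2": 752.49, "CALCA": 218.27,
    }


def differential_map_values() -> pd.DataFrame:
    """Selected thyroid vs non-thyroid pool loci: value A, value B, A/B ratio."""
    rows = [
        ("TG", 8662.34, 46.02, 188.22),
        ("TPO", 2245.11, 14.85, 151.17),
        ("SLC26A7", 1107.90, 16.55, 66.94),
        ("IYD", 890.07, 13.44, 66.25),
        ("TSHR", 487.64, 9.88, 49.36),
        ("TFF3", 2726.93, 168.96, 16.14),
        ("CALCA", None, None, 3.65),
        ("LCE5A", 24.09, 1639.23, 0.01),
    ]
    return pd.DataFrame(rows, columns=["symbol", "value_a", "value_b", "ratio"])
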