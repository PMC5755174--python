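"""Attributing pathway expression to cell populations via marker correlation.

Testis tissue adjacent to a germ-cell tumour is a mixture of germ cells
and GCNIS (germ cell neoplasia in situ) cells.  Whether the PIWI/piRNA
pathway genes are expressed by the germ cells or by the neoplastic cells
can be read off correlation structure: if pathway expression tracks the
germ-cell markers DDX4 and DAZL across samples (Pearson r near 1) while
being uncorrelated or slightly negative with the GCNIS/TGCT markers NANOG
and POU5F1, the pathway signal comes from the germ-cell fraction.

Expression values are first normalized to a reference housekeeping gene
(ACTB by default), removing per-sample scale differences.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import ExpressionTable

__all__ = [
    "GeneSets",
    "CorrelationReport",
    "DEFAULT_GENE_SETS",
    "normalize_to_reference",
    "correlation_report",
    "load_gene_sets",
]


@dataclass(frozen=True)
class GeneSets:
    pathway: tuple[str, ...]
    germline: tuple[str, ...] = ("DDX4", "DAZL")
    tgct: tuple[str, ...] = ("NANOG", "POU5F1")


# The PIWI/piRNA-pathway gene set ships as an editable default: a
# conventional 14-gene core of the pathway, replaceable via a config file.
DEFAULT_GENE_SETS = GeneSets(
    pathway=(
        "PIWIL1", "PIWIL2", "PIWIL3", "PIWIL4",
        "MAEL", "HENMT1", "PLD6", "TDRD1", "TDRD5",
        "TDRD9", "TDRKH", "MOV10L1", "FKBP6", "GPAT2",
    )
)


def load_gene_sets(path) -> GeneSets:
    """Load gene sets from a YAML mapping ``{pathway: [...], germline: [...], tgct: [...]}``."""
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return GeneSets(
        pathway=tuple(raw["pathway"]),
        germline=tuple(raw.get("germline", ("DDX4", "DAZL"))),
        tgct=tuple(raw.get("tgct", ("NANOG", "POU5F1"))),
    )


def normalize_to_reference(table: ExpressionTable, reference: str = "ACTB") -> ExpressionTable:
    """Divide every gene by the same sample's reference-gene value.

    The reference column becomes exactly 1.  A missing reference gene, or a
    sample where it is zero, is an error naming the offender.
    """
    if reference not in table.data.columns:
        raise ValueError(f"reference gene {reference!r} absent from table")
    ref = table.data[reference]
    zero = ref.index[ref <= 0].tolist()
    if zero:
        raise ValueError(f"reference gene {reference!r} non-positive in samples: {zero}")
    return ExpressionTable(data=table.data.div(ref, axis=0), groups=table.groups.copy())


@dataclass
class CorrelationReport:
    """Pairwise Pearson correlations over one sample group, with summaries.

    ``germline_block`` summarises the pairwise r among pathway + germline
    marker genes; ``pathway_vs_tgct`` the r between pathway genes and the
    TGCT markers.  ``rsd`` is the per-gene relative standard deviation in
    percent (100 x sd / mean).
    """

    matrix: pd.DataFrame
    rsd: pd.Series
    gene_sets: GeneSets
    germline_block: dict[str, float]
    pathway_vs_tgct: dict[str, float]
    excluded_genes: list[str] = field(default_factory=list)


def _block_summary(matrix: pd.DataFrame, rows: list[str], cols: list[str], within: bool) -> dict[str, float]:
    values = []
    for g1 in rows:
        for g2 in cols:
            if within and g2 <= g1:  # upper triangle only for within-set blocks
                continue
            values.append(matrix.loc[g1, g2])
    arr = np.array(values, dtype=float)
    if arr.size == 0:
        return {"min": np.nan, "median": np.nan, "max": np.nan}
    return {
        "min": float(np.min(arr)),
        "median": float(np.median(arr)),
        "max": float(np.max(arr)),
    }


def correlation_report(
    table: ExpressionTable,
    group: str | None = None,
    gene_sets: GeneSets = DEFAULT_GENE_SETS,
    log2: bool = False,
) -> CorrelationReport:
    """Pairwise Pearson r among pathway, germline and TGCT marker genes.

    ``group`` restricts to one sample-group label (None = all samples;
    at least 3 samples required).  Zero-variance genes cannot carry a
    correlation; they are excluded from the summaries with a warning.
    Set ``log2`` for correlations on log2(x + 1)-transformed values.
    """
    data = table.data if group is None else table.data[table.groups == group]
    if len(data) < 3:
        raise ValueError(f"need >= 3 samples, got {len(data)} for group {group!r}")
    genes = list(dict.fromkeys(gene_sets.pathway + gene_sets.germline + gene_sets.tgct))
    missing = [g for g in genes if g not in data.columns]
    if missing:
        raise ValueError(f"genes absent from table: {missing}")
    sub = data[genes]
    if log2:
        sub = np.log2(sub + 1.0)

    variances = sub.var(ddof=1)
    excluded = variances.index[variances == 0].tolist()
    if excluded:
        warnings.warn(
            f"zero-variance genes excluded from correlation summaries: {excluded}",
            stacklevel=2,
        )
    matrix = sub.corr(method="pearson")  # NaN rows/cols for constant genes

    mean = sub.mean()
    rsd = 100.0 * sub.std(ddof=1) / mean.where(mean != 0, np.nan)

    keep = [g for g in genes if g not in excluded]
    block = [g for g in gene_sets.pathway + gene_sets.germline if g in keep]
    pathway = [g for g in gene_sets.pathway if g in keep]
    tgct = [g for g in gene_sets.tgct if g in keep]
    return CorrelationReport(
        matrix=matrix,
        rsd=rsd,
        gene_sets=gene_sets,
        germline_block=_block_summary(matrix, block, block, within=True),
        pathway_vs_tgct=_block_summary(matrix, pathway, tgct, within=False),
        excluded_genes=excluded,
    )
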