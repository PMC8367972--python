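"""Transcriptome-wide screening of candidate reference genes from FPKM tables.

Candidate internal-control genes for qRT-PCR are pre-selected from an
RNA-Seq expression matrix in two steps: an abundance filter (housekeeping
genes are highly expressed, so genes below an FPKM cut-off are discarded)
followed by a composite stability score.  For each surviving gene three
per-gene statistics are computed across all samples:

* ``CV``    — coefficient of variation (sample SD / mean), as a fraction;
* ``NMAD``  — median absolute deviation normalised by the median;
* ``p``     — Shapiro–Wilk normality p-value.

The three are combined into a Euclidean stability distance

    d = sqrt(CV^2 + NMAD^2 + (1 - p)^2)

so that a gene scoring well on all three criteria (low spread, symmetric,
approximately normal variation) has a small ``d``.  CV and NMAD are kept as
fractions rather than percentages so that all three terms share the [0, ~1]
scale and contribute comparably to the distance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats as _sps

from .errors import ConfigError, DomainError, ParseError

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionMatrix",
    "ScreeningConfig",
    "read_expression_table",
    "read_tissue_map",
    "filter_low_expression",
    "coefficient_of_variation",
    "normalized_mad",
    "normality_pvalue",
    "stability_distance",
    "screen_candidates",
    "top_candidates",
    "top_k_overlap",
]


@dataclass
class ExpressionMatrix:
    """A gene x sample FPKM matrix with a tissue label per sample.

    ``values`` has genes as the row index and samples as columns; every
    entry must be a finite, non-negative FPKM.  ``tissue_of`` maps every
    sample id to its tissue/group label.
    """

    values: pd.DataFrame
    tissue_of: Mapping[str, str]

    def __post_init__(self) -> None:
        vals = self.values
        if vals.index.duplicated().any():
            dups = vals.index[vals.index.duplicated()].tolist()
            raise ConfigError(f"duplicate gene ids: {dups}")
        if vals.columns.duplicated().any():
            dups = vals.columns[vals.columns.duplicated()].tolist()
            raise ConfigError(f"duplicate sample ids: {dups}")
        if vals.shape[1] < 2:
            raise ConfigError("an expression matrix needs at least 2 samples")
        arr = vals.to_numpy(dtype=float)
        if not np.all(np.isfinite(arr)):
            raise ConfigError("FPKM values must all be finite")
        if (arr < 0).any():
            raise ConfigError("FPKM values must be non-negative")
        missing = [s for s in vals.columns if s not in self.tissue_of]
        if missing:
            raise ConfigError(f"samples without a tissue label: {missing}")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    def subset(self, genes: Iterable[str]) -> "ExpressionMatrix":
        genes = list(genes)
        return ExpressionMatrix(self.values.loc[genes], dict(self.tissue_of))


@dataclass
class ScreeningConfig:
    """Parameters of the abundance filter and the ranking.

    ``abundance_threshold`` is in FPKM units; the filter is inclusive
    (a gene whose ``abundance_statistic`` equals the threshold is kept).
    """

    abundance_threshold: float = 100.0
    abundance_statistic: str = "median"  # or "mean"
    alpha_normality: float = 0.05
    top_k: int = 12
    cv_as_percent: bool = False  # expose CV on the percent scale inside d

    def __post_init__(self) -> None:
        if self.abundance_threshold < 0:
            raise ConfigError("abundance_threshold must be >= 0")
        if self.abundance_statistic not in ("median", "mean"):
            raise ConfigError("abundance_statistic must be 'median' or 'mean'")
        if not 0 < self.alpha_normality < 1:
            raise ConfigError("alpha_normality must lie in (0, 1)")
        if self.top_k < 1:
            raise ConfigError("top_k must be >= 1")


def _sniff_sep(path: Path) -> str:
    with open(path) as fh:
        header = fh.readline()
    return "\t" if "\t" in header else ","


def read_tissue_map(path: str | Path) -> dict[str, str]:
    """Read a two-column sample -> tissue table (TSV or CSV, header optional)."""
    path = Path(path)
    sep = _sniff_sep(path)
    df = pd.read_csv(path, sep=sep, header=None, dtype=str, comment="#")
    if df.shape[1] < 2:
        raise ParseError(f"{path}: expected two columns (sample_id, tissue)")
    first = str(df.iloc[0, 0]).strip().lower()
    if first in ("sample", "sample_id", "id"):
        df = df.iloc[1:]
    return dict(zip(df.iloc[:, 0].str.strip(), df.iloc[:, 1].str.strip()))


def read_expression_table(
    path: str | Path, tissue_map: str | Path | Mapping[str, str]
) -> ExpressionMatrix:
    """Read a delimited gene x sample FPKM table into an :class:`ExpressionMatrix`.

    The first column holds gene ids, the header row sample ids.  Tab and
    comma separators are auto-detected.  Any missing or non-numeric cell is
    a :class:`ParseError` naming the gene and sample.
    """
    path = Path(path)
    sep = _sniff_sep(path)
    raw = pd.read_csv(path, sep=sep, index_col=0, dtype=str)
    raw.index = pd.Index(raw.index.astype(str), name=None)
    if raw.index.duplicated().any():
        dups = sorted(set(raw.index[raw.index.duplicated()]))
        raise ParseError(f"{path}: duplicated gene id(s) {dups}")
    numeric = raw.apply(lambda col: pd.to_numeric(col, errors="coerce"))
    numeric = numeric.rename_axis(None)
    bad = numeric.isna()
    if bad.to_numpy().any():
        gene = bad.index[bad.any(axis=1)][0]
        sample = bad.columns[bad.loc[gene]][0]
        cell = raw.loc[gene, sample]
        raise ParseError(
            f"{path}: non-numeric or missing value {cell!r} "
            f"for gene {gene!r}, sample {sample!r}"
        )
    if not isinstance(tissue_map, Mapping):
        tissue_map = read_tissue_map(tissue_map)
    return ExpressionMatrix(numeric, dict(tissue_map))


def _abundance(values: np.ndarray, statistic: str) -> float:
    return float(np.median(values) if statistic == "median" else np.mean(values))


def filter_low_expression(
    matrix: ExpressionMatrix, config: ScreeningConfig | None = None
) -> ExpressionMatrix:
    """Drop genes whose abundance statistic is below the FPKM cut-off.

    Retains exactly the genes with ``statistic(FPKM) >= threshold`` (the
    comparison is inclusive); gene order is preserved.  An empty result is
    allowed and only logged as a warning.
    """
    config = config or ScreeningConfig()
    keep = [
        g
        for g in matrix.gene_ids
        if _abundance(matrix.values.loc[g].to_numpy(float), config.abundance_statistic)
        >= config.abundance_threshold
    ]
    if not keep:
        logger.warning(
            "abundance filter (%s FPKM >= %g) removed every gene",
            config.abundance_statistic,
            config.abundance_threshold,
        )
    return ExpressionMatrix(matrix.values.loc[keep], dict(matrix.tissue_of))


def coefficient_of_variation(values: Iterable[float]) -> float:
    """Sample SD (n-1 denominator) over the arithmetic mean, as a fraction."""
    arr = np.asarray(list(values), dtype=float)
    if arr.size < 2 or not np.all(np.isfinite(arr)):
        raise DomainError("CV needs >= 2 finite values")
    mean = arr.mean()
    if mean <= 0:
        raise DomainError(f"CV undefined for mean <= 0 (mean={mean:g})")
    return float(arr.std(ddof=1) / mean)


def normalized_mad(values: Iterable[float]) -> float:
    """Median absolute deviation divided by the median (no consistency constant)."""
    arr = np.asarray(list(values), dtype=float)
    if arr.size < 2 or not np.all(np.isfinite(arr)):
        raise DomainError("NMAD needs >= 2 finite values")
    med = np.median(arr)
    if med <= 0:
        raise DomainError(f"NMAD undefined for median <= 0 (median={med:g})")
    return float(np.median(np.abs(arr - med)) / med)


def normality_pvalue(values: Iterable[float]) -> float:
    """Shapiro–Wilk p-value; a zero-variance vector returns 1.0 with a warning.

    A perfectly constant gene is maximally stable, so rather than failing the
    (undefined) test we treat it as compatible with normality and log the
    convention so it can be audited.
    """
    arr = np.asarray(list(values), dtype=float)
    if arr.size < 3:
        raise DomainError("Shapiro–Wilk needs at least 3 values")
    if arr.size > 5000:
        raise DomainError("Shapiro–Wilk p-values are unreliable for n > 5000")
    if not np.all(np.isfinite(arr)):
        raise DomainError("Shapiro–Wilk needs finite values")
    if np.ptp(arr) == 0:
        logger.warning("zero-variance vector: returning Shapiro–Wilk p = 1.0")
        return 1.0
    return float(_sps.shapiro(arr).pvalue)


def stability_distance(cv: float, nmad: float, p_normal: float) -> float:
    """Euclidean distance d = sqrt(cv^2 + nmad^2 + (1 - p)^2); smaller = stabler."""
    if cv < 0 or nmad < 0:
        raise DomainError("cv and nmad must be non-negative")
    if not 0 <= p_normal <= 1:
        raise DomainError("p_normal must lie in [0, 1]")
    return float(np.sqrt(cv**2 + nmad**2 + (1.0 - p_normal) ** 2))


def _strict_rank(df: pd.DataFrame, col: str) -> pd.Series:
    # Strict 1..n ordering; ties broken lexicographically by gene id for
    # reproducibility (mergesort is stable).
    order = df.sort_values([col, "gene_id"], kind="mergesort").index
    return pd.Series(np.arange(1, len(df) + 1), index=order)


def screen_candidates(
    matrix: ExpressionMatrix, config: ScreeningConfig | None = None
) -> pd.DataFrame:
    """Abundance-filter a matrix and score every surviving gene.

    Returns a DataFrame (one row per gene, sorted by ``rank_d``) with columns
    ``gene_id, abundance, cv, nmad, p_normal, d, rank_d, rank_cv, rank_nmad``.
    Genes for which a statistic is undefined (e.g. zero median) are dropped
    with a logged reason.
    """
    config = config or ScreeningConfig()
    filtered = filter_low_expression(matrix, config)
    rows = []
    for gene in filtered.gene_ids:
        vec = filtered.values.loc[gene].to_numpy(float)
        try:
            cv = coefficient_of_variation(vec)
            nmad = normalized_mad(vec)
            p = normality_pvalue(vec)
        except DomainError as exc:
            logger.warning("dropping gene %s from screening: %s", gene, exc)
            continue
        cv_in_d = cv * 100.0 if config.cv_as_percent else cv
        rows.append(
            {
                "gene_id": gene,
                "abundance": _abundance(vec, config.abundance_statistic),
                "cv": cv,
                "nmad": nmad,
                "p_normal": p,
                "d": stability_distance(cv_in_d, nmad, p),
            }
        )
    stats = pd.DataFrame(
        rows, columns=["gene_id", "abundance", "cv", "nmad", "p_normal", "d"]
    )
    if stats.empty:
        return stats.assign(rank_d=[], rank_cv=[], rank_nmad=[])
    stats.index = pd.Index(stats["gene_id"].to_numpy(), name=None)
    stats["rank_d"] = _strict_rank(stats, "d")
    stats["rank_cv"] = _strict_rank(stats, "cv")
    stats["rank_nmad"] = _strict_rank(stats, "nmad")
    return stats.sort_values("rank_d").reset_index(drop=True)


def top_candidates(stats: pd.DataFrame, top_k: int) -> list[str]:
    """The ``top_k`` gene ids with the smallest stability distance ``d``."""
    if top_k < 1:
        raise DomainError("top_k must be >= 1")
    if top_k > len(stats):
        logger.warning(
            "requested top %d candidates but only %d genes passed screening",
            top_k,
            len(stats),
        )
    return stats.sort_values("rank_d")["gene_id"].head(top_k).tolist()


def top_k_overlap(stats: pd.DataFrame, k: int) -> dict:
    """Venn region sizes among the top-k sets ranked by cv, nmad and d.

    Returns a dict with the seven exclusive region sizes (``d_only``,
    ``cv_only``, ``nmad_only``, ``d_cv``, ``d_nmad``, ``cv_nmad``,
    ``all_three``), the ``union`` size and the member lists per region.
    """
    if k < 1 or k > len(stats):
        raise DomainError(f"k={k} out of range for {len(stats)} screened genes")
    by = {
        "d": set(stats.nsmallest(k, "rank_d")["gene_id"]),
        "cv": set(stats.nsmallest(k, "rank_cv")["gene_id"]),
        "nmad": set(stats.nsmallest(k, "rank_nmad")["gene_id"]),
    }
    d, cv, nm = by["d"], by["cv"], by["nmad"]
    regions = {
        "all_three": d & cv & nm,
        "d_cv": (d & cv) - nm,
        "d_nmad": (d & nm) - cv,
        "cv_nmad": (cv & nm) - d,
        "d_only": d - cv - nm,
        "cv_only": cv - d - nm,
        "nmad_only": nm - d - cv,
    }
    sizes = {name: len(members) for name, members in regions.items()}
    sizes["union"] = len(d | cv | nm)
    return {
        "k": k,
        "sizes": sizes,
        "members": {name: sorted(members) for name, members in regions.items()},
    }
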