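"""Quantification-cycle (Cq) handling, standard curves and 2^-dCt normalization.

A qPCR standard curve regresses Cq on log10 of a serial template dilution;
its slope yields the amplification efficiency

    E% = (10^(-1/slope) - 1) * 100

with E = 100% corresponding to perfect product doubling each cycle
(slope = -1/log10(2) ~ -3.3219).  Cq values are converted to relative
quantities per gene as Q = E_b^(Cq_min - Cq), where E_b = 1 + E%/100 is the
amplification base; the sample with the lowest Cq gets Q = 1.

Relative expression of a target against one or more reference genes uses the
2^-dCt method: dCt = Cq_target - Cq_reference and expression = 2^-dCt.  With
several references the normalization factor is the geometric mean of their
relative quantities, which at base 2 is the same as subtracting the
arithmetic mean of the reference Cq values.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as _sps

from .errors import ConfigError, DomainError, ParseError

logger = logging.getLogger(__name__)

__all__ = [
    "CqMatrix",
    "DilutionSeries",
    "StandardCurveFit",
    "QcRule",
    "read_cq_table",
    "read_sample_annotation",
    "read_dilution_series",
    "collapse_replicates",
    "fit_standard_curve",
    "amplification_efficiency",
    "cq_to_relative_quantity",
    "relative_quantities",
    "normalize_expression",
    "qc_check",
]

#: Sanity bounds on a quantification cycle; a 40-cycle run cannot exceed them.
CQ_BOUNDS = (0.0, 50.0)


@dataclass
class CqMatrix:
    """Gene x sample Cq values with a group (tissue) label per sample.

    ``replicate_of`` optionally maps technical-replicate sample ids to their
    biological sample id; :func:`collapse_replicates` averages them away.
    Missing Cq values are NaN.
    """

    cq: pd.DataFrame
    group_of: Mapping[str, str]
    replicate_of: Mapping[str, str] | None = None

    def __post_init__(self) -> None:
        if self.cq.index.duplicated().any():
            raise ConfigError("duplicate gene ids in Cq matrix")
        if self.cq.columns.duplicated().any():
            raise ConfigError("duplicate sample ids in Cq matrix")
        arr = self.cq.to_numpy(dtype=float)
        present = arr[~np.isnan(arr)]
        if present.size and (
            (present <= CQ_BOUNDS[0]).any() or (present >= CQ_BOUNDS[1]).any()
        ):
            raise ConfigError(
                f"Cq values outside the open interval {CQ_BOUNDS} are rejected"
            )
        missing = [s for s in self.cq.columns if s not in self.group_of]
        if missing:
            raise ConfigError(f"samples without a group label: {missing}")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.cq.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.cq.columns)

    def groups(self) -> pd.Series:
        return pd.Series({s: self.group_of[s] for s in self.cq.columns})


@dataclass
class DilutionSeries:
    """A standard-curve input: relative concentrations and their Cq values."""

    gene_id: str
    concentrations: Sequence[float]
    cq: Sequence[float]

    def __post_init__(self) -> None:
        conc = np.asarray(self.concentrations, dtype=float)
        cq = np.asarray(self.cq, dtype=float)
        if conc.shape != cq.shape:
            raise ConfigError("concentrations and cq must have equal length")
        if (conc <= 0).any():
            raise ConfigError("dilution concentrations must be strictly positive")
        if len(np.unique(conc)) < 3:
            raise DomainError(
                "a standard curve needs >= 3 distinct concentrations"
            )


@dataclass
class StandardCurveFit:
    slope: float
    intercept: float
    r_squared: float
    efficiency_percent: float
    gene_id: str = ""


@dataclass
class QcRule:
    """Acceptance limits for a standard-curve fit."""

    min_r_squared: float = 0.980
    efficiency_range: tuple[float, float] = (90.0, 110.0)

    def __post_init__(self) -> None:
        if not 0 < self.min_r_squared < 1:
            raise ConfigError("min_r_squared must lie in (0, 1)")
        lo, hi = self.efficiency_range
        if not lo < hi:
            raise ConfigError("efficiency_range lower bound must be < upper")


def _sniff_sep(path: Path) -> str:
    with open(path) as fh:
        header = fh.readline()
    return "\t" if "\t" in header else ","


def read_sample_annotation(path: str | Path) -> pd.DataFrame:
    """Read a sample annotation table (columns: sample_id, group[, biological_sample])."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sniff_sep(path), dtype=str)
    df.columns = [c.strip().lower() for c in df.columns]
    if "sample_id" not in df.columns or "group" not in df.columns:
        raise ParseError(f"{path}: needs 'sample_id' and 'group' columns")
    return df


def read_cq_table(path: str | Path, annotation: str | Path | pd.DataFrame) -> CqMatrix:
    """Read a gene x sample Cq table plus its sample annotation."""
    path = Path(path)
    raw = pd.read_csv(path, sep=_sniff_sep(path), index_col=0, dtype=str)
    raw.index = raw.index.astype(str)
    numeric = raw.apply(lambda col: pd.to_numeric(col, errors="coerce")).rename_axis(None)
    # blank / "NA" cells are legitimate missing Cq values, but anything else
    # non-numeric is a parse error
    suspicious = numeric.isna() & raw.notna() & ~raw.isin(["", "NA", "NaN", "nan"])
    if suspicious.to_numpy().any():
        gene = suspicious.index[suspicious.any(axis=1)][0]
        sample = suspicious.columns[suspicious.loc[gene]][0]
        raise ParseError(
            f"{path}: non-numeric Cq {raw.loc[gene, sample]!r} "
            f"for gene {gene!r}, sample {sample!r}"
        )
    if not isinstance(annotation, pd.DataFrame):
        annotation = read_sample_annotation(annotation)
    group_of = dict(zip(annotation["sample_id"], annotation["group"]))
    replicate_of = None
    if "biological_sample" in annotation.columns:
        replicate_of = dict(
            zip(annotation["sample_id"], annotation["biological_sample"])
        )
    return CqMatrix(numeric, group_of, replicate_of)


def read_dilution_series(path: str | Path) -> list[DilutionSeries]:
    """Read a three-column (gene_id, concentration, cq) dilution table."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sniff_sep(path))
    df.columns = [c.strip().lower() for c in df.columns]
    needed = {"gene_id", "concentration", "cq"}
    if not needed <= set(df.columns):
        raise ParseError(f"{path}: needs columns {sorted(needed)}")
    out = []
    for gene, sub in df.groupby("gene_id", sort=False):
        out.append(
            DilutionSeries(
                gene_id=str(gene),
                concentrations=sub["concentration"].astype(float).tolist(),
                cq=sub["cq"].astype(float).tolist(),
            )
        )
    return out


def collapse_replicates(matrix: CqMatrix) -> CqMatrix:
    """Average technical replicates (arithmetic mean on the Cq scale).

    Missing replicates are ignored; a (gene, biological sample) whose
    replicates are all missing stays missing and is logged.
    """
    if matrix.replicate_of is None:
        raise ConfigError("collapse_replicates needs a replicate mapping")
    rep_of = matrix.replicate_of
    bio_order: list[str] = []
    for s in matrix.sample_ids:
        b = rep_of.get(s, s)
        if b not in bio_order:
            bio_order.append(b)
    cols = {}
    group_of: dict[str, str] = {}
    for bio in bio_order:
        reps = [s for s in matrix.sample_ids if rep_of.get(s, s) == bio]
        grp = {matrix.group_of[s] for s in reps}
        if len(grp) != 1:
            raise ConfigError(
                f"biological sample {bio!r} spans several groups: {sorted(grp)}"
            )
        group_of[bio] = grp.pop()
        col = matrix.cq[reps].mean(axis=1, skipna=True)
        for gene in col.index[col.isna()]:
            logger.warning(
                "all technical replicates missing for gene %s, sample %s",
                gene,
                bio,
            )
        cols[bio] = col
    collapsed = pd.DataFrame(cols)[bio_order]
    return CqMatrix(collapsed, group_of, replicate_of=None)


def fit_standard_curve(series: DilutionSeries) -> StandardCurveFit:
    """Ordinary least squares of Cq on log10(relative concentration)."""
    conc = np.asarray(series.concentrations, dtype=float)
    cq = np.asarray(series.cq, dtype=float)
    if len(np.unique(conc)) < 3:
        raise DomainError("a standard curve needs >= 3 distinct concentrations")
    res = _sps.linregress(np.log10(conc), cq)
    if res.slope < 0:
        eff = amplification_efficiency(res.slope)
    else:
        logger.warning(
            "standard curve for %s has non-negative slope %.4g; "
            "efficiency undefined",
            series.gene_id,
            res.slope,
        )
        eff = float("nan")
    return StandardCurveFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        efficiency_percent=eff,
        gene_id=series.gene_id,
    )


def amplification_efficiency(slope: float) -> float:
    """E% = (10^(-1/slope) - 1) * 100 for a negative standard-curve slope."""
    if not slope < 0:
        raise DomainError("amplification efficiency requires slope < 0")
    return float((10.0 ** (-1.0 / slope) - 1.0) * 100.0)


def cq_to_relative_quantity(
    cq_row: pd.Series | Iterable[float], efficiency_base: float = 2.0
) -> pd.Series:
    """Convert one gene's Cq values to relative quantities Q = E_b^(Cq_min - Cq).

    ``efficiency_base`` is E_b = 1 + E%/100 and must lie in (1, 2.2]; the
    sample with the smallest Cq gets Q = 1.  Missing Cq stays missing.
    """
    if not 1.0 < efficiency_base <= 2.2:
        raise DomainError("efficiency_base must lie in (1, 2.2]")
    row = pd.Series(cq_row, dtype=float)
    if row.notna().sum() == 0:
        raise DomainError("cannot scale an all-missing Cq row")
    return efficiency_base ** (row.min(skipna=True) - row)


def relative_quantities(
    matrix: CqMatrix, efficiency_base: float | Mapping[str, float] = 2.0
) -> pd.DataFrame:
    """Per-gene relative quantities for a whole Cq matrix.

    ``efficiency_base`` may be a scalar or a per-gene mapping (genes absent
    from the mapping fall back to 2, the perfect-doubling assumption).
    """
    rows = {}
    for gene in matrix.gene_ids:
        base = (
            efficiency_base
            if isinstance(efficiency_base, (int, float))
            else float(efficiency_base.get(gene, 2.0))
        )
        rows[gene] = cq_to_relative_quantity(matrix.cq.loc[gene], base)
    return pd.DataFrame(rows).T[matrix.sample_ids]


def normalize_expression(
    target_cq: pd.Series,
    reference_cqs: pd.Series | pd.DataFrame,
) -> pd.DataFrame:
    """2^-dCt expression of a target against one or several reference genes.

    ``target_cq`` is indexed by sample.  ``reference_cqs`` is a Series
    (single reference) or a DataFrame with reference genes in rows and the
    same samples in columns.  With several references, expression equals the
    target quantity divided by the geometric mean of the reference
    quantities, i.e. dCt = Cq_target - mean(Cq_refs).  Samples missing any
    reference Cq come back missing (logged).
    """
    target = pd.Series(target_cq, dtype=float)
    if isinstance(reference_cqs, pd.Series):
        refs = reference_cqs.to_frame().T
    else:
        refs = reference_cqs
    if refs.shape[0] < 1:
        raise DomainError("at least one reference gene is required")
    refs = refs[target.index].astype(float)
    ref_mean = refs.mean(axis=0, skipna=False)
    for sample in ref_mean.index[ref_mean.isna() & target.notna()]:
        logger.warning("missing reference Cq in sample %s; output missing", sample)
    delta = target - ref_mean
    return pd.DataFrame({"delta_ct": delta, "expression": 2.0 ** (-delta)})


def qc_check(fit: StandardCurveFit, rule: QcRule | None = None) -> list[str]:
    """Flags a standard-curve fit violating the QC rule; empty list = pass."""
    rule = rule or QcRule()
    flags = []
    if fit.r_squared < rule.min_r_squared:
        flags.append("low_r_squared")
    lo, hi = rule.efficiency_range
    if math.isnan(fit.efficiency_percent) or not lo <= fit.efficiency_percent <= hi:
        flags.append("efficiency_out_of_range")
    return flags
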