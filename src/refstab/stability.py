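"""Expression-stability ranking of candidate reference genes.

Implements the four ranking algorithms routinely applied to qPCR panels and
their geometric-mean aggregation:

* **geNorm** — a gene's stability M is the mean, over all other panel genes,
  of the standard deviation of the pairwise log2 expression ratio; the least
  stable gene is excluded stepwise until two remain (reported as a tied best
  pair).  The pairwise variation V_{n/(n+1)} between normalization factors
  built from the n and n+1 most stable genes decides how many references are
  needed (V < 0.15 means n genes suffice).
* **NormFinder** — a model-based decomposition of log expression into
  intra-group (within-tissue) variance and inter-group (gene x tissue)
  deviations, with empirical-Bayes shrinkage of the inter-group terms; the
  stability value combines both sources, smaller = stabler.
* **BestKeeper** — descriptive spread of the raw Cq values (SD and CV%),
  plus the Pearson correlation of each gene with the BestKeeper index (the
  per-sample geometric mean Cq over the panel).
* **Comparative Delta-Ct** — for each gene, the mean over all partner genes
  of the SD of the pairwise Cq difference.
* **RefFinder-style aggregation** — the geometric mean of a gene's ranks
  across methods, with competition (shared-minimum) ranking for ties.

geNorm and NormFinder consume relative quantities (log ratios); BestKeeper
and the Delta-Ct method consume raw, untransformed Cq values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as _sps

from .errors import ConfigError, DomainError
from .qpcr import CqMatrix, collapse_replicates, relative_quantities

logger = logging.getLogger(__name__)

__all__ = [
    "GenormResult",
    "NormfinderResult",
    "BestkeeperResult",
    "StabilityReport",
    "genorm_pairwise_sd",
    "genorm_m_values",
    "genorm_rank",
    "genorm_v_series",
    "optimal_rg_count",
    "normfinder_stability",
    "bestkeeper_stats",
    "delta_ct_stability",
    "rank_genes",
    "reffinder_aggregate",
    "evaluate_panel",
]

#: geNorm's recommended ceiling on M for a usable reference gene.
M_STABLE_THRESHOLD = 0.5
#: geNorm's pairwise-variation cut-off: V < 0.15 means n references suffice.
V_THRESHOLD = 0.15


@dataclass
class GenormResult:
    m_values: pd.Series  # M at the full panel
    stepwise_m: pd.Series  # each gene's M at the step it was excluded
    exclusion_order: list[str]  # least stable first; final tied pair last
    m_trajectory: list[dict]  # per step: remaining panel and its M values
    ranks: pd.Series  # competition ranks; final two genes share rank 1
    v_series: dict[int, float] = field(default_factory=dict)

    def stable_genes(self, threshold: float = M_STABLE_THRESHOLD) -> list[str]:
        """Genes whose stepwise-exclusion M lies below the stability cut-off
        (the M value conventionally plotted per gene by geNorm)."""
        return sorted(self.stepwise_m.index[self.stepwise_m < threshold])


@dataclass
class NormfinderResult:
    stability: pd.Series
    intergroup: pd.DataFrame | None  # gene x group deviations (shrunken)
    intragroup_var: pd.DataFrame | None  # gene x group variance estimates
    grouped: bool


@dataclass
class BestkeeperResult:
    table: pd.DataFrame  # per gene: mean_cq, sd_cq, cv_percent, r_vs_index
    index: pd.Series  # per-sample geometric mean Cq across the panel

    @property
    def sd_cq(self) -> pd.Series:
        return self.table["sd_cq"]


@dataclass
class StabilityReport:
    table: pd.DataFrame  # per gene: <method>_value, <method>_rank, geomean, rank
    genorm: GenormResult | None
    normfinder: NormfinderResult | None
    bestkeeper: BestkeeperResult | None
    delta_ct: pd.Series | None
    v_series: dict[int, float]
    optimal_n: int | None
    optimal_flag: str | None
    failures: dict[str, str] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# geNorm
# ---------------------------------------------------------------------------

def _as_panel(quantities: pd.DataFrame, panel: Sequence[str] | None) -> pd.DataFrame:
    sub = quantities if panel is None else quantities.loc[list(panel)]
    arr = sub.to_numpy(dtype=float)
    if np.isnan(arr).any() or (arr <= 0).any():
        raise DomainError("relative quantities must be positive and non-missing")
    return sub


def genorm_pairwise_sd(
    quantities: pd.DataFrame, gene_j: str, gene_k: str
) -> float:
    """SD (n-1) across samples of log2(Q_j / Q_k)."""
    qj = quantities.loc[gene_j].astype(float)
    qk = quantities.loc[gene_k].astype(float)
    ok = qj.notna() & qk.notna()
    if ok.sum() < 2:
        raise DomainError("pairwise SD needs >= 2 common samples")
    if (qj[ok] <= 0).any() or (qk[ok] <= 0).any():
        raise DomainError("quantities must be strictly positive")
    ratio = np.log2(qj[ok].to_numpy() / qk[ok].to_numpy())
    return float(ratio.std(ddof=1))


def genorm_m_values(
    quantities: pd.DataFrame, panel: Sequence[str] | None = None
) -> pd.Series:
    """M_j = mean over all other panel genes k of SD(log2(Q_j/Q_k))."""
    sub = _as_panel(quantities, panel)
    genes = list(sub.index)
    if len(genes) < 2:
        raise DomainError("geNorm M needs a panel of >= 2 genes")
    log_q = np.log2(sub.to_numpy(dtype=float))
    m = {}
    for i, g in enumerate(genes):
        sds = [
            float(np.std(log_q[i] - log_q[j], ddof=1))
            for j in range(len(genes))
            if j != i
        ]
        m[g] = float(np.mean(sds))
    return pd.Series(m, name="genorm_m")


def genorm_rank(
    quantities: pd.DataFrame, panel: Sequence[str] | None = None
) -> GenormResult:
    """Stepwise geNorm ranking: repeatedly drop the highest-M gene.

    The two genes remaining at the end cannot be ranked against each other
    (their M values are identical by construction) and share rank 1; the
    next gene takes rank 3 under competition ranking.  Ties in the worst M
    are broken lexicographically and logged.
    """
    sub = _as_panel(quantities, panel)
    genes = list(sub.index)
    if len(genes) < 3:
        raise DomainError("stepwise geNorm needs a panel of >= 3 genes")
    full_m = genorm_m_values(sub)
    remaining = list(genes)
    exclusion: list[str] = []
    trajectory: list[dict] = []
    stepwise_m = pd.Series(index=pd.Index(genes), dtype=float)
    while len(remaining) > 2:
        m = genorm_m_values(sub.loc[remaining])
        trajectory.append({"panel": list(remaining), "m_values": m.to_dict()})
        worst_m = m.max()
        tied = sorted(m.index[m == worst_m])
        if len(tied) > 1:
            logger.info(
                "geNorm: tie at M=%.6g among %s; excluding %s (lexicographic)",
                worst_m,
                tied,
                tied[0],
            )
        worst = tied[0]
        stepwise_m.loc[worst] = float(m[worst])
        exclusion.append(worst)
        remaining.remove(worst)
    final_pair = sorted(remaining)
    final_m = genorm_m_values(sub.loc[final_pair])
    stepwise_m.loc[final_pair] = final_m
    trajectory.append(
        {"panel": list(final_pair), "m_values": final_m.to_dict()}
    )
    exclusion_order = exclusion + final_pair
    ranks = pd.Series(index=pd.Index(genes), dtype=int)
    ranks.loc[final_pair] = 1
    # the gene excluded when n genes remained is the n-th most stable
    for step, gene in enumerate(exclusion):
        ranks.loc[gene] = len(genes) - step
    v_series = genorm_v_series(sub, stability_order(exclusion_order))
    return GenormResult(
        m_values=full_m,
        stepwise_m=stepwise_m,
        exclusion_order=exclusion_order,
        m_trajectory=trajectory,
        ranks=ranks.astype(int),
        v_series=v_series,
    )


def stability_order(exclusion_order: Sequence[str]) -> list[str]:
    """Most-stable-first gene order from a least-stable-first exclusion order."""
    return list(reversed(list(exclusion_order)))


def genorm_v_series(
    quantities: pd.DataFrame,
    order_most_stable_first: Sequence[str],
    max_n: int | None = None,
) -> dict[int, float]:
    """Pairwise variations V_{n/(n+1)} for n = 2 .. max_n.

    NF_n is the per-sample geometric mean of the n most stable genes'
    quantities; V_{n/(n+1)} is the SD across samples of log2(NF_n/NF_{n+1}).
    """
    order = list(order_most_stable_first)
    sub = _as_panel(quantities, order)
    if max_n is None:
        max_n = len(order) - 1
    if max_n > len(order) - 1:
        raise DomainError("max_n may not exceed panel size - 1")
    log_q = np.log2(sub.loc[order].to_numpy(dtype=float))
    v: dict[int, float] = {}
    for n in range(2, max_n + 1):
        log_nf_n = log_q[:n].mean(axis=0)
        log_nf_n1 = log_q[: n + 1].mean(axis=0)
        v[n] = float(np.std(log_nf_n - log_nf_n1, ddof=1))
    return v


def optimal_rg_count(
    v_series: Mapping[int, float], threshold: float = V_THRESHOLD
) -> tuple[int, str | None]:
    """Smallest n with V_{n/(n+1)} below the cut-off.

    If no entry is below the threshold, the largest available n is returned
    together with the flag ``"no_n_satisfies_threshold"``.
    """
    if not v_series:
        raise DomainError("v_series is empty")
    for n in sorted(v_series):
        if v_series[n] < threshold:
            return n, None
    return max(v_series), "no_n_satisfies_threshold"


# ---------------------------------------------------------------------------
# NormFinder
# ---------------------------------------------------------------------------

def normfinder_stability(
    log_quantities: pd.DataFrame,
    groups: Mapping[str, str] | pd.Series | None = None,
) -> NormfinderResult:
    """Model-based stability values on log-scale expression.

    Grouped mode decomposes the sample-centred log expression of gene *i* in
    group *g* into an inter-group deviation d_ig (the gene x group
    interaction, summing to zero over genes within each group and over
    groups within each gene) and an intra-group variance sigma2_ig.  Raw
    variances are corrected for the correlation introduced by per-sample
    centring, the d_ig are shrunk toward zero with an empirical-Bayes factor
    gamma2/(gamma2 + var(d_ig)), and the stability value is the mean over
    groups of |shrunken d_ig| + sqrt(sigma2_ig / n_g).  Ungrouped mode
    reduces to the SD of the sample-centred log expression.

    Requires >= 3 genes in grouped mode (the variance correction divides by
    #genes - 2) and >= 2 samples per group.
    """
    y = log_quantities.astype(float)
    if y.isna().to_numpy().any():
        raise DomainError("NormFinder input must be complete (no missing values)")
    k = y.shape[0]
    if k < 2:
        raise DomainError("NormFinder needs >= 2 genes")
    z = y - y.mean(axis=0)  # remove per-sample (loading) effects

    if groups is None:
        sd = z.std(axis=1, ddof=1)
        return NormfinderResult(
            stability=sd.rename("normfinder_stability"),
            intergroup=None,
            intragroup_var=None,
            grouped=False,
        )

    if k < 3:
        raise DomainError("grouped NormFinder needs >= 3 genes")
    grp = pd.Series({s: groups[s] for s in y.columns})
    levels = sorted(grp.unique())
    if len(levels) < 2:
        raise DomainError("grouped NormFinder needs >= 2 groups")
    zbar = pd.DataFrame(index=y.index, columns=levels, dtype=float)
    sigma2 = pd.DataFrame(index=y.index, columns=levels, dtype=float)
    n_per = {}
    for g in levels:
        cols = grp.index[grp == g]
        if len(cols) < 2:
            raise DomainError(f"group {g!r} has fewer than 2 samples")
        n_per[g] = len(cols)
        zg = z[cols]
        zbar[g] = zg.mean(axis=1)
        s2 = zg.var(axis=1, ddof=1)
        # correct for the -1/k correlation induced by per-sample centring:
        # E[s2_ig] = sigma2_ig (k-2)/k + mean_i(sigma2_ig)/k
        sigma2_bar = s2.mean() * k / (k - 1)
        sigma2[g] = np.maximum((s2 - sigma2_bar / k) * k / (k - 2), 0.0)
    d = zbar.sub(zbar.mean(axis=1), axis=0)  # gene x group interaction
    var_d = sigma2.div(pd.Series(n_per))  # sampling variance of d_ig
    n_lev = len(levels)
    gamma2 = max(
        float((d**2).to_numpy().sum()) / ((k - 1) * (n_lev - 1))
        - float(var_d.to_numpy().mean()),
        0.0,
    )
    denom = gamma2 + var_d
    shrink = (gamma2 / denom).where(denom > 0, 0.0)
    d_shrunk = d * shrink
    rho = d_shrunk.abs() + np.sqrt(var_d)
    stability = rho.mean(axis=1).rename("normfinder_stability")
    return NormfinderResult(
        stability=stability,
        intergroup=d,  # centred interaction terms (pre-shrinkage)
        intragroup_var=sigma2,
        grouped=True,
    )


# ---------------------------------------------------------------------------
# BestKeeper and comparative Delta-Ct (raw Cq scale)
# ---------------------------------------------------------------------------

def bestkeeper_stats(
    cq: pd.DataFrame,
    panel: Sequence[str] | None = None,
    sd_method: str = "sample_sd",
) -> BestkeeperResult:
    """Descriptive Cq spread per gene plus correlation with the panel index.

    ``sd_method`` selects the spread estimator: ``"sample_sd"`` (n-1 SD, the
    default) or ``"mean_abs_dev"`` (the original tool's mean absolute
    deviation from the mean).  CV% = spread / mean * 100.  The BestKeeper
    index is the per-sample geometric mean of Cq over the panel; missing Cq
    are handled pairwise-complete.
    """
    if sd_method not in ("sample_sd", "mean_abs_dev"):
        raise ConfigError("sd_method must be 'sample_sd' or 'mean_abs_dev'")
    sub = cq if panel is None else cq.loc[list(panel)]
    if sub.shape[0] < 1:
        raise DomainError("BestKeeper needs a panel of >= 1 gene")
    index = np.exp(np.log(sub).mean(axis=0, skipna=True)).rename("bestkeeper_index")
    rows = {}
    for gene in sub.index:
        vals = sub.loc[gene].astype(float)
        ok = vals.notna()
        if ok.sum() < 2:
            raise DomainError(f"gene {gene!r} has < 2 Cq values")
        v = vals[ok].to_numpy()
        mean = v.mean()
        if sd_method == "sample_sd":
            sd = v.std(ddof=1)
        else:
            sd = np.abs(v - mean).mean()
        both = ok & index.notna()
        if both.sum() >= 2 and np.std(vals[both]) > 0 and np.std(index[both]) > 0:
            r = float(_sps.pearsonr(vals[both], index[both]).statistic)
        else:
            r = float("nan")
        rows[gene] = {
            "mean_cq": float(mean),
            "sd_cq": float(sd),
            "cv_percent": float(sd / mean * 100.0),
            "r_vs_index": r,
        }
    table = pd.DataFrame(rows).T.loc[sub.index]
    return BestkeeperResult(table=table, index=index)


def delta_ct_stability(
    cq: pd.DataFrame, panel: Sequence[str] | None = None
) -> pd.Series:
    """Comparative Delta-Ct: mean over partners of SD(Cq_j - Cq_k)."""
    sub = cq if panel is None else cq.loc[list(panel)]
    genes = list(sub.index)
    if len(genes) < 2:
        raise DomainError("the Delta-Ct method needs a panel of >= 2 genes")
    arr = sub.to_numpy(dtype=float)
    sd = np.full((len(genes), len(genes)), np.nan)
    for i in range(len(genes)):
        for j in range(i + 1, len(genes)):
            diff = arr[i] - arr[j]
            diff = diff[~np.isnan(diff)]
            if diff.size < 2:
                raise DomainError(
                    f"genes {genes[i]!r}/{genes[j]!r} share < 2 complete samples"
                )
            sd[i, j] = sd[j, i] = np.std(diff, ddof=1)
    stability = pd.Series(np.nanmean(sd, axis=1), index=genes, name="delta_ct_sv")
    return stability


# ---------------------------------------------------------------------------
# Ranking and aggregation
# ---------------------------------------------------------------------------

def rank_genes(values: pd.Series | Mapping[str, float], ascending: bool = True) -> pd.Series:
    """Competition ranking: ties share the minimum rank, next value skips."""
    s = pd.Series(values, dtype=float)
    if not np.isfinite(s.to_numpy()).all():
        raise DomainError("ranks require finite values")
    return s.rank(method="min", ascending=ascending).astype(int)


def reffinder_aggregate(ranks_by_method: pd.DataFrame) -> pd.DataFrame:
    """Geometric-mean aggregation of per-method ranks (RefFinder style).

    ``ranks_by_method`` has genes in rows and one column of positive integer
    ranks per method.  Returns a DataFrame sorted by the geometric mean with
    columns ``reffinder_geomean`` and ``reffinder_rank`` (competition
    ranking of the geomeans).
    """
    r = ranks_by_method.astype(float)
    if r.isna().to_numpy().any():
        raise DomainError("every gene needs a rank from every method")
    if (r.to_numpy() < 1).any():
        raise DomainError("ranks must be positive")
    geomean = np.exp(np.log(r).mean(axis=1)).rename("reffinder_geomean")
    out = geomean.to_frame()
    out["reffinder_rank"] = rank_genes(geomean)
    return out.sort_values(["reffinder_geomean", "reffinder_rank"]).join(
        ranks_by_method
    )[list(ranks_by_method.columns) + ["reffinder_geomean", "reffinder_rank"]]


# ---------------------------------------------------------------------------
# Panel-level orchestration
# ---------------------------------------------------------------------------

DEFAULT_METHODS = ("genorm", "normfinder", "bestkeeper", "deltact")


def evaluate_panel(
    cq_matrix: CqMatrix,
    panel: Sequence[str] | None = None,
    efficiency_base: float | Mapping[str, float] = 2.0,
    methods: Sequence[str] = DEFAULT_METHODS,
    v_threshold: float = V_THRESHOLD,
    max_missing_fraction: float = 0.5,
) -> StabilityReport:
    """Run the selected stability methods on a Cq panel and aggregate ranks.

    geNorm and NormFinder run on relative quantities derived from the Cq
    values (per-gene efficiency base, default perfect doubling); BestKeeper
    and the Delta-Ct method run on the raw Cq.  Genes missing in more than
    ``max_missing_fraction`` of samples are excluded with a logged reason.
    A failing method is recorded in ``failures`` and does not abort the
    others.
    """
    unknown = set(methods) - set(DEFAULT_METHODS)
    if unknown:
        raise ConfigError(f"unknown stability methods: {sorted(unknown)}")
    if cq_matrix.replicate_of is not None:
        cq_matrix = collapse_replicates(cq_matrix)
    cq = cq_matrix.cq if panel is None else cq_matrix.cq.loc[list(panel)]
    frac_missing = cq.isna().mean(axis=1)
    dropped = frac_missing.index[frac_missing > max_missing_fraction]
    for gene in dropped:
        logger.warning(
            "excluding gene %s: missing in %.0f%% of samples",
            gene,
            100 * frac_missing[gene],
        )
    cq = cq.drop(index=dropped)
    genes = list(cq.index)
    failures: dict[str, str] = {}
    values: dict[str, pd.Series] = {}
    genorm_res: GenormResult | None = None
    normfinder_res: NormfinderResult | None = None
    bestkeeper_res: BestkeeperResult | None = None
    deltact_sv: pd.Series | None = None
    ranks: dict[str, pd.Series] = {}

    quantities = None
    if "genorm" in methods or "normfinder" in methods:
        sub_matrix = CqMatrix(cq, dict(cq_matrix.group_of))
        quantities = relative_quantities(sub_matrix, efficiency_base)

    if "genorm" in methods:
        try:
            genorm_res = genorm_rank(quantities)
            values["genorm"] = genorm_res.stepwise_m
            ranks["genorm"] = genorm_res.ranks
        except (DomainError, ConfigError) as exc:
            failures["genorm"] = str(exc)
            logger.warning("geNorm failed: %s", exc)
    if "normfinder" in methods:
        try:
            normfinder_res = normfinder_stability(
                np.log2(quantities), groups=cq_matrix.group_of
            )
            values["normfinder"] = normfinder_res.stability
            ranks["normfinder"] = rank_genes(normfinder_res.stability)
        except (DomainError, ConfigError) as exc:
            failures["normfinder"] = str(exc)
            logger.warning("NormFinder failed: %s", exc)
    if "bestkeeper" in methods:
        try:
            bestkeeper_res = bestkeeper_stats(cq)
            values["bestkeeper"] = bestkeeper_res.sd_cq
            ranks["bestkeeper"] = rank_genes(bestkeeper_res.sd_cq)
        except (DomainError, ConfigError) as exc:
            failures["bestkeeper"] = str(exc)
            logger.warning("BestKeeper failed: %s", exc)
    if "deltact" in methods:
        try:
            deltact_sv = delta_ct_stability(cq)
            values["deltact"] = deltact_sv
            ranks["deltact"] = rank_genes(deltact_sv)
        except (DomainError, ConfigError) as exc:
            failures["deltact"] = str(exc)
            logger.warning("Delta-Ct failed: %s", exc)

    table = pd.DataFrame(index=pd.Index(genes, name="gene_id"))
    for method in methods:
        if method in values:
            table[f"{method}_value"] = values[method]
            table[f"{method}_rank"] = ranks[method]
    if ranks:
        agg = reffinder_aggregate(pd.DataFrame(ranks).loc[genes])
        table = table.join(agg[["reffinder_geomean", "reffinder_rank"]])
        table = table.sort_values(["reffinder_geomean", "reffinder_rank"])
    v_series = genorm_res.v_series if genorm_res else {}
    optimal_n = optimal_flag = None
    if v_series:
        optimal_n, optimal_flag = optimal_rg_count(v_series, v_threshold)
    return StabilityReport(
        table=table,
        genorm=genorm_res,
        normfinder=normfinder_res,
        bestkeeper=bestkeeper_res,
        delta_ct=deltact_sv,
        v_series=v_series,
        optimal_n=optimal_n,
        optimal_flag=optimal_flag,
        failures=failures,
    )
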