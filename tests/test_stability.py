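"""Tests for geNorm, NormFinder, BestKeeper, Delta-Ct and rank aggregation.

The brute-force oracles in this file recompute each statistic from its
definition with explicit Python loops and the ``statistics`` module, so
they share no code path with the vectorised implementations they check.
"""

import itertools
import math
import statistics

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from refstab import (
    CqMatrix,
    DomainError,
    bestkeeper_stats,
    delta_ct_stability,
    evaluate_panel,
    genorm_m_values,
    genorm_pairwise_sd,
    genorm_rank,
    genorm_v_series,
    normfinder_stability,
    optimal_rg_count,
    rank_genes,
    reffinder_aggregate,
)
from refstab.stability import stability_order


def _q(rows: dict[str, list[float]]) -> pd.DataFrame:
    df = pd.DataFrame(rows).T
    df.columns = [f"s{i}" for i in range(df.shape[1])]
    return df


# ---------------------------------------------------------------------------
# geNorm
# ---------------------------------------------------------------------------

def test_genorm_pairwise_sd_examples():
    q = _q({"j": [1.0, 2.0, 4.0], "k": [1.0, 1.0, 1.0]})
    assert genorm_pairwise_sd(q, "j", "k") == pytest.approx(1.0, abs=1e-12)
    prop = _q({"j": [1.0, 2.0, 4.0], "k": [3.0, 6.0, 12.0]})
    assert genorm_pairwise_sd(prop, "j", "k") == pytest.approx(0.0, abs=1e-12)
    scaled = _q({"j": [10.0, 20.0, 40.0], "k": [1.0, 1.0, 1.0]})
    assert genorm_pairwise_sd(scaled, "j", "k") == pytest.approx(1.0, abs=1e-12)


def _m_oracle(q: pd.DataFrame) -> dict[str, float]:
    genes = list(q.index)
    out = {}
    for g in genes:
        sds = []
        for h in genes:
            if h == g:
                continue
            ratios = [
                math.log2(q.loc[g, s] / q.loc[h, s]) for s in q.columns
            ]
            sds.append(statistics.stdev(ratios))
        out[g] = sum(sds) / len(sds)
    return out


def test_genorm_m_matches_bruteforce_oracle(rng):
    q = pd.DataFrame(
        rng.lognormal(0, 0.5, size=(3, 4)),
        index=["a", "b", "c"],
        columns=[f"s{i}" for i in range(4)],
    )
    m = genorm_m_values(q)
    oracle = _m_oracle(q)
    for g in q.index:
        assert m[g] == pytest.approx(oracle[g], abs=1e-12)


def test_genorm_m_proportional_pair_is_zero():
    q = _q({"a": [1.0, 2.0, 4.0], "b": [0.5, 1.0, 2.0]})
    m = genorm_m_values(q)
    assert m["a"] == pytest.approx(0.0, abs=1e-12)
    assert m["b"] == pytest.approx(0.0, abs=1e-12)


def test_genorm_rank_excludes_noise_gene_first(rng):
    samples = [f"s{i}" for i in range(8)]
    base = rng.lognormal(0, 0.05, size=8)
    q = pd.DataFrame(
        {
            "steady1": base * 1.0,
            "steady2": base * rng.lognormal(0, 0.05, 8),
            "chaos": rng.lognormal(0, 1.5, 8),
        }
    ).T
    q.columns = samples
    res = genorm_rank(q)
    assert res.exclusion_order[0] == "chaos"
    assert set(res.exclusion_order[-2:]) == {"steady1", "steady2"}
    assert res.ranks["steady1"] == 1 and res.ranks["steady2"] == 1
    assert res.ranks["chaos"] == 3


def test_genorm_stepwise_equals_naive_recomputation(rng):
    genes = list("abcde")
    q = pd.DataFrame(
        rng.lognormal(0, 0.6, size=(5, 6)),
        index=genes,
        columns=[f"s{i}" for i in range(6)],
    )
    res = genorm_rank(q)
    remaining = sorted(genes)
    for step in res.m_trajectory[:-1]:
        assert sorted(step["panel"]) == sorted(remaining)
        oracle = _m_oracle(q.loc[step["panel"]])
        for g, m in step["m_values"].items():
            assert m == pytest.approx(oracle[g], abs=1e-12)
        worst = max(sorted(oracle), key=lambda g: oracle[g])
        remaining = [g for g in remaining if g != worst]
    assert sorted(res.m_trajectory[-1]["panel"]) == sorted(remaining)


def test_genorm_requires_minimum_panel():
    q = _q({"a": [1.0, 2.0], "b": [2.0, 3.0]})
    with pytest.raises(DomainError):
        genorm_rank(q)


def _v_oracle(q: pd.DataFrame, order: list[str], n: int) -> float:
    logs = []
    for s in q.columns:
        nf_n = statistics.geometric_mean([q.loc[g, s] for g in order[:n]])
        nf_n1 = statistics.geometric_mean([q.loc[g, s] for g in order[: n + 1]])
        logs.append(math.log2(nf_n / nf_n1))
    return statistics.stdev(logs)


def test_genorm_v_series_matches_definition(rng):
    genes = list("abcd")
    q = pd.DataFrame(
        rng.lognormal(0, 0.4, size=(4, 6)),
        index=genes,
        columns=[f"s{i}" for i in range(6)],
    )
    order = stability_order(genorm_rank(q).exclusion_order)
    v = genorm_v_series(q, order)
    assert set(v) == {2, 3}
    for n in v:
        assert v[n] == pytest.approx(_v_oracle(q, order, n), abs=1e-12)


def test_genorm_v_zero_when_next_gene_proportional_to_nf():
    # gene c proportional to geomean(a, b) -> adding it changes nothing
    a = [1.0, 2.0, 4.0, 8.0]
    b = [2.0, 2.0, 2.0, 2.0]
    c = [5 * math.sqrt(x * y) for x, y in zip(a, b)]
    q = _q({"a": a, "b": b, "c": c})
    v = genorm_v_series(q, ["a", "b", "c"])
    assert v[2] == pytest.approx(0.0, abs=1e-12)


@pytest.mark.parametrize(
    "series, expected_n, expected_flag",
    [
        ({2: 0.132}, 2, None),
        ({2: 0.20, 3: 0.14}, 3, None),
        ({2: 0.2, 3: 0.18, 4: 0.16}, 4, "no_n_satisfies_threshold"),
    ],
)
def test_optimal_rg_count_threshold_logic(series, expected_n, expected_flag):
    n, flag = optimal_rg_count(series)
    assert (n, flag) == (expected_n, expected_flag)


def test_genorm_invariances(rng):
    genes = list("abcd")
    samples = [f"s{i}" for i in range(6)]
    q = pd.DataFrame(rng.lognormal(0, 0.5, size=(4, 6)), index=genes,
                     columns=samples)
    m = genorm_m_values(q)
    # per-gene rescaling cancels in the log-ratio SD
    scaled = q.mul(pd.Series({"a": 10.0, "b": 0.2, "c": 7.0, "d": 1.0}), axis=0)
    pd.testing.assert_series_equal(m, genorm_m_values(scaled), atol=1e-10)
    perm = list(rng.permutation(samples))
    pd.testing.assert_series_equal(m, genorm_m_values(q[perm]), atol=1e-10)
    order = stability_order(genorm_rank(q).exclusion_order)
    v1 = genorm_v_series(q, order)
    v2 = genorm_v_series(scaled[perm], order)
    for n in v1:
        assert v1[n] == pytest.approx(v2[n], abs=1e-10)


# ---------------------------------------------------------------------------
# NormFinder
# ---------------------------------------------------------------------------

def _normfinder_oracle(y: pd.DataFrame, groups: dict[str, str]) -> dict[str, float]:
    """Loop transliteration of the grouped model-based stability value."""
    genes, samples = list(y.index), list(y.columns)
    k = len(genes)
    levels = sorted(set(groups.values()))
    z = {}
    for s in samples:
        col_mean = sum(y.loc[g, s] for g in genes) / k
        for g in genes:
            z[(g, s)] = y.loc[g, s] - col_mean
    zbar, s2, n_per = {}, {}, {}
    for lev in levels:
        cols = [s for s in samples if groups[s] == lev]
        n_per[lev] = len(cols)
        for g in genes:
            vals = [z[(g, s)] for s in cols]
            zbar[(g, lev)] = statistics.fmean(vals)
            s2[(g, lev)] = statistics.variance(vals)
    sigma2 = {}
    for lev in levels:
        s2bar = statistics.fmean([s2[(g, lev)] for g in genes])
        sigma2bar = s2bar * k / (k - 1)
        for g in genes:
            sigma2[(g, lev)] = max((s2[(g, lev)] - sigma2bar / k) * k / (k - 2), 0.0)
    d = {}
    for g in genes:
        gene_mean = statistics.fmean([zbar[(g, lev)] for lev in levels])
        for lev in levels:
            d[(g, lev)] = zbar[(g, lev)] - gene_mean
    var_d = {key: sigma2[key] / n_per[key[1]] for key in d}
    gamma2 = max(
        sum(v**2 for v in d.values()) / ((k - 1) * (len(levels) - 1))
        - statistics.fmean(var_d.values()),
        0.0,
    )
    out = {}
    for g in genes:
        terms = []
        for lev in levels:
            shrink = gamma2 / (gamma2 + var_d[(g, lev)]) if gamma2 + var_d[(g, lev)] > 0 else 0.0
            terms.append(abs(d[(g, lev)] * shrink) + math.sqrt(var_d[(g, lev)]))
        out[g] = statistics.fmean(terms)
    return out


def test_normfinder_identical_genes_are_symmetric():
    samples = {f"s{i}": ("g1" if i < 3 else "g2") for i in range(6)}
    row = [1.0, 1.2, 0.9, 1.4, 1.1, 1.0]
    y = pd.DataFrame({g: row for g in ["a", "b", "c"]}).T
    y.columns = list(samples)
    res = normfinder_stability(y, samples)
    vals = res.stability.to_numpy()
    np.testing.assert_allclose(vals, vals[0], atol=1e-12)


def test_normfinder_group_shifted_gene_ranks_last(rng):
    groups = {f"s{i}": ("g1" if i < 4 else "g2") for i in range(8)}
    y = pd.DataFrame(
        rng.normal(0, 0.1, size=(4, 8)),
        index=["a", "b", "c", "shifty"],
        columns=list(groups),
    )
    y.loc["shifty", [f"s{i}" for i in range(4)]] += 2.0  # group-specific shift
    res = normfinder_stability(y, groups)
    assert res.stability.idxmax() == "shifty"
    assert res.grouped
    # interaction terms sum to ~0 over genes and over groups
    assert abs(res.intergroup.to_numpy().sum()) < 1e-8


def test_normfinder_matches_loop_transliteration(rng):
    groups = {f"s{i}": ("g1" if i < 3 else "g2") for i in range(6)}
    y = pd.DataFrame(
        rng.normal(0, 0.5, size=(3, 6)),
        index=["a", "b", "c"],
        columns=list(groups),
    )
    res = normfinder_stability(y, groups)
    oracle = _normfinder_oracle(y, groups)
    for g in y.index:
        assert res.stability[g] == pytest.approx(oracle[g], abs=1e-6)


def test_normfinder_ungrouped_is_centered_sd(rng):
    y = pd.DataFrame(
        rng.normal(0, 0.5, size=(3, 6)),
        index=["a", "b", "c"],
        columns=[f"s{i}" for i in range(6)],
    )
    res = normfinder_stability(y, groups=None)
    z = y - y.mean(axis=0)
    for g in y.index:
        assert res.stability[g] == pytest.approx(
            statistics.stdev(z.loc[g].tolist()), abs=1e-12
        )


def test_normfinder_input_validation():
    groups = {"s0": "g1", "s1": "g1", "s2": "g2", "s3": "g2"}
    y = pd.DataFrame([[1.0, 2.0, 3.0, 4.0]], index=["a"], columns=list(groups))
    with pytest.raises(DomainError):
        normfinder_stability(y, groups)  # < 2 genes
    y2 = pd.DataFrame(np.ones((2, 4)), index=["a", "b"], columns=list(groups))
    with pytest.raises(DomainError):
        normfinder_stability(y2, groups)  # grouped mode needs >= 3 genes


# ---------------------------------------------------------------------------
# BestKeeper and Delta-Ct
# ---------------------------------------------------------------------------

def test_bestkeeper_hand_computed_values():
    cq = _q({"flat": [20.0, 20.0], "pair": [19.0, 21.0]})
    res = bestkeeper_stats(cq)
    assert res.table.loc["flat", "sd_cq"] == pytest.approx(0.0, abs=1e-12)
    assert res.table.loc["flat", "cv_percent"] == pytest.approx(0.0, abs=1e-12)
    assert res.table.loc["pair", "sd_cq"] == pytest.approx(math.sqrt(2), abs=1e-9)
    assert res.table.loc["pair", "cv_percent"] == pytest.approx(7.0711, abs=1e-4)


def test_bestkeeper_index_and_correlation_oracle(rng):
    genes = ["a", "b", "c"]
    cq = pd.DataFrame(rng.uniform(15, 25, size=(3, 8)), index=genes,
                      columns=[f"s{i}" for i in range(8)])
    res = bestkeeper_stats(cq)
    for s in cq.columns:
        assert res.index[s] == pytest.approx(
            statistics.geometric_mean([cq.loc[g, s] for g in genes]), abs=1e-9
        )
    for g in genes:
        x = cq.loc[g].to_numpy()
        y = res.index.to_numpy()
        r_oracle = (
            ((x - x.mean()) * (y - y.mean())).sum()
            / math.sqrt(((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum())
        )
        assert res.table.loc[g, "r_vs_index"] == pytest.approx(r_oracle, abs=1e-9)
        assert res.table.loc[g, "cv_percent"] == pytest.approx(
            res.table.loc[g, "sd_cq"] / res.table.loc[g, "mean_cq"] * 100, abs=1e-9
        )


def test_bestkeeper_invariances(rng):
    cq = pd.DataFrame(rng.uniform(15, 25, size=(3, 8)), index=["a", "b", "c"],
                      columns=[f"s{i}" for i in range(8)])
    base = bestkeeper_stats(cq)
    perm = list(rng.permutation(cq.columns))
    permuted = bestkeeper_stats(cq[perm])
    pd.testing.assert_series_equal(base.table["sd_cq"], permuted.table["sd_cq"],
                                   atol=1e-10)
    shifted = cq.copy()
    shifted.loc["a"] += 2.0
    res = bestkeeper_stats(shifted)
    assert res.table.loc["a", "mean_cq"] == pytest.approx(
        base.table.loc["a", "mean_cq"] + 2.0)
    assert res.table.loc["a", "sd_cq"] == pytest.approx(
        base.table.loc["a", "sd_cq"], abs=1e-10)


def test_bestkeeper_mean_abs_dev_variant():
    cq = _q({"pair": [19.0, 21.0, 20.0], "other": [18.0, 19.0, 20.0]})
    res = bestkeeper_stats(cq, sd_method="mean_abs_dev")
    assert res.table.loc["pair", "sd_cq"] == pytest.approx(2.0 / 3.0, abs=1e-12)


def test_delta_ct_examples_and_bruteforce(rng):
    offset = _q({"a": [20.0, 21.0, 22.0], "b": [21.5, 22.5, 23.5]})
    sv = delta_ct_stability(offset)
    assert sv["a"] == pytest.approx(0.0, abs=1e-12)
    assert sv["b"] == pytest.approx(0.0, abs=1e-12)
    cq = pd.DataFrame(rng.uniform(15, 25, size=(3, 6)), index=["a", "b", "c"],
                      columns=[f"s{i}" for i in range(6)])
    sv = delta_ct_stability(cq)
    for g in cq.index:
        sds = []
        for h in cq.index:
            if h == g:
                continue
            diffs = [cq.loc[g, s] - cq.loc[h, s] for s in cq.columns]
            sds.append(statistics.stdev(diffs))
        assert sv[g] == pytest.approx(statistics.fmean(sds), abs=1e-12)


def test_delta_ct_two_gene_panel_is_symmetric(rng):
    cq = pd.DataFrame(rng.uniform(15, 25, size=(2, 5)), index=["a", "b"],
                      columns=[f"s{i}" for i in range(5)])
    sv = delta_ct_stability(cq)
    assert sv["a"] == pytest.approx(sv["b"], abs=1e-12)


# ---------------------------------------------------------------------------
# ranking and aggregation
# ---------------------------------------------------------------------------

def test_rank_genes_competition_convention():
    ranks = rank_genes(pd.Series({"a": 0.1, "b": 0.1, "c": 0.3}))
    assert ranks.tolist() == [1, 1, 3]
    increasing = rank_genes(pd.Series({"a": 1.0, "b": 2.0, "c": 3.0}))
    assert increasing.tolist() == [1, 2, 3]


@settings(max_examples=50, deadline=None, derandomize=True)
@given(st.lists(st.floats(min_value=-100, max_value=100), min_size=1, max_size=20))
def test_rank_genes_agrees_with_counting_oracle(values):
    s = pd.Series(values, index=[f"g{i}" for i in range(len(values))])
    ranks = rank_genes(s)
    for g in s.index:
        assert ranks[g] == 1 + sum(s[h] < s[g] for h in s.index)


def test_reffinder_geomean_worked_examples():
    ranks = pd.DataFrame(
        {"m1": [1, 1, 2], "m2": [1, 2, 2], "m3": [2, 3, 2], "m4": [3, 2, 2]},
        index=["top", "second", "flat"],
    )
    out = reffinder_aggregate(ranks)
    assert out.loc["top", "reffinder_geomean"] == pytest.approx(6 ** 0.25, abs=1e-9)
    assert out.loc["second", "reffinder_geomean"] == pytest.approx(12 ** 0.25, abs=1e-9)
    assert out.loc["flat", "reffinder_geomean"] == pytest.approx(2.0, abs=1e-12)
    assert out["reffinder_rank"].tolist() == [1, 2, 3]
    with pytest.raises(DomainError):
        reffinder_aggregate(ranks.assign(m5=[1, np.nan, 2]))


# ---------------------------------------------------------------------------
# panel-level orchestration
# ---------------------------------------------------------------------------

def test_evaluate_panel_report_invariants(toy_cq):
    report = evaluate_panel(toy_cq)
    table = report.table
    assert not report.failures
    # RefFinder geomean re-verified from the report's own rank columns
    rank_cols = [c for c in table.columns if c.endswith("_rank")
                 and not c.startswith("reffinder")]
    for gene, row in table.iterrows():
        geomean = math.prod(row[c] for c in rank_cols) ** (1.0 / len(rank_cols))
        assert row["reffinder_geomean"] == pytest.approx(geomean, abs=1e-9)
    # the designed group-shifted gene is the least stable under every method
    for c in rank_cols:
        assert table[c].idxmax() == "drift"
    assert report.optimal_n is not None


def test_evaluate_panel_isolates_method_failures(toy_cq):
    two_gene = CqMatrix(toy_cq.cq.loc[["alpha", "beta"]], dict(toy_cq.group_of))
    report = evaluate_panel(two_gene)
    assert "genorm" in report.failures  # stepwise geNorm needs >= 3 genes
    assert "normfinder" in report.failures  # grouped mode needs >= 3 genes
    assert "bestkeeper_value" in report.table.columns
    assert "deltact_value" in report.table.columns


def test_evaluate_panel_drops_mostly_missing_gene(toy_cq, caplog):
    cq = toy_cq.cq.copy()
    cq.loc["sparse"] = [20.0, np.nan, np.nan, np.nan, np.nan, np.nan]
    matrix = CqMatrix(cq, dict(toy_cq.group_of))
    with caplog.at_level("WARNING"):
        report = evaluate_panel(matrix)
    assert "sparse" not in report.table.index
    assert "missing" in caplog.text
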