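"""Synthetic FPKM and Cq datasets with known ground-truth stability.

The generator emulates a multi-tissue reference-gene study: ``n_groups``
tissues with ``reps_per_group`` biological replicates each (default 6 x 3 =
18 samples), and a small panel of genes drawn from four designed classes:

* ``stable_high``  — abundant and stable (the ideal reference gene);
* ``stable_low``   — stable but below the abundance cut-off;
* ``tissue_specific`` — one tissue carries a fixed +4 log2 shift (e.g. a
  leaf-specific light-harvesting gene), otherwise quiet;
* ``noisy``        — large random tissue effects plus large within-tissue
  noise (the designed-unstable gene).

Expression is log-normal: for gene g, sample s in tissue t,

    log2 FPKM = baseline_g + group_effect_{g,t} + N(0, intragroup_sd)

with the group effect drawn once per gene x tissue from
N(0, intergroup_sd) (plus the fixed shift for tissue-specific genes).
Cq values derive from the *same* per-sample log2 expression:

    Cq = offset - log2(expression) / log2(E_b) + N(0, cq_noise_sd)

so that at E_b = 2 and zero noise, converting Cq back to relative
quantities recovers the simulated quantities exactly.

Each gene consumes its own deterministic random substream derived from the
dataset seed, so adding genes to a configuration never perturbs the values
of existing ones.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, DomainError
from .qpcr import CqMatrix
from .screen import ExpressionMatrix

__all__ = [
    "GeneClassSpec",
    "SimulationConfig",
    "SyntheticTruth",
    "default_screen_config",
    "default_stability_config",
    "simulate_fpkm",
    "simulate_cq",
    "truth_ranking",
]

GENE_CLASSES = ("stable_high", "stable_low", "tissue_specific", "noisy")

#: Default tissue labels for the six-group design.
DEFAULT_TISSUES = ("leaf", "root", "rhizome", "flower", "inflorescence", "seed")

#: Fixed log2 elevation of the expressing tissue for tissue-specific genes.
TISSUE_SHIFT_LOG2 = 4.0


@dataclass
class GeneClassSpec:
    """Parameters of one designed gene class (all SDs in log2 units)."""

    name: str
    count: int
    baseline_log2: float
    intergroup_sd: float
    intragroup_sd: float

    def __post_init__(self) -> None:
        if self.name not in GENE_CLASSES:
            raise ConfigError(f"unknown gene class {self.name!r}")
        if self.count < 0:
            raise ConfigError("class count must be >= 0")
        if self.intergroup_sd < 0 or self.intragroup_sd < 0:
            raise ConfigError("SDs must be >= 0")


@dataclass
class SimulationConfig:
    n_groups: int = 6
    reps_per_group: int = 3
    gene_classes: list[GeneClassSpec] = field(default_factory=list)
    cq_noise_sd: float = 0.2
    efficiency_base: float = 2.0
    cq_offset: float = 28.0
    technical_replicates: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_groups < 1 or self.reps_per_group < 1:
            raise ConfigError("n_groups and reps_per_group must be >= 1")
        if not 1.0 < self.efficiency_base <= 2.2:
            raise ConfigError("efficiency_base must lie in (1, 2.2]")
        if self.cq_noise_sd < 0:
            raise ConfigError("cq_noise_sd must be >= 0")
        if self.technical_replicates < 1:
            raise ConfigError("technical_replicates must be >= 1")
        if sum(c.count for c in self.gene_classes) < 2:
            raise ConfigError("a simulation needs at least 2 genes in total")

    def group_labels(self) -> list[str]:
        if self.n_groups <= len(DEFAULT_TISSUES):
            return list(DEFAULT_TISSUES[: self.n_groups])
        return [f"group{i + 1}" for i in range(self.n_groups)]


def default_screen_config(seed: int = 0) -> SimulationConfig:
    """The default screening scenario: 5 genes per designed class."""
    return SimulationConfig(
        gene_classes=[
            GeneClassSpec("stable_high", 5, baseline_log2=9.0, intergroup_sd=0.0, intragroup_sd=0.15),
            GeneClassSpec("stable_low", 5, baseline_log2=4.0, intergroup_sd=0.0, intragroup_sd=0.15),
            GeneClassSpec("tissue_specific", 5, baseline_log2=7.5, intergroup_sd=0.0, intragroup_sd=0.15),
            GeneClassSpec("noisy", 5, baseline_log2=9.0, intergroup_sd=1.5, intragroup_sd=1.0),
        ],
        seed=seed,
    )


def default_stability_config(seed: int = 0) -> SimulationConfig:
    """A qPCR-panel scenario: several stable genes, one tissue-specific
    gene and one designed-unstable gene."""
    return SimulationConfig(
        gene_classes=[
            GeneClassSpec("stable_high", 5, baseline_log2=9.0, intergroup_sd=0.0, intragroup_sd=0.15),
            GeneClassSpec("tissue_specific", 1, baseline_log2=7.5, intergroup_sd=0.0, intragroup_sd=0.15),
            GeneClassSpec("noisy", 1, baseline_log2=9.0, intergroup_sd=2.0, intragroup_sd=1.0),
        ],
        seed=seed,
    )


@dataclass
class SyntheticTruth:
    """Designed parameters and the realised latent expression per gene.

    ``table`` holds per-gene class labels, designed SDs and the realised
    per-group mean log2 expression; ``log2_expression`` is the latent
    per-sample log2 expression shared by the FPKM and Cq outputs.
    """

    table: pd.DataFrame  # gene_id, gene_class, baseline_log2, intergroup_sd, intragroup_sd
    group_means: pd.DataFrame  # gene x group true mean log2 expression
    log2_expression: pd.DataFrame  # gene x sample latent log2 expression
    tissue_of: dict[str, str]

    def to_json(self) -> str:
        payload = {
            "genes": self.table.to_dict(orient="index"),
            "group_means": self.group_means.round(10).to_dict(orient="index"),
            "tissue_of": self.tissue_of,
        }
        return json.dumps(payload, indent=2, sort_keys=True)


def _gene_rng(seed: int, gene_index: int, stream: int) -> np.random.Generator:
    # one substream per (gene, purpose); adding genes leaves earlier ones intact
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(gene_index, stream))
    )


def _gene_table(config: SimulationConfig) -> list[tuple[str, GeneClassSpec]]:
    out = []
    counters: dict[str, int] = {}
    for spec in config.gene_classes:
        for _ in range(spec.count):
            counters[spec.name] = counters.get(spec.name, 0) + 1
            out.append((f"{spec.name}_{counters[spec.name]:02d}", spec))
    return out


def simulate_fpkm(config: SimulationConfig) -> tuple[ExpressionMatrix, SyntheticTruth]:
    """Draw an FPKM matrix plus its ground truth from the configuration."""
    groups = config.group_labels()
    samples = [f"{g}_r{r + 1}" for g in groups for r in range(config.reps_per_group)]
    tissue_of = {s: s.rsplit("_r", 1)[0] for s in samples}
    gene_rows = _gene_table(config)
    log2_expr = pd.DataFrame(index=[g for g, _ in gene_rows], columns=samples, dtype=float)
    group_means = pd.DataFrame(index=log2_expr.index, columns=groups, dtype=float)
    meta = {}
    for idx, (gene, spec) in enumerate(gene_rows):
        rng = _gene_rng(config.seed, idx, stream=0)
        effects = rng.normal(0.0, spec.intergroup_sd, size=len(groups))
        if spec.name == "tissue_specific":
            effects = effects.copy()
            effects[idx % len(groups)] += TISSUE_SHIFT_LOG2
        means = spec.baseline_log2 + effects
        group_means.loc[gene] = means
        noise = rng.normal(0.0, spec.intragroup_sd, size=len(samples))
        per_sample = np.repeat(means, config.reps_per_group) + noise
        log2_expr.loc[gene] = per_sample
        # the truth records the *designed* spread: the population SD of the
        # realised group means (0 by construction for stable classes)
        meta[gene] = {
            "gene_class": spec.name,
            "baseline_log2": spec.baseline_log2,
            "intergroup_sd": float(np.std(means, ddof=0)),
            "intragroup_sd": spec.intragroup_sd,
        }
    truth = SyntheticTruth(
        table=pd.DataFrame(meta).T,
        group_means=group_means,
        log2_expression=log2_expr,
        tissue_of=tissue_of,
    )
    matrix = ExpressionMatrix(2.0**log2_expr, tissue_of)
    return matrix, truth


def simulate_cq(config: SimulationConfig, truth: SyntheticTruth) -> CqMatrix:
    """Derive a Cq matrix from the latent expression of a simulated dataset.

    Quantities are the same 2^log2-expression values underlying the FPKM
    output; Cq = offset - log_{E_b}(quantity) + Gaussian technical noise.
    With ``technical_replicates > 1``, replicate columns ``<sample>_t<j>``
    share the biological quantity and differ only in noise.
    """
    log2_expr = truth.log2_expression
    if not np.isfinite(log2_expr.to_numpy()).all():
        raise DomainError("latent expression must be finite and positive")
    base_log2 = np.log2(config.efficiency_base)
    n_rep = config.technical_replicates
    samples = list(log2_expr.columns)
    if n_rep == 1:
        columns = samples
        replicate_of = None
        group_of = dict(truth.tissue_of)
    else:
        columns = [f"{s}_t{j + 1}" for s in samples for j in range(n_rep)]
        replicate_of = {c: c.rsplit("_t", 1)[0] for c in columns}
        group_of = {c: truth.tissue_of[replicate_of[c]] for c in columns}
    cq = pd.DataFrame(index=log2_expr.index, columns=columns, dtype=float)
    for idx, gene in enumerate(log2_expr.index):
        rng = _gene_rng(config.seed, idx, stream=1)
        clean = config.cq_offset - log2_expr.loc[gene].to_numpy(float) / base_log2
        noisy = np.repeat(clean, n_rep) + rng.normal(0.0, config.cq_noise_sd, len(columns))
        cq.loc[gene] = noisy
    return CqMatrix(cq, group_of, replicate_of)


def truth_ranking(truth: SyntheticTruth) -> list[str]:
    """Designed stability ordering: ascending total designed variation
    sqrt(intergroup_sd^2 + intragroup_sd^2), ties broken by gene id."""
    t = truth.table
    total = np.sqrt(
        t["intergroup_sd"].astype(float) ** 2 + t["intragroup_sd"].astype(float) ** 2
    )
    order = sorted(t.index, key=lambda g: (total[g], g))
    return order
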