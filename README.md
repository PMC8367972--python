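# refstab

Reference-gene screening and qPCR expression-stability ranking for
multi-tissue gene-expression studies.

## The problem

Relative quantification by qRT-PCR reports the expression of a target gene
as a ratio against one or more *reference genes* (internal controls) that
are assumed to be stably expressed across all samples. Classical
"housekeeping" genes (actins, *GAPDH*, ubiquitins) often fail that
assumption, so modern studies determine references empirically in two
phases:

1. **Transcriptome-wide screening.** From an RNA-Seq FPKM matrix covering
   the tissues of interest, abundant genes (median FPKM ≥ 100) are scored
   by a composite Euclidean stability distance

   *d* = √(CV² + NMAD² + (1 − *p*)²)

   where CV is the coefficient of variation (SD/mean), NMAD the median
   absolute deviation normalised by the median, and *p* the Shapiro–Wilk
   normality p-value of the gene's FPKM values. Small *d* means low,
   symmetric, approximately normal variation; the top-*k* genes become the
   qPCR candidate panel.

2. **qPCR stability ranking.** The candidates' quantification cycles (Cq)
   across tissues are ranked by four algorithms — geNorm (*M* values and
   pairwise variation *V*<sub>n/n+1</sub>), NormFinder (intra-/inter-group
   variance decomposition), BestKeeper (SD and CV of raw Cq) and the
   comparative ΔCt method — and the ranks are aggregated by their geometric
   mean (RefFinder style). geNorm's *V*<sub>n/n+1</sub> < 0.15 criterion
   decides how many references are needed, and the chosen references are
   validated by 2<sup>−ΔCt</sup> normalization of test genes.

`refstab` implements both phases as a library, a CLI (`refstab`) and an
orchestrating pipeline, together with a synthetic-data generator that
produces FPKM and Cq datasets with *known* ground-truth stability classes,
so the whole workflow is testable without any external data.

## Worked example

```python
from refstab import (default_stability_config, simulate_fpkm, simulate_cq,
                     screen_candidates, evaluate_panel)

cfg = default_stability_config(seed=42)       # 5 stable + 1 tissue-specific + 1 noisy gene
matrix, truth = simulate_fpkm(cfg)            # 6 tissues x 3 replicates

stats = screen_candidates(matrix)             # abundance filter + d ranking
print(stats[["gene_id", "cv", "nmad", "p_normal", "d"]].head(3).round(3))

report = evaluate_panel(simulate_cq(cfg, truth))
print(report.table[["genorm_rank", "normfinder_rank", "bestkeeper_rank",
                    "deltact_rank", "reffinder_geomean"]].round(2))
print("optimal number of references:", report.optimal_n)
```

prints

```
       gene_id    cv  nmad  p_normal     d
stable_high_02 0.097 0.058     0.739 0.285
stable_high_01 0.132 0.084     0.306 0.712
stable_high_04 0.113 0.093     0.152 0.860

                    genorm_rank  normfinder_rank  bestkeeper_rank  deltact_rank  reffinder_geomean
stable_high_04                1                1                2             1               1.19
stable_high_02                3                4                1             2               2.21
stable_high_01                1                3                3             4               2.45
stable_high_03                5                2                4             3               3.31
stable_high_05                4                5                5             5               4.73
noisy_01                      6                7                6             6               6.24
tissue_specific_01            7                6                7             7               6.74

optimal number of references: 2
```

The screening table shows the stability distance assembled from its three
components (the best gene has low CV/NMAD *and* a high normality p-value).
The stability report ranks each gene under all four algorithms — geNorm's
final tied pair both take rank 1 — and aggregates the ranks by geometric
mean: the designed-unstable `noisy_01` and the tissue-specific gene fall to
the bottom, and the *V* series says two reference genes suffice
(*V*<sub>2/3</sub> < 0.15).

The same workflow is available from the shell:

```bash
refstab simulate --seed 3 --out sim
refstab screen --fpkm sim/fpkm.tsv --tissues sim/tissues.tsv --top-k 12 --out screen_out
refstab stability --cq sim/cq.tsv --groups sim/samples.tsv --out stab_out
refstab validate --cq sim/cq.tsv --annotation sim/samples.tsv \
    --targets tissue_specific_01 --refs stable_high_01,stable_high_02 \
    --unstable-ref noisy_01 --out val_out
refstab run-all --config pipeline.yaml   # everything, from a YAML config
```

## Layout

| module | contents |
| --- | --- |
| `refstab.screen` | FPKM matrix I/O, abundance filter, CV/NMAD/Shapiro–Wilk, stability distance, top-k overlap |
| `refstab.qpcr` | Cq matrices, technical-replicate collapsing, standard curves, efficiency, 2^−ΔCt normalization, QC |
| `refstab.stability` | geNorm M/V, NormFinder, BestKeeper, comparative ΔCt, RefFinder aggregation, optimal-count decision |
| `refstab.simulate` | synthetic FPKM/Cq generator with ground-truth stability classes |
| `refstab.pipeline` | end-to-end orchestration, YAML config, TSV/JSON reports |
| `refstab.cli` | `refstab` command-line entry points |

See `docs/methods.md` for the statistical details and design choices.
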