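# Methods

This note documents the statistical procedures implemented in `refstab`,
the choices made where the methods literature leaves room, and what the
synthetic-data tests do and do not demonstrate.

## Screening statistics

For each gene the screening phase computes, across **all** samples (not
per-tissue means):

* **CV** — sample standard deviation (n−1 denominator) divided by the
  arithmetic mean, kept as a *fraction*;
* **NMAD** — median(|x − median(x)|) / median(x). No 1.4826 Gaussian
  consistency constant is applied: the normalisation here is by the
  median, not to an SD-equivalent scale;
* ***p*** — the Shapiro–Wilk p-value (scipy implementation, valid for
  3 ≤ n ≤ 5000);
* ***d*** = √(CV² + NMAD² + (1 − p)²).

CV and NMAD enter *d* as fractions so that all three coordinates live on a
comparable [0, ~1] scale; a percent-scale CV would dominate the distance.
A config flag (`cv_as_percent`) exposes the percent variant for
sensitivity analysis, but the reported `cv` column is always the fraction.

Degenerate inputs: a perfectly constant positive gene has CV = NMAD = 0
and an undefined Shapiro–Wilk statistic; we return p = 1.0 with a logged
warning so the most stable imaginable gene is not discarded. Genes with
non-positive mean or median (impossible after an abundance filter with a
positive threshold) are dropped with a logged reason rather than poisoning
the ranking.

The abundance filter keeps genes whose median (configurable: mean) FPKM is
**≥** the threshold (default 100, inclusive). Rankings by *d*, CV and NMAD
are strict 1..n orderings with lexicographic gene-id tie-breaks for
reproducibility; the top-k overlap report gives the seven exclusive Venn
regions of the three top-k sets.

## qPCR quantities

Standard curves are ordinary least squares of Cq on log10(relative
concentration); amplification efficiency is E% = (10^(−1/slope) − 1) × 100,
so slope = −1/log10(2) ≈ −3.3219 is perfect doubling. QC defaults:
R² ≥ 0.980 and E ∈ [90, 110]% (both configurable; the upper default is
110 rather than 105 because efficiencies just above 105% are routinely
accepted in practice).

Cq values are converted to within-gene relative quantities
Q = E_b^(Cq_min − Cq) with amplification base E_b = 1 + E%/100 ∈ (1, 2.2];
when no gene-specific curve is available E_b defaults to 2. Technical
replicates are averaged arithmetically on the Cq scale with available-case
handling of missing wells. Cq values outside (0, 50) cycles are rejected
outright as physically implausible.

Normalization follows the 2^−ΔCt method: ΔCt = Cq_target − Cq_ref. With
several references the normalization factor is the geometric mean of the
reference quantities, which at base 2 is identical to subtracting the
arithmetic mean of the reference Cq values; the identity is asserted in
the test suite to 1e−10.

## Stability algorithms

**Input scales.** geNorm and NormFinder consume relative quantities (their
statistics are built on log ratios); BestKeeper and the comparative ΔCt
method consume raw, untransformed Cq. This split follows the standard
usage of the four tools.

**geNorm.** M_j is the mean over partners k of SD(log2(Q_j/Q_k)). The
stepwise procedure recomputes M on the reduced panel after excluding the
highest-M gene (ties broken lexicographically, logged) until two genes
remain; those two are inseparable by construction and share rank 1, the
next gene taking rank 3 under competition ranking. Each gene is also
assigned its *stepwise* M — its M value at the step it was excluded (the
final pair gets the two-gene M) — which is the quantity geNorm plots per
gene and the one compared against the M < 0.5 usability cut-off; the
full-panel M is reported separately. V_{n/(n+1)} is the SD across samples
of log2(NF_n/NF_{n+1}) with NF_n the geometric mean of the n most stable
genes' quantities; the smallest n with V < 0.15 is the recommended number
of references (if none qualifies the largest n is returned with an
explicit flag).

**NormFinder.** On log2 quantities, per-sample means over genes are
removed, and for gene i in group g the model estimates an intra-group
variance σ²_ig and an inter-group (gene × group interaction) deviation
d_ig, centred so it sums to zero over genes within a group and over groups
within a gene. Because per-sample centring couples the genes, raw
within-cell variances are corrected via
σ̂²_ig = (s²_ig − σ̄²_g/k) · k/(k−2) with σ̄²_g = mean_i(s²_ig) · k/(k−1)
(floored at zero); this is why grouped mode needs ≥ 3 genes. The d̂_ig are
shrunk toward zero by the empirical-Bayes factor γ²/(γ² + var(d̂_ig)) with
γ² = ΣΣ d̂²/((k−1)(G−1)) − mean(var(d̂)) (floored at zero), and the
stability value is mean_g(|d̃_ig| + √(σ̂²_ig/n_g)). Ungrouped mode reduces
to the SD of the sample-centred log quantities. A loop-coded
transliteration of the same model serves as an independent oracle in the
tests.

**BestKeeper.** Per gene, the sample SD (n−1) of Cq and CV% = SD/mean×100;
the BestKeeper index is the per-sample geometric mean of Cq over the
panel, and each gene's Pearson correlation with the index is reported.
The original tool's mean-absolute-deviation spread is available via
`sd_method="mean_abs_dev"`. Genes are ranked by SD.

**Comparative ΔCt.** stability(j) = mean over partners k of
SD(Cq_j − Cq_k); for a two-gene panel both values coincide.

**Aggregation.** Every method's values are ranked with competition
(shared-minimum) ranking; the RefFinder-style score is the geometric mean
of a gene's ranks over the available methods, and the final ordering is
ascending in that geomean. With geNorm's tied final pair at rank 1 this
arithmetic reproduces published worked examples (e.g. ranks {1,1,2,3} →
6^(1/4) ≈ 1.57) exactly.

**Missing data.** Pairwise statistics use pairwise-complete samples; a
gene missing in more than half the samples is excluded from the panel with
a logged reason. geNorm/NormFinder require complete quantity matrices and
fail (isolated, recorded per method) otherwise.

## Synthetic data

The generator emulates a 6-tissue × 3-replicate design (18 samples, the
standard layout of multi-tissue reference-gene surveys) with log-normal
expression: log2 FPKM = baseline + group effect + N(0, σ_intra), group
effects drawn once per gene × tissue from N(0, σ_inter). Four designed
classes (defaults):

| class | baseline log2 FPKM | σ_inter | σ_intra | role |
| --- | --- | --- | --- | --- |
| stable_high | 9.0 (≈512 FPKM) | 0 | 0.15 | ideal reference |
| stable_low | 4.0 (≈16 FPKM) | 0 | 0.15 | stable but fails abundance filter |
| tissue_specific | 7.5 | 0 (+4 log2 in one tissue) | 0.15 | regulated gene |
| noisy | 9.0 | 1.5–2.0 | 1.0 | designed-unstable |

Cq values derive from the *same* latent per-sample expression:
Cq = 28 − log2(expression)/log2(E_b) + N(0, 0.2 cycles), placing Cq in the
mid-teens to high-20s range typical of abundant transcripts, with 0.2
cycles of technical noise. Each gene draws from its own substream of the
dataset seed (`SeedSequence(seed, spawn_key=(gene, purpose))`), so adding
genes never perturbs existing ones and every dataset is reproducible from
its seed. The truth table records each gene's class, designed σ values
(for the tissue-specific class, the population SD of its realised group
means) and the latent expression itself; `truth_ranking` orders genes by
√(σ_inter² + σ_intra²).

**What the simulations show — and don't.** Recovery tests demonstrate that
the implemented statistics separate designed-stable from designed-unstable
genes at realistic noise levels (screening places all stable-abundant
genes above all noisy/tissue-specific ones in ≈97% of seeds; the residual
failures are stable genes drawing an unlucky Shapiro–Wilk p, which the
(1 − p)² term then penalises — an inherent property of the distance, not a
bug). They do not model FPKM estimation error, amplification inhibitors,
primer-dimer artefacts, or correlated co-regulation between candidate
genes, so passing them says the algorithms are implemented correctly, not
that any particular biological panel is stable.

Problem sizes used by the default test/acceptance runs — 15–20 genes × 18
samples, 100 seeds — keep every suite in the seconds-to-a-minute range
while leaving the recovery estimates with ≈2% Monte-Carlo error.

## Pipeline

Stages (simulate → screen → standard-curve QC → stability → validation)
are isolated: a failing method or stage is recorded in the report and the
rest proceeds. All tables are written with 6 significant digits; the JSON
report carries full precision plus a provenance block (package version,
seed, config echo, timestamp). Given identical inputs, config and seed,
all outputs except the timestamp are byte-identical. An explicit
`exclude_genes` list models candidates dropped for wet-lab reasons (e.g.
primers that fail to amplify), keeping such exclusions auditable.

## Known limitations

* geNorm and NormFinder require complete (no-missing) quantity matrices;
  imputation is out of scope.
* NormFinder's grouped mode needs ≥ 3 genes and ≥ 2 samples per group;
  with exactly 2 genes only the ungrouped variant is defined.
* BestKeeper's descriptive SD ignores amplification-efficiency
  differences between genes, as in the original tool.
* The screening distance treats CV, NMAD and (1 − p) as commensurate;
  genes with heavy-tailed but symmetric variation can be over-penalised
  through the normality term.
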