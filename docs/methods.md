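# Methods

This note documents the statistical procedures, the model behind the
synthetic generator, the numerical conventions, and the design choices that
were genuinely open.

## Relative quantification

All ratio-based statistics operate on relative quantities
`q_ij = E_i^-(Ct_ij − min_j' Ct_ij')`, the classic `2^-ΔCt` transform with
per-gene base `E_i` (default 2). The per-gene minimum is taken **within the
analysis subset**, not globally: each subset (a stress time course, the
tissue panel, the pooled set) is analyzed independently, and both geNorm's
log-ratio SDs and NormFinder's centered residuals are exactly invariant to
any per-gene rescaling, so the choice of reference sample cannot affect
results — it only keeps every `q` in (0, 1]. Per-gene efficiency correction
(bases in (1, 2], e.g. measured per-cycle efficiencies of 1.77–1.88) is
available but off by default, matching the common practice of analyzing on
the idealized doubling scale.

## geNorm

Pairwise variation between genes j and k is `V_jk = SD_{n−1}(log2 q_j/q_k)`
across the subset's samples; the stability measure `M_j` is the mean of
`V_jk` over all partners. Ranking proceeds by stepwise elimination of the
gene with the largest M, recomputing M on the survivors, until two genes
remain; those two are mutually unrankable (only their pairwise V is left)
and are reported tied at rank 1. Ties at the maximal M are broken by
removing the **later-listed** gene, making the procedure deterministic in
the input gene order. Genes whose full-panel M exceeds 1.5 are flagged as
unstable (the threshold is configurable); the flag is informational and
does not remove genes from the ranking.

The optimal reference count uses normalization factors
`NF_n = geometric mean of the top-n genes' quantities` per sample and
`V(n/n+1) = SD_{n−1}(log2 NF_n/NF_{n+1})`. The recommended count is the
smallest n with `V(n/n+1) < 0.15`; when no V falls below the cutoff the
package reports "no recommendation" rather than a number — a candidate
panel that heterogeneous needs more or better references.

Log base 2 is used throughout so that V and M are in the same
cycles-equivalent units as ΔCt.

## NormFinder-style stability values

Model: `y_ij = α_i + β_j + ε_ij` for log2 quantities of gene i in sample j,
with a shared per-sample effect `β_j` (loading, RT yield) and gene-specific
noise `ε_ij ~ (0, σ_i²)`. Centering each sample over the k genes,
`z_ij = y_ij − ȳ_·j`, removes `β_j` but mixes noise: substituting the model,

    z_ij − z̄_i· = (ε_ij − ε̄_i·) − (ε̄_·j − ε̄_··),

so the naive residual variance `v_i = Var_{n−1,j}(z_ij)` has expectation

    E[v_i] = (1 − 2/k)·σ_i² + Σ_i' σ_i'² / (k(k−1)).

Solving for σ_i² gives the bias-corrected estimator used here,

    σ̂_i² = max(0, (k/(k−2)) · (v_i − Σ_i' v_i' / (k(k−1)))),

which requires k ≥ 3 and is unbiased under the model (verified by
simulation: the mean of σ̂²/σ² over 1000 null tables stays within ±10% of
1; the test suite runs this check). The ungrouped stability value is
`SV_i = σ̂_i`, in log2 cycles-equivalents.

In grouped mode the same decomposition runs within each group g (sizes
n_g ≥ 2), giving `σ̂²_ig` and group means `a_ig` of the centered values.
A gene's intergroup deviation is `d_ig = a_ig − mean_g a_ig`; the variance
of true intergroup effects is estimated across all genes and groups as

    γ̂² = max(0, Σ_ig d_ig² / ((k−1)(G−1)) − mean_ig(σ̂²_ig/n_g)),

each observed deviation is shrunk, `d̃_ig = d_ig · γ̂²/(γ̂² + σ̂²_ig/n_g)`
(an empirical-Bayes damping of deviations that could be sampling noise),
and

    SV_i = (1/G) Σ_g [ |d̃_ig| + sqrt( (σ̂²_ig/n_g) · γ̂²/(γ̂² + σ̂²_ig/n_g) ) ].

With a single group label the intergroup terms vanish and the grouped path
reduces to the ungrouped one (the implementation routes G = 1 to the
ungrouped estimator). Negative variance estimates are clamped to zero
before square roots. The exact degrees-of-freedom constants in γ̂² follow
the standard model-based formulation; because the recovery and
unbiasedness simulations — not agreement with any one program's printout —
are the validation surface, small differences in these constants would not
change rankings.

Grouping is used only when the study design supplies labels; time-course
subsets default to ungrouped, since a monotone drift across time points is
exactly what the ungrouped estimator should (and does) penalize.

## BestKeeper

BestKeeper works on raw Ct. Its "SD" is the **mean absolute deviation**
about the arithmetic mean Ct — the convention of the original spreadsheet
tool, not the n−1 sample SD (a `convention="sample_sd"` switch exists for
sensitivity analysis; MAD ≤ sample SD always, so the exclusion rule is
slightly more permissive under the default). `CV = 100·SD/mean Ct`. Genes
with SD > 1 cycle are flagged unacceptable but stay in the ranking —
whole subsets can fail the threshold, and a total order is still needed.
Ranking sorts by SD ascending, then CV, then input order, with excluded
genes after all included ones; SD leads because the exclusion rule is
stated on SD, while published "CV ± SD" phrasing does not disambiguate the
sort key (when the two orders differ, both are available from the stats
table). The BestKeeper index is the per-sample geometric mean Ct over
included genes (all genes when fewer than two pass), and each gene is
summarized by Pearson r (with two-sided p) against the index.

## Consensus ranking

Each program contributes a competition ranking ("1, 1, 3" for a two-way
tie at the top); geNorm's final pair enters with **both genes at rank 1**
(not 1.5/1.5). Genes are ordered by the geometric mean of their ranks,
compared internally on the integer product of ranks so exact ties are not
subject to floating-point fuzz. Ties break by the worst single-program
rank (the gene whose worst case is less damaging wins), then by the
canonical panel order. Both conventions — both-at-1 and
worst-rank-then-panel-order — were selected because they are the unique
simple policies that reproduce all nine published comprehensive rankings
in the bundled fixture exactly; the test suite asserts this panel by
panel. The aggregator accepts any ≥ 2 rankings over the same gene set, so
an RNA-seq CV ranking can be mixed in experimentally.

## RNA-seq screen and ranking comparison

Per unigene: `MV = mean FPKM`, `SD` (n−1), `CV = SD/MV`; zero-mean rows are
flagged rather than dropped. Screening keeps unigenes with `MV ≥ min_mv`
(default 1.0 FPKM — a conventional detectability floor; the "adequate
expression" requirement has no principled universal value), `CV ≤ max_cv`,
and optional membership in an annotation-backed set, sorted by CV. Two
stability rankings are compared by Pearson correlation of their rank
vectors (equivalently Spearman of the underlying scores); Kendall's τ is
available as a robustness check.

## Target-gene validation

A target's normalized quantity is `q_target / geomean(q_references)` per
sample; fold changes are ratios of per-condition replicate means to the
control-condition mean, so the control is exactly 1 by construction
(replicate means first, then the ratio — matching how mean fold changes
are conventionally reported). Because the references absorb the shared
per-sample effect, fold changes are invariant to loading — the premise of
reference-gene normalization, asserted as a test. The distortion
diagnostic divides two fold-change series for the same target obtained
with different reference sets; a reference drifting +1 cycle by some time
point inflates the apparent fold change there two-fold (base 2).

## Synthetic generator

Ct values follow the additive cycle-scale model

    Ct_i,(c,b,r) = baseline_i + loading_(c,b) + effect_i(c) + ε_i,(c,b) + tech_i,(c,b,r)

with per-gene baselines drawn uniformly from 13–25 cycles (the span of
moderately-to-highly expressed candidates), a shared per-sample loading
effect (SD 0.5 cycles by default), optional gene×condition shifts, per-gene
Gaussian noise, and small technical-replicate jitter (SD 0.05). Additive
effects on the Ct scale are multiplicative on abundance — the standard
qPCR error model. The implied true stability of a gene is
`sqrt(noise_sd² + Var_pop(condition shifts))`, and the generator returns it
with every table, so rankings can be scored against truth.

The default scenario is a 14-gene panel over a 0/1/6/24 h time course with
3 biological replicates: two designed-stable genes at noise 0.1 cycles,
ten ordinary candidates graded 0.3–0.5 (a spread, because real panels show
a spread — ten genes with identical noise would be statistically
indistinguishable at 12 samples and would make rank-recovery tests
meaningless), one treatment-responsive gene induced 0/+1/+2/+3 cycles
(8-fold by 24 h) at noise 0.3, and one erratic gene at noise 1.5. These
levels were fixed once by a design-phase power analysis so that the
generator's contract — consensus top-3 recovery of the stable pair and
bottom-3 placement of the unstable pair in ≥ 95% of seeds — holds at this
sample size. A full-study generator draws seven treatment subsets plus a
nine-tissue panel with shared baselines and unions them into an
"all-samples" subset.

FPKM tables are drawn log-normally with moment-matched mean and CV
(`σ² = ln(1+CV²)`, `μ = ln(mean) − σ²/2`).

What the generator does **not** emulate: amplification-curve artifacts,
primer-dimer signals, inter-plate calibration drift, heavy-tailed or
correlated noise between genes (beyond the shared loading term), and
missing wells. Tests passing on this generator therefore demonstrate
correctness of the statistics under their own model assumptions, not
robustness of qPCR normalization to assay pathology.

## Numerical conventions and degenerate inputs

- Sample SD uses the n−1 denominator everywhere it is called SD; the
  BestKeeper "SD" is the MAD as described above.
- Ct validity window (0, 45]; values above 40 cycles are accepted with a
  near-floor warning (standard protocols run 40–45 cycles).
- Missing Ct cells are an error by default; with `allow_missing` the
  affected samples can be dropped explicitly, with a logged exclusion
  (geNorm/NormFinder require complete matrices).
- Technical replicates collapse by arithmetic mean on the Ct scale;
  biological replicates stay separate (stability statistics need
  biological variation). Replicate groups spanning > 0.5 cycles warn.
- All-proportional tables give M = 0 for every gene; elimination then
  proceeds purely by the documented tie policy. Zero-variance rank
  vectors make ranking correlations NaN (flagged, not raised).
- Determinism: every stochastic path takes a seed; rerunning the pipeline
  with the same config and seed produces byte-identical CSVs.

## Problem sizes used by the test suite

Oracle-equivalence checks run 200 random 5-gene × 8-sample tables;
recovery checks use k = 10 genes × 100 samples (50 seeds), 1000 null
tables of 10 × 20, and 100-seed end-to-end runs of the 14 × 12 default
scenario — sizes at which the asserted margins hold with room while the
whole suite stays fast.

## Known limitations

- BestKeeper's published workflow includes regressions of each gene on the
  index; only Pearson correlation is provided here.
- NormFinder's "best pair" combination value and confidence intervals are
  not implemented.
- No weighted (RefFinder-style) aggregation beyond the plain geometric
  mean; no ΔCt-comparative fourth method.
- Efficiency values are consumed as inputs; there is no standard-curve or
  amplification-curve estimation.
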