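# refstab

Reference-gene stability analysis for quantitative real-time PCR (qRT-PCR).

Quantifying a transcript by qRT-PCR requires dividing out sample-to-sample
differences in template input, RT yield and loading. That normalization rests
on one or more *reference* ("housekeeping") genes assumed stable across the
experimental conditions — an assumption that must be validated per organism,
tissue and treatment, because no gene is universally stable. `refstab`
implements the standard validation workflow used throughout plant and animal
expression studies: screen candidates from RNA-seq, rank their stability with
three complementary statistics, aggregate the rankings into a consensus,
decide how many references are needed, and quantify what an unstable choice
does to a target gene. A ground-truth synthetic generator makes every step
testable end to end.

## What it computes

Ct values (quantification cycles; one cycle ≈ one doubling) are first
transformed to relative quantities per gene, `q = E^-ΔCt` with
`ΔCt = Ct − min Ct` (default efficiency `E = 2`). Then:

- **geNorm** — a gene's stability `M_j` is the mean over partners `k` of
  `V_jk = SD(log2 q_j/q_k)` (sample SD, n−1). The least stable gene is
  removed stepwise until two remain (reported tied at rank 1). The optimal
  reference count is the smallest `n` with pairwise variation
  `V(n/n+1) = SD(log2 NF_n/NF_{n+1}) < 0.15`, where `NF_n` is the per-sample
  geometric mean of the top-`n` genes' quantities.
- **NormFinder** — fits `y_ij = α_i + β_j + ε_ij` on the log2 scale, removes
  the shared sample effect `β_j` by per-sample centering, and reports
  `SV_i = σ̂_i`, a bias-corrected estimate of each gene's own fluctuation SD
  (see `docs/methods.md` for the estimator and its derivation). A grouped
  mode adds shrunken between-group deviations for designs with treatment or
  tissue groups.
- **BestKeeper** — descriptive statistics on raw Ct: `SD` = mean absolute
  deviation about the mean Ct, `CV = 100·SD/mean`; genes with SD > 1 cycle
  are flagged unacceptable; the BestKeeper index (per-sample geometric mean
  Ct) and each gene's Pearson `r` against it are reported.
- **Consensus** — genes are ordered by the geometric mean of their three
  ordinal ranks (competition ranking; geNorm's final pair both at rank 1);
  ties break by the worst single-program rank, then panel order.
- **RNA-seq screen** — per-unigene mean FPKM (MV), SD and `CV = SD/MV` for
  candidate discovery, plus Pearson-on-ranks comparison of qPCR and RNA-seq
  stability orderings.
- **Target validation** — `2^-ΔΔCt` fold changes of a target gene normalized
  by the geometric mean of chosen references, and the per-condition
  distortion ratio between a stable and an unstable reference choice.

The package ships a transcribed 14-candidate assay panel (plus the
*CYP72A1* validation target) and the per-program stability orderings of a
published nine-subset *Lycoris aurea* study as fixtures; the consensus
implementation reproduces all nine published comprehensive rankings exactly.

## Worked example

Simulate the default 14-gene, 4-time-point × 3-replicate scenario (two
designed-stable genes G01/G02, a treatment-responsive G13, an erratic G14)
and rank it:

```console
$ refstab simulate --seed 7 -o ct_sim.csv --layout long
wrote 14 genes x 12 samples to ct_sim.csv
$ refstab genorm ct_sim.csv --layout long
ranking (best first): G01, G02, G03, G04, G06, G08, G05, G11, G10, G07, G09, G12, G13, G14
final pair: G01 & G02
V(2/3) = 0.0575
...
V(13/14) = 0.1213
recommended number of reference genes: 2
```

The designed-stable pair G01/G02 is recovered as geNorm's final pair; the
drifting (G13) and noisy (G14) genes land last. `V(2/3) = 0.058 < 0.15`
means two references already normalize adequately — adding a third gene
would change the normalization factor by less than the cutoff. The same
table run through `refstab normfinder` puts G02/G03/G04/G01 at the lowest
stability values, and `refstab run <config.yaml>` executes every subset of
a multi-treatment study and writes tidy CSVs plus a JSON run manifest.

From Python:

```python
import refstab as rs

table, truth = rs.simulate_ct(rs.default_scenario(seed=7))
rq = rs.delta_ct_transform(table)
rankings = [
    rs.genorm_rank(rq).to_ranking(),
    rs.normfinder_sv(rq).to_ranking(),
    rs.bestkeeper_analysis(table).to_ranking(),
]
consensus = rs.consensus_rank(rankings, gene_order=table.genes)
print(consensus.order[:3])   # ['G03', 'G02', 'G01'] — truth.designed_stable in the top 3
```

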