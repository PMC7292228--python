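# Methods

## Screen model and hit-calling

A pooled in vivo shRNA screen reads out, per injection pool, a
hairpin × sample matrix of sequencing counts over three sample classes:
the plasmid library (starting material), pregraft cell populations, and
drug-resistant tumors. Pools are the experimental unit: each pool of
~100 hairpins is injected at 10 independent sites, and each tumor grows
from a bottlenecked subsample of the injected cells, so most hairpins
dilute while resistant (or stochastically lucky) clones expand.

The pipeline stages and their tunables:

- **Normalization** rescales every sample column to a fixed depth
  (`scale`, default 10⁷ reads — the per-pool sequencing unit). All-zero
  columns are left untouched with a warning.
- **Zero-filling**: tumors that never scored by the harvest week are kept
  as all-zero columns so the matrix stays complete; they count in
  denominators but can never contribute enrichment evidence.
- **Hairpin scores**: `log2((mean over tumor columns + c)/(mean over
  plasmid columns + c))` with pseudocount `c = 1` normalized read
  (negligible except at zero at the 10⁷ scale). Plasmid columns are the
  reference by default; pregraft is a config alternative
  (`reference="pregraft"`).
- **Gene ranking** is a weighted KS enrichment over the score-sorted
  hairpin list. With hit weights |score|^α the running sum rises by the
  hit's weight share and falls by 1/(#misses); the enrichment score (ES)
  is the extremum of largest magnitude, positive on ties. α = 0 (classic
  KS) is the default; α = 1 is available. The p-value is
  `(1 + #{null ES ≥ observed}) / (1 + P)` with `P = 10,000` permutations
  of hairpin-position sets of the gene's size.

  *Stratification.* Null position sets are drawn within the gene's own
  pool (`stratify_by_pool=True`). This matters: pools see disjoint tumor
  sets, so pool-level batch structure correlates the scores of co-pooled
  hairpins, and because pooling is gene-blocked every gene's hairpins
  share that batch. An unstratified null is measurably anti-conservative
  (~2.7× inflation at α = 0.05 in our null simulations); the stratified
  null restores uniform-valid p-values. An `exact_p` option enumerates
  all position sets when their number is feasible (≤ 2×10⁵).
- **Enrichment calls**: hairpin × tumor calls at ≥ `fold` (4) times the
  plasmid mean plus pseudocount, with a `floor` of 100 normalized reads
  that suppresses ratio blow-ups at low counts. Both thresholds are
  config fields; neither is stated numerically in the source protocol,
  so they are exposed rather than buried.
- **Reproducibility filters**: φ(g) = fraction of the gene's pool's
  xenografted tumors (zero-filled included) with ≥ 1 enriched hairpin;
  h(g) = number of distinct hairpins enriched in ≥ 1 tumor. The
  denominator is per-pool by construction: a gene exists in exactly one
  pool, and "total tumors xenografted" for that gene means that pool's
  injection sites.
- **Candidates**: `p < 10⁻⁴ ∧ φ > 0.08 ∧ h ≥ 4`. The φ cutoff mirrors
  the stochastic enrichment rate of a negative-control gene; the h cutoff
  is where the triangle (Zack) threshold lands on a typical
  hairpin-support histogram. `triangle_threshold` implements the
  geometric rule directly: the bin of maximal perpendicular distance from
  the peak-to-tail line, plus one.

## TF driver prediction

Inputs are per-TF values for four cell lines: RNA log2 fold changes
(vs the non-targeting control) and ATAC motif-displacement differentials,
for two resistant-xenograft (XE) lines and two knockdown-only (sh) lines.
Per modality a single weight γ = Σ|XE values| / Σ|sh values| is computed
over the whole table, and each TF's overall score is
`Σ XE + γ · Σ sh`. Multiplying the *sh* group by γ makes the two groups
contribute equal total magnitude; the design intent is that no one line
group dominates, and which group carries the weight is genuinely
ambiguous, so `weight_group="xe"` implements the inverse reading.

The Combined-Score is the product of the overall RNA- and ATAC-Scores.
Sign adjustments run in a fixed order: rule 1 negates the product for TFs
negative in both modalities (concordant downregulation must not rank as a
positive driver — the product of two negatives is spuriously positive);
rule 2 then flips negative scores positive for TFs inside the top-12
RNA-Scores or top-5 ATAC-Scores (a strong single-modality TF may act
without a concordant signal in the other assay). Rule 1 before rule 2 is
the only order in which rule 2 can function as the rescue it is described
as. Membership in the top lists is by signed overall score, descending,
ties broken by TF id. Candidates are the union of the top `n_combined`
(20) by adjusted Combined-Score and the top `n_atac` (2) by ATAC-Score —
up to 22 TFs, fewer when the sets overlap.

The DE pre-filter keeps genes with |fold change| > 2 and FDR < 0.1
(strict inequality; the ≤ reading is a config flag).

## Interval statistics

Intervals are 0-based half-open; peak centers are the summit when present
(narrowPeak offset converted to an absolute position), else the midpoint.
All primitives are sorted-array sweeps checked against quadratic brute
force in the test suite.

- **Consensus peaks**: coverage present in every replicate and
  pseudoreplicate (≥ 1 bp overlaps, intersection spans). Merging uses
  coverage semantics (book-ended intervals merge, as `bedtools merge`).
- **Gain/loss peaks** are presence/absence: condition peaks with zero
  control overlap and vice versa. Affinity-model differential binding is
  deliberately out of scope; gain/loss tabulation is what the downstream
  integration consumes.
- **Annotation** classes each peak center with priority
  promoter (TSS ± 2 kb) > exon > intron (gene body outside exons) >
  intergenic, and assigns the nearest gene by TSS distance
  (ties: lexicographically first gene id).
- **MD score**: per motif, each hit is counted once against its nearest
  peak center; `md = n(≤ r_small) / n(≤ r_large)` with radii 150/1500 bp
  (the canonical motif-displacement definition; both configurable). A
  motif with zero hits inside `r_large` is flagged undefined and
  propagates as missing through the differential Δ = md(cond) − md(ctrl).
- **Concordance CDF**: genes whose differential peaks pass |FC| > {2, 5}
  and p ≤ 0.01 are compared to all genes by a two-sample KS on RNA log2
  fold changes (`scipy.stats.ks_2samp`).

## Synthetic data: what it emulates, what it does not

`simulate_screen` draws a plasmid column from near-uniform lognormal
representation (σ = 0.25), then per tumor: a multinomial engraftment
bottleneck (10,000 cells — ~100× per-hairpin coverage), lognormal clonal
growth (σ = 0.5) on every engrafted clone, and multinomial sequencing at
2×10⁶ reads. Planted resistant genes expand their active hairpins by
150× in a randomly chosen subset of round(penetrance × 10) tumors — the
penetrance is the fraction of injection sites where the resistant clone
establishes. Jackpot clones (rate 0.1/tumor) and the stochastic
negative-control gene (one random hairpin per tumor at rate 0.08) amplify
by 300×. A tumor scores whenever it harbors an expanded clone; tumors
with only diluting background fail to score at rate 0.2. These defaults
were set, once, so that the three calibration behaviors hold jointly —
zero candidates under the null, full recovery of planted genes at
penetrance 0.3, and a negative-control tumor fraction concentrating near
its 8% rate — which is exactly what the thresholds they feed were designed
around.

The generator reproduces the distributional signature the pipeline
assumes (tight plasmid, broad tumors) without modeling tumor biology:
no clonal interference dynamics, no time dimension, no sequencing error,
no hairpin-specific knockdown efficacy. Passing recovery tests therefore
show the statistics behave as designed under their own assumptions, not
that real screens meet those assumptions.

`simulate_tf_tables` adds positive shifts (RNA 3.0/1.5 log2 units for
XE/sh, motif Δ 0.25/0.12) with per-line lognormal multipliers (σ = 0.25,
emulating divergent resistant sublines) over zero-mean noise
(σ = 0.7 RNA, 0.06 ATAC). `simulate_atac` jitters replicate peak edges
(± 20 bp) around a latent set; background motifs place 20% of hits near
*shared* peak centers (null Δ by construction), planted motifs place
their fraction near condition-only (gained) centers.

## Problem sizes

Calibration and recovery runs use a 200-gene / ~1,100-hairpin library in
11 pools (10 tumors each). This is a deliberate scale-down of the
730-gene / 4,234-hairpin / 43-pool design: it preserves the quantities
that drive the statistics — pool size ~100, hairpins per gene 5–6,
tumors per pool 10, and a planted-hit fraction ≈ 2% of the ranked list —
while keeping 50-replicate calibrations cheap. The library/pool
arithmetic itself is always exercised at full scale.

## Numerical choices and degenerate inputs

- ES magnitude ties resolve positive, with a 10⁻¹² tolerance absorbing
  floating-point noise in the running sums; the permutation tail count
  uses the same tolerance.
- All-zero weight vectors (α > 0 with all-zero scores) fall back to
  unweighted steps.
- Genes with no scored hairpins are excluded from the ranking with a
  warning; all-zero sample columns normalize to zero with a warning;
  FACS fractions at 0 or 1 and empty gene lists are rejected (the
  quantities are undefined there).
- Ranking ties (ES, top-list membership, candidate selection, nearest
  gene) break lexicographically by identifier, making every output
  byte-reproducible for a given seed.

## Limitations

- The KS gene statistic is brittle to a fully inert hairpin: a 5-hairpin
  gene with 4 strong hairpins caps near ES 0.8, whose null tail
  (~3×10⁻⁴) sits above the 10⁻⁴ cutoff. This is a property of the
  classic statistic, not of the implementation; the weighted variant
  (α = 1) is less sensitive and available.
- The MD score counts each hit once against the nearest peak center;
  versions that count per-peak or allow multiple assignments would differ
  at high peak density.
- Consensus intersection spans are conservative; a union-based consensus
  would retain more peak territory.
- The φ denominator is per-pool; a global-denominator reading exists and
  can be obtained by passing `total_tumors` explicitly to
  `gene_filters`.
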