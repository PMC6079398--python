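# Methods

## Model and assumptions

`sscnet` addresses candidate-gene screening between two conditions with
**one expression profile each**. With no replicates there is no
dispersion estimate, so the package makes no distributional claim about
measurement noise. Instead it ranks genes by a deterministic score and
shifts the statistical question to where it can be answered exactly:
*is a chosen selection enriched for a trusted positive-reference gene
set?* — a hypergeometric (Fisher's exact) question that needs no
replicates.

The score for a gene with abundances *a*, *b*:

- change percentage `c = 2|a − b| / (a + b)`. This is the symmetric
  relative difference: bounded on [0, 2], zero iff `a = b`, exactly 2
  iff exactly one abundance is 0, symmetric in its arguments, and a
  monotone transform of fold change. These boundary properties pin the
  form down uniquely among the standard relative-change measures; it is
  nevertheless pluggable (`score_table(change_strategy=...)`) should a
  different mapping be preferred.
- percentile ranks are tie-averaged ranks divided by N, computed
  **after** the detection filter, so the retained-gene universe defines
  the ranks; the maximum maps to 1.0 and ranks are invariant under
  rescaling a whole condition (so library-size factors between the two
  columns do not affect them).
- expression index `EI = c · (r_a + r_b)/2`, unsigned; direction
  (up/down/flat by the sign of `a − b`) is carried separately, because
  downstream both up- and downregulated genes belong in the network.

Assumptions worth stating: abundances are comparable between the two
columns (same normalization, e.g. FPKM); the positive-reference genes
are genuinely associated with the contrast of interest; and interaction
evidence (STRING combined scores) is informative about functional
relatedness at the chosen confidence.

## Parameters

| parameter | default | units / scale | why |
|---|---|---|---|
| `min_fpkm` | 0.1 | FPKM | detection limit; a gene is kept if **either** condition reaches it (a `both` mode exists). Requiring both would delete every on/off gene, contradicting the score's own "absent change → 2" case. |
| `step` | 0.001 | index units | scan grid spacing; the index lives on [0, 2], so ~2000 grid points resolve every practically distinct selection. |
| `edge_threshold` | 0.7 | STRING combined score (0–1) | the conventional "high confidence" level; 0–999 integer files are rescaled by 1000 before comparison, inclusively. |
| `alpha` | 0.05 | p-value | significance flag for the scan optimum and enrichment rows; raw p by default, Benjamini–Hochberg optional (`fdr=True`). |

Selection at a cutoff is closed (`EI ≥ t`); cutoff ties at equal
minimal p go to the **largest** cutoff — the shortest gene list
achieving the same enrichment. The scan's 2×2 table uses disjoint
margins (selected vs unselected), the standard reading; enrichment uses
the same convention (foreground vs background-minus-foreground), with
set membership intersected with the background first.

## Synthetic data: what it emulates, what it does not

`simulate_expression` draws baseline abundances log-normal
(σ = 1.5 — a heavy right tail with a realistic FPKM dynamic range),
then plants:

- **markers** (8 by default) above the 0.85 abundance quantile with
  fold changes 1.25–2.86, assigned *anti-rank* to abundance so the most
  abundant marker changes the least. This reproduces the regime that
  motivates the method — abundant, modestly-changed reference genes
  with a negative abundance/fold-change correlation.
- **signal genes** (50) at abundance quantiles 0.35–0.95 with fold
  changes 2.5–6 in random directions: the co-expressed, functionally
  related cohort the screen is supposed to recover. They are placed at
  moderate-to-high abundance because genuinely co-regulated pathway
  members in the profiled cells are expressed there; this also keeps
  their expression indices separated from the null population, which is
  the regime the generator is contracted to produce.
- **null genes** with multiplicative log-normal noise (σ = 0.10) on
  both columns, 2% of them zeroed in one random condition (on/off
  "dropout" genes — these are the score's hardest false-positive class,
  since absent change maps to 2).

`simulate_interactions` adds an Erdős–Rényi background (density 0.004,
scores U[0.4, 1]) plus a planted module over marker ∪ signal genes
(density 0.35, scores U[0.7, 1], so module edges always survive the 0.7
filter). `simulate_gene_sets` emits the true function set
(marker ∪ signal), a phenotype set (a random half of it) and
size-matched random decoys. All randomness flows from one seed.

What the generator does **not** emulate: count-level sampling noise,
length/GC bias, isoform ambiguity, cell-type mixtures within a profile,
correlated null genes, or any numeric feature of a specific public
dataset. Passing the recovery tests therefore shows the pipeline is
*internally consistent* — it finds structure of the kind it assumes —
not that any particular biological dataset contains such structure.

## Numerical choices

- Fisher's exact enrichment is computed as the hypergeometric upper
  tail `P(X ≥ k)` via `scipy.stats.hypergeom.sf(k−1, …)`; tests verify
  it to 1e-10 against an independent `math.comb` tail sum (exhaustively
  for small universes, densely sampled up to margins of 60).
- Grid arithmetic: cutoffs are `i·step`; comparisons use an absolute
  slack of 1e-9 so a gene whose index equals a grid point is never lost
  to float rounding, and the inclusive cutoff is the grid floor of the
  minimum positive index with the same slack.
- Ties: percentile ranks average tied ranks; candidate ordering is
  descending index, then gene id, making every output deterministic.
- Degenerate inputs: `a = b = 0` is undefined for both change
  percentage and fold change (such genes cannot pass a positive
  detection filter and are rejected with a clear error); a reference
  set with fewer than 3 usable markers suppresses the correlation
  diagnostic rather than reporting a meaningless r; zero-variance
  marker points report "not computable".
- Duplicate gene symbols (case-insensitive) collapse to the record with
  the largest total expression, first occurrence winning ties — keeping
  the dominant isoform/probe signal.

## Design choices where the design was open

- Detection filter semantics (`either` across conditions, inclusive at
  the threshold) — see the parameter table; exposed as a flag.
- The marker diagnostic's abundance axis defaults to the average
  percentile (the same abundance measure the index uses) with mean raw
  FPKM as an option.
- Positives absent from the score table are warned about and excluded,
  never imputed an index of 0: a missing reference gene says nothing
  about its enrichment.
- No multiple-testing correction across the scan grid: the grid rows
  are nested selections of one statistic, not independent hypotheses;
  the optimum's p is reported as a ranking criterion, with the `alpha`
  flag only guarding against declaring a best-of-noise cutoff
  significant.

## Problem sizes

The test suite and examples run the full pipeline at 1000 genes /
8 markers / 50 signal genes across 20 seeds — transcriptome-shaped but
small enough to iterate on quickly; component oracles run exhaustively
at universes ≤ 16 and sampled up to 60, and percentile oracles up to
n = 200. Scan cost is O(genes·log genes + grid) per scan, so real
tables (tens of thousands of genes) run in seconds.

## Known limitations

- One profile per condition is the design target; with replicates
  available, established count-model tools are the right choice and
  this package is not a substitute.
- The expression index has no calibrated null: its cutoff is
  meaningful only relative to a positive-reference set, and a poorly
  chosen reference steers the scan accordingly.
- On/off genes (absent in one condition) receive the maximum change
  percentage by construction; at very low abundance these can be
  dropout artifacts, mitigated — not eliminated — by the percentile
  weighting.
- Interaction refinement inherits STRING's ascertainment biases:
  well-studied genes are better connected and survive refinement more
  easily.
- Gene-set enrichment uses no ontology-graph propagation; sets are
  taken as flat member lists from the GMT.
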