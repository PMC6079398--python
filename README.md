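# sscnet

Knowledge-guided gene prioritization for **two-condition transcriptomes
without replicates**, with interaction-based refinement into an
annotated expression–function network.

## The problem

Comparing two cell states with one RNA-seq profile each — for example
primitive type A spermatogonia (mostly self-renewing spermatogonial
stem cells, SSCs) versus type A spermatogonia (mostly differentiating) —
leaves no way to compute replicate-based p-values. Worse, the genes
that matter biologically are often *abundant but modestly changed*:
canonical SSC self-renewal markers (Bcl6b, Csf1r, Etv5, Gfra1, Lhx1,
Pou3f1, Ret, Zbtb16) sit high in the abundance distribution while their
fold changes stay small, so fold-change or p-value thresholds bury
them. `sscnet` ranks genes by a score that rewards confident change in
abundant genes, lets a positive-reference gene set pick the threshold,
and then prunes the list through protein–protein interactions.

## The method

For each gene with abundances *a*, *b* (FPKM, one per condition),
retained when max(*a*, *b*) ≥ 0.1:

- **average change percentage** `c = 2|a − b| / (a + b)` ∈ [0, 2] — a
  symmetric fold-change transform; a gene expressed in only one
  condition maps to exactly 2;
- **average percentile rank** `r̄ = (r_a + r_b) / 2`, the mean of the
  gene's within-condition abundance percentiles (ties averaged);
- **expression index** `EI = c · r̄`.

A **dynamic cutoff scan** evaluates every threshold *t* on a 0.001 grid:
genes with `EI ≥ t` are selected and a one-sided Fisher's exact test
(hypergeometric upper tail) measures enrichment of the positive
reference among them versus the rest of the identified genes. The
**optimal cutoff** minimizes p (ties → largest cutoff, i.e. the
shortest list); the **inclusive cutoff** is the largest grid value
retaining every reference gene. Candidates are then intersected with a
STRING-style edge list (combined score ≥ 0.7), isolated genes are
dropped, and the surviving **refined network** is annotated with
expression direction/level and function/phenotype gene-set flags, and
tested for gene-set over-representation against the identified-gene
background.

## Worked example

```bash
python examples/02_cutoff_scan.py
```

prints (1000 simulated genes, 8 planted markers, seed 42):

```
markers found: 8/8; abundance vs fold change r = -0.89 (p = 0.003)
marker expression-index range: 0.254 to 0.842

optimal cutoff  0.253: 8/8 markers in 84 candidates (p = 1.81e-09)
inclusive cutoff 0.253: 8/8 markers in 84 genes (p = 1.81e-09)

recall of all 58 planted genes at the optimum: 1.00
```

The negative Pearson r is the signature regime: the most abundant
markers change the least. The scan still recovers all eight markers in
a 84-gene list out of 1000, because the expression index keeps them
near the top. The other examples (`examples/01…05`) walk through
scoring, network refinement, enrichment and the full pipeline; each
prints what its numbers mean.

The same workflow runs from the shell:

```bash
sscnet simulate --out fixture --seed 7
sscnet index fixture/expression.tsv --out scores.tsv --markers fixture/positives.txt
sscnet scan scores.tsv fixture/positives.txt --out-prefix scan
sscnet network scan_candidates.txt fixture/edges.tsv scores.tsv --out-prefix net
sscnet enrich <(cut -f1 net_nodes.tsv | tail +2) <(cut -f1 scores.tsv | tail +2) \
    fixture/sets.gmt --out enrichment.tsv
sscnet run config.yaml --out results/
```

To analyze real data, point `index` at a gene × 2-condition FPKM table
(TSV/CSV), `scan` at a plain-text positive gene list, and `network` at
a STRING edge export (0–999 integer scores are auto-detected and
rescaled).

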