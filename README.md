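# metintegrate

Integrative analysis of bulk transcriptomics, CRISPR gene-dependency
screens and pharmacogenomic viability data, aimed at nominating
metastasis **diagnostic markers** (surface-bound or secreted, dispensable
for viability) and **therapeutic targets** (upregulated *and* broadly
essential) — the workflow used in metastatic prostate cancer reanalyses
of public tissue cohorts and cancer cell-line panels.

## What it computes

**Differential ranking.** Genes are ranked between two sample classes
(metastasis vs. primary tumor) by the signal-to-noise ratio

```
SNR = (μ_A − μ_B) / (σ_A + σ_B)
```

with each group's sample standard deviation floored at
`max(σ, 0.2·|μ|)` (and 0.2 if that is zero) — the GenePattern
convention.  Fold changes are linear ratios `2^(μ_A − μ_B)` of the log2
input.  Significance comes from a two-sided class-label permutation
test with the add-one convention, `p = (#{|SNR*| ≥ |SNR|} + 1)/(n_perm + 1)`;
at the default 499 permutations the attainable floor is `1/500 = 0.002`.

**Gene-set enrichment**, two ways:

* *Over-representation (ORA):* for a query of n genes and a set covering
  T of the U universe genes, `p = P(Bin(n, T/U) ≥ F)` where F is the
  observed overlap, with Benjamini–Hochberg FDR across tested sets.
* *Running-sum enrichment score (ES):* walking down the SNR-ranked list,
  set members add `|score|^w / N_R` and non-members subtract
  `1/(N − N_hits)`; ES is the running sum at its maximum absolute
  deviation and the **leading edge** ("core enrichment genes") are the
  members at or before the peak.

**Dependency triage.** Gene-dependency probabilities `P_GC ∈ [0, 1]`
from genome-wide knockout screens are averaged per gene within
primary-tumor-derived and metastasis-derived cell lines; upregulated
genes with overall mean GD ≥ 0.9 are therapeutic candidates, those with
mean GD ≤ 0.1 are marker candidates.

**Drug-response stratification.** Cell lines are split on viability log
fold change: responsive (LFC ≤ −0.5), non-responsive (−0.5 < LFC ≤ 0.5),
excluded (LFC > 0.5).  The responsive-vs-non-responsive SNR signature's
top 150 genes feed ORA to name the pathways tracking sensitivity.

**Annotation shortlists.** The top-300 upregulated pool is joined with
surfaceome (confidence categories 1–3), secretome (curation tag OR
protein-atlas "Secreted" location — either evidence suffices) and
drug-target tables.

A synthetic-data module generates every input with recorded ground
truth — planted differential genes, coherent gene sets, essential
genes, a co-expressed response signature coupled to drug viability —
so the whole pipeline is testable without external downloads.

## Worked example

```sh
met-integrate demo --seed 7 --out demo/
```

generates a synthetic study (3000 genes; 41 normal / 140 primary / 31
metastasis tissue samples split over two cohorts; a 200-line cell panel
with dependencies, drug response and annotations) and runs the full
pipeline.  It prints:

```
demo complete under demo/ (seed=7); row counts: {'diff.tsv': 3000,
'ora.tsv': 25, 'gsea.tsv': 25, 'triage.tsv': 3000, 'sig_ora.tsv': 25,
'surface.tsv': 46, 'secreted.tsv': 40, 'druggable.tsv': 33}
```

The top of `demo/results/diff.tsv` lists the strongest
metastasis-upregulated genes — all planted ones, at the permutation
floor:

```
gene    snr                 fold_change        perm_p  rank
G2870   1.1605214559076207  3.694783715508485  0.002   1
G0873   1.0859891262840655  3.661692195259255  0.002   2
G2469   1.0388292751530703  4.506853585745668  0.002   3
```

`ora.tsv` shows the planted coherent set crushing 24 decoys
(F = T = 46 of its members in the top-500 query):

```
set_id          found  total  p_value                 fdr
SET_PLANTED_01  46     46     1.1157387177902091e-21  2.789e-20
SET_DECOY_007   15     54     0.04000511022225067     0.500
```

and `triage.tsv` classifies each top gene by its mean dependency — the
first rows are marker candidates (upregulated, mean GD ≈ 0.05, i.e.
dispensable), while planted essential-and-upregulated genes appear as
`therapeutic_candidate` with mean GD ≈ 0.95.

Individual stages are available as subcommands (`merge`, `diff`, `ora`,
`gsea`, `triage`, `pharmaco`, `surface`, `secreted`, `druggable`) and a
YAML-configured `met-integrate run --config run.yaml`; the demo writes
its own `run.yaml` you can edit and re-run.

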