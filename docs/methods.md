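# Methods

## Statistical model and procedures

### Signal-to-noise differential ranking

Two-class comparisons use the signal-to-noise ratio
`SNR = (μ_A − μ_B)/(σ_A + σ_B)` with sample standard deviations
(n − 1 denominator).  The statistic is undefined for constant groups
and unstable for near-constant ones, so each group's σ is floored at
`0.2·|μ|`, falling back to the constant 0.2 when the mean is also zero.
This is the convention of the GenePattern / GSEA ecosystem, which keeps
results comparable with analyses done in those tools.  Consequences
worth knowing: SNR is exactly antisymmetric under group swap and
scale-equivariant (floors scale with the data), but shift-invariant
only while the |μ|-scaled floor does not bind, and the constant 0.2
fallback does not scale.  Fold changes are reported as linear ratios
`2^(μ_A − μ_B)` since inputs are log2.

Permutation p-values are two-sided on |SNR| with the add-one
convention, `(hits + 1)/(n_perm + 1)`, so p is never 0 and never above
1.  Permutations are uniform draws of class-label assignments without
uniqueness enforcement.  The default `n_perm = 499` puts the attainable
floor at 1/500 = 0.002; whether a published table's 0.002 derives from
499 or 999 permutations is generally not stated, so the count is
configurable and 499 is the default.  All genes of a matrix share one
permutation stream (standard in phenotype-permutation tools, and what
makes the matrix-level test vectorizable); the per-gene marginal
distribution of p is unaffected.  Ranking ties are broken
lexicographically by gene id for determinism.

### Over-representation analysis

ORA uses the one-sided upper-tail binomial: submitting n query genes
against a set covering T of U universe genes, `p = P(Bin(n, T/U) ≥ F)`.
The binomial (rather than hypergeometric) tail matches the
Reactome-style service this reimplements.  The universe defaults to
the genes of the expression matrix — the measurable universe — rather
than all annotated genes anywhere.  Sets are tested only when their
universe intersection has 5–2000 members (configurable); BH FDR is
computed across the sets actually tested.  Query ids outside the
universe are dropped with a logged count.  `F = 0` yields p = 1.

### Running-sum enrichment score

The weighted Kolmogorov–Smirnov-like statistic: genes sorted by score
descending (stable sort, so equal scores keep input order — the
documented, deterministic tie rule), hits increment by
`|score|^w / N_R` with `N_R = Σ_hits |score|^w`, misses decrement by
`1/(N − N_H)`.  ES is the running sum at the maximum |deviation| (first
such index on exact ties); the leading edge is the hits at or before
the peak for ES ≥ 0, at or after it otherwise.  `w = 1` is the default
weighting; `w = 0` reduces to the classic KS statistic on hit
positions.  Degenerate cases: a set covering the whole list or none of
it is rejected; if all hit scores are exactly 0 under `w > 0` (so
`N_R = 0`) increments fall back to uniform `1/N_H`.  ES significance,
when requested, uses phenotype-label permutation with re-ranking by
SNR, the same add-one convention as above.  A normalized enrichment
score and cross-set permutation FDR are deliberately out of scope; the
raw ES and its leading edge are the reported quantities.

### Dependency aggregation and triage

Gene-dependency values are probabilities in [0, 1] that a knockout
reduces viability.  Means are taken per gene within primary-derived
and metastasis-derived line groups, excluding missing cells from both
numerator and denominator (screens do not cover every gene–line pair);
observed counts are emitted alongside.  Both stratified means and
their count-weighted overall mean are reported, since published
figures do not always say which was used.  Triage thresholds: with SNR
at or above the cut (default: the SNR of the 300th-ranked gene,
matching the size of the top-upregulated pool) a gene is a therapeutic
candidate at overall mean GD ≥ 0.9 and a marker candidate at ≤ 0.1 —
"close to 1" and "closer to 0" made explicit and configurable.  A
lineage filter can restrict the panel (e.g. prostate-only views).

### Drug-response stratification

Responsive lines: LFC ≤ −0.5 (boundary included, per the published
definition).  Non-responsive: −0.5 < LFC ≤ 0.5 — the published interval
is open-ended about its upper boundary, so +0.5 was assigned to the
non-responsive side (the published group totals suggest the boundary
rarely binds); both thresholds are configurable.  Lines above the
upper threshold are excluded.  Lines lacking expression data are
dropped with a logged count.  The signature is the SNR rank table of
responsive vs. non-responsive lines; its top 150 genes (configurable)
feed ORA.

### Annotation shortlists

Pool size defaults to the top 300 ranked genes (configurable to 500 or
150 to mirror the other analyses; published usage is ambiguous between
300 and 500, and 300 was chosen as the default because it matches the
pool used for dependency annotation).  Secretion passes on *either*
evidence line: a curation tag containing "secreted (curated)",
"secreted (highly likely)" or "secreted (likely)" — matched
case-insensitively as substrings, because source databases vary in
capitalization — or a protein-atlas location containing "secreted".
Genes absent from an annotation table are non-members, never errors.

### Cohort merging

Cohorts are merged on the intersection of gene ids (first-cohort
order), samples concatenated with cohort tags.  Gene identity is the
raw symbol string, case-sensitive, with no alias resolution.  The
merger assumes comparably normalized inputs; an optional per-cohort
per-gene median-centering switch (off by default) makes the batch
assumption explicit rather than silent.  Missing expression values are
rejected at read time since SNR and ES assume complete vectors.

## Synthetic data: what it emulates and what it does not

The generators reproduce the *structure* the pipeline exploits, with
defaults shaped like the real study:

* **Tissue cohort** — per-gene baselines from N(7, 1.5) log2 units
  (typical RMA-normalized array intensities), additive Gaussian noise
  with σ = 0.5 log2 units, class sizes 41 normal / 140 primary / 31
  metastasis, and 300 planted genes upshifted by 2.0 log2 units in the
  metastasis class only — so the primary-vs-normal contrast is flat,
  as in a metastasis-specific signature.  Planted effects are
  upregulation by default because the shortlists being emulated are
  metastasis-upregulated.
* **Cell panel** — Beta(20, 1) dependencies for planted essential
  genes and Beta(1, 20) for the rest, giving the bimodal near-1/near-0
  mixture seen in genome-wide screens; ~40% metastatic-origin lines.
  An optional planted signature adds a shared per-line latent activity
  (N(0, 1), scaled by 1.0 log2 units) to its member genes — the
  co-expression that makes a pathway signature detectable across lines.
* **Drug response** — `LFC = −coupling · z(mean signature expression)
  + N(0, σ)`: signature-high lines are the most responsive, mirroring
  the observation that invasion-signature-high lines respond to kinase
  inhibition.
* **Annotations and gene sets** — membership drawn at requested
  fractions; secretome members always carry at least one evidence
  line; planted gene sets are sampled from the planted differential
  genes so that, composed with the tissue simulation, they are
  genuinely enriched.

Not emulated: probe-level microarray effects, cross-cohort batch
structure, heavy-tailed or count-based noise, correlated background
co-expression beyond the planted signature, lineage-specific
dependency differences, dose–response curves, copy-number/mutation
layers.  Passing tests therefore demonstrate correctness of the
statistics and recovery under clean Gaussian conditions, not
robustness to real-data pathologies; on real cohorts the same code
runs, but effect recovery will degrade with batch effects and weaker
signal-to-noise.

## Numerical and design choices

* Full determinism: every stochastic routine takes a seed; the
  pipeline fans one seed into per-stage substreams via
  `numpy.random.SeedSequence` so stages stay independently
  reproducible.  A repeated run with the same seed is byte-identical,
  and the run manifest records a hash of parameters plus input-file
  digests (not paths).
* TSV expression round-trips bit-exactly: floats are written with full
  `repr` precision and parsed back with `strtod`-exact conversion.
* Problem sizes in the test and acceptance runs (1000–3000 genes,
  200–400 lines, 9–499 permutations depending on whether the p-values
  or only the ranking is consumed) were chosen so each recovery
  property is measured over 20 independent seeds while the whole suite
  stays desk-scale.
* The published headline numbers (e.g. specific ES values and SNR
  tables) depend on the original cohorts and contemporaneous gene-set
  releases and are not reproducible from synthetic data; the package's
  guarantees are therefore property-based: exact oracle agreement for
  the three enrichment statistics, calibration of the permutation
  null, and recovery of planted structure.

## Known limitations

The SNR floor makes shift-invariance conditional (see above).  ORA
treats the query as an unordered set; rank information beyond the
cutoff is discarded.  The ES is reported without normalization, so
values are not comparable across sets of very different sizes.  Shared
permutation streams across genes induce weak dependence among per-gene
p-values (their marginals remain exact).  Cell-line expression and
tissue expression are assumed to share gene identifiers; no ortholog
or alias mapping is provided.
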