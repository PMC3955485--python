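# Methods

## Statistical model

The pipeline treats each cohort as an independent two-group comparison of
log2 expression intensities. All gene-level testing uses the classical
equal-variance (pooled) two-sample Student's *t*, oriented tumor minus
normal, with `df = n_T + n_N − 2` and two-sided p-values from the *t*
distribution. Although the motivating cohorts are paired designs, the
analysis deliberately applies **unpaired** tests throughout; pairing labels
are read and stored but never used. This sacrifices some power in exchange
for a single, uniform test across cohorts, and it is the convention the
whole downstream calibration assumes.

### Preprocessing

Order: restrict → filter → collapse, each per cohort.

- *Restrict*: probes whose gene symbol is absent from the pathway
  collection's gene universe (or empty) are dropped. Pathway membership is
  the unit of inference, so unannotated genes cannot contribute.
- *IQR filter*: probes with interquartile range < 0.5 (log2 scale,
  both groups pooled) are removed; a probe exactly at 0.5 is kept
  ("under 0.5" read strictly). Quartiles interpolate linearly between
  order statistics (the `(n−1)·q` positional convention, R's default
  type-7). The cutoff is exposed as `iqr_cutoff`.
- *Collapse*: where several probes target one gene, the probe with the
  largest IQR is retained; exact IQR ties break to the lexicographically
  smallest probe id so results are reproducible across platforms. The
  survivor keeps its probe id; output rows are sorted by gene symbol and
  collapsing is idempotent.

Degenerate genes (zero pooled variance with a nonzero mean difference,
i.e. infinite *t*) are excluded from testing with a logged warning; zero
variance with equal means yields *t* = 0, p = 1.

### Pathway permutation test

The pathway statistic is the arithmetic mean of member-gene *t* values —
the classic "category"-style gene-set statistic. Its null distribution is
obtained by shuffling **sample labels** (preserving group sizes), not
genes: sample permutation preserves inter-gene correlation, which a
gene-permutation null would destroy. One shared stream of B shuffles
(default B = 1000) scores all pathways, which is cheaper than per-pathway
streams and makes p-values comparable across pathways. One-sided p-values
use the plus-one estimator

    p_up = (1 + #{permuted score ≥ observed}) / (B + 1),

so p is never 0 and is floored at 1/(B+1). For small designs an
exhaustive mode enumerates all C(n, n_T) label assignments (identity
included) and reports exact fractions; enumeration is refused above
200,000 assignments. Implementation note: the observed labeling is scored
inside the same vectorized BLAS call as the permutations so that the
identity assignment ties the observed score bit-exactly — otherwise
1-ulp rounding differences silently drop the tie that the plus-one
estimator assumes.

Per cohort, a pathway enters the up (down) set when `p_up ≤ α`
(`p_down ≤ α`), α = 0.05; if both pass, the smaller p wins. The
cross-cohort **common** sets are plain intersections of the per-cohort
directional sets, so a pathway significant up in one cohort and down in
another qualifies in neither. No multiple-testing correction is applied
at this stage; the raw α is part of the workflow being reproduced.

Note on calibration semantics: the stage makes two one-sided claims per
pathway, each of size ≈ α under the null. The union event ("significant
in either direction") has probability ≈ 2α; calibration checks therefore
target the per-direction rates.

### Fisher's-method meta-analysis

For a gene with two-sided p-values `P¹ … Pᵏ` from the k cohorts in which
it survived preprocessing, `X² = −2 Σ ln Pᵢ` is referred to χ² with 2k
degrees of freedom (natural logarithms). Genes missing from some cohorts
keep a reduced k rather than being dropped — the standard Fisher
treatment of unbalanced availability. Per-dataset p-values are floored at
1e-300 before taking logs because extreme *t* statistics can underflow to
p = 0, which is outside Fisher's domain; `fisher_combine` itself raises
on p = 0 so the floor is an explicit caller responsibility. Gene
significance uses strict `p_combined < 0.05` (the pathway stage uses ≤;
the asymmetry mirrors how the two stage rules are stated, and matters
only on exact boundaries). Each gene also carries `mean_t` (average of
contributing *t*) whose sign defines its direction. A `--bh`-style
correction is deliberately absent from the default path.

### Over-representation

The significant-gene list is tested per pathway with the one-sided
hypergeometric upper tail `P(X ≥ x)` — Fisher's exact test, the model the
popular annotation services' EASE score derives from. The background is
the pathway-annotated universe intersected with genes tested in at least
one cohort, *not* the whole genome: enrichment should be judged against
what could have been detected. Pathways with zero overlap are omitted
(`P(X ≥ 0) = 1` carries no evidence). An EASE-style variant (overlap
reduced by one, more conservative) is available behind the `ease` flag,
off by default. Direction labels come from a majority vote over the
overlapping genes' meta directions; an exact tie falls back to the sign
of their summed `mean_t`, and a zero sum leaves UNDEFINED with a warning.
The discreteness of the hypergeometric makes its p-values super-uniform,
so null enrichment rates sit at or below α.

### Consensus

A pathway reaches the final report iff it is in the GSEA common up- or
down-set, is enriched at `p_enrich < 0.05`, and the two directions agree;
direction conflicts are logged and excluded. Key genes are the pathway's
meta-significant members (`p_combined < 0.05`), sorted by combined p and
rendered `GENE(p)` with three significant digits and an uppercase
exponent (`FH(8.33E-05)`); a parser inverts the rendering. An empty
consensus is a valid outcome, not an error.

## Synthetic studies

The generator emulates the target study design: by default three cohorts
of 7/7, 10/10 and 23/23 tumor/normal samples sharing one gene universe of
800 genes, 50 disjoint 15-gene pathways, 1–3 probes per gene (drawn once,
shared across cohorts, mirroring a common annotation), per-gene baselines
`N(8, 1)` on the log2 scale and homoscedastic `N(0, 1)` observation
noise. Ten pathways are planted up- and ten down-regulated: every member
gene's tumor mean is shifted by ±δ (default δ = 1), identically in every
cohort — the simplest structure under which "up-regulated pathway" is
well defined and cross-cohort consensus is the right answer. A fraction
(default 10%) of the *unaffected* genes are "decoys" with noise SD 0.1,
whose expected IQR (≈ 1.35 × 0.1) sits far below the 0.5 cutoff — they
exercise the variability filter. Generation is a pure function of the
config; the same seed reproduces every matrix bit for bit.

Deliberate omissions, and hence what passing tests do **not** show about
real data: no within-pair correlation (samples are independent despite
the paired labels), no batch or platform effects, no intensity-dependent
variance, no cross-hybridizing probes, no correlation between genes
beyond the shared mean shift. Real cohorts violate all of these; the
synthetic studies validate the *machinery* (calibration under the stated
model, recovery of planted signal, determinism), not field performance.

`expected_detectable_power` provides a Monte-Carlo estimate of
single-gene detection power in the smallest cohort, computed with scipy's
t-test directly (independent of the pipeline's own code paths); it
anchors test expectations — pathway-level recovery must beat it, since
the mean-*t* statistic pools members — and plays no role in analysis.

## Numerical choices and edge cases

- Expression matrices are written with 17 significant digits and parsed
  through numpy's correctly-rounded string conversion, so write→read is
  exact (pandas' fast parser can be 1 ulp off). Result tables use 6
  significant digits.
- Quantiles: linear interpolation (see above); `compute_iqr` refuses
  fewer than 2 values.
- Within permutations, a zero-pooled-variance cell maps to *t* = 0 — a
  probability-zero event under the continuous noise model, guarded so
  pathway means stay finite on pathological inputs.
- Group labels are normalized case-insensitively to TUMOR/NORMAL on read;
  any other label is a named load error identifying the sample.
- The GMT description field is overloaded as `name|classification` so
  pathway class labels survive a format that has no slot for them.
- Problem sizes in the packaged checks (2,000 genes / 200 pathways for
  null calibration; the default design for recovery) were chosen as the
  smallest sizes at which binomial/KS bands are informative; they run in
  seconds.

## Known limitations

- The permutation floor 1/(B+1) bounds attainable pathway significance;
  with B = 1000 no pathway can report p < ~0.001.
- Mean-*t* scoring favors coherent, moderate shifts over single-gene
  spikes; it is the intended statistic, not a general-purpose GSEA (no
  weighted Kolmogorov–Smirnov walk, no NES/FDR machinery).
- Reduced-k Fisher combination weights genes unevenly when platforms
  differ in coverage; genes observed once are judged by a single cohort.
- The consensus rule is a hard intersection: a pathway barely missing α
  in one cohort disappears entirely. That brittleness is inherent to the
  reproduced workflow, not a bug.
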