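# Methods

This note records the models implemented in `lncarray`, the assumptions
and parameter choices behind them, what the synthetic-data generator does
and does not emulate, and the numerical conventions a maintainer needs.

## Coordinates and domain types

All internal genomic coordinates are 0-based half-open; dialect
conversions (GFF3's 1-based inclusive) happen once, at the I/O boundary.
Transcript length is the sum of exon spans. INSS stage labels collapse
`2a`/`2b` to 2; stage `4s` is stored as 4 with a distinguishing flag and
excluded by default from stage-ordered analyses, because 4s is
prognostically anomalous and its grouping in the source cohorts is not
documented. Missing expression values are rejected at read time rather
than imputed — no imputation rule exists for these data.

## Probe filtration cascade

A probe set is retained as an lncRNA candidate iff all of:

1. it maps one genomic location and one target transcript (`non_unique`);
2. the target is not an annotated protein-coding transcript
   (`protein_annotated`);
3. no placement overlaps a protein exon on the same strand, overlap
   meaning ≥ 1 shared base in half-open coordinates
   (`same_strand_protein_exon_overlap`) — antisense overlap is allowed by
   construction, since many bona fide lncRNAs (HOXD-AS1-like) lie
   antisense to coding genes;
4. the coding-potential filter passes (`coding_potential`);
5. transcript length ≥ 200 nt (`below_min_length`, configurable).

Rules are evaluated in this fixed order and *all* failing rules are
recorded, so audits are complete (`|retained| + |excluded| = |input|`)
and filtering is idempotent and order-insensitive.

External sequence tools are not re-implemented. Coding-potential and
reference-alignment verdicts enter as optional evidence tables; built-in
stand-ins are used otherwise: a transcript is coding iff its longest
forward-strand ORF (ATG to stop, three frames) is ≥ 100 codons *and*
covers ≥ 30 % of the transcript; a candidate matches a reference
transcript iff every placement lies within one of its exons on the same
strand, and high confidence requires exactly one matching reference
transcript. The 100-codon/30 % thresholds are conventional and
configurable. Their null behaviour is worth knowing: on uniform-random
1,000 nt sequences the heuristic calls ~5 % coding (≈ 15 ATG starts ×
(61/64)^100 ≈ 0.8 % each), so it is a guardrail, not a classifier.

## Length-class mixture

The population of candidate lengths is summarised by the empirical iCDF
(fraction of transcripts ≥ L), evaluated at each distinct observed length
without binning — the histogram view is presentation-only. In double-log
space the model is piecewise quadratic ("extended power law"; the linear
special case is a pure power law): three segments fitted by OLS, with the
segmentation chosen to minimise total squared error over candidate
breakpoint pairs on the distinct-length grid, at least 8 points per
segment. This exhaustive-search formulation is deterministic and needs no
initialisation. Implementation details:

- Segment SSE is computed in O(1) from prefix sums of `x^0..x^4`, `x^k y`
  and `y²` (x centred globally for conditioning; SSE is shift-invariant).
- When the distinct grid exceeds 160 candidate breakpoints, the scan runs
  coarse-to-fine: exhaustive on a thinned grid, then exhaustive local
  refinement on the full grid around the coarse optimum. On the recovery
  study this equals the full scan at a fraction of the cost.
- Class cutoffs are the intersection points of adjacent fitted
  components, solving the quadratic difference; with two interior roots
  the one nearer the segments' shared boundary wins. Adjacent quadratics
  occasionally fail to cross (complex roots); the fallback is their point
  of closest approach — the vertex of the difference parabola — clamped
  to the segment boundary, and logged.
- Classes are `class1 = [200, c1]`, `class2 = (c1, c2]`,
  `class3 = (c2, ∞)`; ties at a cutoff go to the lower class; lengths
  under 200 nt are `below_min`. The partition is total.
- The shortest class is additionally summarised by a log-normal body
  (moment fit of ln L), matching its visually log-normal shape.

Under the generator's default conditions (n = 5,000, breakpoints 400 /
2,300 nt, shares 4/87/9 %) the fit recovers both cutoffs within ±15 % in
10/10 seeds with a median relative error of a few percent.

## Neighbor genes and enrichment

Neighbors are protein-coding genes whose *gene body* lies within ±10 kb
(inclusive) of the lncRNA transcript interval, strand-agnostic, overlap
counting as distance 0. Gene-body distance is the conservative reading of
"vicinity"; TSS anchoring is not used. Enrichment of a neighbor gene set
is the one-sided hypergeometric upper tail P(X ≥ k) for drawing k
term-annotated genes in n selected from a universe of N containing K,
with enrichment ratio (k/n)/(K/N); significance requires raw p < 0.01 and
ratio ≥ 2, with no multiple-testing correction — the procedure is a
screen with an effect-size floor, not an inference. The term mapping is a
user-supplied GMT-like table, so the stage is testable offline; no web
annotation service is called.

## Clinical screening cascade

Per probe, expression in early (stages 1–2) vs late (stages 3–4) tumors
is compared with both the Mann–Whitney U test (exact enumeration for
combined n ≤ 12 without ties, otherwise normal approximation with tie and
continuity corrections) and the pooled-variance Student's t test. The
p < 0.001 cut is applied to **raw** p-values of both tests, with BH
q-values reported alongside (`cut_on="q"` switches the cut to q). Kendall
τ-b (tie-corrected in both variables) is computed against ordinal stage
over *all* restricted staged samples, not just the binary split, and
selection additionally requires |τ| > 0.25. Conventions: a zero-pooled-
variance t test returns p = 1 for equal means and p = 0 otherwise; a
constant probe has undefined τ and simply fails the τ filter.

The function-level default is `restrict="all"`; the biomarker pipeline
config defaults to `restrict="non_mna"`, mirroring the primary clinical
screen in MYCN-non-amplified patients (MYCN amplification is itself a
dominant risk marker and would confound stage ordering).

## Nearest-shrunken-centroid signature

Standardized centroid differences
`d_ik = (x̄_ik − x̄_i) / (m_k (s_i + s0))` with `m_k = √(1/n_k − 1/n)`,
pooled within-class sd `s_i` and fudge `s0 = median(s_i)` are
soft-thresholded by Δ; features with all-zero shrunken differences leave
the signature. Classification minimises
`Σ_i (x_i − x̄'_ik)² / (s_i + s0)² − 2 ln π_k` with empirical priors;
exact ties go to the first class in label order (logged). Δ is chosen on
a grid by stratified k-fold cross-validation (fixed seed) with the
one-standard-error parsimony rule: the largest Δ whose CV error is within
one SE of the minimum. At Δ = 0 the classifier is exactly the unshrunken
standardized nearest-centroid rule, and the surviving-feature count is
non-increasing in Δ — both are asserted in tests. Signature probes are
grouped by average-linkage hierarchical clustering on distance 1 − τ,
cut at two clusters; constant probes get undefined τ and the maximum
distance 2 (logged). The relapse evaluation applies the stage-trained
model unchanged to the second cohort — no retraining.

## Knock-down DE calling

Per siRNA condition a probe must satisfy all of: t-test p < 0.05 against
control; median fold change (after exponentiation when the matrix is
log2) beyond `fc_min`, default 1.3 with 1.4 also exercised — the source
procedure quotes both thresholds without resolving which applied where,
so it is a single configurable parameter; and ≥ 3 replicates beyond the
control median *in the fold-change direction* — the criterion is made
direction-aware because a literal "above the median" reading would make
down-regulation calls impossible. The consensus list keeps probes passing
in both siRNA conditions with the same direction. Raising `fc_min` or
`min_reps` can only shrink the consensus. An optional post-step collapses
probes to genes by maximum variance.

## Synthetic-data generator

The generator defines the study conditions; its defaults are fixed, not
tuned per run:

- **Lengths**: three components with shares (0.04, 0.87, 0.09) —
  the observed class shares — around breakpoints 400 / 2,300 nt; a
  log-normal body (µ = ln 290, σ = 0.35, truncated to [200, 400]) for the
  short class and truncated-Pareto tails with log-log iCDF slopes −1.6
  and −2.6, sampled by inverse transform. Pareto is the simplest law
  whose iCDF is linear in log-log, i.e. exactly the fitting target.
- **Cohorts**: 64 patients balanced over stages 1–4 (frac. MYCN-amplified
  14/64), planted stage-monotone probes with expectation
  `baseline + sign · effect · (stage − 1)`, sign positive for ~80 % of
  planted probes (mirroring the observed 79 % positive correlation;
  configurable), residual sd 0.5 on the log2 scale with effect 1.0 per
  stage step (≈ 2× noise); relapse is logistic in stage (intercept −2.2,
  slope 0.8 — no generation model is documented, these give ~10 % →
  ~55 % relapse from stage 1 to 4).
- **Knock-downs**: control + two siRNA conditions × 4 replicates; planted
  genes shift by ± effect (default 2.0 log2) in both siRNA conditions;
  replicate noise sd 0.1 log2, the dispersion scale of *technical*
  replicates (the same RNA hybridized repeatedly), which these designs
  use.
- **Toy genome**: a hand-enumerated fixture planting one probe per filter
  path, including the antisense-overlap probe that must survive; the seed
  only permutes probe order.

What passing tests do and do not show: the generator plants clean
monotone effects with i.i.d. Gaussian noise and exchangeable replicates.
It does not emulate probe-level hybridization physics, array batch or
spatial artifacts, correlated probe blocks beyond the planted structure,
or the heavy-tailed intensity distributions of real scans. Recovery and
error-control results on these fixtures validate the *logic and
calibration* of the cascade, not its field performance on GEO cohorts.

## Problem sizes and determinism

Analyses and the acceptance script run at n = 5,000 lengths, 60–64
patients × 1,000 probes, and 1,000-probe knock-down designs — sizes at
which every stage completes in seconds while leaving the statistical
behaviour (power, type-I control, recovery) well resolved. All
randomness flows from explicit seeds through `numpy.random.default_rng`;
every pipeline run writes a manifest (config hash, seed, stage counts)
sufficient to reproduce it exactly.

## Known limitations

- The quality/uniqueness pre-filter reducing raw probe sets to uniquely
  mapping ones lives in the upstream probe-annotation database; here
  `unique_match` is accepted as a precomputed input flag.
- Survival is handled as a binary 5-year group test; no Kaplan–Meier or
  Cox modelling.
- The mixture fit reports no standard errors on cutoffs, and no
  latent-class maximum-likelihood alternative is provided.
- Whether the source analysis fitted the iCDF or the density histogram is
  ambiguous; the iCDF is fitted and the fit report records that choice.
- Reproducing the original accession-derived numbers (1,581 probes ≥ 200
  nt; cutoffs 386/2,345 nt; 223/164-probe screen counts; the 159-probe
  signature and its 79–88 % / 74–80 % accuracies) requires the GEO
  cohorts and the original probe annotation, which are deliberately out
  of scope offline; the pipeline accepts such data through the same
  readers when available.
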