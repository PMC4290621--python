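# lncarray

Long noncoding RNAs (lncRNAs) are measured — mostly unintentionally — by
thousands of probe sets on popular expression microarrays such as the
Affymetrix U133 family. `lncarray` re-implements, as a tested and reusable
Python pipeline, the computational procedure behind that kind of resource:

1. **Probe-set filtration** — from all probe-set genomic mappings down to
   lncRNA candidates: unique genomic/transcript match, not annotated as
   protein-coding, no overlap with a protein exon *on the same DNA strand*
   (antisense overlap survives — the geometry of lncRNAs such as HOXD-AS1,
   which lies antisense to HOXD1/HOXD3), a coding-potential filter, and a
   200 nt length floor. Every probe gets a complete audit record, and
   candidates uniquely matching an external lncRNA catalogue are flagged
   high-confidence.
2. **Length classes** — the transcript-length population is summarised by
   its inverse cumulative distribution (iCDF), the fraction of transcripts
   with length ≥ L. In double-log coordinates each class is an "extended
   power law", a quadratic `y = a0 + a1·x + a2·x²` with `x = log10 L`.
   A three-segment least-squares fit plus intersection of adjacent
   components yields nt cutoffs splitting lncRNAs into three classes
   (in the reference U133 analysis: 386 nt and 2,345 nt).
3. **Neighbor-gene enrichment** — protein-coding genes within ±10 kb of an
   lncRNA, tested for term over-representation with a hypergeometric test
   (significant at raw p < 0.01 and enrichment ratio ≥ 2).
4. **Clinical biomarker screen** — per probe, early (INSS stages 1–2) vs
   late (3–4) tumors compared with both Mann–Whitney U and Student's t
   (raw p < 0.001 on both, Benjamini–Hochberg q reported alongside), then
   Kendall |τ-b| > 0.25 against ordinal stage; selected probes feed a
   nearest-shrunken-centroid (PAM) signature with stratified
   cross-validation and a two-cluster τ-correlation grouping.
5. **Knock-down DE calling** — a probe responds to an siRNA knock-down iff
   t-test p < 0.05, median fold change > 1.3 (or 1.4), and ≥ 3 replicates
   beyond the control median, simultaneously in **both** siRNA conditions
   with the same direction.

Because the original study's raw microarray data live in GEO accessions,
a first-class synthetic-data module (`lncarray.simulate`) generates every
input from a seed — a toy genome with planted filter outcomes, length
populations with known breakpoints, staged cohorts with planted markers,
and knock-down replicate matrices — so the whole pipeline is testable
offline, with known ground truth.

## Worked example

The `analysis/` scripts run the full study on synthetic data
(`python analysis/01_simulate_data.py` first; intermediate matrices go to
`scratch/data/`, summary tables to `results/`). What they print:

```
$ python analysis/03_fit_length_classes.py
fitted cutoffs: 402 nt and 2311 nt (generative breakpoints 400 / 2300)
class shares: {'class1': '4.9%', 'class2': '86.3%', 'class3': '8.8%'}
recovery study: 10/10 seeds within +/-15% of both breakpoints, median relative error 3.7%

$ python analysis/04_screen_biomarkers.py
screen: 50 probes pass both tests at p<0.001; 50 also pass |tau|>0.25
planted-marker recall: 100%; 84% of selected correlate positively with stage
signature: 50 probes survive shrinkage at delta=4.00; CV accuracy 100%
signature probes group into 2 correlation clusters, sizes {1: 42, 2: 8}

$ python analysis/05_knockdown_targets.py
DE consensus: 43 up, 53 down (planted 43 up / 53 down)
exact recovery: True
```

The fitted cutoffs sit within 1% of the generative breakpoints; all 50
planted stage markers are recovered (with the planted ~80/20
positive/negative direction split visible in the τ signs); and the DE
caller returns exactly the planted 43 up- and 53 down-regulated genes.

The same stages are available as a CLI (`lncarray simulate|annotate|
classify-lengths|neighbors|enrich|screen|signature|knockdown-de|
run-annotation|run-biomarker`) driven by flags or a YAML config.

## Layout

- `src/lncarray/` — the library: `core` (domain types), `io`,
  `simulate`, `annotation`, `length_classes`, `neighbors`, `screen`,
  `nsc`, `knockdown`, `pipelines`, `config`, `cli`.
- `analysis/` — numbered narrative drivers reproducing the study flow.
- `docs/methods.md` — models, assumptions, parameter choices, limitations.
- `tests/` — unit, property and acceptance tests (enumeration oracles for
  the statistical primitives; planted-fixture recovery for the pipelines).
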