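# Methods

This note documents the models implemented in hrdkit, the parameter
choices that matter, what the synthetic-data generators do and do not
emulate, and the numerical conventions.  Nothing here states an empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Genomic-scar scoring

The engine consumes allele-specific copy-number segments that are already
adjusted for tumor purity and ploidy; allele copy numbers are integerized
by rounding half-away-from-zero and the minor allele is re-oriented so
minor ≤ major.  Sex chromosomes are excluded by default because minor-
allele semantics differ there; the scar literature scores autosomes.

Component definitions (all thresholds are `ScarConfig` fields so published
variants can be configured):

| component | rule | default |
|---|---|---|
| LOH | maximal runs with minor = 0, total ≥ 1; strictly longer than `loh_min_len`; whole-chromosome runs excluded | 15 Mb |
| TAI | maximal runs with minor ≠ major that touch coordinate 0 or the chromosome length, do not intersect the centromere interval, strictly longer than `tai_min_len` | 11 Mb |
| LST | per arm: merge equal states, drop segments < `lst_smooth_len`, re-merge equal states across gaps ≤ `lst_smooth_len`, count junctions where both flanks ≥ `lst_min_seg`, the state changes, and the inter-segment gap ≤ `lst_smooth_len` | 10 Mb / 3 Mb |

Run lengths are covered (not spanned) lengths; segments separated by an
assembly gap below `gap_merge_max` (default 1 Mb) are treated as adjacent.
These precise tie-break and gap rules exist so that an independent
per-base oracle (state vectors at 0.1 Mb, definitions applied literally)
reproduces the counts exactly; that equivalence is exercised on 200 random
profiles in the test suite.

The genomic-instability score is the unweighted sum of the three
components.  The decision rule is strict: GI > 42 → HRD, GI < 42 → HRP.  A
score of exactly 42 is not defined by the published rule; we call it HRP
(respecting the strict inequality) and attach a boundary warning rather
than guessing intent.  The threshold is recalibratable as the nearest-rank
5th percentile (the ceil(0.05·n)-th order statistic) of GI scores from a
reference set of BRCA-mutated samples; at least 20 scores are required
because a 5th percentile of fewer samples is dominated by a single order
statistic.  Samples called HRP by score but carrying a retained
pathogenic/likely-pathogenic BRCA1/2 variant are overridden to HRD.

The shipped human-like build has 22 autosomes with lengths and centromere
intervals rounded to a 0.1 Mb grid; the rounding is immaterial at the
10 Mb scale the scores operate on, and all operations accept any
`GenomeBuild`.

## Shallow-WGS scoring

The upstream pipeline this emulates delegates segmentation to external
scripts and publishes no formulas, so the implementation here is a fully
specified, oracle-checkable procedure with every choice parameterized:

- **Re-binning**: counts are summed into windows that must be integer
  multiples of the native bin width; the trailing partial window drops.
  The six default windows {5, 10, 50, 100, 500, 1000} kb form a geometric
  ladder over the stated 5–1000 kb span (the exact production window set
  is not disclosed; these are declared stand-ins).
- **Normalization**: per-sample median-centred log₂ ratios; zero counts
  floored at 0.5 reads.  No GC or mappability correction is applied — the
  synthetic inputs carry no such biases; a hook exists where a correction
  would slot in.
- **Segmentation**: exact penalized least-squares changepoints via PELT.
  The per-changepoint penalty defaults to 3·σ̂²·ln n with σ̂ the MAD of
  first differences divided by √2 (a BIC-like choice that detects the
  ≥ 0.2 log₂ steps relevant to LGA counting while ignoring bin noise);
  it is overridable.  PELT is validated against an unpruned O(n²) dynamic
  program and an exhaustive single-changepoint scan in the tests.
- **LGA counting**: per arm, segments < 3 Mb are dropped, neighbours
  closer than 0.2 in mean log₂ are merged (length-weighted), and a
  junction counts when both flanks are ≥ 10 Mb and |Δlog₂| ≥ 0.2.
- **Ensemble call**: each window-size model votes HRD when its LGA count
  reaches the cutoff (default 20, recalibratable by maximizing Youden's J
  on a labeled training set, ties resolved toward higher specificity).
  The consensus is the majority label when ≥ 4 of 6 models agree,
  otherwise Inconclusive.  "Level of agreement" as majority-vote fraction
  is an operationalization; the production statistic is not published.
  BRCA status is never an input.  Samples whose bins cover < 80% of the
  build are failed with reason "insufficient coverage".

## RAD51 functional scoring

The module starts at the per-cell count table (image analysis is
upstream): geminin positivity, RAD51 focus count, γH2AX positivity,
area id.  Gates are evaluated in order — no cells at all (`fail_no_tumor`),
then < 40 geminin-positive cells (`fail_few_cells`), then γH2AX in < 25%
of geminin-positive cells (`fail_low_gh2ax`).  The published failure
conditions are strict inequalities, so exactly 40 cells or exactly 25%
pass.  The score is 100 × (geminin⁺ cells with ≥ 5 foci)/(geminin⁺ cells);
HRD iff score ≤ 10%.  Whether "100 geminin-positive cells from ≥ 3 areas"
is a cap or a minimum is ambiguous in the source protocol; it is
implemented as a cap via seeded, area-stratified subsampling (round-robin
across areas, deterministic per seed), and scoring on all cells is equally
supported.  γH2AX positivity is consumed as a per-cell boolean; the
per-cell focus threshold behind it is not stated upstream.

## Concordance statistics

All metrics are complete-case: pairs with a missing call on either side
are excluded and counted.  Cohen's κ uses the standard 2×2 form with
p_e from the margin products; the SE is the large-sample approximation
√(p_o(1−p_o)/(n(1−p_e)²)) — the source does not name its SE formula, so κ
CIs are reported but not held to the printed intervals.  Interpretation
bands: <0 none, ≤0.20 slight, ≤0.40 fair, ≤0.60 moderate, ≤0.80
substantial, >0.80 almost perfect.  Clopper–Pearson intervals come from
beta quantiles with the conventional closed ends at x=0 and x=n.  The
κ-precision planning size is n = ⌈(z·sd/(width/2))²⌉.

One reconstruction caveat: recomputing the second genomic assay's
agreement/κ from its published cross-tabulation gives 0.88/0.75 where the
source prints 0.87/0.74 — a ±0.01 discrepancy whose origin (a different
complete-case set or a rounding chain) cannot be resolved from the printed
counts.  Those two printed values are therefore documented here and not
asserted; that assay's sensitivity and specificity, which do reconcile
with the cross-tabulation, are asserted.

## Survival analysis

Kaplan–Meier, log-rank, and Cox go through lifelines behind the module
surface.  Cox uses Efron tie handling (event times at month resolution tie
often); a warning fires when events fall below 10 per model term.
Medians never reached are reported as not estimable.  The log-rank
statistic is checked against a hand-written Cox score test at β = 0 on
untied toy data (they coincide exactly there).

## Synthetic data: what it emulates and what it does not

`gen_profile` composes a fully covering profile whose scar counts equal
the requested (LOH, TAI, LST) targets exactly: LOH runs (16–30 Mb) and
telomeric imbalance runs (12.4–25 Mb) are laid down as alternating
sub-3 Mb slivers of equivalent state so they are invisible to LST
smoothing; each LST unit is a pair of 10.5–12.5 Mb segments with different
states, insulated from the balanced diploid filler by 3.6–4.2 Mb buffer
segments (long enough to survive smoothing, short enough never to be an
LST flank); features are separated by ≥ 3.6 Mb of filler.  Infeasible
targets raise.  Breakpoints sit on a 0.1 Mb grid so the per-base oracle is
exact.

`gen_coverage` draws gamma-Poisson (negative-binomial) counts with mean
depth·window/read-length·CN/2 and log₂-scale extra-dispersion σ; σ = 0
degenerates to pure Poisson counting noise, reflecting that FFPE shallow
WGS is overdispersed relative to Poisson.  It does not simulate GC
content, mappability, replication timing, or read-level artifacts — so
passing recovery tests demonstrates correctness of the segmentation and
counting logic, not robustness to those real-data biases.

`gen_cells` draws geminin-positive cells whose ≥ 5-foci indicator is
Bernoulli(p_RAD51) (focus counts 5 + Poisson(3) above threshold, uniform
0–4 below) and γH2AX booleans Bernoulli(p_γH2AX); it does not model
staining intensity, spatial correlation within areas, or reader
variability.

`gen_cohort` draws a latent HRD state per sample (default fraction 0.59,
the value that moment-matches the published complete-case table of the
first genomic assay against a near-perfect reference), per-assay labels
from designed sensitivity/specificity/missingness (defaults match the
observed error patterns of the three assays), exponential progression
times with a designed HRD-vs-HRP hazard ratio of 0.53 (the published
multivariable estimate, used as the design point; baseline HRP median 15
months), uniform censoring over 24–60 months (yielding roughly the
observed event fraction), and response/covariate frequencies matching the
published baseline table.  Real trial outcome tables (patient-level
medians and adjusted hazard ratios) cannot be reproduced from printed
summaries; the cohort generator reproduces them structurally, and the
outcome modules are validated by parameter recovery instead.

## Problem sizes and numerical choices

- Scar oracle equivalence: 200 random 50-segment profiles on six
  chromosomes of the human-like build; target recovery: 50 random triples
  in {0..15}³ on the full build.
- Shallow recovery: compact simulation build (8 metacentric chromosomes ×
  160 Mb, 3 Mb centromeres) so that up to 25 LGA units fit and a
  100-genome study runs at desk scale; 25 replicates per G in the test
  suite and 10 per G in the acceptance script (both sizes stated in the
  respective files).  Recovery is asserted for windows ≤ 100 kb; the
  500/1000 kb models occasionally miss one unit because a 3.6–4.2 Mb
  buffer spans only 3–4 coarse bins, which is exactly the cross-window
  disagreement the ensemble absorbs.
- Cox recovery: n = 2000 simulated subjects, designed HR 0.53, assertion
  within 3 SE of the true log-hazard.
- Rounding for display is half-away-from-zero at the printed precision;
  machine outputs keep full precision.  All generators are pure functions
  of (parameters, seed).

## Known limitations

- The scar-component definitions follow the cited scar literature, not a
  disclosed production algorithm; the production score may weight or
  filter components differently ("there are some differences" is all that
  is published).  All thresholds are configurable for that reason.
- The shallow pipeline's exact window set, agreement statistic, and HRD
  cutoff are stand-ins (declared above), not inferred facts.
- Mutation-level BRCA concordance counts "same status, different variant"
  as disagreement in the headline rate; both tallies are always reported
  so the alternative convention can be read off.  The published BRCA κ
  values cannot be reconstructed from printed counts and are not asserted.
- No purity/ploidy estimation, no read alignment, no image analysis:
  profiles, bins, and cell tables are the unit of input.
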