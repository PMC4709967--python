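# Methods

This note documents the models, numerical choices, and limitations behind
each stage of the pipeline, and what the simulation-based tests do and do
not establish about real sequencing data.

## Sequencing QC gates (`readqc`)

Three tiers, all with inclusive (≤ / ≥) threshold comparisons:

| tier | criterion | default |
|---|---|---|
| lane | sequencing error rate | ≤ 2.5 % |
| lane | Q20 / Q30 base fraction | ≥ 80 % / ≥ 75 % |
| lane | GC/AT separation | ≤ 0.4 % |
| read | adaptor-flagged fraction (batch rule) | ≤ 10 % |
| read | N fraction per read | ≤ 10 % |
| read | bases below Q5 per read | ≤ 50 % |
| sample | mean depth (WGS / WES) | ≥ 30× / ≥ 100× |
| sample | mapping rate / mismatch rate | ≥ 95 % / ≤ 10 % |

Open definitional points resolved here: "GC or AT separation rate" is
implemented as |GC fraction − AT fraction| over non-N base calls (the
simplest reading; any monotone variant only rescales the 0.4 % cutoff);
adaptor contamination arrives as a per-read boolean flag set upstream (read
trimmers' internals are out of scope) and the 10 % rule is applied to the
batch, discarding flagged reads only when the batch exceeds it. The lane
error rate is instrument-reported and passed through rather than estimated
from spike-ins.

## Somatic SNV filter (`snv_filter`)

A site passes only if all nine criteria hold (see README for the list).
Alpha comparisons are strict (`p < α`), matching the stated cutoffs.
Resolved ambiguities:

* **Quality-support tests (criteria 5–6).** The criteria demand alt-read
  MAPQ/baseQ "significantly higher than" a constant; a two-sample rank-sum
  test needs two samples, so these are implemented as one-sample, one-sided
  Wilcoxon signed-rank tests against the constant. Zero differences are
  dropped (Wilcoxon's reduced-sample rule; the Pratt variant would retain
  them in ranking — at these n the decisions rarely differ, and dropping is
  the scipy-compatible default). Consequence: a site whose alt reads all sit
  at the reference value carries no evidence and fails, and fewer than 3
  informative alt reads cannot reach p < 0.2 (2⁻² = 0.25), which dovetails
  with the ≥ 3-alt-read criterion.
* **Exact nulls with ties.** Quality scores are small integers, so ties are
  the norm, and textbook exact tables (and scipy's `method="exact"`) assume
  distinct ranks. Both rank tests therefore build the exact conditional
  null *given the observed tied midranks* by dynamic programming over
  doubled midranks (integers), equivalent to enumerating all 2ⁿ sign
  assignments or C(N, n₁) relabelings; counts stay below 2⁵³ so float64
  arithmetic is exact. Exact up to n = 25 (signed-rank) / N = 30
  (rank-sum); beyond that, normal approximations with tie correction and
  0.5 continuity correction.
* **Read-end test (criterion 7).** Each read's call is scored by distance
  to the nearest read end, min(offset, L−1−offset); a one-sided rank-sum
  tests whether alt distances are stochastically smaller than ref
  distances, and the site is rejected when that enrichment is significant
  at p < 0.1. Reads supporting neither allele join neither group (they
  still count toward depth and VAF denominators).
* **Adjacency (criterion 4).** Applied cohort-wide after the per-site
  criteria (order does not change the final set): any site whose nearest
  same-chromosome candidate is ≤ 10 bp away is removed, and both members of
  a close pair are dropped — the violation is a property of the pair. A
  `keep_first` greedy alternative is exposed.
* **Fisher tests** (criteria 8–9) are two-sided (sidedness is not dictated
  by the criteria text) and delegate to `scipy.stats.fisher_exact`; the
  test suite pins them to a full-margin hypergeometric enumeration for
  every 2×2 table with total ≤ 40, to 10⁻¹².
* **Validation mode** lowers the tumor-VAF floor from 10 % to 5 % for deep
  target-capture re-sequencing, leaving everything else unchanged.

## Indel classification (`indel_filter`)

Candidates arrive post-calling and post-realignment with per-normal support
counts. Germline iff any covered normal shows ≥ `min_support` (default 1)
supporting reads; somatic otherwise; `unevaluable` when no normal has
coverage. One supporting read is an aggressive germline rule at high depth,
hence the knob; the default follows the "any evidence" reading. Adding
normal evidence can only move a call toward germline (monotone).

## Recurrent copy-number significance (`cnv_gscore`)

Segments carry absolute copy number (diploid = 2). Gene-level CN is the
overlap-length-weighted mean over the gene interval (missing when nothing
overlaps). Marker projection uses fixed windows (default 1 kb, trailing
partial windows kept); base pairs not covered by any segment contribute the
neutral value 2, which avoids spurious deletions from missing data.

The G-score combines alteration frequency and amplitude:
G = (k/N)·mean(aᵢ) over the altered samples, which algebraically equals
Σaᵢ/N — the "frequency × mean amplitude" and "summed amplitude over cohort
size" readings coincide, so a single formula is implemented. Calls use
CN ≤ 1.5 / CN ≥ 2.5 inclusively; sub-threshold excursions contribute
nothing.

The permutation null circularly shifts each sample's marker vector by an
independent uniform offset per permutation. This breaks marker–sample
association while preserving each sample's segment-length autocorrelation;
an i.i.d. marker shuffle would destroy that structure and anti-conservatively
inflate significance for segmented data. Empirical p uses the +1-corrected
estimator (1 + #{G_null ≥ G_obs})/(1 + B), so p ≥ 1/(B+1) and is monotone
non-increasing in observed G. A marker is significant only when
G > 0.1 **and** p < 0.05: the printed equivalence of those two cutoffs is
data-dependent and deliberately not assumed, so both are enforced
conjunctively. Adjacent significant markers merge into regions with the
max-G marker as peak.

Per-sample SCNA burden is the length-weighted fraction of assayed bp called
deleted or amplified; stages are compared by a one-sided rank-sum test
(exact under the same engine for small groups).

## qPCR copy number (`qpcr_cn`)

Comparative-Ct model with amplification efficiency fixed at 2.0 per cycle
(no efficiency correction is described for these assays). Replicate Ct
values are averaged **before** exponentiation — the standard practice, and
the two orders genuinely differ (a fixture asserts it): averaging after
exponentiation would upper-bias CN by Jensen's inequality. The calibrator
(a pooled diploid normal is assumed; the instrument files do not name one)
anchors CN(calibrator) = 2 exactly; CN halves per unit ΔΔCt; CN < 0.3
flags homozygous deletion (strict <).

## Cohort statistics (`cohort_stats`)

* Landscape classes partition genes by cohort frequency: mountain ≥ 10 %,
  hill [5 %, 10 %), low [2 %, 5 %); band edges inclusive on the left.
* Printed-style percentages use round-half-up (`decimal`), matching how
  such frequencies are conventionally reported (21 % = 22/104,
  16.7 % = 6/36, 44 % = 46/104).
* Stage association: Fisher exact on the 2×2 stage × mutated table, gene
  sets scored as "any member mutated". Two-sided by default; the one-sided
  (pre-specified stage-I-enrichment) variant is what reproduces the
  reported significance bounds on the reconstructed tables, and both are
  available. BH adjustment is applied across whatever feature family the
  caller supplies.
* Pathway enrichment: upper-tail hypergeometric of the overlap against the
  declared gene universe, BH-corrected across pathways.
* Spectrum: the six pyrimidine-context substitution classes, purine
  references folded to their complement — the standard convention.

**Conservativeness of exact tests.** Fisher's exact test on discrete 2×2
tables has achieved type-I level strictly below nominal α: at 51-vs-53
group sizes and α = 0.05 the exactly enumerated null rejection probability
is ≈ 3–4 % depending on the marginal rate. The calibration test therefore
checks the empirical null rejection rate against the *enumerated* expected
level of the discrete test, not against nominal 5 % — no exact conditional
test can center on 5 % there.

## Synthetic cohort generator (`simulate`)

No generative model is dictated by the analysis being emulated; every
distribution here is an explicit artifact choice, fixed once:

* **Cohort**: 51 stage I + 53 stage III samples; one planted gene mutated
  at 35 % / 8 % by stage over a 2 % Bernoulli background across 200 genes.
* **Depths**: negative binomial with mean 100 (exome-like scale) and size
  25 — overdispersed coverage deliberately stresses the depth criterion.
* **Qualities**: discrete Illumina-like ranges, MAPQ ∈ [50, 60] and
  baseQ ∈ [33, 41] for well-behaved reads; artifact classes shift these
  (e.g. alt baseQ ∈ [5, 18] for the low-quality class) relative to the
  filter's 30/20 reference values.
* **Site classes**: clean_somatic satisfies all nine criteria by
  construction (VAF ∈ [0.2, 0.4] clamped to ≥ max(3 reads, 10 % of depth),
  alt-free normal); germline mirrors tumor VAF in the normal; low_vaf caps
  tumor VAF below 10 %; strand_artifact puts every alt read on one strand
  with enough alt reads for the exact test to see it; readend_artifact
  places alt calls within 5 bp of a read end; lowqual_artifact draws alt
  baseQ below 20. Clean-site read offsets are stratified-uniform (evenly
  tiled with jitter): the marginal stays uniform, but the chance end
  clustering that i.i.d. draws produce at 20–40 alt reads — which would
  spuriously trip the read-end criterion on ~10 % of genuinely clean
  sites — cannot occur, matching how densely tiled real loci behave.
* **Copy number**: 25-kb segments with Gaussian jitter (σ = 0.15) around
  2.0, floored at 0; planted regions (chr1:100–200 kb at CN 3.2 biased to
  stage I; chr2:300–400 kb at CN 0.8 biased to stage III) are carried by
  40 % of the biased stage's samples.
* **Ct tables**: triplicates, replicate noise σ = 0.05 cycles, target Ct
  derived from the sample's simulated CN through the inverse ΔΔCt relation,
  with a diploid calibrator sample.

All randomness flows from the single config seed through named
`SeedSequence` substreams (matrix, segments, sites, Ct, reads), so outputs
are reproducible and stages are independently stable under config edits.

**What passing tests show — and do not.** The recovery results (filter
sensitivity/specificity ≥ 0.9, planted-region significance, planted-rate
recovery) certify that the implementation detects exactly the violations
the classes are built to contain, at realistic depths and effect sizes.
They do not certify performance on real tumors: the generator has no
alignment error, no tumor purity/clonality structure, no contamination, no
GC-dependent coverage, and its artifact classes are pure rather than mixed.
Real-data operating points will be worse and assay-dependent.

## Problem sizes

Defaults keep the full pipeline interactive: a 2 × 500 kb genome
(1,000 one-kb markers), 104 samples, 120 evidence sites, and 1,000
permutations run end-to-end in a few seconds; the calibration checks use
500 markers × 40 samples × 1,000 permutations and 500 simulated sites per
class. All sizes scale up linearly through `SimConfig`/`CnvParams`.

## Known limitations

* The signed-rank reading of criteria 5–6 is one plausible resolution of an
  ambiguous description; an alt-vs-ref two-sample variant is defensible and
  would be slightly less strict at low depth.
* Uncovered marker windows filled with CN 2 bias G toward zero in sparsely
  segmented genomes rather than dropping markers.
* The ΔΔCt model assumes perfect doubling; real assay efficiencies of
  0.9–1.0 per cycle bias CN multiplicatively.
* `gene_copy_number` is a straightforward per-gene scan (adequate for
  hundreds of genes; an interval index would be needed for genome-wide gene
  models).
* Indel evidence is count-based only; mapping-quality weighting of normal
  evidence is not modeled.
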