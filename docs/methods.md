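# Methods

This note documents the models, conventions and numerical choices behind
`cnvburden`, and what its synthetic cohorts do and do not establish.

## Coordinates and interval arithmetic

All intervals are half-open `[start, end)`, so a region's size is exactly
`end − start` and file coordinates are ingested verbatim with no ±1
adjustment; intervals that merely touch share zero bases. Strand is ignored
throughout (copy-number events are unstranded). The overlap fraction of a
query against a reference set is query-anchored: the number of query bases
covered by the **union** of references, divided by the query length. This
is the most conservative common reading of an "overlapping rate"; a
reference-anchored mode is available where the anchor matters (pathogenic
matching).

CNV regions (CNVRs) aggregate calls pooled across samples that overlap by
at least 1 bp, directly or through a chain of intermediates. A region's
type is DEL or DUP when all members agree and BOTH otherwise. Merging is a
single sweep over (chrom, start)-sorted intervals; it is idempotent and its
union length is property-tested against a per-base boolean oracle.

## Read-depth normalization and CNV calling

The caller follows the standard exome read-depth recipe (an XHMM-style
design):

1. subtract each target's cross-sample mean;
2. compute the SVD of the centered samples × targets matrix and remove
   every principal component whose variance exceeds 0.7 × the mean
   component variance (capture batch, GC and library-size structure appear
   as dominant low-rank components); the cap on removed components is
   configurable and uncapped by default;
3. scale each target column to unit variance, dropping (with a warning)
   columns with zero residual variance.

Segmentation is a three-state HMM (deletion, diploid, duplication) decoded
per sample and per chromosome with the Viterbi algorithm. Emissions are
Gaussian with unit variance and means (−M, 0, +M), default M = 3.
Transitions out of diploid enter either CNV state with probability
p = 1e-8; within a CNV the continuation probability is (1 − 1/T), T = 6,
attenuated by exp(−d/D) for the distance d between consecutive target
midpoints, D = 70 kb, so well-separated targets rarely share an event.
Exact Viterbi ties are broken toward diploid — calls need strict evidence —
though ties have measure zero on real-valued input. Viterbi decoding is
validated against exhaustive 3^n path enumeration.

Call confidence is a phred-scaled "some quality": −10·log10 P(the call
span is entirely diploid | data), computed exactly from a forward pass
restricted to the diploid state inside the span, capped at 99.

### The quality threshold

The retention default is Q ≥ 60, the convention of the published tool this
design follows. Users should know its operating characteristics at the
model's own design point: a clean 6-target event at exactly the emission
shift (|z| = 3) scores Q ≈ 18 (P(diploid) ≈ 1.4%); Q reaches ~57 at shift
3.5 and ~96 at shift 4. A Q ≥ 60 cut therefore retains only events well
above the emission mean. Experiments on synthetic cohorts implanted *at*
the design shift use explicit lower thresholds: Q ≥ 0 when measuring raw
discovery sensitivity, Q ≥ 13 (P(diploid) < 5%) for end-to-end
demonstrations.

### Sensitivity at the design point

With p = 1e-8 pinned, a 6-target event is Viterbi-called roughly when its
summed z clears the ~18.4-nat entry cost plus continuation/exit costs —
about |z̄| ≥ 2.7 per target. For implants whose realized per-target shift is
N(3, ~1), detection probability is ≈ 0.80; measured recovery on 100 × 500
cohorts is 80–82% with ~0 false calls per sample. This is a property of the
prior, not of the decoder: any caller honoring the same prior odds is
similarly bounded, and even contiguous targets (no attenuation) only reach
~85–87%. Larger or stronger events are recovered essentially always.

## Rare-CNV filtering

A call is common when the union of matching references covers **strictly
more** than 50% of it (exactly 50% is retained), matching references being
the common-CNV map plus control-cohort calls, type-matched by default
(deletions masked only by deletion references). Control calls are merged
per sample and pooled; a `min_control_carriers` knob (default 1) requires a
segment to be carried by at least that many distinct controls before it
joins the reference set. No allele-frequency model is used: "rare" is
purely overlap-defined. Filtering is a partition (rare + removed = input)
and idempotent.

## Landscape statistics

Per-chromosome burden is count and count per Mb; the loss/gain ratio is
n_DEL / n_DUP, reported as NaN when a chromosome has no duplications. Size
classes are six bins over edges {10, 50, 100, 250, 500} kb, half-open on
the left and closed on the right (a 10,000 bp call falls in the first bin);
only the outermost bins are anchored in the source material, so the inner
edges are configurable. The chromosome-length vs count association uses
Spearman's rank correlation with mid-ranks for ties; the two-sided p-value
is exact (full permutation enumeration) for n ≤ 9 chromosomes and uses the
t-approximation otherwise. Pathogenic matching flags calls or CNVRs whose
overlap fraction with a curated region is **at least** 50% (inclusive),
anchored on the case item by default with a switch for region anchoring.

## Gene burden testing

The burden unit is the carrier subject: a sample carries a gene if any of
its rare calls overlaps the gene by ≥ 1 bp, counted once per gene. Each
gene's 2×2 table (case/control × carrier/non-carrier) is tested with a
two-sided Fisher exact test under the point-probability rule — the sum of
hypergeometric probabilities of all tables with the observed margins whose
point probability is at most the observed one, compared with a 1e-7
relative tolerance and computed in log space via log-gamma. The
implementation is validated against exact rational enumeration to 1e-12
and cross-checked against an independent library implementation.
Candidates are genes with p < 0.05 (strict); no multiple-testing
correction is applied to the flag, but a Benjamini–Hochberg column is
emitted for information. Useful calibration points at the default cohort
sizes (150 cases / 100 controls, zero control carriers): 6 case carriers
give p = 0.084, 7 give 0.044, 8 give 0.023 — a case-only gene needs at
least 7 carriers to be flagged.

## Network hubs

Maximal Clique Centrality of a node v is the sum over maximal cliques C
containing v of (|C| − 1)!; an isolated vertex scores 0! = 1. Maximal
cliques come from Bron–Kerbosch with pivoting; enumeration is guarded by a
configurable clique-count budget since it is exponential in the worst
case. Rankings are by descending MCC with ties broken by degree then name;
candidate names absent from the graph score 0 with a warning. How the edge
list was built (e.g. a STRING export and its confidence cutoff) is the
caller's concern.

## Expression screening

Counts are normalized to CPM per condition column (each column sums to
1e6). The "high and dynamic" screen flags genes with max CPM ≥ 10 and
(max+1)/(min+1) ≥ 2 across the time course; the source material never
defines its screen quantitatively, so both components are reported and
both thresholds are configurable. Per-cluster single-cell summaries report
mean CPM and the expressing-cell fraction; clustering is upstream and
labels are an input.

## Synthetic cohorts

The generator produces the study conditions every stage is tested under:
150 cases and 100 controls by default, exon-like targets tiled over a few
chromosomes, and per-target depth drawn negative-binomially around
base_depth × exp(low-rank confounders) × dosage multiplier. Deletions
multiply expected depth by 0.5 and duplications by 1.5. The NB size of 150
gives a ~11.5% coefficient of variation at depth 100 — typical of exome
target coverage — and is calibrated so the *realized* standardized shift
at implants after PCA normalization is ≈ 3, the caller's design point
(normalization slightly inflates residual variance and absorbs part of any
single-sample deviation, so naive calibration against raw counting noise
undershoots).

The common-CNV map contains jittered copies (≤ 10% of length per edge) of
a random subset of implants plus decoy records that overlap no implant, so
every implant's rare/common label is known at generation time; the
rare-filter partition can then be compared with truth exactly. Burden
genes are planted with exactly the configured carrier counts (default
8 cases / 0 controls — at least 7 case-only carriers are needed to clear
p < 0.05, see above) and background implants avoid their targets, so
planted counts are exact; this mirrors the empirical observation that
candidate genes carry no control CNVs, and keeps the planted-burden
property well-posed on a genome only a few hundred targets long. A planted
event must also stay rare in the cohort sense: events shared by a large
fraction of samples constitute low-rank structure that PCA normalization
legitimately removes.

PPI graphs are Erdős–Rényi backgrounds with planted cliques through
designated hub nodes; time-course expression plants Gaussian-bump
trajectories with peak/trough fold drawn log-uniformly from [6, 16] (the
lower bound leaves a 3× margin over the screen's fold-2 threshold under
counting noise) over flat log-uniform backgrounds.

What the synthetic cohorts do **not** emulate: GC- and
mappability-dependent bias, target-length variation, relatedness,
population stratification, breakpoints inside targets, and real common-CNV
population frequencies. Passing tests demonstrate the pipeline's internal
correctness and its behavior under the stated noise model, not calling
performance on real exomes.

## Problem sizes

Default test and demonstration cohorts use a few hundred samples by a few
hundred to a thousand targets — large enough for the PCA step to be
meaningful and for planted-burden Fisher tests to be decisive, and small
enough that the full suite and the acceptance script each run in well
under a minute of compute per experiment. All randomness flows from a
single integer seed; identical configurations produce byte-identical
outputs, which the pipeline manifest verifies by SHA-256.
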