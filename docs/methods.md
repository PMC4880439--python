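# Methods

This note documents the models and procedures implemented in
`snvconsensus`, the parameters that matter, the scope of the synthetic
data the tests rely on, and the numerical choices made where the design
was genuinely open.

## Variant categorization

An SNV is assigned exactly one of five categories.  Coding calls come
from codon translation: the affected codon is located in the spliced CDS
(reverse-complemented for minus-strand transcripts), the reference and
alternate codons are translated with the standard nuclear code, and the
call is *nonsense* if the alternate codon is a stop and the amino acid
changed, *missense* if the amino acid changed otherwise, *synonymous* if
unchanged.  A stop-retaining substitution in a stop codon (e.g. TAA→TAG)
is therefore synonymous, and stop-loss/start-loss substitutions fall out
as missense — the five-way scheme has no finer classes for them.  This
rule is pinned by a property test: for every possible CDS substitution of
a simulated transcript set, the per-codon call must equal the call
implied by translating the entire mutant CDS and comparing whole
proteins.

*Splicing* is an intronic position within `splice_window` bp of an exon
boundary; the default of 2 bp corresponds to the canonical splice
dinucleotides (GT donor, AG acceptor) and is configurable.  Everything
else — intergenic, deep intronic, UTR/non-coding exonic, up/downstream —
collapses into *regulatory*: the category is defined as the non-coding,
non-splice-proximal remainder.

When transcripts overlap, the most severe call wins:
nonsense > missense > splicing > synonymous > regulatory.  Severity
precedence is the conservative convention for a screening tool; no
transcript prioritization by biotype or canonical flags is attempted.
The reference allele is checked against the FASTA and a mismatch is a
hard data-integrity error, not a warning — silent coordinate mix-ups are
the most common failure mode of variant pipelines.

## Dataset construction

Neutral controls are matched 1:1 to deleterious variants by greedy
nearest-neighbor distance on the same chromosome, without replacement,
processing deleterious variants in (chromosome, position) order.  The
fixed processing order makes the result deterministic; distance ties go
to the lower genomic position.  Matching is performed within one category
— cross-chromosome distance is undefined and cross-category matching
would mix distributions.  Deleterious variants left without a
same-chromosome candidate are dropped (with a warning) so the result is
exactly balanced.

Train/test splits are either date-based (submission date strictly after
the cutoff goes to test; a matched pair follows its deleterious member)
or, for coding categories, leakage-controlled: protein sequences are
clustered greedily by descending length, each sequence joining the first
cluster whose representative it matches at ≥ 50% identity, and whole
clusters are assigned to one side by seeded shuffle until the target test
fraction is approximately met.  Identity is the number of identical
aligned residues in the optimal global alignment (match +1, mismatch 0,
gap open −1, gap extend −0.5) divided by the shorter sequence length —
the CD-HIT convention.  The greedy word-filter heuristics of CD-HIT
itself are not reproduced; at package scale exact alignment is cheap.

## Threshold optimization

For a tool with "higher is deleterious" polarity the decision rule is
*deleterious iff score ≥ t* (inclusive, favoring sensitivity); the
mirrored rule applies to inverted tools.  Candidates are the midpoints
between consecutive distinct training scores plus one candidate outside
each end of the range, so the search space is exactly the set of
achievable confusion matrices.  The objective is normalized (balanced)
accuracy, appropriate because the constructed datasets are 1:1 balanced
by design; ties break toward the more sensitive threshold.  The
implementation is a vectorized cumulative scan; its equivalence to a
brute-force candidate-by-candidate evaluation is asserted over a thousand
random instances in the tests.

## Confidence calibration

Training points are sorted by raw score and partitioned into
`n_bins = 66` bins of equal size; per-bin fractions of deleterious labels
are smoothed with a centered moving average of `window = 11` bins.  The
66/11 defaults suit training sets of a few thousand points (≈ 30+ points
per bin); for smaller sets the bin count shrinks to `min(66, n // 2)` so
every bin keeps at least two points (remainder points distributed one per
bin from the lowest-score bin), and the smoothing window truncates
symmetrically at the edges — at bin *i* the half-width is
`min(window // 2, i, B − 1 − i)`, which keeps the window centered and
leaves a constant signal unchanged.

A query score is mapped to the smoothed fraction-deleterious by linear
interpolation between bin centers, clamped to the outermost bin beyond
the training range.  Two sides of the transform serve the two prediction
classes: a deleterious call is assigned that fraction, a neutral call its
complement, scaled to an integer confidence capped at 99 (the scale is
0–99 by construction, so a perfectly pure bin does not claim certainty).
Interpolation rather than step-function lookup was chosen to avoid
confidence jumps at bin boundaries; both agree at bin centers.
Calibration quality is verified on held-out data: per confidence decile,
the empirical accuracy must track the stated confidence within 0.10.
Probability calibration by logistic or isotonic regression is deliberately
out of scope — the binned observed-accuracy transform *is* the method.

The curves are fitted on the training split and evaluated on the test
split.  Confidences therefore estimate held-out accuracy only insofar as
the binned training accuracies generalize — which the decile test checks.

## Consensus

With vᵢ = +1 for a deleterious vote, −1 for neutral, and wᵢ = cᵢ/100,
the consensus score is S = Σwᵢvᵢ / Σwᵢ.  Normalizing by Σwᵢ keeps S in
[−1, +1] whatever subset of tools had a score available, so the learned
consensus threshold transfers across missingness patterns; an all-zero
weight set scores 0, and exact ties resolve to deleterious (conservative
screening behavior).  Both choices are config-visible rather than hidden.

S is then treated as a raw score: a consensus threshold is optimized and
a consensus calibration curve fitted on training consensus scores, so the
final call also carries a 0–99 confidence.  Because uninformative tools
dilute the vote, the tool subset is selected per category by exhaustively
evaluating all subsets of size ≥ 2 (26 subsets for five tools) on
training normalized accuracy, ties breaking toward fewer tools then
lexicographic names.  The best single tool is recorded for reporting but
never selected as "the consensus".  Variants with no available score in
the selected subset are flagged `NO_SCORES` and never silently dropped —
dropping them would bias any downstream evaluation.

## Evaluation

AUC uses the rank (Mann–Whitney) statistic with average ranks, which
equals the trapezoidal ROC area with half-credit ties and is
O(n log n); the tests assert exact equality with the O(n²) pairwise
probability.  MCC returns 0 when a marginal is empty.  Variants missing a
tool's score are excluded from that tool's confusion counts but disclosed
as `n_missing`.  Report tables emit both micro- (pooled counts) and
macro- (category-averaged) "Overall" rows, explicitly labeled, since
either aggregation is defensible.

## Synthetic data

`simulate_scores` draws class-conditional Gaussian scores with a latent
equicorrelation structure: zᵢ = √ρ·g + √(1−ρ)·eᵢ per tool, giving
pairwise score correlation ρ with one knob.  The default specification
has five categories × five tools: four informative tools with
class-mean separations of 0.40/0.30/0.25/0.20 (σ = 0.15), one of them
with inverted polarity, plus one label-independent noise tool; class
means shift by category (−0.10 to +0.30) so category-optimal thresholds
genuinely beat a pooled one.  Defaults are ρ = 0.3 and 500 variants per
class per category.  What this emulates: unimodal, overlapping,
category-shifted score distributions and correlated tools.  What it does
not: heavy-tailed or multimodal score shapes, structured (non-random)
missingness, label noise, and linkage between nearby variants — so
passing tests demonstrate correctness of the machinery and its behavior
under the stated model, not real-data performance.

`simulate_genome` builds two-exon genes (CDS starting ATG, ending a stop,
length divisible by 3, introns ≥ 20 bp, strands alternating) separated by
intergenic spacers, and plants variants of every category.  Coding
plants are verified at generation time by whole-CDS retranslation — the
same oracle the categorizer is tested against, applied from the opposite
direction — and splice/regulatory plants are placed at known distances
from exon boundaries.  All generators are pure functions of their seed;
FASTA/GFF3 output is byte-identical across runs.

## Problem sizes and numerical notes

The test suite and the acceptance script run at deliberately modest
scale: 1,000 random instances (n ≤ 50) for the threshold oracle, 200
instances (n ≤ 200) for the AUC oracle, a 10-gene transcript set
(~4,400 coding substitutions) for the codon oracle, 2,000 points per
class for parameter recovery, 10,000 variants for the ensemble-gain
check and 5,000 held-out points for calibration — sizes at which the
checked properties are already sharp (binomial standard errors well below
the asserted tolerances).  Model persistence uses JSON with full float
repr, so save/load round trips are bit-exact; a schema-version field
guards against loading foreign files.  Chromosome names are compared
after stripping a leading `chr`, coordinates are 1-based throughout, and
only biallelic SNVs enter the pipeline (indels and MNVs are skipped with
a count, not errored).

## Known limitations

The categorizer implements a deliberate subset of a full consequence
annotator: no frameshifts or block substitutions (SNVs only), no
UTR/ncRNA subcategories, no transcript prioritization.  The greedy
identity clustering is exact but quadratic in the number of distinct
sequences.  Subset selection maximizes training accuracy and, like any
selection on the training set, is mildly optimistic there; held-out
evaluation is the supported way to quote performance.  Tools whose
scores are constant (or single-class) within a category cannot be
thresholded and are skipped for that category.
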