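# Methods

## Regulatory-potential model

A TF's potential for regulating a gene is modelled as a weighted sum of
ChIP-seq peak contributions. The weight of a peak at distance *d* from the
TSS is `w(d) = 2^(−d/d0)`: 1 on the TSS, 1/2 at the decay distance d₀, and
negligible beyond a few d₀. Only peaks within `window_multiple × d0`
(default 15·d₀, closed interval, so a peak at exactly 15·d₀ contributes
`2^−15`) enter the sum; the closed boundary and the floor-division peak
center make results bit-reproducible. Distances are symmetric — strand is
recorded but never used, since the weight depends only on |center − TSS|.

The half-life form is a deliberate choice: "decay distance" is read as the
distance at which a peak's influence halves. A logistic-shaped variant
(`w(d) = 2e^(−μd)/(1+e^(−μd))`) used elsewhere in this method family
behaves almost identically near the TSS and was not adopted; with the
window cutoff the two orderings of genes are nearly always the same.

Assumptions worth keeping in mind:

- peak *centers* carry the binding evidence (summits are not modelled);
- peak weights add linearly — two peaks at d₀ count the same as one at 0;
- genes on chromosomes without peaks score 0 and still participate in
  scaling and ranking, because the normalisation is defined over all
  annotated genes;
- a gene with several isoform TSSs takes the **maximum** RP over its TSSs,
  which preserves promoter signal instead of averaging it away.

Raw scores are min–max scaled per experiment to [0, 1]; a constant score
vector (including the single-gene case) scales to all zeros rather than
dividing by zero. Scaling is invariant under positive affine
transformations of the raw scores.

## Baseline adjustment

Some genes attract peaks in nearly every experiment. The baseline RP of a
gene is the median of its scaled RP over a panel of reference cistromes
(genes unscored in a panel member contribute 0 for that member). Adjusted
RP = scaled − baseline, so it lies in [−1, 1] and can be negative; genes
missing from a supplied baseline table get baseline 0 (counted and
logged), and with no table the adjusted score equals the scaled score.
`compute_baseline` implements the panel computation at any scale; in
practice users supply a precomputed table, and the operation is exercised
here on synthetic panels of a few cistromes.

## Promoter/enhancer classification and d₀

Peaks are sorted by significance (−log₁₀ p, stable sort so equal scores
keep file order; peaks without scores sort last, and with no scored peaks
only the "all" subset is evaluated). For each applicable subset — top
2000, 5000, 10000 (only when that many peaks exist) and all peaks — the
fraction of peak centers within 1 kb (closed) of the nearest TSS is
computed. If **any** fraction exceeds the threshold (default 0.20,
strictly greater), the TF is promoter-dominant and d₀ defaults to 1 kb;
otherwise enhancer-dominant with d₀ = 10 kb. A user-supplied d₀ bypasses
the default but the classification report is still emitted.

## Expression integration

R^DE ranks genes by ascending differential-expression p-value after an
optional direction filter (up: log2FC > 0; down: < 0); the filter is
applied before ranking, so direction-inconsistent genes are excluded
rather than demoted. The ensemble ordering is the rank product R^RP·R^DE
over the **intersection** of the two gene universes — union-with-penalty
schemes were rejected because they fabricate evidence for unmeasured genes
— and both ranks are recomputed within the intersection (from the
underlying scores, preserving ties as mid-ranks) so the two factors share
a scale. Dropped gene counts are surfaced in the run log. No significance
is attached to the product itself; it is used purely as an ordering.

ROC/PR diagnostics label genes by padj < 0.05 (per-record fallback to the
raw p-value when padj is missing; both the cutoff and the column are
configurable), restricted to the chosen direction, and score them by
adjusted RP. The ROC is a threshold sweep with tied scores grouped into
single steps, making the trapezoid area exactly the tie-corrected
Mann–Whitney U / (n₊·n₋); the PR curve anchors recall 0 at the precision
of the single top prediction.

## The exact mHG test

For a ranked universe of N genes containing B members of a term, the
indicator series' prefix at cutoff n holds bₙ ones; the enrichment of that
prefix is the hypergeometric tail HGT(n) = P[X ≥ bₙ], X ~ Hyp(N, B, n).
The mHG statistic is min over n = 1..N of HGT(n), with the smallest
attaining cutoff n\* reported, and the enrichment score is the fold
enrichment at that cutoff, (b/n\*)/(B/N).

Because the cutoff is optimised, the statistic is not a p-value. The exact
p-value is the probability that a uniformly random arrangement of the B
ones achieves a minimum tail ≤ the observed one. It is computed by the
standard path-counting dynamic program: an arrangement is a monotone
lattice path from (0,0) to (N,B); cells whose tail falls at or below the
observed statistic form the rejection region; the DP propagates path
probability row by row, zeroing rejected cells and accumulating the zeroed
mass, which *is* the p-value. Cost is O(N·B) per term.

Numerical choices:

- tails for the lattice come from log-factorials (`gammaln`) and a per-row
  reverse cumulative sum; the log-pmf separates into b-only, n-only and
  (n−b)-only vectors, so the lattice is three 1-D precomputes and one
  gather;
- the rejection comparison uses a 1e−9 relative slack so the boundary cell
  that defines the statistic is always rejected despite float jitter
  between the lattice tails and the `scipy.stats.hypergeom` tails used for
  a standalone statistic call;
- accumulating rejected mass directly (instead of 1 − surviving mass)
  preserves relative accuracy for very small p-values; tails below
  ~1e−300 underflow to zero and are then automatically rejected, which
  only affects p-values far below any reporting threshold; returned
  p-values are clamped into (0, 1] with a 1e−300 floor;
- the DP only walks rows between the first and last rejecting prefix
  length: before the first the state is the plain hypergeometric pmf
  (computed directly), after the last no mass can be rejected;
- the DP inner loop is compiled with numba when available, with an
  identical pure-numpy fallback;
- rankings must be total orders: tied scores are broken lexicographically
  by gene id before the indicator series is built.

The test suite checks the DP against exhaustive enumeration in exact
rational arithmetic for every instance with N ≤ 12 and all B, and checks
null calibration (fraction of random terms with p < 0.05) at N = 1000.

## Term filtering and reporting

Sets are intersected with the ranked universe first; the 10 ≤ size ≤ 2000
filter applies to post-intersection sizes (both bounds inclusive).
Redundancy removal is a greedy pass in decreasing size order (ties by set
id): a set is dropped when its Jaccard index with an already-kept set
exceeds 0.85, so the larger of a redundant pair survives. FDR is
Benjamini–Hochberg across all tested sets of one collection (each GMT file
is a collection and is tested separately); the full table is always
written, the reported table restricts to FDR < 0.2.

## Synthetic data generator

The generator emulates the statistical structure the method assumes, on a
toy genome: evenly spaced genes (default 5000 genes, 100 kb apart, two
chromosomes, alternating strand), a planted target set (default 50 genes)
whose TSSs receive Poisson(λ = 5) peaks at exponential offsets (scale
300 bp) with significance scores strictly above the uniform background
(default 10 000 peaks); an expression table where planted targets draw
−log₁₀ p from 3 + Exp(2) with direction-consistent fold changes and null
genes draw p uniformly (padj by Benjamini–Hochberg); and gene-set files
with the planted term(s) plus null terms whose sizes are log-spaced over
[5, 2500] so both size-filter boundaries are exercised. All randomness
flows from one integer seed through a single generator; identical
spec + seed give byte-identical files.

What the toy genome does **not** model: real chromosome lengths and gene
density, isoform structure, GC/mappability bias, correlated gene programs,
and peak-width variation. Passing tests therefore demonstrate that the
machinery recovers planted structure under its own assumptions, not
performance on real cistromes.

Simulation scales used by the test suite and the acceptance script —
planted-term recovery at 5000 genes × 20 replicates, ensemble-improvement
contrasts at 2000 genes × 20 replicates with a deliberately weakened
binding signal (λ = 2, offset scale 1 kb) so expression evidence has room
to help, ROC calibration at 2000/10 000 genes × 5 replicates — were chosen
so each property is measured with comfortable margins at desk scale.

## Determinism and output conventions

Given identical configuration and input bytes, every output table is
byte-identical between runs: all tie-breaks are deterministic
(lexicographic gene id; stable sorts; input order for equally scored
peaks), floats print with 6 significant digits, and the only randomness in
the package lives in the fixture generator behind an explicit seed. The
run log records the resolved mode, every applied default, classification
fractions, and all dropped-record counts, so a run is reconstructible from
the log. On failure, partially written outputs are removed.

## Known limitations

- Peak summits are ignored in favour of interval centers.
- The mHG search runs over all cutoffs n ≤ N; no n_max cap is offered.
- No significance for the rank product itself, and no GO-DAG awareness —
  terms are flat gene sets exactly as supplied.
- Baseline tables must share the gene namespace of the annotation; no id
  mapping is attempted.
- For gene universes much larger than ~20 000 with many large terms the
  O(N·B) DP per term becomes the dominant cost.
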