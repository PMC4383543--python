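# Methods

## The two-library design and its model

The pipeline targets the replicate-free tag-profiling design: two pooled
cDNA libraries (one per condition), each yielding millions of short
(~49 nt) tags that are counted per gene against an assembled unigene
reference. With a single library per condition there is no within-condition
variance estimate, so the test models only sampling noise: a gene's tag
count is Poisson because its tags are a small fraction of the library.

Given count x in library 1 (size N1 total tags) and the null hypothesis
that the gene's per-tag rate is equal in both libraries, the count y in
library 2 (size N2) has the posterior predictive

    p(y|x) = (N2/N1)^y (x+y)! / (x! y!) (1 + N2/N1)^-(x+y+1),

obtained by integrating Pois(x; λ)·Pois(y; λ·N2/N1) over a flat prior on
λ. Algebraically this is a negative binomial pmf with x+1 successes and
success probability N1/(N1+N2); the package derives it from the log-gamma
form and uses the negative-binomial identity only as an independent
cross-check in the tests. The two-sided p-value doubles the smaller tail
of S = Σ_{i≤y} p(i|x). The p-value depends on N1, N2 only through their
ratio (tested).

Because the model captures only Poisson sampling noise, p-values on real
biological replicates would be anti-conservative; that is a property of
the design, not of this implementation, and replicate-aware dispersion
modelling is deliberately out of scope.

## Significance calling

Benjamini–Hochberg step-up FDR (the only supported multiple-testing
procedure) is applied over all tested genes. A gene is called
differentially expressed when FDR ≤ 0.001 and |log2(empty RPKM / full
RPKM)| ≥ 1, both bounds inclusive. RPKM = 10⁹·C/(N·L) with C the
unambiguous (uniquely mapped) tag count, N the library denominator, and L
the gene length in bases. Both RPKMs are floored at 0.01 before the ratio
so genes absent from one library keep a finite fold change; the floor value
matches the smallest RPKM the design can print at 2-decimal precision.

Two denominators circulate for N in this design (total mapped reads vs
unique-only); the pipeline defaults to each library's total mapped reads
and exposes the choice (`n1`/`n2` in config and CLI). The exact test
consumes raw unambiguous counts, never RPKM; RPKM enters only the ratio.

## Quality filtering

Reads are dropped, in fixed order with first-match-wins bookkeeping, when
(1) a configured adaptor occurs as an exact substring (the adaptor list
defaults to empty, leaving the rule inert, because adaptor sequences are
assay-specific); (2) the N fraction is strictly greater than 5%; (3) the
fraction of bases with Phred quality ≤ 10 (inclusive) is strictly greater
than 20%. The strict/inclusive boundaries follow the rules' wording
exactly and are exercised at their boundary cases in the tests. Phred
encoding is configurable (offset 33 default, 64 supported). Q20 is the
percentage of clean-read bases with quality ≥ 20.

## Mapping

Tags are placed exhaustively on every offset of both strands of every
reference gene; a placement with Hamming distance ≤ 2 (substitutions only,
N always mismatching) is a hit. The implementation is a vectorised
sliding-window comparison whose semantics are defined to equal the
brute-force per-position scan (asserted against an independent Python
oracle in the tests). Reads are classified as perfect / ≤2-mismatch /
unique / multi-position / unmapped; a read hitting two offsets of the
*same* gene counts as multi-position and is excluded from unambiguous
counts (the conservative reading of "unambiguous"). Coordinates are
0-based half-open. Coverage is the union length of a gene's uniquely
mapped tag intervals over its length.

## qPCR quantification

ΔCt = mean(Ct_target) − mean(Ct_reference) per condition (replicate means,
per the standard formulation, not per-replicate pairing);
ΔΔCt = ΔCt(empty) − ΔCt(full); fold = 2^−ΔΔCt. The fold's sd is the
standard deviation of 2^−ΔΔCt over all per-replicate combinations of the
four Ct sets, a propagation rule chosen because the assay reports sd over
replicate experiments without prescribing one. Efficiency correction and
ANOVA-based significance are out of scope.

## Synthetic data

`simulate_counts` draws x ~ Pois(μ_g) and y ~ Pois(μ_g·2^lfc·N2/N1) with
baseline means μ_g log-uniform over [20, 200] (a realistic per-gene count
range at tag-profiling depth), 10% DE genes at |log2FC| = 3 split evenly
up/down, gene lengths uniform on [200, 3000] nt, and N1 = N2 = 10⁶ by
default. The simulated genes are a subset of a larger library, so gene
counts do not sum to N1/N2; N1/N2 act purely as the test and RPKM
denominators. An optional negative-binomial mode (variance μ + φμ²)
exists to probe robustness to extra-Poisson dispersion and is labelled an
extension. `simulate_fastq` plants mutually exclusive defect classes
(adaptor splice at the 3′ end, 10% N bases, 30% low-quality bases) built
to coincide exactly with the QC rules, plus 0–2 substitutions against the
source position, with per-read ground truth; read length defaults to
49 nt. `simulate_qpcr` encodes each true fold as a −log2(fold) shift of
the empty-condition target Ct with Gaussian replicate noise. All
generators are pure functions of (config, seed).

What passing synthetic tests do *not* show: real libraries have
overdispersion, non-uniform tag start positions, sequence-dependent
errors and mapping biases none of which the generators emulate, so
planted-truth recovery quantifies correctness of the computation, not
expected performance on real data.

## Numerical choices

- All factorials via `scipy.special.gammaln`; tail sums accumulate log
  terms by a recurrence and exponentiate once (stable for counts ≤ 10⁷).
- When S > 0.5 the p-value is computed as twice the directly-summed upper
  tail rather than 2(1−S): the complement form loses all precision once S
  is within ~1e−16 of 1, clamping strongly upregulated genes to p ≈ 0.
  The tail sum truncates when the geometric bound on the remainder falls
  below 1e−16 of the accumulated value.
- p-values are clamped to [0, 1] to guard round-off at S ≈ 0.5.
- The exact test is discrete, so the doubled two-sided p-value is
  conservative near p = 1 at small counts; the null p-value distribution
  is near-uniform (KS < 0.02 at 20,000 genes) only for baseline means
  ≳ 100. Type-I error at the 0.05 level is nominal already at means ≥ 20.
- Output formatting mirrors the design's reporting conventions: RPKM and
  log2 ratio to 2 decimals, p/FDR to 3 significant digits; full precision
  is kept internally.
- Degenerate inputs: empty read streams yield zero tallies and Q20 = 0 by
  convention; an empty count table runs to completion with zero calls;
  empty tags, empty references and out-of-bounds intervals raise input
  errors.

## Validation problem sizes

The suite checks the exact test against numerical quadrature of the
Poisson product on the full (x, y) ≤ 50 grid at depth ratios {0.5, 1, 2}
(1e−8), normalisation to 1e−10 for x ≤ 200, null calibration on 20,000
genes, planted-DE recovery on 1,000 genes (10% DE, |log2FC| = 3, mean
count 200), QC ground-truth tallies on 5,000 reads, and mapping
equivalence on a ~3 kb toy reference — sizes chosen so the whole suite
completes in a few minutes while each property is measured at scale
sufficient for its tolerance.

## Known limitations

- No adaptor trimming (whole-read removal only), no paired-end handling.
- The mapper is exhaustive and in-memory; it is meant for unigene-scale
  references, not genomes.
- Multi-position reads are discarded entirely rather than fractionally
  allocated.
- qPCR fold changes carry no significance test by design.
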