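# Methods

## Model and assumptions

OGM mapping is modeled as decoding a random code over a discrete
memoryless channel. The binned genome supplies the codebook: every
position offset, in both orientations, of a window of *n* per-bin pattern
counts is a candidate message, M = 2G/B messages in total (the factor 2
for the unknown strand orientation of an imaged fragment). The channel
acts independently per bin, taking the capped occurrence count *x* to the
capped detected-label count *y* with likelihood p(y|x). The error
probability of the maximum-likelihood decoder is evaluated with the
normal (second-order / finite-blocklength) approximation

    ε = Φ( (ln M − n I − ½ ln n) / √(n V) ),

where I and V are the mean and variance of
r(x, y) = ln[p(x, y)/(p(x) p(y))] under the joint distribution.

Assumptions inherited by everything downstream:

- statistical independence of bins (bin size large enough that label
  localization error does not couple neighbours);
- fragments are bin-aligned (start on a bin boundary), matching the
  model rather than the unknown bin phase of real measurements;
- no modeling of sub-bin label positions, fragment stretching, optical
  artifacts — all of that is absorbed empirically into p(y|x);
- candidate codewords treated as independent, although overlapping
  genome windows are not (each window is independent of almost all
  others, so the random-coding approximation is close for i.i.d.
  genomes).

## Parameters

| parameter | meaning | default | rationale |
|---|---|---|---|
| B | bin size, bp | 1000 | standard OGM binning scale; the built-in channel was estimated at 1 kb |
| cap | max per-bin count for x and y | 2 | length-6 patterns are sparse and close labels are optically unresolvable |
| k | pattern length, bp | 6 | the length of commercially labeled recognition sites; scans accept 1–12 |
| L | fragment length, bp | user-set | n = ⌊L/B⌋ bins per fragment |
| trials | Monte-Carlo fragments per configuration | 512 | gives a Wilson 95% CI of width ≲ 0.09 at worst |
| margin_bins | allowed placement error, bins | 0 | exact-position error definition; 1 relaxes it to one bin |

The built-in channel (`default_table1()`) is the published estimate for
`CTTAAG` on the human genome: p_x = (0.81555, 0.16278, 0.02168) and a
3×3 detection likelihood with p(0|0) = 0.95961, p(1|1) = 0.67492,
p(2|2) = 0.50913. The printed p_x column sums to 1.00001; it is
renormalized on construction (relative change ~1e-5) so that validated
invariants hold exactly.

## Numerical choices

- All logarithms are natural. ε is provably invariant to the base when
  it is applied consistently (the test suite checks base-2 agreement to
  1e-12), so this is presentation only.
- Cells with zero joint probability contribute nothing to I and V
  (0·log 0 = 0 convention); the stored r value there is 0 by convention.
- M uses whole-bin truncation (2·Σ bins). An `exact_offsets` switch
  computes 2·Σ max(0, bins − n + 1) instead; the difference enters ε
  only through ln M and is negligible whenever G ≫ L.
- When the Φ argument is far in the lower tail, ε underflows to 0; the
  natural-log tail is always reported alongside (`log_epsilon`, via the
  normal log-CDF), so extreme predictions remain comparable.
- Degenerate channels (I numerically 0, e.g. a pattern absent from the
  genome) are flagged and reported at the chance limit ε = 1 rather than
  evaluating an undefined formula.
- Decoder ties: two placements whose log-likelihood scores differ by
  less than 1e-9 are treated as tied and resolved deterministically —
  first record in input order, forward before reverse, smallest start
  bin. Exact float equality is not a usable tie definition because
  mathematically equal scores summed in different orders differ by an
  ulp. The batched decoder computes scores with an exact sliding-window
  matrix product (keeping equal-content windows bit-identical) and
  switches to FFT cross-correlation only for very large problems.
- The decoder refuses zero likelihood cells unless an explicit floor
  (1e-12) is enabled; the floor exists for channels estimated from
  sparse data, not for the built-in table.
- Occurrences are assigned to bins by their 0-based start coordinate;
  trailing partial bins are dropped (≤ B − 1 bp lost per record). The
  convention is a package choice — center- or label-site assignment
  would shift counts by at most one bin.
- Reverse orientation is realized by reversing bin-count vectors, not by
  re-scanning reverse-complemented sequence; pattern sets are closed
  under reverse complement, so the two differ only by sub-bin boundary
  effects.
- Unobserved likelihood rows in estimation are an error (strict mode) or
  NaN with a warning — never silently imputed, because imputation would
  corrupt I and V invisibly. An optional pseudocount (default 0) exists
  for downstream decoding safety.
- The Wilson score interval is used for simulated rates; its bounds are
  snapped to exactly 0/1 at empirical rates of 0%/100%, where the
  analytic bound is exact.

## Synthetic data

Random genomes are i.i.d. uniform over {A, C, G, T}, seeded and
reproducible, up to 1e8 bp. They emulate the null model under which a
length-6 pattern union has per-position density 2·4⁻⁶ (4⁻⁶ for
palindromes) and per-bin counts are approximately capped-Poisson. They do
**not** emulate repeats, centromeric/telomeric anomalies, unplaced
contigs, or inter-species similarity — precisely the features that make
real genomes deviate from the model at long fragment lengths. Passing
tests on random genomes therefore validate the information-theoretic
machinery, not the claim that any real genome is homogeneous.

Simulated label counts are drawn per bin from p(y|x); a single integer
seed determines the full experiment, with trial *t* using the stream
seeded by (seed, t).

## Problem sizes and observed calibration

The shipped tests and the acceptance script run on 10-Mb random genomes
(10⁴ bins, M = 2·10⁴) with 512 fragments per length over an 8-point grid
(20–75 kb) chosen so that predicted ε spans ~0.01–0.9; a full 10⁸-bp run
reproduces the same comparison at scale and is left to the user. At the
10-Mb scale the closed-form prediction tracks the simulated rate closely
but sits a few percentage points above it at the shortest lengths
(e.g. theory 0.80 vs simulated 0.70–0.73 at 20 kb): the normal
approximation ignores the positive skew of r, and the discrepancy shrinks
with n and with ln M. Wilson-interval coverage of the prediction over the
grid is accordingly seed-dependent (typically 5–7 of 8 lengths).

## Known limitations

- The model predicts ML-decoder accuracy from bin counts only;
  algorithms using exact label positions within bins can do better, so ε
  is best read as an upper bound on achievable error for real aligners
  on non-anomalous regions.
- Pattern ranking holds p(y|x) fixed across patterns; labeling
  chemistries with different error profiles would need their own
  estimate.
- Multi-pattern (multi-color) designs are expressible as unions of
  pattern sets but no combinatorial optimization over combinations is
  provided.
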