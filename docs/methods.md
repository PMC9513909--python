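# Methods

## The model

The statistical object at the core of the package is a census-versus-null
comparison for degenerate nucleotide motifs.  A motif is an IUPAC string
compiled to per-position allowed-base sets; an occurrence is any sequence
window (overlaps included) whose bases all fall in the corresponding sets.
Two references are available for an observed occurrence count *k* in a
region of *n* nucleotides:

* **Composition null.**  Bases are assumed independent and identically
  distributed with symmetric frequencies derived from the regional GC
  fraction *g*: *f*(G) = *f*(C) = *g*/2, *f*(A) = *f*(T) = (1 − *g*)/2.  The
  motif's expected per-nucleotide frequency is the product over positions of
  the summed allowed-base frequencies (an N position contributes a factor of
  exactly 1, so NGACTTTN and GACTTT have identical expected frequencies).
  An `empirical` parameterisation using the four observed base proportions
  is also available; `symmetric` is the default because motif occurrence is
  counted on both strands by default and the null should be
  strand-agnostic.
* **External reference frequency.**  Typically the same motif's genome-wide
  observed frequency; the region count is tested directly against it.

Both comparisons use the exact one-sided upper tail
P(X ≥ k), X ~ Binomial(n, p).  The tail is enrichment-only by design: the
scientific claims the package supports are of the form "more often than
expected", and depletion is deliberately not flagged (a lower-tail helper
exists for the complementarity identity).  No multiple-testing correction is
applied across motifs by default, matching the practice the census analysis
follows for the 16-member WT-box family; the per-motif p-values are reported
in full so any correction can be applied downstream.

### Numerical notes

* The upper tail is computed through the regularised incomplete-beta
  identity (scipy's `binom.sf`), accurate to ~1e-14 relative error for n up
  to at least 1e8 (verified against a 50-digit PMF-recurrence oracle in the
  test suite).
* P-values below ~1e-300 underflow doubles; `binomial_upper_logpvalue`
  returns the natural-log tail, switching to a log-space PMF summation with
  a geometric-series truncation bound in that regime.  Reports carry both
  columns.
* The binomial test is discrete: its attained size (the largest achievable
  rejection probability not exceeding α) is strictly below the nominal level
  when the null mean is small.  The calibration test asserts exactly this
  behaviour — never anticonservative against nominal α, consistent with the
  attained size — rather than pretending the test is continuous.

### Conventions with more than one defensible choice

* **Denominator.**  Frequencies use total region nucleotides (N excluded) as
  the denominator, not the number of valid window start positions
  Σ max(L−k+1, 0).  The total-nucleotide convention is the one under which
  the shipped census frequencies were derived; `valid_start_positions`
  exposes the alternative, and report headers record which was used.  For
  L = 500 windows and k = 8 the two differ by 1.4%.
* **Printed precision.**  `CompositionProfile.from_gc_fraction(gc,
  round_digits=4)` rounds the per-base frequencies before use (0.3262 →
  0.3369/0.1631).  This reproduces analyses carried out with
  fixed-precision frequencies to the printed digit; the default is full
  precision.
* **Strand policy.**  Explicit everywhere, default `both` (occurrences of
  the reverse-complement pattern on the forward string, reported in forward
  coordinates).  A palindromic pattern counts twice per site under `both`;
  this is documented rather than silently collapsed, since the WT-box and
  W-box are not palindromic.  Whether the shipped census was produced
  forward-only or both-strand is not recorded with it, which is why scanning
  runs always record their policy in output headers and the per-gene
  analyses are runnable under either policy.
* **Subject N.**  An unknown or ambiguity-collapsed base never matches any
  pattern position, including pattern N: an unverifiable base is never
  claimed as a hit.  N is likewise excluded from composition counts and the
  nucleotide denominator.
* **Upstream windows.**  1-based inclusive coordinates; the window is the
  `window` nucleotides strictly 5′ of the TSS (TSS excluded), interval
  [tss−window, tss−1] for plus-strand genes and the reverse complement of
  [tss+1, tss+window] for minus-strand genes, clipped at contig ends.
  Overlapping neighbouring genes are not masked out of each other's
  windows.  Gene identifiers are compared case-insensitively.

## The synthetic-data generator

`simulate` draws backgrounds iid at a chosen GC fraction — exactly the
process the composition null assumes — so null simulations are null by
construction and calibration claims are about the statistics, not about an
accidental match between generator and model.  Defaults mirror the study
system: GC 0.3262, 500-nt windows subtending each TSS, organellar contigs
labelled for subtraction.  Motif copies are planted at uniform
non-overlapping positions over the background; ground truth is the planted
position list.  Planted copies can still gain incidental flanking matches
from background bases, so exact-count assertions use motifs with no
prefix/suffix self-overlap (`is_non_self_overlapping`); for arbitrary motifs
ground truth is "at least the planted positions".

What the generator does **not** emulate: repeats, isochores and
dinucleotide (Markov) structure, alternative TSSs, or overlapping gene
models.  Passing tests therefore demonstrate correctness of the counting
and testing machinery under the model's own assumptions, not that real
promoters lack compositional structure the independent-base null ignores —
on real data the null is knowingly simple, and the genome-wide reference
comparison exists precisely to absorb genome-scale composition effects.

A single seeded `numpy` Generator drives each run, consumed in documented
order (background sequences first, then per-sequence planting), so a seed
pins every output byte.

## Problem sizes in the shipped checks

The test suite calibrates the enrichment test over 2000 null runs of 1e5 nt
each (non-self-overlapping AT-rich 8-mer AAATTTTT, null mean ≈ 16.6 per
run) and measures detection power over 200 runs with planting at 3× the
composition-expected frequency against both references (observed power
1.00); matcher/oracle equivalence runs 1e4 random sequences.  These sizes
give sub-minute wall times while keeping every binomial band tight enough
to be informative.

## Known limitations

* No mismatch tolerance, PWM scoring, or Markov background models.
* The census constants in `wtbox.published` are inputs transcribed from the
  published distribution table; the genome-wide frequencies there imply a
  ~135.7 Mb denominator that matches neither one nor two strands of the
  nuclear genome assembly, so the module never hard-codes a genome size and
  all region sizes are explicit parameters.
* Venn output is numeric (region counts and member lists); plotting is left
  to external tools.
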