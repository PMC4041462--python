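# Methods

## The annotation model

A junction read is modelled as

```
left germline flank (minus del_left) · P_left · N · P_right · right germline flank (minus del_right)
```

with an optional microhomology overlap counted once.  Annotation inverts
this model by greedy maximal matching: `left_retained` is the longest
prefix of the read equal to a prefix of the left coding flank (the flank is
stored with its junction-proximal end last), `right_retained` the symmetric
suffix match.  `N` bases never match.  Greedy maximal matching is exactly
the minimal-edit decomposition: extending a flank match by one base removes
one deletion and one insertion from the edit count, so the maximal matches
minimise `deletions + insertions`; the test suite verifies this against an
exhaustive search over all decompositions on short windows.

When the two maximal matches overlap, the shared bases are assignable to
either end.  Overlaps of at least `microhomology_min` (default 2 nt, the
conventional reporting cutoff) are reported as microhomology; smaller
overlaps are deliberately invisible and folded into the left retained
stretch.  All ambiguity is therefore resolved toward the left end — a
deterministic tie-break mirrored by the brute-force oracle.

**P nucleotides** are called only on ends with zero deletion, since
hairpin-derived palindromes require an unresected coding end.  The call is
the longest contiguous extension of the middle bases equal to the reverse
complement of the flank's terminal bases, up to `max_p_length` (default
4 nt; longer templated palindromes are not credible P products).  P takes
precedence over N: a base assignable to either class counts as P.  This
matters downstream because the ADR null excludes P-compatible insertions.

**Frame** is classified from optional per-segment frame anchors: the joint
is in frame iff the net length change relative to the blunt reference
configuration, plus the anchor offset, is 0 mod 3; a missing anchor yields
`unknown`.

**Signal joints** are aligned against the two full RSSs fused heptamer to
heptamer; the left RSS appears reverse-complemented, so a blunt fusion of
consensus heptamers reads `...CACTGTG|CACAGTG...` and necessarily contains
the ApaL1 site `GTGCAC` across the fusion point.  `precise` requires both
heptamers intact and no inserted bases; the ApaL1 site is searched within
±6 nt of the inferred fusion point, tolerating small insertions that
coincidentally restore a site (so `precise ⇒ ApaL1`, but not conversely).
**Miscleavage** — cleavage displaced into the coding segment — is flagged
when at least `miscleavage_min_match` (default 2) inserted bases adjacent
to a signal end copy the germline coding bases abutting that RSS (reverse
complemented on the inverted left side).

Annotation treats sequences as exact (Sanger-grade); there is no model of
sequencing error or somatic hypermutation, and reads are assumed trimmed to
the germline window.

## Adjacent direct repeats

An ADR is a tandem pair of identical 3–5-mers, immediately adjacent and in
direct orientation, straddling the junction so that one copy lies (wholly
or partly) in inserted sequence while the other is germline-templated.
Detection enumerates all such pairs, reports only the maximal k per window
(a 4-mer is not re-reported as its internal 3-mers), and flags as
`borderline` pairs in which both copies touch inserted bases — the clean
calls require one fully templated copy.

Chance correction: per locus, the per-base insertion probabilities are the
pooled frequencies of N-classified inserted bases (P-compatible bases
excluded, because templated palindromes are not draws from the N-addition
process), and the expected number of junctions carrying repeat `b1..bk` is
`∏ P(bi) × N` with `N` the total junction count at the locus.  A repeat is
significant when the expectation is strictly below 0.5: an expectation of 1
already means one chance occurrence is likely, so the cutoff is set
stringently at half that.  No multiple-testing correction is applied across
loci — the expected-count rule is itself the filter.  When a cohort has no
usable insertions the null falls back to uniform with a logged warning.

## Cryptic RSS scoring

A candidate site is scored as the count of positionwise identities of its 7
heptamer and 9 nonamer positions against the consensus (`CACAGTG`,
`ACAAAAACC` — configurable; these canonical strings are the package
default).  Spacer positions are never scored and the spacer length is exact
(12 or 23) unless a tolerance is configured, since the score has no
spacer-length term.  Site scores are 0–16; a breakpoint is classified by
the best 12/23 pair (sum 0–32) with heptamers oriented toward the
breakpoint, reflecting cleavage geometry: on a context whose breakpoint is
at its right end only reverse-strand sites qualify.  Ties between
equal-scoring sites break by heptamer distance to the breakpoint, then
forward strand, then lowest coordinate.  The positivity threshold of 19 is
anchored on the match count of the well-characterised Notch1 cryptic RSS
pair.  This is deliberately a match-count score, not an information-content
(RIC-style) model.

## Cohort summaries and tests

Signal-joint tables report N addition, deletion, miscleavage and
microhomology out of imprecise junctions; deletions longer than the 5-bp
cutoff out of deleted ends (5 bp being the longest deletion observed in
wild-type joints); pooled rows sum raw counts across loci before computing
percentages, so every percentage recomputes from its printed
numerator/denominator.  N prevalence is additionally reported over all
junctions, since both denominators are used in practice.  Coding-joint
tables report per-region (V-side/J-side) deleted fractions out of all
events, with mean length and the >4-bp fraction out of deleted events only
(4 bp being the wild-type average deletion).

Group comparisons use the Pearson chi-squared test of independence
*without* continuity correction; on sparse 2×2 tables (e.g. 4/5 vs 0/4
translocation-positive animals) the corrected and uncorrected tests
straddle the 0.02 significance bound, and the uncorrected form is the one
consistent with the reported analyses this package mirrors.  The t-test is
the classic pooled-variance unpaired two-tailed test; Welch is available
behind a flag.  Percentages are reported to one decimal.

## The simulator

The generator draws, per coding end: resection with probability
`p_deletion_per_end` and geometric length (memoryless nibbling; mean 4 nt
by default, matching the wild-type average), otherwise an optional P
palindrome (1–2 nt by default); then Poisson-length N bases from a
configurable composition.  With probability `p_microhomology_join` the join
is instead forced at an existing sequence overlap of 2–5 nt between the
ends (searched over small deletions of both flanks; if no overlap exists
the generator falls back to a plain join and flags the truth record).  With
probability `p_adr_mechanism` the junction is built by the
strand-displacement mechanism: the left end's terminal 3–5-mer is
duplicated as inserted sequence, guaranteeing the tandem-repeat signature
with one templated copy.  Signal joints are precise blunt fusions with
probability `1 − sj_imprecision_prob`; imprecise joints draw RSS deletions,
N insertions and (optionally) miscleavage, rejection-sampling until at
least one deviation is present.

Geometric deletion and Poisson N lengths are the simplest defensible
choices; no distributional form is claimed by the data the package mirrors,
and both are configurable.  The bundled `table1`-style preset pairs a
wild-type-like regime (21% imprecise, short deletions) with a
truncation-mutant-like regime (45% imprecise, mean 6-nt deletions, 20%
miscleavage), sized at 160 and 140 junctions — the scale of real
signal-joint cohorts.

What the simulator does **not** emulate: chromosomal context and
translocation partner choice, selection during lymphocyte development,
sequencing error, and locus-specific base composition.  Passing round-trip
tests therefore demonstrate internal consistency of annotation and
simulation under the stated generative model, not accuracy on real reads
whose flanks may be more repetitive or whose insertions longer.

## Numerical and design choices

* Coordinates are 0-based half-open internally, 1-based inclusive in
  human-readable reports.
* `N` bases are permitted in reads but never count as matches anywhere
  (flank matching, P extension, ADR copies, cRSS positions).
* A read matching neither flank at ≥1 nt is an annotation error rather
  than an all-deleted decomposition.
* Truth-recovery tests use engineered flanks (junction-proximal A-run vs
  C-run, insertions restricted to G/T) so that no inserted base can extend
  a flank match; under ambiguous flanks only the weaker reconstruction
  invariant holds, which is the honest limit of any junction annotator.
* Test problem sizes: 10,000 simulated junctions for the reconstruction
  sweep, 1,000 for parameter recovery, 2 kb for scan-oracle equivalence —
  large enough for tight Monte-Carlo bounds while keeping the default
  suite fast.

## Known limitations

* The greedy decomposition reports one of possibly several minimal-edit
  parses; bases are never probabilistically apportioned between flanks.
* Coding-end annotation assumes reads trimmed to the germline window; no
  local realignment is attempted.
* The ADR "germline copy" rule requires one fully templated copy for a
  clean call; repeats in which both copies mix inserted and templated bases
  are only flagged borderline, and their prevalence is unknown.
* The cRSS score ignores spacer sequence entirely; sites with degenerate
  heptamer/nonamer but RSS-like spacers score low.
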