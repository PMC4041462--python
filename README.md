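# vdjoin

Annotation, simulation and cohort statistics for V(D)J recombination
junctions.

During lymphocyte development the RAG recombinase cuts between antigen
receptor gene segments and their recombination signal sequences (RSS: a
conserved heptamer and nonamer separated by a 12- or 23-nt spacer), leaving
two hairpin coding ends and two blunt signal ends that the cell's
end-joining machinery must reseal.  The fine structure of the resulting
junctions — nucleotides deleted from each end, templated palindromic (P)
additions, nontemplated (N) additions, junctional microhomology, and
whether a signal joint is a precise heptamer-to-heptamer fusion — is the
standard read-out for which DNA repair pathway handled the break.  `vdjoin`
is for researchers who sequence such junctions (or breakpoints of aberrant,
RAG-mediated genome rearrangements) and need the bookkeeping done
reproducibly:

* **Junction annotation** — greedy maximal decomposition of each read into
  retained germline, per-end deletions, P/N nucleotides and microhomology
  for coding joints; precision, RSS deletions, insertions, miscleavage and
  an in-silico ApaL1 check (precise signal joints regenerate `GTGCAC`) for
  signal joints.
* **Adjacent Direct Repeats (ADRs)** — detection of tandem 3–5-nt repeats
  with one inserted and one germline-templated copy, plus a
  chance-correction null: the expected number of junctions carrying a
  repeat `b1..bk` at a locus with `N` junctions is
  `P(b1)·…·P(bk)·N`, with per-base insertion probabilities estimated from
  N-classified insertions (P-compatible insertions excluded); a repeat is
  significant when this expectation is `< 0.5`.
* **Cryptic RSS scanning** — positionwise match counting of heptamer (7)
  and nonamer (9) against the consensus (`CACAGTG` / `ACAAAAACC`), both
  strands, both spacer classes; breakpoints are classified by the best
  12/23 pair, positive at a summed score of ≥ 19.
* **Cohort statistics** — signal-joint and coding-joint summary tables with
  the field's denominator conventions (features out of imprecise junctions,
  long deletions out of deleted ends, per-region coding deletions out of
  all vs. deleted events), Pearson chi-squared tests of independence
  (no continuity correction) and unpaired two-tailed t-tests.
* **Synthetic cohorts** — a seeded junction simulator emitting FASTA plus
  ground-truth TSV under configurable classical/alternative-NHEJ-like
  regimes, including the strand-displacement mechanism that creates ADRs.

## Worked example

```python
from vdjoin import (GeneSegmentRef, JunctionRead, LocusReference, RssSpec,
                    annotate_coding_joint, detect_adrs, estimate_null, score_adr)

rss23 = RssSpec("CACAGTG", "GCTAGCTAGCTAGCTAGCTAGCT", "ACAAAAACC")
rss12 = RssSpec("CACAGTG", "ATCGATCGATCG", "ACAAAAACC")
locus = LocusReference(
    "Vtest-Jtest",
    GeneSegmentRef("V", "GGTTAACCTGGTAGGCT", rss23, "upstream_of_junction"),
    GeneSegmentRef("J", "TGGACAGGGTTCATTAA", rss12, "downstream_of_junction"),
    "coding",
)
read = JunctionRead("r1", "GGTTAACCTGGTAGGCT" + "GCT" + "TGGACAGGGTTCATTAA", locus)
ann = annotate_coding_joint(read)
print(ann.del_left, ann.del_right, ann.n_insertion)   # -> 0 0 GCT
call = detect_adrs(ann, locus)[0]
print(call.repeat_seq, call.inserted_copy)            # -> GCT 2
null = estimate_null([ann], locus)                    # single-junction toy null
print(round(score_adr(call, null).expected_count, 3)) # -> 0.037
```

The junction carries a 3-nt insertion `GCT` that duplicates the germline
`...AGGCT` terminus: an adjacent direct repeat whose second copy is the
inserted one.  Against a null with `N = 22` junctions and uniform base
probabilities the expectation would be `0.25**3 * 22 = 0.34375 < 0.5`,
i.e. significant — the repeat is unlikely to be a chance product of random
N addition.

From the shell, the same pipeline is available as subcommands:

```bash
vdjoin simulate --reference ref.tsv --outdir cohort --preset table1 --seed 1
vdjoin annotate --reads cohort/cohort.fasta --reference ref.tsv \
    --locus mylocus --out ann.tsv
vdjoin summarize --annotations ann.tsv --out-prefix summary
vdjoin adr --annotations ann.tsv --reference ref.tsv --locus mylocus --out adr.tsv
vdjoin crss-scan --fasta genome.fasta --out hits.bed
```

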