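"""Bundled example cohort: published-style mouse TCRb/TCRd signal-joint counts.

The example reproduces the count structure of a two-genotype signal-joint
sequencing cohort (wild-type versus a RAG2 C-terminal truncation) across
four rearranging loci.  Counts are expanded into a per-junction table so the
cohort summaries can be recomputed from scratch rather than copied: each
junction row carries precision, per-end deletion lengths, insertion,
miscleavage and microhomology, and the summary layer re-derives every
percentage from these rows.

Per-locus record fields:
  total           junctions sequenced
  imprecise       junctions deviating from the precise blunt fusion
  n_addition      imprecise junctions with inserted nucleotides
  deleted         imprecise junctions with >=1 deleted signal end
  deleted_ends    deleted ends (a junction may lose bases from both RSSs)
  long_ends       deleted ends with more than 5 nt lost
  miscleavage     imprecise junctions carrying coding-end sequence
  microhomology   imprecise junctions with >=2 bp junctional microhomology
"""

from __future__ import annotations

import pandas as pd

#: (genotype, locus) -> counts; loci are V-D signal joints.
SIGNAL_JOINT_COUNTS: dict[tuple[str, str], dict[str, int]] = {
    ("WT", "Vb14-Db1"): dict(total=79, imprecise=11, n_addition=10, deleted=0,
                             deleted_ends=0, long_ends=0, miscleavage=1, microhomology=0),
    ("WT", "Vd5-Dd2"): dict(total=28, imprecise=9, n_addition=9, deleted=3,
                            deleted_ends=3, long_ends=0, miscleavage=0, microhomology=0),
    ("WT", "Vb8.3-Db1.1"): dict(total=27, imprecise=8, n_addition=8, deleted=3,
                                deleted_ends=3, long_ends=0, miscleavage=0, microhomology=0),
    ("WT", "Vb10-Db1.1"): dict(total=25, imprecise=6, n_addition=6, deleted=0,
                               deleted_ends=0, long_ends=0, miscleavage=0, microhomology=0),
    ("FS", "Vb14-Db1"): dict(total=70, imprecise=23, n_addition=16, deleted=9,
                             deleted_ends=14, long_ends=10, miscleavage=3, microhomology=2),
    ("FS", "Vd5-Dd2"): dict(total=26, imprecise=20, n_addition=14, deleted=17,
                            deleted_ends=30, long_ends=16, miscleavage=4, microhomology=2),
    ("FS", "Vb8.3-Db1.1"): dict(total=28, imprecise=13, n_addition=13, deleted=4,
                                deleted_ends=4, long_ends=4, miscleavage=5, microhomology=0),
    ("FS", "Vb10-Db1.1"): dict(total=16, imprecise=7, n_addition=6, deleted=2,
                               deleted_ends=2, long_ends=0, miscleavage=2, microhomology=1),
}

#: Translocation-positive mice per genotype: (positive, negative).
TRANSLOCATION_COUNTS: dict[str, tuple[int, int]] = {"FS": (4, 1), "WT": (0, 4)}


def expand_signal_counts(counts: dict[str, int]) -> list[dict]:
    """Per-junction rows realising one locus' count record.

    Features are assigned to the leading imprecise junctions so that every
    marginal count is met; feature co-occurrence is otherwise arbitrary and
    does not affect the marginal summaries.
    """
    n_both_ends = counts["deleted_ends"] - counts["deleted"]
    if not 0 <= n_both_ends <= counts["deleted"]:
        raise ValueError("deleted_ends must lie in [deleted, 2*deleted]")
    long_left = counts["long_ends"]
    rows: list[dict] = []
    for i in range(counts["total"]):
        if i >= counts["imprecise"]:
            rows.append(dict(precise=True, del_left=0, del_right=0, insertion="",
                             miscleavage=False, microhomology_len=0))
            continue
        row = dict(precise=False, del_left=0, del_right=0, insertion="",
                   miscleavage=False, microhomology_len=0)
        if i < counts["n_addition"]:
            row["insertion"] = "GG"
        if i < counts["deleted"]:
            ends = 2 if i < n_both_ends else 1
            for end in ("del_left", "del_right")[:ends]:
                row[end] = 6 if long_left > 0 else 2
                long_left -= 1 if long_left > 0 else 0
        if i < counts["miscleavage"]:
            row["miscleavage"] = True
        if i < counts["microhomology"]:
            row["microhomology_len"] = 2
        rows.append(row)
    if long_left:
        raise ValueError("long_ends exceeds deleted_ends")
    return rows


def example_signal_cohort() -> pd.DataFrame:
    """The bundled example cohort as a tidy per-junction DataFrame."""
    rows = []
    for (genotype, locus), counts in SIGNAL_JOINT_COUNTS.items():
        for i, row in enumerate(expand_signal_counts(counts)):
            rows.append({"read_id": f"{genotype}_{locus}_{i:03d}", "locus": locus,
                         "genotype": genotype, **row})
    return pd.DataFrame(rows)
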