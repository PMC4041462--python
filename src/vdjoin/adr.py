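"""Adjacent Direct Repeats: detection and chance-corrected significance.

An ADR is a tandem pair of identical 3-5 nt sequences sitting immediately
next to each other in direct orientation at a junction, with one copy
templated by germline and the other produced during end processing
(annealing of complementary P/N extensions followed by strand-displacement
fill-in).  Because short tandem repeats also arise by chance from random N
addition, each detected ADR is scored against a per-locus null: the expected
number of junctions carrying that repeat by chance is the product of the
inserted copy's per-base insertion probabilities times the number of
junctions at the locus.  An ADR is significant when that expectation falls
below 0.5 (a deliberately stringent cutoff: an expectation of 1 already
means one chance occurrence is likely).

Insertion probabilities are estimated from N-classified inserted bases only;
insertions explainable as P nucleotides are excluded so that templated
palindromic additions do not inflate the null.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Sequence

from .annotate import CodingJointAnnotation, SignalJointAnnotation
from .locus import LocusReference

logger = logging.getLogger(__name__)

ADR_MIN_K = 3
ADR_MAX_K = 5
SIGNIFICANCE_CUTOFF = 0.5


@dataclass(frozen=True)
class AdrNullModel:
    """Per-locus insertion-composition null for ADR significance.

    base_probs: insertion probability of each base, from pooled N-classified
    inserted bases at the locus (P-compatible insertions omitted).
    n_junctions: total junctions sequenced at the locus (all junctions, not
    only those with insertions).
    """

    locus_name: str
    base_probs: dict[str, float]
    n_junctions: int

    def __post_init__(self) -> None:
        if self.n_junctions < 1:
            raise ValueError("n_junctions must be >= 1")
        total = sum(self.base_probs.values())
        if abs(total - 1.0) > 1e-9 or min(self.base_probs.values()) < 0:
            raise ValueError(f"base_probs must be a distribution, sum={total}")


@dataclass
class AdrCall:
    """One detected adjacent direct repeat (unscored until score_adr)."""

    read_id: str
    repeat_seq: str
    copy1_span: tuple[int, int]  # 0-based half-open, copy2 starts where copy1 ends
    copy2_span: tuple[int, int]
    inserted_copy: int  # 1 or 2: which copy lies in inserted sequence
    borderline: bool = False  # both copies touch inserted bases
    expected_count: float | None = None
    significant: bool | None = None

    def __post_init__(self) -> None:
        k = len(self.repeat_seq)
        if not ADR_MIN_K <= k <= ADR_MAX_K:
            raise ValueError(f"ADR length must be {ADR_MIN_K}-{ADR_MAX_K}, got {k}")
        if self.copy2_span[0] != self.copy1_span[1]:
            raise ValueError("ADR copies must be immediately adjacent")


def estimate_null(
    annotations: Sequence[CodingJointAnnotation],
    locus: LocusReference,
) -> AdrNullModel:
    """Estimate the per-locus insertion null from annotated junctions.

    Pools the N-classified inserted bases of every junction at the locus
    (P nucleotides already excluded by annotation).  Falls back to a uniform
    distribution, with a warning, when no usable inserted bases exist.
    """
    if not annotations:
        raise ValueError(f"{locus.locus_name}: cannot estimate a null from an empty cohort")
    counts: Counter[str] = Counter()
    for ann in annotations:
        counts.update(b for b in ann.n_insertion if b in "ACGT")
    total = sum(counts.values())
    if total == 0:
        logger.warning(
            "%s: no N-classified insertions after P exclusion; uniform null used",
            locus.locus_name,
        )
        probs = {b: 0.25 for b in "ACGT"}
    else:
        probs = {b: counts[b] / total for b in "ACGT"}
    return AdrNullModel(locus_name=locus.locus_name, base_probs=probs, n_junctions=len(annotations))


def _inserted_overlap(span: tuple[int, int], ins: tuple[int, int]) -> int:
    return max(0, min(span[1], ins[1]) - max(span[0], ins[0]))


def detect_adrs(
    annotation: CodingJointAnnotation,
    locus: LocusReference | None = None,
    read_sequence: str | None = None,
) -> list[AdrCall]:
    """Find candidate ADRs in one annotated junction.

    Scans for every tandem pair of identical k-mers (k = 5 down to 3,
    immediately adjacent, direct orientation) where exactly one copy overlaps
    the inserted (P/N) bases and the other is wholly germline-templated.
    Pairs where both copies touch inserted bases but one still carries
    templated bases are returned flagged ``borderline``.  Only the maximal k
    is reported per site: a 4-mer ADR is not re-reported as its internal
    3-mers.

    ``read_sequence`` is reconstructed from the annotation when not given.
    """
    ins_start, ins_end = annotation.inserted_span()
    if ins_end == ins_start:
        return []
    if read_sequence is None:
        read_sequence = _reconstruct(annotation, locus)
    return _scan_window(read_sequence, (ins_start, ins_end), annotation.read_id)


def _scan_window(seq: str, ins: tuple[int, int], read_id: str) -> list[AdrCall]:
    calls: list[AdrCall] = []
    covered: list[tuple[int, int]] = []
    for k in range(ADR_MAX_K, ADR_MIN_K - 1, -1):
        for i in range(0, len(seq) - 2 * k + 1):
            c1 = (i, i + k)
            c2 = (i + k, i + 2 * k)
            if seq[c1[0] : c1[1]] != seq[c2[0] : c2[1]]:
                continue
            if "N" in seq[c1[0] : c2[1]]:
                continue
            # suppress sub-repeats of an already reported larger ADR
            if any(c1[0] >= s and c2[1] <= e for s, e in covered):
                continue
            o1 = _inserted_overlap(c1, ins)
            o2 = _inserted_overlap(c2, ins)
            if o1 == 0 and o2 == 0:
                continue  # fully germline tandem repeat, not an ADR
            if o1 == k and o2 == k:
                continue  # both copies fully inserted: no templated copy
            if (o1 > 0) != (o2 > 0):
                inserted_copy = 1 if o1 > 0 else 2
                borderline = False
            else:
                # both copies touch inserted bases; at least one is partly templated
                inserted_copy = 1 if o1 >= o2 else 2
                borderline = True
            calls.append(
                AdrCall(
                    read_id=read_id,
                    repeat_seq=seq[c1[0] : c1[1]],
                    copy1_span=c1,
                    copy2_span=c2,
                    inserted_copy=inserted_copy,
                    borderline=borderline,
                )
            )
            covered.append((c1[0], c2[1]))
    calls.sort(key=lambda c: (c.copy1_span[0], -len(c.repeat_seq)))
    return calls


def detect_adrs_in_signal(
    annotation: SignalJointAnnotation,
    read_sequence: str,
) -> list[AdrCall]:
    """Same tandem-repeat scan applied to a signal-joint insertion.

    Signal-joint ADRs are reported separately from coding-joint ones and are
    not entered into the coding-joint null model.
    """
    if not annotation.insertion:
        return []
    ins = (annotation.left_retained, annotation.left_retained + len(annotation.insertion))
    return _scan_window(read_sequence, ins, annotation.read_id)


def _reconstruct(annotation: CodingJointAnnotation, locus: LocusReference | None) -> str:
    if locus is None:
        raise ValueError("detect_adrs needs either read_sequence or the locus reference")
    L = locus.left_segment.coding_flank
    R = locus.right_segment.coding_flank
    left = L[: annotation.left_retained]
    right = R[len(R) - annotation.right_retained :]
    if annotation.microhomology_len:
        right = right[annotation.microhomology_len :]
    return left + annotation.insertion + right


def score_adr(call: AdrCall, null: AdrNullModel) -> AdrCall:
    """Attach the chance-expected junction count and the significance flag.

    expected_count = prod(base_probs[b] for b in inserted copy) * n_junctions;
    the call is significant when expected_count < 0.5 (strict).  A base with
    zero estimated insertion probability makes the expectation 0 (significant).
    """
    p = 1.0
    for b in call.repeat_seq:
        p *= null.base_probs.get(b, 0.0)
    expected = p * null.n_junctions
    return replace(call, expected_count=expected, significant=expected < SIGNIFICANCE_CUTOFF)


def analyze_cohort(
    annotations: Sequence[CodingJointAnnotation],
    locus: LocusReference,
) -> tuple[AdrNullModel, list[AdrCall]]:
    """Full per-locus ADR analysis: estimate the null, detect, score.

    Scored calls are also attached to each annotation's ``adrs`` field.
    """
    null = estimate_null(annotations, locus)
    all_calls: list[AdrCall] = []
    for ann in annotations:
        scored = [score_adr(c, null) for c in detect_adrs(ann, locus)]
        ann.adrs = scored
        all_calls.extend(scored)
    return null, all_calls
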