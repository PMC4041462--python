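"""Cryptic RSS scanning and 12/23 pair scoring.

Genomic sequence fortuitously resembling a recombination signal sequence (a
cryptic RSS, cRSS) can be recognised by the RAG recombinase and mediate
aberrant rearrangements.  A candidate site is scored as the count of
positionwise matches of its 7 heptamer and 9 nonamer positions to the
consensus (spacer positions are never scored), giving 0-16 per site.  To
respect the 12/23 rule, candidate breakpoints are evaluated as a pair of one
12-spacer and one 23-spacer site; the pair score is the sum of the two site
scores (0-32) and a pair is called positive at 19 or more matches — the
score of the well-characterised Notch1 cRSS pair.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .locus import ConsensusRss, revcomp

HEPTAMER_LEN = 7
NONAMER_LEN = 9


@dataclass(frozen=True)
class CrssConfig:
    """pair_threshold: minimum 12+23 pair score called positive.
    spacer_tolerance: +/- nt allowed around the canonical spacer lengths.
    report_floor: minimum site score reported by scans (weaker sites are
    still considered when forming pairs).
    max_pair_distance: maximum nt between paired sites (None = unlimited
    within the supplied window)."""

    pair_threshold: int = 19
    spacer_tolerance: int = 0
    report_floor: int = 10
    max_pair_distance: int | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.pair_threshold <= 32:
            raise ValueError("pair_threshold must be in [0, 32]")


@dataclass(frozen=True)
class CrssHit:
    """A scored candidate site.  ``position`` is the 0-based start of the
    site footprint (heptamer on + strand) in forward coordinates."""

    sequence_name: str
    position: int
    strand: str  # "+" | "-"
    spacer_class: int  # 12 | 23
    spacer_len: int
    heptamer_matches: int
    nonamer_matches: int

    @property
    def site_score(self) -> int:
        return self.heptamer_matches + self.nonamer_matches

    @property
    def footprint(self) -> tuple[int, int]:
        """Half-open forward-strand interval covered by the site."""
        return self.position, self.position + HEPTAMER_LEN + self.spacer_len + NONAMER_LEN

    @property
    def heptamer_interval(self) -> tuple[int, int]:
        """Forward-strand interval of the heptamer (at the footprint's
        left end on +, right end on -)."""
        s, e = self.footprint
        return (s, s + HEPTAMER_LEN) if self.strand == "+" else (e - HEPTAMER_LEN, e)


@dataclass(frozen=True)
class CrssPair:
    hit12: CrssHit
    hit23: CrssHit
    pair_threshold: int = 19

    def __post_init__(self) -> None:
        if self.hit12.spacer_class != 12 or self.hit23.spacer_class != 23:
            raise ValueError("a cRSS pair needs one 12-spacer and one 23-spacer site (12/23 rule)")

    @property
    def pair_score(self) -> int:
        return self.hit12.site_score + self.hit23.site_score

    @property
    def positive(self) -> bool:
        return self.pair_score >= self.pair_threshold


def _matches(window: str, target: str) -> int:
    return sum(1 for a, b in zip(window, target) if a == b and a != "N")


def score_site(
    window: str,
    spacer_class: int,
    consensus: ConsensusRss | None = None,
    *,
    sequence_name: str = "",
    position: int = 0,
    strand: str = "+",
    spacer_len: int | None = None,
) -> CrssHit:
    """Score one heptamer+spacer+nonamer window against the consensus.

    The window must be exactly 7 + spacer + 9 nt; spacer positions are never
    scored and 'N' never matches.
    """
    consensus = consensus or ConsensusRss()
    spacer_len = spacer_class if spacer_len is None else spacer_len
    expected = HEPTAMER_LEN + spacer_len + NONAMER_LEN
    if len(window) != expected:
        raise ValueError(f"window must be {expected} nt for a {spacer_len}-spacer site")
    window = window.upper()
    return CrssHit(
        sequence_name=sequence_name,
        position=position,
        strand=strand,
        spacer_class=spacer_class,
        spacer_len=spacer_len,
        heptamer_matches=_matches(window[:HEPTAMER_LEN], consensus.heptamer),
        nonamer_matches=_matches(window[-NONAMER_LEN:], consensus.nonamer),
    )


def _spacer_lengths(spacer_class: int, tolerance: int) -> list[int]:
    return [s for s in range(spacer_class - tolerance, spacer_class + tolerance + 1) if s >= 0]


def scan_sequence(
    seq: str,
    consensus: ConsensusRss | None = None,
    config: CrssConfig | None = None,
    *,
    sequence_name: str = "",
    report_floor: int | None = None,
) -> list[CrssHit]:
    """Score every position, strand and spacer class of a sequence.

    Returns hits at or above the reporting floor (``config.report_floor``
    unless overridden), sorted by position.  Coordinates always refer to the
    forward strand; a - strand hit at position p covers forward interval
    [p, p+len) with its heptamer at the right end.
    """
    consensus = consensus or ConsensusRss()
    config = config or CrssConfig()
    floor = config.report_floor if report_floor is None else report_floor
    seq = seq.upper()
    rc = revcomp(seq)
    n = len(seq)
    hits: list[CrssHit] = []
    for spacer_class in (12, 23):
        for spacer_len in _spacer_lengths(spacer_class, config.spacer_tolerance):
            w = HEPTAMER_LEN + spacer_len + NONAMER_LEN
            for i in range(0, n - w + 1):
                hit = score_site(
                    seq[i : i + w],
                    spacer_class,
                    consensus,
                    sequence_name=sequence_name,
                    position=i,
                    strand="+",
                    spacer_len=spacer_len,
                )
                if hit.site_score >= floor:
                    hits.append(hit)
                hit = score_site(
                    rc[i : i + w],
                    spacer_class,
                    consensus,
                    sequence_name=sequence_name,
                    position=n - i - w,
                    strand="-",
                    spacer_len=spacer_len,
                )
                if hit.site_score >= floor:
                    hits.append(hit)
    hits.sort(key=lambda h: (h.position, h.strand, h.spacer_class))
    return hits


def score_pair(hit12: CrssHit, hit23: CrssHit, config: CrssConfig | None = None) -> CrssPair:
    """Form and score a 12/23 pair; raises if both sites share a spacer class."""
    config = config or CrssConfig()
    if hit12.spacer_class == hit23.spacer_class:
        raise ValueError(
            f"12/23 rule violation: both sites are {hit12.spacer_class}-spacer"
        )
    if hit12.spacer_class != 12:
        hit12, hit23 = hit23, hit12
    return CrssPair(hit12=hit12, hit23=hit23, pair_threshold=config.pair_threshold)


def _best_site(
    hits: Iterable[CrssHit],
    breakpoint_at: str,
    context_len: int,
) -> dict[int, CrssHit]:
    """Best hit per spacer class with the heptamer oriented toward the
    breakpoint.  ``breakpoint_at`` is 'right' (left context) or 'left'.

    Cleavage geometry: the heptamer abuts the break, so for a context whose
    breakpoint is at its right end only - strand sites qualify (heptamer at
    the footprint's right end), and conversely + strand sites for a
    breakpoint at the left end.  Ties break by heptamer distance to the
    breakpoint, then + strand, then lowest coordinate.
    """
    want_strand = "-" if breakpoint_at == "right" else "+"
    best: dict[int, CrssHit] = {}

    def distance(h: CrssHit) -> int:
        hs, he = h.heptamer_interval
        return context_len - he if breakpoint_at == "right" else hs

    for h in hits:
        if h.strand != want_strand:
            continue
        cur = best.get(h.spacer_class)
        key = (-h.site_score, distance(h), h.strand != "+", h.position)
        if cur is None or key < (-cur.site_score, distance(cur), cur.strand != "+", cur.position):
            best[h.spacer_class] = h
    return best


def classify_breakpoint_pair(
    left_context: str,
    right_context: str,
    consensus: ConsensusRss | None = None,
    config: CrssConfig | None = None,
) -> CrssPair | None:
    """Best 12/23 cRSS pair explaining a breakpoint, or None.

    Each context is scanned for its best site with the heptamer pointing
    toward the breakpoint (right end of the left context, left end of the
    right context); the 12/23 assignment maximising the pair score is
    returned.  Returns None when no orientation-consistent 12/23 pair
    exists.
    """
    consensus = consensus or ConsensusRss()
    config = config or CrssConfig()
    if min(len(left_context), len(right_context)) < HEPTAMER_LEN + 12 + NONAMER_LEN:
        raise ValueError("each breakpoint context must be at least 28 nt")
    left_hits = scan_sequence(
        left_context, consensus, config, sequence_name="left", report_floor=0
    )
    right_hits = scan_sequence(
        right_context, consensus, config, sequence_name="right", report_floor=0
    )
    best_left = _best_site(left_hits, "right", len(left_context))
    best_right = _best_site(right_hits, "left", len(right_context))

    candidates: list[CrssPair] = []
    if 12 in best_left and 23 in best_right:
        candidates.append(score_pair(best_left[12], best_right[23], config))
    if 23 in best_left and 12 in best_right:
        candidates.append(score_pair(best_right[12], best_left[23], config))
    if not candidates:
        return None
    return max(candidates, key=lambda p: p.pair_score)


def hits_to_bed(hits: Sequence[CrssHit]) -> str:
    """BED-like TSV rendering of scan hits (0-based half-open intervals)."""
    lines = []
    for h in hits:
        s, e = h.footprint
        name = f"cRSS{h.spacer_class}"
        lines.append(f"{h.sequence_name}\t{s}\t{e}\t{name}\t{h.site_score}\t{h.strand}")
    return "\n".join(lines) + ("\n" if lines else "")
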