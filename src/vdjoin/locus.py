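"""Germline locus references: gene segments, RSSs and junction reads.

A recombination signal sequence (RSS) is a conserved heptamer and nonamer
separated by a spacer of 12 or 23 nt.  Productive RAG cleavage pairs one
12-spacer RSS with one 23-spacer RSS (the 12/23 rule), producing two hairpin
coding ends and two blunt signal ends.  Everything downstream (annotation,
ADR detection, summaries) is anchored on the germline context held by these
types.

Coordinate convention: 0-based half-open internally; 1-based inclusive in
human-readable reports.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from Bio import SeqIO

logger = logging.getLogger(__name__)

DNA_ALPHABET = frozenset("ACGTN")

#: Canonical mouse/human consensus RSS elements.  Overridable per run; 'N'
#: in a scanned sequence never counts as a match against these.
CONSENSUS_HEPTAMER = "CACAGTG"
CONSENSUS_NONAMER = "ACAAAAACC"

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement of an upper-case DNA string (N maps to N)."""
    return seq.translate(_COMPLEMENT)[::-1]


def _check_dna(seq: str, what: str) -> str:
    seq = seq.upper()
    bad = set(seq) - DNA_ALPHABET
    if bad:
        raise ValueError(f"{what} contains non-DNA characters {sorted(bad)}")
    return seq


class LocusValidationError(ValueError):
    """A reference record violates an RSS or locus invariant."""


@dataclass(frozen=True)
class RssSpec:
    """One recombination signal sequence: heptamer + spacer + nonamer."""

    heptamer: str
    spacer: str
    nonamer: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "heptamer", _check_dna(self.heptamer, "heptamer"))
        object.__setattr__(self, "spacer", _check_dna(self.spacer, "spacer"))
        object.__setattr__(self, "nonamer", _check_dna(self.nonamer, "nonamer"))
        if len(self.heptamer) != 7:
            raise LocusValidationError(f"heptamer must be 7 nt, got {len(self.heptamer)}")
        if len(self.nonamer) != 9:
            raise LocusValidationError(f"nonamer must be 9 nt, got {len(self.nonamer)}")
        if len(self.spacer) not in (12, 23):
            raise LocusValidationError(
                f"spacer must be 12 or 23 nt (12/23 rule), got {len(self.spacer)}"
            )

    @property
    def spacer_class(self) -> int:
        return len(self.spacer)

    @property
    def full(self) -> str:
        """The RSS written 5'->3' from the coding segment: heptamer, spacer, nonamer."""
        return self.heptamer + self.spacer + self.nonamer


@dataclass(frozen=True)
class ConsensusRss:
    """Consensus heptamer/nonamer used for cryptic-RSS match counting."""

    heptamer: str = CONSENSUS_HEPTAMER
    nonamer: str = CONSENSUS_NONAMER

    def __post_init__(self) -> None:
        if len(self.heptamer) != 7 or len(self.nonamer) != 9:
            raise LocusValidationError("consensus heptamer/nonamer must be 7/9 nt")


@dataclass(frozen=True)
class GeneSegmentRef:
    """A germline gene segment: coding flank plus its RSS.

    ``coding_flank`` is oriented so its RSS-proximal end is LAST; ``side``
    says whether the segment sits upstream (left) or downstream (right) of
    the junction, which fixes the end deletions are counted from.
    ``frame_anchor`` is the reading-frame offset (0-2) at the RSS-proximal
    coding boundary, when known.
    """

    name: str
    coding_flank: str
    rss: RssSpec
    side: str  # "upstream_of_junction" | "downstream_of_junction"
    frame_anchor: int | None = None

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "coding_flank", _check_dna(self.coding_flank, f"{self.name} coding_flank")
        )
        if not self.coding_flank:
            raise LocusValidationError(f"{self.name}: coding_flank must be non-empty")
        if self.side not in ("upstream_of_junction", "downstream_of_junction"):
            raise LocusValidationError(f"{self.name}: bad side {self.side!r}")
        if self.frame_anchor is not None and self.frame_anchor not in (0, 1, 2):
            raise LocusValidationError(f"{self.name}: frame_anchor must be 0-2")


@dataclass(frozen=True)
class LocusReference:
    """A rearranging segment pair, e.g. a Vbeta14-Jbeta1.1 pairing.

    For signal joints the two RSS spacer classes must differ (12 with 23).
    """

    locus_name: str
    left_segment: GeneSegmentRef
    right_segment: GeneSegmentRef
    joint_kind: str  # "coding" | "signal"

    def __post_init__(self) -> None:
        if self.joint_kind not in ("coding", "signal"):
            raise LocusValidationError(f"{self.locus_name}: bad joint_kind {self.joint_kind!r}")
        if self.joint_kind == "signal":
            c1 = self.left_segment.rss.spacer_class
            c2 = self.right_segment.rss.spacer_class
            if c1 == c2:
                raise LocusValidationError(
                    f"{self.locus_name}: signal locus violates the 12/23 rule "
                    f"(both spacers {c1} nt)"
                )


@dataclass(frozen=True)
class JunctionRead:
    """One observed junction sequence with its locus and cohort metadata."""

    read_id: str
    sequence: str
    locus: LocusReference
    genotype: str = ""
    cohort: str = ""

    def __post_init__(self) -> None:
        if not self.sequence:
            raise LocusValidationError(f"{self.read_id}: empty sequence")
        object.__setattr__(self, "sequence", _check_dna(self.sequence, self.read_id))


# ---------------------------------------------------------------------------
# Reference file I/O
#
# The reference file is a TSV with one row per segment, two rows per locus:
#   locus  joint_kind  side  segment_name  coding_flank  heptamer  spacer  nonamer  [frame_anchor]
# side is "left" or "right".  Lines starting with '#' are comments.
# ---------------------------------------------------------------------------

_REF_COLUMNS = [
    "locus",
    "joint_kind",
    "side",
    "segment_name",
    "coding_flank",
    "heptamer",
    "spacer",
    "nonamer",
]


def load_locus_reference(path: str | Path) -> list[LocusReference]:
    """Load and validate a locus reference TSV.

    Raises :class:`LocusValidationError` naming the offending record and
    field on any malformed row; an empty file yields an empty list with a
    logged warning.
    """
    path = Path(path)
    rows: list[dict[str, str]] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(
            (line for line in fh if line.strip() and not line.startswith("#")),
            delimiter="\t",
        )
        if reader.fieldnames is not None:
            missing = set(_REF_COLUMNS) - set(reader.fieldnames)
            if missing:
                raise LocusValidationError(
                    f"{path}: missing reference columns {sorted(missing)}"
                )
        rows = list(reader)
    if not rows:
        logger.warning("reference file %s contains no records", path)
        return []

    by_locus: dict[str, dict[str, GeneSegmentRef]] = {}
    kinds: dict[str, str] = {}
    order: list[str] = []
    for i, row in enumerate(rows, start=2):
        name = row.get("locus") or f"<row {i}>"
        try:
            rss = RssSpec(row["heptamer"], row["spacer"], row["nonamer"])
            side_key = row["side"].strip().lower()
            if side_key not in ("left", "right"):
                raise LocusValidationError(f"side must be 'left' or 'right', got {row['side']!r}")
            anchor_raw = (row.get("frame_anchor") or "").strip()
            seg = GeneSegmentRef(
                name=row["segment_name"],
                coding_flank=row["coding_flank"],
                rss=rss,
                side="upstream_of_junction" if side_key == "left" else "downstream_of_junction",
                frame_anchor=int(anchor_raw) if anchor_raw else None,
            )
        except (KeyError, ValueError) as exc:
            raise LocusValidationError(f"{path} locus {name!r} (line {i}): {exc}") from exc
        if name not in by_locus:
            order.append(name)
        slot = by_locus.setdefault(name, {})
        if side_key in slot:
            raise LocusValidationError(f"{path} locus {name!r}: duplicate {side_key} segment")
        slot[side_key] = seg
        kinds[name] = row["joint_kind"].strip().lower()

    loci = []
    for name in order:
        slot = by_locus[name]
        if set(slot) != {"left", "right"}:
            raise LocusValidationError(f"{path} locus {name!r}: needs one left and one right segment")
        try:
            loci.append(
                LocusReference(
                    locus_name=name,
                    left_segment=slot["left"],
                    right_segment=slot["right"],
                    joint_kind=kinds[name],
                )
            )
        except LocusValidationError as exc:
            raise LocusValidationError(f"{path}: {exc}") from exc
    return loci


def write_locus_reference(loci: Iterable[LocusReference], path: str | Path) -> None:
    """Write loci back to the reference TSV format (round-trips with load)."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(_REF_COLUMNS + ["frame_anchor"])
        for locus in loci:
            for side_key, seg in (("left", locus.left_segment), ("right", locus.right_segment)):
                writer.writerow(
                    [
                        locus.locus_name,
                        locus.joint_kind,
                        side_key,
                        seg.name,
                        seg.coding_flank,
                        seg.rss.heptamer,
                        seg.rss.spacer,
                        seg.rss.nonamer,
                        "" if seg.frame_anchor is None else seg.frame_anchor,
                    ]
                )


def load_junction_reads(
    path: str | Path,
    locus: LocusReference,
    metadata: Mapping[str, str] | None = None,
) -> list[JunctionRead]:
    """Read junction sequences from FASTA, uppercasing and validating them.

    ``metadata`` may carry ``genotype`` and ``cohort`` labels applied to every
    read.  Non-DNA characters or duplicate ids raise with the read_id in the
    message.
    """
    metadata = dict(metadata or {})
    reads: list[JunctionRead] = []
    seen: set[str] = set()
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in seen:
            raise LocusValidationError(f"duplicate read_id {record.id!r} in {path}")
        seen.add(record.id)
        try:
            reads.append(
                JunctionRead(
                    read_id=record.id,
                    sequence=str(record.seq),
                    locus=locus,
                    genotype=metadata.get("genotype", ""),
                    cohort=metadata.get("cohort", ""),
                )
            )
        except ValueError as exc:
            raise LocusValidationError(f"read {record.id!r}: {exc}") from exc
    return reads
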