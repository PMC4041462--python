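"""Synthetic junction cohorts with ground truth.

The generator emulates the end-processing steps of V(D)J joint formation:

* coding ends open as hairpins, so an unresected end may carry P
  nucleotides (the reverse-complement palindrome of its terminal bases);
* each end may be resected, with geometrically distributed deletion length
  (memoryless nucleolytic nibbling);
* nontemplated N bases are added from a configurable base composition
  (TdT-like);
* a junction may instead be resolved by annealing at a pre-existing
  microhomology shared by the two ends; and
* the adjacent-direct-repeat (ADR) mechanism: one end acquires a
  complementary 3' extension copying the partner's terminal 3-5 nt, the
  ends anneal, and strand-displacement fill-in duplicates the repeat —
  leaving a tandem copy with one inserted and one templated half.

Signal joints are blunt heptamer-to-heptamer fusions; an imprecise joint
may lose bases into either RSS, gain N bases, or carry miscleavage (coding
flank sequence slipped onto a signal end).

Every read is emitted together with a TruthRecord so tests never re-derive
ground truth.  Output is fully determined by (params, seed).
"""

from __future__ import annotations

import csv
import json
from dataclasses import asdict, dataclass, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .annotate import signal_flanks
from .locus import JunctionRead, LocusReference, revcomp

BASES = "ACGT"


@dataclass(frozen=True)
class SimulationParams:
    """Knobs of the junction generator; probabilities are per junction or
    per end as noted.  Defaults are a wild-type-like regime: mostly short
    deletions (mean 4 nt, the wild-type average), frequent N addition,
    no microhomology dependence, rare imprecise signal joints."""

    seed: int = 0
    n_junctions: int = 100
    joint_kind: str = "coding"
    # --- coding-end processing ---
    p_deletion_per_end: float = 0.8
    deletion_mean: float = 4.0  # geometric, support >= 1
    p_p_nucleotides: float = 0.3  # per unresected end
    max_p: int = 2
    n_addition_mean: float = 2.0  # Poisson N-length
    n_base_composition: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    p_microhomology_join: float = 0.0
    mh_min: int = 2
    mh_max: int = 5
    p_adr_mechanism: float = 0.0
    adr_k_min: int = 3
    adr_k_max: int = 5
    # --- signal-joint processing ---
    sj_imprecision_prob: float = 0.2
    sj_p_deletion_per_end: float = 0.2
    sj_deletion_mean: float = 2.0
    sj_p_n_addition: float = 0.95
    p_miscleavage: float = 0.0
    miscleavage_len_max: int = 3

    def __post_init__(self) -> None:
        for name in (
            "p_deletion_per_end", "p_p_nucleotides", "p_microhomology_join",
            "p_adr_mechanism", "sj_imprecision_prob", "sj_p_deletion_per_end",
            "sj_p_n_addition", "p_miscleavage",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a probability, got {v}")
        if abs(sum(self.n_base_composition) - 1.0) > 1e-9:
            raise ValueError("n_base_composition must sum to 1")


@dataclass
class TruthRecord:
    """Ground truth for one simulated read."""

    read_id: str
    joint_kind: str
    del_left: int = 0
    del_right: int = 0
    p_left: str = ""
    p_right: str = ""
    n_insertion: str = ""
    microhomology_len: int = 0
    adr_repeat: str = ""
    miscleavage: bool = False
    precise: bool = False
    fallback: bool = False  # requested mechanism impossible, plain join emitted


def _geometric_len(rng: np.random.Generator, mean: float) -> int:
    # geometric on {1, 2, ...} with the given mean
    return int(rng.geometric(1.0 / max(mean, 1.0)))


def _n_bases(rng: np.random.Generator, length: int, comp: Sequence[float]) -> str:
    if length <= 0:
        return ""
    return "".join(rng.choice(list(BASES), size=length, p=list(comp)))


def _find_mh_joins(L: str, R: str, k_min: int, k_max: int, max_del: int = 10):
    """Candidate (del_left, del_right, k) joins where the k retained bases at
    the left end's terminus equal the first k retained bases of the right end."""
    out = []
    for k in range(k_max, k_min - 1, -1):
        for dl in range(0, min(max_del, len(L) - k) + 1):
            left_tail = L[: len(L) - dl][-k:]
            for dr in range(0, min(max_del, len(R) - k) + 1):
                if R[dr : dr + k] == left_tail:
                    out.append((dl, dr, k))
    return out


def simulate_coding_joint(
    locus: LocusReference,
    params: SimulationParams,
    rng: np.random.Generator,
    read_id: str = "cj1",
    genotype: str = "",
) -> tuple[JunctionRead, TruthRecord]:
    """Draw one coding joint and its ground truth."""
    if locus.joint_kind != "coding":
        raise ValueError(f"{locus.locus_name} is not a coding locus")
    L = locus.left_segment.coding_flank
    R = locus.right_segment.coding_flank
    truth = TruthRecord(read_id=read_id, joint_kind="coding")

    u = rng.random()
    if u < params.p_adr_mechanism:
        # ADR: strand-displacement fill-in duplicates the left end's terminal
        # k-mer; the second copy is inserted, the first is germline-templated.
        k = int(rng.integers(params.adr_k_min, params.adr_k_max + 1))
        repeat = L[-k:]
        if "N" in repeat or len(L) < k:
            truth.fallback = True
        else:
            del_r = _geometric_len(rng, params.deletion_mean) if rng.random() < params.p_deletion_per_end else 0
            del_r = min(del_r, len(R) - 1)
            n_len = int(rng.poisson(params.n_addition_mean))
            n_seq = _n_bases(rng, n_len, params.n_base_composition)
            seq = L + repeat + n_seq + R[del_r:]
            truth.del_right = del_r
            truth.n_insertion = repeat + n_seq
            truth.adr_repeat = repeat
            return JunctionRead(read_id, seq, locus, genotype), truth
    elif u < params.p_adr_mechanism + params.p_microhomology_join:
        cands = _find_mh_joins(L, R, params.mh_min, params.mh_max)
        if not cands:
            truth.fallback = True
        else:
            dl, dr, k = cands[int(rng.integers(len(cands)))]
            seq = L[: len(L) - dl] + R[dr + k :]
            truth.del_left, truth.del_right, truth.microhomology_len = dl, dr, k
            return JunctionRead(read_id, seq, locus, genotype), truth

    # standard c-NHEJ-like join: per-end resection or P, then N addition
    del_l = _geometric_len(rng, params.deletion_mean) if rng.random() < params.p_deletion_per_end else 0
    del_r = _geometric_len(rng, params.deletion_mean) if rng.random() < params.p_deletion_per_end else 0
    del_l = min(del_l, len(L) - 1)
    del_r = min(del_r, len(R) - 1)
    p_left = p_right = ""
    if del_l == 0 and rng.random() < params.p_p_nucleotides:
        k = int(rng.integers(1, params.max_p + 1))
        p_left = revcomp(L[-k:])
    if del_r == 0 and rng.random() < params.p_p_nucleotides:
        k = int(rng.integers(1, params.max_p + 1))
        p_right = revcomp(R[:k])
    n_len = int(rng.poisson(params.n_addition_mean))
    n_seq = _n_bases(rng, n_len, params.n_base_composition)
    seq = L[: len(L) - del_l] + p_left + n_seq + p_right + R[del_r:]
    truth.del_left, truth.del_right = del_l, del_r
    truth.p_left, truth.p_right, truth.n_insertion = p_left, p_right, n_seq
    return JunctionRead(read_id, seq, locus, genotype), truth


def simulate_signal_joint(
    locus: LocusReference,
    params: SimulationParams,
    rng: np.random.Generator,
    read_id: str = "sj1",
    genotype: str = "",
) -> tuple[JunctionRead, TruthRecord]:
    """Draw one signal joint (precise blunt fusion or imprecise) and truth."""
    if locus.joint_kind != "signal":
        raise ValueError(f"{locus.locus_name} is not a signal locus")
    SL, SR = signal_flanks(locus)
    truth = TruthRecord(read_id=read_id, joint_kind="signal")
    if rng.random() >= params.sj_imprecision_prob:
        truth.precise = True
        return JunctionRead(read_id, SL + SR, locus, genotype), truth

    for _ in range(100):  # rejection: an imprecise joint must deviate somehow
        del_l = _geometric_len(rng, params.sj_deletion_mean) if rng.random() < params.sj_p_deletion_per_end else 0
        del_r = _geometric_len(rng, params.sj_deletion_mean) if rng.random() < params.sj_p_deletion_per_end else 0
        del_l = min(del_l, len(SL) - 1)
        del_r = min(del_r, len(SR) - 1)
        n_len = int(rng.poisson(params.n_addition_mean)) if rng.random() < params.sj_p_n_addition else 0
        misc_left = misc_right = ""
        if rng.random() < params.p_miscleavage:
            m = int(rng.integers(2, params.miscleavage_len_max + 1))
            if rng.random() < 0.5:
                misc_left = revcomp(locus.left_segment.coding_flank[-m:])
                del_l = 0  # cleavage slipped into the coding segment, RSS intact
            else:
                misc_right = locus.right_segment.coding_flank[-m:]
                del_r = 0
        if del_l or del_r or n_len or misc_left or misc_right:
            break
    else:
        n_len, misc_left, misc_right = 1, "", ""  # degenerate params: force one N
        truth.fallback = True

    n_seq = _n_bases(rng, n_len, params.n_base_composition)
    insertion = misc_left + n_seq + misc_right
    seq = SL[: len(SL) - del_l] + insertion + SR[del_r:]
    truth.del_left, truth.del_right = del_l, del_r
    truth.n_insertion = insertion
    truth.miscleavage = bool(misc_left or misc_right)
    return JunctionRead(read_id, seq, locus, genotype), truth


def simulate_batch(
    locus: LocusReference,
    params: SimulationParams,
    genotype: str = "",
    id_prefix: str | None = None,
) -> tuple[list[JunctionRead], list[TruthRecord]]:
    """Simulate ``params.n_junctions`` reads at one locus, seeded by params."""
    rng = np.random.default_rng(params.seed)
    sim = simulate_coding_joint if params.joint_kind == "coding" else simulate_signal_joint
    prefix = id_prefix or f"{locus.locus_name}_{genotype or 'x'}"
    reads, truths = [], []
    for i in range(params.n_junctions):
        read, truth = sim(locus, params, rng, read_id=f"{prefix}_{i:05d}", genotype=genotype)
        reads.append(read)
        truths.append(truth)
    return reads, truths


# ---------------------------------------------------------------------------
# Cohort presets and file output
# ---------------------------------------------------------------------------


def wt_like_signal_params(seed: int = 0, n: int = 160) -> SimulationParams:
    """Wild-type-like signal joints: ~21% imprecise, short deletions only."""
    return SimulationParams(
        seed=seed, n_junctions=n, joint_kind="signal",
        sj_imprecision_prob=0.21, sj_p_deletion_per_end=0.17,
        sj_deletion_mean=2.0, sj_p_n_addition=0.95,
        p_miscleavage=0.02,
    )


def fs_like_signal_params(seed: int = 0, n: int = 140) -> SimulationParams:
    """RAG2-C-terminal-truncation-like regime: ~45% imprecise, half of
    imprecise junctions deleted with long (mean 6 nt) deletions, occasional
    microhomology and miscleavage."""
    return SimulationParams(
        seed=seed, n_junctions=n, joint_kind="signal",
        sj_imprecision_prob=0.45, sj_p_deletion_per_end=0.33,
        sj_deletion_mean=6.0, sj_p_n_addition=0.8,
        p_miscleavage=0.2,
    )


def table1_like_presets(seed: int = 0) -> dict[str, SimulationParams]:
    """Bundled two-genotype signal-joint demonstration preset."""
    return {"WT": wt_like_signal_params(seed), "FS": fs_like_signal_params(seed + 1)}


TRUTH_COLUMNS = [
    "read_id", "joint_kind", "del_left", "del_right", "p_left", "p_right",
    "n_insertion", "microhomology_len", "adr_repeat", "miscleavage",
    "precise", "fallback",
]


def simulate_cohort(
    loci: Sequence[LocusReference],
    params_by_genotype: Mapping[str, SimulationParams],
    outdir: str | Path,
    basename: str = "cohort",
) -> dict[str, Path]:
    """Write a multi-locus, multi-genotype cohort: FASTA + truth + metadata.

    Per genotype, each locus gets an independent stream seeded from the
    genotype's params (offset by locus index), so output is byte-identical
    for identical inputs.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    fasta = outdir / f"{basename}.fasta"
    truth_path = outdir / f"{basename}.truth.tsv"
    meta_path = outdir / f"{basename}.meta.tsv"
    params_path = outdir / f"{basename}.params.json"

    with open(fasta, "w") as ff, open(truth_path, "w", newline="") as tf, open(
        meta_path, "w", newline=""
    ) as mf:
        tw = csv.writer(tf, delimiter="\t", lineterminator="\n")
        tw.writerow(TRUTH_COLUMNS)
        mw = csv.writer(mf, delimiter="\t", lineterminator="\n")
        mw.writerow(["read_id", "locus", "genotype", "joint_kind"])
        for genotype, params in params_by_genotype.items():
            usable = [l for l in loci if l.joint_kind == params.joint_kind]
            for li, locus in enumerate(usable):
                lp = replace(params, seed=params.seed + li)
                reads, truths = simulate_batch(locus, lp, genotype=genotype)
                for read, truth in zip(reads, truths):
                    ff.write(f">{read.read_id}\n{read.sequence}\n")
                    tw.writerow([getattr(truth, c) for c in TRUTH_COLUMNS])
                    mw.writerow([read.read_id, locus.locus_name, genotype, params.joint_kind])
    with open(params_path, "w") as pf:
        json.dump({g: asdict(p) for g, p in params_by_genotype.items()}, pf, indent=2)
    return {"fasta": fasta, "truth": truth_path, "metadata": meta_path, "params": params_path}
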