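"""Cohort-level summaries of junction annotations and the associated tests.

Signal-joint summaries follow the convention of reporting N addition,
deletion, miscleavage and microhomology out of IMPRECISE junctions, while
the long-deletion fraction (> 5 bp) is computed out of deleted ENDS (two
ends per junction).  Coding-joint summaries report, per region (V side / J
side), the fraction of junctions deleted out of all events and the mean
deletion length and > 4 bp fraction out of deleted events only.  Pooled rows
sum raw counts across loci before computing percentages, so pooled
percentages always recompute from their numerator/denominator.

Group comparisons use the Pearson chi-squared test of independence without
continuity correction, and the classic pooled-variance two-tailed unpaired
t-test (Welch available behind a flag).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps


class DegenerateDataError(ValueError):
    """A statistical test is undefined on the given data."""


@dataclass(frozen=True)
class SummaryConfig:
    """sj_deletion_cutoff: signal-end deletions longer than this are 'long'
    (5 bp: the longest deletion ever seen in wild-type signal joints).
    cj_deletion_cutoff: coding-end cutoff (4 bp: the average deletion length
    in wild-type coding joints).
    microhomology_min: shortest overlap counted as microhomology."""

    sj_deletion_cutoff: int = 5
    cj_deletion_cutoff: int = 4
    microhomology_min: int = 2

    def __post_init__(self) -> None:
        if min(self.sj_deletion_cutoff, self.cj_deletion_cutoff, self.microhomology_min) < 1:
            raise ValueError("all SummaryConfig cutoffs must be positive")


@dataclass(frozen=True)
class ContingencyTable:
    """r x c nonnegative integer counts with labels."""

    counts: tuple[tuple[int, ...], ...]
    row_labels: tuple[str, ...] = ()
    col_labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        arr = np.asarray(self.counts)
        if arr.ndim != 2 or arr.shape[0] < 2 or arr.shape[1] < 2:
            raise ValueError("contingency table must be at least 2x2")
        if (arr < 0).any():
            raise ValueError("contingency table counts must be nonnegative")

    def as_array(self) -> np.ndarray:
        return np.asarray(self.counts, dtype=float)


# ---------------------------------------------------------------------------
# Signal-joint summaries
# ---------------------------------------------------------------------------

#: Columns expected in the per-junction signal-joint frame
#: (annotate.annotations_to_frame produces a superset).
SJ_REQUIRED = ["locus", "genotype", "precise", "del_left", "del_right",
               "insertion", "miscleavage", "microhomology_len"]


def _pct(num: int, den: int) -> float:
    return round(100.0 * num / den, 1) if den else float("nan")


def _summarize_sj_group(g: pd.DataFrame, config: SummaryConfig) -> dict:
    n_total = len(g)
    precise = g["precise"].astype(bool)
    imp = g[~precise]
    n_imp = len(imp)
    dl = imp["del_left"].astype(int)
    dr = imp["del_right"].astype(int)
    deleted_ends = int((dl > 0).sum() + (dr > 0).sum())
    long_ends = int((dl > config.sj_deletion_cutoff).sum() + (dr > config.sj_deletion_cutoff).sum())
    n_with_n = int((imp["insertion"].astype(str).str.len() > 0).sum())
    n_with_del = int(((dl > 0) | (dr > 0)).sum())
    n_misc = int(imp["miscleavage"].astype(bool).sum())
    n_mh = int((imp["microhomology_len"].astype(int) >= config.microhomology_min).sum())
    return {
        "n_total": n_total,
        "n_precise": int(precise.sum()),
        "n_imprecise": n_imp,
        "n_with_n": n_with_n,
        "n_with_deletion": n_with_del,
        "n_deleted_ends": deleted_ends,
        "n_deleted_ends_gt_cutoff": long_ends,
        "n_miscleavage": n_misc,
        "n_microhomology": n_mh,
        "pct_imprecise": _pct(n_imp, n_total),
        "pct_n": _pct(n_with_n, n_imp),
        "pct_n_of_total": _pct(n_with_n, n_total),
        "pct_deletion": _pct(n_with_del, n_imp),
        "pct_deleted_ends_gt_cutoff": _pct(long_ends, deleted_ends),
        "pct_miscleavage": _pct(n_misc, n_imp),
        "pct_microhomology": _pct(n_mh, n_imp),
    }


def summarize_signal_joints(
    frame: pd.DataFrame,
    config: SummaryConfig | None = None,
) -> pd.DataFrame:
    """Per-(genotype, locus) signal-joint summary plus a pooled row per genotype.

    ``frame`` is the tidy per-junction table (one row per junction) with the
    columns in :data:`SJ_REQUIRED`.  The pooled row (locus = "pooled") sums
    counts across loci before computing percentages.
    """
    config = config or SummaryConfig()
    missing = [c for c in SJ_REQUIRED if c not in frame.columns]
    if missing:
        raise KeyError(f"signal-joint frame lacks columns {missing}")
    rows = []
    for genotype, gframe in frame.groupby("genotype", sort=False):
        for locus, lg in gframe.groupby("locus", sort=False):
            rows.append({"genotype": genotype, "locus": locus, **_summarize_sj_group(lg, config)})
        rows.append({"genotype": genotype, "locus": "pooled", **_summarize_sj_group(gframe, config)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Coding-joint summaries
# ---------------------------------------------------------------------------

CJ_REQUIRED = ["locus", "genotype", "del_left", "del_right"]


def _summarize_cj_group(g: pd.DataFrame, config: SummaryConfig) -> dict:
    out: dict = {"n_total": len(g)}
    for region, col in (("v", "del_left"), ("j", "del_right")):
        dels = g[col].astype(int)
        deleted = dels[dels > 0]
        out[f"frac_deleted_{region}"] = round(len(deleted) / len(g), 3) if len(g) else float("nan")
        out[f"mean_del_{region}"] = round(float(deleted.mean()), 2) if len(deleted) else float("nan")
        out[f"frac_gt_cutoff_{region}"] = (
            round(float((deleted > config.cj_deletion_cutoff).mean()), 3)
            if len(deleted)
            else float("nan")
        )
    return out


def summarize_coding_joints(
    frame: pd.DataFrame,
    config: SummaryConfig | None = None,
) -> pd.DataFrame:
    """Per-(genotype, locus) coding-joint deletion summary.

    The V region is the left flank, the J region the right flank.  Deleted
    fraction is out of all events; mean length and the > cutoff fraction are
    out of deleted events only.
    """
    config = config or SummaryConfig()
    missing = [c for c in CJ_REQUIRED if c not in frame.columns]
    if missing:
        raise KeyError(f"coding-joint frame lacks columns {missing}")
    rows = []
    for genotype, gframe in frame.groupby("genotype", sort=False):
        for locus, lg in gframe.groupby("locus", sort=False):
            rows.append({"genotype": genotype, "locus": locus, **_summarize_cj_group(lg, config)})
        rows.append({"genotype": genotype, "locus": "pooled", **_summarize_cj_group(gframe, config)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Tests
# ---------------------------------------------------------------------------


def chi_squared_independence(
    table: ContingencyTable | Sequence[Sequence[int]],
) -> tuple[float, int, float]:
    """Pearson chi-squared test of independence, no continuity correction.

    Returns (statistic, degrees of freedom, p).  Raises
    :class:`DegenerateDataError` on a zero row or column margin.
    """
    if not isinstance(table, ContingencyTable):
        table = ContingencyTable(tuple(tuple(int(x) for x in row) for row in table))
    arr = table.as_array()
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        raise DegenerateDataError("chi-squared test undefined: zero row/column margin")
    res = sps.chi2_contingency(arr, correction=False)
    return float(res.statistic), int(res.dof), float(res.pvalue)


def two_tailed_unpaired_t_test(
    group_a: Sequence[float],
    group_b: Sequence[float],
    *,
    welch: bool = False,
) -> tuple[float, float, float]:
    """Two-sided unpaired t-test; pooled variance unless ``welch``.

    Returns (t, df, p).  Two identical constant groups give (0, df, 1); a
    zero-variance comparison with unequal means is flagged degenerate.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise DegenerateDataError("each group needs n >= 2")
    pooled_var = (a.var(ddof=1) * (len(a) - 1) + b.var(ddof=1) * (len(b) - 1)) / (
        len(a) + len(b) - 2
    )
    if pooled_var == 0:
        if a.mean() == b.mean():
            return 0.0, float(len(a) + len(b) - 2), 1.0
        raise DegenerateDataError("zero variance with unequal means")
    res = sps.ttest_ind(a, b, equal_var=not welch)
    df = float(res.df) if hasattr(res, "df") else float(len(a) + len(b) - 2)
    return float(res.statistic), df, float(res.pvalue)
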