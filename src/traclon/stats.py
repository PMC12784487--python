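"""Per-sample scoring of clonotype sets and the study's group comparisons.

A clonotype set (e.g. the flattened members of a phenotype's meta-clonotypes)
is scored per sample as its summed template-count frequency; unpaired group
differences are tested with the two-sided Mann-Whitney U test, paired
before/after designs with the two-sided Wilcoxon signed-rank test
(zero differences dropped before ranking).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io import ClonotypeKey, Repertoire

logger = logging.getLogger(__name__)

#: exact Mann-Whitney enumeration is used up to this combined sample size
#: (and only for tie-free data); beyond it, the tie-corrected normal
#: approximation with continuity correction.
MANN_WHITNEY_EXACT_MAX_N = 12
#: exact signed-rank null up to this many nonzero differences (tie-free).
WILCOXON_EXACT_MAX_N = 15


@dataclass(frozen=True)
class ClonotypeSet:
    name: str
    keys: frozenset[ClonotypeKey]

    def __post_init__(self) -> None:
        if not self.keys:
            raise ValueError(f"clonotype set {self.name!r} is empty")


@dataclass(frozen=True)
class GroupComparison:
    group_a: str
    group_b: str
    n_a: int
    n_b: int
    statistic: float
    p_value: float
    paired: bool
    degenerate: bool = False


def set_expansion(rep: Repertoire, cset: ClonotypeSet) -> float:
    """Summed frequency of the set's clonotypes in a preprocessed
    repertoire: sum of matching productive counts over total_count."""
    total = rep.total_count
    if total == 0:
        raise ValueError(f"{rep.sample_id}: empty repertoire")
    t = rep.table.loc[rep.table["productive"]]
    mask = [ClonotypeKey(v, j, c) in cset.keys
            for v, j, c in zip(t["v_gene"], t["j_gene"], t["cdr3_aa"])]
    return float(t.loc[mask, "count"].sum()) / total


def expansion_table(cohort, csets: list[ClonotypeSet]) -> pd.DataFrame:
    """Per-(sample, set) expansion joined with cohort metadata."""
    rows = []
    for sid in cohort.sample_ids:
        for cset in csets:
            rows.append({"sample_id": sid, "set": cset.name,
                         "expansion": set_expansion(cohort.repertoires[sid], cset)})
    out = pd.DataFrame(rows, columns=["sample_id", "set", "expansion"])
    if out.empty:
        return out
    return out.merge(cohort.metadata, on="sample_id", how="left")


def mann_whitney_u(x, y, group_a: str = "a", group_b: str = "b"
                   ) -> GroupComparison:
    """Two-sided Mann-Whitney U comparison of two independent samples.

    Exact enumeration of the U null distribution when the combined sample
    size is small (<= 12) and the data are tie-free; tie-corrected normal
    approximation with continuity correction otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    combined = np.concatenate([x, y])
    tie_free = np.unique(combined).size == combined.size
    method = ("exact" if tie_free and combined.size <= MANN_WHITNEY_EXACT_MAX_N
              else "asymptotic")
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return GroupComparison(group_a, group_b, x.size, y.size,
                           float(res.statistic), float(res.pvalue), paired=False)


def wilcoxon_paired(before, after, group_a: str = "before",
                    group_b: str = "after") -> GroupComparison:
    """Two-sided Wilcoxon signed-rank test on paired measurements.

    Zero differences are dropped before ranking (classic Wilcoxon
    treatment).  If every difference is zero the comparison is degenerate:
    p is reported as 1 with a logged warning.  Exact null when <= 15
    tie-free nonzero differences remain, normal approximation otherwise.
    """
    before = np.asarray(before, dtype=float)
    after = np.asarray(after, dtype=float)
    if before.size != after.size:
        raise ValueError("paired samples must have equal length")
    if before.size == 0:
        raise ValueError("empty paired samples")
    diffs = after - before
    nz = diffs[diffs != 0]
    if nz.size == 0:
        logger.warning("all paired differences are zero; degenerate comparison")
        return GroupComparison(group_a, group_b, before.size, after.size,
                               0.0, 1.0, paired=True, degenerate=True)
    tie_free = np.unique(np.abs(nz)).size == nz.size
    method = ("exact" if tie_free and nz.size <= WILCOXON_EXACT_MAX_N
              else "approx")
    res = sps.wilcoxon(nz, zero_method="wilcox", alternative="two-sided",
                       method=method)
    return GroupComparison(group_a, group_b, before.size, after.size,
                           float(res.statistic), float(res.pvalue), paired=True)


def compare_groups(table: pd.DataFrame, value_col: str, group_col: str,
                   pairs: list[tuple[str, str]], paired: bool = False,
                   pair_col: str = "pair_id") -> list[GroupComparison]:
    """Run one comparison per requested label pair on a long-format table.

    In paired mode samples are joined on ``pair_col``; unmatched samples are
    dropped with a logged count.
    """
    out = []
    for a, b in pairs:
        ta = table[table[group_col] == a]
        tb = table[table[group_col] == b]
        if paired:
            merged = ta.merge(tb, on=pair_col, suffixes=("_a", "_b"))
            n_dropped = (len(ta) - len(merged)) + (len(tb) - len(merged))
            if n_dropped:
                logger.info("paired comparison %s vs %s: dropped %d unmatched "
                            "samples", a, b, n_dropped)
            if merged.empty:
                raise ValueError(f"no matched pairs for {a} vs {b}")
            out.append(wilcoxon_paired(merged[f"{value_col}_a"],
                                       merged[f"{value_col}_b"],
                                       group_a=a, group_b=b))
        else:
            out.append(mann_whitney_u(ta[value_col], tb[value_col],
                                      group_a=a, group_b=b))
    return out


def comparisons_to_frame(comparisons: list[GroupComparison],
                         set_name: str | None = None) -> pd.DataFrame:
    rows = []
    for c in comparisons:
        row = {"group_a": c.group_a, "group_b": c.group_b, "n_a": c.n_a,
               "n_b": c.n_b, "statistic": c.statistic, "p": c.p_value,
               "paired": c.paired}
        if set_name is not None:
            row = {"set": set_name, **row}
        rows.append(row)
    return pd.DataFrame(rows)
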