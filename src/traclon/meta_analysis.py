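"""Cross-cohort meta-analysis of clonotype association evidence.

Per-cohort one-sided Fisher p-values for each candidate clonotype (the
union of the cohorts' associated seeds, restricted to clonotypes detected
in every cohort) are merged with Fisher's combined probability method,

    X^2 = -2 * sum_i ln p_i  ~  chi-square(2k)  under the joint null,

and the combined p-values are Benjamini-Hochberg adjusted over the
candidate list; clonotypes with adjusted p < 0.05 form the meta-analysis
associated set.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2
from statsmodels.stats.multitest import multipletests

from .association import CohortAssociationResults
from .io import ClonotypeKey

_KEY_COLS = ["v_gene", "j_gene", "cdr3_aa"]


def fisher_combine(ps: Sequence[float]) -> tuple[float, float]:
    """Fisher's combined probability: returns (statistic, combined p).

    The statistic is accumulated in log space so that p-values near the
    floating-point underflow limit remain usable.
    """
    if len(ps) == 0:
        raise ValueError("no p-values to combine")
    stat = 0.0
    for p in ps:
        if not 0.0 < p <= 1.0:
            raise ValueError(f"p-value {p} outside (0, 1]")
        stat -= 2.0 * math.log(p)
    combined = float(chi2.sf(stat, df=2 * len(ps)))
    return stat, min(max(combined, np.nextafter(0, 1)), 1.0)


def benjamini_hochberg(ps: Sequence[float]) -> np.ndarray:
    """Step-up FDR-adjusted p-values, returned in input order."""
    arr = np.asarray(ps, dtype=float)
    if arr.size == 0:
        return arr
    if ((arr < 0) | (arr > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(arr, method="fdr_bh")[1]


@dataclass(frozen=True)
class MetaAnalysisResult:
    key: ClonotypeKey
    per_cohort_p: tuple[tuple[str, float], ...]
    combined_statistic: float
    combined_p: float
    adjusted_p: float
    significant: bool


class MetaAnalysisModel:
    """Fisher-combination meta-analysis over k >= 1 fitted cohort
    association results.

    Parameters
    ----------
    results_by_cohort : mapping cohort_id -> CohortAssociationResults; the
        per-cohort p entering the combination is recomputed for every
        candidate from each cohort's incidence index.
    alpha_adjusted : significance cutoff on the BH-adjusted combined p.
    min_presence_per_cohort : a candidate must be carried by at least this
        many samples in every cohort's compared groups to be testable.
    candidate_keys : defaults to the union of the cohorts' associated seeds.
    """

    def __init__(self,
                 results_by_cohort: Mapping[str, CohortAssociationResults],
                 alpha_adjusted: float = 0.05,
                 min_presence_per_cohort: int = 1,
                 candidate_keys: set[ClonotypeKey] | None = None):
        if not results_by_cohort:
            raise ValueError("need at least one cohort")
        self.results_by_cohort = dict(results_by_cohort)
        self.alpha_adjusted = float(alpha_adjusted)
        self.min_presence_per_cohort = int(min_presence_per_cohort)
        self.candidate_keys = candidate_keys

    def fit(self) -> "MetaAnalysisResults":
        cohorts = list(self.results_by_cohort)
        candidates = self.candidate_keys
        if candidates is None:
            candidates = set()
            for res in self.results_by_cohort.values():
                candidates |= set(res.associated_keys())
        # presence filter: detected in every cohort's compared groups
        testable = []
        for key in sorted(candidates):
            present_everywhere = True
            for cid in cohorts:
                a, b = self.results_by_cohort[cid].index.counts_for(key)
                if a + b < self.min_presence_per_cohort:
                    present_everywhere = False
                    break
            if present_everywhere:
                testable.append(key)
        rows = []
        for key in testable:
            per = [(cid, self.results_by_cohort[cid].p_for(key))
                   for cid in cohorts]
            stat, comb = fisher_combine([p for _, p in per])
            row = {"v_gene": key.v_gene, "j_gene": key.j_gene,
                   "cdr3_aa": key.cdr3_aa}
            for cid, p in per:
                row[f"p_{cid}"] = p
            row["combined_statistic"] = stat
            row["combined_p"] = comb
            rows.append(row)
        table = pd.DataFrame(rows)
        if not table.empty:
            table["adjusted_p"] = benjamini_hochberg(table["combined_p"].to_numpy())
            table["significant"] = table["adjusted_p"] < self.alpha_adjusted
            table = (table.sort_values(["adjusted_p", "combined_p"] + _KEY_COLS,
                                       kind="mergesort").reset_index(drop=True))
        else:
            table = pd.DataFrame(columns=_KEY_COLS + [f"p_{c}" for c in cohorts]
                                 + ["combined_statistic", "combined_p",
                                    "adjusted_p", "significant"])
        return MetaAnalysisResults(self, tuple(cohorts), table)


@dataclass
class MetaAnalysisResults:
    model: MetaAnalysisModel
    cohort_ids: tuple[str, ...]
    table: pd.DataFrame

    @property
    def records(self) -> list[MetaAnalysisResult]:
        out = []
        for r in self.table.itertuples(index=False):
            d = r._asdict()
            per = tuple((cid, float(d[f"p_{cid}"])) for cid in self.cohort_ids)
            out.append(MetaAnalysisResult(
                ClonotypeKey(d["v_gene"], d["j_gene"], d["cdr3_aa"]), per,
                float(d["combined_statistic"]), float(d["combined_p"]),
                float(d["adjusted_p"]), bool(d["significant"])))
        return out

    def significant_keys(self) -> list[ClonotypeKey]:
        sel = self.table[self.table["significant"]]
        return [ClonotypeKey(r.v_gene, r.j_gene, r.cdr3_aa)
                for r in sel.itertuples(index=False)]

    def summary(self, top: int = 20) -> str:
        n_sig = int(self.table["significant"].sum()) if not self.table.empty else 0
        lines = [
            "Cross-cohort meta-analysis (Fisher combined probability, BH-adjusted)",
            f"  cohorts:     {', '.join(self.cohort_ids)} (k={len(self.cohort_ids)})",
            f"  candidates tested (present in all cohorts): {len(self.table)}",
            f"  significant at adjusted p < {self.model.alpha_adjusted:g}: {n_sig}",
        ]
        if top > 0:
            lines.append("")
            lines.append(self.table.head(top).to_string(index=False)
                         if not self.table.empty
                         else "  (no testable candidates)")
        return "\n".join(lines)

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def meta_associate(results_by_cohort: Mapping[str, CohortAssociationResults],
                   candidate_keys: set[ClonotypeKey] | None = None,
                   alpha_adjusted: float = 0.05,
                   min_presence_per_cohort: int = 1) -> MetaAnalysisResults:
    """Functional wrapper: fit a :class:`MetaAnalysisModel`."""
    return MetaAnalysisModel(results_by_cohort,
                             alpha_adjusted=alpha_adjusted,
                             min_presence_per_cohort=min_presence_per_cohort,
                             candidate_keys=candidate_keys).fit()
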