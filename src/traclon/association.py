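"""Public-clonotype incidence association testing.

A clonotype is *public* when it is carried by more than one individual.  For
each public clonotype the numbers of carriers among cases and controls form
a 2x2 contingency table; enrichment in cases is scored with a one-sided
Fisher's exact test (upper hypergeometric tail), and clonotypes below a
fixed discovery cutoff (default 1e-3, uncorrected — multiplicity is handled
later at the meta-analysis stage) are flagged as disease-associated.

The entry point is :class:`CohortAssociationModel`, whose :meth:`fit`
returns a :class:`CohortAssociationResults` carrying the per-clonotype
table, the incidence index (reused by the meta-clonotype and meta-analysis
stages) and a ``summary()`` view.
"""

from __future__ import annotations

from dataclasses import dataclass, field


import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .io import Cohort, ClonotypeKey

_KEY_COLS = ["v_gene", "j_gene", "cdr3_aa"]


@dataclass
class IncidenceIndex:
    """Carrier counts (and sample sets) per clonotype for one case/control
    comparison.  A clonotype is 'present' in a sample iff its productive,
    collapsed count is >= 1."""

    case_label: str
    control_label: str
    case_samples: tuple[str, ...]
    control_samples: tuple[str, ...]
    #: long format: one row per (clonotype, carrying sample)
    long: pd.DataFrame = field(repr=False)
    #: per-clonotype carrier counts, indexed by (v_gene, j_gene, cdr3_aa)
    counts: pd.DataFrame = field(repr=False)

    @property
    def n_case(self) -> int:
        return len(self.case_samples)

    @property
    def n_control(self) -> int:
        return len(self.control_samples)

    def keys(self) -> list[ClonotypeKey]:
        return [ClonotypeKey(*t) for t in self.counts.index]

    def counts_for(self, key: ClonotypeKey) -> tuple[int, int]:
        """(case carriers, control carriers); (0, 0) for unseen keys."""
        try:
            row = self.counts.loc[tuple(key)]
        except KeyError:
            return 0, 0
        return int(row["case_present"]), int(row["control_present"])

    def carriers(self, key: ClonotypeKey) -> tuple[set[str], set[str]]:
        """Sets of case and control sample ids carrying the clonotype."""
        sel = self.long[(self.long["v_gene"] == key.v_gene)
                        & (self.long["j_gene"] == key.j_gene)
                        & (self.long["cdr3_aa"] == key.cdr3_aa)]
        case = set(sel.loc[sel["is_case"], "sample_id"])
        ctrl = set(sel.loc[~sel["is_case"], "sample_id"])
        return case, ctrl


def build_incidence(cohort: Cohort, case_label: str,
                    control_label: str) -> IncidenceIndex:
    """Index which samples carry which clonotypes, restricted to the two
    compared phenotype groups.  Repertoires must be preprocessed
    (productive-filtered and collapsed)."""
    case_ids = cohort.samples_with_label(case_label)
    control_ids = cohort.samples_with_label(control_label)
    if not case_ids or not control_ids:
        raise ValueError(
            f"cohort {cohort.cohort_id}: need >=1 sample in each group "
            f"({case_label}: {len(case_ids)}, {control_label}: {len(control_ids)})")
    frames = []
    for sid in case_ids + control_ids:
        t = cohort.repertoires[sid].table
        t = t.loc[t["productive"] & (t["count"] >= 1), _KEY_COLS]
        t = t.drop_duplicates()
        f = t.copy()
        f["sample_id"] = sid
        f["is_case"] = sid in set(case_ids)
        frames.append(f)
    long = pd.concat(frames, ignore_index=True)
    grp = long.groupby(_KEY_COLS, sort=True)["is_case"]
    counts = pd.DataFrame({"case_present": grp.sum().astype(int),
                           "n_present": grp.size().astype(int)})
    counts["control_present"] = counts["n_present"] - counts["case_present"]
    return IncidenceIndex(case_label, control_label, tuple(case_ids),
                          tuple(control_ids), long, counts)


def public_clonotypes(index: IncidenceIndex,
                      min_individuals: int = 2) -> set[ClonotypeKey]:
    """Clonotypes carried by at least ``min_individuals`` distinct samples
    across the two compared groups combined."""
    sel = index.counts[index.counts["n_present"] >= min_individuals]
    return {ClonotypeKey(*t) for t in sel.index}


def fisher_one_sided(case_present: int, case_total: int,
                     control_present: int, control_total: int) -> float:
    """Exact one-sided (enrichment-in-cases) Fisher p for a 2x2 incidence
    table: the upper hypergeometric tail P(X >= case_present) with
    population size case_total+control_total, case_total draws and
    case_present+control_present successes."""
    _validate_table(case_present, case_total, control_present, control_total)
    M = case_total + control_total
    K = case_present + control_present
    p = float(hypergeom.sf(case_present - 1, M, K, case_total))
    return min(max(p, np.nextafter(0, 1)), 1.0)


def fisher_one_sided_vec(case_present, case_total: int,
                         control_present, control_total: int) -> np.ndarray:
    """Vectorised :func:`fisher_one_sided` over arrays of carrier counts."""
    cp = np.asarray(case_present, dtype=np.int64)
    kp = np.asarray(control_present, dtype=np.int64)
    if case_total <= 0 or control_total <= 0:
        raise ValueError("group totals must be positive")
    M = case_total + control_total
    p = hypergeom.sf(cp - 1, M, cp + kp, case_total)
    return np.clip(p, np.nextafter(0, 1), 1.0)


def _validate_table(a: int, n1: int, b: int, n2: int) -> None:
    if n1 <= 0 or n2 <= 0:
        raise ValueError("group totals must be positive")
    if not (0 <= a <= n1):
        raise ValueError(f"case_present {a} outside [0, {n1}]")
    if not (0 <= b <= n2):
        raise ValueError(f"control_present {b} outside [0, {n2}]")


@dataclass(frozen=True)
class AssociationResult:
    key: ClonotypeKey
    n_case_present: int
    n_case_total: int
    n_control_present: int
    n_control_total: int
    p_value: float
    associated: bool


class CohortAssociationModel:
    """Incidence association of public clonotypes within one cohort.

    Parameters
    ----------
    cohort : preprocessed cohort (productive, collapsed repertoires)
    case_label, control_label : phenotype labels to compare; the one-sided
        alternative is enrichment among ``case_label`` carriers
    alpha : discovery cutoff; a clonotype is associated iff p < alpha (strict)
    min_individuals : publicity threshold on carriers in the two groups
    """

    def __init__(self, cohort: Cohort, case_label: str, control_label: str,
                 alpha: float = 1e-3, min_individuals: int = 2):
        self.cohort = cohort
        self.case_label = case_label
        self.control_label = control_label
        self.alpha = float(alpha)
        self.min_individuals = int(min_individuals)

    def fit(self) -> "CohortAssociationResults":
        index = build_incidence(self.cohort, self.case_label, self.control_label)
        sel = index.counts[index.counts["n_present"] >= self.min_individuals]
        p = fisher_one_sided_vec(sel["case_present"].to_numpy(), index.n_case,
                                 sel["control_present"].to_numpy(), index.n_control)
        table = sel.reset_index()
        table["case_total"] = index.n_case
        table["control_total"] = index.n_control
        table["p_value"] = p
        table["associated"] = table["p_value"] < self.alpha
        table = (table.sort_values(["p_value"] + _KEY_COLS, kind="mergesort")
                 .reset_index(drop=True))
        cols = _KEY_COLS + ["case_present", "case_total", "control_present",
                            "control_total", "p_value", "associated"]
        return CohortAssociationResults(self, index, table[cols])


@dataclass
class CohortAssociationResults:
    """Fitted per-clonotype association table for one cohort comparison.

    ``table`` is sorted by ascending p-value (ties broken lexicographically
    by V gene, J gene, CDR3).
    """

    model: CohortAssociationModel
    index: IncidenceIndex
    table: pd.DataFrame

    @property
    def records(self) -> list[AssociationResult]:
        return [AssociationResult(ClonotypeKey(r.v_gene, r.j_gene, r.cdr3_aa),
                                  int(r.case_present), int(r.case_total),
                                  int(r.control_present), int(r.control_total),
                                  float(r.p_value), bool(r.associated))
                for r in self.table.itertuples(index=False)]

    def associated_keys(self) -> list[ClonotypeKey]:
        sel = self.table[self.table["associated"]]
        return [ClonotypeKey(r.v_gene, r.j_gene, r.cdr3_aa)
                for r in sel.itertuples(index=False)]

    def p_for(self, key: ClonotypeKey) -> float:
        """One-sided Fisher p for any clonotype (not only public ones),
        recomputed from the incidence index; 1.0 for keys absent from the
        compared groups."""
        a, b = self.index.counts_for(key)
        return fisher_one_sided(a, self.index.n_case, b, self.index.n_control)

    def summary(self, top: int = 20) -> str:
        m = self.model
        n_assoc = int(self.table["associated"].sum())
        lines = [
            "Cohort incidence association (one-sided Fisher's exact test)",
            f"  cohort:        {m.cohort.cohort_id}",
            f"  comparison:    {m.case_label} (n={self.index.n_case}) vs "
            f"{m.control_label} (n={self.index.n_control})",
            f"  public clonotypes tested: {len(self.table)} "
            f"(publicity >= {m.min_individuals} carriers)",
            f"  associated at p < {m.alpha:g}: {n_assoc}",
        ]
        if top > 0:
            lines.append("")
            lines.append(self.table.head(top).to_string(index=False))
        return "\n".join(lines)

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def associate(cohort: Cohort, case_label: str, control_label: str,
              alpha: float = 1e-3, min_individuals: int = 2
              ) -> CohortAssociationResults:
    """Functional wrapper: fit a :class:`CohortAssociationModel`."""
    return CohortAssociationModel(cohort, case_label, control_label,
                                  alpha=alpha,
                                  min_individuals=min_individuals).fit()
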