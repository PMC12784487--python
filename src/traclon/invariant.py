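"""Quantification of semi-invariant T cell populations from TRA repertoires.

Two populations are shipped as built-in definitions:

* **CAIT** (Crohn's-associated invariant T) cells — TRAV12-1/TRAJ6 alpha
  chains whose CDR3 matches the wildcard motif ``CVV**A*GGSYIPTF`` ('*'
  matches exactly one arbitrary residue).
* **MAIT** (mucosal-associated invariant T) cells — TRAV1-2/TRAJ33 alpha
  chains, with no CDR3 constraint.

Per-sample "expansion" of a population is the summed template-count
frequency of matching clonotypes within the productive repertoire; a
clonotype-fraction metric is available as an alternative.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from .io import Cohort, ClonotypeKey, Repertoire


@dataclass(frozen=True)
class InvariantCellDefinition:
    """A semi-invariant population: optional V gene, J gene and a
    fixed-length wildcard CDR3 pattern ('*' = any single residue)."""

    name: str
    v_gene: str | None = None
    j_gene: str | None = None
    cdr3_pattern: str | None = None

    def __post_init__(self) -> None:
        if self.v_gene is None and self.j_gene is None and self.cdr3_pattern is None:
            raise ValueError(f"{self.name}: definition is empty")
        if self.cdr3_pattern is not None and len(self.cdr3_pattern) < 1:
            raise ValueError(f"{self.name}: empty cdr3_pattern")


CAIT = InvariantCellDefinition("CAIT", "TRAV12-1", "TRAJ6", "CVV**A*GGSYIPTF")
MAIT = InvariantCellDefinition("MAIT", "TRAV1-2", "TRAJ33", None)

BUILTIN_DEFINITIONS: tuple[InvariantCellDefinition, ...] = (CAIT, MAIT)


@dataclass(frozen=True)
class ExpansionProfile:
    sample_id: str
    definition: str
    matched_clonotype_count: int
    summed_frequency: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.summed_frequency <= 1.0 + 1e-12:
            raise ValueError("summed_frequency outside [0, 1]")


def matches_pattern(cdr3: str, pattern: str) -> bool:
    """Fixed-length wildcard match: same length, and every non-'*' pattern
    position equals the CDR3 residue."""
    if len(cdr3) != len(pattern):
        return False
    return all(p == "*" or p == c for p, c in zip(pattern, cdr3))


def matches_definition(key: ClonotypeKey, defn: InvariantCellDefinition) -> bool:
    """True iff the clonotype satisfies every stated constraint of the
    definition (absent constraints match anything)."""
    if defn.v_gene is not None and key.v_gene != defn.v_gene:
        return False
    if defn.j_gene is not None and key.j_gene != defn.j_gene:
        return False
    if defn.cdr3_pattern is not None and not matches_pattern(key.cdr3_aa,
                                                             defn.cdr3_pattern):
        return False
    return True


def _match_mask(rep: Repertoire, defn: InvariantCellDefinition) -> pd.Series:
    t = rep.table
    mask = t["productive"].copy()
    if defn.v_gene is not None:
        mask &= t["v_gene"] == defn.v_gene
    if defn.j_gene is not None:
        mask &= t["j_gene"] == defn.j_gene
    if defn.cdr3_pattern is not None:
        pat = defn.cdr3_pattern
        mask &= t["cdr3_aa"].apply(lambda s: matches_pattern(s, pat))
    return mask


def quantify_expansion(rep: Repertoire, defn: InvariantCellDefinition,
                       metric: str = "frequency") -> ExpansionProfile:
    """Per-sample expansion of one invariant population.

    ``metric='frequency'`` (default): summed template counts of matching
    clonotypes over the productive total count.  ``metric='clonotype_fraction'``:
    number of matching clonotypes over the number of productive clonotypes.
    """
    if metric not in ("frequency", "clonotype_fraction"):
        raise ValueError(f"unknown metric {metric!r}")
    mask = _match_mask(rep, defn)
    n_matched = int(mask.sum())
    if metric == "frequency":
        denom = rep.total_count
    else:
        denom = rep.n_clonotypes
    if denom == 0:
        raise ValueError(f"{rep.sample_id}: empty repertoire, frequency undefined")
    if metric == "frequency":
        num = int(rep.table.loc[mask, "count"].sum())
    else:
        num = n_matched
    return ExpansionProfile(rep.sample_id, defn.name, n_matched, num / denom)


def cohort_expansion_table(cohort: Cohort,
                           defns: Sequence[InvariantCellDefinition] = BUILTIN_DEFINITIONS,
                           metric: str = "frequency") -> pd.DataFrame:
    """One row per (sample, definition) with the expansion and the sample's
    metadata columns, ready for group comparisons."""
    rows = []
    for sid in cohort.sample_ids:
        rep = cohort.repertoires[sid]
        for defn in defns:
            prof = quantify_expansion(rep, defn, metric=metric)
            rows.append({"sample_id": sid, "definition": defn.name,
                         "matched_clonotypes": prof.matched_clonotype_count,
                         "summed_frequency": prof.summed_frequency})
    cols = ["sample_id", "definition", "matched_clonotypes", "summed_frequency"]
    out = pd.DataFrame(rows, columns=cols)
    if out.empty:
        return out
    return out.merge(cohort.metadata, on="sample_id", how="left")


def read_definitions(path: str | Path) -> list[InvariantCellDefinition]:
    """Read definitions from YAML (list of mappings) or TSV with columns
    name, v_gene, j_gene, cdr3_pattern (empty cell = unconstrained)."""
    path = Path(path)
    if path.suffix.lower() in (".yaml", ".yml"):
        raw = yaml.safe_load(path.read_text())
        entries = raw if isinstance(raw, list) else raw.get("definitions", [])
    else:
        df = pd.read_csv(path, sep="\t", dtype=str)
        entries = df.to_dict("records")
    defs = []
    for e in entries:
        defs.append(InvariantCellDefinition(
            name=str(e["name"]),
            v_gene=_opt(e.get("v_gene")),
            j_gene=_opt(e.get("j_gene")),
            cdr3_pattern=_opt(e.get("cdr3_pattern"))))
    return defs


def _opt(value) -> str | None:
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return None
    s = str(value).strip()
    return s or None
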