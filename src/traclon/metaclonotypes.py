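"""Seeded clustering of associated clonotypes into meta-clonotypes.

Association testing only has power for relatively common public clonotypes.
To pull in rarer clonotypes likely carrying the same signal, each associated
clonotype (the *seed*) is expanded in three steps:

1. every distinct clonotype in the compared repertoires with the same V and
   J genes and a CDR3 within Levenshtein distance 1 of the seed's CDR3 is a
   candidate (seed + candidates = the *unpurified* meta-clonotype);
2. for each candidate a union-presence 2x2 table is formed — a sample is
   positive iff it carries the seed OR the candidate — and scored with the
   same one-sided Fisher test;
3. the candidate is kept iff the union p-value is not larger than the
   seed's own p-value (ties keep).  Seed plus kept candidates form the
   *purified* meta-clonotype.

Purification is pairwise (each candidate judged against the seed alone),
and a clonotype may be a member of several meta-clonotypes.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass

import edlib
import pandas as pd

from .association import CohortAssociationResults, fisher_one_sided
from .io import ClonotypeKey


def levenshtein(a: str, b: str) -> int:
    """Edit distance with unit-cost substitutions, insertions, deletions."""
    if a == b:
        return 0
    if not a or not b:
        return max(len(a), len(b))
    return int(edlib.align(a, b, task="distance")["editDistance"])


@dataclass(frozen=True)
class MemberDecision:
    candidate: ClonotypeKey
    union_p: float
    kept: bool


@dataclass
class MetaClonotype:
    seed: ClonotypeKey
    seed_p: float
    members: set[ClonotypeKey]
    decisions: list[MemberDecision]

    def __post_init__(self) -> None:
        if self.seed not in self.members:
            raise ValueError("seed must be a member of its meta-clonotype")

    @property
    def size(self) -> int:
        return len(self.members)


def extended_search(seed: ClonotypeKey,
                    universe: set[ClonotypeKey]) -> set[ClonotypeKey]:
    """All clonotypes in ``universe`` (other than the seed itself) with the
    seed's V and J genes and CDR3 within Levenshtein distance 1."""
    out = set()
    for key in universe:
        if key == seed:
            continue
        if key.v_gene != seed.v_gene or key.j_gene != seed.j_gene:
            continue
        if abs(len(key.cdr3_aa) - len(seed.cdr3_aa)) > 1:
            continue
        if levenshtein(key.cdr3_aa, seed.cdr3_aa) <= 1:
            out.add(key)
    return out


def purify(seed: ClonotypeKey, candidates: set[ClonotypeKey],
           assoc: CohortAssociationResults,
           seed_p: float | None = None) -> MetaClonotype:
    """Apply the pairwise purification rule to each candidate.

    A sample counts as positive for the (seed, candidate) union iff it
    carries either clonotype; the union table's one-sided Fisher p must not
    exceed the seed's own p for the candidate to be kept.
    """
    index = assoc.index
    if seed_p is None:
        seed_p = assoc.p_for(seed)
    seed_case, seed_ctrl = index.carriers(seed)
    members = {seed}
    decisions: list[MemberDecision] = []
    for cand in sorted(candidates):
        c_case, c_ctrl = index.carriers(cand)
        a = len(seed_case | c_case)
        b = len(seed_ctrl | c_ctrl)
        union_p = fisher_one_sided(a, index.n_case, b, index.n_control)
        kept = union_p <= seed_p
        decisions.append(MemberDecision(cand, union_p, kept))
        if kept:
            members.add(cand)
    return MetaClonotype(seed, seed_p, members, decisions)


def build_metaclonotypes(assoc: CohortAssociationResults,
                         seeds: list[ClonotypeKey] | None = None
                         ) -> list[MetaClonotype]:
    """One purified meta-clonotype per associated seed, in ascending seed
    p-value order.  ``seeds`` defaults to the fitted associated set."""
    if seeds is None:
        seeds = assoc.associated_keys()
    universe = {ClonotypeKey(*t) for t in
                assoc.index.long[["v_gene", "j_gene", "cdr3_aa"]]
                .drop_duplicates().itertuples(index=False)}
    # bucket the universe by (V, J) so each seed only scans its own locus pair
    by_vj: dict[tuple[str, str], set[ClonotypeKey]] = defaultdict(set)
    for key in universe:
        by_vj[(key.v_gene, key.j_gene)].add(key)
    out = []
    for seed in seeds:
        bucket = by_vj.get((seed.v_gene, seed.j_gene), set())
        candidates = extended_search(seed, bucket)
        out.append(purify(seed, candidates, assoc))
    return out


def metaclonotypes_to_frame(metas: list[MetaClonotype]) -> pd.DataFrame:
    """Flatten decisions to a table: one self-row per seed plus one row per
    (seed, candidate) decision."""
    rows = []
    for m in metas:
        rows.append({"seed_v": m.seed.v_gene, "seed_j": m.seed.j_gene,
                     "seed_cdr3": m.seed.cdr3_aa, "seed_p": m.seed_p,
                     "member_v": m.seed.v_gene, "member_j": m.seed.j_gene,
                     "member_cdr3": m.seed.cdr3_aa, "union_p": m.seed_p,
                     "kept": True, "is_seed": True})
        for d in m.decisions:
            rows.append({"seed_v": m.seed.v_gene, "seed_j": m.seed.j_gene,
                         "seed_cdr3": m.seed.cdr3_aa, "seed_p": m.seed_p,
                         "member_v": d.candidate.v_gene,
                         "member_j": d.candidate.j_gene,
                         "member_cdr3": d.candidate.cdr3_aa,
                         "union_p": d.union_p, "kept": d.kept,
                         "is_seed": False})
    cols = ["seed_v", "seed_j", "seed_cdr3", "seed_p", "member_v", "member_j",
            "member_cdr3", "union_p", "kept", "is_seed"]
    return pd.DataFrame(rows, columns=cols)


def flatten_members(metas: list[MetaClonotype]) -> set[ClonotypeKey]:
    """Deduplicated union of all meta-clonotype members (for set scoring)."""
    out: set[ClonotypeKey] = set()
    for m in metas:
        out |= m.members
    return out
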