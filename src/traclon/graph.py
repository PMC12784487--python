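"""Clonotype similarity graphs and CDR3 motif summaries.

Clonotypes are nodes; two clonotypes are joined by an edge iff they share
the same V and J genes and their CDR3 sequences are equal length with
Hamming distance exactly 1.  Connected components (ranked by size) expose
clusters of highly similar chains; each component is summarised by a
per-position residue count matrix and a consensus string in which positions
with more than one observed residue are written '*'.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .io import ClonotypeKey


def hamming(a: str, b: str) -> int | None:
    """Number of mismatching positions for equal-length strings; ``None``
    when lengths differ (no edge is possible)."""
    if len(a) != len(b):
        return None
    return sum(1 for x, y in zip(a, b) if x != y)


@dataclass
class ClonotypeGraph:
    graph: nx.Graph
    #: components ordered by decreasing size, ties by lexicographically
    #: smallest member; singletons are their own component
    components: list[list[ClonotypeKey]]

    @property
    def nodes(self) -> set[ClonotypeKey]:
        return set(self.graph.nodes)

    @property
    def edges(self) -> set[frozenset]:
        return {frozenset(e) for e in self.graph.edges}


def build_graph(keys: set[ClonotypeKey] | list[ClonotypeKey]) -> ClonotypeGraph:
    """Build the same-V/J Hamming-1 similarity graph over a clonotype set."""
    keys = sorted(set(keys))
    g = nx.Graph()
    g.add_nodes_from(keys)
    buckets: dict[tuple[str, str, int], list[ClonotypeKey]] = defaultdict(list)
    for k in keys:
        buckets[(k.v_gene, k.j_gene, len(k.cdr3_aa))].append(k)
    for bucket in buckets.values():
        if len(bucket) < 2:
            continue
        arr = np.frombuffer("".join(k.cdr3_aa for k in bucket).encode("ascii"),
                            dtype=np.uint8).reshape(len(bucket), -1)
        for i in range(len(bucket)):
            dists = (arr[i + 1:] != arr[i]).sum(axis=1)
            for off in np.nonzero(dists == 1)[0]:
                g.add_edge(bucket[i], bucket[i + 1 + int(off)])
    comps = [sorted(c) for c in nx.connected_components(g)]
    comps.sort(key=lambda c: (-len(c), c[0]))
    return ClonotypeGraph(g, comps)


@dataclass
class MotifSummary:
    component_id: int
    n_members: int
    modal_length: int
    #: members whose CDR3 length differs from the modal length (indel
    #: neighbours reachable through shared contacts); excluded from the
    #: matrix because they cannot be column-aligned without an alignment step
    off_length_members: list[ClonotypeKey]
    #: rows = positions (0-based), columns = residues, values = counts over
    #: modal-length members
    matrix: pd.DataFrame
    consensus: str


def motif_summary(component: list[ClonotypeKey] | set[ClonotypeKey],
                  component_id: int = 0) -> MotifSummary:
    """Position frequency matrix and wildcard consensus for one component.

    The matrix is built from members of the modal CDR3 length (smallest
    length wins a tie); a column is written as its residue in the consensus
    when unanimous and as '*' when two or more residues are observed.
    """
    members = sorted(component)
    if not members:
        raise ValueError("empty component")
    lengths = Counter(len(k.cdr3_aa) for k in members)
    modal_length = min(sorted(lengths, key=lambda L: (-lengths[L], L))[:1])
    aligned = [k for k in members if len(k.cdr3_aa) == modal_length]
    off = [k for k in members if len(k.cdr3_aa) != modal_length]
    residues = sorted({ch for k in aligned for ch in k.cdr3_aa})
    mat = pd.DataFrame(0, index=range(modal_length), columns=residues)
    for k in aligned:
        for pos, ch in enumerate(k.cdr3_aa):
            mat.loc[pos, ch] += 1
    consensus = "".join(
        row.index[row > 0][0] if (row > 0).sum() == 1 else "*"
        for _, row in mat.iterrows())
    return MotifSummary(component_id, len(members), modal_length, off, mat,
                        consensus)


def summarize_components(cg: ClonotypeGraph,
                         min_size: int = 1) -> list[MotifSummary]:
    return [motif_summary(comp, component_id=i)
            for i, comp in enumerate(cg.components) if len(comp) >= min_size]


def edges_to_frame(cg: ClonotypeGraph) -> pd.DataFrame:
    comp_of = {}
    for i, comp in enumerate(cg.components):
        for k in comp:
            comp_of[k] = i
    rows = [{"v_gene": a.v_gene, "j_gene": a.j_gene, "cdr3_a": a.cdr3_aa,
             "cdr3_b": b.cdr3_aa, "component": comp_of[a]}
            for a, b in sorted(cg.graph.edges)]
    return pd.DataFrame(rows, columns=["v_gene", "j_gene", "cdr3_a", "cdr3_b",
                                       "component"])


def write_graphml(cg: ClonotypeGraph, path) -> None:
    """Emit the graph as GraphML with v_gene/j_gene/cdr3/component node
    attributes (nodes relabelled to flat strings for serialisation)."""
    comp_of = {}
    for i, comp in enumerate(cg.components):
        for k in comp:
            comp_of[k] = i
    g = nx.Graph()
    for k in cg.graph.nodes:
        g.add_node(f"{k.v_gene}|{k.j_gene}|{k.cdr3_aa}", v_gene=k.v_gene,
                   j_gene=k.j_gene, cdr3=k.cdr3_aa, component=comp_of[k])
    for a, b in cg.graph.edges:
        g.add_edge(f"{a.v_gene}|{a.j_gene}|{a.cdr3_aa}",
                   f"{b.v_gene}|{b.j_gene}|{b.cdr3_aa}")
    nx.write_graphml(g, path)


def motifs_to_frame(summaries: list[MotifSummary]) -> pd.DataFrame:
    """Long-format motif table: (component, position, residue, count)."""
    rows = []
    for s in summaries:
        for pos in s.matrix.index:
            for res in s.matrix.columns:
                n = int(s.matrix.loc[pos, res])
                if n:
                    rows.append({"component": s.component_id, "position": pos,
                                 "residue": res, "count": n})
    return pd.DataFrame(rows, columns=["component", "position", "residue",
                                       "count"])
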