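"""Reading, normalisation and preprocessing of TRA clonotype tables.

The analysis unit everywhere downstream is the *clonotype*: a unique
(V gene, J gene, CDR3 amino acid sequence) triple from the T cell receptor
alpha chain.  Per-sample clonotype tables arrive in the AIRR Rearrangement
TSV dialect as exported by common repertoire pipelines (MiXCR, immunoSEQ);
this module normalises gene names across those dialects, removes
non-productive rearrangements, collapses nucleotide-level variants encoding
the same protein-level chain, and drops under-sampled repertoires.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, NamedTuple

import pandas as pd

logger = logging.getLogger(__name__)

#: The 20 standard amino acid one-letter codes.
STANDARD_AA = frozenset("ACDEFGHIKLMNPQRSTVWY")

#: Letters that may legally appear in a junction string but mark a
#: non-functional chain: '*' (stop codon) and '_' (out-of-frame marker).
NONPRODUCTIVE_CHARS = frozenset("*_")

#: Ambiguity/non-standard letters; clonotypes carrying them cannot take part
#: in motif or edit-distance analyses and are dropped at read time.
AMBIGUOUS_AA = frozenset("BJOUXZ")

_GENE_RE = re.compile(r"^(TR[AB][VJ])(\d+)(?:-(\d+))?$")

#: Recognised column names, in priority order, for each logical field of the
#: AIRR Rearrangement dialect.
AIRR_COLUMN_ALIASES = {
    "v_call": ("v_call", "v_gene", "vGeneName"),
    "j_call": ("j_call", "j_gene", "jGeneName"),
    "junction_aa": ("junction_aa", "cdr3_aa", "aminoAcid"),
    "count": ("duplicate_count", "templates", "count", "cloneCount"),
    "productive": ("productive",),
}


class ClonotypeKey(NamedTuple):
    """Identity of a clonotype: normalized V gene, J gene and CDR3 sequence.

    Two keys are equal iff all three fields are equal; this identity is used
    for collapsing, incidence counting, clustering and graph construction.
    """

    v_gene: str
    j_gene: str
    cdr3_aa: str


@dataclass(frozen=True)
class ClonotypeRecord:
    key: ClonotypeKey
    count: int
    productive: bool = True

    def __post_init__(self) -> None:
        if self.count < 0:
            raise ValueError(f"negative clonotype count: {self.count}")


_REP_COLUMNS = ["v_gene", "j_gene", "cdr3_aa", "count", "productive"]


@dataclass
class Repertoire:
    """One sample's clonotype table.

    ``table`` has columns ``v_gene, j_gene, cdr3_aa, count, productive``.
    Before :func:`collapse_clonotypes` the same key may occupy several rows
    (nucleotide-level variants); afterwards rows are unique per key.
    """

    sample_id: str
    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in _REP_COLUMNS if c not in self.table.columns]
        if missing:
            raise ValueError(f"repertoire table missing columns {missing}")
        self.table = self.table[_REP_COLUMNS].reset_index(drop=True)

    @property
    def total_count(self) -> int:
        """Sum of template counts over productive records."""
        t = self.table
        return int(t.loc[t["productive"], "count"].sum())

    @property
    def n_clonotypes(self) -> int:
        """Number of distinct productive clonotype keys."""
        t = self.table.loc[self.table["productive"]]
        return int(t.drop_duplicates(["v_gene", "j_gene", "cdr3_aa"]).shape[0])

    def keys(self) -> list[ClonotypeKey]:
        t = self.table.drop_duplicates(["v_gene", "j_gene", "cdr3_aa"])
        return [ClonotypeKey(v, j, c) for v, j, c in
                zip(t["v_gene"], t["j_gene"], t["cdr3_aa"])]

    def records(self) -> list[ClonotypeRecord]:
        return [
            ClonotypeRecord(ClonotypeKey(r.v_gene, r.j_gene, r.cdr3_aa),
                            int(r.count), bool(r.productive))
            for r in self.table.itertuples(index=False)
        ]

    @classmethod
    def from_records(cls, sample_id: str,
                     records: Iterable[ClonotypeRecord]) -> "Repertoire":
        rows = [(r.key.v_gene, r.key.j_gene, r.key.cdr3_aa, r.count,
                 r.productive) for r in records]
        return cls(sample_id,
                   pd.DataFrame(rows, columns=_REP_COLUMNS))


METADATA_COLUMNS = ["sample_id", "cohort_id", "phenotype", "pair_id", "age",
                    "sex", "subphenotype"]


@dataclass
class Cohort:
    """A set of repertoires with per-sample phenotype metadata."""

    cohort_id: str
    repertoires: dict[str, Repertoire]
    metadata: pd.DataFrame  # one row per sample_id

    def __post_init__(self) -> None:
        meta_ids = list(self.metadata["sample_id"])
        if len(meta_ids) != len(set(meta_ids)):
            raise ValueError("duplicate sample_id in metadata")
        missing = set(self.repertoires) - set(meta_ids)
        if missing:
            raise ValueError(f"repertoires without metadata: {sorted(missing)[:5]}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.repertoires)

    def samples_with_label(self, label: str) -> list[str]:
        m = self.metadata
        ids = m.loc[m["phenotype"] == label, "sample_id"]
        return [s for s in ids if s in self.repertoires]

    def subset(self, sample_ids: Iterable[str]) -> "Cohort":
        keep = [s for s in self.sample_ids if s in set(sample_ids)]
        meta = self.metadata[self.metadata["sample_id"].isin(keep)].copy()
        return Cohort(self.cohort_id, {s: self.repertoires[s] for s in keep},
                      meta.reset_index(drop=True))


def normalize_gene_name(raw: str) -> str:
    """Normalise a TRA gene symbol across annotation dialects.

    Strips the allele designation after ``*``, removes zero padding from
    family/gene numbers (``TRAV01-02`` → ``TRAV1-2``) and upper-cases the
    symbol.  ``/DV`` composite designations are preserved verbatim.  J genes
    carry no gene subnumber in the reference nomenclature, so a ``-NN``
    suffix on a TRAJ symbol (immunoSEQ style, e.g. ``TRAJ06-01``) is
    dropped: ``TRAJ06-01`` → ``TRAJ6``.
    """
    if not raw or not str(raw).strip():
        raise ValueError("empty gene name")
    name = str(raw).strip().upper()
    name = name.split("*", 1)[0]  # drop allele
    dv_suffix = ""
    if "/DV" in name:
        name, dv = name.split("/DV", 1)
        dv_suffix = "/DV" + dv
    m = _GENE_RE.match(name)
    if m is None:
        # unknown shape: return allele-stripped uppercase form untouched
        return name + dv_suffix
    locus, fam, gene = m.groups()
    fam = str(int(fam))
    if gene is None:
        return f"{locus}{fam}{dv_suffix}"
    if locus.endswith("J"):
        # J segments have no subnumber: the '-NN' is a dialect artefact
        return f"{locus}{fam}{dv_suffix}"
    return f"{locus}{fam}-{int(gene)}{dv_suffix}"


def derive_productive(cdr3_aa: str) -> bool:
    """A junction is non-productive iff it contains a stop ('*') or
    frameshift ('_') marker."""
    return not any(ch in NONPRODUCTIVE_CHARS for ch in cdr3_aa)


def _resolve_column(columns: list[str], logical: str,
                    required: bool) -> str | None:
    for alias in AIRR_COLUMN_ALIASES[logical]:
        if alias in columns:
            return alias
    if required:
        raise ValueError(
            f"input table lacks a recognised '{logical}' column "
            f"(looked for {AIRR_COLUMN_ALIASES[logical]})")
    return None


_TRUTHY = {"t", "true", "1", "yes", "y"}


def read_airr_repertoire(path: str | Path, sample_id: str) -> Repertoire:
    """Read one sample's AIRR Rearrangement TSV into a :class:`Repertoire`.

    Column aliases are resolved per :data:`AIRR_COLUMN_ALIASES`; a missing
    count column defaults every row to count 1; a missing productive column
    derives productivity from stop/frameshift characters in the junction.
    Rows whose junction contains ambiguity letters (B, J, O, U, X, Z) or is
    empty are dropped with a logged warning.
    """
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    except OSError as exc:
        raise OSError(f"cannot read repertoire file {path}: {exc}") from exc
    cols = list(df.columns)
    v_col = _resolve_column(cols, "v_call", required=True)
    j_col = _resolve_column(cols, "j_call", required=True)
    cdr3_col = _resolve_column(cols, "junction_aa", required=True)
    count_col = _resolve_column(cols, "count", required=False)
    prod_col = _resolve_column(cols, "productive", required=False)

    cdr3 = df[cdr3_col].fillna("").str.strip().str.upper()
    bad_empty = cdr3 == ""
    bad_ambig = cdr3.apply(lambda s: any(ch in AMBIGUOUS_AA for ch in s))
    drop = bad_empty | bad_ambig
    if drop.any():
        logger.warning("%s: dropped %d rows with empty or ambiguous junctions",
                       sample_id, int(drop.sum()))
    df = df.loc[~drop].reset_index(drop=True)
    cdr3 = cdr3[~drop].reset_index(drop=True)

    if count_col is None:
        counts = pd.Series(1, index=df.index)
    else:
        counts = pd.to_numeric(df[count_col], errors="coerce").fillna(1)
        counts = counts.round().astype(int).clip(lower=0)
    if prod_col is None:
        productive = cdr3.apply(derive_productive)
    else:
        productive = df[prod_col].fillna("").str.strip().str.lower().isin(_TRUTHY)

    table = pd.DataFrame({
        "v_gene": df[v_col].apply(normalize_gene_name),
        "j_gene": df[j_col].apply(normalize_gene_name),
        "cdr3_aa": cdr3,
        "count": counts.astype(int),
        "productive": productive.astype(bool),
    })
    return Repertoire(sample_id, table)


def write_airr_repertoire(rep: Repertoire, path: str | Path) -> None:
    """Write a repertoire back out as AIRR Rearrangement TSV."""
    out = rep.table.rename(columns={"v_gene": "v_call", "j_gene": "j_call",
                                    "cdr3_aa": "junction_aa",
                                    "count": "duplicate_count"})
    out["productive"] = out["productive"].map({True: "T", False: "F"})
    out.to_csv(path, sep="\t", index=False)


def filter_productive(rep: Repertoire) -> Repertoire:
    """Remove non-productive clonotypes (frameshift or stop codon)."""
    table = rep.table.loc[rep.table["productive"]].reset_index(drop=True)
    return Repertoire(rep.sample_id, table)


def collapse_clonotypes(rep: Repertoire) -> Repertoire:
    """Merge rows encoding the same protein-level chain.

    Different VJ recombination encodings (nucleotide variants) of the same
    (V, J, CDR3aa) triple are grouped into a single clonotype and their
    template counts summed.
    """
    grouped = (rep.table
               .groupby(["v_gene", "j_gene", "cdr3_aa", "productive"],
                        as_index=False, sort=True)["count"].sum())
    return Repertoire(rep.sample_id, grouped)


def preprocess_repertoire(rep: Repertoire) -> Repertoire:
    """Productive filter followed by protein-level collapsing."""
    return collapse_clonotypes(filter_productive(rep))


def apply_depth_filter(cohort: Cohort, min_clonotypes: int = 1000) -> Cohort:
    """Drop samples with fewer than ``min_clonotypes`` distinct productive
    clonotypes (strict 'fewer than': a sample at the threshold is kept)."""
    keep = [s for s, rep in cohort.repertoires.items()
            if rep.n_clonotypes >= min_clonotypes]
    removed = sorted(set(cohort.sample_ids) - set(keep))
    if removed:
        logger.info("%s: depth filter removed %d samples: %s",
                    cohort.cohort_id, len(removed), removed[:10])
    out = cohort.subset(keep)
    if not out.repertoires:
        logger.warning("%s: depth filter removed every sample", cohort.cohort_id)
    return out


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read the cohort metadata CSV (sample_id, cohort_id, phenotype and
    optional pair_id, age, sex, subphenotype columns)."""
    meta = pd.read_csv(path, dtype=str, comment="#")
    for col in ("sample_id", "cohort_id", "phenotype"):
        if col not in meta.columns:
            raise ValueError(f"metadata lacks required column '{col}'")
    return meta


def load_cohort(metadata: str | Path | pd.DataFrame, input_dir: str | Path,
                cohort_id: str | None = None) -> Cohort:
    """Load a cohort from a metadata table and a directory of per-sample
    AIRR TSVs named ``<sample_id>.tsv``.  sample_id comes from the metadata,
    never from file contents."""
    meta = metadata if isinstance(metadata, pd.DataFrame) else read_metadata(metadata)
    if cohort_id is not None:
        meta = meta[meta["cohort_id"] == cohort_id]
    ids = meta["cohort_id"].unique()
    if len(ids) != 1:
        raise ValueError(f"metadata covers cohorts {list(ids)}; pass cohort_id")
    input_dir = Path(input_dir)
    reps = {}
    for sid in meta["sample_id"]:
        reps[sid] = read_airr_repertoire(input_dir / f"{sid}.tsv", sid)
    return Cohort(str(ids[0]), reps, meta.reset_index(drop=True))


def preprocess_cohort(cohort: Cohort, min_clonotypes: int = 1000
                      ) -> tuple[Cohort, pd.DataFrame]:
    """Apply the three preprocessing rules to every repertoire and return the
    surviving cohort plus a per-sample report table."""
    rows = []
    processed: dict[str, Repertoire] = {}
    for sid, rep in cohort.repertoires.items():
        n_raw = len(rep.table)
        prod = filter_productive(rep)
        coll = collapse_clonotypes(prod)
        processed[sid] = coll
        rows.append({"sample_id": sid, "n_raw": n_raw,
                     "n_productive": len(prod.table),
                     "n_collapsed": len(coll.table),
                     "retained": coll.n_clonotypes >= min_clonotypes})
    pre = Cohort(cohort.cohort_id, processed, cohort.metadata.copy())
    filtered = apply_depth_filter(pre, min_clonotypes)
    report = pd.DataFrame(rows, columns=["sample_id", "n_raw", "n_productive",
                                         "n_collapsed", "retained"])
    return filtered, report
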