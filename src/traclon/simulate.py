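"""Synthetic multi-cohort TRA repertoire generator with known ground truth.

Real IBD repertoire cohorts are access-restricted, so every pipeline stage
is exercised on simulated data that emulates the statistical structure the
analyses assume:

* a shared pool of *background* public clonotypes whose population carriage
  probabilities follow a right-skewed Beta distribution (most public
  clonotypes are rare, a few are common);
* *spiked* clonotypes carried at a higher rate in cases than controls
  (incidence effect — the scale the Fisher test operates on), shared across
  cohorts with optional per-cohort attenuation;
* *CAIT-like* clonotypes constructed to satisfy the CAIT definition
  (TRAV12-1/TRAJ6, CDR3 matching ``CVV**A*GGSYIPTF``) and forming a
  Hamming-1 family around a base sequence; they receive both a carriage
  differential and a template-count multiplier in cases (expansion effect —
  the scale the Mann-Whitney comparisons operate on);
* per-sample *private* filler clonotypes and heavy-tailed (log-normal)
  clonal abundances, plus a configurable fraction of non-productive decoy
  records for preprocessing tests.

Identical config + seed yields byte-identical output trees.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .invariant import CAIT, matches_definition
from .io import Cohort, ClonotypeKey, Repertoire

_AA = np.array(list("ACDEFGHIKLMNPQRSTVWY"))

#: normalized TRA V/J gene catalogues used for background and filler keys
DEFAULT_V_GENES: tuple[str, ...] = tuple(
    ["TRAV1-1", "TRAV1-2", "TRAV2", "TRAV3", "TRAV4", "TRAV5", "TRAV6",
     "TRAV8-1", "TRAV8-2", "TRAV8-3", "TRAV8-4", "TRAV8-6", "TRAV9-1",
     "TRAV9-2", "TRAV10", "TRAV12-1", "TRAV12-2", "TRAV12-3", "TRAV13-1",
     "TRAV13-2", "TRAV14/DV4", "TRAV16", "TRAV17", "TRAV18", "TRAV19",
     "TRAV20", "TRAV21", "TRAV22", "TRAV23/DV6", "TRAV24", "TRAV25",
     "TRAV26-1", "TRAV26-2", "TRAV27", "TRAV29/DV5", "TRAV30", "TRAV34",
     "TRAV35", "TRAV36/DV7", "TRAV38-1", "TRAV38-2/DV8", "TRAV39",
     "TRAV40", "TRAV41"])
DEFAULT_J_GENES: tuple[str, ...] = tuple(
    f"TRAJ{i}" for i in [3, 4, 5, 6, 7, 8, 9, 10, 11, 12, 13, 15, 16, 17,
                         18, 20, 21, 22, 23, 24, 26, 27, 28, 29, 30, 31,
                         32, 33, 34, 36, 37, 38, 39, 40, 41, 42, 43, 44,
                         45, 46, 47, 48, 49, 50, 52, 53, 54, 56, 57, 58])

#: wildcard positions (0-based) of the CAIT CDR3 motif
_CAIT_PATTERN = CAIT.cdr3_pattern
_CAIT_WILDCARDS = tuple(i for i, ch in enumerate(_CAIT_PATTERN) if ch == "*")


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one simulated multi-cohort dataset.

    ``q_case``/``q_control`` are the per-cohort carriage probabilities of
    spiked clonotypes (scalar = same in every cohort); ``cait_q_*`` play the
    same role for the CAIT-like family, whose per-sample template counts in
    cases are additionally multiplied by ``cait_case_multiplier``.
    """

    seed: int = 0
    n_cohorts: int = 3
    n_case: int = 60
    n_control: int = 60
    case_label: str = "CD"
    control_label: str = "control"
    repertoire_size: int = 2000
    background_pool_size: int = 20000
    incidence_alpha: float = 0.3
    incidence_beta: float = 15.0
    clonal_mu: float = 1.0
    clonal_sigma: float = 1.5
    n_spiked: int = 20
    q_case: float | Sequence[float] = 0.4
    q_control: float | Sequence[float] = 0.05
    n_cait_like: int = 8
    cait_q_case: float = 0.75
    cait_q_control: float = 0.35
    cait_case_multiplier: float = 5.0
    nonproductive_fraction: float = 0.02
    paired: bool = False
    cdr3_len_mean: float = 14.0
    cdr3_len_sd: float = 2.0
    cdr3_len_min: int = 8
    cdr3_len_max: int = 22
    v_genes: tuple[str, ...] = DEFAULT_V_GENES
    j_genes: tuple[str, ...] = DEFAULT_J_GENES

    def per_cohort(self, value, name: str) -> list[float]:
        if np.isscalar(value):
            vals = [float(value)] * self.n_cohorts
        else:
            vals = [float(v) for v in value]
            if len(vals) != self.n_cohorts:
                raise ValueError(f"{name}: need {self.n_cohorts} values")
        for v in vals:
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}: probability {v} outside [0, 1]")
        return vals

    def validate(self) -> None:
        if self.n_cohorts < 1:
            raise ValueError("n_cohorts must be >= 1")
        for name in ("n_case", "n_control", "repertoire_size",
                     "background_pool_size", "n_spiked", "n_cait_like"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.cait_case_multiplier < 1.0:
            raise ValueError("cait_case_multiplier must be >= 1")
        if not 0.0 <= self.nonproductive_fraction < 1.0:
            raise ValueError("nonproductive_fraction outside [0, 1)")
        self.per_cohort(self.q_case, "q_case")
        self.per_cohort(self.q_control, "q_control")
        self.per_cohort(self.cait_q_case, "cait_q_case")
        self.per_cohort(self.cait_q_control, "cait_q_control")


def null_config(**overrides) -> SimulationConfig:
    """A no-signal variant: no spiked clonotypes, CAIT family carried and
    expanded identically in both groups."""
    base = dict(n_spiked=0, cait_case_multiplier=1.0, cait_q_case=0.5,
                cait_q_control=0.5)
    base.update(overrides)
    return SimulationConfig(**base)


PRESETS = {
    # spec'd desk-scale conditions: 3 cohorts of 60/60, 2,000-clonotype
    # repertoires over a 20,000-clonotype public background
    "default-3cohort": lambda: SimulationConfig(),
    # acceptance-scale spiked design: 100 cases/100 controls per cohort
    "spiked-100": lambda: SimulationConfig(
        n_case=100, n_control=100, background_pool_size=4000,
        repertoire_size=1200),
    "null-small": lambda: null_config(
        n_case=30, n_control=30, background_pool_size=1000,
        repertoire_size=300),
}


def _random_cdr3(rng: np.random.Generator, length: int) -> str:
    middle = "".join(rng.choice(_AA, size=max(length - 2, 0)))
    return "C" + middle + "F"


def _draw_length(rng: np.random.Generator, config: SimulationConfig) -> int:
    L = int(round(rng.normal(config.cdr3_len_mean, config.cdr3_len_sd)))
    return int(np.clip(L, config.cdr3_len_min, config.cdr3_len_max))


def _random_keys(rng: np.random.Generator, config: SimulationConfig,
                 n: int) -> list[tuple[str, str, str]]:
    """Vectorised draw of n (V, J, CDR3) triples: random catalogue genes and
    random-length CDR3s framed by the canonical C...F residues."""
    if n == 0:
        return []
    v_idx = rng.integers(0, len(config.v_genes), size=n)
    j_idx = rng.integers(0, len(config.j_genes), size=n)
    lengths = np.clip(np.round(rng.normal(config.cdr3_len_mean,
                                          config.cdr3_len_sd, size=n)),
                      config.cdr3_len_min, config.cdr3_len_max).astype(int)
    middles = lengths - 2
    letters = _AA[rng.integers(0, len(_AA), size=int(middles.sum()))]
    out = []
    pos = 0
    for i in range(n):
        m = int(middles[i])
        out.append((config.v_genes[int(v_idx[i])],
                    config.j_genes[int(j_idx[i])],
                    "C" + "".join(letters[pos:pos + m]) + "F"))
        pos += m
    return out


def _cait_family(rng: np.random.Generator, n: int,
                 max_tries: int = 1000) -> list[ClonotypeKey]:
    """A base motif-conforming CDR3 plus variants differing from it at
    exactly one wildcard position (a Hamming-1 star, all matching the CAIT
    pattern)."""
    base = list(_CAIT_PATTERN)
    for pos in _CAIT_WILDCARDS:
        base[pos] = str(rng.choice(_AA))
    keys = [ClonotypeKey(CAIT.v_gene, CAIT.j_gene, "".join(base))]
    seen = {keys[0].cdr3_aa}
    tries = 0
    while len(keys) < n:
        tries += 1
        if tries > max_tries:
            raise RuntimeError("could not build a distinct CAIT family")
        pos = int(_CAIT_WILDCARDS[(len(keys) - 1) % len(_CAIT_WILDCARDS)])
        variant = list(keys[0].cdr3_aa)
        variant[pos] = str(rng.choice(_AA))
        cdr3 = "".join(variant)
        if cdr3 in seen:
            continue
        seen.add(cdr3)
        keys.append(ClonotypeKey(CAIT.v_gene, CAIT.j_gene, cdr3))
    return keys


def generate_pool(config: SimulationConfig, rng: np.random.Generator
                  ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Build the shared clonotype pool and its truth table.

    Returns ``(pool, truth)``: ``pool`` has one row per clonotype with role
    and per-cohort carriage probabilities (columns ``q_case_<c>`` /
    ``q_control_<c>``); ``truth`` is the same minus internal columns.
    """
    config.validate()
    rows: list[dict] = []
    seen: set[tuple[str, str, str]] = set()

    def _add(key: ClonotypeKey, role: str, qc: list[float], qk: list[float]):
        t = (key.v_gene, key.j_gene, key.cdr3_aa)
        if t in seen:
            return False
        seen.add(t)
        row = {"v_gene": key.v_gene, "j_gene": key.j_gene,
               "cdr3_aa": key.cdr3_aa, "role": role}
        for i in range(config.n_cohorts):
            row[f"q_case_{i}"] = qc[i]
            row[f"q_control_{i}"] = qk[i]
        rows.append(row)
        return True

    # background: same carriage probability in cases and controls
    n_bg = 0
    tries = 0
    while n_bg < config.background_pool_size:
        tries += 1
        if tries > 20:
            raise RuntimeError("pool collision retry budget exhausted")
        batch = _random_keys(rng, config, config.background_pool_size - n_bg)
        for v, j, c in batch:
            q = float(rng.beta(config.incidence_alpha, config.incidence_beta))
            q = min(max(q, 1e-4), 0.999)
            if _add(ClonotypeKey(v, j, c), "background",
                    [q] * config.n_cohorts, [q] * config.n_cohorts):
                n_bg += 1

    qc = config.per_cohort(config.q_case, "q_case")
    qk = config.per_cohort(config.q_control, "q_control")
    n_sp = 0
    tries = 0
    while n_sp < config.n_spiked:
        tries += 1
        if tries > 20:
            raise RuntimeError("pool collision retry budget exhausted")
        for v, j, c in _random_keys(rng, config, config.n_spiked - n_sp):
            if _add(ClonotypeKey(v, j, c), "spiked", qc, qk):
                n_sp += 1

    cqc = config.per_cohort(config.cait_q_case, "cait_q_case")
    cqk = config.per_cohort(config.cait_q_control, "cait_q_control")
    if config.n_cait_like:
        for key in _cait_family(rng, config.n_cait_like):
            if not _add(key, "cait_like", cqc, cqk):
                raise RuntimeError("CAIT family collided with pool")

    pool = pd.DataFrame(rows)
    for key in pool.loc[pool["role"] == "cait_like"].itertuples(index=False):
        assert matches_definition(
            ClonotypeKey(key.v_gene, key.j_gene, key.cdr3_aa), CAIT)
    return pool, pool.copy()


def generate_sample(pool: pd.DataFrame, phenotype: str, cohort_idx: int,
                    config: SimulationConfig, rng: np.random.Generator,
                    sample_id: str,
                    reuse: tuple[np.ndarray, np.ndarray] | None = None
                    ) -> tuple[Repertoire, tuple[np.ndarray, np.ndarray]]:
    """Draw one repertoire.

    Pool clonotypes are independently present with their phenotype- and
    cohort-specific carriage probability; present clonotypes get counts
    ``1 + Poisson(w)`` with log-normal clonal weights ``w`` (multiplied by
    ``cait_case_multiplier`` for the CAIT family in cases); private fillers
    top the repertoire up to ``repertoire_size`` distinct clonotypes, and a
    configurable fraction of non-productive decoy rows is appended.

    ``reuse=(present, weights)`` regenerates a correlated repertoire (same
    carriage and clonal weights, fresh count noise) for paired designs.
    """
    is_case = phenotype == config.case_label
    qcol = (f"q_case_{cohort_idx}" if is_case else f"q_control_{cohort_idx}")
    if reuse is None:
        present = rng.random(len(pool)) < pool[qcol].to_numpy()
        weights = rng.lognormal(config.clonal_mu, config.clonal_sigma,
                                size=int(present.sum()))
    else:
        present, weights = reuse
    sub = pool.loc[present, ["v_gene", "j_gene", "cdr3_aa", "role"]].copy()
    w = weights.copy()
    if is_case and config.cait_case_multiplier != 1.0:
        w = np.where(sub["role"].to_numpy() == "cait_like",
                     w * config.cait_case_multiplier, w)
    counts = 1 + rng.poisson(w)

    n_fill = max(config.repertoire_size - len(sub), 0)
    fill_rows = _random_keys(rng, config, n_fill)
    fill_w = rng.lognormal(config.clonal_mu, config.clonal_sigma, size=n_fill)
    fill_counts = 1 + rng.poisson(fill_w)

    table = pd.DataFrame({
        "v_gene": list(sub["v_gene"]) + [r[0] for r in fill_rows],
        "j_gene": list(sub["j_gene"]) + [r[1] for r in fill_rows],
        "cdr3_aa": list(sub["cdr3_aa"]) + [r[2] for r in fill_rows],
        "count": np.concatenate([counts, fill_counts]).astype(int),
    })
    table["productive"] = True
    table = table.drop_duplicates(["v_gene", "j_gene", "cdr3_aa"],
                                  keep="first").reset_index(drop=True)

    n_np = int(round(config.nonproductive_fraction * len(table)))
    if n_np:
        np_rows = []
        for v, j, cdr3 in _random_keys(rng, config, n_np):
            pos = int(rng.integers(1, len(cdr3)))
            cdr3 = cdr3[:pos] + "*" + cdr3[pos:]
            np_rows.append((v, j, cdr3,
                            int(1 + rng.poisson(
                                rng.lognormal(config.clonal_mu,
                                              config.clonal_sigma))), False))
        table = pd.concat([table, pd.DataFrame(
            np_rows, columns=["v_gene", "j_gene", "cdr3_aa", "count",
                              "productive"])], ignore_index=True)
    return Repertoire(sample_id, table), (present, weights)


def generate_cohorts(config: SimulationConfig,
                     out_dir: str | Path | None = None
                     ) -> tuple[list[Cohort], pd.DataFrame]:
    """Generate ``n_cohorts`` cohorts sharing the spiked/CAIT-like keys.

    When ``out_dir`` is given, each cohort is written as a directory of
    AIRR TSVs plus a ``metadata.csv``, with ``truth_table.tsv`` and the
    resolved ``config.yaml`` at the root.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    pool, truth = generate_pool(config, rng)
    cohorts = []
    for ci in range(config.n_cohorts):
        cohort_id = f"C{ci + 1}"
        reps: dict[str, Repertoire] = {}
        meta_rows = []
        for gi, (label, n) in enumerate([(config.case_label, config.n_case),
                                         (config.control_label,
                                          config.n_control)]):
            for si in range(n):
                sid = f"{cohort_id}_{label}_{si:03d}"
                rep, state = generate_sample(pool, label, ci, config, rng, sid)
                reps[sid] = rep
                pair_id = ""
                if config.paired and label == config.case_label:
                    pair_id = sid
                    fid = sid + "_followup"
                    frep, _ = generate_sample(pool, label, ci, config, rng,
                                              fid, reuse=state)
                    reps[fid] = frep
                    meta_rows.append({"sample_id": fid, "cohort_id": cohort_id,
                                      "phenotype": label, "pair_id": pair_id,
                                      "age": "", "sex": "",
                                      "subphenotype": "followup"})
                meta_rows.append({"sample_id": sid, "cohort_id": cohort_id,
                                  "phenotype": label, "pair_id": pair_id,
                                  "age": "", "sex": "",
                                  "subphenotype": "baseline" if pair_id else ""})
        meta = pd.DataFrame(meta_rows, columns=["sample_id", "cohort_id",
                                                "phenotype", "pair_id", "age",
                                                "sex", "subphenotype"])
        meta = meta.sort_values("sample_id", kind="mergesort").reset_index(drop=True)
        cohorts.append(Cohort(cohort_id, dict(sorted(reps.items())), meta))

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        from .io import write_airr_repertoire
        for cohort in cohorts:
            cdir = out_dir / cohort.cohort_id
            cdir.mkdir(parents=True, exist_ok=True)
            for sid, rep in cohort.repertoires.items():
                write_airr_repertoire(rep, cdir / f"{sid}.tsv")
            cohort.metadata.to_csv(cdir / "metadata.csv", index=False)
        truth.to_csv(out_dir / "truth_table.tsv", sep="\t", index=False)
        resolved = {k: (list(v) if isinstance(v, tuple) else v)
                    for k, v in vars(config).items()}
        (out_dir / "config.yaml").write_text(
            yaml.safe_dump(resolved, sort_keys=True))
    return cohorts, truth


def truth_keys(truth: pd.DataFrame, role: str) -> set[ClonotypeKey]:
    sel = truth[truth["role"] == role]
    return {ClonotypeKey(r.v_gene, r.j_gene, r.cdr3_aa)
            for r in sel.itertuples(index=False)}
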