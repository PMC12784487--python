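from __future__ import annotations

import pandas as pd
import pytest

from traclon.io import Cohort, ClonotypeKey, Repertoire


def make_repertoire(sample_id, rows):
    """rows: iterable of (v, j, cdr3, count[, productive])."""
    recs = []
    for row in rows:
        v, j, c, n = row[:4]
        prod = row[4] if len(row) > 4 else True
        recs.append((v, j, c, n, prod))
    table = pd.DataFrame(recs, columns=["v_gene", "j_gene", "cdr3_aa",
                                        "count", "productive"])
    return Repertoire(sample_id, table)


def make_cohort(samples, cohort_id="T"):
    """samples: mapping sample_id -> (phenotype, rows)."""
    reps = {sid: make_repertoire(sid, rows)
            for sid, (label, rows) in samples.items()}
    meta = pd.DataFrame({"sample_id": list(samples),
                         "cohort_id": cohort_id,
                         "phenotype": [label for label, _ in samples.values()]})
    return Cohort(cohort_id, reps, meta)


def carrier_cohort(case_carriers, n_case, control_carriers, n_control,
                   keys, filler_key=("TRAV2", "TRAJ4", "CFILLERF"),
                   cohort_id="T", case_label="CD", control_label="control"):
    """Build a cohort where ``keys[i]`` is carried by the sample index sets
    ``case_carriers[i]`` / ``control_carriers[i]``.  Every sample also
    carries a shared filler clonotype so no repertoire is empty."""
    samples = {}
    fv, fj, fc = filler_key
    for i in range(n_case):
        rows = [(fv, fj, fc, 1)]
        for key, carriers in zip(keys, case_carriers):
            if i in carriers:
                rows.append((key.v_gene, key.j_gene, key.cdr3_aa, 2))
        samples[f"case{i:02d}"] = (case_label, rows)
    for i in range(n_control):
        rows = [(fv, fj, fc, 1)]
        for key, carriers in zip(keys, control_carriers):
            if i in carriers:
                rows.append((key.v_gene, key.j_gene, key.cdr3_aa, 2))
        samples[f"ctrl{i:02d}"] = (control_label, rows)
    return make_cohort(samples, cohort_id)


@pytest.fixture
def toy_repertoire():
    return make_repertoire("s1", [
        ("TRAV12-1", "TRAJ6", "CVVADAGGSYIPTF", 3),
        ("TRAV12-1", "TRAJ6", "CVVADAGGSYIPTF", 2),
        ("TRAV1-2", "TRAJ33", "CAVMDSNYQLIW", 4),
        ("TRAV2", "TRAJ4", "CAVR*GSF", 1, False),
    ])
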