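import numpy as np
import pandas as pd
import pytest

from traclon.io import ClonotypeKey
from traclon.stats import (ClonotypeSet, compare_groups, expansion_table,
                           mann_whitney_u, set_expansion, wilcoxon_paired)

from conftest import carrier_cohort, make_cohort, make_repertoire
from oracles import mann_whitney_exact_two_sided, wilcoxon_exact_two_sided

K1 = ClonotypeKey("TRAV2", "TRAJ4", "CAAAAF")
K2 = ClonotypeKey("TRAV3", "TRAJ5", "CGGGGF")
K3 = ClonotypeKey("TRAV5", "TRAJ7", "CTTTTF")


def test_set_expansion_examples():
    rep = make_repertoire("s1", [
        ("TRAV2", "TRAJ4", "CAAAAF", 3),
        ("TRAV3", "TRAJ5", "CGGGGF", 7),
        ("TRAV5", "TRAJ7", "CTTTTF", 90)])
    cset = ClonotypeSet("cd", frozenset({K1, K2}))
    assert set_expansion(rep, cset) == pytest.approx(0.10)
    assert set_expansion(rep, ClonotypeSet("all", frozenset({K1, K2, K3}))) == 1.0
    miss = ClonotypeSet("none", frozenset({ClonotypeKey("TRAV9-1", "TRAJ3",
                                                        "CWWWWF")}))
    assert set_expansion(rep, miss) == 0.0


def test_set_expansion_additive_over_disjoint_sets():
    rep = make_repertoire("s1", [
        ("TRAV2", "TRAJ4", "CAAAAF", 5),
        ("TRAV3", "TRAJ5", "CGGGGF", 5),
        ("TRAV5", "TRAJ7", "CTTTTF", 10)])
    a = set_expansion(rep, ClonotypeSet("a", frozenset({K1})))
    b = set_expansion(rep, ClonotypeSet("b", frozenset({K2})))
    ab = set_expansion(rep, ClonotypeSet("ab", frozenset({K1, K2})))
    assert ab == pytest.approx(a + b)


def test_empty_set_rejected():
    with pytest.raises(ValueError):
        ClonotypeSet("empty", frozenset())


def test_mann_whitney_micro_example():
    cmp = mann_whitney_u([1, 2, 3], [4, 5, 6])
    assert cmp.statistic == 0.0
    assert cmp.p_value == pytest.approx(0.1)


def test_mann_whitney_identical_samples():
    cmp = mann_whitney_u([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
    assert cmp.p_value == pytest.approx(1.0, abs=0.05)


def test_mann_whitney_extreme_shift_reaches_enumerable_minimum():
    from math import comb
    x = [1, 2, 3, 4]
    y = [100, 101, 102, 103]
    cmp = mann_whitney_u(x, y)
    assert cmp.p_value == pytest.approx(2 / comb(8, 4))


def test_mann_whitney_matches_enumeration_oracle():
    rng = np.random.default_rng(13)
    for _ in range(30):
        n = int(rng.integers(2, 6))
        m = int(rng.integers(2, 6))
        vals = rng.permutation(100)[:n + m].astype(float)
        x, y = list(vals[:n]), list(vals[n:])
        assert mann_whitney_u(x, y).p_value == pytest.approx(
            mann_whitney_exact_two_sided(x, y), abs=1e-12)


def test_mann_whitney_empty_sample_errors():
    with pytest.raises(ValueError):
        mann_whitney_u([], [1.0])


def test_wilcoxon_micro_example():
    cmp = wilcoxon_paired([0, 0, 0], [1, 2, 3])
    assert cmp.p_value == pytest.approx(0.25)
    assert cmp.paired


def test_wilcoxon_degenerate_all_zero():
    cmp = wilcoxon_paired([1.0, 2.0], [1.0, 2.0])
    assert cmp.p_value == 1.0
    assert cmp.degenerate


def test_wilcoxon_sign_flip_antisymmetry():
    before = [1.0, 5.0, 2.0, 8.0, 3.0]
    after = [2.0, 4.0, 6.0, 9.0, 1.0]
    assert (wilcoxon_paired(before, after).p_value
            == pytest.approx(wilcoxon_paired(after, before).p_value))


def test_wilcoxon_matches_sign_pattern_oracle():
    rng = np.random.default_rng(17)
    for _ in range(20):
        n = int(rng.integers(3, 9))
        diffs = rng.permutation(50)[:n].astype(float) + 1
        signs = rng.choice([-1.0, 1.0], size=n)
        after = diffs * signs
        before = np.zeros(n)
        assert wilcoxon_paired(before, after).p_value == pytest.approx(
            wilcoxon_exact_two_sided(after), abs=1e-12)


def test_compare_groups_runs_requested_pairs():
    table = pd.DataFrame({
        "phenotype": ["CD"] * 4 + ["UC"] * 4 + ["control"] * 4,
        "expansion": [5, 6, 7, 8, 1, 2, 3, 4, 1.5, 2.5, 0.5, 3.5]})
    comps = compare_groups(table, "expansion", "phenotype",
                           [("CD", "control"), ("CD", "UC"), ("UC", "control")])
    assert len(comps) == 3
    assert comps[0].n_a == 4 and comps[0].n_b == 4
    assert not comps[0].paired


def test_compare_groups_paired_joins_on_pair_id():
    table = pd.DataFrame({
        "phenotype": ["before"] * 4 + ["after"] * 3,
        "pair_id": ["p1", "p2", "p3", "p4", "p1", "p2", "p3"],
        "expansion": [1.0, 2.0, 3.0, 4.0, 2.0, 3.0, 5.0]})
    comps = compare_groups(table, "expansion", "phenotype",
                           [("before", "after")], paired=True)
    assert comps[0].n_a == 3  # p4 dropped as unmatched
    assert comps[0].paired


def test_compare_groups_paired_no_matches_errors():
    table = pd.DataFrame({"phenotype": ["a", "b"], "pair_id": ["x", "y"],
                          "expansion": [1.0, 2.0]})
    with pytest.raises(ValueError):
        compare_groups(table, "expansion", "phenotype", [("a", "b")],
                       paired=True)


def test_discovery_set_scores_case_high_in_matched_validation_cohort():
    """A clonotype set discovered against controls separates cases from
    controls in an independent cohort with the same spike structure, while a
    set discovered by a case-vs-othercase contrast carries no such
    guarantee (the asymmetry seen when a control-free cohort is used for
    discovery)."""
    from traclon.association import associate
    import traclon.simulate as sim

    config = sim.SimulationConfig(
        seed=42, n_cohorts=2, n_case=40, n_control=40,
        repertoire_size=250, background_pool_size=800, n_spiked=8,
        n_cait_like=0, q_case=0.5, q_control=0.05)
    cohorts, truth = sim.generate_cohorts(config)
    disc, valid = cohorts
    res = associate(disc, "CD", "control", alpha=1e-3)
    keys = frozenset(res.associated_keys())
    assert keys, "discovery produced no hits"
    cset = ClonotypeSet("cd_set", keys)
    table = expansion_table(valid, [cset])
    comps = compare_groups(table, "expansion", "phenotype",
                           [("CD", "control")])
    x = table.loc[table["phenotype"] == "CD", "expansion"]
    y = table.loc[table["phenotype"] == "control", "expansion"]
    assert comps[0].p_value < 0.05
    assert x.median() > y.median()
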