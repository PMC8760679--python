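"""Differential testing, BH correction, and pathway enrichment."""
import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import metacap as mc


def bh_brute_force(p):
    """Literal step-up definition: q_k = p_(k) * m / k, cumulative min from
    the largest rank, capped at 1, original order restored."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        idx = order[rank - 1]
        running = min(running, p[idx] * m / rank)
        q[idx] = min(running, 1.0)
    return q


def fisher_tail_oracle(a, b, c, d):
    """One-sided over-representation p as an explicit hypergeometric tail
    sum over combinatorial counts."""
    n = a + b + c + d
    row1 = a + b
    col1 = a + c
    p = 0.0
    for x in range(a, min(row1, col1) + 1):
        p += (math.comb(col1, x) * math.comb(n - col1, row1 - x)) / math.comb(n, row1)
    return p


def test_t_identical_groups():
    t, p, ok = mc.two_sample_t([1, 2, 3], [1, 2, 3])
    assert ok and t == pytest.approx(0.0) and p == pytest.approx(1.0)


def test_t_zero_pooled_variance_untestable():
    t, p, ok = mc.two_sample_t([0, 0, 0], [1, 1, 1])
    assert not ok and math.isnan(t) and math.isnan(p)


def test_t_pooled_closed_form():
    """A=(1,2,3,4), B=(3,4,5,6): means 2.5/4.5, pooled var 5/3, df 6."""
    t, p, ok = mc.two_sample_t([1, 2, 3, 4], [3, 4, 5, 6])
    se = math.sqrt((5 / 3) * (1 / 4 + 1 / 4))
    assert ok
    assert t == pytest.approx(-2.0 / se, abs=1e-12)
    assert t == pytest.approx(-2.1909, abs=1e-4)
    assert p == pytest.approx(0.0710, abs=1e-4)


def test_t_sign_follows_mean_difference():
    t, _, _ = mc.two_sample_t([5, 6, 7], [1, 2, 3])
    assert t > 0


def test_t_needs_two_values_per_group():
    with pytest.raises(mc.ContractError):
        mc.two_sample_t([1.0], [1, 2, 3])


@pytest.mark.parametrize(
    "p,expected",
    [
        ([0.01, 0.02, 0.03, 0.04], [0.04, 0.04, 0.04, 0.04]),
        ([0.2], [0.2]),
        ([1.0, 1.0, 1.0], [1.0, 1.0, 1.0]),
    ],
)
def test_bh_hand_cases(p, expected):
    assert mc.benjamini_hochberg(p) == pytest.approx(expected)


def test_bh_rejects_out_of_range():
    with pytest.raises(mc.ContractError):
        mc.benjamini_hochberg([0.5, 1.5])


@settings(max_examples=60, derandomize=True, deadline=None)
@given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=40))
def test_bh_matches_step_up_definition(pvals):
    got = mc.benjamini_hochberg(pvals)
    want = bh_brute_force(pvals)
    assert np.max(np.abs(got - want)) < 1e-12
    assert np.all(got >= np.asarray(pvals) - 1e-15)  # adjusted >= raw


def test_fisher_worked_table():
    """[[3,0],[0,3]]: point mass C(3,3)C(3,0)/C(6,3) = 1/20."""
    import scipy.stats as sps

    p = sps.fisher_exact([[3, 0], [0, 3]], alternative="greater")[1]
    assert p == pytest.approx(0.05, abs=1e-12)
    assert fisher_tail_oracle(3, 0, 0, 3) == pytest.approx(0.05, abs=1e-12)


def _study(sim_catalog, fixture):
    cfg_or_none, target, (table, tax, meta, _, truth) = (
        (fixture[0], fixture[1], fixture[2]) if isinstance(fixture, tuple) and len(fixture) == 3
        else (None, None, fixture)
    )
    E = mc.build_expectation_matrix(mc.match_all(tax, sim_catalog), sim_catalog)
    ab = mc.compute_reaction_abundances(table, E)
    return ab, meta, truth, target


def test_planted_shift_detected_with_correct_sign(sim_catalog, sim_shifted):
    ab, meta, truth, _ = _study(sim_catalog, sim_shifted)
    diff = mc.differential_reactions(ab, meta, ("CD", "IM"))
    strong = sorted(
        r for r in truth.shifted_between("CD", "IM")
        if abs(truth.expected_reaction_abundance.loc["CD", r]
               - truth.expected_reaction_abundance.loc["IM", r]) >= 0.05
    )
    assert strong
    hits = diff.loc[strong]
    assert hits["significant"].mean() >= 0.9
    # detected reactions carry the sign the oracle predicts
    expected_sign = np.sign(
        truth.expected_reaction_abundance.loc["CD", strong].to_numpy()
        - truth.expected_reaction_abundance.loc["IM", strong].to_numpy()
    )
    detected = hits["significant"].to_numpy()
    assert np.all(np.sign(hits["mean_diff"].to_numpy()[detected]) == expected_sign[detected])


def test_constant_equal_reaction_not_tested():
    ab = pd.DataFrame({"r_flat": [0.5] * 6, "r_var": [0.1, 0.2, 0.3, 0.4, 0.5, 0.6]},
                      index=[f"s{i}" for i in range(6)])
    meta = mc.SampleMetadata(pd.DataFrame({"group": ["A"] * 3 + ["B"] * 3},
                                          index=ab.index))
    d = mc.differential_reactions(ab, meta, ("A", "B"))
    assert not d.loc["r_flat", "tested"]
    assert math.isnan(d.loc["r_flat", "p"])
    assert d.loc["r_var", "tested"]


def test_unknown_diet_label_rejected(sim_catalog, sim_null):
    ab, meta, *_ = _study(sim_catalog, sim_null)
    with pytest.raises(mc.ContractError, match="unknown diet"):
        mc.differential_reactions(ab, meta, ("CD", "NOPE"))


def test_label_swap_antisymmetry(sim_catalog, sim_shifted):
    ab, meta, *_ = _study(sim_catalog, sim_shifted)
    d12 = mc.differential_reactions(ab, meta, ("CD", "IM"))
    d21 = mc.differential_reactions(ab, meta, ("IM", "CD"))
    tested = d12["tested"]
    assert np.allclose(d12.loc[tested, "t"], -d21.loc[tested, "t"])
    assert np.allclose(d12.loc[tested, "mean_diff"], -d21.loc[tested, "mean_diff"])
    assert np.allclose(d12.loc[tested, "p"], d21.loc[tested, "p"])


def test_enrichment_counts_sum_and_invariants(sim_catalog, sim_shifted):
    ab, meta, *_ = _study(sim_catalog, sim_shifted)
    diff = mc.differential_reactions(ab, meta, ("CD", "IM"))
    enr = mc.pathway_enrichment(diff, sim_catalog)
    n_tested = int(diff["tested"].sum())
    for _, row in enr.iterrows():
        assert row[["sig_in", "sig_out", "nonsig_in", "nonsig_out"]].sum() == n_tested
        assert row["p_adj"] >= row["p"] - 1e-15
        if row["enriched"]:
            assert row["sig_in"] >= 1
    # Fisher p agrees with the combinatorial tail oracle
    for _, row in enr.iterrows():
        want = fisher_tail_oracle(*row[["sig_in", "sig_out", "nonsig_in", "nonsig_out"]])
        assert row["p"] == pytest.approx(want, abs=1e-12)


def test_enrichment_empty_without_significant_reactions(sim_catalog, sim_null):
    ab, meta, *_ = _study(sim_catalog, sim_null)
    diff = mc.differential_reactions(ab, meta, ("DFIM", "DCIM"))
    if diff["significant"].any():
        pytest.skip("null draw produced significant calls")
    enr = mc.pathway_enrichment(diff, sim_catalog)
    assert enr.empty


def test_direction_follows_sign_of_mean_t():
    diff = pd.DataFrame(
        {
            "diet1": "A", "diet2": "B",
            "mean1": 1.0, "mean2": 0.0, "mean_diff": 1.0,
            "t": [3.0, 4.0, -0.5, 0.2],
            "p": [0.001, 0.001, 0.8, 0.9],
            "p_adj": [0.004, 0.004, 0.9, 0.9],
            "significant": [True, True, False, False],
            "tested": True,
        },
        index=["r1", "r2", "r3", "r4"],
    )
    cat = mc.ModelCatalog(
        models=[mc.Model("m", "genus", "G", frozenset({"r1", "r2", "r3", "r4"}))],
        subsystems={"r1": ("S1",), "r2": ("S1",), "r3": ("S2",), "r4": ("S2",)},
    )
    enr = mc.pathway_enrichment(diff, cat)
    assert enr.loc["S1", "direction"] == "A"  # all significant t positive


def test_pairwise_enumeration_and_ordering(sim_catalog, sim_null):
    ab, meta, *_ = _study(sim_catalog, sim_null)
    res = mc.pairwise_all(ab, meta, catalog=sim_catalog)
    assert len(res) == math.comb(6, 2) == 15
    groups = meta.groups()
    for d1, d2 in res:
        assert groups.index(d1) < groups.index(d2)
    # two-group subset yields a single pair
    sub = meta.table[meta.table["group"].isin(["CD", "IM"])]
    res2 = mc.pairwise_all(ab.loc[sub.index], mc.SampleMetadata(sub), catalog=None)
    assert list(res2) == [("CD", "IM")]


def test_results_invariant_to_sample_row_order(sim_catalog, sim_shifted):
    ab, meta, *_ = _study(sim_catalog, sim_shifted)
    rng = np.random.default_rng(0)
    perm = rng.permutation(len(ab.index))
    ab_shuf = ab.iloc[perm]
    d1 = mc.differential_reactions(ab, meta, ("CD", "IM"))
    d2 = mc.differential_reactions(ab_shuf, meta, ("CD", "IM"))
    pd.testing.assert_frame_equal(d1, d2)


def test_direction_matrix_codes(sim_catalog, sim_shifted):
    ab, meta, *_ = _study(sim_catalog, sim_shifted)
    res = mc.pairwise_all(ab, meta, catalog=sim_catalog)
    mat = mc.direction_matrix(res)
    assert mat.shape[1] == 15
    assert set(np.unique(mat.to_numpy())) <= {-1, 0, 1}
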