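"""Community summaries: aggregation, core sets, overlap, rarefaction,
alpha diversity."""
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import metacap as mc
from metacap.containers import RANKS


def _table(counts, samples, asvs):
    return mc.AsvCountTable(pd.DataFrame(counts, index=samples, columns=asvs))


def _tax(rows, asvs):
    return mc.TaxonomyTable(pd.DataFrame(rows, index=asvs, columns=list(RANKS)))


def test_aggregate_fixed_rank_and_conservation():
    table = _table([[2, 3, 5]], ["s1"], ["a", "b", "c"])
    tax = _tax(
        [
            ["Bacteria", "P", "C", "O", "F", "GenusA", None],
            ["Bacteria", "P", "C", "O", "F", "GenusA", None],
            ["Bacteria", "P", "C", "O", "F", "GenusB", None],
        ],
        ["a", "b", "c"],
    )
    agg = mc.aggregate_relative_abundance(table, tax, "genus")
    assert agg.loc["s1", "GenusA"] == pytest.approx(0.5)
    assert agg.sum(axis=1).to_numpy() == pytest.approx([1.0])


def test_aggregate_lowest_assigned_uses_family_label():
    table = _table([[4, 6]], ["s1"], ["a", "b"])
    tax = _tax(
        [
            ["Bacteria", "P", "C", "O", "FamOnly", None, None],
            ["Bacteria", "P", "C", "O", "F", "GenusB", None],
        ],
        ["a", "b"],
    )
    agg = mc.aggregate_relative_abundance(table, tax, "lowest")
    assert agg.loc["s1", "FamOnly"] == pytest.approx(0.4)
    assert agg.loc["s1", "GenusB"] == pytest.approx(0.6)


def test_aggregate_empty_sample_warns_and_stays_zero():
    table = _table([[1, 1], [0, 0]], ["s1", "s2"], ["a", "b"])
    tax = _tax([["Bacteria", "P", None, None, None, None, None]] * 2, ["a", "b"])
    with pytest.warns(UserWarning, match="empty"):
        agg = mc.aggregate_relative_abundance(table, tax, "phylum")
    assert agg.loc["s2"].sum() == 0.0


def test_top_taxa_coverage_and_ties():
    agg = pd.DataFrame({"x": [0.5], "y": [0.3], "z": [0.2]}, index=["s1"])
    taxa, cov = mc.top_taxa(agg, 2)
    assert taxa == ["x", "y"] and cov == pytest.approx(0.8)
    taxa_all, cov_all = mc.top_taxa(agg, 10)
    assert cov_all == pytest.approx(1.0)
    tied = pd.DataFrame({"b": [0.5], "a": [0.5]}, index=["s1"])
    assert mc.top_taxa(tied, 1)[0] == ["a"]  # lexicographic tie-break


def test_core_prevalence_threshold_is_inclusive():
    # ASV 'a' in 4 of 5 samples = 80% prevalence -> core at threshold 80
    counts = [[1, 1], [1, 0], [1, 1], [1, 1], [0, 1]]
    table = _table(counts, [f"s{i}" for i in range(5)], ["a", "b"])
    cs = mc.core_asvs(table, prevalence_threshold=80)
    assert "a" in cs.members and "b" in cs.members
    assert cs.prevalence["a"] == pytest.approx(80.0)
    cs100 = mc.core_asvs(table, prevalence_threshold=100)
    assert cs100.members == frozenset()


def test_core_tiny_abundance_counts_as_present_by_default():
    table = _table([[1, 10000], [1, 10000]], ["s1", "s2"], ["tiny", "big"])
    cs = mc.core_asvs(table, prevalence_threshold=100)
    assert "tiny" in cs.members
    # but an abundance floor excludes it
    cs2 = mc.core_asvs(table, prevalence_threshold=100, min_rel_abundance=0.01)
    assert "tiny" not in cs2.members and "big" in cs2.members


def test_core_sets_shrink_as_threshold_rises(sim_null):
    table, *_ = sim_null
    sizes = [len(mc.core_asvs(table, prevalence_threshold=t).members)
             for t in (20, 50, 80, 100)]
    assert sizes == sorted(sizes, reverse=True)


def test_core_empty_subset_rejected(sim_null):
    table, *_ = sim_null
    with pytest.raises(mc.ContractError):
        mc.core_asvs(table, samples_subset=[])


def test_set_intersections_regions():
    regions = mc.set_intersections({"X": {"A", "B"}, "Y": {"B", "C"}})
    assert regions[frozenset({"X"})] == 1
    assert regions[frozenset({"Y"})] == 1
    assert regions[frozenset({"X", "Y"})] == 1
    identical = mc.set_intersections({"X": {"A", "B"}, "Y": {"A", "B"}})
    assert identical[frozenset({"X", "Y"})] == 2
    disjoint = mc.set_intersections({"X": {"A"}, "Y": {"B"}})
    assert disjoint[frozenset({"X", "Y"})] == 0
    with pytest.raises(mc.ContractError):
        mc.set_intersections({str(i): {i} for i in range(5)})


def test_shared_asvs_hand_fixture():
    # 5 ASVs; c and d pass the presence rule in both groups
    counts = [
        [100, 0, 50, 50, 0],  # group A
        [0, 0, 60, 40, 1],  # group A
        [0, 100, 30, 70, 0],  # group B
    ]
    table = _table(counts, ["a1", "a2", "b1"], list("vwxyz"))
    res = mc.shared_asvs(table, ["a1", "a2"], ["b1"], min_rel_abundance=0.01,
                         labels=("gut", "feed"))
    assert res.shared == frozenset({"x", "y"})
    assert res.n_shared == 2
    # hand count: group A reads on x,y = 200 of 301; group B = 100 of 200
    assert res.abundance_fraction_a == pytest.approx(200 / 301)
    assert res.abundance_fraction_b == pytest.approx(100 / 200)


def test_shared_presence_threshold_is_inclusive_at_0_05_percent():
    # 0.04% everywhere -> absent under the 0.05% rule
    below = _table([[4, 9996]], ["s1"], ["rare", "big"])
    res = mc.shared_asvs(below, ["s1"], [], min_rel_abundance=0.0005)
    assert "rare" not in {a for a in below.asv_ids
                          if (below.relative_abundance().loc["s1", a] >= 0.0005)}
    at = _table([[5, 9995]], ["s1"], ["rare", "big"])
    assert at.relative_abundance().loc["s1", "rare"] >= 0.0005


def test_shared_identical_groups_fraction_one():
    table = _table([[10, 20], [30, 40]], ["s1", "s2"], ["a", "b"])
    res = mc.shared_asvs(table, ["s1"], ["s2"], min_rel_abundance=0.0005)
    assert res.shared == frozenset({"a", "b"})
    assert res.abundance_fraction_a == pytest.approx(1.0)
    assert res.abundance_fraction_b == pytest.approx(1.0)


def test_shared_overlapping_groups_rejected(sim_null):
    table, *_ = sim_null
    s = table.sample_ids
    with pytest.raises(mc.ContractError):
        mc.shared_asvs(table, s[:2], s[1:3])


def test_rarefy_exact_depth_unchanged_and_sums():
    table = _table([[3, 7], [60, 40]], ["s1", "s2"], ["a", "b"])
    out = mc.rarefy(table, 10, seed=0)
    assert list(out.counts.loc["s1"]) == [3, 7]  # already at depth
    assert out.counts.sum(axis=1).tolist() == [10, 10]


def test_rarefy_drops_shallow_samples_with_warning():
    table = _table([[3, 2], [60, 40]], ["s1", "s2"], ["a", "b"])
    with pytest.warns(UserWarning, match="dropped"):
        out = mc.rarefy(table, 10, seed=0)
    assert out.sample_ids == ["s2"]
    with pytest.raises(mc.ContractError):
        mc.rarefy(table, 0, seed=0)


def test_rarefy_deterministic_and_unbiased():
    table = _table([[500, 300, 200]], ["s1"], ["a", "b", "c"])
    r1 = mc.rarefy(table, 100, seed=9).counts
    r2 = mc.rarefy(table, 100, seed=9).counts
    pd.testing.assert_frame_equal(r1, r2)
    reps = np.array([
        mc.rarefy(table, 100, seed=s).counts.loc["s1"].to_numpy() for s in range(1000)
    ]) / 100.0
    mean = reps.mean(axis=0)
    # hypergeometric marginals: mean p, var p(1-p)/n * finite-pop correction
    p = np.array([0.5, 0.3, 0.2])
    fpc = (1000 - 100) / (1000 - 1)
    se = np.sqrt(p * (1 - p) / 100 * fpc / 1000)
    assert np.all(np.abs(mean - p) < 3 * se + 1e-9)


def test_alpha_uniform_and_single_asv():
    table = _table([[5, 5, 5, 5], [9, 0, 0, 0]], ["u", "single"], list("abcd"))
    div = mc.alpha_diversity(table)
    assert div.loc["u", "observed_asvs"] == 4
    assert div.loc["u", "shannon"] == pytest.approx(math.log(4))
    assert div.loc["u", "pielou"] == pytest.approx(1.0)
    assert div.loc["single", "observed_asvs"] == 1
    assert div.loc["single", "shannon"] == 0.0
    assert div.loc["single", "pielou"] == 0.0


def test_shannon_base_flag():
    table = _table([[5, 5, 5, 5]], ["u"], list("abcd"))
    div = mc.alpha_diversity(table, shannon_base=2)
    assert div.loc["u", "shannon"] == pytest.approx(2.0)
    assert div.loc["u", "pielou"] == pytest.approx(1.0)


def test_faith_pd_star_tree_manual_sum():
    tree = mc.parse_tree("(a:1,b:1,c:1,d:1,e:1);")
    table = _table([[1, 1, 1, 0, 0]], ["s1"], list("abcde"))
    div = mc.alpha_diversity(table, tree=tree)
    assert div.loc["s1", "faith_pd"] == pytest.approx(3.0)


def test_faith_pd_all_leaves_equals_total_length(tiny_tree, tiny_table):
    full = mc.AsvCountTable(tiny_table.counts.clip(lower=1))
    div = mc.alpha_diversity(full, tree=tiny_tree)
    assert np.allclose(div["faith_pd"], tiny_tree.total_branch_length())


def test_faith_pd_monotone_under_added_presence(tiny_tree):
    asvs = tiny_tree.leaf_names
    base = np.zeros(len(asvs), dtype=int)
    base[0] = 1
    pd_vals = []
    for k in range(1, len(asvs) + 1):
        counts = base.copy()
        counts[:k] = 1
        t = _table([counts], ["s"], asvs)
        pd_vals.append(mc.alpha_diversity(t, tree=tiny_tree).loc["s", "faith_pd"])
    assert all(b >= a - 1e-12 for a, b in zip(pd_vals, pd_vals[1:]))


def test_faith_pd_missing_leaves_rejected(tiny_table):
    small_tree = mc.parse_tree("(asv_sp:1,asv_ge:1);")
    with pytest.raises(mc.ContractError, match="asv_fa"):
        mc.alpha_diversity(tiny_table, tree=small_tree)


@settings(max_examples=40, derandomize=True, deadline=None)
@given(st.lists(st.integers(min_value=1, max_value=500), min_size=2, max_size=12))
def test_shannon_bounded_by_log_richness(counts):
    table = _table([counts], ["s"], [f"a{i}" for i in range(len(counts))])
    div = mc.alpha_diversity(table)
    k = div.loc["s", "observed_asvs"]
    assert div.loc["s", "shannon"] <= math.log(k) + 1e-9
    if len(set(counts)) == 1:
        assert div.loc["s", "shannon"] == pytest.approx(math.log(k))


def test_faith_pd_agrees_with_skbio_on_bifurcating_tree(tiny_tree):
    """Independent cross-check of the branch-sum against scikit-bio."""
    from skbio.diversity.alpha import faith_pd as skbio_faith_pd

    asvs = tiny_tree.leaf_names
    rng = np.random.default_rng(8)
    for _ in range(10):
        counts = rng.integers(0, 3, size=len(asvs))
        if counts.sum() == 0:
            counts[0] = 1
        t = _table([counts], ["s"], asvs)
        ours = mc.alpha_diversity(t, tree=tiny_tree).loc["s", "faith_pd"]
        ref = skbio_faith_pd(counts, taxa=asvs, tree=tiny_tree.tree)
        assert ours == pytest.approx(float(ref), abs=1e-12)
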