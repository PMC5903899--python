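import math

import networkx as nx
import numpy as np
import pytest

from conftest import disjoint_ffls
from motifclust.errors import SamplingError, ValidationError
from motifclust.fixtures import make_type_fixture
from motifclust.motifcore import FBL, FFL, count_instances, find_instances
from motifclust.motiftypes import type_distribution
from motifclust.nullmodels import (
    degree_preserving_randomize,
    duplication_growth,
    edge_removal_robustness,
    erdos_renyi,
    motif_preserving_sample,
    significance,
)


# ---------------------------------------------------------------------------
# Erdős-Rényi


def test_er_p_zero_is_empty():
    g = erdos_renyi(10, 0.0, seed=1)
    assert g.number_of_nodes() == 10 and g.number_of_edges() == 0


def test_er_p_one_is_complete():
    g = erdos_renyi(3, 1.0, seed=1)
    assert g.number_of_edges() == 6


def test_er_rejects_invalid_p():
    with pytest.raises(ValidationError):
        erdos_renyi(10, 1.5, seed=0)


def test_er_edge_count_matches_binomial_expectation():
    n, p, seeds = 100, 0.05, 200
    counts = [erdos_renyi(n, p, seed=s).number_of_edges() for s in range(seeds)]
    mean = np.mean(counts)
    se = np.std(counts, ddof=1) / math.sqrt(seeds)
    assert abs(mean - n * (n - 1) * p) <= 3 * se


def test_er_reproducible_and_seeds_decorrelate():
    a = erdos_renyi(30, 0.1, seed=42)
    b = erdos_renyi(30, 0.1, seed=42)
    c = erdos_renyi(30, 0.1, seed=43)
    assert set(a.edges) == set(b.edges)
    assert set(a.edges) != set(c.edges)


# ---------------------------------------------------------------------------
# duplication growth


def test_duplication_target_equals_template_returns_template():
    g = duplication_growth(FFL, 3, seed=0)
    assert set(g.edges) == {
        ("input0", "intermediate0"),
        ("input0", "output0"),
        ("intermediate0", "output0"),
    }


def test_forced_output_duplication_yields_type12_union():
    g = duplication_growth(FFL, 4, seed=5, role_bias={"output": 1.0})
    dist = type_distribution(g, [FFL])
    assert dist.n_pairs_clustered == 1 and dist.counts[12] == 1


def test_duplicating_any_motif_node_creates_fully_clustered_copy():
    """A duplicate of a motif member forms a new instance of the same
    pattern sharing the two other members (fully clustered)."""
    for role, expected_type in (("input", 7), ("intermediate", 10), ("output", 12)):
        g = duplication_growth(FFL, 4, seed=1, role_bias={role: 1.0})
        instances = find_instances(g, FFL)
        assert len(instances) == 2
        i1, i2 = instances
        assert len(i1.node_set & i2.node_set) == 2
        dist = type_distribution(g, [FFL])
        assert dist.counts[expected_type] == 1


def test_duplication_rejects_degenerate_bias():
    with pytest.raises(ValidationError):
        duplication_growth(FFL, 5, seed=0, role_bias={"input": 0.0})
    with pytest.raises(ValidationError):
        duplication_growth(FFL, 2, seed=0)


def test_duplication_reproducible():
    a = duplication_growth(FFL, 15, seed=11)
    b = duplication_growth(FFL, 15, seed=11)
    assert set(a.edges) == set(b.edges)


# ---------------------------------------------------------------------------
# degree-preserving randomization


def test_swap_preserves_degree_sequences():
    g, _ = make_type_fixture(6, k=6)
    r = degree_preserving_randomize(g, seed=3)
    assert dict(g.in_degree()) == dict(r.in_degree())
    assert dict(g.out_degree()) == dict(r.out_degree())
    assert r.number_of_edges() == g.number_of_edges()


def test_two_edge_network_swap():
    g = nx.DiGraph([("a", "b"), ("c", "d")])
    # the only accepted swap is (a->d, c->b); try until it happens
    swapped = degree_preserving_randomize(g, n_swaps_per_edge=50, seed=1)
    assert set(swapped.edges) in ({("a", "d"), ("c", "b")}, {("a", "b"), ("c", "d")})
    assert dict(g.out_degree()) == dict(swapped.out_degree())


def test_randomization_erodes_motif_excess():
    """An FFL-rich fixture loses most of its FFLs under degree-preserving
    rewiring: the null mean sits far below the observed count.  (A type-6
    star would not do here: its degree sequence forces the hub edges and
    only permutes the intermediate-to-output edges, leaving the FFL count
    invariant.)"""
    g = disjoint_ffls(8)
    observed = count_instances(g, FFL)
    null_counts = [
        count_instances(degree_preserving_randomize(g, seed=s), FFL)
        for s in range(30)
    ]
    assert np.mean(null_counts) < observed


# ---------------------------------------------------------------------------
# motif-count-preserving rejection sampler


def test_single_ffl_sample_is_ffl_relabeling(single_ffl):
    sample = motif_preserving_sample(single_ffl, FFL, seed=2)
    assert sample.number_of_nodes() == 3
    assert sample.number_of_edges() == 3
    assert count_instances(sample, FFL) == 1


def test_samples_preserve_motif_and_edge_counts():
    g, _ = make_type_fixture(12, k=4)  # 4 FFLs on 6 nodes, 9 edges
    for seed in range(5):
        sample = motif_preserving_sample(g, FFL, seed=seed)
        assert sample.number_of_nodes() == g.number_of_nodes()
        assert sample.number_of_edges() == g.number_of_edges()
        assert count_instances(sample, FFL) == count_instances(g, FFL)


def test_exhausted_restart_budget_raises():
    # a dense clustered fixture almost never assembles in one free-run
    # attempt, so a zero-restart budget must fail loudly
    g, _ = make_type_fixture(6, k=6)
    with pytest.raises(SamplingError, match="max_restarts=0"):
        motif_preserving_sample(g, FFL, seed=0, max_restarts=0)


# ---------------------------------------------------------------------------
# significance


def test_significance_motif_count_on_ffl_rich_fixture():
    g = disjoint_ffls(8)
    res = significance(g, statistic="motif_count", n_samples=40, seed=7, pattern=FFL)
    assert res.null_model == "degree_preserving"
    assert res.z > 3  # the fixture is motif-rich relative to its degrees
    assert res.p_empirical == pytest.approx(1 / 41)


def test_significance_mc_type6_star_above_chance():
    g, _ = make_type_fixture(6, k=5)
    res = significance(g, statistic="mc", n_samples=30, seed=9, pattern=FFL)
    assert res.null_model == "motif_preserving"
    assert res.z > 0  # star clustering exceeds random placement of 5 FFLs


def test_zero_variance_null_yields_sentinel(single_ffl):
    # every motif-preserving sample of a lone FFL has exactly one motif
    with pytest.warns(UserWarning, match="zero standard deviation"):
        res = significance(
            single_ffl, statistic="motif_count", null="motif_preserving",
            n_samples=2, seed=1, pattern=FFL,
        )
    assert res.z == 0.0  # observed equals the degenerate null exactly


def test_significance_validates_inputs(single_ffl):
    with pytest.raises(ValidationError):
        significance(single_ffl, statistic="nope")
    with pytest.raises(ValidationError):
        significance(single_ffl, n_samples=1)


# ---------------------------------------------------------------------------
# edge-removal robustness


def test_removing_all_edges_empties_distribution():
    g, _ = make_type_fixture(6, k=4)
    (point,) = edge_removal_robustness(g, [1.0], trials=3, seed=0, patterns=[FFL])
    assert point.mean_motif_count == 0.0
    assert all(v == 0.0 for v in point.mean_fractions.values())


def test_fraction_rounding_to_zero_keeps_distribution():
    g, _ = make_type_fixture(6, k=4)  # 12 edges; 0.01 * 12 rounds to 0
    (point,) = edge_removal_robustness(g, [0.01], trials=2, seed=0, patterns=[FFL])
    baseline = type_distribution(g, [FFL])
    assert point.n_removed == 0
    assert point.mean_motif_count == baseline.n_instances
    assert point.mean_fractions == pytest.approx(baseline.fractions)


def test_motif_count_monotone_under_removal():
    g, _ = make_type_fixture(6, k=6)
    points = edge_removal_robustness(
        g, [0.1, 0.3, 0.5], trials=30, seed=4, patterns=[FFL]
    )
    counts = [p.mean_motif_count for p in points]
    assert counts == sorted(counts, reverse=True)


def test_robustness_validates_fractions():
    g, _ = make_type_fixture(6, k=3)
    with pytest.raises(ValidationError):
        edge_removal_robustness(g, [0.0], trials=1, seed=0)
    with pytest.raises(ValidationError):
        edge_removal_robustness(g, [0.5], trials=0, seed=0)


def test_determinism_under_fixed_seed():
    g, _ = make_type_fixture(6, k=5)
    a = edge_removal_robustness(g, [0.2], trials=5, seed=8, patterns=[FFL])
    b = edge_removal_robustness(g, [0.2], trials=5, seed=8, patterns=[FFL])
    assert a == b
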