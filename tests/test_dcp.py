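"""The per-gene dC statistic and its permutation null."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dcreg import (
    LinkCutoff,
    PermutationPlan,
    SimulationConfig,
    ValidationError,
    build_network_pair,
    call_dcp_dcgs,
    dc_statistic,
    pairwise_correlations,
    permutation_pvalues,
    simulate,
)

from conftest import make_network


def brute_force_dc(x, y):
    """Direct transliteration of the RMS-of-differences formula."""
    n = len(x)
    return math.sqrt(sum((xi - yi) ** 2 for xi, yi in zip(x, y)) / n)


corr_vectors = st.lists(
    st.floats(min_value=-1, max_value=1, allow_nan=False), min_size=1, max_size=12
)


class TestDcStatistic:
    def test_identical_vectors_give_zero(self, rng):
        v = rng.uniform(-1, 1, 7)
        assert dc_statistic(v, v) == 0.0

    @pytest.mark.parametrize(
        "x, y, expected",
        [([1, 0], [0, 1], 1.0), ([0.9], [0.1], 0.8), ([1, -1], [-1, 1], 2.0)],
    )
    def test_hand_computed_values(self, x, y, expected):
        assert dc_statistic(x, y) == pytest.approx(expected, abs=1e-12)

    def test_matches_brute_force_on_random_pairs(self, rng):
        for _ in range(200):
            n = rng.integers(1, 30)
            x, y = rng.uniform(-1, 1, n), rng.uniform(-1, 1, n)
            assert dc_statistic(x, y) == pytest.approx(brute_force_dc(x, y), abs=1e-12)

    def test_empty_vectors_are_undefined(self):
        assert math.isnan(dc_statistic([], []))

    def test_length_mismatch_raises(self):
        with pytest.raises(ValidationError, match="length"):
            dc_statistic([1, 2], [1])

    @settings(derandomize=True, max_examples=60)
    @given(x=corr_vectors, y=corr_vectors, seed=st.integers(0, 10**6))
    def test_bounds_and_joint_reordering_invariance(self, x, y, seed):
        n = min(len(x), len(y))
        x, y = np.array(x[:n]), np.array(y[:n])
        dc = dc_statistic(x, y)
        assert 0.0 <= dc <= 2.0
        perm = np.random.default_rng(seed).permutation(n)
        assert dc_statistic(x[perm], y[perm]) == pytest.approx(dc, abs=1e-12)

    def test_strictly_increasing_in_any_single_difference(self, rng):
        x = rng.uniform(-1, 1, 6)
        y = rng.uniform(-1, 1, 6)
        j = 3
        base = dc_statistic(x, y)
        x2 = x.copy()
        # Push x_j further from y_j while staying in [-1, 1].
        x2[j] = y[j] + np.sign(x[j] - y[j] + 1e-9) * min(1.0, abs(x[j] - y[j]) + 0.2)
        assert dc_statistic(x2, y) > base


def two_group_network(seed=0, n_genes=40, cutoff=0.75):
    expr, _ = simulate(
        SimulationConfig(n_genes=n_genes, n_tf_hubs=2, targets_per_hub=4, seed=seed)
    )
    c1 = pairwise_correlations(expr, "disease")
    c2 = pairwise_correlations(expr, "control")
    net = build_network_pair(
        c1, c2, LinkCutoff("threshold", cutoff), ("disease", "control")
    )
    return expr, net


class TestPermutationPvalues:
    def test_pvalues_within_add_one_bounds(self):
        expr, net = two_group_network()
        res = permutation_pvalues(expr, net, PermutationPlan(50, seed=3))
        p = res.table["p_value"]
        assert (p >= 1 / 51 - 1e-12).all() and (p <= 1.0).all()
        assert (res.table["fdr"] >= p / len(p)).all()
        assert set(res.table["gene"]) | set(res.skipped) == set(expr.gene_ids)

    def test_zero_observed_dc_gives_p_one(self):
        # Both "conditions" alias the same structure: dC = 0 everywhere.
        expr, _ = simulate(SimulationConfig(n_genes=20, n_tf_hubs=1, targets_per_hub=4, seed=2))
        c1 = pairwise_correlations(expr, "disease")
        net = build_network_pair(c1, c1, LinkCutoff("threshold", 0.7), ("disease", "disease"))
        res = permutation_pvalues(expr, net, PermutationPlan(30, seed=1))
        assert (res.table["p_value"] == 1.0).all()

    def test_seed_determinism_bit_for_bit(self):
        expr, net = two_group_network(seed=4)
        r1 = permutation_pvalues(expr, net, PermutationPlan(40, seed=11))
        r2 = permutation_pvalues(expr, net, PermutationPlan(40, seed=11))
        pd.testing.assert_frame_equal(r1.table, r2.table)

    def test_planted_reversal_hub_detected(self):
        expr, truth = simulate(
            SimulationConfig(n_genes=40, n_tf_hubs=1, targets_per_hub=8, seed=7)
        )
        c1 = pairwise_correlations(expr, "disease")
        c2 = pairwise_correlations(expr, "control")
        net = build_network_pair(c1, c2, LinkCutoff(), ("disease", "control"))
        res = permutation_pvalues(expr, net, PermutationPlan(500, seed=9))
        (hub,) = truth.planted_dcg_genes
        assert res.p_value_of(hub) <= 0.05

    def test_too_few_samples_raises(self):
        expr, net = two_group_network()
        small = expr.values[[c for c in expr.sample_ids if c.endswith(("_01", "_02"))]]
        from dcreg import ExpressionMatrix

        tiny = ExpressionMatrix(values=small, conditions=expr.conditions[small.columns])
        with pytest.raises(ValidationError, match=">= 3 samples"):
            permutation_pvalues(tiny, net, PermutationPlan(10, seed=0))


class TestCallDcgs:
    def fixture_table(self):
        ps = [0.001, 0.018596, 0.03, 0.049, 0.05, 0.051, 0.2, 0.5, 0.9, 1.0]
        return pd.DataFrame(
            {
                "gene": [f"G{i}" for i in range(10)],
                "dC": np.linspace(1, 0.1, 10),
                "n_neighbors": 3,
                "p_value": ps,
                "fdr": [min(1.0, p * 2) for p in ps],
            }
        )

    def test_matches_brute_force_filter(self):
        table = self.fixture_table()
        got = call_dcp_dcgs(table, p_threshold=0.05)
        expected = {r.gene for r in table.itertuples() if r.p_value <= 0.05}
        assert got == expected
        assert "G1" in got  # p = 0.018596 retained at 0.05

    def test_joint_fdr_filter(self):
        table = self.fixture_table()
        got = call_dcp_dcgs(table, p_threshold=0.05, fdr_threshold=0.05)
        expected = {
            r.gene for r in table.itertuples() if r.p_value <= 0.05 and r.fdr <= 0.05
        }
        assert got == expected

    def test_zero_threshold_is_empty(self):
        assert call_dcp_dcgs(self.fixture_table(), p_threshold=0.0) == frozenset()


def test_network_fixture_roundtrip_through_statistic(star_network):
    x, y = star_network.neighbor_vectors("H")
    assert dc_statistic(x, y) == pytest.approx(brute_force_dc(x, y), abs=1e-12)
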