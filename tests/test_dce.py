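"""Reversal typing, LFC link selection and binomial DCG enrichment."""

import math

import numpy as np
import pytest

from dcreg import (
    ValidationError,
    binomial_enrichment,
    call_dce_dcgs,
    dce_counts,
    dce_dcg_pvalues,
    lfc_select_dcls,
    reversal_type,
)

from conftest import make_network


def exhaustive_binomial_tail(n, k, q):
    """Independent oracle: exact term-by-term summation of the upper tail."""
    return sum(math.comb(n, x) * q**x * (1 - q) ** (n - x) for x in range(k, n + 1))


class TestReversalType:
    @pytest.mark.parametrize(
        "r1, r2, expected",
        [
            (0.94, 0.14, 0),     # strong-to-weak, same sign
            (-0.60, 0.97, 1),    # negative regulation switching to positive
            (-0.71, 0.97, 1),
            (0.51, -0.95, 1),
            (0.0, 0.5, 0),       # zero product: no sign change demonstrable
            (-0.88, -0.02, 0),
        ],
    )
    def test_sign_rule(self, r1, r2, expected):
        assert reversal_type(r1, r2) == expected

    def test_symmetric_under_condition_swap(self, rng):
        for _ in range(100):
            r1, r2 = rng.uniform(-1, 1, 2)
            assert reversal_type(r1, r2) == reversal_type(r2, r1)

    def test_out_of_range_raises(self):
        with pytest.raises(ValidationError):
            reversal_type(1.5, 0.2)


class TestLfcSelection:
    def test_single_bin_top_half_by_fold_change(self):
        # Same-sign links with FC ratios 10, 5, 2, 1; delta=0.5 keeps the top two.
        net = make_network(
            links=[("A", "B"), ("C", "D"), ("E", "F"), ("G", "H")],
            r1=[1.0, 0.5, 0.8, 0.6],
            r2=[0.1, 0.1, 0.4, 0.6],
        )
        out = lfc_select_dcls(net, delta=0.5, n_bins=1)
        flagged = set(zip(out.loc[out.is_dcl, "gene_a"], out.loc[out.is_dcl, "gene_b"]))
        assert flagged == {("A", "B"), ("C", "D")}

    def test_reversal_link_flagged_with_type_one(self):
        net = make_network(
            links=[("JUN", "CHURC1"), ("A", "B")], r1=[0.51, 0.9], r2=[-0.95, 0.88]
        )
        out = lfc_select_dcls(net, delta=0.5)
        row = out[out.gene_a == "CHURC1"].iloc[0]
        assert bool(row.is_dcl) and row.reversal_type == 1 and row.selection_bin == -1

    def test_no_differential_signal_flags_nothing(self, rng):
        r = rng.uniform(-1, 1, 12)
        net = make_network([(f"A{i}", f"B{i}") for i in range(12)], r, r.copy())
        out = lfc_select_dcls(net, delta=0.9)
        assert not out.is_dcl.any()

    @pytest.mark.parametrize("n_links, delta, expected", [(4, 0.25, 1), (5, 0.5, 3), (3, 0.3, 1), (6, 0.24, 1)])
    def test_round_half_up_selection_count(self, n_links, delta, expected):
        # One bin of same-sign links, all with distinct fold changes.
        r1 = np.linspace(0.9, 0.95, n_links)
        r2 = np.linspace(0.05, 0.4, n_links)
        net = make_network([(f"A{i}", f"B{i}") for i in range(n_links)], r1, r2)
        out = lfc_select_dcls(net, delta=delta, n_bins=1)
        assert int(out.is_dcl.sum()) == expected

    def test_bins_recorded_and_groups_separated(self, rng):
        n = 60
        r1 = rng.uniform(0.5, 1.0, n)
        r2 = np.concatenate([rng.uniform(0.0, 1.0, n // 2), rng.uniform(-1.0, 0.0, n - n // 2)])
        net = make_network([(f"A{i:02d}", f"B{i:02d}") for i in range(n)], r1, r2)
        out = lfc_select_dcls(net, delta=0.25, n_bins=3, min_bin_count=10)
        same = out[out.reversal_type == 0]
        opp = out[out.reversal_type == 1]
        assert set(same.selection_bin) <= {0, 1, 2}
        assert (opp.selection_bin == -1).all()
        # Per-bin flagged counts respect the rounded delta fraction.
        for _, grp in same.groupby("selection_bin"):
            assert int(grp.is_dcl.sum()) <= int(np.floor(0.25 * len(grp) + 0.5))


class TestCounts:
    def test_k_count_conservation(self, rng):
        n = 30
        genes = [f"G{i}" for i in range(12)]
        links = set()
        while len(links) < n:
            a, b = rng.choice(genes, 2, replace=False)
            links.add(tuple(sorted((a, b))))
        links = sorted(links)
        r1 = rng.uniform(-1, 1, len(links))
        r2 = rng.uniform(-1, 1, len(links))
        net = make_network(links, r1, r2)
        counts = dce_counts(lfc_select_dcls(net, delta=0.3))
        assert int(counts.table["k_i"].sum()) == 2 * counts.K
        assert counts.N == len(links)
        assert (counts.table["k_i"] <= counts.table["n_i"]).all()


class TestBinomialEnrichment:
    def test_zero_hits_is_exactly_one(self):
        assert binomial_enrichment(5, 0, 3, 10) == 1.0

    def test_hand_summed_values(self):
        assert binomial_enrichment(2, 1, 1, 2) == pytest.approx(0.75, abs=1e-12)
        assert binomial_enrichment(3, 3, 1, 10) == pytest.approx(0.001, abs=1e-12)

    def test_matches_exhaustive_summation(self):
        for n in range(1, 9):
            for k in range(n + 1):
                for q in (0.01, 0.2, 0.5, 0.8, 0.99):
                    got = binomial_enrichment(n, k, int(q * 100), 100)
                    assert got == pytest.approx(exhaustive_binomial_tail(n, k, q), abs=1e-10)

    def test_monotone_nonincreasing_in_k(self):
        ps = [binomial_enrichment(8, k, 10, 100) for k in range(9)]
        assert all(a >= b for a, b in zip(ps, ps[1:]))
        assert ps[0] == 1.0

    def test_bound_violations_raise(self):
        with pytest.raises(ValidationError):
            binomial_enrichment(2, 3, 1, 10)
        with pytest.raises(ValidationError):
            binomial_enrichment(2, 1, 11, 10)


class TestCallDceDcgs:
    def make_counts(self, spec, K, N):
        import pandas as pd

        from dcreg import DCeCounts

        table = pd.DataFrame(
            [(g, n, k) for g, (n, k) in spec.items()], columns=["gene", "n_i", "k_i"]
        )
        return DCeCounts(N=N, K=K, table=table)

    def test_matches_exhaustive_oracle(self):
        spec = {"A": (8, 8), "B": (4, 1), "C": (3, 0), "D": (6, 4), "E": (1, 1)}
        counts = self.make_counts(spec, K=7, N=140)
        got = call_dce_dcgs(counts, 0.05)
        expected = {
            g
            for g, (n, k) in spec.items()
            if exhaustive_binomial_tail(n, k, 7 / 140) <= 0.05
        }
        assert got == expected
        assert "C" not in got  # k_i = 0 excluded at any threshold < 1

    def test_fully_differential_hub_called(self):
        spec = {"HUB": (8, 8)} | {f"T{i}": (1, 1) for i in range(8)}
        counts = self.make_counts(spec, K=8, N=160)
        table = dce_dcg_pvalues(counts)
        assert table.loc[table.gene == "HUB", "p_value"].iloc[0] == pytest.approx(
            0.05**8, rel=1e-9
        )
        assert "HUB" in call_dce_dcgs(counts, 0.05)
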