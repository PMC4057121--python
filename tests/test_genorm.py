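"""geNorm relative quantities, M values, stepwise exclusion and V_n/n+1."""

import math
import statistics

import numpy as np
import pandas as pd
import pytest

from refstab.errors import TooFewGenesError, UndefinedGeneError
from refstab.genorm import (
    genorm_analysis,
    m_values,
    pairwise_variation_v,
    relative_quantities,
    stepwise_exclusion,
)
from refstab.synthetic import GeneSpec, GroupSpec, SimConfig, simulate_ct_table
from refstab.ct_data import ct_table_from_long


def brute_force_m(quantities: pd.DataFrame) -> dict[str, float]:
    """Independent double-loop M computation with statistics.stdev."""
    genes = list(quantities.columns)
    out = {}
    for j in genes:
        sds = []
        for k in genes:
            if k == j:
                continue
            ratios = [
                math.log2(quantities.at[s, j] / quantities.at[s, k])
                for s in quantities.index
                if not (
                    math.isnan(quantities.at[s, j]) or math.isnan(quantities.at[s, k])
                )
            ]
            sds.append(statistics.stdev(ratios))
        out[j] = sum(sds) / len(sds)
    return out


class TestRelativeQuantities:
    def test_calibrator_sample_has_quantity_one(self, make_table):
        t = make_table({"a": [20.0, 22.0, 25.0], "b": [18.0, 19.0, 21.0]})
        q = relative_quantities(t)
        assert (q.max(axis=0) == 1.0).all()

    def test_two_cycle_difference_quarters_quantity(self, make_table):
        t = make_table({"a": [20.0, 22.0], "b": [20.0, 20.0]})
        q = relative_quantities(t)
        assert q.at["s2", "a"] == pytest.approx(0.25)

    def test_efficiency_correction_uses_assay_factor(self, make_table):
        t = make_table(
            {"a": [20.0, 21.0], "b": [20.0, 20.0]},
            efficiencies={"a": 2.025, "b": 2.0},
        )
        q = relative_quantities(t)
        assert q.at["s2", "a"] == pytest.approx(1 / 2.025)

    def test_fully_missing_gene_raises(self, make_table):
        t = make_table({"a": [20.0, 21.0], "b": [np.nan, np.nan]})
        with pytest.raises(UndefinedGeneError):
            relative_quantities(t)


class TestMValues:
    def test_shifted_copies_have_zero_m(self, make_table):
        t = make_table(
            {"a": [20.0, 21.0, 23.0], "b": [22.0, 23.0, 25.0], "c": [25.0, 26.0, 28.0]}
        )
        m = m_values(relative_quantities(t))
        assert m.abs().max() < 1e-12

    def test_hand_computed_three_gene_example(self, make_table):
        # genes a, b are shifted copies; c deviates from a by (0, .5, 0, .5)
        t = make_table(
            {
                "a": [20.0, 21.0, 22.0, 23.0],
                "b": [21.0, 22.0, 23.0, 24.0],
                "c": [20.0, 21.5, 22.0, 23.5],
            }
        )
        m = m_values(relative_quantities(t))
        sd = statistics.stdev([0.0, 0.5, 0.0, 0.5])  # 0.288675
        assert m["a"] == pytest.approx(sd / 2, abs=1e-9)
        assert m["b"] == pytest.approx(sd / 2, abs=1e-9)
        assert m["c"] == pytest.approx(sd, abs=1e-9)

    def test_sample_order_invariance(self, random_table):
        t = random_table(4, 6, seed=7)
        q = relative_quantities(t)
        shuffled = q.sample(frac=1.0, random_state=1)
        pd.testing.assert_series_equal(m_values(q), m_values(shuffled))

    @pytest.mark.parametrize("seed", range(30))
    def test_matches_brute_force_oracle(self, random_table, seed):
        rng = np.random.default_rng(seed + 1000)
        t = random_table(int(rng.integers(3, 6)), int(rng.integers(2, 9)), seed=seed)
        q = relative_quantities(t)
        m = m_values(q)
        expected = brute_force_m(q)
        for g in q.columns:
            assert m[g] == pytest.approx(expected[g], abs=1e-10)

    def test_sample_scaling_invariance(self, random_table):
        """Multiplying one sample's quantities by a constant leaves M alone."""
        t = random_table(4, 6, seed=3)
        q = relative_quantities(t)
        scaled = q.copy()
        scaled.iloc[2] *= 7.5
        pd.testing.assert_series_equal(m_values(q), m_values(scaled))

    def test_duplicating_a_gene_never_raises_its_m(self, random_table):
        t = random_table(4, 6, seed=11)
        q = relative_quantities(t)
        q2 = q.copy()
        q2["g0_copy"] = q["g0"]
        assert m_values(q2)["g0"] <= m_values(q)["g0"] + 1e-12

    def test_requires_three_genes(self, make_table):
        t = make_table({"a": [20.0, 21.0], "b": [20.0, 21.0]})
        with pytest.raises(TooFewGenesError):
            m_values(relative_quantities(t))


class TestStepwiseExclusion:
    def test_deviating_gene_excluded_first(self, make_table):
        t = make_table(
            {
                "a": [20.0, 21.0, 22.0, 23.0],
                "b": [21.0, 22.0, 23.0, 24.0],
                "c": [20.0, 21.5, 22.0, 23.5],
            }
        )
        res = stepwise_exclusion(relative_quantities(t))
        assert res.exclusion_order == ["c"]
        assert set(res.final_pair) == {"a", "b"}
        assert res.ranks["a"] == res.ranks["b"] == 1
        assert res.ranks["c"] == 3

    def test_identical_genes_tie_broken_by_input_order(self, make_table):
        t = make_table({g: [20.0, 21.0, 23.0] for g in ("a", "b", "c")})
        res = stepwise_exclusion(relative_quantities(t))
        assert res.exclusion_order == ["c"]  # later in input order goes first
        assert res.final_pair == ("a", "b")

    def test_high_noise_gene_excluded_first_in_simulation(self):
        hits = 0
        n_runs = 100
        for seed in range(n_runs):
            genes = tuple(
                GeneSpec(f"g{i}", 20.0 + i, 2.0, noise_sd=0.2) for i in range(9)
            ) + (GeneSpec("noisy", 30.0, 2.0, noise_sd=1.0),)
            cfg = SimConfig(genes=genes, groups=(GroupSpec("all", 12),), seed=seed)
            table = ct_table_from_long(
                simulate_ct_table(cfg), efficiencies=cfg.efficiencies
            )
            res = stepwise_exclusion(relative_quantities(table))
            if res.exclusion_order[0] == "noisy":
                hits += 1
        assert hits >= 95


class TestPairwiseVariation:
    def test_exact_copies_give_zero_v_and_two_genes(self, make_table):
        t = make_table(
            {g: [20.0 + i, 21.0 + i, 23.0 + i] for i, g in enumerate("abcd")}
        )
        q = relative_quantities(t)
        res = stepwise_exclusion(q)
        v, recommended, warning = pairwise_variation_v(q, res.stability_order)
        assert all(val == pytest.approx(0.0, abs=1e-12) for val in v.values())
        assert recommended == 2
        assert not warning

    def test_recommendation_is_smallest_n_below_cutoff(self, random_table):
        t = random_table(6, 8, seed=5)
        q = relative_quantities(t)
        res = stepwise_exclusion(q)
        for cutoff in (0.02, 0.05, 0.15, 0.5):
            v, recommended, warning = pairwise_variation_v(
                q, res.stability_order, cutoff
            )
            below = [n for n, val in v.items() if val < cutoff]
            if below:
                assert recommended == min(below)
                assert not warning
            else:
                assert recommended == len(q.columns)
                assert warning

    def test_v_defined_for_two_through_g_minus_one(self, random_table):
        t = random_table(5, 8, seed=9)
        res = genorm_analysis(t)
        assert sorted(res.v_values) == [2, 3, 4]
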