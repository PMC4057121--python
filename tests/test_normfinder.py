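"""NormFinder-style variance decomposition and pair recommendation."""

import itertools

import numpy as np
import pandas as pd
import pytest

from refstab.errors import InsufficientGroupError, TooFewGenesError
from refstab.normfinder import best_pair_normfinder, normfinder_stability
from refstab.synthetic import GeneSpec, GroupSpec, SimConfig, simulate_ct_table
from refstab.ct_data import ct_table_from_long


def oracle_pair(result):
    """Independent exhaustive pair scoring from the result's components."""
    genes = list(result.stability.index)
    best, best_val = None, np.inf
    for a, b in itertools.combinations(genes, 2):
        val = 0.0
        for g in result.intergroup.columns:
            z = (result.intergroup.at[a, g] + result.intergroup.at[b, g]) / 2
            v = (result.intragroup_var.at[a, g] + result.intragroup_var.at[b, g]) / 4
            val += abs(z) + (v / result.group_sizes[g]) ** 0.5
        val /= len(result.intergroup.columns)
        if val < best_val - 1e-15:
            best, best_val = (a, b), val
    return best


def grouped_table(make_table, cts, n_a, n_b, **kw):
    groups = ["A"] * n_a + ["B"] * n_b
    return make_table(cts, groups=groups, **kw)


class TestStability:
    def test_gene_without_residual_variation_is_perfectly_stable(self, make_table):
        # gene a carries only the shared sample effect; b and c wobble
        t_s = [0.0, 1.0, 2.0, 3.0]
        e_s = [0.1, -0.1, 0.2, -0.2]
        t = make_table(
            {
                "a": [25.0 - x for x in t_s],
                "b": [25.0 - (x + e) for x, e in zip(t_s, e_s)],
                "c": [25.0 - (x - e) for x, e in zip(t_s, e_s)],
            }
        )
        res = normfinder_stability(t)
        assert res.stability["a"] == pytest.approx(0.0, abs=1e-12)
        assert res.ranking["a"] == 1

    def test_single_group_mode_has_zero_intergroup(self, random_table):
        t = random_table(5, 8, seed=2)
        res = normfinder_stability(t)
        assert not res.grouped
        assert (res.intergroup == 0).all().all()

    def test_single_group_ranking_follows_intragroup_variance(self, random_table):
        t = random_table(6, 10, seed=4)
        res = normfinder_stability(t)
        by_var = res.intragroup_var.iloc[:, 0].rank(method="first")
        pd.testing.assert_series_equal(
            res.ranking.astype(float), by_var, check_names=False
        )

    def test_sample_scaling_invariance(self, make_table):
        """Adding a constant to one sample's log2 vector (RNA input at a
        shared efficiency) changes nothing: the centring removes it."""
        rng = np.random.default_rng(6)
        cts = {f"g{j}": list(22.0 + rng.normal(0, 1.0, 8)) for j in range(5)}
        t = make_table(cts, groups=["A"] * 4 + ["B"] * 4)
        res1 = normfinder_stability(t)
        t.values.iloc[3] -= 1.7  # uniform Ct shift == +1.7 log2 at E = 2
        res2 = normfinder_stability(t)
        pd.testing.assert_series_equal(res1.stability, res2.stability)

    def test_identical_genes_rank_by_input_order(self, make_table):
        t = grouped_table(
            make_table, {g: [20.0, 21.0, 22.0, 23.0] for g in "abcd"}, 2, 2
        )
        res = normfinder_stability(t)
        assert res.stability.nunique() == 1
        assert list(res.ranking.sort_values(kind="stable").index) == list("abcd")

    def test_group_shifted_gene_ranks_worst(self):
        hits = 0
        for seed in range(100):
            genes = tuple(
                GeneSpec(f"g{i}", 22.0 + i, 2.0, noise_sd=0.2) for i in range(9)
            ) + (GeneSpec("shifted", 25.0, 2.0, noise_sd=0.2),)
            cfg = SimConfig(
                genes=genes,
                groups=(
                    GroupSpec("A", 6, {"shifted": 1.0}),
                    GroupSpec("B", 6),
                ),
                sample_scaling_sd=1.0,
                seed=seed,
            )
            table = ct_table_from_long(
                simulate_ct_table(cfg), efficiencies=cfg.efficiencies
            )
            res = normfinder_stability(table)
            if res.ranking["shifted"] == len(genes):
                hits += 1
        assert hits >= 95

    def test_small_group_raises(self, make_table):
        t = grouped_table(make_table, {g: [20.0, 21.0, 22.0] for g in "abc"}, 1, 2)
        with pytest.raises(InsufficientGroupError):
            normfinder_stability(t)

    def test_two_genes_raise(self, make_table):
        t = make_table({"a": [20.0, 21.0], "b": [20.0, 21.0]})
        with pytest.raises(TooFewGenesError):
            normfinder_stability(t)


class TestBestPair:
    def test_opposite_group_shifts_cancel(self):
        """Two low-noise genes with equal and opposite group shifts average
        to a shift-free signal and beat individually flat but noisier
        candidates."""
        genes = (
            GeneSpec("up", 24.0, 2.0, noise_sd=0.05),
            GeneSpec("down", 25.0, 2.0, noise_sd=0.05),
        ) + tuple(GeneSpec(f"flat{i}", 26.0 + i, 2.0, noise_sd=0.4) for i in range(4))
        cfg = SimConfig(
            genes=genes,
            groups=(
                GroupSpec("A", 6, {"up": 0.5, "down": -0.5}),
                GroupSpec("B", 6),
            ),
            seed=17,
        )
        table = ct_table_from_long(simulate_ct_table(cfg), efficiencies=cfg.efficiencies)
        res = normfinder_stability(table)
        assert set(best_pair_normfinder(res)) == {"up", "down"}

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_exhaustive_oracle(self, random_table, seed):
        rng = np.random.default_rng(seed)
        n_genes = int(rng.integers(3, 7))
        t = random_table(n_genes, 8, seed=seed + 500, groups=["A"] * 4 + ["B"] * 4)
        res = normfinder_stability(t)
        assert best_pair_normfinder(res) == oracle_pair(res)

    def test_identical_genes_choose_first_two(self, make_table):
        t = grouped_table(
            make_table, {g: [20.0, 21.0, 22.0, 23.0] for g in "abcd"}, 2, 2
        )
        res = normfinder_stability(t)
        assert best_pair_normfinder(res) == ("a", "b")

    def test_single_group_falls_back_to_lowest_individual(self, random_table):
        t = random_table(5, 8, seed=8)
        res = normfinder_stability(t)
        pair = best_pair_normfinder(res)
        expected = tuple(res.stability.sort_values(kind="stable").index[:2])
        assert pair == expected

    def test_low_shift_low_noise_genes_selected(self):
        hits = 0
        for seed in range(100):
            genes = tuple(
                GeneSpec(f"g{i}", 22.0 + i, 2.0, noise_sd=0.4) for i in range(8)
            ) + (
                GeneSpec("calm1", 21.0, 2.0, noise_sd=0.05),
                GeneSpec("calm2", 20.0, 2.0, noise_sd=0.05),
            )
            # balanced +/- shifts keep the panel-wide mean shift near zero
            effects = {f"g{i}": (0.5 if i % 2 == 0 else -0.5) for i in range(8)}
            cfg = SimConfig(
                genes=genes,
                groups=(GroupSpec("A", 6, effects), GroupSpec("B", 6)),
                seed=seed,
            )
            table = ct_table_from_long(
                simulate_ct_table(cfg), efficiencies=cfg.efficiencies
            )
            pair = best_pair_normfinder(normfinder_stability(table))
            if set(pair) == {"calm1", "calm2"}:
                hits += 1
        assert hits >= 90
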