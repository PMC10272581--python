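import numpy as np
import pandas as pd
import pytest

import ecoassembly as ea
from ecoassembly.simulate import (
    SCENARIOS,
    AssemblyScenario,
    niche_blocks,
    scenario_fixture,
    simulate_dataset,
)


class TestSimulateTree:
    def test_two_tips_is_a_cherry(self):
        tree = ea.simulate_tree(2, seed=0)
        tips = list(tree.tips())
        assert len(tips) == 2
        d = [t.accumulate_to_ancestor(tree) for t in tips]
        assert d[0] == pytest.approx(d[1], abs=1e-9)

    @pytest.mark.parametrize("death", [0.0, 0.5])
    def test_ultrametric_with_requested_tips(self, death):
        tree = ea.simulate_tree(25, 1.0, death, seed=3)
        depths = [t.accumulate_to_ancestor(tree) for t in tree.tips()]
        assert len(depths) == 25
        assert max(depths) - min(depths) < 1e-8

    def test_pure_birth_depth_expectation(self):
        """Crown-to-tip depth matches the Yule expectation sum_{k=2..n} 1/k."""
        n = 40
        depths = []
        for seed in range(100):
            tree = ea.simulate_tree(n, 1.0, 0.0, seed=seed)
            depths.append(next(tree.tips()).accumulate_to_ancestor(tree))
        expected = sum(1.0 / k for k in range(2, n + 1))
        se = np.std(depths, ddof=1) / np.sqrt(len(depths))
        assert abs(np.mean(depths) - expected) < 3 * se

    def test_invalid_rates_rejected(self):
        with pytest.raises(ValueError):
            ea.simulate_tree(10, 1.0, 1.0)
        with pytest.raises(ValueError):
            ea.simulate_tree(1, 1.0, 0.0)

    def test_deterministic(self):
        a = str(ea.simulate_tree(15, seed=7))
        b = str(ea.simulate_tree(15, seed=7))
        assert a == b


class TestEvolveTraits:
    def test_zero_rate_gives_zero_traits(self, random_tree):
        tr = ea.evolve_traits(random_tree(10, seed=1), sigma2=0.0, seed=2)
        assert (tr == 0).all()

    def test_negative_rate_rejected(self, random_tree):
        with pytest.raises(ValueError):
            ea.evolve_traits(random_tree(5, seed=1), sigma2=-1)

    def test_cherry_contrast_variance(self):
        """Var(trait_A - trait_B) on a cherry equals 2 * sigma2 * branch."""
        from io import StringIO
        from skbio import TreeNode

        tree = TreeNode.read(StringIO("(A:0.7,B:0.7);"))
        sigma2 = 1.3
        contrasts = [
            np.diff(ea.evolve_traits(tree, sigma2, seed=s).to_numpy())[0]
            for s in range(4000)
        ]
        var = np.var(contrasts, ddof=1)
        expected = 2 * sigma2 * 0.7
        se = expected * np.sqrt(2.0 / (len(contrasts) - 1))
        assert abs(var - expected) < 3 * se

    def test_trait_distance_tracks_phylogeny(self, random_tree):
        """|trait difference| correlates positively with patristic distance."""
        hits = 0
        for seed in range(20):
            tree = ea.simulate_tree(64, seed=seed)
            tr = ea.evolve_traits(tree, 1.0, seed=seed + 500)
            d = ea.patristic_distances(tree)
            dt = np.abs(tr.to_numpy()[:, None] - tr.to_numpy()[None, :])
            iu = np.triu_indices(len(tr), 1)
            r = np.corrcoef(dt[iu], d.loc[tr.index, tr.index].to_numpy()[iu])[0, 1]
            hits += r > 0
        assert hits >= 18


class TestNicheBlocks:
    def test_blocks_partition_tips_into_tight_clades(self, random_tree):
        tree = random_tree(40, seed=4)
        bl = niche_blocks(tree, 0.25)
        assert sorted(bl.index) == sorted(t.name for t in tree.tips())
        d = ea.patristic_distances(tree)
        depth = d.to_numpy().max() / 2
        for b in bl.unique():
            members = bl.index[bl == b]
            if len(members) > 1:
                sub = d.loc[members, members].to_numpy()
                assert sub.max() <= 2 * 0.25 * depth + 1e-9


class TestScenarios:
    def test_registry_contract(self):
        sc = scenario_fixture("tiny")
        assert sc.n_sites == 4 and sc.pool_richness == 12
        with pytest.raises(KeyError, match="tiny"):
            scenario_fixture("not-a-scenario")

    def test_lake_survey_dimensions(self):
        sc = scenario_fixture("lake-survey")
        assert sc.n_groups == 3
        assert sc.richnesses() == (834, 99, 102)
        assert sc.depths() == (32029, 13975, 16313)

    def test_mixture_weights_validated(self):
        with pytest.raises(ValueError):
            AssemblyScenario(regime={"drift": 0.4})
        AssemblyScenario(regime={"drift": 0.5, "variable_selection": 0.5})

    def test_dataset_invariants_and_determinism(self):
        sc = scenario_fixture("tiny", seed=11)
        ds1 = simulate_dataset(sc)
        ds2 = simulate_dataset(sc)
        for g in ds1.groups:
            t = ds1.tables[g]
            assert (t.to_numpy() >= 0).all()
            assert (t.sum(axis=1) == sc.depths()[0]).all()
            tips = {tip.name for tip in ds1.trees[g].tips()}
            assert set(t.columns) <= tips
            pd.testing.assert_frame_equal(t, ds2.tables[g])
        assert str(ds1.trees["g1"]) == str(ds2.trees["g1"])

    def test_all_registered_scenarios_run(self):
        for name, sc in SCENARIOS.items():
            if name == "lake-survey":
                continue  # exercised via dimensions test; heavy to assemble
            small = scenario_fixture(name, seed=1)
            ds = simulate_dataset(small)
            for g in ds.groups:
                assert ds.tables[g].sum().sum() > 0

    def test_mass_effects_make_sites_converge(self):
        """Near-total homogenizing dispersal: between-site Bray-Curtis is
        far below the drift scenario's at matched depth."""
        hd = simulate_dataset(scenario_fixture("homogenizing_dispersal", seed=2))
        dr = simulate_dataset(scenario_fixture("drift", seed=2))
        bc_hd = ea.bray_curtis_matrix(hd.tables["g1"]).to_numpy()
        bc_dr = ea.bray_curtis_matrix(dr.tables["g1"]).to_numpy()
        iu = np.triu_indices(10, 1)
        assert bc_hd[iu].mean() < 0.5 * bc_dr[iu].mean()

    def test_opposite_gradient_ends_share_little(self):
        ds = simulate_dataset(scenario_fixture("variable_selection", seed=3))
        t = ds.tables["g1"]
        bc = ea.bray_curtis(t.iloc[0], t.iloc[-1])
        bc_adj = ea.bray_curtis(t.iloc[0], t.iloc[1])
        assert bc > bc_adj
        assert bc > 0.8
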