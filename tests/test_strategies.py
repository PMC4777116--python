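"""Breeding-strategy cycles: selection, mating, transfers, elites."""

import numpy as np
import pytest

import treebreed as tb
from treebreed.genome import ConfigurationError
from treebreed.strategies import (
    SelectionError,
    group_mass_select,
    initialize_state,
)


def _state(founder_population, strategy, scenario="intermediate-additive", seed=0,
           **cfg_overrides):
    _, p, eff, s2e, founders, rng = founder_population(scenario, seed=seed)
    config = tb.StrategyConfig.preset(strategy, **cfg_overrides)
    state = initialize_state(
        founders, config, float(founders.gvalue.mean()), eff, s2e, rng
    )
    return state, config, rng


class TestConfigPresets:
    @pytest.mark.parametrize("name", tb.strategies.STRATEGY_NAMES)
    def test_total_progeny_is_9600(self, name):
        assert tb.StrategyConfig.preset(name).total_progeny == 9600

    @pytest.mark.parametrize(
        "name, selected",
        [
            ("SBPM", 192),
            ("SBPW", 192),
            ("SUBL", 192),
            ("SELFL", 192),
            ("SELFP", 192),
            ("NUCU", 216),  # 20 + 168 own selections + 24 + 4 transfers
            ("NUCR", 192),  # 20 + 144 own selections + 24 + 4 transfers
        ],
    )
    def test_selected_counts(self, name, selected):
        assert tb.StrategyConfig.preset(name).total_selected == selected

    def test_nucleus_designs(self):
        nucu = tb.StrategyConfig.preset("NUCU")
        assert (nucu.nucleus_progeny, nucu.main_progeny) == (4800, 4800)
        assert (nucu.nucleus_parents, nucu.main_parents_own) == (20, 168)
        nucr = tb.StrategyConfig.preset("NUCR")
        assert (nucr.nucleus_progeny, nucr.main_progeny) == (4560, 5040)
        assert (nucr.nucleus_parents, nucr.main_parents_own) == (20, 144)
        # per-cross / per-mother counts are integers by design
        assert nucr.nucleus_progeny % nucr.nucleus_crosses == 0
        assert nucr.main_progeny % (nucr.main_parents_own + 24) == 0

    def test_intensified_selection_only_for_selfl(self):
        cfg = tb.StrategyConfig.preset("SELFL", intensified_selection_factor=4)
        assert cfg.progeny_per_compartment == 200
        with pytest.raises(ConfigurationError):
            tb.StrategyConfig.preset("SBPM", intensified_selection_factor=4)

    def test_unknown_strategy(self):
        with pytest.raises(ConfigurationError):
            tb.StrategyConfig.preset("OCS")


class TestSelectionOperators:
    def _tiny_pop(self, phenotypes, mothers=None, fathers=None):
        n = len(phenotypes)
        return tb.Population(
            trait=np.zeros((n, 2, 4), dtype=np.uint8),
            neutral=np.zeros((n, 2, 4), dtype=np.int16),
            ids=np.arange(n, dtype=np.int64),
            mother=np.array(mothers if mothers is not None else [-1] * n),
            father=np.array(fathers if fathers is not None else [-1] * n),
            group=np.zeros(n, dtype=np.int32),
            gvalue=np.asarray(phenotypes, dtype=float),
            phenotype=np.asarray(phenotypes, dtype=float),
        )

    def test_mass_select_ranks_by_phenotype(self):
        pop = self._tiny_pop([3.0, 1.0, 2.0])
        assert tb.mass_select(pop, 2).ids.tolist() == [0, 2]
        assert tb.mass_select(pop, 3).ids.tolist() == [0, 1, 2]  # identity
        with pytest.raises(SelectionError):
            tb.mass_select(pop, 4)

    def test_mass_select_tie_breaks_by_lower_id(self):
        pop = self._tiny_pop([1.0, 1.0, 1.0])
        assert tb.mass_select(pop, 2).ids.tolist() == [0, 1]

    def test_within_family_select_equal_contributions(self):
        phen = [5.0, 4.0, 3.0, 9.0, 8.0, 7.0]
        pop = self._tiny_pop(phen, mothers=[0, 0, 0, 1, 1, 1], fathers=[2] * 6)
        sel = tb.within_family_select(pop, 2)
        assert sel.ids.tolist() == [0, 1, 3, 4]
        # one family: equivalent to mass selection
        one = self._tiny_pop(phen, mothers=[0] * 6, fathers=[1] * 6)
        assert (
            tb.within_family_select(one, 2).ids.tolist()
            == tb.mass_select(one, 2).ids.tolist()
        )
        with pytest.raises(SelectionError):
            tb.within_family_select(pop, 4)


class TestBreedingCycles:
    @pytest.mark.parametrize(
        "name", ["SBPM", "SBPW", "SUBL", "SELFL", "SELFP", "NUCU", "NUCR"]
    )
    def test_cycle_counts(self, founder_population, name):
        state, config, rng = _state(founder_population, name)
        new_state, progeny = tb.advance_generation(state, config, rng)
        assert sum(p.size for p in progeny.values()) == 9600
        if name in ("NUCU", "NUCR"):
            assert new_state.compartments["nucleus"].size == 24
            assert new_state.compartments["main"].size == config.main_parents_own + 24
        else:
            assert new_state.compartments["BP"].size == 192

    def test_sbpw_equal_family_contributions(self, founder_population):
        state, config, rng = _state(founder_population, "SBPW")
        new_state, _ = tb.advance_generation(state, config, rng)
        bp = new_state.compartments["BP"]
        fams = np.unique(np.stack([bp.mother, bp.father], 1), axis=0)
        assert fams.shape[0] == 96
        for m, f in fams:
            assert np.sum((bp.mother == m) & (bp.father == f)) == 2

    def test_subl_sublines_are_closed(self, founder_population):
        _, p, eff, s2e, founders, rng = founder_population("intermediate-additive")
        config = tb.StrategyConfig.preset("SUBL")
        state = initialize_state(
            founders, config, float(founders.gvalue.mean()), eff, s2e, rng
        )
        # founder neutral-label sets per subline
        label_sets = {
            g: set(founders.neutral[state.compartments["BP"].group == g, :, 0].ravel().tolist())
            for g in range(4)
        }
        for _ in range(3):
            state, _ = tb.advance_generation(state, config, rng)
        bp = state.compartments["BP"]
        for g in range(4):
            seen = set(bp.neutral[bp.group == g].ravel().tolist())
            assert seen <= label_sets[g]

    def test_selfl_lines_closed_and_f_recursion(self, founder_population):
        state, config, rng = _state(founder_population, "SELFL")
        for t in range(1, 6):
            state, _ = tb.advance_generation(state, config, rng)
        bp = state.compartments["BP"]
        assert bp.size == 192
        # single seed descent: each line continues through one survivor
        assert np.unique(bp.group).size == 192
        f = tb.inbreeding_coefficients(bp)
        assert f.mean() == pytest.approx(1 - 2**-5, abs=0.01)
        # lines are closed: survivor's neutral labels come from its own founder
        assert np.all(bp.neutral[:, 0, 0] // 2 == bp.group)

    def test_selfl_homozygous_line_stays_fixed(self, founder_population):
        state, config, rng = _state(founder_population, "SELFL")
        bp = state.compartments["BP"]
        bp.trait[0] = 1  # line 0's founder fully homozygous favorable
        bp.neutral[0, 1, :] = bp.neutral[0, 0, :]
        for _ in range(2):
            state, _ = tb.advance_generation(state, config, rng)
        bp = state.compartments["BP"]
        line0 = bp.group == 0
        assert np.all(bp.trait[line0] == 1)
        assert tb.inbreeding_coefficients(bp)[line0][0] == 1.0

    def test_nucr_transfer_and_parent_sets_disjoint(self, founder_population):
        state, config, rng = _state(founder_population, "NUCR")
        new_state, progeny = tb.advance_generation(state, config, rng)
        nucleus_ids = set(new_state.compartments["nucleus"].ids.tolist())
        main_ids = set(new_state.compartments["main"].ids.tolist())
        assert not nucleus_ids & main_ids
        # transfers outrank retained parents: best nucleus progeny went to main
        nuc_prog = progeny["nucleus"]
        best = nuc_prog.ids[np.argmax(nuc_prog.phenotype)]
        assert best in main_ids

    def test_nucu_allows_dual_use(self, founder_population):
        state, config, rng = _state(founder_population, "NUCU")
        new_state, progeny = tb.advance_generation(state, config, rng)
        nucleus_ids = set(new_state.compartments["nucleus"].ids.tolist())
        main_ids = set(new_state.compartments["main"].ids.tolist())
        # the best nucleus progeny serves as parent (nucleus) AND transfer (main)
        nuc_prog = progeny["nucleus"]
        best = nuc_prog.ids[np.argmax(nuc_prog.phenotype)]
        assert best in nucleus_ids and best in main_ids

    def test_nucleus_tier_progeny_split(self, founder_population):
        for name, nuc_n, main_n in [("NUCU", 4800, 4800), ("NUCR", 4560, 5040)]:
            state, config, rng = _state(founder_population, name)
            _, progeny = tb.advance_generation(state, config, rng)
            assert progeny["nucleus"].size == nuc_n
            assert progeny["main"].size == main_n


class TestProductionPopulation:
    @pytest.mark.parametrize("name", ["SBPM", "SUBL", "SELFL", "NUCU"])
    def test_elites_paired_once_into_12_crosses(self, founder_population, name):
        state, config, rng = _state(founder_population, name)
        state, progeny = tb.advance_generation(state, config, rng)
        pp = tb.build_production_population(state, progeny, config, rng)
        assert pp.size == 1200
        parents = np.concatenate([pp.mother, pp.father])
        ids, counts = np.unique(parents, return_counts=True)
        assert ids.size == 24  # 24 elites
        assert np.all(counts == 100)  # each elite in exactly one cross
        assert np.all(pp.mother != pp.father)  # outcrosses only

    def test_subl_takes_six_elites_per_subline(self, founder_population):
        state, config, rng = _state(founder_population, "SUBL")
        state, progeny = tb.advance_generation(state, config, rng)
        pp = tb.build_production_population(state, progeny, config, rng)
        elite_ids = np.unique(np.concatenate([pp.mother, pp.father]))
        prog = progeny["BP"]
        groups = prog.group[np.searchsorted(prog.ids, elite_ids)]
        assert np.bincount(groups, minlength=4).tolist() == [6, 6, 6, 6]

    def test_selfl_pp_outbred_at_high_generation(self, founder_population):
        state, config, rng = _state(founder_population, "SELFL")
        for _ in range(5):
            state, progeny = tb.advance_generation(state, config, rng)
        pp = tb.build_production_population(state, progeny, config, rng)
        # elites come from 24 distinct unrelated lines: crosses are outbred
        assert tb.population_inbreeding(pp) == 0.0
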