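"""The seven breeding strategies: selection, mating, transfers, elites.

Every strategy starts from 192 unrelated founders, produces 9600 progeny
per generation, and selects 192 individuals (188 own selections + 4
transfers for the nucleus schemes) to parent the next cycle:

* ``SBPM`` — single population, 96 random pair crosses x 100 progeny,
  mass selection of 192.
* ``SBPW`` — same mating, but the best 2 per full-sib family are kept,
  equalizing family contributions.
* ``SUBL`` — four closed sublines of 48 parents (24 crosses x 100);
  mass selection of 48 within each subline.
* ``SELFL`` — 192 closed selfing lines under single seed descent: one
  parent selfed to 50 progeny (200 under fourfold-intensified selection),
  best one continues the line.
* ``SELFP`` — 192 parents each selfed to 50 progeny, pooled; mass
  selection of 192 from the pool.
* ``NUCU`` / ``NUCR`` — two-tier nucleus breeding.  The nucleus (24
  parents, 12 pair crosses) exports its top 24 progeny to the main tier
  and keeps 20 as parents; the open-pollinated main tier exports its top 4
  to the nucleus and keeps 168 (NUCU) or 144 (NUCR) as mothers.  In NUCU
  the very best individuals may serve both as parents and as transfers; in
  NUCR the two sets are disjoint, transfers being taken first by rank.

A production population (PP) of 12 outcrosses x 100 progeny between 24
phenotypically elite trees is built each generation; its statistics
represent the material deployed to forestry.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .genome import ConfigurationError, LocusEffects
from .population import Population, make_progeny, open_pollinate

__all__ = [
    "STRATEGY_NAMES",
    "StrategyConfig",
    "BreedingState",
    "mass_select",
    "within_family_select",
    "group_mass_select",
    "initialize_state",
    "advance_generation",
    "build_production_population",
]

STRATEGY_NAMES = ("SBPM", "SBPW", "SUBL", "SELFL", "SELFP", "NUCU", "NUCR")

NUCLEUS, MAIN = 0, 1  # tier group codes for the nucleus strategies


class SelectionError(ValueError):
    """Requested more selections than candidates available."""


@dataclass(frozen=True)
class StrategyConfig:
    """Design numbers of one breeding strategy.

    Defaults reproduce the published designs; individual counts can be
    overridden for sensitivity runs.  ``intensified_selection_factor``
    multiplies the per-line progeny count of SELFL (4 -> 200 selfed
    progeny per line, selection intensity 0.5%).
    """

    name: str
    n_compartments: int
    progeny_per_compartment: int
    selected_per_compartment: int
    # nucleus-only design numbers (ignored elsewhere)
    nucleus_progeny: int = 0
    nucleus_parents: int = 20
    nucleus_crosses: int = 12
    main_progeny: int = 0
    main_parents_own: int = 0
    transfer_nucleus_to_main: int = 24
    transfer_main_to_nucleus: int = 4
    # production-population design
    elite_count: int = 24
    pp_crosses: int = 12
    pp_progeny_per_cross: int = 100
    intensified_selection_factor: int = 1

    @classmethod
    def preset(cls, name: str, **overrides) -> "StrategyConfig":
        """The published design for ``name``, with optional overrides."""
        if name not in STRATEGY_NAMES:
            raise ConfigurationError(f"unknown strategy {name!r}")
        factor = int(overrides.pop("intensified_selection_factor", 1))
        if factor != 1 and name != "SELFL":
            raise ConfigurationError(
                "intensified selection is defined only for SELFL"
            )
        base: dict
        if name in ("SBPM", "SBPW", "SELFP"):
            base = dict(
                n_compartments=1,
                progeny_per_compartment=9600,
                selected_per_compartment=192,
            )
        elif name == "SUBL":
            base = dict(
                n_compartments=4,
                progeny_per_compartment=2400,
                selected_per_compartment=48,
            )
        elif name == "SELFL":
            base = dict(
                n_compartments=192,
                progeny_per_compartment=50 * factor,
                selected_per_compartment=1,
                intensified_selection_factor=factor,
            )
        elif name == "NUCU":
            base = dict(
                n_compartments=2,
                progeny_per_compartment=4800,
                selected_per_compartment=20,
                nucleus_progeny=4800,
                main_progeny=4800,
                main_parents_own=168,
            )
        else:  # NUCR
            base = dict(
                n_compartments=2,
                progeny_per_compartment=4560,
                selected_per_compartment=20,
                nucleus_progeny=4560,
                main_progeny=5040,
                main_parents_own=144,
            )
        base.update(overrides)
        return cls(name=name, **base)

    def __post_init__(self) -> None:
        if self.name not in STRATEGY_NAMES:
            raise ConfigurationError(f"unknown strategy {self.name!r}")
        if self.elite_count != 2 * self.pp_crosses:
            raise ConfigurationError("elite count must be twice the PP cross count")
        if self.name in ("NUCU", "NUCR"):
            n_parents = self.nucleus_parents + self.transfer_main_to_nucleus
            if self.nucleus_progeny % self.nucleus_crosses:
                raise ConfigurationError(
                    "nucleus progeny must divide evenly over nucleus crosses"
                )
            if n_parents != 2 * self.nucleus_crosses:
                raise ConfigurationError(
                    "nucleus parents (own + transferred) must pair into the "
                    "nucleus crosses"
                )

    @property
    def total_progeny(self) -> int:
        if self.name in ("NUCU", "NUCR"):
            return self.nucleus_progeny + self.main_progeny
        return self.n_compartments * self.progeny_per_compartment

    @property
    def total_selected(self) -> int:
        if self.name in ("NUCU", "NUCR"):
            return (
                self.nucleus_parents
                + self.main_parents_own
                + self.transfer_nucleus_to_main
                + self.transfer_main_to_nucleus
            )
        return self.n_compartments * self.selected_per_compartment


@dataclass
class BreedingState:
    """Parents of the next breeding cycle, per compartment, plus bookkeeping."""

    generation: int
    compartments: dict[str, Population]
    founder_mean: float
    effects: LocusEffects
    sigma2_e: float
    next_id: int

    def population(self, label: str = "BP") -> Population:
        return self.compartments[label]


# ---------------------------------------------------------------------------
# selection operators


def _ranking(pop: Population) -> np.ndarray:
    """Indices ordered by descending phenotype, ties broken by lower id."""
    return np.lexsort((pop.ids, -pop.phenotype))


def mass_select(pop: Population, k: int, label: str | None = None) -> Population:
    """Truncation selection on phenotype over the whole candidate set."""
    if k > pop.size:
        raise SelectionError(f"cannot select {k} of {pop.size}")
    idx = np.sort(_ranking(pop)[:k])
    return pop.subset(idx, label=label)


def within_family_select(
    pop: Population, k_per_family: int, label: str | None = None
) -> Population:
    """Top ``k_per_family`` by phenotype within each full-sib family."""
    fam_keys = np.stack((pop.mother, pop.father), axis=1)
    _, fam = np.unique(fam_keys, axis=0, return_inverse=True)
    return _segmented_select(pop, fam, k_per_family, label)


def group_mass_select(
    pop: Population, k_per_group: int, label: str | None = None
) -> Population:
    """Truncation selection applied separately within each compartment."""
    return _segmented_select(pop, pop.group, k_per_group, label)


def _segmented_select(
    pop: Population, segment: np.ndarray, k: int, label: str | None
) -> Population:
    order = np.lexsort((pop.ids, -pop.phenotype, segment))
    seg_sorted = segment[order]
    sizes = np.bincount(seg_sorted)
    if np.any(sizes[np.unique(seg_sorted)] < k):
        raise SelectionError(f"a segment holds fewer than {k} candidates")
    offsets = np.concatenate(([0], np.cumsum(sizes)[:-1]))
    rank_within = np.arange(pop.size) - offsets[seg_sorted]
    idx = np.sort(order[rank_within < k])
    return pop.subset(idx, label=label)


# ---------------------------------------------------------------------------
# one breeding cycle


def initialize_state(
    founders: Population,
    config: StrategyConfig,
    founder_mean: float,
    effects: LocusEffects,
    sigma2_e: float,
    rng: np.random.Generator,
) -> BreedingState:
    """Partition the founders into the strategy's compartments.

    Single-population strategies use all founders as one breeding
    population.  SUBL splits them at random into four sublines of 48 and
    SELFL starts one line per founder.  The nucleus strategies rank the
    founders on phenotype: the top 24 seed the nucleus tier, the remaining
    168 seed the main tier.
    """
    n = founders.size
    compartments: dict[str, Population]
    if config.name in ("SBPM", "SBPW", "SELFP"):
        bp = founders.subset(np.arange(n), label="BP")
        bp.group[:] = 0
        compartments = {"BP": bp}
    elif config.name == "SUBL":
        bp = founders.subset(np.arange(n), label="BP")
        per = n // config.n_compartments
        assignment = np.empty(n, dtype=np.int32)
        assignment[rng.permutation(n)] = np.repeat(
            np.arange(config.n_compartments, dtype=np.int32), per
        )
        bp.group[:] = assignment
        compartments = {"BP": bp}
    elif config.name == "SELFL":
        bp = founders.subset(np.arange(n), label="BP")
        bp.group[:] = np.arange(n, dtype=np.int32)
        compartments = {"BP": bp}
    else:  # nucleus strategies
        ranked = _ranking(founders)
        n_nuc = config.nucleus_parents + config.transfer_main_to_nucleus
        nucleus = founders.subset(np.sort(ranked[:n_nuc]), label="nucleus")
        nucleus.group[:] = NUCLEUS
        main = founders.subset(np.sort(ranked[n_nuc:]), label="main")
        main.group[:] = MAIN
        compartments = {"nucleus": nucleus, "main": main}
    return BreedingState(
        generation=0,
        compartments=compartments,
        founder_mean=founder_mean,
        effects=effects,
        sigma2_e=sigma2_e,
        next_id=int(founders.ids.max()) + 1,
    )


def _pair_within_groups(
    pop: Population, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Random perfect matching of parents, respecting compartments."""
    mothers, fathers = [], []
    for g in np.unique(pop.group):
        idx = np.flatnonzero(pop.group == g)
        if idx.size % 2:
            raise ConfigurationError("odd parent count cannot be pair-mated")
        perm = idx[rng.permutation(idx.size)]
        mothers.append(perm[0::2])
        fathers.append(perm[1::2])
    return np.concatenate(mothers), np.concatenate(fathers)


def _pair_mating_progeny(
    state: BreedingState,
    pop: Population,
    progeny_per_cross: int,
    rng: np.random.Generator,
    label: str,
) -> Population:
    m, f = _pair_within_groups(pop, rng)
    progeny = make_progeny(
        pop,
        np.repeat(m, progeny_per_cross),
        np.repeat(f, progeny_per_cross),
        state.effects,
        state.sigma2_e,
        rng,
        start_id=state.next_id,
        label=label,
    )
    state.next_id += progeny.size
    return progeny


def _selfing_progeny(
    state: BreedingState,
    pop: Population,
    progeny_per_parent: int,
    rng: np.random.Generator,
    label: str,
) -> Population:
    idx = np.repeat(np.arange(pop.size), progeny_per_parent)
    progeny = make_progeny(
        pop, idx, idx, state.effects, state.sigma2_e, rng, state.next_id, label=label
    )
    state.next_id += progeny.size
    return progeny


def _merge(pops: list[Population], group: int, label: str) -> Population:
    """Concatenate selections into one compartment, ordered by id."""
    merged = replace(
        pops[0],
        trait=np.concatenate([p.trait for p in pops]),
        neutral=np.concatenate([p.neutral for p in pops]),
        ids=np.concatenate([p.ids for p in pops]),
        mother=np.concatenate([p.mother for p in pops]),
        father=np.concatenate([p.father for p in pops]),
        group=np.full(sum(p.size for p in pops), group, dtype=np.int32),
        gvalue=np.concatenate([p.gvalue for p in pops]),
        phenotype=np.concatenate([p.phenotype for p in pops]),
        label=label,
    )
    order = np.argsort(merged.ids)
    return merged.subset(order, label=label)


def advance_generation(
    state: BreedingState,
    config: StrategyConfig,
    rng: np.random.Generator,
) -> tuple[BreedingState, dict[str, Population]]:
    """Run one full breeding cycle; returns the new state and the progeny.

    The returned progeny populations (before selection) are the candidate
    sets from which the production population's elites are drawn.
    """
    name = config.name
    progeny: dict[str, Population]
    if name in ("SBPM", "SBPW"):
        bp = state.population()
        per_cross = config.progeny_per_compartment // (bp.size // 2)
        prog = _pair_mating_progeny(state, bp, per_cross, rng, "BP")
        if name == "SBPM":
            selected = mass_select(prog, config.total_selected)
        else:
            k = config.total_selected // (bp.size // 2)
            selected = within_family_select(prog, k)
        compartments = {"BP": selected}
        progeny = {"BP": prog}
    elif name == "SUBL":
        bp = state.population()
        crosses_per_subline = config.selected_per_compartment // 2
        per_cross = config.progeny_per_compartment // crosses_per_subline
        prog = _pair_mating_progeny(state, bp, per_cross, rng, "BP")
        selected = group_mass_select(prog, config.selected_per_compartment)
        compartments = {"BP": selected}
        progeny = {"BP": prog}
    elif name == "SELFL":
        bp = state.population()
        prog = _selfing_progeny(state, bp, config.progeny_per_compartment, rng, "BP")
        selected = group_mass_select(prog, 1)  # single seed descent
        compartments = {"BP": selected}
        progeny = {"BP": prog}
    elif name == "SELFP":
        bp = state.population()
        per_parent = config.progeny_per_compartment // bp.size
        prog = _selfing_progeny(state, bp, per_parent, rng, "BP")
        selected = mass_select(prog, config.total_selected)
        compartments = {"BP": selected}
        progeny = {"BP": prog}
    else:  # nucleus strategies
        nucleus, main = state.population("nucleus"), state.population("main")
        nuc_prog = _pair_mating_progeny(
            state, nucleus, config.nucleus_progeny // config.nucleus_crosses, rng,
            "nucleus",
        )
        all_main = np.arange(main.size)
        main_prog = open_pollinate(
            main,
            all_main,
            all_main,
            config.main_progeny,
            state.effects,
            state.sigma2_e,
            rng,
            start_id=state.next_id,
            label="main",
        )
        state.next_id += main_prog.size
        nuc_rank = _ranking(nuc_prog)
        main_rank = _ranking(main_prog)
        if name == "NUCU":
            # dual use allowed: the very best can be both parent and transfer
            nuc_parents = nuc_rank[: config.nucleus_parents]
            nuc_to_main = nuc_rank[: config.transfer_nucleus_to_main]
            main_parents = main_rank[: config.main_parents_own]
            main_to_nuc = main_rank[: config.transfer_main_to_nucleus]
        else:
            # disjoint: transfers are taken first by rank, parents next
            t_nm, t_mn = config.transfer_nucleus_to_main, config.transfer_main_to_nucleus
            nuc_to_main = nuc_rank[:t_nm]
            nuc_parents = nuc_rank[t_nm : t_nm + config.nucleus_parents]
            main_to_nuc = main_rank[:t_mn]
            main_parents = main_rank[t_mn : t_mn + config.main_parents_own]
        new_nucleus = _merge(
            [
                nuc_prog.subset(np.sort(nuc_parents)),
                main_prog.subset(np.sort(main_to_nuc)),
            ],
            NUCLEUS,
            "nucleus",
        )
        new_main = _merge(
            [
                main_prog.subset(np.sort(main_parents)),
                nuc_prog.subset(np.sort(nuc_to_main)),
            ],
            MAIN,
            "main",
        )
        compartments = {"nucleus": new_nucleus, "main": new_main}
        progeny = {"nucleus": nuc_prog, "main": main_prog}

    new_state = BreedingState(
        generation=state.generation + 1,
        compartments=compartments,
        founder_mean=state.founder_mean,
        effects=state.effects,
        sigma2_e=state.sigma2_e,
        next_id=state.next_id,
    )
    return new_state, progeny


def build_production_population(
    state: BreedingState,
    progeny: dict[str, Population],
    config: StrategyConfig,
    rng: np.random.Generator,
) -> Population:
    """Elite selection and outcrossing into the production population.

    24 elite trees are chosen on phenotype: the top 24 of the single
    candidate population (SBPM, SBPW, SELFP), the top 6 within each subline
    (SUBL), the survivors of the 24 best selfing lines (SELFL, lines ranked
    by their survivor's phenotype), or the top 24 of the nucleus progeny
    (NUC).  Elites are paired at random into 12 outcrosses (each elite used
    exactly once, self-mating impossible) of 100 progeny each.
    """
    name = config.name
    if name in ("SBPM", "SBPW", "SELFP"):
        elites = mass_select(progeny["BP"], config.elite_count, label="elite")
    elif name == "SUBL":
        per = config.elite_count // 4
        elites = group_mass_select(progeny["BP"], per, label="elite")
    elif name == "SELFL":
        # each line's single survivor; best 24 lines by survivor phenotype
        survivors = state.population()
        elites = mass_select(survivors, config.elite_count, label="elite")
    else:
        elites = mass_select(progeny["nucleus"], config.elite_count, label="elite")
    if elites.size < config.elite_count:
        raise SelectionError("not enough elite candidates")
    perm = rng.permutation(elites.size)
    mothers = np.repeat(perm[0::2], config.pp_progeny_per_cross)
    fathers = np.repeat(perm[1::2], config.pp_progeny_per_cross)
    pp = make_progeny(
        elites,
        mothers,
        fathers,
        state.effects,
        state.sigma2_e,
        rng,
        start_id=state.next_id,
        group=np.zeros(mothers.size, dtype=np.int32),
        label="PP",
    )
    # the PP belongs to the breeding cycle its elites came from
    pp.generation = state.generation
    state.next_id += pp.size
    return pp
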