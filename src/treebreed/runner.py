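"""Replicate orchestration: configuration, seeding, runs and TSV output.

A run is a (genomic scenario, breeding strategy) pair simulated for a
number of generations and replicates.  Replicate seeds are derived from
the master seed with :class:`numpy.random.SeedSequence` spawning, so runs
are bit-reproducible for a given configuration and master seed and
replicates are statistically independent.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .genome import (
    GenomicScenario,
    build_locus_effects,
    calibrate_environmental_variance,
    hwe_additive_variance,
    hwe_genotypic_variance,
    sample_founder_frequencies,
    scale_to_target,
)
from .population import create_founders
from .stats import aggregate_replicates, summarize_by_group, summarize_population
from .strategies import (
    StrategyConfig,
    advance_generation,
    build_production_population,
    initialize_state,
)

__all__ = [
    "SCENARIO_FAMILIES",
    "RunConfig",
    "scenario_from_name",
    "build_calibrated_genome",
    "run_replicate",
    "run_experiment",
    "write_tsv",
    "read_tsv",
]

#: named allele-frequency / architecture families; combined with a
#: dominance level ("intermediate-complete") they name the nine scenarios
SCENARIO_FAMILIES = {
    "intermediate": dict(frequency_model="intermediate", architecture="uniform"),
    "u_shaped": dict(frequency_model="u_shaped", architecture="uniform"),
    "major_minor": dict(frequency_model="intermediate", architecture="major_minor"),
}


def scenario_from_name(name: str, **overrides) -> GenomicScenario:
    """Build a scenario from a ``family-dominance`` name.

    E.g. ``"intermediate-complete"``, ``"u_shaped-additive"``,
    ``"major_minor-partial"``.
    """
    family, _, dominance = name.rpartition("-")
    if family not in SCENARIO_FAMILIES:
        raise ValueError(f"unknown scenario family in {name!r}")
    return GenomicScenario(
        dominance_level=dominance, **SCENARIO_FAMILIES[family], **overrides
    )


@dataclass(frozen=True)
class RunConfig:
    """Flat key-value run configuration (YAML-compatible)."""

    strategy: str = "SBPM"
    dominance_level: str = "additive"
    architecture: str = "uniform"
    frequency_model: str = "intermediate"
    ne: int = 192
    target_sigma_a2: float = 50.0
    h2: float = 0.3
    n_trait_loci: int = 100
    n_neutral_loci: int = 100
    n_founders: int = 192
    n_generations: int = 20
    n_replicates: int = 500
    master_seed: int = 1
    intensified_selection_factor: int = 1
    pp_progeny_per_cross: int = 100
    track_pp: bool = True
    report_generations: tuple[int, ...] | None = None  # None = all

    def __post_init__(self) -> None:
        if self.n_generations < 1 or self.n_replicates < 1:
            raise ValueError("generations and replicates must be >= 1")

    def scenario(self) -> GenomicScenario:
        return GenomicScenario(
            dominance_level=self.dominance_level,
            architecture=self.architecture,
            frequency_model=self.frequency_model,
            ne=self.ne,
            target_additive_variance=self.target_sigma_a2,
            heritability=self.h2,
            n_trait_loci=self.n_trait_loci,
            n_neutral_loci=self.n_neutral_loci,
            n_founders=self.n_founders,
        )

    def strategy_config(self) -> StrategyConfig:
        return StrategyConfig.preset(
            self.strategy,
            intensified_selection_factor=self.intensified_selection_factor,
            pp_progeny_per_cross=self.pp_progeny_per_cross,
        )

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        if "report_generations" in d and d["report_generations"] is not None:
            d = dict(d, report_generations=tuple(d["report_generations"]))
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)


def build_calibrated_genome(
    scenario: GenomicScenario, rng: np.random.Generator
):
    """Sample founder frequencies, scale effects, calibrate sigma2_E.

    Returns ``(p, effects, sigma2_e)`` with the effects scaled so the
    founder HWE additive variance equals the scenario target and the
    environmental variance giving the target founder heritability.
    """
    effects = build_locus_effects(scenario)
    p = sample_founder_frequencies(scenario, rng)
    effects, _ = scale_to_target(effects, p, scenario.target_additive_variance)
    sigma2_e = calibrate_environmental_variance(
        hwe_additive_variance(p, effects),
        hwe_genotypic_variance(p, effects),
        scenario.heritability,
    )
    return p, effects, sigma2_e


def run_replicate(config: RunConfig, replicate_seed) -> pd.DataFrame:
    """Simulate one replicate; returns the per-generation summary table.

    Deterministic given (config, replicate_seed).  The genome is built and
    calibrated, founders created, and the strategy advanced for
    ``n_generations`` cycles; one row is emitted per tracked population
    (breeding compartments pooled per tier, plus the production
    population) and generation.
    """
    rng = np.random.default_rng(replicate_seed)
    scenario = config.scenario()
    strat = config.strategy_config()
    p, effects, sigma2_e = build_calibrated_genome(scenario, rng)
    founders = create_founders(scenario, p, effects, sigma2_e, rng)
    founder_mean = float(founders.gvalue.mean())
    state = initialize_state(founders, strat, founder_mean, effects, sigma2_e, rng)

    rows = []

    def _emit(pop, label):
        rows.append(
            summarize_by_group(pop, effects, founder_mean, label).as_dict()
        )

    for label, pop in state.compartments.items():
        _emit(pop, label)
    wanted = (
        None
        if config.report_generations is None
        else set(config.report_generations)
    )
    for _ in range(config.n_generations):
        state, progeny = advance_generation(state, strat, rng)
        keep = wanted is None or state.generation in wanted
        if keep:
            for label, pop in state.compartments.items():
                _emit(pop, label)
        if config.track_pp and keep:
            pp = build_production_population(state, progeny, strat, rng)
            rows.append(
                summarize_population(pp, effects, founder_mean, "PP").as_dict()
            )
    return pd.DataFrame(rows)


def run_experiment(
    config: RunConfig, progress: bool = False
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run all replicates; returns (per-replicate table, aggregate table).

    Replicates that raise are reported and excluded; the run fails if more
    than 1% of them do.
    """
    seeds = np.random.SeedSequence(config.master_seed).spawn(config.n_replicates)
    iterator = enumerate(seeds)
    if progress:
        from tqdm import tqdm

        iterator = tqdm(list(iterator), desc=f"{config.strategy}", unit="rep")
    tables, failures = [], []
    for i, seed in iterator:
        try:
            table = run_replicate(config, seed)
        except Exception as exc:  # noqa: BLE001 - partial-failure policy
            failures.append((i, repr(exc)))
            continue
        table.insert(0, "replicate", i)
        tables.append(table)
    if len(failures) > max(0.01 * config.n_replicates, 0):
        raise RuntimeError(
            f"{len(failures)} of {config.n_replicates} replicates failed; "
            f"first: replicate {failures[0][0]}: {failures[0][1]}"
        )
    replicate_table = pd.concat(tables, ignore_index=True)
    return replicate_table, aggregate_replicates(replicate_table)


def write_tsv(df: pd.DataFrame, path: str | Path, config: RunConfig) -> None:
    """Write a table as TSV with a '#'-prefixed self-describing header."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for key, value in config.as_dict().items():
            fh.write(f"# {key} = {value}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_tsv(path: str | Path) -> pd.DataFrame:
    """Read a table written by :func:`write_tsv` (header lines skipped)."""
    return pd.read_csv(path, sep="\t", comment="#")
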