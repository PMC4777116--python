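"""Individuals, meiosis, mating operators and identity-by-descent tracking.

A :class:`Population` stores one generation's individuals as a structure of
arrays: trait genotypes are a ``(n, 2, n_trait_loci)`` array of {0, 1}
allele codes (1 = favorable), and neutral genotypes a ``(n, 2,
n_neutral_loci)`` array of integer allele labels.  Every founder carries a
unique pair of labels at every neutral locus, so identity-by-state at
neutral loci *is* identity-by-descent, and the inbreeding coefficient of an
individual is simply the fraction of neutral loci at which its two labels
coincide.

All loci are unlinked: a gamete picks one of the two parental alleles
independently at every locus (trait and neutral alike).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .genome import FounderFrequencies, GenomicScenario, LocusEffects

__all__ = [
    "Population",
    "create_founders",
    "genotypic_values",
    "assign_phenotypes",
    "make_gametes",
    "make_progeny",
    "cross",
    "self_cross",
    "open_pollinate",
    "inbreeding_coefficients",
    "population_inbreeding",
]

FOUNDER_PARENT = -1  #: sentinel parent id for founders


class NoValidFatherError(ValueError):
    """Open pollination where the only available father is the mother."""


@dataclass
class Population:
    """One generation of individuals (structure-of-arrays).

    ``group`` labels the breeding compartment (line, subline or tier index)
    an individual belongs to; single-population strategies use group 0.
    """

    trait: np.ndarray  # (n, 2, n_trait_loci) uint8, allele codes {0, 1}
    neutral: np.ndarray  # (n, 2, n_neutral_loci) int16, founder allele labels
    ids: np.ndarray  # (n,) int64, unique within a replicate
    mother: np.ndarray  # (n,) int64, FOUNDER_PARENT for founders
    father: np.ndarray  # (n,) int64
    group: np.ndarray  # (n,) int32 compartment index
    gvalue: np.ndarray  # (n,) float64 genotypic value
    phenotype: np.ndarray  # (n,) float64
    generation: int = 0
    label: str = "BP"

    def __post_init__(self) -> None:
        if self.size == 0:
            raise ValueError("population must be nonempty")

    @property
    def size(self) -> int:
        return self.trait.shape[0]

    @property
    def n_trait_loci(self) -> int:
        return self.trait.shape[2]

    @property
    def n_neutral_loci(self) -> int:
        return self.neutral.shape[2]

    def allele_counts(self) -> np.ndarray:
        """Favorable-allele dosage per individual and locus, values {0, 1, 2}."""
        return self.trait.sum(axis=1, dtype=np.int64)

    def subset(self, idx: np.ndarray, label: str | None = None) -> "Population":
        """A new population holding the selected individuals (copies)."""
        idx = np.asarray(idx)
        return replace(
            self,
            trait=self.trait[idx].copy(),
            neutral=self.neutral[idx].copy(),
            ids=self.ids[idx].copy(),
            mother=self.mother[idx].copy(),
            father=self.father[idx].copy(),
            group=self.group[idx].copy(),
            gvalue=self.gvalue[idx].copy(),
            phenotype=self.phenotype[idx].copy(),
            label=self.label if label is None else label,
        )

    def to_frame(self):
        """Tabular debug dump: one row per individual."""
        import pandas as pd

        return pd.DataFrame(
            {
                "id": self.ids,
                "mother_id": self.mother,
                "father_id": self.father,
                "group": self.group,
                "F": inbreeding_coefficients(self),
                "genotypic_value": self.gvalue,
                "phenotype": self.phenotype,
            }
        )


def genotypic_values(trait: np.ndarray, effects: LocusEffects) -> np.ndarray:
    """Genotypic value under the a/d coding.

    Per locus: +a for the favorable homozygote, d for the heterozygote,
    -a for the unfavorable homozygote; values sum over loci.
    """
    g0 = trait[:, 0, :]
    g1 = trait[:, 1, :]
    dosage = (g0 + g1).astype(np.float64)  # (n, L) in {0, 1, 2}
    het = (g0 != g1).astype(np.float64)
    return dosage @ effects.a - effects.a.sum() + het @ effects.d


def assign_phenotypes(
    gvalue: np.ndarray, sigma2_e: float, rng: np.random.Generator
) -> np.ndarray:
    """Phenotype = genotypic value + i.i.d. Normal(0, sigma2_e) deviate."""
    if sigma2_e < 0:
        raise ValueError("environmental variance must be nonnegative")
    if sigma2_e == 0:
        return gvalue.astype(float, copy=True)
    return gvalue + rng.normal(0.0, np.sqrt(sigma2_e), size=gvalue.shape)


def create_founders(
    scenario: GenomicScenario,
    p: FounderFrequencies,
    effects: LocusEffects,
    sigma2_e: float,
    rng: np.random.Generator,
    start_id: int = 0,
) -> Population:
    """Unrelated founder individuals at Hardy-Weinberg proportions.

    Trait alleles are drawn Bernoulli(p_i) independently per haplotype;
    founder k carries the unique labels (2k, 2k+1) at every neutral locus,
    so the founder generation has inbreeding coefficient exactly 0.
    """
    n = scenario.n_founders
    trait = (
        rng.random((n, 2, scenario.n_trait_loci)) < p.p[None, None, :]
    ).astype(np.uint8)
    labels = np.arange(2 * n, dtype=np.int16).reshape(n, 2)
    neutral = np.repeat(labels[:, :, None], scenario.n_neutral_loci, axis=2)
    gvalue = genotypic_values(trait, effects)
    return Population(
        trait=trait,
        neutral=neutral,
        ids=start_id + np.arange(n, dtype=np.int64),
        mother=np.full(n, FOUNDER_PARENT, dtype=np.int64),
        father=np.full(n, FOUNDER_PARENT, dtype=np.int64),
        group=np.zeros(n, dtype=np.int32),
        gvalue=gvalue,
        phenotype=assign_phenotypes(gvalue, sigma2_e, rng),
        generation=0,
        label="founders",
    )


def make_gametes(
    genotypes: np.ndarray, parent_idx: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """One gamete per entry of ``parent_idx``: independent assortment.

    At each locus one of the parent's two alleles is transmitted with
    probability 1/2, independently across loci and gametes.
    """
    parent_idx = np.asarray(parent_idx)
    n_loci = genotypes.shape[2]
    # one random bit per (gamete, locus); low bit of a raw byte stream
    pick = (
        np.frombuffer(rng.bytes(parent_idx.size * n_loci), dtype=np.uint8)
        & np.uint8(1)
    ).reshape(parent_idx.size, n_loci)
    h0 = genotypes[parent_idx, 0, :]
    h1 = genotypes[parent_idx, 1, :]
    diff = h0 ^ h1
    if genotypes.dtype == np.uint8:
        return h0 ^ (diff & pick)
    # integer labels: expand the bit to an all-ones mask of the label dtype
    return h0 ^ (diff & -pick.astype(genotypes.dtype))


def make_progeny(
    pop: Population,
    mother_idx: np.ndarray,
    father_idx: np.ndarray,
    effects: LocusEffects,
    sigma2_e: float,
    rng: np.random.Generator,
    start_id: int,
    group: np.ndarray | None = None,
    label: str | None = None,
) -> Population:
    """Progeny from per-progeny parent index arrays (selfing when equal).

    Progeny inherit their mother's compartment label unless ``group``
    overrides it.
    """
    mother_idx = np.asarray(mother_idx)
    father_idx = np.asarray(father_idx)
    if mother_idx.size != father_idx.size or mother_idx.size == 0:
        raise ValueError("mother and father index arrays must match and be nonempty")
    n = mother_idx.size
    trait = np.empty((n, 2, pop.n_trait_loci), dtype=np.uint8)
    trait[:, 0, :] = make_gametes(pop.trait, mother_idx, rng)
    trait[:, 1, :] = make_gametes(pop.trait, father_idx, rng)
    neutral = np.empty((n, 2, pop.n_neutral_loci), dtype=pop.neutral.dtype)
    neutral[:, 0, :] = make_gametes(pop.neutral, mother_idx, rng)
    neutral[:, 1, :] = make_gametes(pop.neutral, father_idx, rng)
    gvalue = genotypic_values(trait, effects)
    return Population(
        trait=trait,
        neutral=neutral,
        ids=start_id + np.arange(n, dtype=np.int64),
        mother=pop.ids[mother_idx].astype(np.int64),
        father=pop.ids[father_idx].astype(np.int64),
        group=(pop.group[mother_idx] if group is None else np.asarray(group)).astype(
            np.int32
        ),
        gvalue=gvalue,
        phenotype=assign_phenotypes(gvalue, sigma2_e, rng),
        generation=pop.generation + 1,
        label=pop.label if label is None else label,
    )


def cross(
    pop: Population,
    mother_idx: int,
    father_idx: int,
    n_progeny: int,
    effects: LocusEffects,
    sigma2_e: float,
    rng: np.random.Generator,
    start_id: int = 0,
    label: str | None = None,
) -> Population:
    """A single (out- or self-) cross producing ``n_progeny`` individuals."""
    if n_progeny < 1:
        raise ValueError("n_progeny must be >= 1")
    m = np.full(n_progeny, mother_idx)
    f = np.full(n_progeny, father_idx)
    return make_progeny(pop, m, f, effects, sigma2_e, rng, start_id, label=label)


def self_cross(
    pop: Population,
    parent_idx: int,
    n_progeny: int,
    effects: LocusEffects,
    sigma2_e: float,
    rng: np.random.Generator,
    start_id: int = 0,
    label: str | None = None,
) -> Population:
    """Self-mating: the mother == father case of :func:`cross`."""
    return cross(
        pop, parent_idx, parent_idx, n_progeny, effects, sigma2_e, rng, start_id, label
    )


def even_allocation(total: int, n_mothers: int) -> np.ndarray:
    """Split ``total`` progeny among mothers as evenly as possible.

    The remainder is distributed round-robin over mothers in id order,
    which is deterministic given the seed and unbiased in expectation.
    """
    base, extra = divmod(total, n_mothers)
    counts = np.full(n_mothers, base, dtype=np.int64)
    counts[:extra] += 1
    return counts


def open_pollinate(
    pop: Population,
    mother_idx: np.ndarray,
    father_pool_idx: np.ndarray,
    total_progeny: int,
    effects: LocusEffects,
    sigma2_e: float,
    rng: np.random.Generator,
    start_id: int = 0,
    label: str | None = None,
) -> Population:
    """Open pollination: each progeny's father drawn uniformly from the pool.

    The total progeny count is divided as evenly as possible among mothers;
    each progeny's father is sampled with replacement from the father pool
    excluding the mother herself (no selfing).
    """
    mother_idx = np.asarray(mother_idx)
    father_pool_idx = np.asarray(father_pool_idx)
    if mother_idx.size == 0 or father_pool_idx.size == 0:
        raise ValueError("mother and father pools must be nonempty")
    pool = father_pool_idx
    if pool.size == 1 and np.any(mother_idx == pool[0]):
        raise NoValidFatherError("father pool contains only the mother")
    counts = even_allocation(total_progeny, mother_idx.size)
    mothers = np.repeat(mother_idx, counts)
    fathers = pool[rng.integers(0, pool.size, size=mothers.size)]
    # resample fathers that collided with their own mother (selfing excluded)
    bad = fathers == mothers
    while np.any(bad):
        fathers[bad] = pool[rng.integers(0, pool.size, size=int(bad.sum()))]
        bad = fathers == mothers
    return make_progeny(
        pop, mothers, fathers, effects, sigma2_e, rng, start_id, label=label
    )


def inbreeding_coefficients(pop: Population) -> np.ndarray:
    """Per-individual F: fraction of neutral loci with two identical labels.

    Founder neutral alleles are unique, so identity-by-state equals
    identity-by-descent and this is the pedigree inbreeding coefficient's
    realized value.
    """
    return (pop.neutral[:, 0, :] == pop.neutral[:, 1, :]).mean(axis=1)


def population_inbreeding(pop: Population) -> float:
    """Mean inbreeding coefficient over the population."""
    return float(inbreeding_coefficients(pop).mean())
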