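"""Per-generation summary statistics of simulated populations.

Everything here is computed from true genotypes, not estimated from
phenotypes: genetic gain relative to the founder mean, identity-by-descent
inbreeding, the realized inbreeding-depression capacity mu_D (the
dominance contribution summed over heterozygous loci), unfavorable /
favorable fixation, and a variance decomposition separating the genic
additive variance from the linkage-disequilibrium covariance.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .genome import LocusEffects
from .population import Population, population_inbreeding

__all__ = [
    "GenerationSummary",
    "VarianceComponents",
    "FixationStats",
    "realized_id_capacity",
    "genetic_gain",
    "allele_frequencies",
    "fixation_stats",
    "variance_components",
    "id_per_sigma",
    "summarize_population",
    "summarize_by_group",
    "aggregate_replicates",
]


@dataclass(frozen=True)
class FixationStats:
    """Loci at which one allele is lost from the population."""

    n_fixed_unfavorable: int
    n_fixed_favorable: int
    pct_fixed_unfavorable: float  # percent of the evaluated locus class
    pct_fixed_favorable: float


@dataclass(frozen=True)
class VarianceComponents:
    """Genetic variance decomposition at the current allele frequencies.

    ``sigma2_A`` is the sample variance of per-individual breeding-value
    scores sum_i alpha_i (x_i - 2 p_i) at current frequencies and average
    effects; ``genic_variance`` is the corresponding no-association closed
    form sum 2 p q alpha^2 (1 + F_i), with F_i the locus-wise heterozygote
    deficit; their difference is the linkage-disequilibrium covariance.
    """

    sigma2_G: float
    sigma2_A: float
    sigma2_D: float
    genic_variance: float
    ld_covariance: float


def realized_id_capacity(pop: Population, effects: LocusEffects) -> float:
    """Realized ID capacity mu_D = mean over individuals of sum_j d_j H_ij.

    H_ij indicates heterozygosity of individual i at locus j; mu_D is the
    average genetic value currently protected by heterozygosity at
    dominance loci — the gain that would be lost on complete inbreeding.
    """
    het = pop.allele_counts() == 1
    return float((het @ effects.d).mean())


def genetic_gain(pop: Population, founder_mean: float) -> float:
    """Mean genotypic value minus the founder-generation mean."""
    return float(pop.gvalue.mean() - founder_mean)


def allele_frequencies(pop: Population) -> np.ndarray:
    """Current favorable-allele frequency per trait locus."""
    return pop.allele_counts().mean(axis=0) / 2.0


def fixation_stats(
    pop: Population,
    effects: LocusEffects,
    locus_class: np.ndarray | None = None,
) -> FixationStats:
    """Count loci fixed for the unfavorable / favorable allele.

    A locus is unfavorably fixed iff every individual is homozygous for
    the allele with the negative additive effect.  Percentages are taken
    relative to the size of ``locus_class`` (a boolean mask; default all
    trait loci), so major- and minor-locus fixation can be reported on
    their own denominators.
    """
    counts = pop.allele_counts()
    if locus_class is None:
        locus_class = np.ones(pop.n_trait_loci, dtype=bool)
    counts = counts[:, locus_class]
    n_class = counts.shape[1]
    unfav = int(np.sum(counts.max(axis=0) == 0))
    fav = int(np.sum(counts.min(axis=0) == 2))
    return FixationStats(
        n_fixed_unfavorable=unfav,
        n_fixed_favorable=fav,
        pct_fixed_unfavorable=100.0 * unfav / n_class,
        pct_fixed_favorable=100.0 * fav / n_class,
    )


def variance_components(
    pop: Population, effects: LocusEffects
) -> VarianceComponents:
    """Decompose the genotypic variance at current allele frequencies.

    Uses the gene-content score per locus (average effect alpha at the
    population's own frequencies); the genic term inflates 2 p q alpha^2 by
    (1 + F_i) with F_i = 1 - H_obs / (2 p q) floored at -1, the textbook
    form under departures from Hardy-Weinberg proportions.
    """
    if pop.size < 2:
        raise ValueError("variance components require at least two individuals")
    counts = pop.allele_counts().astype(float)
    p = counts.mean(axis=0) / 2.0
    q = 1.0 - p
    alpha = effects.average_effects(p)
    scores = (counts - 2.0 * p) @ alpha
    sigma2_a = float(np.var(scores, ddof=1))
    sigma2_g = float(np.var(pop.gvalue, ddof=1))
    h_obs = (counts == 1.0).mean(axis=0)
    pq2 = 2.0 * p * q
    with np.errstate(divide="ignore", invalid="ignore"):
        f_locus = np.where(pq2 > 0, 1.0 - h_obs / pq2, 0.0)
    f_locus = np.maximum(f_locus, -1.0)
    genic = float(np.sum(pq2 * alpha**2 * (1.0 + f_locus)))
    return VarianceComponents(
        sigma2_G=sigma2_g,
        sigma2_A=sigma2_a,
        sigma2_D=sigma2_g - sigma2_a,
        genic_variance=genic,
        ld_covariance=sigma2_a - genic,
    )


def id_per_sigma(id_percent: float, cva_percent: float) -> float:
    """Convert a literature ID percentage to mu_D per additive genetic SD.

    Empirical inbreeding depression is usually reported as a percentage of
    the non-inbred mean; dividing by the percentage additive genetic
    coefficient of variation (CV_A = 100 sigma_A / mu) yields mu_D /
    sigma_A, directly comparable across traits and to simulated scenarios.
    """
    if cva_percent <= 0:
        raise ValueError("CV_A must be positive")
    return id_percent / cva_percent


@dataclass(frozen=True)
class GenerationSummary:
    """Statistics of one population at one generation."""

    generation: int
    population: str
    n: int
    mean_genotypic_value: float
    genetic_gain: float
    mean_F: float
    mu_D: float
    mean_p_favorable: float
    n_fixed_unfavorable: float
    pct_fixed_unfavorable: float
    n_fixed_favorable: float
    pct_fixed_favorable: float
    sigma2_G: float
    sigma2_A: float
    sigma2_D: float
    genic_variance: float
    ld_covariance: float
    pct_fixed_unfavorable_major: float = float("nan")
    pct_fixed_unfavorable_minor: float = float("nan")

    def as_dict(self) -> dict:
        return asdict(self)


def summarize_population(
    pop: Population,
    effects: LocusEffects,
    founder_mean: float,
    population_label: str | None = None,
) -> GenerationSummary:
    """All summary statistics of one (pooled) population."""
    fx = fixation_stats(pop, effects)
    vc = variance_components(pop, effects)
    major = effects.major
    pct_major = pct_minor = float("nan")
    if major is not None:
        pct_major = fixation_stats(pop, effects, major).pct_fixed_unfavorable
        pct_minor = fixation_stats(pop, effects, ~major).pct_fixed_unfavorable
    return GenerationSummary(
        generation=pop.generation,
        population=population_label or pop.label,
        n=pop.size,
        mean_genotypic_value=float(pop.gvalue.mean()),
        genetic_gain=genetic_gain(pop, founder_mean),
        mean_F=population_inbreeding(pop),
        mu_D=realized_id_capacity(pop, effects),
        mean_p_favorable=float(allele_frequencies(pop).mean()),
        n_fixed_unfavorable=fx.n_fixed_unfavorable,
        pct_fixed_unfavorable=fx.pct_fixed_unfavorable,
        n_fixed_favorable=fx.n_fixed_favorable,
        pct_fixed_favorable=fx.pct_fixed_favorable,
        sigma2_G=vc.sigma2_G,
        sigma2_A=vc.sigma2_A,
        sigma2_D=vc.sigma2_D,
        genic_variance=vc.genic_variance,
        ld_covariance=vc.ld_covariance,
        pct_fixed_unfavorable_major=pct_major,
        pct_fixed_unfavorable_minor=pct_minor,
    )


def summarize_by_group(
    pop: Population,
    effects: LocusEffects,
    founder_mean: float,
    population_label: str | None = None,
) -> GenerationSummary:
    """Summary for a compartmented population (lines / sublines).

    Fixation is evaluated inside each compartment and averaged over
    compartments — a closed selfing line of one survivor can be fixed
    while the pooled 192 lines are not.  Gain, F, mu_D and allele
    frequencies are individual-level means and therefore identical to the
    pooled computation; variance components are computed on the pooled
    population (between- plus within-compartment variation).
    """
    groups = np.unique(pop.group)
    if groups.size == 1:
        return summarize_population(pop, effects, founder_mean, population_label)
    counts = pop.allele_counts()
    major = effects.major

    def _pct(mask: np.ndarray | None) -> tuple[float, float, float]:
        sub = counts if mask is None else counts[:, mask]
        n_class = sub.shape[1]
        unfav = fav = 0.0
        for g in groups:
            rows = sub[pop.group == g]
            unfav += np.sum(rows.max(axis=0) == 0)
            fav += np.sum(rows.min(axis=0) == 2)
        k = groups.size
        return unfav / k, fav / k, n_class

    unfav_all, fav_all, n_all = _pct(None)
    pct_major = pct_minor = float("nan")
    if major is not None:
        u_maj, _, n_maj = _pct(major)
        u_min, _, n_min = _pct(~major)
        pct_major = 100.0 * u_maj / n_maj
        pct_minor = 100.0 * u_min / n_min
    vc = variance_components(pop, effects)
    return GenerationSummary(
        generation=pop.generation,
        population=population_label or pop.label,
        n=pop.size,
        mean_genotypic_value=float(pop.gvalue.mean()),
        genetic_gain=genetic_gain(pop, founder_mean),
        mean_F=population_inbreeding(pop),
        mu_D=realized_id_capacity(pop, effects),
        mean_p_favorable=float(allele_frequencies(pop).mean()),
        n_fixed_unfavorable=unfav_all,
        pct_fixed_unfavorable=100.0 * unfav_all / n_all,
        n_fixed_favorable=fav_all,
        pct_fixed_favorable=100.0 * fav_all / n_all,
        sigma2_G=vc.sigma2_G,
        sigma2_A=vc.sigma2_A,
        sigma2_D=vc.sigma2_D,
        genic_variance=vc.genic_variance,
        ld_covariance=vc.ld_covariance,
        pct_fixed_unfavorable_major=pct_major,
        pct_fixed_unfavorable_minor=pct_minor,
    )


_ID_COLUMNS = ["generation", "population"]


def aggregate_replicates(replicate_table: pd.DataFrame) -> pd.DataFrame:
    """Replicate mean, SD and quantiles per (generation, population) cell.

    Expects the long per-replicate table produced by the experiment runner
    (one row per replicate x generation x population).  A single replicate
    yields SD 0 with ``sd_defined = False``.  The result is invariant to
    replicate order.
    """
    if replicate_table.empty:
        raise ValueError("no replicate summaries to aggregate")
    value_cols = [
        c
        for c in replicate_table.columns
        if c not in _ID_COLUMNS + ["replicate"]
        and pd.api.types.is_numeric_dtype(replicate_table[c])
    ]
    grouped = replicate_table.groupby(_ID_COLUMNS, sort=True)[value_cols]
    n_rep = grouped.size().rename("n_replicates")
    mean = grouped.mean().add_suffix("_mean")
    sd = grouped.std(ddof=1).fillna(0.0).add_suffix("_sd")
    quantiles = {}
    for tag, q in [("min", 0.0), ("q1", 0.25), ("median", 0.5), ("q3", 0.75), ("max", 1.0)]:
        quantiles[tag] = grouped.quantile(q).add_suffix(f"_{tag}")
    out = pd.concat([n_rep, mean, sd, *quantiles.values()], axis=1).reset_index()
    out["sd_defined"] = out["n_replicates"] > 1
    return out
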