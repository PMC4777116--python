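"""Virtual genome construction and calibration.

The trait is controlled by a finite set of unlinked biallelic loci, each
with an additive effect ``a`` and a directional dominance effect ``d``
(``0 <= d <= a``, favorable allele coded 1).  A genomic scenario combines a
dominance level (none / partial / complete), an effect-size architecture
(uniform, or 20 major + 80 minor loci), and a founder allele-frequency
model (all intermediate at 0.5, or the neutral U-shaped spectrum for a
given effective population size).

To compare scenarios at equal starting conditions, effects are rescaled so
that the Hardy-Weinberg additive variance of the founder generation equals
a fixed target (50 trait-units^2 by default), and the environmental
variance is calibrated once so that the founder narrow-sense heritability
equals its target (0.3 by default).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "DOMINANCE_LEVELS",
    "ARCHITECTURES",
    "FREQUENCY_MODELS",
    "GenomicScenario",
    "LocusEffects",
    "FounderFrequencies",
    "build_locus_effects",
    "sample_founder_frequencies",
    "hwe_additive_variance",
    "hwe_dominance_variance",
    "hwe_genotypic_variance",
    "scale_to_target",
    "expected_id_capacity",
    "calibrate_environmental_variance",
]

DOMINANCE_LEVELS = ("additive", "partial", "complete")
ARCHITECTURES = ("uniform", "major_minor")
FREQUENCY_MODELS = ("intermediate", "u_shaped")

#: d/a ratio implied by each dominance level
_DOMINANCE_RATIO = {"additive": 0.0, "partial": 0.5, "complete": 1.0}


class ConfigurationError(ValueError):
    """Invalid scenario or strategy configuration."""


class DegenerateGenomeError(ValueError):
    """A genome whose initial additive variance is zero cannot be scaled."""


class CalibrationError(ValueError):
    """Heritability calibration produced a negative environmental variance."""


@dataclass(frozen=True)
class GenomicScenario:
    """One cell of the dominance-level x architecture x frequency grid.

    Parameters
    ----------
    dominance_level
        ``additive`` (d = 0), ``partial`` (d = a/2) or ``complete`` (d = a).
    architecture
        ``uniform`` (all loci a = 1) or ``major_minor`` (20 loci with a = 5
        carrying all dominance, 80 loci with a = 1 and d = 0).
    frequency_model
        ``intermediate`` (every founder frequency exactly 0.5) or
        ``u_shaped`` (neutral-equilibrium spectrum truncated at 1/(2Ne)).
    ne
        Effective population size parameterizing the U-shaped spectrum.
    target_additive_variance
        Founder Hardy-Weinberg additive variance after effect scaling.
    heritability
        Narrow-sense heritability of the founder generation, used to
        calibrate the environmental variance.
    """

    dominance_level: str = "additive"
    architecture: str = "uniform"
    frequency_model: str = "intermediate"
    ne: int = 192
    target_additive_variance: float = 50.0
    heritability: float = 0.3
    n_trait_loci: int = 100
    n_major_loci: int = 20
    n_neutral_loci: int = 100
    n_founders: int = 192

    def __post_init__(self) -> None:
        if self.dominance_level not in DOMINANCE_LEVELS:
            raise ConfigurationError(
                f"unknown dominance level {self.dominance_level!r}"
            )
        if self.architecture not in ARCHITECTURES:
            raise ConfigurationError(f"unknown architecture {self.architecture!r}")
        if self.frequency_model not in FREQUENCY_MODELS:
            raise ConfigurationError(
                f"unknown frequency model {self.frequency_model!r}"
            )
        if self.ne < 1:
            raise ConfigurationError("effective population size must be >= 1")
        if not 0.0 < self.heritability <= 1.0:
            raise ConfigurationError("heritability must lie in (0, 1]")
        if self.target_additive_variance <= 0:
            raise ConfigurationError("target additive variance must be positive")
        if self.architecture == "major_minor" and not (
            0 < self.n_major_loci < self.n_trait_loci
        ):
            raise ConfigurationError("major loci must be a proper subset of trait loci")


@dataclass(frozen=True)
class LocusEffects:
    """Per-locus additive (a) and dominance (d) effects, favorable allele = 1."""

    a: np.ndarray
    d: np.ndarray
    major: np.ndarray = field(default=None)  # boolean mask; None = all one class

    def __post_init__(self) -> None:
        a = np.asarray(self.a, dtype=float)
        d = np.asarray(self.d, dtype=float)
        if a.shape != d.shape or a.ndim != 1:
            raise ValueError("a and d must be 1-D arrays of equal length")
        if np.any(a <= 0):
            raise ValueError("additive effects must be strictly positive")
        if np.any(d < 0) or np.any(d > a + 1e-12):
            raise ValueError("dominance must be directional: 0 <= d <= a")
        object.__setattr__(self, "a", a)
        object.__setattr__(self, "d", d)
        if self.major is not None:
            object.__setattr__(self, "major", np.asarray(self.major, dtype=bool))

    @property
    def n_loci(self) -> int:
        return self.a.size

    def average_effects(self, p: np.ndarray) -> np.ndarray:
        """Average allele-substitution effects alpha_i = a_i + d_i (1 - 2 p_i)."""
        return self.a + self.d * (1.0 - 2.0 * np.asarray(p, dtype=float))

    def scaled(self, factor: float) -> "LocusEffects":
        return replace(self, a=self.a * factor, d=self.d * factor)


@dataclass(frozen=True)
class FounderFrequencies:
    """Favorable-allele frequency per trait locus in the founder gene pool."""

    p: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.p, dtype=float)
        if np.any(p <= 0.0) or np.any(p >= 1.0):
            raise ValueError("founder frequencies must lie strictly in (0, 1)")
        object.__setattr__(self, "p", p)

    @property
    def n_loci(self) -> int:
        return self.p.size


def build_locus_effects(scenario: GenomicScenario) -> LocusEffects:
    """Unscaled effect sizes for a scenario.

    Uniform architecture: every locus has a = 1 and d = a * dominance ratio.
    Major/minor architecture: the major loci get a = 5 and carry all of the
    dominance; the minor loci are purely additive with a = 1.
    """
    n = scenario.n_trait_loci
    ratio = _DOMINANCE_RATIO[scenario.dominance_level]
    if scenario.architecture == "uniform":
        a = np.ones(n)
        d = np.full(n, ratio)
        major = None
    else:
        major = np.zeros(n, dtype=bool)
        major[: scenario.n_major_loci] = True
        a = np.where(major, 5.0, 1.0)
        d = np.where(major, 5.0 * ratio, 0.0)
    return LocusEffects(a=a, d=d, major=major)


def sample_founder_frequencies(
    scenario: GenomicScenario, rng: np.random.Generator
) -> FounderFrequencies:
    """Draw founder favorable-allele frequencies per trait locus.

    The U-shaped model uses the neutral-equilibrium density proportional to
    1/(x(1-x)), truncated to [1/(2Ne), 1 - 1/(2Ne)].  Its CDF is linear in
    logit(x), so inverse-CDF sampling reduces to drawing a uniform on the
    truncated logit range and applying the logistic function.
    """
    n = scenario.n_trait_loci
    if scenario.frequency_model == "intermediate":
        return FounderFrequencies(np.full(n, 0.5))
    lo = 1.0 / (2.0 * scenario.ne)
    logit_lo = np.log(lo / (1.0 - lo))
    u = rng.uniform(logit_lo, -logit_lo, size=n)
    return FounderFrequencies(1.0 / (1.0 + np.exp(-u)))


def hwe_additive_variance(p: FounderFrequencies, effects: LocusEffects) -> float:
    """Additive variance sum(2 p q alpha^2) at Hardy-Weinberg proportions."""
    _check_lengths(p, effects)
    q = 1.0 - p.p
    alpha = effects.average_effects(p.p)
    return float(np.sum(2.0 * p.p * q * alpha**2))


def hwe_dominance_variance(p: FounderFrequencies, effects: LocusEffects) -> float:
    """Dominance variance sum((2 p q d)^2) at Hardy-Weinberg proportions."""
    _check_lengths(p, effects)
    return float(np.sum((2.0 * p.p * (1.0 - p.p) * effects.d) ** 2))


def hwe_genotypic_variance(p: FounderFrequencies, effects: LocusEffects) -> float:
    """Total genotypic variance (additive + dominance) at HWE."""
    return hwe_additive_variance(p, effects) + hwe_dominance_variance(p, effects)


def scale_to_target(
    effects: LocusEffects,
    p: FounderFrequencies,
    target: float = 50.0,
) -> tuple[LocusEffects, float]:
    """Rescale effects so the HWE additive variance equals ``target``.

    Returns the scaled effects and the mean-type scale factor
    sqrt(target / sigma^2_A,init), which applies to any quantity on the
    trait scale (variance-type quantities scale by its square).
    """
    init = hwe_additive_variance(p, effects)
    if init < 1e-12:  # numerically zero: genome carries no usable variation
        raise DegenerateGenomeError("initial additive variance is zero")
    factor = float(np.sqrt(target / init))
    return effects.scaled(factor), factor


def expected_id_capacity(
    p: FounderFrequencies,
    f_per_locus: np.ndarray,
    effects: LocusEffects,
) -> float:
    """Expected inbreeding-depression capacity E(mu_D) = 2 sum (1-F) p q d.

    Assumes no epistasis, no linkage disequilibrium and no directed
    selection; ``f_per_locus`` is the locus-wise inbreeding coefficient.
    """
    _check_lengths(p, effects)
    f = np.broadcast_to(np.asarray(f_per_locus, dtype=float), (p.n_loci,))
    if np.any(f < 0.0) or np.any(f > 1.0):
        raise ValueError("locus-wise inbreeding coefficients must lie in [0, 1]")
    return float(np.sum(2.0 * (1.0 - f) * p.p * (1.0 - p.p) * effects.d))


def calibrate_environmental_variance(
    additive_variance: float,
    genotypic_variance: float,
    heritability: float,
) -> float:
    """Environmental variance giving the requested narrow-sense heritability.

    Solves h^2 = sigma^2_A / (sigma^2_G + sigma^2_E) for sigma^2_E; the
    dominance variance is part of the phenotypic denominator.
    """
    if not 0.0 < heritability <= 1.0:
        raise CalibrationError("heritability must lie in (0, 1]")
    if genotypic_variance < additive_variance:
        raise CalibrationError("genotypic variance cannot be below additive variance")
    sigma2_e = additive_variance / heritability - genotypic_variance
    if sigma2_e < -1e-9:
        raise CalibrationError(
            f"negative environmental variance ({sigma2_e:.3f}): heritability "
            f"{heritability} unattainable with sigma2_A={additive_variance}, "
            f"sigma2_G={genotypic_variance}"
        )
    return max(sigma2_e, 0.0)


def _check_lengths(p: FounderFrequencies, effects: LocusEffects) -> None:
    if p.n_loci != effects.n_loci:
        raise ValueError(
            f"frequency vector ({p.n_loci}) and effects ({effects.n_loci}) disagree"
        )
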