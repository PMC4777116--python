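# Methods

## Genetic model

The trait is governed by a finite set of `n_trait_loci` (default 100)
unlinked biallelic loci. Genotypic values use the classical a/d coding
per locus (+a favorable homozygote, d heterozygote, −a unfavorable
homozygote) summed over loci; dominance is strictly directional
(0 ≤ d ≤ a), so there is no overdominance, and no epistasis, mutation or
recombination map is modeled — loci segregate independently at meiosis.
These restrictions are deliberate: they keep the additive/dominance
decomposition analytic at the founder generation and make closed-form
checks (HWE variances, expected ID capacity) exact.

Scenario grid (3 × 3):

| axis | values | notes |
|---|---|---|
| dominance level | additive, partial (d = a/2), complete (d = a) | uniform d/a ratio per scenario |
| architecture | uniform (a = 1); major/minor (20 loci a = 5 with all dominance, 80 loci a = 1, d = 0) | dominance confined to major loci in the second |
| founder frequencies | intermediate (p = 0.5 exactly); U-shaped neutral spectrum | U-shaped: density ∝ 1/(p(1 − p)) truncated to [1/(2Ne), 1 − 1/(2Ne)], Ne = 192 |

The U-shaped form is the neutral-equilibrium spectrum; it is sampled by
inverse CDF (logit of a uniform over the truncated logit range). Its
adequacy is corroborated by the expected initial ID capacities it
induces: Monte-Carlo means of E(µD) over genome draws are 13.9 (partial)
and 25.1 (complete dominance), i.e. roughly half the intermediate-
frequency values, as expected from E(pq) under the truncated spectrum.

### Calibration

Two normalizations make scenarios comparable at generation 0:

* **Effect scaling.** All effects are multiplied by √(50 / σ²A,init),
  where σ²A,init = Σ 2pᵢqᵢαᵢ² (αᵢ = aᵢ + dᵢ(1 − 2pᵢ)) is evaluated at the
  *nominal* sampled frequencies, not at realized founder genotype counts.
  Nominal scaling keeps the intermediate-frequency surface exact
  (E(µD) = 25/50, 10.4/20.8) and independent of founder sampling noise;
  realized-frequency scaling would add ~√(2/N) relative jitter per locus
  with no compensating benefit.
* **Environmental variance.** σ²E = σ²A/h² − σ²G with h² = 0.3 and σ²G
  including the HWE dominance variance Σ(2pqd)². σ²E is calibrated once
  per replicate at the founder generation and held constant; heritability
  therefore drifts over generations as genetic variance erodes, which is
  the realistic behavior for a fixed-environment trait. σ²E is
  nonnegative for every shipped scenario (worst case, complete dominance
  intermediate: 50/0.3 − 75 ≈ 91.7).

## Populations and inbreeding

A generation is stored as a structure of arrays (genotypes as
(N, 2, loci) allele matrices), not as individual objects; all mating,
meiosis and statistics operators are vectorized over the population.
This is purely an implementation choice — the per-individual semantics
(ids, parent ids, compartment label, genotypic value, phenotype) are
retained per row.

Each founder carries a unique allele pair at each of the 100 neutral
loci, so identity-by-state at neutral loci equals identity-by-descent and
an individual's F is the fraction of neutral loci with identical labels.
With 100 neutral loci the per-individual binomial standard error of F is
≤ 0.05, and averages over populations are much tighter. Environmental
deviates are i.i.d. normal per individual; there are no common-
environment, maternal or genotype-by-environment effects.

Open pollination divides a tier's total progeny as evenly as possible
over mothers (remainder round-robin in id order — deterministic given the
seed, unbiased in expectation) and samples each progeny's father
uniformly with replacement from the selected set, excluding the mother.
Single-pair mating is a random perfect matching of the selected set.

## Breeding strategies

All seven designs share 192 founders, 9600 progeny per generation and a
~2% overall selection intensity; design counts (progeny per compartment,
selections, transfers) are built in per strategy name and overridable for
sensitivity analyses. Noteworthy resolved details:

* **Nucleus transfer direction.** The per-tier transfer counts (24 from
  the nucleus, 4 from the main tier) are read as selections *from* that
  tier's progeny sent *to* the other tier. This is the only reading under
  which both tiers' progeny-per-cross and progeny-per-mother counts are
  integers in both nucleus variants (4800/12 and 4800/192 for NUCU;
  4560/12 and 5040/168 for NUCR).
* **NUCR disjointness.** Transfers are taken first by phenotypic rank,
  parents from the remainder, so the restricted variant differs from NUCU
  only in forbidding dual use of the same individual.
* **Founder bootstrap.** The first cycle needs compartments: SUBL splits
  founders at random into four sublines of 48; SELFL starts one line per
  founder; the nucleus strategies rank founders on phenotype and seed the
  nucleus with the top 24, the main tier with the remaining 168 (the main
  tier's first-cycle progeny total is met by the round-robin allocation).
  From generation 1 the published steady-state counts apply exactly.
* **Production population.** 24 elites (top-of-population, top-6 per
  subline, best-24 line survivors, or top-24 nucleus progeny, per
  strategy) are randomly paired into 12 outcrosses × 100 progeny = 1200.
  PP size is a free choice; PP statistics are means/variances and
  insensitive to it beyond Monte-Carlo error. Selfing is excluded in PP
  crosses; SELFL elites come from distinct lines by construction, so
  SELFL PP crosses are between unrelated lines.

## Statistics

All statistics are computed from true genotypes (no REML or phenotypic
estimation). Per generation and population the runner reports gain
(mean genotypic value minus founder mean), mean F, realized µD, allele
frequencies, fixation counts and variance components.

* **Fixation** is evaluated inside each closed compartment and averaged
  over compartments (a single selfing line can be fixed while the pooled
  192 lines are not); percentages for major/minor classes use the class
  sizes (20, 80) as denominators.
* **Variance decomposition.** σ²A is the sample variance of breeding-
  value scores Σᵢ α̂ᵢ(xᵢⱼ − 2p̂ᵢ) at current frequencies; the genic
  variance is Σ 2p̂q̂α̂²(1 + F̂ᵢ) with the locus-wise heterozygote deficit
  F̂ᵢ = 1 − Hobs/(2p̂q̂) floored at −1 (the textbook genic form under
  inbreeding); their difference is the linkage-disequilibrium covariance;
  σ²D = σ²G − σ²A. The decomposition is validated internally: LD
  covariance vanishes for freshly drawn founders as N grows, and one
  selfing generation splits the additive variance into the expected
  within-line (1 − F)σ²₀ = 25 and pooled (1 + F)σ²₀ = 75 shares.
* **Literature conversion.** `id_per_sigma` divides a percentage ID
  estimate by the percentage additive genetic coefficient of variation,
  giving µD/σA on the same scale as the simulated scenarios
  (e.g. 17% height ID at CVA 10% → 1.7).

## Seeding and reproducibility

A master seed spawns per-replicate `numpy` SeedSequence children, so runs
are bit-reproducible on a platform and replicates are independent.
Replicates that raise are excluded and reported; a run aborts if more
than 1% fail. Output tables are TSV with a `#`-prefixed header recording
the full configuration.

## Problem sizes

Full reproduction uses 500 replicates per cell. The shipped test suite
and the acceptance script use 100 replicates for the 20-generation
stochastic surfaces (fixation percentages, gain orderings), 30 or fewer
for single-generation variance checks, and 6 for trajectory-shape
checks; at these sizes the replicate standard error of the fixation
percentages is ≈ 0.04 points, ample for the comparisons made. The CLI's
`--profile test|full` switch exposes the same scaled-down (50) versus
full (500) replicate counts.

## Known limitations

* No linkage, mutation, epistasis or overdominance; trait loci are
  biallelic. Purging dynamics under tight linkage (e.g. pseudo-
  overdominance) are outside the model.
* Selection is strictly phenotypic mass / within-family truncation;
  no BLUP, optimum-contribution selection or minimum-coancestry mating.
* Generations are discrete and non-overlapping; no rolling-front
  logistics, sex structure beyond mother/father bookkeeping, or
  fecundity/viability selection.
* Generation-20 production-population gains of the three best-performing
  designs (single-population mass selection, sublines, nucleus) differ by
  only fractions of a trait unit and are sensitive to details of elite
  pairing; their fine ordering should not be over-interpreted.
* The synthetic founder population is idealized (unrelated, exact HWE,
  frequency spectra as specified); conclusions transfer to real base
  populations only insofar as those assumptions hold. Passing tests
  certify internal consistency and reproduction of the simulated result
  surface, not field performance of any strategy.
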